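"""Repeat-family expression profiling.

For each repeat family (e.g. the LINE families L1 and L2) this module
computes per-sample read counts normalised to the total of mapped reads,
condition fold changes (merged and per biological replicate),
antisense/sense ratios measured against the repeat's own annotated strand,
and the strand concordance of intron-hosted repeats with their hosting
gene.  A "Tot" row aggregates all families.
"""

from __future__ import annotations

from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import RegionClass, RepeatOverlay
from .assignment import RegionCounts
from .landscape import DEFAULT_ALPHA, ProportionTestResult, proportion_comparison

TOTAL_ROW = "Tot"

Design = Mapping[str, Tuple[str, str]]  # sample_id -> (condition, replicate)


def _families(counts_by_sample: Mapping[str, RegionCounts], families: Optional[Sequence[str]]) -> List[str]:
    if families is not None:
        return list(families)
    seen = set()
    for rc in counts_by_sample.values():
        seen.update(f for (f, _h, _o) in rc.repeat_counts)
    return sorted(seen)


def family_profile(
    counts_by_sample: Mapping[str, RegionCounts],
    design: Design,
    families: Optional[Sequence[str]] = None,
    host_class: Optional[str] = None,
    conditions: Tuple[str, str] = ("T1", "T2"),
) -> pd.DataFrame:
    """Per-family expression table: normalised abundance, fold changes, ratios.

    ``host_class`` restricts counting to repeats hosted in one primary class
    (e.g. ``"INTRON"`` for an intronic-repeat table); ``None`` counts all.
    Fold changes divide the second condition's normalised abundance by the
    first's, pooled over replicates ("merged") and within each replicate.
    Families with no reads get zero counts and NaN ratios.
    """
    for sid, rc in counts_by_sample.items():
        if rc.total_retained <= 0:
            raise ValueError(f"sample {sid} has zero total mapped reads")
    fams = _families(counts_by_sample, families)
    c1, c2 = conditions
    samples = sorted(counts_by_sample)
    by_cond: Dict[str, List[str]] = {c1: [], c2: []}
    for sid in samples:
        cond, _rep = design[sid]
        by_cond[cond].append(sid)

    rows = []
    for fam in fams + [TOTAL_ROW]:
        def fam_count(rc: RegionCounts, orientation: Optional[str] = None) -> int:
            names = fams if fam == TOTAL_ROW else [fam]
            if orientation is None:
                return sum(rc.family_total(f, host_class) for f in names)
            return sum(rc.family_orientation(f, orientation, host_class) for f in names)

        row: Dict[str, object] = {"family": fam}
        norm: Dict[str, float] = {}
        for sid in samples:
            rc = counts_by_sample[sid]
            n = fam_count(rc)
            row[f"count_{sid}"] = n
            norm[sid] = n / rc.total_retained
            row[f"norm_{sid}"] = norm[sid]
            sense = fam_count(rc, "sense")
            anti = fam_count(rc, "antisense")
            row[f"as_ratio_{sid}"] = anti / sense if sense else float("nan")
        # pooled per condition
        for cond in conditions:
            tot = sum(counts_by_sample[s].total_retained for s in by_cond[cond])
            n = sum(fam_count(counts_by_sample[s]) for s in by_cond[cond])
            sense = sum(fam_count(counts_by_sample[s], "sense") for s in by_cond[cond])
            anti = sum(fam_count(counts_by_sample[s], "antisense") for s in by_cond[cond])
            row[f"norm_{cond}"] = n / tot if tot else float("nan")
            row[f"as_ratio_{cond}"] = anti / sense if sense else float("nan")
        n1, n2 = row[f"norm_{c1}"], row[f"norm_{c2}"]
        row[f"fc_{c2}/{c1}"] = (n2 / n1) if n1 else float("nan")
        # per-replicate fold changes (replicate label pairs samples across conditions)
        reps = sorted({rep for (_c, rep) in design.values()})
        for rep in reps:
            s1 = [s for s in by_cond[c1] if design[s][1] == rep]
            s2 = [s for s in by_cond[c2] if design[s][1] == rep]
            if len(s1) == 1 and len(s2) == 1:
                a, b = norm[s1[0]], norm[s2[0]]
                row[f"fc_{rep}2/{rep}1"] = b / a if a else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("family")


def intron_concordance(overlay: RepeatOverlay) -> pd.DataFrame:
    """Strand concordance of intron-hosted repeats with their hosting gene.

    A repeat is concordant when its annotated strand equals the strand of
    the gene owning the hosting intron.  Fractions are over intron-hosted
    repeats only; empty families report NaN fractions with zero counts.
    """
    fams = overlay.families
    rows = []
    for fam in fams + [TOTAL_ROW]:
        entries = [
            r
            for r in overlay.entries
            if r.host_class == RegionClass.INTRON
            and (fam == TOTAL_ROW or r.family == fam)
            and r.host_strand in "+-"
        ]
        n = len(entries)
        conc = sum(1 for r in entries if r.strand == r.host_strand)
        rows.append(
            {
                "family": fam,
                "n_intronic": n,
                "concordant": conc,
                "opposite": n - conc,
                "frac_concordant": conc / n if n else float("nan"),
                "frac_opposite": (n - conc) / n if n else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("family")


def family_proportion_test(
    counts_by_sample: Mapping[str, RegionCounts],
    design: Design,
    families: Optional[Sequence[str]] = None,
    alpha: float = DEFAULT_ALPHA,
    host_class: Optional[str] = None,
    conditions: Tuple[str, str] = ("T1", "T2"),
) -> Dict[str, ProportionTestResult]:
    """Replicate-concordant proportion test of family counts vs total reads."""
    fams = _families(counts_by_sample, families)
    results: Dict[str, ProportionTestResult] = {}
    for fam in fams + [TOTAL_ROW]:
        names = fams if fam == TOTAL_ROW else [fam]
        xn = {}
        for sid, rc in counts_by_sample.items():
            cond, rep = design[sid]
            x = sum(rc.family_total(f, host_class) for f in names)
            xn[(cond, rep)] = (x, rc.total_retained)
        results[fam] = proportion_comparison(xn, alpha=alpha, conditions=conditions, region=fam)
    return results
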