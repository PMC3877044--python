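"""Read-distribution statistics and two-condition proportion testing.

Per sample, four statistics summarise how reads fall over the partition:
the fraction of retained reads per class, the expression density
(reads x read length / class length), the fraction of class bases covered
by at least one read, and the antisense/sense ratio.  Between two
conditions with biological replicates, class proportions are compared with
a two-proportion chi-square test with continuity correction, run
independently per replicate; a difference is called significant only when
both replicates agree (p < alpha in each), and the reported p-value is the
larger of the two — a deliberately conservative compound rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import REPEAT_LABEL, PartitionIndex, RegionClass, STRANDED_CLASSES
from .assignment import CoverageTracker, RegionCounts

DEFAULT_ALPHA = 0.05
DEFAULT_READ_LENGTH = 50
DEFAULT_LOG_OFFSET = 1.0

#: Region labels profiled per sample: the primary classes plus the repeat overlay.
PROFILE_LABELS = [c.name for c in RegionClass if c != RegionClass.RRNA] + [REPEAT_LABEL]


@dataclass
class DistributionProfile:
    sample_id: str
    fraction: Dict[str, float]
    density: Dict[str, float]
    covered_fraction: Dict[str, float]
    as_ratio: Dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (
                self.sample_id,
                label,
                self.fraction.get(label, 0.0),
                self.density.get(label, float("nan")),
                self.covered_fraction.get(label, float("nan")),
                self.as_ratio.get(label, float("nan")),
            )
            for label in PROFILE_LABELS
        ]
        return pd.DataFrame(
            rows,
            columns=["sample", "region", "fraction", "density", "covered_fraction", "as_ratio"],
        )


@dataclass
class ProportionTestResult:
    region: str
    fractions: Dict[str, float]  # per (condition, replicate) and pooled per condition
    p_per_replicate: Dict[str, float]
    p_reported: float
    significant: bool
    fold_change_per_replicate: Dict[str, float]
    fold_change_merged: float
    fold_change_mean: float


def two_proportion_test(x1: int, n1: int, x2: int, n2: int) -> Tuple[float, float]:
    """Two-sided test of equal proportions (chi-square, Yates correction).

    Returns (statistic, p).  Degenerate tables where one margin is empty
    (both counts 0, or both complements 0) carry no evidence and return
    (0, 1).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("totals must be positive")
    if x1 < 0 or x2 < 0 or x1 > n1 or x2 > n2:
        raise ValueError("counts must satisfy 0 <= x <= n")
    if (x1 + x2 == 0) or ((n1 - x1) + (n2 - x2) == 0):
        return 0.0, 1.0
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    stat, p, _dof, _exp = stats.chi2_contingency(table, correction=True)
    return float(stat), float(p)


def profile_sample(
    counts: RegionCounts,
    index: PartitionIndex,
    coverage: Optional[CoverageTracker] = None,
    read_length: int = DEFAULT_READ_LENGTH,
) -> DistributionProfile:
    """Compute the four per-sample distribution statistics.

    Density divides by the total class length (not the covered length).
    Classes with zero sense reads report the antisense/sense ratio as NaN
    rather than infinity; for intergenic reads, which have no feature
    strand, the ratio is minus/plus.
    """
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    lengths = {c.name: index.class_lengths[c] for c in RegionClass}
    lengths[REPEAT_LABEL] = index.repeats.merged_length() if index.repeats else 0
    total = counts.total_retained
    covered = coverage.covered_by_class(index) if coverage is not None else {}

    fraction: Dict[str, float] = {}
    density: Dict[str, float] = {}
    covered_fraction: Dict[str, float] = {}
    as_ratio: Dict[str, float] = {}
    for label in PROFILE_LABELS:
        n = counts.class_total(label)
        fraction[label] = n / total if total else 0.0
        length = lengths.get(label, 0)
        density[label] = (n * read_length / length) if length else float("nan")
        if coverage is not None and length:
            covered_fraction[label] = covered.get(label, 0) / length
        else:
            covered_fraction[label] = float("nan")
        if label == RegionClass.INTERGENIC.name:
            plus = counts.orientation_total(label, "plus")
            minus = counts.orientation_total(label, "minus")
            as_ratio[label] = minus / plus if plus else float("nan")
        else:
            sense = counts.orientation_total(label, "sense")
            anti = counts.orientation_total(label, "antisense")
            as_ratio[label] = anti / sense if sense else float("nan")
    return DistributionProfile(counts.sample_id, fraction, density, covered_fraction, as_ratio)


def proportion_comparison(
    xn: Mapping[Tuple[str, str], Tuple[int, int]],
    alpha: float = DEFAULT_ALPHA,
    conditions: Tuple[str, str] = ("T1", "T2"),
    region: str = "",
) -> ProportionTestResult:
    """Replicate-concordant comparison of one proportion between conditions.

    ``xn`` maps (condition, replicate) to (count, total).  The test runs
    independently within each replicate pairing; significance requires
    p < alpha in every replicate, and the reported p is the maximum.
    """
    c1, c2 = conditions
    reps = sorted({rep for (_c, rep) in xn})
    if not reps:
        raise ValueError("no replicates provided")
    for c in conditions:
        for rep in reps:
            if (c, rep) not in xn:
                raise ValueError(f"missing counts for condition {c} replicate {rep}")
            if xn[(c, rep)][1] <= 0:
                raise ValueError(f"zero total for condition {c} replicate {rep}")
    fractions: Dict[str, float] = {}
    p_per_rep: Dict[str, float] = {}
    fc_per_rep: Dict[str, float] = {}
    for rep in reps:
        x1, n1 = xn[(c1, rep)]
        x2, n2 = xn[(c2, rep)]
        f1, f2 = x1 / n1, x2 / n2
        fractions[f"{c1}_{rep}"] = f1
        fractions[f"{c2}_{rep}"] = f2
        _stat, p = two_proportion_test(x1, n1, x2, n2)
        p_per_rep[rep] = p
        fc_per_rep[rep] = f2 / f1 if f1 > 0 else float("nan")
    x1p = sum(xn[(c1, r)][0] for r in reps)
    n1p = sum(xn[(c1, r)][1] for r in reps)
    x2p = sum(xn[(c2, r)][0] for r in reps)
    n2p = sum(xn[(c2, r)][1] for r in reps)
    f1p, f2p = x1p / n1p, x2p / n2p
    fractions[f"{c1}_pooled"] = f1p
    fractions[f"{c2}_pooled"] = f2p
    p_reported = max(p_per_rep.values())
    significant = all(p < alpha for p in p_per_rep.values())
    finite_fc = [v for v in fc_per_rep.values() if math.isfinite(v)]
    return ProportionTestResult(
        region=region,
        fractions=fractions,
        p_per_replicate=p_per_rep,
        p_reported=p_reported,
        significant=significant,
        fold_change_per_replicate=fc_per_rep,
        fold_change_merged=f2p / f1p if f1p > 0 else float("nan"),
        fold_change_mean=float(np.mean(finite_fc)) if finite_fc else float("nan"),
    )


def compare_conditions(
    counts: Mapping[Tuple[str, str], RegionCounts],
    region: str,
    alpha: float = DEFAULT_ALPHA,
    conditions: Tuple[str, str] = ("T1", "T2"),
) -> ProportionTestResult:
    """Compare one region's read fraction between two conditions.

    ``counts`` maps (condition, replicate) to that sample's tallies; the
    tested proportion is the region's read count over the sample's total
    retained reads.
    """
    xn = {
        key: (rc.class_total(region), rc.total_retained) for key, rc in counts.items()
    }
    return proportion_comparison(xn, alpha=alpha, conditions=conditions, region=region)


def comparison_table(
    counts: Mapping[Tuple[str, str], RegionCounts],
    alpha: float = DEFAULT_ALPHA,
    conditions: Tuple[str, str] = ("T1", "T2"),
    regions: Sequence[str] = tuple(PROFILE_LABELS),
) -> pd.DataFrame:
    rows = []
    for region in regions:
        res = compare_conditions(counts, region, alpha=alpha, conditions=conditions)
        row: Dict[str, object] = {"region": region}
        row.update({f"frac_{k}": v for k, v in res.fractions.items()})
        row.update({f"p_{r}": p for r, p in res.p_per_replicate.items()})
        row["p_reported"] = res.p_reported
        row["significant"] = res.significant
        row.update({f"fc_{r}": v for r, v in res.fold_change_per_replicate.items()})
        row["fc_merged"] = res.fold_change_merged
        rows.append(row)
    return pd.DataFrame(rows)


def replicate_correlation(
    counts_matrix: pd.DataFrame, log_offset: float = DEFAULT_LOG_OFFSET
) -> pd.DataFrame:
    """Pairwise Pearson correlation of log-transformed counts.

    Rows are transcripts/genes, columns samples.  A constant column yields
    NaN for its pairs (undefined correlation) rather than an error.
    """
    if counts_matrix.shape[1] < 2:
        raise ValueError("need at least two samples")
    logged = np.log(counts_matrix.astype(float) + log_offset)
    return logged.corr(method="pearson")
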