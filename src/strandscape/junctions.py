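"""Splice-junction discovery, filtering, confirmation and classification.

A gapped alignment with k+1 blocks yields k junction observations, each
keyed by (chrom, donor, acceptor) where the donor is the end coordinate of
the upstream block and the acceptor the start of the downstream block
(half-open, so the junction of blocks [100,130) and [200,220) is
(130, 200)).  A junction is accepted within a condition when at least
``min_reads`` supporting reads with distinct alignment starts each span it
by at least ``min_overhang`` aligned bases on both sides, pooling the
condition's replicates.  Accepted junctions are confirmed against the
collapsed annotation (exact donor and acceptor match of the same gene's
intron) and classified by the region classes flanking the two splice
sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .annotation import CollapsedGene, PartitionIndex, RegionClass

JunctionKey = Tuple[str, int, int]  # chrom, donor, acceptor

DEFAULT_MIN_READS = 2
DEFAULT_MIN_OVERHANG = 15

#: Canonical side-label order used to collapse A_B / B_A into one category.
CANONICAL_ORDER = ["3UTR", "5UTR", "CDS", "Intergenic", "Intron", "Repeat"]
_SIDE_LABEL = {
    RegionClass.UTR3: "3UTR",
    RegionClass.UTR5: "5UTR",
    RegionClass.CDS: "CDS",
    RegionClass.INTRON: "Intron",
}


@dataclass(frozen=True)
class JunctionObservation:
    read_id: str
    alignment_start: int
    left_overhang: int
    right_overhang: int


def extract_junctions(reads: Iterable) -> Dict[JunctionKey, List[JunctionObservation]]:
    """Collect every block gap of every spliced read with its overhangs.

    The overhang on each side is the length of the block immediately
    flanking the gap — the contiguous aligned stretch across the junction.
    """
    raw: Dict[JunctionKey, List[JunctionObservation]] = {}
    for read in reads:
        blocks = read.blocks
        for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
            key = (read.chrom, e1, s2)
            raw.setdefault(key, []).append(
                JunctionObservation(read.read_id, read.start, e1 - s1, e2 - s2)
            )
    return raw


def filter_junctions(
    raw: Mapping[JunctionKey, Sequence[JunctionObservation]],
    min_reads: int = DEFAULT_MIN_READS,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
) -> Set[JunctionKey]:
    """Junctions with >= min_reads independent eligible observations.

    An observation is eligible when both overhangs reach ``min_overhang``;
    independence means distinct alignment start coordinates, which guards
    against amplification duplicates counting twice.
    """
    accepted: Set[JunctionKey] = set()
    for key, obs in raw.items():
        starts = {
            o.alignment_start
            for o in obs
            if min(o.left_overhang, o.right_overhang) >= min_overhang
        }
        if len(starts) >= min_reads:
            accepted.add(key)
    return accepted


def pool_observations(
    per_sample: Mapping[str, Mapping[JunctionKey, Sequence[JunctionObservation]]],
    design: Mapping[str, Tuple[str, str]],
) -> Dict[str, Dict[JunctionKey, List[JunctionObservation]]]:
    """Pool each condition's replicate observations (evidence is per condition)."""
    pooled: Dict[str, Dict[JunctionKey, List[JunctionObservation]]] = {}
    for sample, raw in per_sample.items():
        cond = design[sample][0]
        bucket = pooled.setdefault(cond, {})
        for key, obs in raw.items():
            bucket.setdefault(key, []).extend(obs)
    return pooled


def annotated_junctions(genes: Iterable[CollapsedGene]) -> Dict[JunctionKey, str]:
    """All intron (donor, acceptor) pairs of the collapsed models."""
    out: Dict[JunctionKey, str] = {}
    for g in genes:
        for s, e in g.introns:
            out[(g.chrom, s, e)] = g.gene_id
    return out


def match_known(
    junctions: Iterable[JunctionKey], genes: Sequence[CollapsedGene]
) -> Tuple[Dict[JunctionKey, str], float]:
    """Label each junction known/novel; report annotated-junction confirmation.

    Known means both the donor and the acceptor coincide exactly with the
    boundaries of one annotated intron of the same gene.  The second return
    value is the fraction of all annotated junctions confirmed by the input
    set (NaN when the annotation has no junctions).
    """
    known = annotated_junctions(genes)
    status = {key: ("known" if key in known else "novel") for key in junctions}
    if known:
        confirmed = sum(1 for key in known if status.get(key) == "known")
        frac = confirmed / len(known)
    else:
        frac = float("nan")
    return status, frac


def _side_label(index: PartitionIndex, chrom: str, pos: int) -> str:
    if index.repeats is not None and index.repeats.overlapping(chrom, pos, pos + 1):
        return "Repeat"
    cls, _gene, _strand = index.lookup(chrom, pos)
    return _SIDE_LABEL.get(cls, "Intergenic")


def classify_junction(key: JunctionKey, index: PartitionIndex) -> str:
    """Region-pair category from the two flanking aligned bases.

    The donor side is read at base donor-1 (last aligned base of the
    upstream block) and the acceptor side at the acceptor base itself.  A
    base inside an annotated repeat labels its side "Repeat"; flank and
    rRNA classes fold into "Intergenic", giving the six canonical side
    labels.  The pair is sorted canonically so e.g. Intron_CDS and
    CDS_Intron are one category.
    """
    chrom, donor, acceptor = key
    a = _side_label(index, chrom, donor - 1)
    b = _side_label(index, chrom, acceptor)
    a, b = sorted((a, b), key=CANONICAL_ORDER.index)
    return f"{a}_{b}"


@dataclass
class VennResult:
    shared: Set[JunctionKey]
    exclusive: Dict[str, Set[JunctionKey]]  # condition -> exclusive set

    def counts(self) -> Dict[str, int]:
        out = {"shared": len(self.shared)}
        out.update({f"{c}_exclusive": len(s) for c, s in sorted(self.exclusive.items())})
        return out


def venn_partition(accepted: Mapping[str, Set[JunctionKey]]) -> VennResult:
    """Set algebra on per-condition accepted junction keys."""
    conds = sorted(accepted)
    if len(conds) != 2:
        raise ValueError("venn partition requires exactly two conditions")
    a, b = (accepted[c] for c in conds)
    return VennResult(shared=a & b, exclusive={conds[0]: a - b, conds[1]: b - a})


def category_percentages(
    keys: Iterable[JunctionKey], index: PartitionIndex
) -> pd.Series:
    """Percentage distribution of junctions over region-pair categories."""
    cats = [classify_junction(k, index) for k in keys]
    if not cats:
        return pd.Series(dtype=float)
    counts = pd.Series(cats).value_counts().sort_index()
    return 100.0 * counts / counts.sum()


def junction_table(
    pooled: Mapping[str, Mapping[JunctionKey, Sequence[JunctionObservation]]],
    accepted: Mapping[str, Set[JunctionKey]],
    genes: Sequence[CollapsedGene],
    index: PartitionIndex,
) -> pd.DataFrame:
    """Tabulate all accepted junctions with support, status and category."""
    conds = sorted(accepted)
    all_keys = sorted(set().union(*accepted.values())) if accepted else []
    status, _frac = match_known(all_keys, genes)
    rows = []
    for key in all_keys:
        chrom, donor, acceptor = key
        row: Dict[str, object] = {
            "chrom": chrom,
            "donor": donor,
            "acceptor": acceptor,
            "status": status[key],
            "region_pair": classify_junction(key, index),
        }
        for c in conds:
            obs = pooled.get(c, {}).get(key, [])
            row[f"support_{c}"] = len({o.alignment_start for o in obs})
            row[f"accepted_{c}"] = key in accepted[c]
        rows.append(row)
    return pd.DataFrame(rows)
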