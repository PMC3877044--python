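"""Read filtering and region assignment.

Uniquely mapped, non-ribosomal reads are each assigned to exactly one
region: the primary class covering the majority of their aligned bases, or
the repeat overlay when most bases fall inside an annotated repeat.  A read
is counted once, never fractionally.  Orientation is sense/antisense
relative to the owning feature's strand (the repeat's own strand for
overlay hits), and raw plus/minus for intergenic reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .annotation import (
    REPEAT_LABEL,
    PartitionIndex,
    RegionClass,
    RepeatEntry,
)
from .intervals import Interval

DEFAULT_MAPQ_MIN = 10


@dataclass
class AlignedRead:
    """A single-end alignment reduced to its aligned blocks.

    ``blocks`` are sorted, non-overlapping half-open intervals; more than
    one block means the read is spliced.  ``nh`` is the reported number of
    genomic hits when available (NH tag); otherwise uniqueness falls back to
    a MAPQ threshold.
    """

    read_id: str
    chrom: str
    blocks: List[Interval]
    strand: str
    nh: Optional[int] = None
    mapq: int = 255

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"read {self.read_id}: strand must be + or -")
        for (s1, e1), (s2, e2) in zip(self.blocks, self.blocks[1:]):
            if s2 < e1:
                raise ValueError(f"read {self.read_id}: blocks overlap or unsorted")

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def spliced(self) -> bool:
        return len(self.blocks) > 1


@dataclass
class RegionAssignment:
    read_id: str
    region: str  # RegionClass name or REPEAT_LABEL
    gene_id: Optional[str]
    orientation: str  # sense/antisense, or plus/minus for intergenic
    family: Optional[str] = None  # repeat family when region == REPEAT
    host_class: Optional[str] = None  # repeat host class when region == REPEAT


@dataclass
class FilterTallies:
    input_alignments: int = 0
    retained: int = 0
    nonunique_removed: int = 0
    rrna_removed: int = 0
    unmapped: int = 0
    secondary: int = 0

    def as_dict(self) -> Dict[str, int]:
        return dict(self.__dict__)


@dataclass
class RegionCounts:
    """Per-sample read tallies by region class / repeat family and orientation."""

    sample_id: str
    counts: Dict[Tuple[str, str], int] = field(default_factory=dict)
    repeat_counts: Dict[Tuple[str, str, str], int] = field(default_factory=dict)
    total_retained: int = 0
    rrna_removed: int = 0
    nonunique_removed: int = 0

    def add(self, a: RegionAssignment) -> None:
        if a.region == REPEAT_LABEL:
            key = (a.family or "", a.host_class or "", a.orientation)
            self.repeat_counts[key] = self.repeat_counts.get(key, 0) + 1
        key2 = (a.region, a.orientation)
        self.counts[key2] = self.counts.get(key2, 0) + 1
        self.total_retained += 1

    def class_total(self, region: str) -> int:
        return sum(v for (r, _o), v in self.counts.items() if r == region)

    def family_total(self, family: str, host_class: Optional[str] = None) -> int:
        return sum(
            v
            for (f, h, _o), v in self.repeat_counts.items()
            if f == family and (host_class is None or h == host_class)
        )

    def family_orientation(self, family: str, orientation: str, host_class: Optional[str] = None) -> int:
        return sum(
            v
            for (f, h, o), v in self.repeat_counts.items()
            if f == family and o == orientation and (host_class is None or h == host_class)
        )

    def orientation_total(self, region: str, orientation: str) -> int:
        return self.counts.get((region, orientation), 0)

    def check_conservation(self) -> bool:
        return sum(self.counts.values()) == self.total_retained

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (region, orient), n in sorted(self.counts.items()):
            if region == REPEAT_LABEL:
                continue
            rows.append((self.sample_id, region, "", "", orient, n))
        for (fam, host, orient), n in sorted(self.repeat_counts.items()):
            rows.append((self.sample_id, REPEAT_LABEL, fam, host, orient, n))
        return pd.DataFrame(
            rows, columns=["sample", "region", "family", "host_class", "orientation", "count"]
        )


# ---------------------------------------------------------------------------
# alignment sources

def iter_sam(path: str) -> Iterator[AlignedRead]:
    """Stream primary records from a SAM/BAM file as :class:`AlignedRead`.

    Adjacent CIGAR match blocks separated only by indels are merged, so
    block gaps always correspond to skipped reference (N) regions, i.e.
    splice junctions.  Unmapped/secondary/supplementary records are yielded
    as ``None`` markers via the companion filter; here they are skipped by
    the caller using pysam flags.
    """
    import pysam

    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for rec in fh:
            yield rec


def _sam_to_read(rec) -> Optional[AlignedRead]:
    blocks: List[Interval] = []
    pos = rec.reference_start
    for op, length in rec.cigartuples or []:
        if op in (0, 7, 8):  # M, =, X consume both
            if blocks and blocks[-1][1] == pos:
                blocks[-1] = (blocks[-1][0], pos + length)
            else:
                blocks.append((pos, pos + length))
            pos += length
        elif op in (2,):  # D consumes reference but stays within an exon block
            if blocks and blocks[-1][1] == pos:
                blocks[-1] = (blocks[-1][0], pos + length)
            else:
                blocks.append((pos, pos + length))
            pos += length
        elif op == 3:  # N: splice gap
            pos += length
    if not blocks:
        return None
    nh = rec.get_tag("NH") if rec.has_tag("NH") else None
    return AlignedRead(
        read_id=rec.query_name,
        chrom=rec.reference_name,
        blocks=blocks,
        strand="-" if rec.is_reverse else "+",
        nh=nh,
        mapq=rec.mapping_quality,
    )


def read_alignment_tsv(path: str) -> List[AlignedRead]:
    """Plain fixture format: read_id, chrom, strand, blocks, [nh], [mapq].

    ``blocks`` is comma-separated ``start-end`` pairs in 0-based half-open
    coordinates.
    """
    reads = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            rid, chrom, strand, blocks_s = parts[:4]
            nh = int(parts[4]) if len(parts) > 4 and parts[4] != "" else None
            mapq = int(parts[5]) if len(parts) > 5 else 255
            blocks = []
            for b in blocks_s.split(","):
                s, e = b.split("-")
                blocks.append((int(s), int(e)))
            reads.append(AlignedRead(rid, chrom, blocks, strand, nh, mapq))
    return reads


# ---------------------------------------------------------------------------
# assignment core

def _base_tallies(read: AlignedRead, index: PartitionIndex):
    """Per-class and per-(class,gene,strand) base counts over the block union."""
    by_class: Dict[RegionClass, int] = {}
    by_feature: Dict[Tuple[RegionClass, Optional[str], str], int] = {}
    for bs, be in read.blocks:
        for s, e, cls, gid, strand in index.segments(read.chrom, bs, be):
            n = e - s
            by_class[cls] = by_class.get(cls, 0) + n
            key = (cls, gid, strand)
            by_feature[key] = by_feature.get(key, 0) + n
    return by_class, by_feature


def majority_primary_class(read: AlignedRead, index: PartitionIndex) -> RegionClass:
    by_class, _ = _base_tallies(read, index)
    return min(by_class, key=lambda c: (-by_class[c], int(c)))


def assign_read(read: AlignedRead, index: PartitionIndex) -> RegionAssignment:
    """Assign one retained read to a region class or repeat-overlay hit.

    The repeat overlay is checked first: when the majority of aligned bases
    (strictly more than half) fall inside annotated repeats, the read is a
    REPEAT hit attributed to the single repeat with the most overlapping
    bases.  Otherwise the majority primary class wins, with ties broken by
    partition precedence.
    """
    if read.chrom not in index.chrom_sizes:
        raise KeyError(f"read {read.read_id}: chromosome {read.chrom!r} not in index")
    total = read.aligned_length
    overlay = index.repeats
    if overlay is not None:
        per_repeat: Dict[int, int] = {}
        repeat_bases = 0
        entries: Dict[int, RepeatEntry] = {}
        for bs, be in read.blocks:
            for entry, ov in overlay.overlap_bases(read.chrom, bs, be):
                key = id(entry)
                per_repeat[key] = per_repeat.get(key, 0) + ov
                entries[key] = entry
        if per_repeat:
            # bases under distinct repeats may overlap only if repeats do;
            # planted annotations keep repeats disjoint, so a plain sum is exact
            repeat_bases = sum(per_repeat.values())
            if 2 * repeat_bases > total:
                best = min(
                    entries.values(),
                    key=lambda r: (-per_repeat[id(r)], r.start, r.family),
                )
                orientation = "sense" if read.strand == best.strand else "antisense"
                return RegionAssignment(
                    read.read_id,
                    REPEAT_LABEL,
                    best.host_gene,
                    orientation,
                    family=best.family,
                    host_class=best.host_class.name if best.host_class else None,
                )
    by_class, by_feature = _base_tallies(read, index)
    cls = min(by_class, key=lambda c: (-by_class[c], int(c)))
    feats = {k: v for k, v in by_feature.items() if k[0] == cls}
    _, gene_id, fstrand = min(feats, key=lambda k: (-feats[k], k[1] or ""))
    if cls == RegionClass.INTERGENIC:
        orientation = "plus" if read.strand == "+" else "minus"
    else:
        orientation = "sense" if read.strand == fstrand else "antisense"
    return RegionAssignment(read.read_id, cls.name, gene_id, orientation)


def filter_reads(
    source: Union[str, Iterable[AlignedRead]],
    index: PartitionIndex,
    mapq_min: int = DEFAULT_MAPQ_MIN,
) -> Tuple[List[AlignedRead], FilterTallies]:
    """Keep uniquely mapped non-rRNA reads; tally every drop reason.

    Uniqueness means a primary alignment with NH tag equal to 1, or MAPQ at
    least ``mapq_min`` when no NH tag is present.  rRNA removal uses the
    same majority-base rule as assignment.
    """
    tallies = FilterTallies()
    retained: List[AlignedRead] = []

    def handle(read: AlignedRead) -> None:
        tallies.input_alignments += 1
        unique = read.nh == 1 if read.nh is not None else read.mapq >= mapq_min
        if not unique:
            tallies.nonunique_removed += 1
            return
        if majority_primary_class(read, index) == RegionClass.RRNA:
            tallies.rrna_removed += 1
            return
        tallies.retained += 1
        retained.append(read)

    if isinstance(source, str):
        for rec in iter_sam(source):
            if rec.is_unmapped:
                tallies.unmapped += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                tallies.secondary += 1
                continue
            read = _sam_to_read(rec)
            if read is not None:
                handle(read)
    else:
        for read in source:
            handle(read)
    return retained, tallies


def count_by_region(
    assignments: Iterable[RegionAssignment],
    sample_id: str,
    tallies: Optional[FilterTallies] = None,
) -> RegionCounts:
    """Exhaustively tally one sample's assignments (order-invariant)."""
    rc = RegionCounts(sample_id=sample_id)
    for a in assignments:
        rc.add(a)
    if tallies is not None:
        rc.rrna_removed = tallies.rrna_removed
        rc.nonunique_removed = tallies.nonunique_removed
    return rc


class CoverageTracker:
    """Per-chromosome base coverage bitmaps for covered-fraction statistics."""

    def __init__(self, chrom_sizes: Dict[str, int]):
        self._cov = {c: np.zeros(n, dtype=bool) for c, n in chrom_sizes.items()}

    def add(self, read: AlignedRead) -> None:
        cov = self._cov[read.chrom]
        for s, e in read.blocks:
            cov[s:e] = True

    def covered_in(self, chrom: str, start: int, end: int) -> int:
        return int(self._cov[chrom][start:end].sum())

    def covered_by_class(self, index: PartitionIndex) -> Dict[str, int]:
        out: Dict[str, int] = {c.name: 0 for c in RegionClass}
        for chrom, size in index.chrom_sizes.items():
            for s, e, cls, _g, _st in index.segments(chrom, 0, size):
                out[cls.name] += self.covered_in(chrom, s, e)
        if index.repeats is not None:
            rep = 0
            for chrom, ivs in index.repeats.intervals_by_chrom().items():
                for s, e in ivs:
                    rep += self.covered_in(chrom, s, e)
            out[REPEAT_LABEL] = rep
        return out
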