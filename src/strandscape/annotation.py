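"""Gene/repeat annotation parsing and strand-aware genome partitioning.

The genome is split into eight mutually exclusive *primary* region classes
(rRNA, CDS, 5'UTR, 3'UTR, intron, 1-kb upstream/downstream flanks,
intergenic).  Where candidate regions overlap, the class earlier in
:class:`RegionClass` wins, so coding annotation is never diluted by a
neighbouring gene's flank or intron.  Repetitive elements form an *overlay*
on top of the primary partition: they never puncture it, and each repeat is
tagged with the primary class hosting the majority of its bases.

Coordinates are 0-based half-open internally; GTF I/O converts from the
1-based inclusive convention at the boundary.
"""

from __future__ import annotations

import enum
import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import intervals as ivl
from .intervals import Interval

DEFAULT_RRNA_BIOTYPES = frozenset({"rRNA", "rrna", "Mt_rRNA", "rRNA_pseudogene"})
DEFAULT_FLANK = 1000


class RegionClass(enum.IntEnum):
    """Primary region classes, in overlap-precedence order (low value wins)."""

    RRNA = 0
    CDS = 1
    UTR5 = 2
    UTR3 = 3
    INTRON = 4
    UP1K = 5
    DOWN1K = 6
    INTERGENIC = 7


#: Classes that carry a gene strand (sense/antisense is defined for them).
STRANDED_CLASSES = frozenset(
    {RegionClass.RRNA, RegionClass.CDS, RegionClass.UTR5, RegionClass.UTR3,
     RegionClass.INTRON, RegionClass.UP1K, RegionClass.DOWN1K}
)

#: Label used for the repeat overlay in tallies and reports (not a primary class).
REPEAT_LABEL = "REPEAT"


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in "+-.":
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class CollapsedGene:
    """All isoforms of a gene merged into a single exon-union model."""

    gene_id: str
    chrom: str
    strand: str
    exonic: List[Interval]
    cds: List[Interval]
    utr5: List[Interval]
    utr3: List[Interval]
    introns: List[Interval]
    span: Interval

    @property
    def junctions(self) -> List[Tuple[int, int]]:
        """Annotated splice junctions: (intron start, intron end) pairs."""
        return [(s, e) for s, e in self.introns]


def collapse_gene(
    gene_id: str,
    chrom: str,
    strand: str,
    exons: Iterable[Interval],
    cds: Iterable[Interval] = (),
) -> CollapsedGene:
    """Merge isoform exons/CDS into one collapsed model and infer UTRs.

    Exonic bases outside the CDS are called 5'UTR when 5' of the CDS span
    and 3'UTR otherwise (relative to gene strand).  A gene with no CDS has
    all exonic bases reported as 3'UTR-like non-coding exon sequence.
    Idempotent: collapsing an already collapsed model is a no-op.
    """
    exonic = ivl.normalize(exons)
    if not exonic:
        raise ValueError(f"gene {gene_id} has no exons")
    cds_u = ivl.intersect(ivl.normalize(cds), exonic)
    span = (exonic[0][0], exonic[-1][1])
    noncds = ivl.subtract(exonic, cds_u)
    if cds_u:
        cds_lo, cds_hi = cds_u[0][0], cds_u[-1][1]
        before = [(s, e) for s, e in noncds if s < cds_lo]
        after = [(s, e) for s, e in noncds if e > cds_hi]
        before = ivl.clip(before, span[0], cds_lo)
        after = ivl.clip(after, cds_hi, span[1])
        utr5, utr3 = (before, after) if strand == "+" else (after, before)
    else:
        utr5, utr3 = [], noncds
    introns = ivl.subtract([span], exonic)
    return CollapsedGene(gene_id, chrom, strand, exonic, cds_u, utr5, utr3, introns, span)


def load_gene_models(
    path: str,
    rrna_biotypes: frozenset = DEFAULT_RRNA_BIOTYPES,
) -> Tuple[List[CollapsedGene], List[GenomicInterval]]:
    """Parse a GTF/GFF file into collapsed gene models plus rRNA intervals.

    Transcript isoforms are merged per ``gene_id`` (exon union / CDS union).
    Genes whose biotype matches ``rrna_biotypes`` are emitted as rRNA
    intervals instead of gene models, so ribosomal filtering downstream is
    explicit and countable.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            path,
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # pragma: no cover - exercised via malformed input test
        raise ValueError(f"failed to parse annotation {path}: {exc}") from exc

    exons: Dict[str, List[Interval]] = {}
    cds: Dict[str, List[Interval]] = {}
    meta: Dict[str, Tuple[str, str, str]] = {}  # gene_id -> (chrom, strand, biotype)
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        gids = feat.attributes.get("gene_id")
        if not gids:
            raise ValueError(f"{path}: feature without gene_id at line {feat}")
        gid = gids[0]
        biotype = (feat.attributes.get("gene_biotype") or feat.attributes.get("gene_type") or [""])[0]
        meta.setdefault(gid, (feat.seqid, feat.strand, biotype))
        # GTF 1-based inclusive -> 0-based half-open
        iv = (feat.start - 1, feat.end)
        (exons if feat.featuretype == "exon" else cds).setdefault(gid, []).append(iv)

    genes: List[CollapsedGene] = []
    rrna: List[GenomicInterval] = []
    for gid in sorted(meta):
        chrom, strand, biotype = meta[gid]
        gene_exons = exons.get(gid)
        if not gene_exons:
            warnings.warn(f"gene {gid} has no exon features; skipped")
            continue
        if biotype in rrna_biotypes:
            for s, e in ivl.normalize(gene_exons):
                rrna.append(GenomicInterval(chrom, s, e, strand))
            continue
        genes.append(collapse_gene(gid, chrom, strand, gene_exons, cds.get(gid, [])))
    return genes, rrna


@dataclass
class RepeatEntry:
    chrom: str
    start: int
    end: int
    family: str
    strand: str
    host_class: Optional[RegionClass] = None
    host_gene: Optional[str] = None
    host_strand: str = "."


@dataclass
class RepeatOverlay:
    """Repeat annotation layered over (never altering) the primary partition."""

    entries: List[RepeatEntry] = field(default_factory=list)
    _trees: Dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def build_index(self) -> None:
        self._trees = {}
        for i, r in enumerate(self.entries):
            self._trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, i)

    def overlapping(self, chrom: str, start: int, end: int) -> List[RepeatEntry]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [self.entries[hit.data] for hit in tree.overlap(start, end)]

    def overlap_bases(self, chrom: str, start: int, end: int) -> List[Tuple[RepeatEntry, int]]:
        out = []
        tree = self._trees.get(chrom)
        if tree is None:
            return out
        for hit in tree.overlap(start, end):
            ov = min(end, hit.end) - max(start, hit.begin)
            if ov > 0:
                out.append((self.entries[hit.data], ov))
        return out

    def merged_length(self) -> int:
        by_chrom: Dict[str, List[Interval]] = {}
        for r in self.entries:
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
        return sum(ivl.total_length(ivl.normalize(v)) for v in by_chrom.values())

    def intervals_by_chrom(self) -> Dict[str, List[Interval]]:
        out: Dict[str, List[Interval]] = {}
        for r in self.entries:
            out.setdefault(r.chrom, []).append((r.start, r.end))
        return {c: ivl.normalize(v) for c, v in out.items()}

    @property
    def families(self) -> List[str]:
        return sorted({r.family for r in self.entries})


class PartitionIndex:
    """Maps every genomic base to exactly one primary region class.

    Per chromosome the partition is stored as sorted, disjoint segments
    covering ``[0, size)``; lookups are binary searches.  An optional
    :class:`RepeatOverlay` rides on top for repeat-aware queries.
    """

    def __init__(self, chrom_sizes: Mapping[str, int]):
        self.chrom_sizes: Dict[str, int] = dict(chrom_sizes)
        self.gene_ids: List[str] = []
        self._gene_index: Dict[str, int] = {}
        self._starts: Dict[str, np.ndarray] = {}
        self._ends: Dict[str, np.ndarray] = {}
        self._classes: Dict[str, np.ndarray] = {}
        self._genes: Dict[str, np.ndarray] = {}
        self._strands: Dict[str, np.ndarray] = {}
        self.class_lengths: Dict[RegionClass, int] = {c: 0 for c in RegionClass}
        self.repeats: Optional[RepeatOverlay] = None

    # -- construction ------------------------------------------------------
    def _gene_idx(self, gene_id: Optional[str]) -> int:
        if gene_id is None:
            return -1
        if gene_id not in self._gene_index:
            self._gene_index[gene_id] = len(self.gene_ids)
            self.gene_ids.append(gene_id)
        return self._gene_index[gene_id]

    def _set_segments(self, chrom: str, segs: List[Tuple[int, int, int, int, int]]) -> None:
        segs.sort()
        self._starts[chrom] = np.array([s[0] for s in segs], dtype=np.int64)
        self._ends[chrom] = np.array([s[1] for s in segs], dtype=np.int64)
        self._classes[chrom] = np.array([s[2] for s in segs], dtype=np.uint8)
        self._genes[chrom] = np.array([s[3] for s in segs], dtype=np.int32)
        self._strands[chrom] = np.array([s[4] for s in segs], dtype=np.int8)

    # -- queries -----------------------------------------------------------
    @property
    def genome_length(self) -> int:
        return sum(self.chrom_sizes.values())

    def lookup(self, chrom: str, pos: int) -> Tuple[RegionClass, Optional[str], str]:
        """Class, owning gene id (or None) and feature strand at one base."""
        if chrom not in self._starts:
            raise KeyError(f"chromosome {chrom!r} not in partition")
        if not 0 <= pos < self.chrom_sizes[chrom]:
            raise IndexError(f"position {pos} outside {chrom}")
        i = int(np.searchsorted(self._starts[chrom], pos, side="right")) - 1
        gi = int(self._genes[chrom][i])
        strand = {1: "+", -1: "-", 0: "."}[int(self._strands[chrom][i])]
        return RegionClass(int(self._classes[chrom][i])), (self.gene_ids[gi] if gi >= 0 else None), strand

    def segments(self, chrom: str, start: int, end: int) -> Iterator[Tuple[int, int, RegionClass, Optional[str], str]]:
        """Yield (start, end, class, gene_id, strand) clipped to [start, end)."""
        if chrom not in self._starts:
            raise KeyError(f"chromosome {chrom!r} not in partition")
        starts = self._starts[chrom]
        i = max(0, int(np.searchsorted(starts, start, side="right")) - 1)
        while i < len(starts) and starts[i] < end:
            s = max(int(starts[i]), start)
            e = min(int(self._ends[chrom][i]), end)
            if s < e:
                gi = int(self._genes[chrom][i])
                strand = {1: "+", -1: "-", 0: "."}[int(self._strands[chrom][i])]
                yield s, e, RegionClass(int(self._classes[chrom][i])), (
                    self.gene_ids[gi] if gi >= 0 else None
                ), strand
            i += 1

    def class_intervals(self, cls: RegionClass) -> Dict[str, List[Interval]]:
        out: Dict[str, List[Interval]] = {}
        code = int(cls)
        for chrom, classes in self._classes.items():
            mask = classes == code
            if mask.any():
                pairs = list(zip(self._starts[chrom][mask].tolist(), self._ends[chrom][mask].tolist()))
                out[chrom] = ivl.normalize(pairs)
        return out

    def gene_strand(self, gene_id: str) -> Optional[str]:
        gi = self._gene_index.get(gene_id)
        if gi is None:
            return None
        for chrom, genes in self._genes.items():
            hits = np.nonzero(genes == gi)[0]
            if len(hits):
                return {1: "+", -1: "-", 0: "."}[int(self._strands[chrom][hits[0]])]
        return None

    def to_bed(self, path: str) -> None:
        """Dump the partition as BED with the class label in the name column."""
        with open(path, "w") as fh:
            for chrom in sorted(self._starts):
                for s, e, c, g, strand in self.segments(chrom, 0, self.chrom_sizes[chrom]):
                    name = c.name if g is None else f"{c.name}|{g}"
                    bed_strand = strand if strand in "+-" else "."
                    fh.write(f"{chrom}\t{s}\t{e}\t{name}\t0\t{bed_strand}\n")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in sorted(self._starts):
            for s, e, c, g, strand in self.segments(chrom, 0, self.chrom_sizes[chrom]):
                rows.append((chrom, s, e, c.name, g, strand))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "region", "gene_id", "strand"])


def build_partition(
    genes: Sequence[CollapsedGene],
    rrna: Sequence[GenomicInterval] = (),
    chrom_sizes: Mapping[str, int] = (),
    flank: int = DEFAULT_FLANK,
) -> PartitionIndex:
    """Assemble the exhaustive primary partition of the genome.

    Candidate regions are projected per class, and overlaps are resolved by
    the :class:`RegionClass` precedence (rRNA > CDS > 5'UTR > 3'UTR > intron
    > upstream flank > downstream flank); whatever remains is intergenic.
    Within a class, overlapping candidates from different genes are resolved
    deterministically by (start, end, gene id), so gene input order never
    changes the result.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    index = PartitionIndex(chrom_sizes)
    chroms = set(chrom_sizes)
    for g in genes:
        if g.chrom not in chroms:
            raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
        if g.span[1] > chrom_sizes[g.chrom]:
            raise ValueError(f"gene {g.gene_id} exceeds chromosome {g.chrom} length")
    for r in rrna:
        if r.chrom not in chroms or r.end > chrom_sizes[r.chrom]:
            raise ValueError(f"rRNA interval outside chromosome bounds: {r}")

    strand_code = {"+": 1, "-": -1, ".": 0}
    # candidates[chrom][class] -> list of (start, end, gene_id or None, strand)
    candidates: Dict[str, Dict[RegionClass, List[Tuple[int, int, Optional[str], str]]]] = {
        c: {cls: [] for cls in RegionClass} for c in chroms
    }
    for r in rrna:
        candidates[r.chrom][RegionClass.RRNA].append((r.start, r.end, None, r.strand))
    for g in genes:
        size = chrom_sizes[g.chrom]
        cand = candidates[g.chrom]
        for s, e in g.cds:
            cand[RegionClass.CDS].append((s, e, g.gene_id, g.strand))
        for s, e in g.utr5:
            cand[RegionClass.UTR5].append((s, e, g.gene_id, g.strand))
        for s, e in g.utr3:
            cand[RegionClass.UTR3].append((s, e, g.gene_id, g.strand))
        for s, e in g.introns:
            cand[RegionClass.INTRON].append((s, e, g.gene_id, g.strand))
        up = (g.span[0] - flank, g.span[0]) if g.strand == "+" else (g.span[1], g.span[1] + flank)
        down = (g.span[1], g.span[1] + flank) if g.strand == "+" else (g.span[0] - flank, g.span[0])
        for cls, (s, e) in ((RegionClass.UP1K, up), (RegionClass.DOWN1K, down)):
            s, e = max(0, s), min(size, e)
            if s < e:
                cand[cls].append((s, e, g.gene_id, g.strand))

    for chrom in sorted(chroms):
        size = chrom_sizes[chrom]
        remaining: List[Interval] = [(0, size)]
        segs: List[Tuple[int, int, int, int, int]] = []
        for cls in (RegionClass.RRNA, RegionClass.CDS, RegionClass.UTR5, RegionClass.UTR3,
                    RegionClass.INTRON, RegionClass.UP1K, RegionClass.DOWN1K):
            claimed: List[Interval] = []
            taken: List[Interval] = []
            for s, e, gid, strand in sorted(
                candidates[chrom][cls], key=lambda t: (t[0], t[1], t[2] or "")
            ):
                if e > size:
                    raise ValueError(f"{cls.name} interval [{s},{e}) exceeds {chrom} length {size}")
                pieces = ivl.intersect(ivl.subtract([(s, e)], claimed), remaining)
                gi = index._gene_idx(gid)
                for ps, pe in pieces:
                    segs.append((ps, pe, int(cls), gi, strand_code[strand]))
                taken.extend(pieces)
                claimed = ivl.union(claimed, [(s, e)])
            remaining = ivl.subtract(remaining, ivl.normalize(taken))
        for s, e in remaining:
            segs.append((s, e, int(RegionClass.INTERGENIC), -1, 0))
        index._set_segments(chrom, segs)

    lengths = {c: 0 for c in RegionClass}
    for chrom in chroms:
        spans = (index._ends[chrom] - index._starts[chrom])
        for cls in RegionClass:
            lengths[cls] += int(spans[index._classes[chrom] == int(cls)].sum())
    index.class_lengths = lengths
    assert sum(lengths.values()) == index.genome_length
    return index


def load_repeats(
    path: str,
    index: PartitionIndex,
    family_map: Optional[Mapping[str, str]] = None,
) -> RepeatOverlay:
    """Read a BED6 repeat annotation and attach it to the partition.

    Each repeat keeps its family label (optionally collapsed through
    ``family_map``, e.g. L1MA/L1MB -> L1) and is assigned the primary class
    hosting the majority of its bases, plus that host's owning gene and
    strand.  Strandless records are rejected: orientation analyses need the
    repeat's annotated strand.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        overlay = RepeatOverlay()
        overlay.build_index()
        index.repeats = overlay
        return overlay
    if df.shape[1] < 6:
        raise ValueError(f"{path}: BED6 with name=family and strand required")
    overlay = RepeatOverlay()
    for row in df.itertuples(index=False):
        chrom, start, end, family, _score, strand = row[:6]
        start, end = int(start), int(end)
        if strand not in "+-":
            raise ValueError(f"{path}: repeat {chrom}:{start}-{end} has no strand")
        if family_map:
            family = family_map.get(family, family)
        # majority-base host class, ties broken by class precedence
        by_class: Dict[RegionClass, int] = {}
        by_gene: Dict[Tuple[RegionClass, Optional[str], str], int] = {}
        for s, e, cls, gid, gstrand in index.segments(chrom, start, end):
            by_class[cls] = by_class.get(cls, 0) + (e - s)
            key = (cls, gid, gstrand)
            by_gene[key] = by_gene.get(key, 0) + (e - s)
        host = min(by_class, key=lambda c: (-by_class[c], int(c)))
        gene_hits = {k: v for k, v in by_gene.items() if k[0] == host}
        _, host_gene, host_strand = min(
            gene_hits, key=lambda k: (-gene_hits[k], k[1] or "")
        )
        overlay.entries.append(
            RepeatEntry(chrom, start, end, str(family), strand, host, host_gene, host_strand)
        )
    overlay.entries.sort(key=lambda r: (r.chrom, r.start, r.end, r.family))
    overlay.build_index()
    index.repeats = overlay
    return overlay


def read_chrom_sizes(path: str) -> Dict[str, int]:
    """Two-column TSV: chromosome name, length."""
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, length = line.split()[:2]
            sizes[name] = int(length)
    return sizes
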