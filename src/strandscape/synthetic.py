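"""Synthetic annotated toy genome and stranded read simulator.

Emulates a two-condition x two-replicate stranded single-end 50-nt RNA-seq
design over a ~260-kb toy genome with full ground truth: genes with
CDS/UTR/intron structure (including a multi-isoform gene, a single-exon
gene and a flank-collision gene pair), an rRNA gene, strand-annotated
L1/L2 repeats both intronic and intergenic, planted splice junctions
(known, novel shared/exclusive, and deliberately sub-threshold decoys) and
planted transfrags of known class.

Reads are drawn per sample from a region-class fraction vector: class ->
uniform placement inside a class-pure interval -> orientation by a
per-class antisense probability.  All placement arithmetic is integer-
based, so a fixed seed reproduces output files byte for byte.  The
generator records every planted quantity in a manifest of expected
statistics with binomial tolerance bounds, enabling end-to-end recovery
assertions downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import intervals as ivl
from .annotation import (
    CollapsedGene,
    GenomicInterval,
    PartitionIndex,
    RegionClass,
    REPEAT_LABEL,
    RepeatEntry,
    RepeatOverlay,
    build_partition,
    collapse_gene,
)
from .assignment import AlignedRead
from .intervals import Interval
from .transfrags import Transfrag

READ_LENGTH = 50

#: Primary classes reads can be drawn from (rRNA is handled separately).
DRAW_CLASSES = ["CDS", "UTR5", "UTR3", "INTRON", "UP1K", "DOWN1K", "INTERGENIC", REPEAT_LABEL]

#: Resting-condition region-fraction vector: mostly coding signal with a
#: large intronic/intergenic component, as in mammalian PBMC poly-A libraries.
DEFAULT_BASE_FRACTIONS = {
    "CDS": 0.355,
    "UTR5": 0.02,
    "UTR3": 0.045,
    "INTRON": 0.14,
    "UP1K": 0.05,
    "DOWN1K": 0.05,
    "INTERGENIC": 0.27,
    REPEAT_LABEL: 0.07,
}

#: Stress-condition shifts: coding down, intron and repeat expression up.
#: The three overrides sum to the same mass as their baseline values, so
#: every other class keeps its exact baseline fraction.
DEFAULT_T2_OVERRIDES = {"CDS": 0.30, "INTRON": 0.18, REPEAT_LABEL: 0.085}

#: Antisense probability per class: near-pure sense in coding sequence,
#: substantially more antisense signal in introns and flanking regions.
#: For INTERGENIC the value is the minus-strand probability.
DEFAULT_ANTISENSE = {
    "CDS": 0.01,
    "UTR5": 0.02,
    "UTR3": 0.02,
    "INTRON": 0.25,
    "UP1K": 0.30,
    "DOWN1K": 0.30,
    "INTERGENIC": 0.50,
}

DEFAULT_FAMILY_WEIGHTS = {"L1": 0.66, "L2": 0.34}
#: L1 expression is antisense-dominated (~3:1); L2 leans sense.
DEFAULT_FAMILY_ANTISENSE = {"L1": 0.75, "L2": 0.43}


# ---------------------------------------------------------------------------
# toy genome layout


@dataclass
class ToyGenomeConfig:
    chrom_sizes: Dict[str, int] = field(
        default_factory=lambda: {"chr1": 160_000, "chr2": 100_000}
    )
    n_intronic_repeats: Dict[str, int] = field(default_factory=lambda: {"L1": 50, "L2": 25})
    intronic_concordance: Dict[str, float] = field(default_factory=lambda: {"L1": 0.34, "L2": 0.44})
    n_intergenic_repeats: Dict[str, int] = field(default_factory=lambda: {"L1": 8, "L2": 8})
    repeat_length: int = 400
    include_repeats: bool = True


#: Hand-laid gene templates: (gene_id, chrom, strand, biotype,
#: [(transcript_id, exons, cds), ...]).  Coordinates are 0-based half-open.
def _gene_templates() -> List[Tuple[str, str, str, str, List[Tuple[str, List[Interval], List[Interval]]]]]:
    return [
        # multi-isoform gene: two transcripts sharing the first exon
        ("g01", "chr1", "+", "protein_coding", [
            ("g01.t1", [(5000, 5800), (8000, 9000), (12000, 13000)],
             [(5400, 5800), (8000, 9000), (12000, 12600)]),
            ("g01.t2", [(5000, 5800), (8500, 9000), (11000, 13000)],
             [(5400, 5800), (8500, 9000), (11000, 12600)]),
        ]),
        # single-exon gene on the minus strand
        ("g02", "chr1", "-", "protein_coding", [
            ("g02.t1", [(18000, 20500)], [(18300, 20200)]),
        ]),
        # ribosomal RNA gene (excluded from the gene set, primary RRNA class)
        ("rrna1", "chr1", "+", "rRNA", [
            ("rrna1.t1", [(23000, 23500)], []),
        ]),
        # big-intron genes hosting the intronic repeats
        ("g03", "chr1", "+", "protein_coding", [
            ("g03.t1", [(26000, 26600), (56000, 56800), (59000, 60000)],
             [(26200, 26600), (56000, 56800), (59000, 59400)]),
        ]),
        ("g04", "chr1", "-", "protein_coding", [
            ("g04.t1", [(64000, 65000), (88000, 88600), (91000, 92000)],
             [(64200, 65000), (88000, 88600), (91000, 91700)]),
        ]),
        # flank-collision pair: 800 bp apart, well under 2x1kb of flanks
        ("g05", "chr1", "+", "protein_coding", [
            ("g05.t1", [(96000, 96700), (98000, 99000)],
             [(96100, 96700), (98000, 98800)]),
        ]),
        ("g06", "chr1", "+", "protein_coding", [
            ("g06.t1", [(99800, 100400), (101500, 102500)],
             [(99900, 100400), (101500, 102300)]),
        ]),
        ("g12", "chr1", "+", "protein_coding", [
            ("g12.t1", [(132000, 134000)], [(132200, 133800)]),
        ]),
        ("g13", "chr1", "-", "protein_coding", [
            ("g13.t1", [(136000, 136800), (137600, 138500)],
             [(136100, 136800), (137600, 138300)]),
        ]),
        ("g14", "chr1", "+", "protein_coding", [
            ("g14.t1", [(141000, 141900), (142400, 143000)],
             [(141100, 141900), (142400, 142800)]),
        ]),
        ("g07", "chr2", "-", "protein_coding", [
            ("g07.t1", [(5000, 5900), (8000, 9000)], [(5100, 5900), (8000, 8800)]),
        ]),
        ("g08", "chr2", "+", "protein_coding", [
            ("g08.t1", [(12000, 13000), (28000, 28500), (29500, 30000)],
             [(12200, 13000), (28000, 28500), (29500, 29800)]),
        ]),
        ("g09", "chr2", "-", "protein_coding", [
            ("g09.t1", [(34000, 35000), (38000, 38500), (39500, 40000)],
             [(34200, 35000), (38000, 38500), (39500, 39800)]),
        ]),
        ("g10", "chr2", "+", "protein_coding", [
            ("g10.t1", [(44000, 46000)], [(44200, 45800)]),
        ]),
        ("g11", "chr2", "-", "protein_coding", [
            ("g11.t1", [(50000, 50800), (68000, 68500), (69500, 70000)],
             [(50100, 50800), (68000, 68500), (69500, 69800)]),
        ]),
    ]

#: Intergenic repeat placement zones: (chrom, start, slot count).
_INTERGENIC_REPEAT_ZONES = [("chr1", 105_000, 12), ("chr2", 74_000, 4)]
#: Intergenic free zones reserved for transfrags / novel junctions.
_INTERGENIC_TF_ZONES = [("chr1", 146_000, 152_000), ("chr2", 80_000, 86_000)]
_INTERGENIC_JX_ZONES = [("chr1", 152_000, 158_000), ("chr2", 86_000, 98_000)]


@dataclass
class SyntheticTruth:
    """Ground-truth genome layout plus everything planted into it."""

    config: ToyGenomeConfig
    chrom_sizes: Dict[str, int]
    gene_templates: List = field(default_factory=list)
    repeats: List[Dict] = field(default_factory=list)  # chrom,start,end,family,strand,host_gene,host_strand,host_class

    def collapsed_genes(self) -> List[CollapsedGene]:
        genes = []
        for gid, chrom, strand, biotype, txs in self.gene_templates:
            if biotype == "rRNA":
                continue
            exons = [iv for _t, exs, _c in txs for iv in exs]
            cds = [iv for _t, _e, cs in txs for iv in cs]
            genes.append(collapse_gene(gid, chrom, strand, exons, cds))
        return genes

    def rrna_intervals(self) -> List[GenomicInterval]:
        out = []
        for gid, chrom, strand, biotype, txs in self.gene_templates:
            if biotype == "rRNA":
                for _t, exons, _c in txs:
                    for s, e in exons:
                        out.append(GenomicInterval(chrom, s, e, strand))
        return out

    def partition(self, flank: int = 1000) -> PartitionIndex:
        index = build_partition(
            self.collapsed_genes(), self.rrna_intervals(), self.chrom_sizes, flank=flank
        )
        overlay = RepeatOverlay()
        for r in self.repeats:
            overlay.entries.append(
                RepeatEntry(
                    r["chrom"], r["start"], r["end"], r["family"], r["strand"],
                    RegionClass[r["host_class"]], r["host_gene"], r["host_strand"],
                )
            )
        overlay.build_index()
        index.repeats = overlay
        return index

    def to_json(self, path: str) -> None:
        payload = {
            "chrom_sizes": self.chrom_sizes,
            "gene_templates": self.gene_templates,
            "repeats": self.repeats,
            "config": asdict(self.config),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _spread_flags(n: int, frac: float) -> List[bool]:
    """n booleans with floor(n*frac) True, spread evenly and deterministically."""
    return [int((i + 1) * frac) - int(i * frac) == 1 for i in range(n)]


def build_toy_genome(
    outdir: Optional[str] = None, config: Optional[ToyGenomeConfig] = None
) -> SyntheticTruth:
    """Construct the deterministic toy genome; optionally write annotation files.

    Writes ``genes.gtf``, ``repeats.bed``, ``chrom.sizes`` and ``truth.json``
    when ``outdir`` is given.  The layout is fully determined by the config,
    so repeated calls produce byte-identical files.
    """
    config = config or ToyGenomeConfig()
    templates = _gene_templates()
    truth = SyntheticTruth(config=config, chrom_sizes=dict(config.chrom_sizes),
                           gene_templates=templates)
    for gid, chrom, strand, _b, txs in templates:
        for _t, exons, _c in txs:
            for s, e in exons:
                if chrom not in config.chrom_sizes or e > config.chrom_sizes[chrom]:
                    raise ValueError(f"gene {gid} exceeds chromosome {chrom}")

    if config.include_repeats:
        rep_len = config.repeat_length
        margin, gap = 100, 200
        step = rep_len + gap
        # intronic slots: first half of every sufficiently large intron, so the
        # second half stays free for planted transfrags and junctions
        slots: List[Tuple[str, int, str, str]] = []  # chrom, start, host_gene, host_strand
        for g in truth.collapsed_genes():
            for s, e in g.introns:
                usable = (e - s) // 2 - margin
                k = usable // step
                for j in range(k):
                    slots.append((g.chrom, s + margin + j * step, g.gene_id, g.strand))
        needed = sum(config.n_intronic_repeats.values())
        if needed > len(slots):
            raise ValueError(f"not enough intronic repeat slots ({len(slots)} < {needed})")
        i = 0
        for fam in sorted(config.n_intronic_repeats):
            n = config.n_intronic_repeats[fam]
            conc = _spread_flags(n, config.intronic_concordance.get(fam, 0.5))
            for j in range(n):
                chrom, start, host_gene, host_strand = slots[i]
                strand = host_strand if conc[j] else ("-" if host_strand == "+" else "+")
                truth.repeats.append(dict(
                    chrom=chrom, start=start, end=start + rep_len, family=fam,
                    strand=strand, host_gene=host_gene, host_strand=host_strand,
                    host_class="INTRON",
                ))
                i += 1
        # intergenic repeats: alternate family and strand through fixed zones
        ig_slots = [
            (chrom, start + j * (rep_len + 400))
            for chrom, start, k in _INTERGENIC_REPEAT_ZONES
            for j in range(k)
        ]
        wanted = [
            (fam, strand)
            for fam in sorted(config.n_intergenic_repeats)
            for j in range(config.n_intergenic_repeats[fam])
            for strand in (["+"] if j % 2 == 0 else ["-"])
        ]
        if len(wanted) > len(ig_slots):
            raise ValueError("not enough intergenic repeat slots")
        for (fam, strand), (chrom, start) in zip(wanted, ig_slots):
            truth.repeats.append(dict(
                chrom=chrom, start=start, end=start + rep_len, family=fam,
                strand=strand, host_gene=None, host_strand=".",
                host_class="INTERGENIC",
            ))
    truth.repeats.sort(key=lambda r: (r["chrom"], r["start"]))

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_gtf(truth, out / "genes.gtf")
        write_repeats_bed(truth, out / "repeats.bed")
        with open(out / "chrom.sizes", "w") as fh:
            for chrom in sorted(truth.chrom_sizes):
                fh.write(f"{chrom}\t{truth.chrom_sizes[chrom]}\n")
        truth.to_json(str(out / "truth.json"))
    return truth


def write_gtf(truth: SyntheticTruth, path) -> None:
    """Emit gene/transcript/exon/CDS records, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        for gid, chrom, strand, biotype, txs in truth.gene_templates:
            span_s = min(s for _t, exs, _c in txs for s, _e in exs)
            span_e = max(e for _t, exs, _c in txs for _s, e in exs)
            attrs = f'gene_id "{gid}"; gene_biotype "{biotype}";'
            fh.write(f"{chrom}\ttoy\tgene\t{span_s + 1}\t{span_e}\t.\t{strand}\t.\t{attrs}\n")
            for tid, exons, cds in txs:
                tattrs = f'gene_id "{gid}"; transcript_id "{tid}"; gene_biotype "{biotype}";'
                ts = min(s for s, _e in exons)
                te = max(e for _s, e in exons)
                fh.write(f"{chrom}\ttoy\ttranscript\t{ts + 1}\t{te}\t.\t{strand}\t.\t{tattrs}\n")
                for s, e in sorted(exons):
                    fh.write(f"{chrom}\ttoy\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t{tattrs}\n")
                for s, e in sorted(cds):
                    fh.write(f"{chrom}\ttoy\tCDS\t{s + 1}\t{e}\t.\t{strand}\t0\t{tattrs}\n")


def write_repeats_bed(truth: SyntheticTruth, path) -> None:
    with open(path, "w") as fh:
        for r in truth.repeats:
            fh.write(
                f"{r['chrom']}\t{r['start']}\t{r['end']}\t{r['family']}\t0\t{r['strand']}\n"
            )


# ---------------------------------------------------------------------------
# junction and transfrag planting


@dataclass(frozen=True)
class JunctionPlant:
    chrom: str
    donor: int
    acceptor: int
    group: str  # known / shared / T1 / T2 / decoy_single / decoy_overhang
    support: Tuple[Tuple[str, int], ...]  # ((condition, reads per condition), ...)
    overhang: int = 20  # left overhang of the first supporting read

    @property
    def key(self) -> Tuple[str, int, int]:
        return (self.chrom, self.donor, self.acceptor)


def generate_junction_sites(truth: SyntheticTruth, index: PartitionIndex) -> List[Tuple[str, int, int]]:
    """Deterministic pool of novel junction sites over diverse region pairs.

    Sites are drawn from within-CDS, within-intron, CDS-to-intron,
    intron-into-repeat, intergenic and intergenic-into-repeat templates and
    interleaved round-robin, so any prefix of the pool mixes categories.
    None coincides with an annotated splice junction.
    """
    genes = truth.collapsed_genes()
    pools: List[List[Tuple[str, int, int]]] = []

    cds_sites = []
    for g in genes:
        for s, e in g.cds:
            if e - s >= 400:
                d = s + 60
                while d + 160 + 40 <= e:
                    cds_sites.append((g.chrom, d, d + 120))
                    d += 160
    pools.append(cds_sites)

    intron_sites = []
    jx_zones = []
    for g in genes:
        for s, e in g.introns:
            if e - s >= 8000:
                mid = s + (e - s) // 2
                jx_zones.append((g.chrom, mid + (e - s) // 4, e - 200))
    for chrom, zs, ze in jx_zones:
        d = zs + 40
        while d + 300 + 60 <= ze:
            intron_sites.append((chrom, d, d + 250))
            d += 380
    pools.append(intron_sites)

    cds_intron_sites = []
    for g in genes:
        for (cs, ce), (is_, ie) in zip(g.cds, g.introns):
            if ce - cs >= 100 and ce <= is_ and ie - is_ >= 800:
                cds_intron_sites.append((g.chrom, ce - 5, is_ + 300))
    pools.append(cds_intron_sites)

    intron_repeat_sites = []
    for r in truth.repeats:
        if r["host_class"] == "INTRON" and r["start"] >= 150:
            intron_repeat_sites.append((r["chrom"], r["start"] - 60, r["start"] + 100))
    pools.append(intron_repeat_sites)

    ig_sites = []
    for chrom, zs, ze in _INTERGENIC_JX_ZONES:
        d = zs + 40
        while d + 300 + 60 <= ze:
            ig_sites.append((chrom, d, d + 250))
            d += 340
    pools.append(ig_sites)

    ig_repeat_sites = []
    for r in truth.repeats:
        if r["host_class"] == "INTERGENIC":
            ig_repeat_sites.append((r["chrom"], r["start"] - 300, r["start"] + 100))
    pools.append(ig_repeat_sites)

    from .junctions import annotated_junctions

    banned = set(annotated_junctions(genes))
    sites: List[Tuple[str, int, int]] = []
    seen = set()
    i = 0
    while any(i < len(p) for p in pools):
        for p in pools:
            if i < len(p):
                site = p[i]
                if site not in banned and site not in seen:
                    sites.append(site)
                    seen.add(site)
        i += 1
    return sites


@dataclass
class JunctionDesign:
    n_shared: int = 100
    n_t1_exclusive: int = 40
    n_t2_exclusive: int = 60
    n_decoy_single: int = 10  # one supporting read only
    n_decoy_overhang: int = 10  # two reads, both with a 14-nt overhang
    support: int = 3
    known_fraction: float = 0.6


def plan_junctions(
    truth: SyntheticTruth,
    index: PartitionIndex,
    design: JunctionDesign,
    conditions: Tuple[str, str] = ("T1", "T2"),
) -> List[JunctionPlant]:
    from .junctions import annotated_junctions

    c1, c2 = conditions
    sites = generate_junction_sites(truth, index)
    need = (design.n_shared + design.n_t1_exclusive + design.n_t2_exclusive
            + design.n_decoy_single + design.n_decoy_overhang)
    if len(sites) < need:
        raise ValueError(f"junction site pool too small ({len(sites)} < {need})")
    plants: List[JunctionPlant] = []
    pos = 0

    def take(n):
        nonlocal pos
        chunk = sites[pos:pos + n]
        pos += n
        return chunk

    s = design.support
    for chrom, d, a in take(design.n_shared):
        plants.append(JunctionPlant(chrom, d, a, "shared", ((c1, s), (c2, s))))
    for chrom, d, a in take(design.n_t1_exclusive):
        plants.append(JunctionPlant(chrom, d, a, c1, ((c1, s),)))
    for chrom, d, a in take(design.n_t2_exclusive):
        plants.append(JunctionPlant(chrom, d, a, c2, ((c2, s),)))
    for i, (chrom, d, a) in enumerate(take(design.n_decoy_single)):
        cond = conditions[i % 2]
        plants.append(JunctionPlant(chrom, d, a, "decoy_single", ((cond, 1),)))
    for i, (chrom, d, a) in enumerate(take(design.n_decoy_overhang)):
        cond = conditions[i % 2]
        plants.append(JunctionPlant(chrom, d, a, "decoy_overhang", ((cond, 2),), overhang=14))

    known = sorted(annotated_junctions(truth.collapsed_genes()))
    n_known = int(round(design.known_fraction * len(known)))
    for chrom, d, a in known[:n_known]:
        plants.append(JunctionPlant(chrom, d, a, "known", ((c1, s), (c2, s))))
    return plants


def plant_reads(
    plant: JunctionPlant,
    condition: str,
    replicate: str,
    replicates: Sequence[str],
    read_length: int = READ_LENGTH,
) -> List[AlignedRead]:
    """Spliced reads supporting one planted junction in one sample.

    A condition's support is split across its replicates (first replicate
    takes the remainder); supporting reads get distinct alignment starts by
    varying the left overhang.  Decoy plants use a 14-nt overhang, one
    below the acceptance threshold.
    """
    n_cond = dict(plant.support).get(condition, 0)
    if n_cond == 0:
        return []
    r_idx = list(replicates).index(replicate)
    base = n_cond // len(replicates)
    extra = n_cond % len(replicates)
    n_here = base + (1 if r_idx < extra else 0)
    offset = sum(base + (1 if i < extra else 0) for i in range(r_idx))
    reads = []
    for i in range(offset, offset + n_here):
        if plant.group == "decoy_overhang":
            left = 14 if i % 2 == 0 else read_length - 14
        else:
            left = plant.overhang + 3 * i
            left = min(max(left, 15), read_length - 15)
        right = read_length - left
        rid = f"jx:{plant.chrom}:{plant.donor}:{plant.acceptor}:{condition}:{i}"
        reads.append(
            AlignedRead(
                rid, plant.chrom,
                [(plant.donor - left, plant.donor), (plant.acceptor, plant.acceptor + right)],
                "+", nh=1,
            )
        )
    return reads


@dataclass
class TransfragDesign:
    n_intronic: int = 30
    n_intergenic: int = 20
    n_other: int = 5
    length: int = 300


def plant_transfrags(
    truth: SyntheticTruth, design: TransfragDesign
) -> Tuple[List[Transfrag], Dict[str, str]]:
    """Plant transfrags of known class; returns (transfrags, id -> true class).

    Intronic transfrags sit in the reserved third quarter of large introns
    (class share 1.0); intergenic ones in dedicated intergenic zones; the
    "other" decoys straddle an exon/intron boundary half-and-half.
    """
    L = design.length
    genes = truth.collapsed_genes()
    tfs: List[Transfrag] = []
    classes: Dict[str, str] = {}

    zones = []
    for g in genes:
        for s, e in g.introns:
            if e - s >= 8000:
                mid = s + (e - s) // 2
                zones.append((g.chrom, mid + 50, mid + (e - s) // 4 - 50))
    slots = [
        (chrom, zs + j * (L + 100))
        for chrom, zs, ze in zones
        for j in range((ze - zs) // (L + 100))
    ]
    if len(slots) < design.n_intronic:
        raise ValueError("not enough intronic transfrag slots")
    for i in range(design.n_intronic):
        chrom, s = slots[i]
        tid = f"tf_intronic_{i:03d}"
        tfs.append(Transfrag(tid, chrom, "+", [(s, s + L)]))
        classes[tid] = "intronic"

    ig_slots = [
        (chrom, zs + j * (L + 100))
        for chrom, zs, ze in _INTERGENIC_TF_ZONES
        for j in range((ze - zs) // (L + 100))
    ]
    if len(ig_slots) < design.n_intergenic:
        raise ValueError("not enough intergenic transfrag slots")
    for i in range(design.n_intergenic):
        chrom, s = ig_slots[i]
        tid = f"tf_intergenic_{i:03d}"
        tfs.append(Transfrag(tid, chrom, "+", [(s, s + L)]))
        classes[tid] = "intergenic"

    # boundary straddlers: half exonic, half intronic -> neither share > 0.8
    half = L // 2
    candidates = [
        (g.chrom, ce)
        for g in genes
        for (cs, ce), (is_, ie) in zip(g.cds, g.introns)
        if ce <= is_ and ce - cs >= half and ie - is_ >= half + 200
    ]
    for i in range(design.n_other):
        chrom, edge = candidates[i % len(candidates)]
        tid = f"tf_other_{i:03d}"
        tfs.append(Transfrag(tid, chrom, "+", [(edge - half + i, edge + half + i)]))
        classes[tid] = "other"
    return tfs, classes


def write_bed12(transfrags: Sequence[Transfrag], path) -> None:
    with open(path, "w") as fh:
        for tf in transfrags:
            s = tf.intervals[0][0]
            e = tf.intervals[-1][1]
            sizes = ",".join(str(b - a) for a, b in tf.intervals) + ","
            starts = ",".join(str(a - s) for a, b in tf.intervals) + ","
            fh.write(
                f"{tf.chrom}\t{s}\t{e}\t{tf.id}\t0\t{tf.strand}\t{s}\t{e}\t0\t"
                f"{len(tf.intervals)}\t{sizes}\t{starts}\n"
            )


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class SampleSpec:
    sample_id: str
    condition: str
    replicate: str
    n_reads: int
    fractions: Dict[str, float]
    seed: int
    antisense: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ANTISENSE))
    family_weights: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FAMILY_WEIGHTS))
    family_antisense: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FAMILY_ANTISENSE))
    n_rrna: int = 0
    n_multimap: int = 0
    boundary_rate: float = 0.0
    read_length: int = READ_LENGTH

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"sample {self.sample_id}: fractions sum to {total}, not 1")
        if any(v < 0 for v in self.fractions.values()):
            raise ValueError("negative class fraction")


@dataclass
class SampleTruth:
    """Per-sample ground truth emitted alongside the simulated reads."""

    sample_id: str
    drawn_counts: Dict[str, int]  # multinomial realisation per draw category
    extra_counts: Dict[str, int]  # junction/boundary reads per majority class
    labels: Dict[str, str]  # read_id -> truth label ("CDS", "REPEAT:L1", "boundary", ...)
    boundary_reads: List[str] = field(default_factory=list)


class _Pools:
    """Length-weighted placement pools per draw category, repeat-free for
    primary classes so every uniform draw is class-pure."""

    def __init__(self, index: PartitionIndex, read_length: int):
        self.read_length = read_length
        self.by_class: Dict[str, Tuple[List[str], np.ndarray, np.ndarray, List[str]]] = {}
        rep_ivs = index.repeats.intervals_by_chrom() if index.repeats else {}
        acc: Dict[str, List[Tuple[str, int, int, str]]] = {}
        for chrom in sorted(index.chrom_sizes):
            for s, e, cls, _g, strand in index.segments(chrom, 0, index.chrom_sizes[chrom]):
                if cls == RegionClass.RRNA:
                    continue
                # keep per-segment strand: pools never merge across features
                for cs, ce in ivl.subtract([(s, e)], rep_ivs.get(chrom, [])):
                    if ce - cs >= read_length:
                        acc.setdefault(cls.name, []).append((chrom, cs, ce - cs, strand))
        for name, rows in acc.items():
            self.by_class[name] = (
                [r[0] for r in rows],
                np.asarray([r[1] for r in rows], dtype=np.int64),
                np.asarray([r[2] for r in rows], dtype=np.int64),
                [r[3] for r in rows],
            )
        self.repeat_entries: Dict[str, List[RepeatEntry]] = {}
        if index.repeats:
            for r in index.repeats.entries:
                if r.end - r.start >= read_length:
                    self.repeat_entries.setdefault(r.family, []).append(r)

    def draw(self, rng: np.random.Generator, cls: str, n: int):
        chroms, starts, lens, strands = self.by_class[cls]
        w = (lens - self.read_length + 1).astype(float)
        idx = rng.choice(len(starts), size=n, p=w / w.sum())
        offs = rng.integers(0, lens[idx] - self.read_length + 1)
        return idx, starts[idx] + offs, [chroms[i] for i in idx], [strands[i] for i in idx]


def _majority_label(chrom: str, blocks: List[Interval], index: PartitionIndex) -> str:
    """Majority-base truth label for planted reads (repeat overlay first)."""
    total = sum(e - s for s, e in blocks)
    if index.repeats is not None:
        rep = 0
        best = None
        best_ov = 0
        for s, e in blocks:
            for entry, ov in index.repeats.overlap_bases(chrom, s, e):
                rep += ov
                if ov > best_ov:
                    best, best_ov = entry, ov
        if 2 * rep > total:
            return f"{REPEAT_LABEL}:{best.family}"
    tally: Dict[RegionClass, int] = {}
    for bs, be in blocks:
        for s, e, cls, _g, _st in index.segments(chrom, bs, be):
            tally[cls] = tally.get(cls, 0) + (e - s)
    return min(tally, key=lambda c: (-tally[c], int(c))).name


def simulate_reads(
    truth: SyntheticTruth,
    index: PartitionIndex,
    spec: SampleSpec,
    plants: Sequence[JunctionPlant] = (),
    replicates: Sequence[str] = ("A", "B"),
) -> Tuple[List[AlignedRead], SampleTruth]:
    """Draw one sample's reads with per-read ground-truth labels.

    The bulk of reads is a multinomial draw over the class-fraction vector,
    placed uniformly inside class-pure intervals; planted junction reads,
    deliberate boundary-straddlers, rRNA reads and NH=2 multimappers are
    added on top and accounted separately in the returned
    :class:`SampleTruth`.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.read_length
    pools = _Pools(index, L)
    reads: List[AlignedRead] = []
    labels: Dict[str, str] = {}
    categories = [c for c in DRAW_CLASSES if spec.fractions.get(c, 0.0) > 0]
    probs = np.array([spec.fractions[c] for c in categories], dtype=float)
    counts = rng.multinomial(spec.n_reads, probs / probs.sum())
    drawn: Dict[str, int] = {}
    for cls, n in zip(categories, counts):
        drawn[cls] = int(n)
        if n == 0:
            continue
        if cls == REPEAT_LABEL:
            fams = sorted(spec.family_weights)
            fw = np.array([spec.family_weights[f] for f in fams], dtype=float)
            fam_counts = rng.multinomial(n, fw / fw.sum())
            for fam, fn in zip(fams, fam_counts):
                entries = pools.repeat_entries.get(fam, [])
                if fn and not entries:
                    raise ValueError(f"no placeable repeats for family {fam}")
                if not fn:
                    continue
                w = np.array([r.end - r.start - L + 1 for r in entries], dtype=float)
                idx = rng.choice(len(entries), size=fn, p=w / w.sum())
                offs = rng.integers(0, w[idx].astype(np.int64))
                anti = rng.random(fn) < spec.family_antisense.get(fam, 0.5)
                for k in range(fn):
                    r = entries[idx[k]]
                    start = r.start + int(offs[k])
                    strand = r.strand if not anti[k] else ("-" if r.strand == "+" else "+")
                    rid = f"{spec.sample_id}:rep:{fam}:{k}"
                    reads.append(AlignedRead(rid, r.chrom, [(start, start + L)], strand, nh=1))
                    labels[rid] = f"{REPEAT_LABEL}:{fam}"
        else:
            if cls not in pools.by_class:
                raise ValueError(f"class {cls} has no placeable intervals but fraction > 0")
            _idx, starts, chroms, strands = pools.draw(rng, cls, n)
            anti = rng.random(n) < spec.antisense.get(cls, 0.0)
            for k in range(n):
                if cls == "INTERGENIC":
                    strand = "-" if anti[k] else "+"
                else:
                    f = strands[k]
                    strand = f if not anti[k] else ("-" if f == "+" else "+")
                rid = f"{spec.sample_id}:{cls}:{k}"
                s = int(starts[k])
                reads.append(AlignedRead(rid, chroms[k], [(s, s + L)], strand, nh=1))
                labels[rid] = cls

    extras: Dict[str, int] = {}
    st = SampleTruth(spec.sample_id, drawn, extras, labels)

    # planted junction reads
    for plant in plants:
        for read in plant_reads(plant, spec.condition, spec.replicate, replicates, L):
            reads.append(read)
            lab = _majority_label(read.chrom, read.blocks, index)
            labels[read.read_id] = lab
            key = lab.split(":")[0]
            extras[key] = extras.get(key, 0) + 1

    # deliberate boundary straddlers exercising the majority rule
    n_boundary = int(round(spec.boundary_rate * spec.n_reads))
    if n_boundary:
        bounds = []
        for chrom in sorted(index.chrom_sizes):
            prev = None
            for s, e, cls, _g, _st2 in index.segments(chrom, 0, index.chrom_sizes[chrom]):
                if prev is not None and L <= s <= index.chrom_sizes[chrom] - L:
                    bounds.append((chrom, s))
                prev = cls
        pick = rng.choice(len(bounds), size=n_boundary)
        shift = rng.integers(5, L - 5, size=n_boundary)
        for k in range(n_boundary):
            chrom, pos = bounds[int(pick[k])]
            s = pos - int(shift[k])
            rid = f"{spec.sample_id}:boundary:{k}"
            strand = "+" if rng.random() < 0.5 else "-"
            read = AlignedRead(rid, chrom, [(s, s + L)], strand, nh=1)
            reads.append(read)
            lab = _majority_label(chrom, read.blocks, index)
            labels[rid] = lab
            key = lab.split(":")[0]
            extras[key] = extras.get(key, 0) + 1
            st.boundary_reads.append(rid)

    # rRNA reads (to be removed downstream) and NH=2 multimappers
    rrna = truth.rrna_intervals()
    for k in range(spec.n_rrna):
        iv = rrna[k % len(rrna)]
        s = iv.start + int(rng.integers(0, len(iv) - L + 1))
        rid = f"{spec.sample_id}:rrna:{k}"
        reads.append(AlignedRead(rid, iv.chrom, [(s, s + L)], iv.strand, nh=1))
        labels[rid] = "RRNA"
    if spec.n_multimap:
        chroms, starts, lens, _strands = pools.by_class["CDS"]
        for k in range(spec.n_multimap):
            i = k % len(starts)
            rid = f"{spec.sample_id}:multi:{k}"
            s = int(starts[i])
            reads.append(AlignedRead(rid, chroms[i], [(s, s + L)], "+", nh=2))
            labels[rid] = "multimap"
    return reads, st


def write_sam(reads: Sequence[AlignedRead], chrom_sizes: Mapping[str, int], path) -> None:
    """Coordinate-sorted SAM via pysam; block gaps become N CIGAR operations."""
    import pysam

    chroms = sorted(chrom_sizes)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(chrom_sizes[c])} for c in chroms],
    }
    order = {c: i for i, c in enumerate(chroms)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read in sorted(reads, key=lambda r: (order[r.chrom], r.start, r.read_id)):
            a = pysam.AlignedSegment(out.header)
            a.query_name = read.read_id
            a.reference_id = order[read.chrom]
            a.reference_start = read.start
            a.mapping_quality = read.mapq if read.mapq != 255 else 50
            a.flag = 16 if read.strand == "-" else 0
            cig = []
            prev_end = None
            for s, e in read.blocks:
                if prev_end is not None:
                    cig.append((3, s - prev_end))  # N
                cig.append((0, e - s))  # M
                prev_end = e
            a.cigartuples = cig
            if read.nh is not None:
                a.set_tag("NH", int(read.nh))
            out.write(a)


def write_alignment_tsv(reads: Sequence[AlignedRead], path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            blocks = ",".join(f"{s}-{e}" for s, e in read.blocks)
            nh = "" if read.nh is None else str(read.nh)
            fh.write(f"{read.read_id}\t{read.chrom}\t{read.strand}\t{blocks}\t{nh}\t{read.mapq}\n")


# ---------------------------------------------------------------------------
# two-condition design and expectation manifest

Z99 = 2.5758293035489004  # two-sided 99% normal quantile


@dataclass
class EffectSpec:
    """Planted between-condition effects on top of the baseline composition."""

    n_reads: int = 50_000
    base_fractions: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASE_FRACTIONS))
    overrides: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {"T2": dict(DEFAULT_T2_OVERRIDES)}
    )
    renormalize: bool = False
    antisense: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ANTISENSE))
    family_weights: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FAMILY_WEIGHTS))
    family_antisense: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FAMILY_ANTISENSE))
    junctions: JunctionDesign = field(default_factory=JunctionDesign)
    transfrags: TransfragDesign = field(default_factory=TransfragDesign)
    n_rrna: int = 200
    n_multimap: int = 200
    boundary_rate: float = 0.0
    read_length: int = READ_LENGTH
    conditions: Tuple[str, str] = ("T1", "T2")
    replicates: Tuple[str, str] = ("A", "B")
    seed: int = 0


@dataclass
class DesignBundle:
    specs: Dict[str, SampleSpec]
    design: Dict[str, Tuple[str, str]]  # sample -> (condition, replicate)
    plants: List[JunctionPlant]
    transfrags: List[Transfrag]
    transfrag_classes: Dict[str, str]
    manifest: Dict


def condition_fractions(effect: EffectSpec) -> Dict[str, Dict[str, float]]:
    """Resolve per-condition class-fraction vectors from base + overrides.

    Overrides replace class fractions outright.  If the result leaves the
    simplex, the un-overridden classes are rescaled only when
    ``renormalize`` is set; otherwise the spec is rejected — silent
    renormalisation would corrupt the planted truth.
    """
    out: Dict[str, Dict[str, float]] = {}
    for cond in effect.conditions:
        fr = dict(effect.base_fractions)
        over = effect.overrides.get(cond, {})
        for cls, v in over.items():
            if cls not in fr:
                raise ValueError(f"override for unknown class {cls}")
            if v < 0:
                raise ValueError(f"negative fraction for {cls}")
            fr[cls] = v
        total = sum(fr.values())
        if abs(total - 1.0) > 1e-9:
            if not effect.renormalize:
                raise ValueError(
                    f"condition {cond}: fractions sum to {total:.6f}; "
                    "set renormalize=True to rescale un-overridden classes"
                )
            fixed = sum(over.get(c, 0.0) for c in over)
            free = total - fixed
            target_free = 1.0 - fixed
            if target_free < 0 or free <= 0:
                raise ValueError(f"condition {cond}: overrides leave no valid simplex")
            for cls in fr:
                if cls not in over:
                    fr[cls] *= target_free / free
        out[cond] = fr
    return out


def make_two_condition_design(
    truth: SyntheticTruth,
    effect: Optional[EffectSpec] = None,
    index: Optional[PartitionIndex] = None,
) -> DesignBundle:
    """Build the 2x2 sample specs, planted features and expectation manifest.

    Sample ids are replicate+timepoint (A1, B1 at the first condition; A2,
    B2 at the second).  The manifest records, for every statistic the
    pipeline should recover, its expected value and a tolerance bound
    (binomial/delta-method at the 99% level), including the exact
    contribution of planted junction and boundary reads.
    """
    effect = effect or EffectSpec()
    index = index or truth.partition()
    c1, c2 = effect.conditions
    fracs = condition_fractions(effect)
    plants = plan_junctions(truth, index, effect.junctions, effect.conditions)
    tfs, tf_classes = plant_transfrags(truth, effect.transfrags)

    specs: Dict[str, SampleSpec] = {}
    design: Dict[str, Tuple[str, str]] = {}
    for ci, cond in enumerate(effect.conditions, start=1):
        for ri, rep in enumerate(effect.replicates):
            sid = f"{rep}{ci}"
            seed = (effect.seed * 1_000_003 + ci * 101 + ri * 17) % (2**31 - 1)
            specs[sid] = SampleSpec(
                sample_id=sid, condition=cond, replicate=rep,
                n_reads=effect.n_reads, fractions=fracs[cond], seed=seed,
                antisense=dict(effect.antisense),
                family_weights=dict(effect.family_weights),
                family_antisense=dict(effect.family_antisense),
                n_rrna=effect.n_rrna, n_multimap=effect.n_multimap,
                boundary_rate=effect.boundary_rate,
                read_length=effect.read_length,
            )
            design[sid] = (cond, rep)

    # exact planted-read class contributions per sample
    extras: Dict[str, Dict[str, int]] = {sid: {} for sid in specs}
    for sid, spec in specs.items():
        for plant in plants:
            for read in plant_reads(plant, spec.condition, spec.replicate, effect.replicates, effect.read_length):
                lab = _majority_label(read.chrom, read.blocks, index).split(":")[0]
                extras[sid][lab] = extras[sid].get(lab, 0) + 1

    manifest: Dict = {
        "conditions": {cond: fracs[cond] for cond in effect.conditions},
        "n_reads_per_sample": effect.n_reads,
        "expected_fraction": {},
        "expected_significant": [],
        "expected_not_significant": [],
        "repeat": {"fold_change": {}, "as_ratio": {}},
        "junctions": {
            "shared": effect.junctions.n_shared,
            f"{c1}_exclusive": effect.junctions.n_t1_exclusive,
            f"{c2}_exclusive": effect.junctions.n_t2_exclusive,
            "decoys": effect.junctions.n_decoy_single + effect.junctions.n_decoy_overhang,
            "known": sum(1 for p in plants if p.group == "known"),
        },
        "concordance": {},
        "transfrags": {
            "intronic": effect.transfrags.n_intronic,
            "intergenic": effect.transfrags.n_intergenic,
            "other": effect.transfrags.n_other,
        },
    }

    # expected fractions (pooled per condition) with planted extras folded in
    eff_frac: Dict[str, Dict[str, float]] = {}
    for cond in effect.conditions:
        sids = [s for s, (c, _r) in design.items() if c == cond]
        n_draw = effect.n_reads * len(sids)
        extra_by_class: Dict[str, int] = {}
        for sid in sids:
            for cls, n in extras[sid].items():
                extra_by_class[cls] = extra_by_class.get(cls, 0) + n
        n_total = n_draw + sum(extra_by_class.values())
        per_class = {}
        for cls in DRAW_CLASSES:
            p = fracs[cond].get(cls, 0.0)
            exp = (n_draw * p + extra_by_class.get(cls, 0)) / n_total
            tol = Z99 * float(np.sqrt(max(p * (1 - p), 1e-12) / n_draw))
            per_class[cls] = {"expected": exp, "tol": tol}
        manifest["expected_fraction"][cond] = per_class
        eff_frac[cond] = {cls: v["expected"] for cls, v in per_class.items()}

    # power classification per class: z statistic within one replicate
    n_rep = effect.n_reads
    for cls in DRAW_CLASSES:
        p1, p2 = eff_frac[c1][cls], eff_frac[c2][cls]
        pbar = (p1 + p2) / 2
        if pbar <= 0:
            continue
        se = float(np.sqrt(pbar * (1 - pbar) * 2 / n_rep))
        z = abs(p2 - p1) / se
        if z > 6:
            manifest["expected_significant"].append(cls)
        elif z < 1.5:
            manifest["expected_not_significant"].append(cls)

    # repeat-family expectations
    fams = sorted(effect.family_weights)
    wsum = sum(effect.family_weights.values())
    for fam in fams + ["Tot"]:
        share = (effect.family_weights.get(fam, 0.0) / wsum) if fam != "Tot" else 1.0
        f1 = fracs[c1][REPEAT_LABEL] * share
        f2 = fracs[c2][REPEAT_LABEL] * share
        if f1 > 0:
            n1 = 2 * effect.n_reads * f1
            n2 = 2 * effect.n_reads * f2
            fc = f2 / f1
            sd = fc * float(np.sqrt((1 - f1) / max(n1, 1) + (1 - f2) / max(n2, 1)))
            manifest["repeat"]["fold_change"][fam] = {"expected": fc, "tol": Z99 * sd}
        if fam != "Tot":
            pa = effect.family_antisense.get(fam, 0.5)
            manifest["repeat"]["as_ratio"][fam] = {}
            for cond in effect.conditions:
                nf = 2 * effect.n_reads * fracs[cond][REPEAT_LABEL] * share
                ratio = pa / (1 - pa)
                sd = float(np.sqrt(nf * pa * (1 - pa)) / (nf * (1 - pa) ** 2)) if nf else float("nan")
                manifest["repeat"]["as_ratio"][fam][cond] = {
                    "expected": ratio, "tol": Z99 * sd if nf else float("nan")
                }

    # annotation-level concordance truth (no sampling involved)
    cfg = truth.config
    for fam, n in sorted(cfg.n_intronic_repeats.items()):
        conc = sum(_spread_flags(n, cfg.intronic_concordance.get(fam, 0.5)))
        manifest["concordance"][fam] = conc / n if n else float("nan")

    return DesignBundle(specs, design, plants, tfs, tf_classes, manifest)
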