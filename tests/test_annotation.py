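"""Gene collapsing, partition construction and repeat overlay behaviour."""

import numpy as np
import pytest

from strandscape.annotation import (
    GenomicInterval,
    RegionClass,
    build_partition,
    collapse_gene,
    load_gene_models,
    load_repeats,
)

from oracles import CODES, paint_partition


class TestCollapse:
    def test_isoform_union_and_intron_complement(self):
        g = collapse_gene(
            "g", "chr", "+",
            exons=[(0, 100), (200, 300), (0, 100), (250, 400)],
            cds=[(0, 100), (200, 300), (250, 400)],
        )
        assert g.exonic == [(0, 100), (200, 400)]
        assert g.introns == [(100, 200)]

    def test_single_exon_gene_has_no_introns(self):
        g = collapse_gene("g", "chr", "+", exons=[(10, 500)], cds=[(50, 400)])
        assert g.introns == []
        assert g.utr5 == [(10, 50)] and g.utr3 == [(400, 500)]

    def test_utr_sides_respect_minus_strand(self):
        g = collapse_gene("g", "chr", "-", exons=[(0, 300)], cds=[(100, 200)])
        assert g.utr5 == [(200, 300)] and g.utr3 == [(0, 100)]

    def test_collapse_is_idempotent(self):
        g = collapse_gene("g", "chr", "+", exons=[(0, 100), (200, 400)], cds=[(50, 100)])
        again = collapse_gene(g.gene_id, g.chrom, g.strand, g.exonic, g.cds)
        assert again == g

    def test_gene_without_exons_rejected(self):
        with pytest.raises(ValueError):
            collapse_gene("g", "chr", "+", exons=[], cds=[])


class TestLoadGeneModels:
    def test_rrna_biotype_goes_to_rrna_list(self, genome_dir):
        genes, rrna = load_gene_models(str(genome_dir / "genes.gtf"))
        ids = {g.gene_id for g in genes}
        assert "rrna1" not in ids
        assert len(rrna) == 1 and (rrna[0].start, rrna[0].end) == (23000, 23500)

    def test_isoforms_merge_per_gene(self, genome_dir):
        genes, _ = load_gene_models(str(genome_dir / "genes.gtf"))
        g01 = next(g for g in genes if g.gene_id == "g01")
        assert g01.exonic == [(5000, 5800), (8000, 9000), (11000, 13000)]
        assert g01.introns == [(5800, 8000), (9000, 11000)]


class TestBuildPartition:
    def test_lone_gene_flanks_and_intergenic(self):
        g = collapse_gene("g", "chr", "+", exons=[(5000, 8000)], cds=[(5000, 8000)])
        idx = build_partition([g], [], {"chr": 20000})
        assert idx.lookup("chr", 4500) == (RegionClass.UP1K, "g", "+")
        assert idx.lookup("chr", 8500) == (RegionClass.DOWN1K, "g", "+")
        assert idx.lookup("chr", 3999)[0] == RegionClass.INTERGENIC
        assert idx.lookup("chr", 9000)[0] == RegionClass.INTERGENIC
        assert idx.class_lengths[RegionClass.UP1K] == 1000
        assert idx.class_lengths[RegionClass.DOWN1K] == 1000

    def test_close_genes_leave_no_intergenic_gap(self):
        a = collapse_gene("a", "chr", "+", exons=[(2000, 3000)], cds=[(2000, 3000)])
        b = collapse_gene("b", "chr", "+", exons=[(3500, 4500)], cds=[(3500, 4500)])
        idx = build_partition([a, b], [], {"chr": 10000})
        gap_classes = {idx.lookup("chr", p)[0] for p in range(3000, 3500)}
        assert RegionClass.INTERGENIC not in gap_classes
        assert gap_classes <= {RegionClass.UP1K, RegionClass.DOWN1K}

    def test_class_lengths_partition_the_genome(self, index):
        assert sum(index.class_lengths.values()) == index.genome_length

    def test_gene_order_never_changes_partition(self, truth):
        genes = truth.collapsed_genes()
        rrna = truth.rrna_intervals()
        a = build_partition(genes, rrna, truth.chrom_sizes)
        b = build_partition(list(reversed(genes)), rrna, truth.chrom_sizes)
        assert a.to_frame().equals(b.to_frame())

    def test_matches_per_base_painting_oracle(self, truth, index):
        classes, _ = paint_partition(
            truth.collapsed_genes(), truth.rrna_intervals(), truth.chrom_sizes
        )
        rng = np.random.default_rng(0)
        for chrom, size in truth.chrom_sizes.items():
            for pos in rng.integers(0, size, size=1500):
                cls, _g, _s = index.lookup(chrom, int(pos))
                assert int(cls) == classes[chrom][pos]

    def test_interval_beyond_chromosome_rejected(self):
        g = collapse_gene("g", "chr", "+", exons=[(5000, 8000)], cds=[])
        with pytest.raises(ValueError):
            build_partition([g], [], {"chr": 6000})

    def test_flank_precedence_never_covers_exons(self, index):
        # g05/g06 are 800 bp apart: g06's upstream flank abuts g05's gene body
        cls, gid, _ = index.lookup("chr1", 98990)
        assert cls in (RegionClass.CDS, RegionClass.UTR3) and gid == "g05"
        assert index.lookup("chr1", 99100)[0] in (RegionClass.UP1K, RegionClass.DOWN1K)


class TestRepeatOverlay:
    def test_host_class_by_majority(self, genome_dir, tmp_path, truth):
        genes, rrna = load_gene_models(str(genome_dir / "genes.gtf"))
        idx = build_partition(genes, rrna, truth.chrom_sizes)
        # g03 intron1 = [26600, 56000): 60% of this repeat is intronic
        bed = tmp_path / "r.bed"
        bed.write_text("chr1\t55940\t56040\tL1\t0\t+\n")
        overlay = load_repeats(str(bed), idx)
        assert overlay.entries[0].host_class == RegionClass.INTRON
        assert overlay.entries[0].host_gene == "g03"

    def test_planted_repeats_recover_truth_hosts(self, genome_dir, truth, index):
        overlay = load_repeats(str(genome_dir / "repeats.bed"), index)
        assert len(overlay.entries) == len(truth.repeats)
        for entry, planted in zip(overlay.entries, truth.repeats):
            assert entry.host_class.name == planted["host_class"]
            assert entry.strand == planted["strand"]
            assert entry.host_gene == planted["host_gene"]

    def test_strandless_repeat_rejected(self, tmp_path, index):
        bed = tmp_path / "r.bed"
        bed.write_text("chr1\t100\t200\tL1\t0\t.\n")
        with pytest.raises(ValueError):
            load_repeats(str(bed), index)

    def test_empty_bed_gives_empty_overlay(self, tmp_path, truth):
        idx = truth.partition()
        bed = tmp_path / "empty.bed"
        bed.write_text("")
        overlay = load_repeats(str(bed), idx)
        assert overlay.entries == [] and overlay.merged_length() == 0
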