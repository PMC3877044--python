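"""Read filtering, majority-rule assignment and counting."""

import numpy as np
import pytest

from strandscape.annotation import REPEAT_LABEL, RegionClass
from strandscape.assignment import (
    AlignedRead,
    assign_read,
    count_by_region,
    filter_reads,
    read_alignment_tsv,
)
from strandscape.synthetic import SampleSpec, simulate_reads, write_alignment_tsv, write_sam

from oracles import oracle_assign, paint_partition, paint_repeats


def _spec(n_reads, seed=3, **kw):
    fractions = {
        "CDS": 0.30, "UTR5": 0.03, "UTR3": 0.05, "INTRON": 0.17,
        "UP1K": 0.05, "DOWN1K": 0.05, "INTERGENIC": 0.25, REPEAT_LABEL: 0.10,
    }
    return SampleSpec("s1", "T1", "A", n_reads, fractions, seed, **kw)


class TestFilter:
    def test_drop_reasons_are_tallied(self, index):
        reads = [
            AlignedRead("multi", "chr1", [(5100, 5150)], "+", nh=2),
            AlignedRead("ribo", "chr1", [(23100, 23150)], "+", nh=1),
            AlignedRead("keep", "chr1", [(5450, 5500)], "+", nh=1),
        ]
        retained, tallies = filter_reads(reads, index)
        assert [r.read_id for r in retained] == ["keep"]
        assert tallies.nonunique_removed == 1 and tallies.rrna_removed == 1
        assert tallies.input_alignments == 3 and tallies.retained == 1

    def test_mapq_fallback_when_nh_absent(self, index):
        low = AlignedRead("low", "chr1", [(5450, 5500)], "+", nh=None, mapq=3)
        high = AlignedRead("high", "chr1", [(5450, 5500)], "+", nh=None, mapq=30)
        retained, tallies = filter_reads([low, high], index, mapq_min=10)
        assert [r.read_id for r in retained] == ["high"]

    def test_empty_input_is_not_an_error(self, index):
        retained, tallies = filter_reads([], index)
        assert retained == [] and tallies.input_alignments == 0


class TestAssign:
    def test_pure_cds_read_is_sense(self, index):
        # g01 CDS on the plus strand
        a = assign_read(AlignedRead("r", "chr1", [(5450, 5500)], "+", nh=1), index)
        assert (a.region, a.orientation, a.gene_id) == ("CDS", "sense", "g01")

    def test_majority_wins_on_boundary_read(self, index):
        # 30 bases in g01 intron1 [5800, 8000), 20 bases in CDS
        a = assign_read(AlignedRead("r", "chr1", [(5780, 5830)], "+", nh=1), index)
        assert a.region == "INTRON"

    def test_antisense_repeat_hit(self, index):
        rep = next(r for r in index.repeats.entries if r.strand == "+" and r.family == "L1")
        flip = "-"
        a = assign_read(AlignedRead("r", rep.chrom, [(rep.start + 10, rep.start + 60)], flip, nh=1), index)
        assert (a.region, a.family, a.orientation) == (REPEAT_LABEL, "L1", "antisense")
        assert a.host_class == rep.host_class.name

    def test_unknown_chromosome_is_an_error(self, index):
        with pytest.raises(KeyError):
            assign_read(AlignedRead("r", "chrX", [(0, 50)], "+", nh=1), index)

    def test_matches_per_base_oracle_read_for_read(self, truth, index):
        classes, strands = paint_partition(
            truth.collapsed_genes(), truth.rrna_intervals(), truth.chrom_sizes
        )
        rep_arr = paint_repeats(truth.repeats, truth.chrom_sizes)
        reads, _st = simulate_reads(truth, index, _spec(800, boundary_rate=0.05), plants=())
        retained, _t = filter_reads(reads, index)
        for read in retained:
            a = assign_read(read, index)
            label, family, orient = oracle_assign(read, classes, strands, rep_arr, truth.repeats)
            assert (a.region, a.family, a.orientation) == (label, family, orient)

    def test_strand_flip_swaps_orientations(self, truth, index):
        reads, _st = simulate_reads(truth, index, _spec(500, seed=5), plants=())
        retained, _t = filter_reads(reads, index)
        fwd = count_by_region([assign_read(r, index) for r in retained], "s")
        flipped = [
            AlignedRead(r.read_id, r.chrom, r.blocks, "-" if r.strand == "+" else "+", r.nh)
            for r in retained
        ]
        rev = count_by_region([assign_read(r, index) for r in flipped], "s")
        swap = {"sense": "antisense", "antisense": "sense", "plus": "minus", "minus": "plus"}
        assert rev.counts == {(reg, swap[o]): n for (reg, o), n in fwd.counts.items()}


class TestCounting:
    def test_tally_and_conservation(self, index):
        reads = [AlignedRead(f"c{i}", "chr1", [(5450, 5500)], "+", nh=1) for i in range(6)]
        reads += [AlignedRead(f"i{i}", "chr1", [(10000, 10050)], "+", nh=1) for i in range(4)]
        rc = count_by_region([assign_read(r, index) for r in reads], "s")
        assert rc.counts[("CDS", "sense")] == 6
        assert rc.counts[("INTRON", "sense")] == 4
        assert rc.total_retained == 10 and rc.check_conservation()

    def test_empty_stream_gives_zero_counts(self):
        rc = count_by_region([], "s")
        assert rc.total_retained == 0 and rc.counts == {}

    def test_order_invariance(self, truth, index):
        reads, _st = simulate_reads(truth, index, _spec(300, seed=9), plants=())
        retained, _t = filter_reads(reads, index)
        a = count_by_region([assign_read(r, index) for r in retained], "s")
        b = count_by_region([assign_read(r, index) for r in reversed(retained)], "s")
        assert a.counts == b.counts and a.repeat_counts == b.repeat_counts


class TestRoundTrips:
    def test_sam_round_trip_preserves_counts(self, truth, index, tmp_path):
        reads, _st = simulate_reads(truth, index, _spec(400, seed=11, n_rrna=20, n_multimap=10), plants=())
        direct, t1 = filter_reads(reads, index)
        sam = tmp_path / "s.sam"
        write_sam(reads, truth.chrom_sizes, sam)
        from_sam, t2 = filter_reads(str(sam), index)
        assert t2.retained == t1.retained
        assert t2.rrna_removed == t1.rrna_removed
        assert t2.nonunique_removed == t1.nonunique_removed
        a = count_by_region([assign_read(r, index) for r in direct], "s")
        b = count_by_region([assign_read(r, index) for r in from_sam], "s")
        assert a.counts == b.counts and a.repeat_counts == b.repeat_counts

    def test_tsv_round_trip(self, tmp_path):
        reads = [
            AlignedRead("a", "chr1", [(10, 40), (100, 120)], "+", nh=1),
            AlignedRead("b", "chr2", [(5, 55)], "-", nh=None, mapq=7),
        ]
        path = tmp_path / "r.tsv"
        write_alignment_tsv(reads, path)
        back = read_alignment_tsv(str(path))
        assert back == reads
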