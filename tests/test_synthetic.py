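"""Generator determinism, construction guarantees and truth-label fidelity."""

import filecmp

import numpy as np
import pytest

from strandscape.annotation import REPEAT_LABEL, RegionClass
from strandscape.assignment import assign_read, filter_reads
from strandscape.synthetic import (
    EffectSpec,
    SampleSpec,
    ToyGenomeConfig,
    build_toy_genome,
    condition_fractions,
    make_two_condition_design,
    simulate_reads,
    write_sam,
)

FRACTIONS = {
    "CDS": 0.30, "UTR5": 0.03, "UTR3": 0.05, "INTRON": 0.17,
    "UP1K": 0.05, "DOWN1K": 0.05, "INTERGENIC": 0.25, REPEAT_LABEL: 0.10,
}


class TestToyGenome:
    def test_same_config_gives_byte_identical_files(self, tmp_path):
        build_toy_genome(tmp_path / "a")
        build_toy_genome(tmp_path / "b")
        for name in ("genes.gtf", "repeats.bed", "chrom.sizes", "truth.json"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False)

    def test_construction_guarantees(self, truth):
        genes = {g.gene_id: g for g in truth.collapsed_genes()}
        multi = [gid for gid, _c, _s, _b, txs in truth.gene_templates if len(txs) > 1]
        assert multi  # at least one multi-isoform gene
        assert any(not g.introns for g in genes.values())  # single-exon gene
        assert truth.rrna_intervals()
        for fam in ("L1", "L2"):
            for host in ("INTRON", "INTERGENIC"):
                strands = {
                    r["strand"] for r in truth.repeats
                    if r["family"] == fam and r["host_class"] == host
                }
                assert strands == {"+", "-"}, (fam, host)
        # flank-collision pair: two genes closer than 2 kb
        spans = sorted((g.span, g.chrom) for g in genes.values())
        gaps = [
            b[0][0] - a[0][1]
            for a, b in zip(spans, spans[1:]) if a[1] == b[1] and b[0][0] >= a[0][1]
        ]
        assert any(0 < gap < 2000 for gap in gaps)

    def test_zero_repeat_config(self, tmp_path):
        truth = build_toy_genome(tmp_path, ToyGenomeConfig(include_repeats=False))
        assert truth.repeats == []
        assert (tmp_path / "repeats.bed").read_text() == ""

    def test_infeasible_layout_rejected(self):
        cfg = ToyGenomeConfig(chrom_sizes={"chr1": 50_000, "chr2": 100_000})
        with pytest.raises(ValueError):
            build_toy_genome(config=cfg)


class TestSimulation:
    def test_seed_determinism(self, truth, index, tmp_path):
        spec = SampleSpec("s", "T1", "A", 1000, FRACTIONS, seed=5)
        r1, _ = simulate_reads(truth, index, spec)
        r2, _ = simulate_reads(truth, index, spec)
        assert r1 == r2
        write_sam(r1, truth.chrom_sizes, tmp_path / "a.sam")
        write_sam(r2, truth.chrom_sizes, tmp_path / "b.sam")
        assert filecmp.cmp(tmp_path / "a.sam", tmp_path / "b.sam", shallow=False)
        r3, _ = simulate_reads(truth, index, SampleSpec("s", "T1", "A", 1000, FRACTIONS, seed=6))
        assert r3 != r1

    def test_realized_fractions_within_binomial_bounds(self, truth, index):
        n = 10_000
        spec = SampleSpec("s", "T1", "A", n, FRACTIONS, seed=17)
        _reads, st = simulate_reads(truth, index, spec)
        p = FRACTIONS["INTRON"]
        ci = 2.576 * np.sqrt(n * p * (1 - p))
        assert abs(st.drawn_counts["INTRON"] - n * p) < ci

    def test_zero_antisense_probability_is_respected(self, truth, index):
        anti = {k: 0.0 for k in FRACTIONS}
        spec = SampleSpec("s", "T1", "A", 2000, FRACTIONS, seed=2, antisense=anti)
        reads, st = simulate_reads(truth, index, spec)
        for read in reads:
            if st.labels[read.read_id] == "CDS":
                a = assign_read(read, index)
                assert a.orientation == "sense"

    def test_truth_labels_agree_with_assignment(self, truth, index):
        spec = SampleSpec("s", "T1", "A", 2000, FRACTIONS, seed=8,
                          boundary_rate=0.02, n_rrna=20, n_multimap=10)
        reads, st = simulate_reads(truth, index, spec)
        retained, tallies = filter_reads(reads, index)
        assert tallies.nonunique_removed == 10
        assert tallies.rrna_removed == 20  # every rRNA read placed fully inside the gene
        boundary = set(st.boundary_reads)
        mismatches = []
        for read in retained:
            a = assign_read(read, index)
            got = f"{REPEAT_LABEL}:{a.family}" if a.region == REPEAT_LABEL else a.region
            if got != st.labels[read.read_id]:
                mismatches.append(read.read_id)
        # pure placements must agree exactly; only boundary reads may deviate
        assert all(rid in boundary for rid in mismatches)
        assert len(mismatches) / max(len(retained), 1) < 0.01


class TestDesign:
    def test_override_off_simplex_rejected_without_renormalize(self):
        effect = EffectSpec(overrides={"T2": {"CDS": 0.50}})
        with pytest.raises(ValueError, match="renormalize"):
            condition_fractions(effect)

    def test_explicit_renormalization_rescales_untouched(self):
        effect = EffectSpec(overrides={"T2": {"CDS": 0.50}}, renormalize=True)
        fr = condition_fractions(effect)
        assert sum(fr["T2"].values()) == pytest.approx(1.0)
        assert fr["T2"]["CDS"] == 0.50
        ratio = fr["T2"]["INTRON"] / fr["T1"]["INTRON"]
        assert fr["T2"]["INTERGENIC"] / fr["T1"]["INTERGENIC"] == pytest.approx(ratio)

    def test_default_design_expectations(self, truth, index):
        bundle = make_two_condition_design(truth, EffectSpec(seed=1), index)
        man = bundle.manifest
        assert set(man["expected_significant"]) == {"CDS", "INTRON", REPEAT_LABEL}
        assert "INTERGENIC" in man["expected_not_significant"]
        assert man["junctions"]["shared"] == 100
        assert man["concordance"] == {"L1": 0.34, "L2": 0.44}

    def test_seed_changes_reads_not_manifest(self, truth, index):
        b1 = make_two_condition_design(truth, EffectSpec(seed=1, n_reads=500), index)
        b2 = make_two_condition_design(truth, EffectSpec(seed=2, n_reads=500), index)
        assert b1.manifest == b2.manifest
        r1, _ = simulate_reads(truth, index, b1.specs["A1"], b1.plants)
        r2, _ = simulate_reads(truth, index, b2.specs["A1"], b2.plants)
        assert r1 != r2
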