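"""Distribution profiles, proportion tests and replicate correlation."""

import math

import numpy as np
import pandas as pd
import pytest

from strandscape.annotation import REPEAT_LABEL, RegionClass
from strandscape.assignment import (
    AlignedRead,
    CoverageTracker,
    RegionCounts,
    assign_read,
    count_by_region,
)
from strandscape.landscape import (
    profile_sample,
    proportion_comparison,
    replicate_correlation,
    two_proportion_test,
)

from oracles import yates_two_proportion


class TestProfile:
    def test_density_formula(self, index):
        reads = [AlignedRead(f"r{i}", "chr1", [(5450, 5500)], "+", nh=1) for i in range(10)]
        rc = count_by_region([assign_read(r, index) for r in reads], "s")
        prof = profile_sample(rc, index, read_length=50)
        assert prof.density["CDS"] == pytest.approx(
            10 * 50 / index.class_lengths[RegionClass.CDS]
        )
        assert prof.fraction["CDS"] == 1.0

    def test_fractions_sum_to_one(self, truth, index):
        from strandscape.synthetic import SampleSpec, simulate_reads

        fr = {"CDS": 0.4, "INTRON": 0.3, "INTERGENIC": 0.2, REPEAT_LABEL: 0.1}
        reads, _ = simulate_reads(truth, index, SampleSpec("s", "T1", "A", 2000, fr, 5))
        rc = count_by_region([assign_read(r, index) for r in reads], "s")
        prof = profile_sample(rc, index)
        assert sum(prof.fraction.values()) == pytest.approx(1.0, abs=1e-9)

    def test_covered_fraction_counts_bases_once(self, index):
        cov = CoverageTracker(index.chrom_sizes)
        # tile 100 bases of CDS twice over; covered bases still 100
        for s in range(5450, 5550, 25):
            cov.add(AlignedRead(f"r{s}", "chr1", [(s, s + 50)], "+", nh=1))
        covered = cov.covered_by_class(index)
        assert covered["CDS"] == 125  # overlapping 50-mers tile [5450, 5575) once
        rc = RegionCounts("s", counts={("CDS", "sense"): 4}, total_retained=4)
        prof = profile_sample(rc, index, coverage=cov)
        assert prof.covered_fraction["CDS"] == pytest.approx(
            covered["CDS"] / index.class_lengths[RegionClass.CDS]
        )

    def test_as_ratio_and_undefined_marker(self, index):
        rc = RegionCounts(
            "s",
            counts={("INTRON", "sense"): 100, ("INTRON", "antisense"): 300,
                    ("UTR5", "antisense"): 7},
            total_retained=407,
        )
        prof = profile_sample(rc, index)
        assert prof.as_ratio["INTRON"] == pytest.approx(3.0)
        assert math.isnan(prof.as_ratio["UTR5"])  # zero sense reads

    def test_bad_read_length_rejected(self, index):
        rc = RegionCounts("s", counts={("CDS", "sense"): 1}, total_retained=1)
        with pytest.raises(ValueError):
            profile_sample(rc, index, read_length=0)


class TestTwoProportion:
    def test_equal_proportions_give_p_one(self):
        stat, p = two_proportion_test(30, 100, 60, 200)
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n1, n2 = rng.integers(10, 5000, size=2)
            x1 = int(rng.integers(0, n1 + 1))
            x2 = int(rng.integers(0, n2 + 1))
            stat, p = two_proportion_test(x1, int(n1), x2, int(n2))
            ostat, op = yates_two_proportion(x1, int(n1), x2, int(n2))
            assert stat == pytest.approx(ostat, abs=1e-10)
            assert p == pytest.approx(op, abs=1e-10)

    def test_headline_contrast_is_significant(self):
        _stat, p = two_proportion_test(355, 1000, 300, 1000)
        assert p < 0.05

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            two_proportion_test(1, 0, 1, 10)
        with pytest.raises(ValueError):
            two_proportion_test(11, 10, 1, 10)


class TestConcordanceRule:
    def test_discordant_replicates_not_significant(self):
        xn = {
            ("T1", "A"): (100, 1000), ("T2", "A"): (200, 1000),  # strong shift
            ("T1", "B"): (150, 1000), ("T2", "B"): (150, 1000),  # none
        }
        res = proportion_comparison(xn)
        assert not res.significant
        assert res.p_reported == max(res.p_per_replicate.values())
        assert res.p_per_replicate["A"] < 0.05 < res.p_per_replicate["B"]

    def test_condition_swap_preserves_p_and_inverts_fold(self):
        xn = {("T1", "A"): (120, 1000), ("T2", "A"): (180, 1000),
              ("T1", "B"): (110, 1000), ("T2", "B"): (170, 1000)}
        fwd = proportion_comparison(xn)
        swapped = {("T1" if c == "T2" else "T2", r): v for (c, r), v in xn.items()}
        rev = proportion_comparison(swapped)
        assert rev.p_reported == pytest.approx(fwd.p_reported)
        assert rev.fold_change_merged == pytest.approx(1 / fwd.fold_change_merged)

    def test_null_flag_rate_below_alpha(self):
        # compound both-replicates rule is conservative: empirical null rate
        # should be far below alpha (roughly alpha squared)
        rng = np.random.default_rng(7)
        n, p, sims = 2000, 0.2, 500
        flags = 0
        for _ in range(sims):
            xn = {
                (c, r): (int(rng.binomial(n, p)), n)
                for c in ("T1", "T2") for r in ("A", "B")
            }
            if proportion_comparison(xn).significant:
                flags += 1
        assert flags / sims < 0.05

    def test_zero_total_rejected(self):
        xn = {("T1", "A"): (0, 0), ("T2", "A"): (1, 10)}
        with pytest.raises(ValueError):
            proportion_comparison(xn)


class TestReplicateCorrelation:
    def test_self_and_scaled_correlations_are_one(self):
        x = pd.Series([3, 10, 40, 7, 100, 2], dtype=float)
        mat = pd.DataFrame({"a": x, "b": x, "c": 2 * x})
        corr = replicate_correlation(mat, log_offset=0)  # pure scaling: exact in log space
        assert corr.loc["a", "a"] == pytest.approx(1.0)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(1.0)

    def test_constant_vector_is_undefined(self):
        mat = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        corr = replicate_correlation(mat)
        assert math.isnan(corr.loc["a", "b"])

    def test_independent_counts_near_zero(self):
        rng = np.random.default_rng(11)
        mat = pd.DataFrame({
            "a": rng.poisson(20, size=1000).astype(float),
            "b": rng.poisson(20, size=1000).astype(float),
        })
        corr = replicate_correlation(mat)
        assert abs(corr.loc["a", "b"]) < 0.1

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            replicate_correlation(pd.DataFrame({"a": [1, 2]}))
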