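import numpy as np
import pandas as pd
import pytest

from aidnipt.baselines import (DegenerateReferenceError, NCV_DENOMINATORS,
                               ReferenceStats, adjust_counts,
                               adjusted_chrom_counts, build_reference,
                               chrom_fraction, ncv_ratio, ncv_score, z_score)
from aidnipt.simulate import SimConfig, simulate_bin_counts


class TestAdjustCounts:
    def test_uniform_bias_free_sample_unchanged(self):
        counts = np.full(50, 120.0)
        gc = np.full(50, 40.0)
        mp = np.full(50, 100.0)
        np.testing.assert_allclose(adjust_counts(counts, gc, mp), counts)

    def test_mappability_division(self):
        counts = np.full(20, 100.0)
        gc = np.full(20, 40.0)
        mp = np.full(20, 100.0)
        mp[3] = 50.0
        adjusted = adjust_counts(counts, gc, mp)
        assert adjusted[3] == pytest.approx(2 * adjusted[0])

    def test_quadratic_gc_bias_removed(self, study_genome, study_bins):
        """After correction, the count-on-GC regression slope collapses."""
        cfg = SimConfig(genome=study_genome, n_fragments=400_000, seed=17)
        counts = simulate_bin_counts(cfg, study_bins)
        bt = study_bins.table
        keep = bt["retained"].to_numpy()
        raw = counts[keep].astype(float)
        gc = bt["gc"].to_numpy()[keep]
        mp = bt["mappability"].to_numpy()[keep]
        adjusted = adjust_counts(raw, gc, mp)
        slope_raw = abs(np.polyfit(gc, raw / raw.mean(), 1)[0])
        slope_adj = abs(np.polyfit(gc, adjusted / adjusted.mean(), 1)[0])
        assert slope_adj < slope_raw / 5
        assert slope_adj < 1e-3

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            adjust_counts(np.zeros(10), np.full(10, 40.0), np.full(10, 100.0))


class TestChromFraction:
    def test_fractions_sum_to_one(self):
        adjusted = pd.Series({"chr1": 250.0, "chr2": 240.0, "chr21": 50.0})
        assert chrom_fraction(adjusted).sum() == pytest.approx(1.0)

    def test_uniform_coverage_gives_bin_share(self, study_bins):
        bt = study_bins.table
        counts = np.where(bt["retained"], 100.0, 0.0)
        adjusted = pd.Series(counts[bt["retained"]]).groupby(
            bt.loc[bt["retained"], "chrom"].to_numpy()).sum()
        frac = chrom_fraction(adjusted)
        share_bins = (bt["retained"] & (bt["chrom"] == "chr21")).sum() / bt["retained"].sum()
        assert frac["chr21"] == pytest.approx(share_bins)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            chrom_fraction(pd.Series({"chr1": 0.0}))


def _ref(method="z", mean=0.015, sd=0.001):
    return ReferenceStats(method=method, mean={"chr21": mean, "chr18": 0.02,
                                               "chr13": 0.03},
                          sd={"chr21": sd, "chr18": sd, "chr13": sd},
                          cohort_size=100)


class TestReference:
    def _cohort(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        return [pd.Series({c: v for c, v in zip(
            [f"chr{i}" for i in range(1, 23)],
            rng.uniform(50, 150, 22))}) for _ in range(n)]

    def test_mean_sd_match_two_pass_oracle(self):
        cohort = self._cohort()
        ref = build_reference(cohort, "z")
        vals = [chrom_fraction(a)["chr21"] for a in cohort]
        mean = sum(vals) / len(vals)
        sd = (sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)) ** 0.5
        assert ref.mean["chr21"] == pytest.approx(mean)
        assert ref.sd["chr21"] == pytest.approx(sd)
        assert ref.cohort_size == 100

    def test_self_standardization(self):
        """Reference z-scored against itself: sample mean 0, sample SD 1."""
        cohort = self._cohort(seed=5)
        ref = build_reference(cohort, "z")
        scores = np.array([z_score(a, ref, "chr21")[0] for a in cohort])
        assert scores.mean() == pytest.approx(0.0, abs=1e-10)
        assert scores.std(ddof=1) == pytest.approx(1.0)

    def test_identical_cohort_is_degenerate(self):
        sample = pd.Series({f"chr{i}": 100.0 for i in range(1, 23)})
        with pytest.raises(DegenerateReferenceError):
            build_reference([sample.copy() for _ in range(10)], "z")

    def test_cohort_of_one_rejected(self):
        with pytest.raises(DegenerateReferenceError):
            build_reference(self._cohort(n=1), "z")

    def test_json_roundtrip(self):
        ref = build_reference(self._cohort(), "ncv")
        back = ReferenceStats.from_dict(ref.to_dict())
        assert back.mean == ref.mean and back.sd == ref.sd


class TestScores:
    def test_sample_at_reference_mean_scores_zero(self):
        adjusted = pd.Series({"chr21": 0.015, "rest": 0.985})
        score, call = z_score(adjusted, _ref(), "chr21")
        assert score == pytest.approx(0.0) and not call

    @pytest.mark.parametrize("z, expected_call", [
        (3.0, True),    # boundary is inclusive
        (3.5, True),
        (2.57, False),  # a near-cutoff score stays a negative call
        (2.46, False),
        (0.0, False),
    ])
    def test_cutoff_three_boundary(self, z, expected_call):
        # dyadic mean/SD so the z = 3 boundary case is float-exact
        ref = _ref(mean=0.25, sd=0.125)
        x = ref.mean["chr21"] + z * ref.sd["chr21"]
        adjusted = pd.Series({"chr21": x, "rest": 1.0 - x})  # fraction == x
        score, call = z_score(adjusted, ref, "chr21")
        assert score == pytest.approx(z)
        assert bool(call) is expected_call

    def test_scale_invariance(self, study_genome, study_bins):
        cfg = SimConfig(genome=study_genome, n_fragments=200_000, seed=21)
        counts = simulate_bin_counts(cfg, study_bins)
        a1 = adjusted_chrom_counts(counts, study_bins)
        a2 = adjusted_chrom_counts(counts * 7, study_bins)
        ref_z, ref_n = _ref("z"), _ref("ncv", mean=0.1)
        assert z_score(a1, ref_z, "chr21")[0] == pytest.approx(
            z_score(a2, ref_z, "chr21")[0], rel=1e-9)
        assert ncv_score(a1, ref_n, "chr21")[0] == pytest.approx(
            ncv_score(a2, ref_n, "chr21")[0], rel=1e-9)

    def test_ncv_denominators_manual_oracle(self):
        adjusted = pd.Series({f"chr{i}": float(i) for i in range(1, 23)})
        assert ncv_ratio(adjusted, "chr21") == pytest.approx(21.0 / 9.0)
        assert ncv_ratio(adjusted, "chr18") == pytest.approx(18.0 / 8.0)
        assert ncv_ratio(adjusted, "chr13") == pytest.approx(13.0 / (2 + 3 + 4 + 5 + 6))
        assert NCV_DENOMINATORS["chr13"] == ("chr2", "chr3", "chr4", "chr5", "chr6")

    def test_zero_denominator_rejected(self):
        adjusted = pd.Series({"chr21": 5.0, "chr9": 0.0})
        with pytest.raises(ValueError, match="denominator"):
            ncv_ratio(adjusted, "chr21")

    def test_method_mismatch_rejected(self):
        adjusted = pd.Series({"chr21": 0.015})
        with pytest.raises(ValueError):
            ncv_score(adjusted, _ref("z"), "chr21")

    def test_monotone_in_fetal_fraction(self, study_genome, study_bins):
        """The chr21 z-score grows with simulated fetal fraction."""
        cohort = []
        for i in range(30):
            cfg = SimConfig(genome=study_genome, n_fragments=300_000, seed=(88, i))
            cohort.append(adjusted_chrom_counts(simulate_bin_counts(cfg, study_bins),
                                                study_bins))
        ref = build_reference(cohort, "z")
        scores = []
        for f in (0.05, 0.10, 0.20):
            cfg = SimConfig(genome=study_genome, n_fragments=300_000,
                            trisomy="chr21", fetal_fraction=f, seed=(89, 0))
            adj = adjusted_chrom_counts(simulate_bin_counts(cfg, study_bins),
                                        study_bins)
            scores.append(z_score(adj, ref, "chr21")[0])
        assert scores[0] < scores[1] < scores[2]


def test_euploid_false_positive_rate_matches_normal_tail(study_genome, study_bins):
    """At cutoff 3 the euploid FP rate per target is ~ the one-sided
    normal tail (0.135%); checked against a wide binomial band."""
    cohort = []
    for i in range(200):
        cfg = SimConfig(genome=study_genome, n_fragments=150_000, seed=(91, i))
        cohort.append(adjusted_chrom_counts(simulate_bin_counts(cfg, study_bins),
                                            study_bins))
    ref = build_reference(cohort, "z")
    hits = trials = 0
    for i in range(667):
        cfg = SimConfig(genome=study_genome, n_fragments=150_000, seed=(92, i))
        adj = adjusted_chrom_counts(simulate_bin_counts(cfg, study_bins), study_bins)
        for target in ("chr21", "chr18", "chr13"):
            trials += 1
            hits += int(z_score(adj, ref, target)[1])
    # ~2000 trials, expectation ~2.7 under N(0,1); generous Poisson band
    assert hits <= 14


def test_z_power_at_ten_percent_fetal_fraction(study_genome, study_bins):
    """Trisomy-21 at f=0.10 and 1/20-scale depth is detected (Z >= 3)
    in at least 90% of replicates."""
    from aidnipt.study import z_power
    rate = z_power(study_genome, study_bins, seed=13, n_reps=100)
    assert rate >= 0.90
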