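"""Evaluation statistics against independent oracles.

AUC is checked against brute-force enumeration of positive-negative pairs;
the paired DeLong variance against a class-grouped leave-one-out jackknife
of the AUC difference; Clopper-Pearson against its boundary guarantees and
a coverage simulation; the operating point against its counting definition.
"""

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings, strategies as st

from siteshift import stats
from siteshift.stats import (
    ScoredSet,
    auc,
    calibration_summary,
    chi_square_proportions,
    clopper_pearson,
    delong_paired,
    delong_unpaired,
    operating_point_at_sensitivity,
    trivial_prevalence_ranker,
    two_level_ranker_auc,
)


def brute_force_auc(scores, labels):
    """Direct enumeration of all positive-negative pairs; ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


scored_sets = st.integers(min_value=1, max_value=25).flatmap(
    lambda m: st.integers(min_value=1, max_value=25).flatmap(
        lambda n: st.tuples(
            st.lists(st.integers(0, 6), min_size=m + n, max_size=m + n),
            st.just(m),
        )
    )
)


class TestAUC:
    def test_perfect_separation(self):
        est = auc(ScoredSet([3, 4, 5, 0, 1, 2], [1, 1, 1, 0, 0, 0]))
        assert est.auc == 1.0
        assert est.variance == 0.0
        assert est.ci == (1.0, 1.0)

    def test_one_flipped_case_matches_enumeration(self):
        labels = np.array([1] * 5 + [0] * 5)
        scores = labels.astype(float).copy()
        scores[0] = 0.0  # one positive scored like the negatives
        est = auc(ScoredSet(scores, labels))
        assert est.auc == pytest.approx(brute_force_auc(scores, labels))

    @given(scored_sets)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_brute_force_enumeration(self, case):
        values, m = case
        labels = np.array([1] * m + [0] * (len(values) - m))
        est = auc(ScoredSet(np.array(values, dtype=float), labels))
        assert est.auc == pytest.approx(brute_force_auc(values, labels), abs=1e-12)

    def test_two_valued_score_closed_form(self):
        # a site-prevalence ranker takes exactly two values
        rng = np.random.default_rng(0)
        sites = np.array(["hi"] * 300 + ["lo"] * 700)
        scores = np.where(sites == "hi", 0.3, 0.01)
        labels = np.where(
            sites == "hi", rng.random(1000) < 0.3, rng.random(1000) < 0.02
        ).astype(int)
        pos_hi = np.mean(scores[labels == 1] == 0.3)
        neg_hi = np.mean(scores[labels == 0] == 0.3)
        expected = two_level_ranker_auc(pos_hi, neg_hi)
        assert auc(ScoredSet(scores, labels)).auc == pytest.approx(expected, abs=1e-12)
        # the closed form is itself what brute force gives on a subsample
        sub = slice(None, None, 5)
        sub_expected = two_level_ranker_auc(
            np.mean(scores[sub][labels[sub] == 1] == 0.3),
            np.mean(scores[sub][labels[sub] == 0] == 0.3),
        )
        assert brute_force_auc(scores[sub], labels[sub]) == pytest.approx(
            sub_expected, abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc(ScoredSet([1.0, 2.0], [1, 1]))


def grouped_jackknife_delta_var(sa, sb, y):
    """Leave-one-out-within-class jackknife variance of the AUC difference."""
    sa, sb, y = np.asarray(sa, float), np.asarray(sb, float), np.asarray(y, int)

    def delta(mask):
        return (
            stats._structural_components(sa[mask], y[mask])[0]
            - stats._structural_components(sb[mask], y[mask])[0]
        )

    var = 0.0
    for cls in (1, 0):
        idx = np.nonzero(y == cls)[0]
        vals = []
        for i in idx:
            mask = np.ones(len(y), bool)
            mask[i] = False
            vals.append(delta(mask))
        vals = np.asarray(vals)
        var += (len(idx) - 1) / len(idx) * np.sum((vals - vals.mean()) ** 2)
    return var


class TestDeLongPaired:
    y8 = np.array([1, 1, 1, 1, 0, 0, 0, 0])

    def test_identical_scores_null(self):
        s = np.array([0.9, 0.8, 0.4, 0.7, 0.3, 0.2, 0.6, 0.1])
        res = delong_paired(s, s, self.y8)
        assert res.delta_auc == 0.0
        assert res.p == 1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        sa, sb = rng.normal(size=8), rng.normal(size=8)
        ab = delong_paired(sa, sb, self.y8)
        ba = delong_paired(sb, sa, self.y8)
        assert ab.z == pytest.approx(-ba.z)
        assert ab.p == pytest.approx(ba.p)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_variance_matches_grouped_jackknife(self, seed):
        rng = np.random.default_rng(seed)
        sa = rng.normal(size=8)
        sb = 0.5 * sa + 0.5 * rng.normal(size=8)
        res = delong_paired(sa, sb, self.y8)
        jack = grouped_jackknife_delta_var(sa, sb, self.y8)
        if jack > 1e-10 and abs(res.z) > 0:
            var = (res.delta_auc / res.z) ** 2
            assert var == pytest.approx(jack, rel=0.10)

    def test_invariant_to_monotone_transforms(self):
        rng = np.random.default_rng(7)
        sa, sb = rng.normal(size=40), rng.normal(size=40)
        y = np.array([1] * 20 + [0] * 20)
        base = delong_paired(sa, sb, y)
        warped = delong_paired(np.exp(sa), 3 * sb + 10, y)
        assert warped.p == pytest.approx(base.p, abs=1e-12)
        assert warped.z == pytest.approx(base.z, abs=1e-9)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            delong_paired([1, 2], [1, 2, 3], [1, 0, 1])


class TestDeLongUnpaired:
    def test_variance_additivity(self):
        rng = np.random.default_rng(3)
        a = ScoredSet(rng.normal(size=60), np.r_[np.ones(30, int), np.zeros(30, int)])
        b = ScoredSet(rng.normal(size=60), np.r_[np.ones(30, int), np.zeros(30, int)])
        res = delong_unpaired(a, b)
        var = auc(a).variance + auc(b).variance
        assert res.z == pytest.approx(res.delta_auc / np.sqrt(var))

    def test_power_perfect_vs_chance(self):
        rng = np.random.default_rng(4)
        y = np.r_[np.ones(100, int), np.zeros(100, int)]
        perfect = ScoredSet(y + rng.random(200) * 0.1, y)
        chance = ScoredSet(rng.normal(size=200), y)
        assert delong_unpaired(perfect, chance).p < 0.001

    def test_degenerate_variance_convention(self):
        a = ScoredSet([1.0, 1.0, 0.0, 0.0], [1, 1, 0, 0])
        res = delong_unpaired(a, a)
        assert res.p == 1.0


class TestClopperPearson:
    @pytest.mark.parametrize("k,n,expected", [
        (22050, 22062, (0.9991, 0.9997)),
        (449, 449, (0.9918, 1.0)),
    ])
    def test_published_intervals_4dp(self, k, n, expected):
        lo, hi = clopper_pearson(k, n)
        assert (round(lo, 4), round(hi, 4)) == expected

    def test_38_of_39_interval_3dp(self):
        lo, hi = clopper_pearson(38, 39)
        assert (round(lo, 3), round(hi, 3)) == (0.865, 0.999)

    def test_boundaries_exact(self):
        assert clopper_pearson(0, 10)[0] == 0.0
        assert clopper_pearson(10, 10)[1] == 1.0

    def test_invalid_counts_rejected(self):
        for k, n in [(-1, 5), (6, 5), (0, 0)]:
            with pytest.raises(ValueError):
                clopper_pearson(k, n)

    @pytest.mark.parametrize("p", [0.01, 0.5, 0.999])
    def test_coverage_at_least_nominal(self, p):
        rng = np.random.default_rng(100)
        n, reps = 100, 2000
        ks = rng.binomial(n, p, size=reps)
        covered = 0
        for k in ks:
            lo, hi = clopper_pearson(int(k), n)
            covered += lo <= p <= hi
        assert covered / reps >= 0.95


class TestChiSquare:
    def test_equal_proportions_null(self):
        stat, p = chi_square_proportions([10, 10], [100, 100])
        assert stat == 0.0
        assert p == 1.0

    def test_2x2_matches_hand_formula(self):
        a, b = 30, 70  # successes / failures group 1
        c, d = 45, 55
        n = a + b + c + d
        expected = (
            n * (a * d - b * c) ** 2
            / ((a + b) * (c + d) * (a + c) * (b + d))
        )
        stat, _ = chi_square_proportions([a, c], [a + b, c + d])
        assert stat == pytest.approx(expected)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_proportions([0, 0], [10, 10])


class TestOperatingPoint:
    def test_39_positives_achieves_38_of_39(self):
        rng = np.random.default_rng(8)
        scores = np.r_[rng.uniform(0.4, 1.0, 39), rng.uniform(0.0, 0.6, 300)]
        labels = np.r_[np.ones(39, int), np.zeros(300, int)]
        op = operating_point_at_sensitivity(ScoredSet(scores, labels), 0.95)
        assert op.sensitivity.successes == 38
        assert round(op.sensitivity.value, 3) == 0.974
        assert (round(op.sensitivity.ci[0], 3), round(op.sensitivity.ci[1], 3)) == (
            0.865, 0.999,
        )

    def test_target_one_includes_all_positives(self):
        rng = np.random.default_rng(9)
        scored = ScoredSet(rng.normal(size=50), np.r_[np.ones(10, int), np.zeros(40, int)])
        op = operating_point_at_sensitivity(scored, 1.0)
        assert op.sensitivity.value == 1.0
        assert op.threshold <= scored.scores[scored.labels == 1].min()

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_sensitivity_never_below_target_and_threshold_monotone(self, seed):
        rng = np.random.default_rng(seed)
        n_pos = int(rng.integers(1, 30))
        n_neg = int(rng.integers(1, 60))
        scored = ScoredSet(
            rng.normal(size=n_pos + n_neg),
            np.r_[np.ones(n_pos, int), np.zeros(n_neg, int)],
        )
        prev_threshold = None
        for target in (0.99, 0.9, 0.7, 0.5):
            op = operating_point_at_sensitivity(scored, target)
            assert op.sensitivity.value >= target
            if prev_threshold is not None:
                assert op.threshold >= prev_threshold  # lower target, higher cutoff
            prev_threshold = op.threshold

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            operating_point_at_sensitivity(ScoredSet([1.0, 2.0], [0, 0]))


class TestTrivialRanker:
    def test_single_site_constant_scores_auc_half(self):
        scores = trivial_prevalence_ranker(["a"] * 50, {"a": 0.3})
        labels = np.r_[np.ones(10, int), np.zeros(40, int)]
        assert (scores == 0.3).all()
        assert auc(ScoredSet(scores, labels)).auc == 0.5

    def test_two_site_auc_matches_closed_form(self):
        sites = np.array(["msh"] * 500 + ["nih"] * 1500)
        rng = np.random.default_rng(11)
        labels = np.r_[
            (rng.random(500) < 0.342).astype(int),
            (rng.random(1500) < 0.012).astype(int),
        ]
        scores = trivial_prevalence_ranker(sites, {"msh": 0.342, "nih": 0.012})
        pos_hi = np.mean(sites[labels == 1] == "msh")
        neg_hi = np.mean(sites[labels == 0] == "msh")
        assert auc(ScoredSet(scores, labels)).auc == pytest.approx(
            two_level_ranker_auc(pos_hi, neg_hi), abs=1e-12
        )

    def test_order_invariance(self):
        sites = ["a", "b"] * 100
        labels = np.tile([1, 0], 100)
        scores = trivial_prevalence_ranker(sites, {"a": 0.3, "b": 0.01})
        base = auc(ScoredSet(scores, labels)).auc
        perm = np.random.default_rng(0).permutation(200)
        shuffled = auc(ScoredSet(scores[perm], labels[perm])).auc
        assert shuffled == pytest.approx(base)

    def test_unknown_site_rejected(self):
        with pytest.raises(ValueError, match="no training prevalence"):
            trivial_prevalence_ranker(["a", "zzz"], {"a": 0.3})


class TestCalibration:
    def test_well_calibrated_slope_near_one(self):
        rng = np.random.default_rng(12)
        logits = rng.normal(0, 1.5, size=20_000)
        p = 1 / (1 + np.exp(-logits))
        y = (rng.random(20_000) < p).astype(int)
        summary = calibration_summary(p, y)
        assert summary.slope == pytest.approx(1.0, abs=0.1)

    def test_overconfident_doubled_logits_slope_half(self):
        rng = np.random.default_rng(13)
        logits = rng.normal(0, 1.0, size=40_000)
        true_p = 1 / (1 + np.exp(-logits))
        y = (rng.random(40_000) < true_p).astype(int)
        overconfident = 1 / (1 + np.exp(-2 * logits))
        summary = calibration_summary(overconfident, y)
        assert summary.slope == pytest.approx(0.5, abs=0.1)

    def test_constant_probabilities_degenerate(self):
        summary = calibration_summary([0.4] * 100, [0, 1] * 50)
        assert summary.degenerate
        assert summary.slope is None

    def test_bins_partition_and_rates_bounded(self):
        rng = np.random.default_rng(14)
        p = rng.random(500)
        y = (rng.random(500) < p).astype(int)
        summary = calibration_summary(p, y, n_bins=10)
        assert sum(n for _, _, n in summary.bins) == 500
        assert all(0 <= rate <= 1 for _, rate, _ in summary.bins)

    def test_out_of_range_probabilities_clamped_with_warning(self):
        y = np.r_[np.ones(50, int), np.zeros(50, int)]
        p = np.r_[np.ones(50), np.zeros(50)]
        with pytest.warns(UserWarning, match="clamped"):
            summary = calibration_summary(p, y)
        assert summary.slope is not None
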