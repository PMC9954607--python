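import numpy as np
import pytest

from pepscreen.core_data import ValidationError
from pepscreen.evaluation import (
    delong_compare,
    kruskal_wallis,
    operating_point,
    predictive_values,
    reproducibility_cv,
    roc_auc,
)
from pepscreen.synthetic import simulate_score_replicates


def pair_counting_auc(scores, labels):
    """Oracle: exhaustive concordant-pair counting with ties at 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1][:, None]
    neg = scores[labels == 0][None, :]
    total = (pos > neg).sum() + 0.5 * (pos == neg).sum()
    return total / (pos.size * neg.size)


class TestAUC:
    def test_perfect_separation(self):
        auc, lo, hi = roc_auc([3, 4, 1, 2], [1, 1, 0, 0])
        assert auc == 1.0 and hi == 1.0

    def test_four_pair_enumeration(self):
        assert roc_auc([3, 1, 2, 0], [1, 1, 0, 0])[0] == pytest.approx(0.75)

    def test_equals_pair_counting_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n1, n0 = rng.integers(2, 20, 2)
            scores = np.round(rng.normal(size=n1 + n0), 1)  # rounding forces ties
            labels = np.r_[np.ones(n1, int), np.zeros(n0, int)]
            auc, _, _ = roc_auc(scores, labels)
            assert auc == pytest.approx(pair_counting_auc(scores, labels), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        a1, _, _ = roc_auc(scores, labels)
        a2, _, _ = roc_auc(np.exp(3 * scores) + 7, labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=80) + np.r_[np.ones(40), np.zeros(40)]
        labels = np.r_[np.ones(40, int), np.zeros(40, int)]
        for method in ("delong", "binomial"):
            auc, lo, hi = roc_auc(scores, labels, ci=method)
            assert lo <= auc <= hi

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([1, 2], [1, 1])


class TestDeLongCompare:
    def test_identical_scores_give_delta_zero_p_one(self):
        scores = [0.1, 0.9, 0.3, 0.7]
        labels = [0, 1, 0, 1]
        delta, p = delong_compare(scores, scores, labels)
        assert delta == 0.0 and p == 1.0

    def test_negated_scores_on_separable_set(self):
        scores = np.array([3.0, 4.0, 1.0, 2.0])
        labels = [1, 1, 0, 0]
        delta, _ = delong_compare(scores, -scores, labels)
        assert abs(delta) == pytest.approx(1.0)

    def test_calibrated_against_paired_permutation_oracle(self):
        """The asymptotic p tracks a sign-flip (swap a/b per sample)
        permutation oracle across paired score sets of n = 50."""
        discrepancies = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 50
            labels = np.r_[np.ones(25, int), np.zeros(25, int)]
            # equal noise keeps a and b exchangeable, so the sign-flip
            # null matches the equal-AUC hypothesis being tested
            latent = labels + rng.normal(0, 1, n)
            a = latent + rng.normal(0, 0.6, n)
            b = latent + rng.normal(0, 0.6, n)
            _, p = delong_compare(a, b, labels)
            observed = abs(pair_counting_auc(a, labels) - pair_counting_auc(b, labels))
            count = 0
            n_perm = 5_000
            for _ in range(n_perm):
                swap = rng.random(n) < 0.5
                aa = np.where(swap, b, a)
                bb = np.where(swap, a, b)
                d = abs(pair_counting_auc(aa, labels) - pair_counting_auc(bb, labels))
                if d >= observed - 1e-12:
                    count += 1
            discrepancies.append(abs(p - count / n_perm))
        assert np.mean(discrepancies) < 0.02
        assert max(discrepancies) < 0.06


class TestOperatingPoint:
    def test_stated_prevalence_predictive_values(self):
        # 100 cases (93 above cutoff), 100 controls (69 below)
        scores = np.r_[np.ones(93), np.zeros(7), np.zeros(69), np.ones(31)]
        labels = np.r_[np.ones(100, int), np.zeros(100, int)]
        perf = operating_point(scores, labels, cutoff=0.5, prevalence=0.40)
        assert perf.sensitivity == pytest.approx(0.93)
        assert perf.specificity == pytest.approx(0.69)
        assert round(perf.npv * 100, 1) == 93.7
        assert perf.ppv == pytest.approx(0.6667, abs=5e-5)

    def test_perfect_test_has_unit_predictive_values(self):
        npv, ppv = predictive_values(1.0, 1.0, 0.25)
        assert npv == 1.0 and ppv == 1.0

    def test_extreme_cutoffs(self):
        scores = [0.1, 0.9, 0.2, 0.8]
        labels = [0, 1, 0, 1]
        lo = operating_point(scores, labels, cutoff=-np.inf, prevalence=0.4)
        hi = operating_point(scores, labels, cutoff=np.inf, prevalence=0.4)
        assert (lo.sensitivity, lo.specificity) == (1.0, 0.0)
        assert (hi.sensitivity, hi.specificity) == (0.0, 1.0)

    def test_ci_bounds_contain_estimates(self):
        scores = np.r_[np.ones(18), np.zeros(2), np.zeros(15), np.ones(5)]
        labels = np.r_[np.ones(20, int), np.zeros(20, int)]
        perf = operating_point(scores, labels, cutoff=0.5, prevalence=0.4)
        assert perf.sensitivity_ci[0] <= perf.sensitivity <= perf.sensitivity_ci[1]
        assert perf.specificity_ci[0] <= perf.specificity <= perf.specificity_ci[1]


class TestKruskalWallis:
    def test_hand_computed_h(self):
        h, _ = kruskal_wallis([1, 2, 3, 4, 5, 6], ["a", "a", "b", "b", "c", "c"])
        assert h == pytest.approx(12 / 42 * 16, abs=1e-6)  # 4.5714...

    def test_invariant_to_within_group_order(self):
        h1, p1 = kruskal_wallis([1, 2, 3, 4, 5, 6], ["a", "a", "b", "b", "c", "c"])
        h2, p2 = kruskal_wallis([2, 1, 4, 3, 6, 5], ["a", "a", "b", "b", "c", "c"])
        assert h1 == pytest.approx(h2) and p1 == pytest.approx(p2)

    def test_close_to_permutation_oracle(self):
        rng = np.random.default_rng(2)
        values = rng.normal(0, 1, 24) + np.repeat([0.0, 0.4, 0.9], 8)
        groups = np.repeat(["a", "b", "c"], 8)
        h_obs, p = kruskal_wallis(values, groups)
        count = 0
        n_perm = 20_000
        for _ in range(n_perm):
            h, _ = kruskal_wallis(rng.permutation(values), groups)
            if h >= h_obs - 1e-12:
                count += 1
        assert p == pytest.approx(count / n_perm, abs=0.01)

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            kruskal_wallis([1, 2, 3], ["a", "a", "a"])


class TestReproducibilityCV:
    def test_constant_scores_give_zero(self):
        assert reproducibility_cv([-1.1] * 5) == 0.0

    def test_hand_computed_example(self):
        assert reproducibility_cv([-1.0, -1.1, -0.9]) == pytest.approx(10.0)

    def test_replicate_simulation_round_trip(self):
        scores = simulate_score_replicates(50, mean=-1.1, cv=0.03, seed=4)
        assert reproducibility_cv(scores) == pytest.approx(3.0, abs=1.0)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValidationError):
            reproducibility_cv([-1.0, 1.0])
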