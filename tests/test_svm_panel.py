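import numpy as np
import pandas as pd
import pytest
from sklearn.svm import SVC

from pepscreen.core_data import ValidationError
from pepscreen.evaluation import roc_auc
from pepscreen.normalization import TransformedMatrix
from pepscreen.svm_panel import (
    DEFAULT_SVM_C,
    DEFAULT_SVM_GAMMA,
    cross_validate,
    fix_cutoff,
    score_samples,
    train_model,
)


def _transformed(x: np.ndarray, feature_ids=None, sample_ids=None) -> TransformedMatrix:
    """Wrap a samples-x-features array as a transformed matrix."""
    n_samples, n_features = x.shape
    feature_ids = feature_ids or [f"f{i}" for i in range(n_features)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n_samples)]
    values = pd.DataFrame(x.T, index=feature_ids, columns=sample_ids)
    return TransformedMatrix(values=values, detected=values.notna(), features=[])


def _clusters(n=20, sep=10.0, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, (n, 4))
    y = np.r_[np.ones(n // 2, int), np.zeros(n - n // 2, int)]
    x[y == 1] += sep
    return x, y


def test_default_hyperparameters():
    assert DEFAULT_SVM_C == 16.0
    assert DEFAULT_SVM_GAMMA == 0.01


def test_separable_clusters_reach_perfect_training_accuracy():
    x, y = _clusters()
    t = _transformed(x)
    labels = pd.Series(y, index=t.sample_ids)
    model = train_model(t, labels, [f"f{i}" for i in range(4)])
    scores, _ = score_samples(model, t)
    assert (((scores >= 0).astype(int)) == labels).all()


def test_duplicated_sample_scores_identically():
    x, y = _clusters(seed=3)
    x = np.vstack([x, x[0]])
    y = np.r_[y, y[0]]
    t = _transformed(x)
    labels = pd.Series(y, index=t.sample_ids)
    model = train_model(t, labels, [f"f{i}" for i in range(4)])
    scores, _ = score_samples(model, t)
    assert scores.iloc[0] == scores.iloc[-1]


def test_rescoring_training_set_is_bit_reproducible():
    x, y = _clusters(sep=2.0, seed=5)
    t = _transformed(x)
    labels = pd.Series(y, index=t.sample_ids)
    model = train_model(t, labels, [f"f{i}" for i in range(4)])
    s1, _ = score_samples(model, t)
    s2, _ = score_samples(model, t)
    assert (s1 == s2).all()


def test_label_swap_negates_scores():
    x, y = _clusters(sep=2.0, seed=8)
    t = _transformed(x)
    labels = pd.Series(y, index=t.sample_ids)
    m_orig = train_model(t, labels, [f"f{i}" for i in range(4)])
    m_swap = train_model(t, 1 - labels, [f"f{i}" for i in range(4)])
    s_orig, _ = score_samples(m_orig, t)
    s_swap, _ = score_samples(m_swap, t)
    # symmetry holds to the solver's convergence tolerance
    np.testing.assert_allclose(s_swap.to_numpy(), -s_orig.to_numpy(), atol=1e-5)
    a1, _, _ = roc_auc(s_orig, labels)
    a2, _, _ = roc_auc(s_swap, labels)
    assert a2 == pytest.approx(1.0 - a1, abs=1e-12)


def test_single_class_training_rejected():
    x, _ = _clusters()
    t = _transformed(x)
    labels = pd.Series(1, index=t.sample_ids)
    with pytest.raises(ValidationError, match="both classes"):
        train_model(t, labels, ["f0"])


def test_absent_panel_feature_named_in_error():
    x, y = _clusters()
    t = _transformed(x)
    labels = pd.Series(y, index=t.sample_ids)
    with pytest.raises(ValidationError, match="f_missing"):
        train_model(t, labels, ["f0", "f_missing"])


def test_high_missingness_samples_flagged():
    x, y = _clusters(sep=2.0)
    t = _transformed(x)
    t.detected.iloc[:, 0] = False  # sample s0 misses every panel feature
    labels = pd.Series(y, index=t.sample_ids)
    model = train_model(t, labels, [f"f{i}" for i in range(4)])
    _, flagged = score_samples(model, t)
    assert flagged["s0"] and not flagged["s1"]


class TestCrossValidate:
    def test_loo_matches_hand_rolled_refits(self):
        x, y = _clusters(n=14, sep=3.0, seed=2)
        t = _transformed(x)
        labels = pd.Series(y, index=t.sample_ids)
        fids = [f"f{i}" for i in range(4)]
        got = cross_validate(t, labels, fids, scheme="loo")
        # oracle: explicit refits with manual standardization
        for i in range(len(y)):
            train_idx = [j for j in range(len(y)) if j != i]
            xt = x[train_idx]
            mu, sd = xt.mean(axis=0), xt.std(axis=0)
            svm = SVC(C=16.0, gamma=0.01, kernel="rbf", tol=1e-6)
            svm.fit((xt - mu) / sd, y[train_idx])
            expected = svm.decision_function(((x[i] - mu) / sd)[None, :])[0]
            assert got.iloc[i] == pytest.approx(expected, abs=1e-9)

    def test_loo_auc_is_one_on_separable_data(self):
        x, y = _clusters(n=16, sep=10.0, seed=4)
        t = _transformed(x)
        labels = pd.Series(y, index=t.sample_ids)
        scores = cross_validate(t, labels, [f"f{i}" for i in range(4)], scheme="loo")
        auc, _, _ = roc_auc(scores, labels)
        assert auc == 1.0

    def test_permuted_labels_give_chance_level_auc(self):
        rng = np.random.default_rng(13)
        x = rng.normal(0, 1, (60, 6))
        y = rng.permutation(np.r_[np.ones(30, int), np.zeros(30, int)])
        t = _transformed(x)
        labels = pd.Series(y, index=t.sample_ids)
        scores = cross_validate(t, labels, [f"f{i}" for i in range(6)], scheme="loo")
        auc, _, _ = roc_auc(scores, labels)
        assert 0.35 <= auc <= 0.65

    def test_stratified_kfold_scores_every_sample(self):
        x, y = _clusters(n=30, sep=2.0, seed=6)
        t = _transformed(x)
        labels = pd.Series(y, index=t.sample_ids)
        scores = cross_validate(t, labels, [f"f{i}" for i in range(4)],
                                scheme="skf", n_folds=5, seed=0)
        assert scores.notna().all()


class TestFixCutoff:
    def test_separating_midpoint(self):
        cutoff = fix_cutoff([0.9, 0.8, 0.3, 0.7], [1, 1, 0, 0])
        assert cutoff == pytest.approx(0.75)

    def test_tie_broken_toward_smaller_cutoff(self):
        cutoff = fix_cutoff([0.9, 0.6, 0.7, 0.2], [1, 1, 0, 0])
        assert cutoff == pytest.approx(0.4)  # J = 0.5 at 0.4 and 0.8

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            n = int(rng.integers(4, 30))
            scores = np.round(rng.normal(size=n), 1)
            labels = rng.integers(0, 2, n)
            labels[:2] = [0, 1]
            if np.unique(scores).size < 2:
                continue
            distinct = np.unique(scores)
            mids = (distinct[:-1] + distinct[1:]) / 2
            best, best_j = None, -np.inf
            for c in mids:
                se = ((scores >= c) & (labels == 1)).sum() / (labels == 1).sum()
                sp = ((scores < c) & (labels == 0)).sum() / (labels == 0).sum()
                if se + sp - 1 > best_j + 1e-12:
                    best, best_j = c, se + sp - 1
            assert fix_cutoff(scores, labels) == pytest.approx(best)

    def test_constant_scores_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            fix_cutoff([0.5, 0.5], [1, 0])
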