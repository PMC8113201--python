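"""MC fold generation, SMOTE, the nine-member ensemble and label
permutation."""

from math import comb

import numpy as np
import pytest

from petmr_lesionrisk.ensemble import (EnsembleConfig, EnsemblePrediction,
                                       generate_mc_folds, permute_labels,
                                       predict_ensemble, smote_oversample,
                                       train_mixed_ensemble)


def test_folds_52_patients_1000x5():
    ids = [f"p{i:02d}" for i in range(52)]
    scheme = generate_mc_folds(ids, n_folds=1000, n_validation=5, seed=0)
    scheme.validate()
    assert scheme.n_folds == 1000
    vals = {frozenset(v) for _, v in scheme.folds}
    assert len(vals) == 1000  # pairwise distinct
    for train, val in scheme.folds:
        assert len(train) == 47 and len(val) == 5
        assert not set(train) & set(val)
        assert set(train) | set(val) == set(ids)


def test_folds_exhaustive_c65():
    ids = list("abcdef")
    scheme = generate_mc_folds(ids, n_folds=6, n_validation=5, seed=1)
    vals = {frozenset(v) for _, v in scheme.folds}
    assert len(vals) == comb(6, 5) == 6


def test_folds_infeasible_uniqueness():
    with pytest.raises(ValueError, match=r"C\(6,5\) = 6"):
        generate_mc_folds(list("abcdef"), n_folds=7, n_validation=5)
    with pytest.raises(ValueError):
        generate_mc_folds(list("abc"), n_folds=1, n_validation=5)


def test_folds_deterministic():
    ids = [f"p{i}" for i in range(20)]
    a = generate_mc_folds(ids, 50, 5, seed=9)
    b = generate_mc_folds(ids, 50, 5, seed=9)
    assert a.folds == b.folds


def test_smote_balances_classes(rng):
    X = rng.random((14, 3))
    y = np.array([0] * 10 + [1] * 4)
    Xb, yb = smote_oversample(X, y, k_neighbors=5, rng=rng)
    assert (yb == 0).sum() == (yb == 1).sum() == 10
    assert len(Xb) == 20


def test_smote_identical_minority_points(rng):
    X = np.vstack([rng.random((6, 2)), np.tile([0.5, 0.5], (2, 1))])
    y = np.array([0] * 6 + [1] * 2)
    Xb, yb = smote_oversample(X, y, rng=rng)
    synth = Xb[len(X):]
    np.testing.assert_allclose(synth, 0.5)


def test_smote_convexity_on_segment(rng):
    """Minority points on a line segment ⇒ synthetic points stay on it."""
    t = np.linspace(0, 1, 5)
    minority = np.stack([t, 2 * t + 1], axis=1)  # the line y = 2x + 1
    X = np.vstack([rng.random((12, 2)) + 5, minority])
    y = np.array([0] * 12 + [1] * 5)
    Xb, yb = smote_oversample(X, y, rng=rng)
    synth = Xb[len(X):]
    np.testing.assert_allclose(synth[:, 1], 2 * synth[:, 0] + 1, atol=1e-12)
    assert synth[:, 0].min() >= -1e-12 and synth[:, 0].max() <= 1 + 1e-12


def test_smote_minority_of_one_rejected(rng):
    X = rng.random((5, 2))
    y = np.array([0, 0, 0, 0, 1])
    with pytest.raises(ValueError, match="minority"):
        smote_oversample(X, y, rng=rng)


def test_ensemble_config_validation():
    with pytest.raises(ValueError):
        EnsembleConfig(member_configs=[{"n_estimators": 10}] * 8)
    with pytest.raises(ValueError):
        EnsembleConfig(member_configs=[{"n_estimators": -1}] * 9)
    with pytest.raises(ValueError):
        EnsemblePrediction(1, 1.5)


def test_ensemble_separable_and_deterministic(rng):
    X = np.vstack([rng.normal(-3, 0.3, (20, 4)), rng.normal(3, 0.3, (20, 4))])
    y = np.array([0] * 20 + [1] * 20)
    cfg = EnsembleConfig(seed=5)
    model = train_mixed_ensemble(X, y, cfg)
    preds = predict_ensemble(model, X)
    assert [p.label for p in preds] == list(y)  # separable ⇒ perfect fit
    model2 = train_mixed_ensemble(X, y, EnsembleConfig(seed=5))
    preds2 = predict_ensemble(model2, X)
    assert [p.score for p in preds] == [p.score for p in preds2]
    assert all(0.0 <= p.score <= 1.0 for p in preds)

    with pytest.raises(ValueError, match="single-class"):
        train_mixed_ensemble(X, np.zeros(40, dtype=int), cfg)
    with pytest.raises(ValueError, match="feature count"):
        predict_ensemble(model, X[:, :2])


def test_majority_vote_arithmetic():
    """5 positive of 9 hard votes ⇒ label 1, score 5/9."""

    class _Stub:
        def __init__(self, vote):
            self.vote = vote

        def predict(self, X):
            return np.full(len(X), self.vote)

    from petmr_lesionrisk.ensemble import MixedEnsemble
    model = MixedEnsemble([_Stub(1)] * 5 + [_Stub(0)] * 4, 2, "vote")
    pred = predict_ensemble(model, np.zeros((1, 2)))[0]
    assert pred.label == 1
    assert pred.score == pytest.approx(5 / 9)
    model_all = MixedEnsemble([_Stub(1)] * 9, 2, "vote")
    pred = predict_ensemble(model_all, np.zeros((1, 2)))[0]
    assert pred.label == 1 and pred.score == 1.0


def test_probability_averaging_mode(rng):
    X = np.vstack([rng.normal(-0.5, 1, (15, 3)), rng.normal(0.5, 1, (15, 3))])
    y = np.array([0] * 15 + [1] * 15)
    model = train_mixed_ensemble(X, y, EnsembleConfig(seed=1, score_mode="proba"))
    preds = predict_ensemble(model, X)
    assert all(0.0 <= p.score <= 1.0 for p in preds)
    # the score is the mean of the member positive-class probabilities
    expect = np.mean([m.predict_proba(X)[:, list(m.classes_).index(1)]
                      for m in model.members], axis=0)
    np.testing.assert_allclose([p.score for p in preds], expect)


def test_ensemble_null_labels_chance_level(rng):
    """Pure-noise labels, held-out evaluation over folds ⇒ pooled AUC in
    the chance band [0.40, 0.60]."""
    from petmr_lesionrisk.evaluation import roc_auc
    scores, truths = [], []
    X = rng.standard_normal((60, 4))
    for fold in range(60):
        y = rng.integers(0, 2, 60)
        if len(np.unique(y[:45])) < 2:
            continue
        model = train_mixed_ensemble(X[:45], y[:45], EnsembleConfig(seed=fold))
        for p, t in zip(predict_ensemble(model, X[45:]), y[45:]):
            scores.append(p.score)
            truths.append(t)
    assert 0.40 <= roc_auc(scores, truths) <= 0.60


def test_permute_labels_preserves_counts(rng):
    y = np.array([1, 1, 0, 0])
    perm = permute_labels(y, rng)
    assert perm.sum() == 2
    a = permute_labels(np.arange(10), np.random.default_rng(4))
    b = permute_labels(np.arange(10), np.random.default_rng(4))
    np.testing.assert_array_equal(a, b)
    with pytest.raises(ValueError):
        permute_labels(np.array([1]))


def test_permuted_auc_centers_on_half(rng):
    """Expected sham AUC over many permutations ~ 0.5."""
    from petmr_lesionrisk.evaluation import roc_auc
    scores = rng.random(40)
    y = np.array([0] * 20 + [1] * 20)
    aucs = [roc_auc(scores, permute_labels(y, rng)) for _ in range(200)]
    assert abs(np.mean(aucs) - 0.5) < 0.03
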