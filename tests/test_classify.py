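"""Prediction harness: splits, SVM+Platt estimator, pooled ROC/AUC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from neomorph import (
    CohortSpec,
    CvDesign,
    PlattLinearSVC,
    PredictionRecord,
    draw_splits,
    evaluate,
    fit_predict_one,
    pooled_roc,
    simulate_cohort,
)
from neomorph import _kernels


def _records(probs, labels):
    return [
        PredictionRecord(f"s{i}", 0, float(p), int(l))
        for i, (p, l) in enumerate(zip(probs, labels))
    ]


def brute_force_auc(probs, labels):
    """Pair-enumeration Mann-Whitney statistic (independent oracle)."""
    probs, labels = np.asarray(probs), np.asarray(labels)
    pos, neg = probs[labels == 1], probs[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


# ------------------------------------------------------------------ splits

def test_design_validation():
    with pytest.raises(ValueError):
        CvDesign(test_fraction=0.6)
    with pytest.raises(ValueError):
        CvDesign(n_repeats=0)


@pytest.mark.parametrize("n,expected_test", [(86, 5), (66, 4), (153, 8)])
def test_split_sizes_follow_ceil_rule(n, expected_test):
    design = CvDesign(n_repeats=20, test_fraction=0.05, seed=0)
    splits = draw_splits(n, design)
    assert len(splits) == 20
    for train, test in splits:
        assert len(test) == expected_test
        assert len(train) == n - expected_test
        union = np.union1d(train, test)
        np.testing.assert_array_equal(union, np.arange(n))
        assert np.intersect1d(train, test).size == 0


def test_splits_reproducible_and_vary_across_repeats():
    design = CvDesign(n_repeats=10, test_fraction=0.05, seed=42)
    a = draw_splits(100, design)
    b = draw_splits(100, design)
    for (t1, s1), (t2, s2) in zip(a, b):
        np.testing.assert_array_equal(t1, t2)
        np.testing.assert_array_equal(s1, s2)
    assert any(not np.array_equal(a[0][1], a[r][1]) for r in range(1, 10))


# --------------------------------------------------------------- estimator

def test_estimator_sklearn_protocol():
    clf = PlattLinearSVC(C=2.0)
    assert clf.get_params() == {"C": 2.0, "calibration_folds": 3}
    clf2 = clone(clf).set_params(C=0.5)
    assert clf2.get_params()["C"] == 0.5
    rng = np.random.default_rng(0)
    X = rng.random((40, 3))
    y = np.array([0] * 20 + [1] * 20)
    X[y == 1] += 1.0
    fitted = clf.fit(X, y)
    assert fitted.coef_.shape == (1, 3)
    assert fitted.predict_proba(X).shape == (40, 2)
    np.testing.assert_allclose(fitted.predict_proba(X).sum(axis=1), 1.0)
    assert set(fitted.predict(X)) <= {0, 1}
    with pytest.raises(ValueError, match="2 classes"):
        PlattLinearSVC().fit(X, np.zeros(40))


def test_separable_toy_orders_probabilities():
    X = np.array([[0.0], [0.0], [0.0], [1.0], [1.0], [1.0]] * 5)
    y = np.array([0, 0, 0, 1, 1, 1] * 5)
    probs = fit_predict_one(X, y, np.array([[0.0], [1.0]]))
    assert probs[1] > probs[0]


def test_svm_matches_sklearn_on_informative_data(rng):
    """Decision ordering agrees with libsvm's linear SVC."""
    for trial in range(3):
        X = rng.random((150, 6))
        y = (rng.random(150) < 0.3).astype(int)
        X[y == 1, 0] += 0.5
        X[y == 1, 2] += 0.3
        ours = PlattLinearSVC().fit(X, y)
        f_ours = ours.decision_function(X)
        f_sk = SVC(kernel="linear", C=1.0).fit(X, y).decision_function(X)
        assert np.corrcoef(f_ours, f_sk)[0, 1] > 0.99
        assert roc_auc_score(y, f_ours) == pytest.approx(
            roc_auc_score(y, f_sk), abs=0.01
        )


def test_platt_probabilities_match_sklearn_calibration(rng):
    """Calibrated probabilities track CalibratedClassifierCV closely."""
    X = rng.standard_normal((200, 4))
    y = (rng.random(200) < 0.3).astype(int)
    X[y == 1, 0] += 1.5
    Xte = rng.standard_normal((50, 4))
    p_ours = PlattLinearSVC().fit(X, y).predict_proba(Xte)[:, 1]
    ref = CalibratedClassifierCV(SVC(kernel="linear", C=1.0), method="sigmoid", cv=3)
    p_sk = ref.fit(X, y).predict_proba(Xte)[:, 1]
    assert np.corrcoef(p_ours, p_sk)[0, 1] > 0.98
    assert np.abs(p_ours - p_sk).mean() < 0.08


def test_duplicated_training_rows_equal_doubled_cost(rng):
    """Duplicating every row is the same optimization as doubling C.

    The direct refit with C = 2 is the oracle for the duplicated fit;
    at the pipeline level (calibration folds change composition) the
    ranking must stay essentially unchanged.
    """
    X = rng.random((60, 4))
    y = (rng.random(60) < 0.4).astype(int)
    X[y == 1, 1] += 1.0
    ysig = 2.0 * y - 1.0
    Xdup = np.ascontiguousarray(np.vstack([X, X]))
    w_dup, b_dup = _kernels.svm_dual_cd(Xdup, np.concatenate([ysig, ysig]), 1.0)
    w_2c, b_2c = _kernels.svm_dual_cd(np.ascontiguousarray(X), ysig, 2.0)
    # both runs stop at the solver's gap tolerance, not the exact optimum
    np.testing.assert_allclose(w_dup, w_2c, atol=0.05)
    assert b_dup == pytest.approx(b_2c, abs=0.05)

    from scipy.stats import spearmanr

    Xte = rng.random((20, 4))
    p1 = fit_predict_one(X, y, Xte)
    p2 = fit_predict_one(np.vstack([X, X]), np.concatenate([y, y]), Xte)
    assert spearmanr(p1, p2).statistic > 0.95


def test_single_class_training_split_is_an_error():
    X = np.random.default_rng(0).random((10, 2))
    with pytest.raises(ValueError, match="single class"):
        fit_predict_one(X, np.zeros(10, dtype=int), X)


# ------------------------------------------------------------------- ROC

def test_pooled_roc_trivial_cases():
    assert pooled_roc(_records([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])).auc == 1.0
    assert pooled_roc(_records([0.5] * 6, [1, 1, 1, 0, 0, 0])).auc == 0.5
    with pytest.raises(ValueError, match="single class"):
        pooled_roc(_records([0.5, 0.6], [1, 1]))


def test_roc_curve_endpoints():
    roc = pooled_roc(_records([0.9, 0.4, 0.6, 0.1, 0.3], [1, 0, 1, 0, 0]))
    assert roc.fpr[0] == 0.0 and roc.tpr[0] == 0.0
    assert roc.fpr[-1] == 1.0 and roc.tpr[-1] == 1.0
    assert roc.auc == pytest.approx(np.trapezoid(roc.tpr, roc.fpr))


@settings(deadline=None, max_examples=60)
@given(st.data())
def test_auc_equals_mann_whitney_and_flip_symmetry(data):
    n = data.draw(st.integers(4, 60))
    labels = np.array(data.draw(
        st.lists(st.integers(0, 1), min_size=n, max_size=n)
    ))
    if labels.sum() in (0, n):
        labels[0], labels[-1] = 0, 1
    # coarse probability grid to force ties
    probs = np.array(data.draw(
        st.lists(st.integers(0, 8), min_size=n, max_size=n)
    )) / 8.0
    auc = pooled_roc(_records(probs, labels)).auc
    assert auc == pytest.approx(brute_force_auc(probs, labels), abs=1e-12)
    flipped = pooled_roc(_records(probs, 1 - labels)).auc
    assert auc + flipped == pytest.approx(1.0, abs=1e-12)


def test_label_permutation_null_centred_on_half(rng):
    """Permuting labels over fixed scores gives AUC centred at 0.5."""
    probs = rng.random(80)
    labels = np.array([1] * 20 + [0] * 60)
    aucs = []
    for _ in range(50):
        perm = rng.permutation(labels)
        aucs.append(pooled_roc(_records(probs, perm)).auc)
    se = np.std(aucs, ddof=1) / np.sqrt(len(aucs))
    assert abs(np.mean(aucs) - 0.5) < 2 * se + 1e-3


# --------------------------------------------------------------- evaluate

def test_evaluate_deterministic_given_seed():
    table = simulate_cohort(CohortSpec(n=66, n_positive=9, delta={"GI": 1.0}, seed=4))
    design = CvDesign(n_repeats=25, test_fraction=0.05, seed=11)
    a = evaluate(table, ["GA", "GI", "BV"], design, outcome="motor")
    b = evaluate(table, ["GA", "GI", "BV"], design, outcome="motor")
    assert a.pooled_auc == b.pooled_auc
    assert a.records == b.records
    assert a.per_repeat_aucs == b.per_repeat_aucs


def test_evaluate_restricts_to_subset_columns():
    """A pure-noise subset scores worse than the informative one."""
    table = simulate_cohort(CohortSpec(n=400, prevalence=0.25, delta={"GI": 1.5}, seed=8))
    design = CvDesign(n_repeats=40, test_fraction=0.05, seed=2)
    good = evaluate(table, ["GI"], design, outcome="cognitive")
    noise = evaluate(table, ["CB"], design, outcome="cognitive")
    assert good.pooled_auc > 0.75
    assert good.pooled_auc > noise.pooled_auc + 0.1


def test_noise_descriptor_barely_moves_informative_auc():
    table = simulate_cohort(CohortSpec(n=2000, prevalence=0.25, delta={"GI": 1.19}, seed=6))
    design = CvDesign(n_repeats=100, test_fraction=0.05, seed=3)
    base = evaluate(table, ["GI"], design, outcome="cognitive").pooled_auc
    plus = evaluate(table, ["GI", "CB"], design, outcome="cognitive").pooled_auc
    assert abs(base - plus) < 0.05


def test_tiny_cohort_with_skips_still_runs():
    table = simulate_cohort(CohortSpec(n=12, n_positive=2, seed=1))
    design = CvDesign(n_repeats=40, test_fraction=0.1, seed=5)
    res = evaluate(table, ["GA", "GI"], design, outcome="motor")
    assert 0.0 <= res.pooled_auc <= 1.0
    assert res.n_skipped >= 0
    assert len(res.records) == (design.n_repeats - res.n_skipped) * 2
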