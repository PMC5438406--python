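"""Linear-SVM prediction harness with repeated random-subsampling ROC/AUC.

The evaluation protocol: a linear-kernel SVM (C = 1 by default) with
min-max feature scaling estimated on each training split, Platt-sigmoid
probability calibration via 3-fold internal cross-validation on the
training split, evaluated over many (default 500) random splits that
each hold out 5% of the subjects.  Test predictions from all repeats are
pooled into a single ROC curve; the pooled AUC equals the Mann-Whitney
probability that a random low-outcome subject receives a higher
calibrated probability than a random favourable-outcome subject.

Pooling is used because with cohorts of 66-153 subjects a 5% test split
holds 4-8 subjects and is frequently single-class, leaving the
per-repeat ROC undefined; per-repeat AUCs are reported where defined.

The SVM itself is solved by the package's dual coordinate-descent kernel
(:mod:`neomorph._kernels`), exposed here as the scikit-learn-compatible
estimator :class:`PlattLinearSVC`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_curve

from . import _kernels
from .features import CohortTable, DESCRIPTORS, apply_minmax, fit_minmax

__all__ = [
    "CvDesign",
    "PredictionRecord",
    "RocResult",
    "SubsetResult",
    "PlattLinearSVC",
    "draw_splits",
    "fit_predict_one",
    "pooled_roc",
    "evaluate",
]


@dataclass(frozen=True)
class CvDesign:
    """Repeated random-subsampling design.

    ``test_fraction`` of the cohort (rounded up, so at least one subject)
    is held out in each of ``n_repeats`` independent draws; splits are
    reproducible from ``seed`` and independent of execution order
    (repeat r uses the seed stream (seed, r)).
    """

    n_repeats: int = 500
    test_fraction: float = 0.05
    seed: int = 0
    stratified: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 0.5:
            raise ValueError("test_fraction must be in (0, 0.5)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")

    def test_size(self, n: int) -> int:
        return math.ceil(n * self.test_fraction)


@dataclass(frozen=True)
class PredictionRecord:
    """One pooled test prediction: subject, repeat, probability, truth."""

    subject_id: str
    repeat_index: int
    calibrated_probability: float
    true_label: int


@dataclass
class RocResult:
    """A pooled ROC curve with its area."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


@dataclass
class SubsetResult:
    """Evaluation of one descriptor subset under one cv design."""

    subset: tuple[str, ...]
    pooled_auc: float
    roc: RocResult
    records: list[PredictionRecord]
    per_repeat_aucs: dict[int, float]
    n_skipped: int
    design: CvDesign


class PlattLinearSVC(BaseEstimator, ClassifierMixin):
    """Linear-kernel SVM with Platt-calibrated probabilities.

    A hinge-loss linear SVM (regularization ``C``) whose decision values
    are mapped to probabilities by Platt's sigmoid, fitted on held-out
    decision values from ``calibration_folds`` stratified internal folds
    of the training data (falling back to in-sample decision values when
    a class has fewer members than folds).

    Attributes set by :meth:`fit` (trailing underscore): ``coef_``,
    ``intercept_``, ``platt_a_``, ``platt_b_``, ``classes_``,
    ``n_features_in_``.
    """

    def __init__(self, C: float = 1.0, calibration_folds: int = 3) -> None:
        self.C = C
        self.calibration_folds = calibration_folds

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PlattLinearSVC":
        X = np.ascontiguousarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(f"need exactly 2 classes, got {self.classes_!r}")
        y01 = (y == self.classes_[1]).astype(np.float64)
        ysig = 2.0 * y01 - 1.0

        fold_id, fallback = _calibration_folds(y01, self.calibration_folds)
        if fallback:
            w, b = _kernels.svm_dual_cd(X, ysig, self.C)
            f_cal = _kernels.decision_values(X, w, b)
        else:
            f_cal = np.empty(len(y01))
            for fold in range(self.calibration_folds):
                tr = fold_id != fold
                wf, bf = _kernels.svm_dual_cd(
                    np.ascontiguousarray(X[tr]), ysig[tr], self.C
                )
                f_cal[~tr] = _kernels.decision_values(
                    np.ascontiguousarray(X[~tr]), wf, bf
                )
            w, b = _kernels.svm_dual_cd(X, ysig, self.C)
        self.platt_a_, self.platt_b_ = _kernels.platt_fit(f_cal, y01)
        self.coef_ = w.reshape(1, -1)
        self.intercept_ = np.array([b])
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.ascontiguousarray(X, dtype=np.float64)
        return _kernels.decision_values(X, self.coef_[0], float(self.intercept_[0]))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        p1 = _kernels.platt_apply(self.decision_function(X), self.platt_a_, self.platt_b_)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


def _calibration_folds(y01: np.ndarray, n_folds: int = 3) -> tuple[np.ndarray, bool]:
    """Stratified fold assignment for internal Platt calibration.

    Returns (fold_id, fallback): fallback is True when either class has
    fewer members than folds, in which case calibration must use
    in-sample decision values.
    """
    fold_id = np.zeros(len(y01), dtype=np.int64)
    counts = [int((y01 == c).sum()) for c in (0.0, 1.0)]
    if min(counts) < n_folds:
        return fold_id, True
    for c in (0.0, 1.0):
        idx = np.flatnonzero(y01 == c)
        fold_id[idx] = np.arange(len(idx)) % n_folds
    return fold_id, False


def draw_splits(n: int, design: CvDesign,
                labels: np.ndarray | None = None) -> list[tuple[np.ndarray, np.ndarray]]:
    """Draw the design's train/test index pairs.

    Test sets are sampled uniformly without replacement, independently
    across repeats, each of size ``ceil(n * test_fraction)``.  With
    ``design.stratified`` (requires ``labels``) the draw is proportional
    per class.  Fully reproducible from the design seed.
    """
    if n < 4:
        raise ValueError("need at least 4 subjects")
    n_test = design.test_size(n)
    if n_test >= n:
        raise ValueError("test size must be smaller than the cohort")
    if design.stratified and labels is None:
        raise ValueError("stratified splits require labels")
    splits = []
    for r in range(design.n_repeats):
        rng = np.random.default_rng(np.random.SeedSequence([design.seed, r]))
        if design.stratified:
            pos = np.flatnonzero(labels == 1)
            neg = np.flatnonzero(labels == 0)
            k_pos = min(len(pos) - 1, max(1, round(n_test * len(pos) / n)))
            test = np.concatenate([
                rng.choice(pos, size=k_pos, replace=False),
                rng.choice(neg, size=n_test - k_pos, replace=False),
            ])
        else:
            test = rng.choice(n, size=n_test, replace=False)
        test = np.sort(test)
        train = np.setdiff1d(np.arange(n), test)
        splits.append((train, test))
    return splits


def fit_predict_one(train_X: np.ndarray, train_y: np.ndarray, test_X: np.ndarray,
                    C: float = 1.0) -> np.ndarray:
    """One repeat: scale on the training split, fit, calibrate, predict.

    Min-max scaling parameters are estimated on the training rows only
    (no leakage); returns calibrated probabilities of the positive
    (low-outcome) class for the test rows.
    """
    train_y = np.asarray(train_y)
    if len(np.unique(train_y)) < 2:
        raise ValueError("training split contains a single class")
    params = fit_minmax(train_X)
    clf = PlattLinearSVC(C=C).fit(apply_minmax(params, train_X), train_y)
    return clf.predict_proba(apply_minmax(params, test_X))[:, 1]


def pooled_roc(records: Sequence[PredictionRecord]) -> RocResult:
    """ROC over all pooled test predictions; AUC by tie-aware rank statistic."""
    probs = np.array([r.calibrated_probability for r in records])
    labels = np.array([r.true_label for r in records], dtype=np.float64)
    if len(np.unique(labels)) < 2:
        raise ValueError("pooled records contain a single class")
    fpr, tpr, thr = roc_curve(labels, probs)
    auc = float(_kernels.rank_auc(probs, labels))
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


@dataclass
class _Precomputed:
    """Shared per-repeat arrays: scaled features, folds, test bookkeeping."""

    Xtr: np.ndarray          # (R, n_train, D) scaled per repeat
    ytr: np.ndarray          # (R, n_train)
    Xte: np.ndarray          # (R, n_test, D)
    yte: np.ndarray          # (R, n_test)
    fold_id: np.ndarray      # (R, n_train)
    fallback: np.ndarray     # (R,) bool
    test_idx: np.ndarray     # (R, n_test) row indices into the table
    repeat_idx: np.ndarray   # (R,) original repeat numbers
    n_skipped: int


def precompute_design(X: np.ndarray, y: np.ndarray, design: CvDesign) -> _Precomputed:
    """Draw splits and pre-scale features once for reuse across subsets.

    Single-class training splits are redrawn once from a derived stream;
    if still single-class the repeat is skipped and counted.  Scaling is
    refit on every training split (all descriptors at once — min-max is
    per-column, so a subset's scaling is the column subset).
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    splits = draw_splits(n, design, labels=y)
    kept, n_skipped = [], 0
    for r, (tr, te) in enumerate(splits):
        if len(np.unique(y[tr])) < 2:
            rng = np.random.default_rng(np.random.SeedSequence([design.seed, r, 7919]))
            te = np.sort(rng.choice(n, size=design.test_size(n), replace=False))
            tr = np.setdiff1d(np.arange(n), te)
            if len(np.unique(y[tr])) < 2:
                n_skipped += 1
                continue
        kept.append((r, tr, te))
    if not kept:
        raise ValueError("every repeat had a single-class training split")

    R = len(kept)
    n_train, n_test = len(kept[0][1]), len(kept[0][2])
    D = X.shape[1]
    pre = _Precomputed(
        Xtr=np.empty((R, n_train, D)), ytr=np.empty((R, n_train)),
        Xte=np.empty((R, n_test, D)), yte=np.empty((R, n_test)),
        fold_id=np.zeros((R, n_train), dtype=np.int64),
        fallback=np.zeros(R, dtype=np.bool_),
        test_idx=np.empty((R, n_test), dtype=np.int64),
        repeat_idx=np.array([r for r, _, _ in kept], dtype=np.int64),
        n_skipped=n_skipped,
    )
    for k, (r, tr, te) in enumerate(kept):
        params = fit_minmax(X[tr])
        pre.Xtr[k] = apply_minmax(params, X[tr])
        pre.Xte[k] = apply_minmax(params, X[te])
        pre.ytr[k] = y[tr]
        pre.yte[k] = y[te]
        pre.fold_id[k], pre.fallback[k] = _calibration_folds(y[tr])
        pre.test_idx[k] = te
    return pre


def _mask_from_subset(subset: Sequence[str]) -> np.ndarray:
    subset = list(subset)
    if not subset:
        raise ValueError("descriptor subset must be non-empty")
    unknown = [s for s in subset if s not in DESCRIPTORS]
    if unknown:
        raise ValueError(f"unknown descriptors: {unknown}")
    return np.array([d in subset for d in DESCRIPTORS], dtype=np.bool_)


def evaluate(table: CohortTable, subset: Sequence[str], design: CvDesign,
             outcome: str = "cognitive", C: float = 1.0,
             _pre: _Precomputed | None = None) -> SubsetResult:
    """Evaluate one descriptor subset: pooled ROC/AUC over all repeats."""
    mask = _mask_from_subset(subset)
    pre = _pre if _pre is not None else precompute_design(
        table.features(), table.labels(outcome), design
    )
    probs = _kernels.evaluate_mask_probs(
        pre.Xtr, pre.ytr, pre.Xte, pre.fold_id, pre.fallback, mask, C
    )
    ids = table.frame["subject_id"].to_numpy()
    records = [
        PredictionRecord(
            subject_id=str(ids[pre.test_idx[k, i]]),
            repeat_index=int(pre.repeat_idx[k]),
            calibrated_probability=float(probs[k, i]),
            true_label=int(pre.yte[k, i]),
        )
        for k in range(probs.shape[0])
        for i in range(probs.shape[1])
    ]
    roc = pooled_roc(records)
    per_repeat = {}
    for k in range(probs.shape[0]):
        if len(np.unique(pre.yte[k])) == 2:
            per_repeat[int(pre.repeat_idx[k])] = float(
                _kernels.rank_auc(probs[k], pre.yte[k])
            )
    return SubsetResult(
        subset=tuple(d for d in DESCRIPTORS if d in set(subset)),
        pooled_auc=roc.auc,
        roc=roc,
        records=records,
        per_repeat_aucs=per_repeat,
        n_skipped=pre.n_skipped,
        design=design,
    )
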