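"""Class-weighted soft-margin SVM on precomputed Gram matrices.

The classifier is the standard C-SVC dual with separate box constraints for
the two classes: positive examples are bounded by C+ and negative examples by
C-, which compensates for the heavy excess of negatives in the heterodimer
dataset (the usual C-SVC is the special case C+ = C-). The quadratic program
is delegated to scikit-learn's SVC with a precomputed kernel; this module
re-exposes the dual coefficients, bias and decision function and adds the
cross-validation protocol: stratified 10-fold splits, per-training-fold
min-max feature scaling, per-fold precision/recall/F and their arithmetic
means across folds (mean of per-fold F, not F of mean counts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC

from .containers import ConfigError
from .features import FEATURE_NAMES, resolve_feature_set, scale_features
from .kernels import KernelConfig, combine_gram

logger = logging.getLogger(__name__)

_SYMMETRY_RTOL = 1e-8


@dataclass(frozen=True)
class TrainingConfig:
    """Per-class penalties and the kernel configuration used at fit time."""

    c_plus: float = 1.0
    c_minus: float = 1.0
    kernel: KernelConfig = field(default_factory=KernelConfig)

    def __post_init__(self) -> None:
        for name, value in (("c_plus", self.c_plus), ("c_minus", self.c_minus)):
            if not np.isfinite(value) or value <= 0:
                raise ConfigError(f"{name} must be finite and > 0, got {value}")


@dataclass(frozen=True)
class CVConfig:
    n_folds: int = 10
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ConfigError(f"n_folds must be >= 2, got {self.n_folds}")


@dataclass
class TrainedModel:
    """Dual solution of the class-weighted C-SVC on a precomputed Gram.

    ``dual_signed[i]`` is y_i * a_i for support example ``support[i]``; the
    decision value of a test example x is sum_i y_i a_i K(x_i, x) + bias.
    """

    support: np.ndarray
    dual_signed: np.ndarray
    bias: float
    n_train: int
    config: TrainingConfig
    scaler: object | None = None

    def decision_values(self, gram_rows: np.ndarray) -> np.ndarray:
        """Decision values from rows of K(test, train_i) over all training
        examples (columns must match the training set)."""
        gram_rows = np.asarray(gram_rows, dtype=float)
        if gram_rows.ndim == 1:
            gram_rows = gram_rows[None, :]
        if gram_rows.shape[1] != self.n_train:
            raise ValueError(
                f"expected {self.n_train} kernel columns, got {gram_rows.shape[1]}"
            )
        return gram_rows[:, self.support] @ self.dual_signed + self.bias


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if not set(np.unique(labels)) <= {-1, 1}:
        raise ValueError("labels must be +1/-1")
    if len(set(np.unique(labels))) < 2:
        raise ValueError("both classes must be present in the training labels")
    return labels


def fit(gram_train: np.ndarray, labels, config: TrainingConfig) -> TrainedModel:
    """Solve the per-class-penalty soft-margin dual on a precomputed Gram."""
    gram_train = np.asarray(gram_train, dtype=float)
    labels = _check_labels(labels)
    if gram_train.ndim != 2 or gram_train.shape[0] != gram_train.shape[1]:
        raise ValueError(f"Gram must be square, got shape {gram_train.shape}")
    if gram_train.shape[0] != labels.shape[0]:
        raise ValueError("Gram dimension does not match number of labels")
    scale = max(np.abs(gram_train).max(), 1.0)
    if not np.allclose(gram_train, gram_train.T, atol=_SYMMETRY_RTOL * scale):
        raise ValueError("Gram matrix is not symmetric")
    svc = SVC(
        kernel="precomputed",
        C=1.0,
        class_weight={1: config.c_plus, -1: config.c_minus},
    )
    svc.fit(gram_train, labels)
    return TrainedModel(
        support=np.asarray(svc.support_, dtype=int),
        dual_signed=np.asarray(svc.dual_coef_[0], dtype=float),
        bias=float(svc.intercept_[0]),
        n_train=gram_train.shape[0],
        config=config,
    )


def predict(model: TrainedModel, gram_rows: np.ndarray) -> np.ndarray:
    """Predicted labels; a decision value of exactly 0 is called +1."""
    gram_rows = np.asarray(gram_rows, dtype=float)
    if gram_rows.size == 0:
        return np.empty(0, dtype=int)
    values = model.decision_values(gram_rows)
    return np.where(values >= 0.0, 1, -1)


@dataclass(frozen=True)
class PRF:
    """Precision, recall and F-measure with the underlying confusion counts.

    F is the harmonic mean 2PR/(P+R); a zero denominator anywhere yields 0.
    """

    precision: float
    recall: float
    fmeasure: float
    tp: int
    fp: int
    fn: int


def precision_recall_f(predicted, truth) -> PRF:
    """Precision = TP/(TP+FP), recall = TP/(TP+FN), F their harmonic mean;
    degenerate denominators give 0 (logged)."""
    predicted = np.asarray(predicted, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if predicted.shape != truth.shape:
        raise ValueError(f"length mismatch: {predicted.shape} vs {truth.shape}")
    tp = int(np.sum((predicted == 1) & (truth == 1)))
    fp = int(np.sum((predicted == 1) & (truth == -1)))
    fn = int(np.sum((predicted == -1) & (truth == 1)))
    if tp + fp == 0:
        logger.debug("no predicted positives; precision defined as 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        logger.debug("no true positives in the truth; recall defined as 0")
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    fmeasure = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return PRF(precision, recall, fmeasure, tp, fp, fn)


@dataclass(frozen=True)
class CVResult:
    """Arithmetic means over folds plus the per-fold results."""

    precision: float
    recall: float
    fmeasure: float
    folds: tuple[PRF, ...]


def cross_validate(
    feature_rows: np.ndarray,
    labels,
    kdc_matrix: np.ndarray,
    training_config: TrainingConfig,
    cv_config: CVConfig,
    feature_set: str | tuple[int, ...] | None = None,
    scale: bool = True,
) -> CVResult:
    """Stratified k-fold cross-validation of the combined-kernel C-SVC.

    Feature scaling is fit on each training fold only; the linear part of the
    Gram is rebuilt inside the fold from the scaled features, while the
    scale-free K_dc indicator matrix is shared across folds. Deterministic
    given ``cv_config.seed``.
    """
    feature_rows = np.asarray(feature_rows, dtype=float)
    labels = _check_labels(labels)
    kdc_matrix = np.asarray(kdc_matrix, dtype=float)
    n = feature_rows.shape[0]
    if labels.shape[0] != n or kdc_matrix.shape != (n, n):
        raise ValueError("feature rows, labels and K_dc matrix are inconsistently sized")
    if feature_set is None:  # use every column the caller supplied
        cols = list(range(feature_rows.shape[1]))
    else:
        cols = list(resolve_feature_set(feature_set))
    X = feature_rows[:, cols]
    if cv_config.stratified:
        splitter = StratifiedKFold(cv_config.n_folds, shuffle=True, random_state=cv_config.seed)
        splits = splitter.split(X, labels)
    else:
        splitter = KFold(cv_config.n_folds, shuffle=True, random_state=cv_config.seed)
        splits = splitter.split(X)
    folds: list[PRF] = []
    for train_idx, test_idx in splits:
        if not np.any(labels[test_idx] == 1):
            logger.warning("fold without positive examples; recall defined as 0")
        Xtr, Xte = X[train_idx], X[test_idx]
        if scale:
            Xtr, Xte, _ = scale_features(Xtr, Xte)
        kernel = training_config.kernel
        gram_tr = combine_gram(Xtr @ Xtr.T, kdc_matrix[np.ix_(train_idx, train_idx)], kernel)
        gram_te = combine_gram(Xte @ Xtr.T, kdc_matrix[np.ix_(test_idx, train_idx)], kernel)
        model = fit(gram_tr, labels[train_idx], training_config)
        folds.append(precision_recall_f(predict(model, gram_te), labels[test_idx]))
    return CVResult(
        precision=float(np.mean([f.precision for f in folds])),
        recall=float(np.mean([f.recall for f in folds])),
        fmeasure=float(np.mean([f.fmeasure for f in folds])),
        folds=tuple(folds),
    )


def grid_search(
    feature_rows: np.ndarray,
    labels,
    kdc_matrix: np.ndarray,
    alpha_grid,
    cplus_grid,
    cminus_grid,
    cv_config: CVConfig,
    form: str = "convex",
    feature_set: str | tuple[int, ...] | None = None,
    scale: bool = True,
) -> pd.DataFrame:
    """Cross-validate every (alpha, C+, C-) triple; one row per triple."""
    alpha_grid = list(alpha_grid)
    cplus_grid = list(cplus_grid)
    cminus_grid = list(cminus_grid)
    if not (alpha_grid and cplus_grid and cminus_grid):
        raise ValueError("parameter grids must be non-empty")
    rows = []
    for alpha, c_plus, c_minus in product(alpha_grid, cplus_grid, cminus_grid):
        config = TrainingConfig(
            c_plus=c_plus, c_minus=c_minus, kernel=KernelConfig(alpha=alpha, form=form)
        )
        result = cross_validate(
            feature_rows, labels, kdc_matrix, config, cv_config,
            feature_set=feature_set, scale=scale,
        )
        rows.append({
            "alpha": alpha,
            "c_plus": c_plus,
            "c_minus": c_minus,
            "precision": result.precision,
            "recall": result.recall,
            "fmeasure": result.fmeasure,
        })
    return pd.DataFrame(rows)


def select_best(table: pd.DataFrame) -> pd.Series:
    """Best grid row by F-measure; ties go to higher precision, then lower
    alpha, then lower penalties (deterministic)."""
    ordered = table.sort_values(
        by=["fmeasure", "precision", "alpha", "c_plus", "c_minus"],
        ascending=[False, False, True, True, True],
        kind="mergesort",
    )
    return ordered.iloc[0]


def feature_contributions(
    model: TrainedModel, feature_rows: np.ndarray, feature_names=None
) -> pd.DataFrame:
    """Primal weights of a pure linear-kernel model and their contributions.

    Requires a model fit with alpha = 0 (the indicator part has no primal
    representation). ``feature_rows`` must be the matrix the Gram was built
    from (same row order, same scaling). Returns one row per feature with the
    weight w_k = sum_i y_i a_i x_ik, the dataset mean of the feature, their
    product, ranked by descending |product|.
    """
    if model.config.kernel.alpha != 0.0:
        raise ValueError("feature contributions require a model trained with alpha = 0")
    feature_rows = np.asarray(feature_rows, dtype=float)
    if feature_rows.shape[0] != model.n_train:
        raise ValueError("feature rows do not match the training set size")
    if feature_names is None:
        feature_names = list(FEATURE_NAMES[: feature_rows.shape[1]])
    weights = feature_rows[model.support].T @ model.dual_signed
    means = feature_rows.mean(axis=0)
    products = weights * means
    table = pd.DataFrame({
        "feature": list(feature_names),
        "weight": weights,
        "mean": means,
        "product": products,
    })
    table["rank"] = (-table["product"].abs()).rank(method="first").astype(int)
    return table.sort_values("rank", kind="mergesort").reset_index(drop=True)
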