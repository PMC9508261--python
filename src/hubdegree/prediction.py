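"""Degree-based connectome predictive modeling (CPM) with LOOCV.

A linear summary-score model predicts a behavioral outcome from node degree:

1. on the training subjects, correlate each parcel's composite degree with
   behavior and select the parcels with parametric two-tailed p below a
   threshold, split into a positive (r > 0) and a negative (r < 0) set;
2. collapse each subject's degrees into a combined summary score,
   sum over the positive set minus sum over the negative set;
3. fit a one-variable least-squares line of behavior on score;
4. predict the held-out subject from its own score.

Leave-one-out cross-validation repeats selection and fitting on every
training fold, so no information from the held-out subject leaks into the
model that predicts it.  Prediction power is the Pearson correlation of
predicted vs observed behavior across folds, and its significance is
assessed by rerunning the full LOOCV on permuted behavior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "DegreeCPM",
    "PredictionResult",
    "cpm_select",
    "cpm_summary_score",
    "cpm_loocv",
    "cpm_significance",
]


def _feature_correlations(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r and parametric two-tailed p per column; constant columns
    are reported as r=0, p=1 (they can never be selected)."""
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    xn = np.sqrt((Xc**2).sum(axis=0))
    yn = np.sqrt((yc**2).sum())
    ok = (xn > 0) & (yn > 0)
    r = np.zeros(X.shape[1])
    if ok.any():
        r[ok] = (Xc[:, ok].T @ yc) / (xn[ok] * yn)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1 - r**2))
    p = np.where(ok, 2.0 * stats.t.sf(np.abs(t), df=n - 2), 1.0)
    return r, p


def cpm_select(
    train_degrees, train_behavior, p_select: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Select positive- and negative-correlation feature sets.

    Returns the column indices with ``r > 0, p < p_select`` and
    ``r < 0, p < p_select`` respectively.  Constant features are excluded
    with a logged warning.
    """
    X = np.asarray(train_degrees, dtype=float)
    y = np.asarray(train_behavior, dtype=float)
    if X.shape[0] < 5:
        raise ValueError("need at least 5 training subjects")
    constant = X.std(axis=0) == 0
    if constant.any():
        logger.warning(
            "%d constant feature(s) excluded from selection", int(constant.sum())
        )
    r, p = _feature_correlations(X, y)
    pos = np.flatnonzero((r > 0) & (p < p_select))
    neg = np.flatnonzero((r < 0) & (p < p_select))
    return pos, neg


def cpm_summary_score(degrees, positive, negative) -> np.ndarray:
    """Combined degree score: sum over the positive set minus sum over the
    negative set, per subject."""
    X = np.asarray(degrees, dtype=float)
    positive = np.asarray(positive, dtype=int)
    negative = np.asarray(negative, dtype=int)
    if np.intersect1d(positive, negative).size:
        raise ValueError("positive and negative sets must be disjoint")
    return X[:, positive].sum(axis=1) - X[:, negative].sum(axis=1)


class DegreeCPM(BaseEstimator, RegressorMixin):
    """Summary-score linear model over selected degree features.

    Parameters
    ----------
    p_select : float
        Parametric two-tailed p threshold for feature selection.
    mode : {"combined", "separate"}
        "combined" uses the single positive-minus-negative score;
        "separate" regresses on the positive-set and negative-set sums as
        two predictors.

    Fitted attributes: ``r_``, ``pvals_``, ``positive_set_``,
    ``negative_set_``, ``coef_``, ``intercept_``, ``empty_`` (True when no
    feature passed selection, in which case the model predicts the training
    mean).
    """

    def __init__(self, p_select: float = 0.01, mode: str = "combined"):
        self.p_select = p_select
        self.mode = mode

    def _scores(self, X: np.ndarray) -> np.ndarray:
        pos, neg = self.positive_set_, self.negative_set_
        if self.mode == "separate":
            return np.column_stack(
                [X[:, pos].sum(axis=1), X[:, neg].sum(axis=1)]
            )
        return cpm_summary_score(X, pos, neg)[:, None]

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.mode not in ("combined", "separate"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_subjects, n_parcels), y per subject")
        self.r_, self.pvals_ = _feature_correlations(X, y)
        self.positive_set_ = np.flatnonzero((self.r_ > 0) & (self.pvals_ < self.p_select))
        self.negative_set_ = np.flatnonzero((self.r_ < 0) & (self.pvals_ < self.p_select))
        self.n_features_in_ = X.shape[1]
        self.empty_ = (
            self.positive_set_.size == 0 and self.negative_set_.size == 0
        )
        if self.empty_:
            self.coef_ = np.zeros(1 if self.mode == "combined" else 2)
            self.intercept_ = float(y.mean())
            return self
        S = self._scores(X)
        if np.all(S.std(axis=0) == 0):
            logger.warning("summary score has zero variance; predicting the mean")
            self.coef_ = np.zeros(S.shape[1])
            self.intercept_ = float(y.mean())
            return self
        A = np.column_stack([np.ones(len(y)), S])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if self.empty_:
            return np.full(X.shape[0], self.intercept_)
        return self.intercept_ + self._scores(X) @ self.coef_


@dataclass
class PredictionResult:
    """LOOCV prediction outcome."""

    observed: np.ndarray
    predicted: np.ndarray
    scores: np.ndarray
    r: float
    prevalence: np.ndarray
    fold_positive: list = field(repr=False, default_factory=list)
    fold_negative: list = field(repr=False, default_factory=list)
    fold_models: list = field(repr=False, default_factory=list)
    p_select: float = 0.01
    mode: str = "combined"
    permutation_p: float | None = None
    n_perm: int | None = None
    seed: int | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.observed)


def _prediction_r(predicted: np.ndarray, observed: np.ndarray) -> float:
    if np.std(predicted) == 0 or np.std(observed) == 0:
        logger.warning("degenerate prediction (constant); r set to 0")
        return 0.0
    return float(np.corrcoef(predicted, observed)[0, 1])


def _loocv_masks(X: np.ndarray, y: np.ndarray, p_select: float):
    """Per-fold selection masks from leave-one-out training correlations.

    Training-fold sums are obtained by downdating the full-sample sums, so
    the per-fold correlations of every parcel with behavior (and their
    parametric p-values) come out as (n_folds, n_parcels) arrays without an
    explicit loop.  Returns (pos_mask, neg_mask).
    """
    n = X.shape[0]
    m = n - 1  # training size
    Sx = X.sum(axis=0)[None, :] - X
    Sxx = (X**2).sum(axis=0)[None, :] - X**2
    Sy = y.sum() - y
    Syy = (y**2).sum() - y**2
    Sxy = (X.T @ y)[None, :] - X * y[:, None]
    cov = m * Sxy - Sx * Sy[:, None]
    varx = np.maximum(m * Sxx - Sx**2, 0.0)
    vary = np.maximum(m * Syy - Sy**2, 0.0)
    denom = np.sqrt(varx * vary[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, cov / np.maximum(denom, 1e-300), 0.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((m - 2) / np.maximum(1e-300, 1 - r**2))
    p = np.where(denom > 0, 2.0 * stats.t.sf(np.abs(t), df=m - 2), 1.0)
    return (r > 0) & (p < p_select), (r < 0) & (p < p_select)


def _loocv_combined(X: np.ndarray, y: np.ndarray, p_select: float):
    """Vectorized LOOCV with the combined positive-minus-negative score.

    Algebraically identical to fitting a fresh model per fold: selection,
    summary score and the regression line see only the n-1 training rows.
    """
    n = X.shape[0]
    m = n - 1
    pos_mask, neg_mask = _loocv_masks(X, y, p_select)
    M = pos_mask.astype(float) - neg_mask.astype(float)
    S = X @ M.T  # S[k, i]: subject k's score under fold i's selection
    s_own = np.diag(S).copy()
    sum_s = S.sum(axis=0) - s_own
    sum_s2 = (S**2).sum(axis=0) - s_own**2
    sum_sy = (y @ S) - s_own * y
    Sy = y.sum() - y
    var_s = m * sum_s2 - sum_s**2
    cov_sy = m * sum_sy - sum_s * Sy
    scale = np.maximum(m * sum_s2, 1.0)
    degenerate = var_s <= 1e-12 * scale
    empty = ~(pos_mask | neg_mask).any(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(degenerate, 0.0, cov_sy / np.where(degenerate, 1.0, var_s))
    intercept = (Sy - slope * sum_s) / m
    predicted = intercept + slope * s_own
    if np.any(degenerate & ~empty):
        logger.warning(
            "%d fold(s) with zero score variance predict the training mean",
            int((degenerate & ~empty).sum()),
        )
    return predicted, s_own, pos_mask, neg_mask, slope, intercept


def cpm_loocv(
    degrees,
    behavior,
    p_select: float = 0.01,
    mode: str = "combined",
    seed: int | None = None,
) -> PredictionResult:
    """Leave-one-out cross-validated degree-based prediction.

    Feature selection, summary scoring and the regression line are rebuilt
    on the N-1 training subjects of every fold; the held-out subject is
    predicted from its own score.  The combined-score path is computed with
    vectorized leave-one-out updates; the "separate" two-predictor variant
    fits an explicit model per fold.  The procedure is deterministic;
    ``seed`` is recorded for provenance only.
    """
    X = np.asarray(degrees, dtype=float)
    y = np.asarray(behavior, dtype=float)
    n = X.shape[0]
    if n < 10:
        raise ValueError("LOOCV needs at least 10 subjects")

    if mode == "combined":
        predicted, scores, pos_mask, neg_mask, slope, intercept = (
            _loocv_combined(X, y, p_select)
        )
        counts = (pos_mask | neg_mask).sum(axis=0).astype(float)
        fold_pos = [np.flatnonzero(pos_mask[i]) for i in range(n)]
        fold_neg = [np.flatnonzero(neg_mask[i]) for i in range(n)]
        fold_models = [
            {
                "positive": fold_pos[i],
                "negative": fold_neg[i],
                "coef": np.array([slope[i]]),
                "intercept": float(intercept[i]),
            }
            for i in range(n)
        ]
    else:
        predicted = np.empty(n)
        scores = np.empty(n)
        counts = np.zeros(X.shape[1])
        fold_pos, fold_neg, fold_models = [], [], []
        for i in range(n):
            train = np.ones(n, dtype=bool)
            train[i] = False
            model = DegreeCPM(p_select=p_select, mode=mode).fit(
                X[train], y[train]
            )
            predicted[i] = model.predict(X[i])[0]
            scores[i] = model._scores(X[i : i + 1]).sum()
            counts[model.positive_set_] += 1
            counts[model.negative_set_] += 1
            fold_pos.append(model.positive_set_)
            fold_neg.append(model.negative_set_)
            fold_models.append(
                {
                    "positive": model.positive_set_,
                    "negative": model.negative_set_,
                    "coef": model.coef_.copy(),
                    "intercept": model.intercept_,
                }
            )
    return PredictionResult(
        observed=y,
        predicted=predicted,
        scores=scores,
        r=_prediction_r(predicted, y),
        prevalence=counts / n,
        fold_positive=fold_pos,
        fold_negative=fold_neg,
        fold_models=fold_models,
        p_select=p_select,
        mode=mode,
        seed=seed,
    )


def cpm_significance(
    degrees,
    behavior,
    observed_r: float | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
    p_select: float = 0.01,
    mode: str = "combined",
) -> float:
    """Permutation p-value of the LOOCV prediction correlation.

    Behavior is reshuffled ``n_perm`` times and the full LOOCV (including
    per-fold feature selection) is rerun on each shuffle; p is the
    proportion of null prediction correlations >= the observed one.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    X = np.asarray(degrees, dtype=float)
    y = np.asarray(behavior, dtype=float)
    if observed_r is None:
        observed_r = cpm_loocv(X, y, p_select=p_select, mode=mode).r
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        y_perm = rng.permutation(y)
        if mode == "combined":
            predicted, *_ = _loocv_combined(X, y_perm, p_select)
            null_r = _prediction_r(predicted, y_perm)
        else:
            null_r = cpm_loocv(X, y_perm, p_select=p_select, mode=mode).r
        if null_r >= observed_r:
            exceed += 1
    return exceed / n_perm
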