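"""Permutation-based group and brain–behavior inference with FDR control.

Two permutation schemes are provided, mirroring how hub-centrality studies
test node-level effects:

* group differences in degree: group labels are reshuffled (one shared
  schedule across parcels per permutation, preserving the cross-parcel
  dependence of the null) and the p-value is the proportion of permuted
  mean differences at least as large as the observed one;
* degree–behavior correlations: the behavior vector is reshuffled, the
  standard deviation of the permuted correlation coefficients estimates the
  standard error, the observed r divided by that SE gives a z-score, and a
  two-tailed normal p-value follows.

Multiplicity across parcels is controlled with Benjamini–Hochberg FDR; for
correlation tests run on a family of behavioral outcomes the significance
flag uses a Bonferroni-tightened family threshold (0.025 for two outcomes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "cohens_d",
    "bh_fdr",
    "group_permutation_test",
    "correlation_permutation_test",
    "ttest_two_sample",
    "ttest_from_stats",
]


@dataclass(frozen=True)
class TestResult:
    """A two-sample t-test outcome."""

    t: float
    df: float
    p: float
    variant: str


def cohens_d(a, b) -> float:
    """Standardized mean difference (mean_a - mean_b) / pooled SD.

    The pooled SD uses the classical ``n_a + n_b - 2`` denominator.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (
        na + nb - 2
    )
    if pooled_var == 0:
        raise ValueError("pooled standard deviation is zero; d is undefined")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def bh_fdr(p, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up adjusted q-values and rejection flags."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, q <= alpha


def _as_matrix(degrees) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(degrees, pd.DataFrame):
        return degrees.to_numpy(dtype=float), np.asarray(degrees.columns)
    X = np.asarray(degrees, dtype=float)
    return X, np.arange(X.shape[1])


def _vectorized_cohens_d(Xa: np.ndarray, Xb: np.ndarray) -> np.ndarray:
    na, nb = Xa.shape[0], Xb.shape[0]
    pooled_var = (
        (na - 1) * Xa.var(axis=0, ddof=1) + (nb - 1) * Xb.var(axis=0, ddof=1)
    ) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (Xa.mean(axis=0) - Xb.mean(axis=0)) / np.sqrt(pooled_var)
    return np.where(pooled_var > 0, d, np.nan)


def group_permutation_test(
    degrees,
    labels,
    n_perm: int = 5000,
    seed=None,
    alternative: str = "two-sided",
    fdr_alpha: float = 0.05,
    add_one: bool = False,
) -> pd.DataFrame:
    """Permutation test of group mean differences in per-parcel degree.

    Parameters
    ----------
    degrees : (n_subjects, n_parcels) array or DataFrame
    labels : sequence with exactly two distinct values; the statistic is
        mean(first group) - mean(second group), groups ordered by first
        appearance.
    n_perm : number of label reshuffles (>= 100).
    alternative : "two-sided" (default) compares \\|permuted\\| against
        \\|observed\\|; "greater" uses the raw one-sided proportion.
    add_one : apply the (b + 1) / (m + 1) permutation p-value correction
        (off by default: the plain proportion, so p = 0 is possible).

    Returns a DataFrame indexed by parcel with columns
    ``statistic, null_sd, z, p, q, d, significant``.
    """
    X, parcels = _as_matrix(degrees)
    labels = np.asarray(labels)
    if X.shape[0] != labels.shape[0]:
        raise ValueError("labels length does not match number of subjects")
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(groups)}")
    ga, gb = groups
    a_mask = labels == ga
    na, nb = int(a_mask.sum()), int((~a_mask).sum())
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 subjects")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")

    # contrast weights: +1/na for group a, -1/nb for group b
    w = np.where(a_mask, 1.0 / na, -1.0 / nb)
    observed = w @ X

    rng = np.random.default_rng(seed)
    W = np.empty((n_perm, X.shape[0]))
    for i in range(n_perm):
        W[i] = rng.permutation(w)  # one shared schedule across all parcels
    null = W @ X

    if alternative == "two-sided":
        exceed = (np.abs(null) >= np.abs(observed)).sum(axis=0)
    elif alternative == "greater":
        exceed = (null >= observed).sum(axis=0)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    if add_one:
        p = (exceed + 1) / (n_perm + 1)
    else:
        p = exceed / n_perm

    null_sd = null.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(null_sd > 0, observed / null_sd, 0.0)
    q, reject = bh_fdr(p, alpha=fdr_alpha)
    d = _vectorized_cohens_d(X[a_mask], X[~a_mask])
    return pd.DataFrame(
        {
            "statistic": observed,
            "null_sd": null_sd,
            "z": z,
            "p": p,
            "q": q,
            "d": d,
            "significant": reject,
        },
        index=pd.Index(parcels, name="parcel"),
    )


def _pearson_columns(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each column of X with y; zero-variance columns get r=0."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    xn = np.sqrt((Xc**2).sum(axis=0))
    yn = np.sqrt((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc.T @ yc) / (xn * yn)
    return np.where((xn > 0) & (yn > 0), r, 0.0)


def correlation_permutation_test(
    degrees,
    behavior,
    n_perm: int = 5000,
    seed=None,
    family_alpha: float = 0.025,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Permutation-SE z-test of per-parcel degree–behavior correlations.

    For each parcel the Pearson correlation ``r`` between composite degree
    and the behavioral score is computed; the behavior vector is reshuffled
    ``n_perm`` times to estimate the standard error of ``r`` (SD of the
    permuted coefficients), ``z = r / SE`` is referred to the standard
    normal two-tailed, and BH-adjusted q-values are compared against the
    family threshold (default 0.025, Bonferroni over two behavioral
    outcomes).
    """
    X, parcels = _as_matrix(degrees)
    y = np.asarray(behavior, dtype=float)
    if y.ndim != 1 or y.shape[0] != X.shape[0]:
        raise ValueError("behavior must be one value per subject")
    if X.shape[0] < 5:
        raise ValueError("need at least 5 subjects")
    if np.isnan(y).any():
        raise ValueError("behavior contains missing values")
    if y.std() == 0:
        raise ValueError("behavior has zero variance")

    r = _pearson_columns(X, y)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, X.shape[1]))
    for i in range(n_perm):
        null[i] = _pearson_columns(X, rng.permutation(y))
    se = null.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, r / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    q, _ = bh_fdr(p, alpha=fdr_alpha)
    return pd.DataFrame(
        {
            "r": r,
            "se": se,
            "z": z,
            "p": p,
            "q": q,
            "significant": q < family_alpha,
        },
        index=pd.Index(parcels, name="parcel"),
    )


def ttest_from_stats(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
    variant: str = "pooled",
) -> TestResult:
    """Two-sample t-test from summary statistics (pooled or Welch)."""
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    if sd_a <= 0 or sd_b <= 0:
        raise ValueError("standard deviations must be positive")
    equal_var = {"pooled": True, "welch": False}.get(variant)
    if equal_var is None:
        raise ValueError(f"unknown variant {variant!r}")
    res = stats.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=equal_var
    )
    if equal_var:
        df = n_a + n_b - 2
    else:
        va, vb = sd_a**2 / n_a, sd_b**2 / n_b
        df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    return TestResult(
        t=float(res.statistic), df=float(df), p=float(res.pvalue), variant=variant
    )


def ttest_two_sample(a, b, variant: str = "pooled") -> TestResult:
    """Two-sample t-test on raw samples (pooled-variance default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    return ttest_from_stats(
        a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size, variant
    )
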