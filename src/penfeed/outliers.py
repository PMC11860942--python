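"""Robust multivariate outlier removal for meal records.

Anomalous meals (feeder malfunctions, transponder glitches) are flagged
by their robust Mahalanobis distance on (TM, FIM, IBM).  Location and
scatter come from the Minimum Covariance Determinant estimator: the
h = ceil(0.75 n) subset with the smallest covariance determinant.  The
squared distance

    rd(x) = (x - mu)' S^-1 (x - mu)

is compared to 5 x chi2(p, 0.999); with p = 3 the cutoff is 81.33.
Filtering runs separately per breed; first meals (undefined IBM) never
enter the fit and are never flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import MinCovDet

DEFAULT_ALPHA = 0.75
DEFAULT_LEVEL = 0.999
DEFAULT_FACTOR = 5.0
EXHAUSTIVE_MAX_N = 12


@dataclass
class RobustFit:
    """MCD location/scatter with the subset that achieved it."""

    mu: np.ndarray
    S: np.ndarray          # scatter used for distances (consistency-corrected if asked)
    S_raw: np.ndarray      # plain MLE covariance of the h-subset
    h: int
    support: np.ndarray    # boolean mask of the h-subset
    det_S_raw: float
    method: str            # exhaustive | cstep


def consistency_factor(h: int, n: int, p: int) -> float:
    """Scale factor making the MCD scatter consistent at the Gaussian model."""
    alpha = h / n
    q = stats.chi2.ppf(alpha, p)
    return alpha / stats.chi2.cdf(q, p + 2)


def _subset_stats(X: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    sub = X[idx]
    mu = sub.mean(axis=0)
    S = np.cov(sub, rowvar=False, bias=True)
    return mu, S, float(np.linalg.det(S))


def _cstep_all_starts(X: np.ndarray, h: int, max_iter: int = 50) -> np.ndarray:
    """Concentration steps from every elemental (p+1)-subset.

    Each start is concentrated (take the h rows closest to the current
    centre, refit) until the support stabilises; the support with the
    smallest determinant wins.  Feasible for small n only.
    """
    n, p = X.shape
    best_det, best_support = np.inf, None
    for start in combinations(range(n), p + 1):
        sub = X[list(start)]
        mu = sub.mean(axis=0)
        S = np.cov(sub, rowvar=False, bias=True)
        if np.linalg.matrix_rank(S) < p:
            continue
        support = None
        ok = False
        for _ in range(max_iter):
            diff = X - mu
            d = np.einsum("ij,ij->i", diff, np.linalg.solve(S, diff.T).T)
            new_support = np.argsort(d, kind="stable")[:h]
            if support is not None and np.array_equal(new_support, support):
                ok = True
                break
            support = new_support
            mu = X[support].mean(axis=0)
            S = np.cov(X[support], rowvar=False, bias=True)
            if np.linalg.matrix_rank(S) < p:
                break
        if not ok:
            continue
        det = np.linalg.det(S)
        if det < best_det:
            best_det = det
            best_support = support
    if best_support is None:
        raise ValueError(
            "singular MCD scatter: too many duplicate rows; jitter the data"
        )
    mask = np.zeros(n, dtype=bool)
    mask[best_support] = True
    return mask


def mcd_fit(
    X: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    seed: int | None = 0,
    method: str = "auto",
    correct_consistency: bool = True,
) -> RobustFit:
    """Minimum Covariance Determinant fit of location and scatter.

    ``method='exhaustive'`` enumerates every h-subset (exact, feasible
    for small n); ``'cstep'`` uses concentration steps with multiple
    random starts (FastMCD); ``'auto'`` picks exhaustive for
    n <= 12 and cstep otherwise.  Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 10 and method != "exhaustive":
        raise ValueError(f"need at least 10 rows for a stable MCD fit, got {n}")
    if not np.all(np.isfinite(X)):
        raise ValueError("MCD input must be finite (drop undefined rows first)")
    h = int(np.ceil(alpha * n))
    if method == "auto":
        method = "exhaustive" if n <= EXHAUSTIVE_MAX_N else "cstep"

    if method == "exhaustive":
        best = None
        for idx in combinations(range(n), h):
            idx = np.asarray(idx)
            mu, S, det = _subset_stats(X, idx)
            if best is None or det < best[2]:
                best = (mu, S, det, idx)
        mu, S_raw, det, idx = best
        support = np.zeros(n, dtype=bool)
        support[idx] = True
    elif method == "cstep":
        if n <= 15:
            # all elemental (p+1)-subsets as starts, concentrated to convergence
            support = _cstep_all_starts(X, h)
        else:
            mcd = MinCovDet(support_fraction=alpha, random_state=seed, assume_centered=False)
            mcd.fit(X)
            support = mcd.support_
        mu, S_raw, det = _subset_stats(X, np.nonzero(support)[0])
    else:
        raise ValueError(f"unknown MCD method {method!r}")

    if det <= 0 or np.linalg.matrix_rank(S_raw) < p:
        raise ValueError(
            "singular MCD scatter: too many duplicate rows in the best subset; "
            "jitter the data or reduce duplication"
        )
    S = S_raw * consistency_factor(int(support.sum()), n, p) if correct_consistency else S_raw
    return RobustFit(
        mu=mu, S=S, S_raw=S_raw, h=int(support.sum()), support=support,
        det_S_raw=det, method=method,
    )


def robust_distances(X: np.ndarray, fit: RobustFit) -> np.ndarray:
    """Squared robust Mahalanobis distance of each row to the MCD centre."""
    X = np.asarray(X, dtype=float)
    diff = X - fit.mu
    sol = np.linalg.solve(fit.S, diff.T).T
    return np.einsum("ij,ij->i", diff, sol)


def chi2_threshold(p: int = 3, level: float = DEFAULT_LEVEL, factor: float = DEFAULT_FACTOR) -> float:
    """Outlier cutoff on the squared-distance scale: factor x chi2(p, level)."""
    return factor * stats.chi2.ppf(level, p)


def flag_outliers(
    distances: np.ndarray,
    p: int = 3,
    level: float = DEFAULT_LEVEL,
    factor: float = DEFAULT_FACTOR,
) -> tuple[np.ndarray, float, float]:
    """Flag rows whose squared robust distance exceeds the cutoff.

    Returns ``(is_outlier, threshold, removal_rate)``.
    """
    thr = chi2_threshold(p, level, factor)
    d = np.asarray(distances, dtype=float)
    flags = d > thr
    return flags, thr, float(flags.mean()) if d.size else 0.0


def filter_meals(
    meals: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    level: float = DEFAULT_LEVEL,
    factor: float = DEFAULT_FACTOR,
    seed: int | None = 0,
    correct_consistency: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Remove anomalous meals per breed on (TM, FIM, IBM).

    First meals (undefined IBM) and invalid meals' NaN fields stay out
    of the fit; first meals are always retained.  Returns the kept meals
    and a per-breed report of fit and removal statistics.
    """
    cols = ["TM_s", "FIM_g", "IBM_s"]
    keep = pd.Series(True, index=meals.index)
    report: dict = {"per_breed": {}, "threshold": chi2_threshold(3, level, factor)}
    for breed, sub in meals.groupby("breed"):
        complete = sub.dropna(subset=cols)
        entry = {"n": int(len(sub)), "n_fitted": int(len(complete))}
        if len(complete) >= 10:
            fit = mcd_fit(
                complete[cols].to_numpy(), alpha=alpha, seed=seed,
                correct_consistency=correct_consistency,
            )
            rd = robust_distances(complete[cols].to_numpy(), fit)
            flags, thr, rate = flag_outliers(rd, p=3, level=level, factor=factor)
            keep.loc[complete.index[flags]] = False
            entry.update(
                n_flagged=int(flags.sum()),
                removal_rate_pct=100.0 * rate,
                mu=fit.mu.tolist(),
                S=fit.S.tolist(),
            )
        else:
            entry.update(n_flagged=0, removal_rate_pct=0.0, note="too few complete meals")
        report["per_breed"][breed] = entry
    return meals[keep].reset_index(drop=True), report
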