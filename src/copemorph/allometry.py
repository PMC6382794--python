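"""Multivariate regression of shape on covariates and size correction.

Allometry — the shape variation predicted by size — is estimated by
least-squares multivariate regression of tangent-space shape coordinates on
centroid size, optionally pooled within groups (covariate and shapes centred
per group before fitting a common slope).  Size correction keeps the
residuals of that regression; downstream ordination and classification
accept them interchangeably with raw shapes.

Scalar regressions (e.g. spinule counts on centroid size) use ordinary least
squares with a permutation test on r².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["RegressionResult", "regress_shape_on_covariate", "size_correct",
           "regress_count_on_size"]


@dataclass
class RegressionResult:
    """Multivariate regression outcome.

    ``coefficients`` is the tangent-space direction per unit covariate;
    ``percent_predicted`` is 100 * SS_predicted / SS_total of the (group-
    centred) data.
    """

    coefficients: np.ndarray
    percent_predicted: float
    p_value: float | None
    pooling: str
    n: int
    seed: int | None


def _center_within(values: np.ndarray, groups) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if groups is None:
        return values - values.mean(axis=0)
    out = values.copy()
    groups = np.asarray(groups)
    for g in np.unique(groups):
        mask = groups == g
        out[mask] -= out[mask].mean(axis=0)
    return out


def regress_shape_on_covariate(shapes: np.ndarray, covariate: np.ndarray,
                               groups=None, n_perm: int = 0,
                               seed: int | None = None) -> RegressionResult:
    """Regress an n x D shape matrix on a scalar covariate.

    With ``groups`` the covariate and shapes are centred within groups before
    pooling, so the slope is the common within-group allometry.  The
    permutation test shuffles covariate values across units (within groups
    when pooled).
    """
    y = np.asarray(shapes, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if y.shape[0] != x.shape[0]:
        raise ValueError("shapes and covariate must have matching length")
    yc = _center_within(y, groups)
    xc = _center_within(x[:, None], groups)[:, 0]
    sxx = float(np.sum(xc ** 2))
    if sxx == 0.0:
        raise ValueError("zero-variance covariate")
    ss_total = float(np.sum(yc ** 2))

    def percent(xv: np.ndarray) -> tuple[np.ndarray, float]:
        beta = (xv @ yc) / np.sum(xv ** 2)
        ss_pred = float(np.sum(xv ** 2) * np.sum(beta ** 2))
        return beta, 100.0 * ss_pred / ss_total if ss_total > 0 else 0.0

    beta, pct = percent(xc)
    p_value = None
    if n_perm:
        rng = np.random.default_rng(seed)
        groups_arr = None if groups is None else np.asarray(groups)
        count = 0
        for _ in range(n_perm):
            if groups_arr is None:
                xp = rng.permutation(xc)
            else:
                xp = xc.copy()
                for g in np.unique(groups_arr):
                    mask = groups_arr == g
                    xp[mask] = rng.permutation(xp[mask])
            if percent(xp)[1] >= pct:
                count += 1
        p_value = (count + 1) / (n_perm + 1)
    return RegressionResult(coefficients=beta, percent_predicted=pct,
                            p_value=p_value,
                            pooling="within-groups" if groups is not None else "total",
                            n=len(x), seed=seed)


def size_correct(shapes: np.ndarray, centroid_sizes: np.ndarray,
                 groups=None) -> np.ndarray:
    """Residual shapes after regressing out the covariate (idempotent).

    Group means (or the grand mean) are retained so residuals remain
    interpretable as coordinates near the consensus.
    """
    y = np.asarray(shapes, dtype=float)
    fit = regress_shape_on_covariate(y, centroid_sizes, groups=groups)
    xc = _center_within(np.asarray(centroid_sizes, dtype=float)[:, None], groups)[:, 0]
    return y - np.outer(xc, fit.coefficients)


def regress_count_on_size(counts: np.ndarray, sizes: np.ndarray,
                          n_perm: int = 999, seed: int | None = 0
                          ) -> tuple[float, float, float]:
    """OLS of integer counts on size: returns (slope, r², permutation P)."""
    counts = np.asarray(counts, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    if len(counts) < 3:
        raise ValueError("need at least 3 observations")
    res = stats.linregress(sizes, counts)
    r2 = float(res.rvalue ** 2)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = stats.linregress(sizes, rng.permutation(counts))
        if perm.rvalue ** 2 >= r2:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return float(res.slope), r2, p
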