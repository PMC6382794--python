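"""Ordination and pairwise classification of individual mean shapes.

PCA operates on the sample covariance of per-individual (symmetric,
optionally size-corrected) tangent coordinates.  Discriminant analysis is
restricted to species pairs, computed in the principal subspace of the total
covariance (rank control for p >> n) with leave-one-out cross-validation
refitting the discriminant without the held-out individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

__all__ = ["PcaResult", "DiscriminantResult", "pca_shapes", "group_hulls",
           "dfa_pairwise"]


@dataclass
class PcaResult:
    eigenvalues: np.ndarray              # descending
    percent_variance: np.ndarray         # sums to 100
    scores: np.ndarray                   # n x n_axes
    loadings: np.ndarray                 # n_axes x D
    mean: np.ndarray

    def hulls(self, labels, axes: tuple[int, int] = (0, 1)) -> dict[str, np.ndarray]:
        return group_hulls(self.scores[:, list(axes)], labels)


def pca_shapes(shapes: np.ndarray) -> PcaResult:
    """Eigen-decomposition of the sample covariance of shapes (n x D).

    Axis signs are fixed by making the largest-magnitude loading of each
    axis positive.  The number of retained axes is min(n - 1, D).
    """
    y = np.asarray(shapes, dtype=float)
    if y.shape[0] < 3:
        raise ValueError("PCA needs at least 3 individuals")
    mean = y.mean(axis=0)
    yc = y - mean
    cov = yc.T @ yc / (y.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    n_axes = min(y.shape[0] - 1, y.shape[1])
    evals, evecs = evals[:n_axes], evecs[:, :n_axes]
    for j in range(evecs.shape[1]):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] *= -1
    total = evals.sum()
    pct = 100.0 * evals / total if total > 0 else np.zeros_like(evals)
    return PcaResult(eigenvalues=evals, percent_variance=pct,
                     scores=yc @ evecs, loadings=evecs.T, mean=mean)


def group_hulls(points: np.ndarray, labels) -> dict[str, np.ndarray]:
    """Convex hull vertices per group in a 2D score plane."""
    labels = np.asarray(labels)
    out: dict[str, np.ndarray] = {}
    for g in pd.unique(labels):
        pts = np.asarray(points)[labels == g]
        if len(pts) < 3:
            out[str(g)] = pts
            continue
        try:
            hull = ConvexHull(pts)
            out[str(g)] = pts[hull.vertices]
        except QhullError:  # collinear points
            out[str(g)] = pts
    return out


@dataclass
class DiscriminantResult:
    groups: tuple[str, str]
    axis: np.ndarray
    percent_correct: dict[str, float]        # resubstitution, per group
    percent_correct_cv: dict[str, float] | None
    assignments: pd.DataFrame


def _lda_axis(y: np.ndarray, g: np.ndarray, eig_rtol: float = 1e-12,
              reg: float = 1e-10) -> tuple[np.ndarray, float]:
    """Two-group LDA in the principal subspace of the total covariance.

    Returns the discriminant axis (in original coordinates) and the score
    threshold (midpoint of the projected group means, equal priors).
    """
    mean = y.mean(axis=0)
    yc = y - mean
    cov = yc.T @ yc / max(len(y) - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > eig_rtol * evals.max()
    # the pooled within-group covariance has rank at most n - 2 for two
    # groups; restricting the subspace keeps it invertible when p >= n
    n_max = max(len(y) - 2, 1)
    keep &= np.arange(len(evals)) < n_max
    basis = evecs[:, keep]
    z = yc @ basis
    m0, m1 = z[g == 0].mean(axis=0), z[g == 1].mean(axis=0)
    z0, z1 = z[g == 0] - m0, z[g == 1] - m1
    sw = (z0.T @ z0 + z1.T @ z1) / max(len(y) - 2, 1)
    ridge = reg * (np.trace(sw) / len(sw) if np.trace(sw) > 0 else 1.0)
    try:
        w = np.linalg.solve(sw, m1 - m0)
        if not np.all(np.isfinite(w)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        w = np.linalg.solve(sw + ridge * np.eye(len(sw)), m1 - m0)
    if (m1 - m0) @ w < 0:        # orient so group 1 scores above group 0
        w = -w
    axis = basis @ w
    thresh = float((m0 @ w + m1 @ w) / 2 + mean @ axis)
    return axis, thresh


def dfa_pairwise(shapes: np.ndarray, labels, cv: str = "loo") -> DiscriminantResult:
    """Linear discriminant analysis of exactly two groups with optional LOO.

    Percent correct is reported per group both under resubstitution and —
    when ``cv="loo"`` — under leave-one-out, where the discriminant is refit
    without the held-out individual each time.
    """
    y = np.asarray(shapes, dtype=float)
    labels = np.asarray(labels)
    names = pd.unique(labels)
    if len(names) != 2:
        raise ValueError(f"pairwise DFA needs exactly two groups, got {list(names)}")
    g = (labels == names[1]).astype(int)
    if min((g == 0).sum(), (g == 1).sum()) < 3:
        raise ValueError("each group needs at least 3 individuals")

    axis, thresh = _lda_axis(y, g)
    scores = y @ axis
    pred = (scores > thresh).astype(int)
    pct = {str(names[i]): 100.0 * float(np.mean(pred[g == i] == i)) for i in (0, 1)}

    pred_cv = None
    pct_cv = None
    if cv == "loo":
        pred_cv = np.empty(len(y), dtype=int)
        for i in range(len(y)):
            mask = np.ones(len(y), dtype=bool)
            mask[i] = False
            axis_i, thresh_i = _lda_axis(y[mask], g[mask])
            pred_cv[i] = int(y[i] @ axis_i > thresh_i)
        pct_cv = {str(names[i]): 100.0 * float(np.mean(pred_cv[g == i] == i))
                  for i in (0, 1)}
    elif cv != "none":
        raise ValueError(f"unknown cv mode {cv!r}")

    assignments = pd.DataFrame({
        "true": labels,
        "assigned": names[pred],
        "assigned_cv": names[pred_cv] if pred_cv is not None else None,
        "score": scores,
    })
    return DiscriminantResult(groups=(str(names[0]), str(names[1])), axis=axis,
                              percent_correct=pct, percent_correct_cv=pct_cv,
                              assignments=assignments)
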