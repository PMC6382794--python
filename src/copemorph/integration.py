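"""Integration and modularity: two-block PLS, RV coefficient, matrix
correlation, and RV-based modularity tests over landmark partitions.

The RV coefficient generalizes squared correlation to blocks of variables:

    RV = tr(S12 S21) / sqrt(tr(S11^2) tr(S22^2))

on column-centred blocks; it lies in [0, 1] and is invariant to orthogonal
rotation of either block.  Two-block PLS decomposes the between-block
covariance by SVD into paired axes of maximal covariation.  A modularity
hypothesis (a two-subset partition of the landmarks) is supported when the
observed between-subset RV is lower than that of most alternative
partitions of the same subset sizes, optionally restricted to partitions
whose subsets are connected in the scheme's adjacency graph.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = ["PlsResult", "ModularityResult", "rv_coefficient", "pls_two_block",
           "matrix_correlation", "modularity_test"]


def _center(x: np.ndarray, groups=None) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if groups is None:
        return x - x.mean(axis=0)
    out = x.copy()
    groups = np.asarray(groups)
    for g in np.unique(groups):
        mask = groups == g
        out[mask] -= out[mask].mean(axis=0)
    return out


def rv_coefficient(block1: np.ndarray, block2: np.ndarray) -> float:
    """Escoufier's RV between two blocks measured on the same n units."""
    x = _center(block1)
    y = _center(block2)
    if x.shape[0] != y.shape[0]:
        raise ValueError("blocks must have the same number of rows")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 units")
    sxx = x.T @ x
    syy = y.T @ y
    sxy = x.T @ y
    denom = math.sqrt(np.sum(sxx ** 2) * np.sum(syy ** 2))
    if denom == 0.0:
        raise ValueError("zero-variance block")
    return float(np.sum(sxy ** 2) / denom)


@dataclass
class PlsResult:
    singular_values: np.ndarray
    percent_covariance: np.ndarray       # singular value^2 shares, sums to 100
    scores1: np.ndarray
    scores2: np.ndarray
    axes1: np.ndarray                    # p x n_axes
    axes2: np.ndarray                    # q x n_axes
    rv: float
    p_value: float | None
    pooling: str


def pls_two_block(block1: np.ndarray, block2: np.ndarray, pool_by=None,
                  n_perm: int = 999, seed: int | None = 0) -> PlsResult:
    """Two-block partial least squares with RV permutation test.

    Blocks are centred (within pooling cells when ``pool_by`` labels are
    given, e.g. species x sex).  Significance of the RV coefficient is
    assessed by permuting the rows of the second block (within cells),
    simulating independence between blocks.
    """
    x = _center(block1, pool_by)
    y = _center(block2, pool_by)
    if x.shape[0] != y.shape[0]:
        raise ValueError("blocks must be measured on the same individuals")
    n = x.shape[0]
    cov = x.T @ y / (n - 1)
    u, s, vt = np.linalg.svd(cov, full_matrices=False)
    total = np.sum(s ** 2)
    pct = 100.0 * s ** 2 / total if total > 0 else np.zeros_like(s)
    rv_obs = rv_coefficient(x, y)
    p_value = None
    if n_perm:
        rng = np.random.default_rng(seed)
        groups = None if pool_by is None else np.asarray(pool_by)
        count = 0
        for _ in range(n_perm):
            if groups is None:
                yp = y[rng.permutation(n)]
            else:
                yp = y.copy()
                for g in np.unique(groups):
                    mask = np.nonzero(groups == g)[0]
                    yp[mask] = yp[mask[rng.permutation(len(mask))]]
            if rv_coefficient(x, yp) >= rv_obs:
                count += 1
        p_value = (count + 1) / (n_perm + 1)
    return PlsResult(singular_values=s, percent_covariance=pct,
                     scores1=x @ u, scores2=y @ vt.T, axes1=u, axes2=vt.T,
                     rv=rv_obs, p_value=p_value,
                     pooling="pooled" if pool_by is not None else "total")


def _block_mask(k: int, include_diagonal_blocks: bool) -> np.ndarray:
    """Mask over the upper triangle of a 2k x 2k landmark covariance matrix.

    Entries within a landmark's own 2x2 block are excluded when
    ``include_diagonal_blocks`` is false.
    """
    d = 2 * k
    iu = np.triu_indices(d, k=0)
    mask = np.zeros((d, d), dtype=bool)
    mask[iu] = True
    if not include_diagonal_blocks:
        lm = np.arange(d) // 2
        same = lm[:, None] == lm[None, :]
        mask &= ~same
    return mask


def matrix_correlation(cov1: np.ndarray, cov2: np.ndarray,
                       include_diagonal_blocks: bool = True,
                       n_perm: int = 999, seed: int | None = 0
                       ) -> tuple[float, float | None]:
    """Element-wise correlation between two landmark covariance matrices.

    Both matrices must be 2k x 2k over the same landmark scheme.  The
    permutation test permutes landmark identities (whole 2x2 blocks of rows
    and columns) of the second matrix; P = (#{r* >= r} + 1)/(n_perm + 1).
    """
    a = np.asarray(cov1, dtype=float)
    b = np.asarray(cov2, dtype=float)
    if a.shape != b.shape or a.shape[0] != a.shape[1] or a.shape[0] % 2:
        raise ValueError("matrices must be equal, square and 2k x 2k")
    k = a.shape[0] // 2
    mask = _block_mask(k, include_diagonal_blocks)

    def corr(m2: np.ndarray) -> float:
        va, vb = a[mask], m2[mask]
        va = va - va.mean()
        vb = vb - vb.mean()
        return float(va @ vb / np.sqrt((va @ va) * (vb @ vb)))

    r_obs = corr(b)
    p_value = None
    if n_perm:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(k)
            idx = np.empty(2 * k, dtype=int)
            idx[0::2] = 2 * perm
            idx[1::2] = 2 * perm + 1
            if corr(b[np.ix_(idx, idx)]) >= r_obs:
                count += 1
        p_value = (count + 1) / (n_perm + 1)
    return r_obs, p_value


@dataclass
class ModularityResult:
    partition: tuple[tuple[int, ...], tuple[int, ...]]
    rv_observed: float
    rv_alternatives: np.ndarray
    proportion_leq: float
    contiguous_only: bool
    enumerated: bool

    @property
    def n_alternatives(self) -> int:
        return len(self.rv_alternatives)


def _subset_rv(flat: np.ndarray, subset1, subset2) -> float:
    cols1 = np.concatenate([(2 * np.asarray(subset1)), (2 * np.asarray(subset1) + 1)])
    cols2 = np.concatenate([(2 * np.asarray(subset2)), (2 * np.asarray(subset2) + 1)])
    return rv_coefficient(flat[:, np.sort(cols1)], flat[:, np.sort(cols2)])


def _is_contiguous(graph: nx.Graph, subset) -> bool:
    sub = graph.subgraph(subset)
    return sub.number_of_nodes() > 0 and nx.is_connected(sub)


def modularity_test(shapes: np.ndarray, partition, adjacency=None,
                    n_alternatives: int = 10_000, contiguous_only: bool = False,
                    seed: int | None = 0) -> ModularityResult:
    """Compare the RV of a hypothesized landmark partition to alternatives.

    ``shapes`` is n x 2k flattened aligned coordinates; ``partition`` is a
    pair of landmark index collections covering all k landmarks.  All
    same-size alternative partitions are enumerated when their number does
    not exceed ``n_alternatives``; otherwise distinct partitions are sampled
    uniformly.  Support for modularity is the proportion of alternatives
    whose RV is <= the observed (small values support the hypothesis).
    """
    flat = np.asarray(shapes, dtype=float)
    k = flat.shape[1] // 2
    s1 = tuple(sorted(partition[0]))
    s2 = tuple(sorted(partition[1]))
    if set(s1) | set(s2) != set(range(k)) or set(s1) & set(s2):
        raise ValueError("partition must split the landmark set into two disjoint subsets")
    if min(len(s1), len(s2)) < 2:
        raise ValueError("each subset needs at least 2 landmarks")
    graph = None
    if contiguous_only:
        if adjacency is None:
            raise ValueError("contiguous mode requires an adjacency graph")
        graph = adjacency if isinstance(adjacency, nx.Graph) else nx.Graph(list(adjacency))
        graph.add_nodes_from(range(k))

    rv_obs = _subset_rv(flat, s1, s2)
    size1 = len(s1)
    equal_split = (2 * size1 == k)
    n_total = math.comb(k, size1) // (2 if equal_split else 1)

    def ok(sub1: tuple[int, ...]) -> bool:
        if graph is None:
            return True
        rest = tuple(i for i in range(k) if i not in sub1)
        return _is_contiguous(graph, sub1) and _is_contiguous(graph, rest)

    alternatives: list[float] = []
    if n_total <= n_alternatives:
        enumerated = True
        for comb in itertools.combinations(range(k), size1):
            if equal_split and 0 not in comb:
                continue                       # each split counted once
            if not ok(comb):
                continue
            rest = tuple(i for i in range(k) if i not in comb)
            alternatives.append(_subset_rv(flat, comb, rest))
    else:
        enumerated = False
        rng = np.random.default_rng(seed)
        seen = {frozenset(s1)}
        tries = 0
        while len(alternatives) < n_alternatives and tries < 50 * n_alternatives:
            tries += 1
            comb = tuple(sorted(rng.choice(k, size=size1, replace=False)))
            key = frozenset(comb)
            if equal_split:
                key = min(key, frozenset(set(range(k)) - key), key=sorted)
            if key in seen:
                continue
            seen.add(key)
            if not ok(comb):
                continue
            rest = tuple(i for i in range(k) if i not in comb)
            alternatives.append(_subset_rv(flat, comb, rest))
    if not alternatives:
        raise ValueError("no admissible alternative partitions exist")
    alt = np.asarray(alternatives)
    return ModularityResult(partition=(s1, s2), rv_observed=rv_obs,
                            rv_alternatives=alt,
                            proportion_leq=float(np.mean(alt <= rv_obs)),
                            contiguous_only=contiguous_only,
                            enumerated=enumerated)
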