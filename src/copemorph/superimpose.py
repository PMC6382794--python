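"""Generalized Procrustes analysis, semilandmark sliding and symmetry handling.

All shape statistics downstream operate on Procrustes-aligned coordinates:
every configuration is centred, scaled to unit centroid size and rotated to
a consensus that is itself the (renormalized) mean of the aligned set.  The
shape tangent space at the consensus has dimension 2k - 4 for k planar
landmarks (2k coordinates minus 2 for translation, 1 for scale, 1 for
rotation).

Semilandmarks slide along the local tangent of their curve (the chord between
their neighbours) towards the consensus, minimizing Procrustes distance; no
bending-energy criterion is used.

Symmetry is removed in one of two ways.  With *object* symmetry a
reflected-and-relabeled copy of every configuration joins the fit and the
symmetric component of a configuration is the average of the pair.  With
*matching* symmetry the right-side configurations are reflected and the
symmetric component of an individual is the mean of its aligned sides and
replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import Configuration
from .schemes import LandmarkScheme

__all__ = [
    "AlignedSet",
    "SymmetryDecomposition",
    "PairAlignment",
    "centroid_size",
    "procrustes_align_pair",
    "gpa",
    "slide_semilandmarks",
    "decompose_object_symmetry",
    "assemble_matching_symmetry",
    "tangent_coordinates",
    "side_contrast",
]


def centroid_size(coords: np.ndarray) -> float:
    """Root summed squared deviation of landmarks from their centroid."""
    coords = np.asarray(coords, dtype=float)
    dev = coords - coords.mean(axis=0)
    cs = float(np.sqrt(np.sum(dev**2)))
    if cs <= 0.0 or not np.isfinite(cs):
        raise ValueError("degenerate configuration: zero centroid size")
    return cs


def _optimal_rotation(moving: np.ndarray, target: np.ndarray,
                      allow_reflection: bool = False) -> np.ndarray:
    """2x2 matrix R minimizing ||moving @ R - target||_F over rotations."""
    h = moving.T @ target
    u, _, vt = np.linalg.svd(h)
    if allow_reflection:
        return u @ vt
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, d]) @ vt


@dataclass
class PairAlignment:
    """Similarity transform x -> scale * x @ rotation + translation."""

    rotation: np.ndarray
    scale: float
    translation: np.ndarray
    residual: float

    @property
    def angle(self) -> float:
        """Rotation angle in radians (counter-clockwise, row-vector convention)."""
        return float(np.arctan2(self.rotation[0, 1], self.rotation[0, 0]))


def procrustes_align_pair(moving: np.ndarray, target: np.ndarray,
                          allow_reflection: bool = False) -> PairAlignment:
    """Least-squares similarity fit of ``moving`` onto ``target``.

    The residual is the full Procrustes distance: the Frobenius distance
    between the two configurations after centring, scaling to unit centroid
    size and optimal rotation.
    """
    a = np.asarray(moving, dtype=float)
    b = np.asarray(target, dtype=float)
    if a.shape != b.shape:
        raise ValueError("configurations must share dimensions")
    abar, bbar = a.mean(axis=0), b.mean(axis=0)
    ac, bc = a - abar, b - bbar
    cs_a, cs_b = centroid_size(a), centroid_size(b)
    r = _optimal_rotation(ac / cs_a, bc / cs_b, allow_reflection)
    residual = float(np.linalg.norm((ac / cs_a) @ r - bc / cs_b))
    beta = float(np.trace(r.T @ ac.T @ bc) / np.sum(ac**2))
    translation = bbar - beta * abar @ r
    return PairAlignment(rotation=r, scale=beta, translation=translation,
                         residual=residual)


@dataclass
class AlignedSet:
    """Output of generalized Procrustes superimposition.

    ``procrustes_coords`` are centred, unit-centroid-size, consensus-aligned
    configurations; ``centroid_sizes`` are the sizes measured before scaling.
    ``meta`` carries one row of labels per configuration.
    """

    procrustes_coords: np.ndarray        # n x k x 2
    centroid_sizes: np.ndarray           # n
    consensus: np.ndarray                # k x 2
    tangent_dim: int
    iterations_used: int
    meta: pd.DataFrame

    @property
    def n(self) -> int:
        return self.procrustes_coords.shape[0]

    @property
    def k(self) -> int:
        return self.procrustes_coords.shape[1]


def _meta_from_configs(configs: Sequence[Configuration]) -> pd.DataFrame:
    return pd.DataFrame({
        "specimen_id": [c.specimen_id for c in configs],
        "side": [c.side for c in configs],
        "image_rep": [c.image_rep for c in configs],
        "digit_rep": [c.digit_rep for c in configs],
    })


def _gpa_array(coords: np.ndarray, tol: float, max_iter: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Core GPA on an n x k x 2 stack; returns (aligned, consensus, iterations)."""
    n = coords.shape[0]
    x = coords - coords.mean(axis=1, keepdims=True)
    sizes = np.sqrt((x**2).sum(axis=(1, 2)))
    if np.any(sizes <= 0) or not np.all(np.isfinite(sizes)):
        bad = np.nonzero(~((sizes > 0) & np.isfinite(sizes)))[0].tolist()
        raise ValueError(f"degenerate configurations at indices {bad}")
    x = x / sizes[:, None, None]
    consensus = x[0].copy()
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            x[i] = x[i] @ _optimal_rotation(x[i], consensus)
        new_consensus = x.mean(axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        new_consensus /= np.sqrt((new_consensus**2).sum())
        new_consensus = new_consensus @ _optimal_rotation(new_consensus, consensus)
        delta = np.sqrt(((new_consensus - consensus)**2).sum())
        consensus = new_consensus
        if delta < tol:
            break
    return x, consensus, iterations


def gpa(configs: Sequence[Configuration], tol: float = 1e-10,
        max_iter: int = 100, meta: pd.DataFrame | None = None) -> AlignedSet:
    """Generalized Procrustes superimposition of a set of configurations.

    Iterates rotation-to-consensus and consensus update until the consensus
    moves less than ``tol`` (Procrustes norm) or ``max_iter`` is reached.
    """
    if len(configs) < 2:
        raise ValueError("GPA needs at least two configurations")
    ks = {c.k for c in configs}
    if len(ks) > 1:
        raise ValueError(f"mixed landmark counts in GPA input: {sorted(ks)}")
    coords = np.stack([c.coords for c in configs])
    sizes = np.array([centroid_size(c.coords) for c in configs])
    aligned, consensus, iterations = _gpa_array(coords, tol, max_iter)
    k = coords.shape[1]
    return AlignedSet(
        procrustes_coords=aligned,
        centroid_sizes=sizes,
        consensus=consensus,
        tangent_dim=2 * k - 4,
        iterations_used=iterations,
        meta=meta if meta is not None else _meta_from_configs(configs),
    )


def procrustes_ss(aligned: AlignedSet) -> float:
    """Total Procrustes sum of squares around the consensus."""
    return float(np.sum((aligned.procrustes_coords - aligned.consensus)**2))


def slide_semilandmarks(aligned: AlignedSet, scheme: LandmarkScheme,
                        n_cycles: int = 3, tol: float = 1e-10,
                        max_iter: int = 100) -> AlignedSet:
    """Slide semilandmarks along their curve tangents towards the consensus.

    Each slider moves along the chord between its curve neighbours by the
    projection of its deviation from the consensus; sliding alternates with
    re-superimposition for ``n_cycles`` cycles.  The total Procrustes sum of
    squares is non-increasing across cycles (up to numerical tolerance).
    """
    if not scheme.slider_curves:
        raise ValueError(f"scheme {scheme.name!r} has no sliding semilandmarks")
    x = aligned.procrustes_coords.copy()
    consensus = aligned.consensus
    iterations = aligned.iterations_used
    for _ in range(n_cycles):
        for curve in scheme.slider_curves:
            for pos in range(1, len(curve) - 1):
                j, prev_j, next_j = curve[pos], curve[pos - 1], curve[pos + 1]
                tangent = x[:, next_j, :] - x[:, prev_j, :]
                norms = np.linalg.norm(tangent, axis=1, keepdims=True)
                norms[norms == 0] = 1.0
                tangent /= norms
                shift = np.sum((consensus[j] - x[:, j, :]) * tangent, axis=1)
                x[:, j, :] += shift[:, None] * tangent
        x, consensus, iterations = _gpa_array(x, tol, max_iter)
    return AlignedSet(
        procrustes_coords=x,
        centroid_sizes=aligned.centroid_sizes,
        consensus=consensus,
        tangent_dim=aligned.tangent_dim,
        iterations_used=iterations,
        meta=aligned.meta,
    )


@dataclass
class SymmetryDecomposition:
    """Symmetric/asymmetric split of aligned configurations.

    ``symmetric + asymmetric`` reconstructs each aligned original exactly by
    construction.  ``meta`` has one row per original configuration.
    """

    symmetric: np.ndarray                # n x k x 2
    asymmetric: np.ndarray               # n x k x 2
    mode: str
    meta: pd.DataFrame

    @property
    def aligned(self) -> np.ndarray:
        return self.symmetric + self.asymmetric


def _reflect_relabel(coords: np.ndarray, perm: Sequence[int]) -> np.ndarray:
    """Mirror about the y-axis then restore labels via the pairing permutation."""
    reflected = coords.copy()
    reflected[..., 0] *= -1.0
    return reflected[..., list(perm), :]


def decompose_object_symmetry(configs: Sequence[Configuration], scheme: LandmarkScheme,
                              tol: float = 1e-10, max_iter: int = 100,
                              slide_cycles: int = 0) -> tuple[AlignedSet, SymmetryDecomposition]:
    """Joint fit of configurations and their reflected-relabeled copies.

    The symmetric component of a configuration is the average of its aligned
    original and aligned mirror copy; the asymmetric component is the aligned
    original minus the symmetric component.
    """
    if scheme.symmetry != "object":
        raise ValueError(f"scheme {scheme.name!r} does not declare object symmetry")
    perm = scheme.reflection_relabeling()
    n = len(configs)
    coords = np.stack([c.coords for c in configs])
    sizes = np.array([centroid_size(c.coords) for c in configs])
    joint = np.concatenate([coords, _reflect_relabel(coords, perm)])
    meta = _meta_from_configs(configs)
    joint_meta = pd.concat([meta.assign(reflected=False),
                            meta.assign(reflected=True)], ignore_index=True)
    aligned_joint, consensus, iterations = _gpa_array(joint, tol, max_iter)
    aligned = AlignedSet(
        procrustes_coords=aligned_joint,
        centroid_sizes=np.concatenate([sizes, sizes]),
        consensus=consensus,
        tangent_dim=2 * scheme.k - 4,
        iterations_used=iterations,
        meta=joint_meta,
    )
    if slide_cycles and scheme.slider_curves:
        aligned = slide_semilandmarks(aligned, scheme, n_cycles=slide_cycles,
                                      tol=tol, max_iter=max_iter)
    orig = aligned.procrustes_coords[:n]
    # the mirror copies were reflected and relabeled *before* the fit, so the
    # aligned copies are comparable landmark-by-landmark: no second reflection
    mirror = aligned.procrustes_coords[n:]
    symmetric = 0.5 * (orig + mirror)
    decomp = SymmetryDecomposition(symmetric=symmetric, asymmetric=orig - symmetric,
                                   mode="object", meta=meta)
    return aligned, decomp


def assemble_matching_symmetry(configs: Sequence[Configuration], scheme: LandmarkScheme,
                               tol: float = 1e-10, max_iter: int = 100
                               ) -> tuple[AlignedSet, SymmetryDecomposition]:
    """Reflect right sides and jointly superimpose left/right configurations.

    The symmetric component of an individual is the mean of all its aligned
    configurations (both sides, all replicates); each configuration's
    asymmetric component is its deviation from that mean.
    """
    if scheme.symmetry != "matching":
        raise ValueError(f"scheme {scheme.name!r} does not declare matching symmetry")
    perm = scheme.reflection_relabeling()
    coords = np.stack([c.coords for c in configs]).astype(float)
    for i, c in enumerate(configs):
        if c.side == "right":
            coords[i] = _reflect_relabel(coords[i], perm)
    sizes = np.array([centroid_size(c.coords) for c in configs])
    meta = _meta_from_configs(configs)
    aligned_arr, consensus, iterations = _gpa_array(coords, tol, max_iter)
    aligned = AlignedSet(
        procrustes_coords=aligned_arr,
        centroid_sizes=sizes,
        consensus=consensus,
        tangent_dim=2 * scheme.k - 4,
        iterations_used=iterations,
        meta=meta,
    )
    symmetric = np.empty_like(aligned_arr)
    for _, idx in meta.groupby("specimen_id").groups.items():
        idx = np.asarray(idx)
        symmetric[idx] = aligned_arr[idx].mean(axis=0)
    decomp = SymmetryDecomposition(symmetric=symmetric,
                                   asymmetric=aligned_arr - symmetric,
                                   mode="matching", meta=meta)
    return aligned, decomp


def tangent_coordinates(aligned: AlignedSet, rows: np.ndarray | None = None) -> np.ndarray:
    """Flattened coordinates orthogonally projected onto the tangent space.

    The projection removes the component along the (unit) consensus; the
    consensus itself is added back so values stay interpretable as
    coordinates.  Returns an n x 2k array.
    """
    x = aligned.procrustes_coords if rows is None else rows
    flat = x.reshape(x.shape[0], -1)
    c = aligned.consensus.reshape(-1)
    dev = flat - c
    dev = dev - np.outer(dev @ c, c)
    return c + dev


def side_contrast(decomp: SymmetryDecomposition) -> np.ndarray:
    """Mean left-minus-right contrast (k x 2): the directional asymmetry estimate.

    Computed from per-individual side means of aligned coordinates; only
    individuals with both sides contribute.
    """
    if decomp.mode != "matching":
        raise ValueError("side contrast requires a matching-symmetry decomposition")
    aligned = decomp.aligned
    meta = decomp.meta
    contrasts = []
    for _, grp in meta.groupby("specimen_id"):
        left = grp.index[grp["side"] == "left"]
        right = grp.index[grp["side"] == "right"]
        if len(left) and len(right):
            contrasts.append(aligned[np.asarray(left)].mean(axis=0)
                             - aligned[np.asarray(right)].mean(axis=0))
    if not contrasts:
        raise ValueError("no individual has both sides")
    return np.mean(contrasts, axis=0)
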