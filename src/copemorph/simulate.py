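"""Seeded generator of synthetic landmark datasets with the statistical
structure the analyses assume.

The generative model works in the coordinate space of a unit-centroid-size
mean shape ("Procrustes units"):

    individual shape = species(+sex) mean + allometry * (size - mean size)
                       + N(0, sigma^2_individual) per coordinate
    side value       = individual shape +/- DA/2 + N(0, sigma^2_FA)
    image replicate  = side value + N(0, sigma^2_imaging)
    digitization     = image replicate + N(0, sigma^2_digitizing)

Each digitization is emitted in a random similarity pose (rotation,
translation, scaling to the individual's centroid size); right sides are
emitted mirrored, as they would be digitized.  Sizes are log-normal with
multiplicative sex and locality effects.  All randomness flows from the
spec's single seed, and every injected parameter is returned in a truth
record so the pipeline can be closed-loop tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .io import Configuration, read_newick
from .schemes import LandmarkScheme, study_schemes

__all__ = ["SimulationSpec", "simulate_dataset", "simulate_bm_tips",
           "study_fixture", "StudyFixture", "STUDY_TREE_NEWICK",
           "tangent_direction"]

STUDY_TREE_NEWICK = "((vernalis:1,europensis:1):1,(robustus:1,americanus:1):1);"


@dataclass
class SimulationSpec:
    """Parameters of one synthetic dataset for a single structure."""

    scheme: LandmarkScheme
    species_means: Mapping[str, np.ndarray]          # name -> k x 2, unit CS
    n_per_cell: Mapping[tuple[str, str, str], int]   # (species, sex, locality) -> n
    sex_shape_offset: np.ndarray | None = None       # added for males
    sex_size_ratio: float = 1.0                      # male size multiplier
    locality_size_mult: Mapping[str, float] = field(default_factory=dict)
    allometry_vector: np.ndarray | None = None       # k x 2 per unit size
    da_vector: np.ndarray | None = None              # k x 2 left-minus-right
    sigma2_individual: float = 1e-4
    sigma2_fa: float = 0.0
    sigma2_imaging: float = 0.0
    sigma2_digitizing: float = 0.0
    size_log_mean: float = 0.0
    size_log_sd: float = 0.1
    # optional latent individual factor shared across structures: each
    # specimen's scalar loading moves its shape along factor_vector
    factor_vector: np.ndarray | None = None
    factor_values: Mapping[str, float] = field(default_factory=dict)
    n_sides: int = 1
    n_images: int = 1
    n_digits: int = 1
    spinule_rows: Mapping[str, tuple[float, float, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma2_individual", "sigma2_fa", "sigma2_imaging",
                     "sigma2_digitizing"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_sides not in (1, 2):
            raise ValueError("n_sides must be 1 or 2")
        if any(n < 1 for n in self.n_per_cell.values()):
            raise ValueError("cell sample sizes must be at least 1")
        k = self.scheme.k
        for name, mean in self.species_means.items():
            m = np.asarray(mean, dtype=float)
            if m.shape != (k, 2):
                raise ValueError(f"species mean {name!r} must be k x 2")
            if np.allclose(m, m[0]):
                raise ValueError(f"species mean {name!r} is degenerate")


def tangent_direction(vector: np.ndarray, base: np.ndarray) -> np.ndarray:
    """Unit k x 2 direction orthogonal to the similarity directions at ``base``.

    ``base`` must be centred with unit centroid size.  The removed components
    are uniform translations, the scale direction (``base`` itself) and the
    infinitesimal rotation at ``base``.
    """
    k = base.shape[0]
    v = np.asarray(vector, dtype=float).reshape(-1)
    b = base.reshape(-1)
    rot = np.stack([-base[:, 1], base[:, 0]], axis=1).reshape(-1)
    rot = rot / np.linalg.norm(rot)
    tx = np.tile([1.0, 0.0], k) / math.sqrt(k)
    ty = np.tile([0.0, 1.0], k) / math.sqrt(k)
    for direction in (b, rot, tx, ty):
        v = v - (v @ direction) * direction
    return (v / np.linalg.norm(v)).reshape(k, 2)


def _random_pose(coords: np.ndarray, size: float, rng: np.random.Generator,
                 mirror: bool) -> np.ndarray:
    # multiplicative scaling (not renormalization) so landmark-level noise
    # propagates into measured centroid size, as it does in digitized data
    out = (coords - coords.mean(axis=0)) * size
    if mirror:
        out = out * np.array([-1.0, 1.0])
    theta = rng.uniform(0.0, 2.0 * math.pi)
    rot = np.array([[math.cos(theta), math.sin(theta)],
                    [-math.sin(theta), math.cos(theta)]])
    return out @ rot + rng.uniform(-10.0, 10.0, size=2)


def simulate_dataset(spec: SimulationSpec
                     ) -> tuple[list[Configuration], pd.DataFrame, pd.DataFrame, dict]:
    """Generate configurations, classifier and covariate tables, and a truth record."""
    rng = np.random.default_rng(spec.seed)
    k = spec.scheme.k
    mean_size = math.exp(spec.size_log_mean + spec.size_log_sd ** 2 / 2)
    sides = ["none"] if spec.n_sides == 1 else ["left", "right"]
    configs: list[Configuration] = []
    class_rows, cov_rows = [], []
    truth_sizes: dict[str, float] = {}
    counters: dict[tuple[str, str], int] = {}
    for (species, sex, locality), n in spec.n_per_cell.items():
        base = np.asarray(spec.species_means[species], dtype=float)
        if sex == "male" and spec.sex_shape_offset is not None:
            base = base + spec.sex_shape_offset
        for _ in range(n):
            idx = counters.get((species, sex), 0) + 1
            counters[(species, sex)] = idx
            # ids are stable across structures sharing a sampling design, so
            # blocks measured on the same individuals can be matched
            spec_id = f"{species}-{sex[0]}{idx:02d}"
            size = math.exp(rng.normal(spec.size_log_mean, spec.size_log_sd))
            if sex == "male":
                size *= spec.sex_size_ratio
            size *= spec.locality_size_mult.get(locality, 1.0)
            ind = base + rng.normal(0.0, math.sqrt(spec.sigma2_individual), (k, 2))
            if spec.allometry_vector is not None:
                ind = ind + np.asarray(spec.allometry_vector) * (size - mean_size)
            if spec.factor_vector is not None and spec_id in spec.factor_values:
                ind = ind + spec.factor_values[spec_id] * np.asarray(spec.factor_vector)
            truth_sizes[spec_id] = size
            for side in sides:
                val = ind + rng.normal(0.0, math.sqrt(spec.sigma2_fa), (k, 2))
                if spec.da_vector is not None and side != "none":
                    val = val + (0.5 if side == "left" else -0.5) * np.asarray(spec.da_vector)
                for img in range(1, spec.n_images + 1):
                    img_val = val + rng.normal(0.0, math.sqrt(spec.sigma2_imaging), (k, 2))
                    for dig in range(1, spec.n_digits + 1):
                        dig_val = img_val + rng.normal(
                            0.0, math.sqrt(spec.sigma2_digitizing), (k, 2))
                        coords = _random_pose(dig_val, size, rng, mirror=(side == "right"))
                        configs.append(Configuration(
                            specimen_id=spec_id, structure=spec.scheme.name,
                            side=side, image_rep=img, digit_rep=dig, coords=coords))
            class_rows.append(dict(specimen_id=spec_id, species=species,
                                   locality=locality, sex=sex, individual=spec_id))
            if spec.spinule_rows:
                row = {"specimen_id": spec_id}
                for name, (a, b, sd) in spec.spinule_rows.items():
                    row[name] = max(0, round(a + b * size + rng.normal(0.0, sd)))
                cov_rows.append(row)
    classifiers = pd.DataFrame(class_rows).set_index("specimen_id")
    covariates = (pd.DataFrame(cov_rows).set_index("specimen_id")
                  if cov_rows else pd.DataFrame())
    truth = {
        "da_norm": (float(np.linalg.norm(spec.da_vector))
                    if spec.da_vector is not None else 0.0),
        "allometry_norm": (float(np.linalg.norm(spec.allometry_vector))
                           if spec.allometry_vector is not None else 0.0),
        "sigma2_individual": spec.sigma2_individual,
        "sigma2_fa": spec.sigma2_fa,
        "sigma2_imaging": spec.sigma2_imaging,
        "sigma2_digitizing": spec.sigma2_digitizing,
        "mean_size": mean_size,
        "sizes": truth_sizes,
        "seed": spec.seed,
    }
    return configs, classifiers, covariates, truth


def simulate_bm_tips(tree: dendropy.Tree, rate: float, root_shape: np.ndarray,
                     seed: int | None = 0) -> dict[str, np.ndarray]:
    """Brownian-motion tip values: increments N(0, rate * branch length) per coordinate."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    rng = np.random.default_rng(seed)
    root = np.atleast_1d(np.asarray(root_shape, dtype=float))
    values: dict[int, np.ndarray] = {id(tree.seed_node): root}
    tips: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        length = node.edge.length if node.edge.length is not None else 1.0
        step = rng.normal(0.0, math.sqrt(rate * length), root.shape)
        values[id(node)] = values[id(node.parent_node)] + step
        if node.is_leaf():
            tips[node.taxon.label] = values[id(node)]
    return tips


# ---------------------------------------------------------------------------
# The deterministic study fixture
# ---------------------------------------------------------------------------

def _ellipse_shape(k: int, aspect: float = 0.6, rng: np.random.Generator | None = None
                   ) -> np.ndarray:
    angles = 2.0 * math.pi * np.arange(k) / k
    pts = np.stack([np.cos(angles), aspect * np.sin(angles)], axis=1)
    if rng is not None:
        pts = pts + rng.normal(0.0, 0.05, pts.shape)
    pts -= pts.mean(axis=0)
    return pts / math.sqrt(float(np.sum(pts ** 2)))


def _symmetrize(coords: np.ndarray, scheme: LandmarkScheme) -> np.ndarray:
    perm = scheme.reflection_relabeling()
    reflected = coords.copy()
    reflected[:, 0] *= -1.0
    reflected = reflected[perm]
    sym = 0.5 * (coords + reflected)
    for i in scheme.midline:
        sym[i, 0] = 0.0
    return sym


def _gs_base_shape(scheme: LandmarkScheme) -> np.ndarray:
    """Bilaterally symmetric genital-somite template with lateral slider rows."""
    pts = np.zeros((scheme.k, 2))
    # left half (positive x mirrors to negative for partners)
    pts[0] = (-0.45, 0.9)    # LM1 anterior corner
    pts[1] = (-0.55, 0.7)    # LM2 lateral corner (left-curve anchor)
    pts[8] = (-0.5, -0.8)    # LM9 posterior corner (left-curve anchor)
    pts[2] = (-0.3, 0.55)    # LM3 leg-6 seta
    for i in range(5):       # LM4-8 sensilla column
        pts[3 + i] = (-0.22, 0.4 - 0.2 * i)
    for j, i in enumerate(range(19, 32)):    # LM20-32 left lateral edge
        frac = (j + 1) / 14.0
        pts[i] = (-0.55 - 0.12 * math.sin(math.pi * frac), 0.7 - 1.5 * frac)
    pts[18] = (0.0, 0.1)     # LM19 median pore
    # mirror partners
    for a, b in scheme.pairing:
        pts[b] = pts[a] * np.array([-1.0, 1.0])
    pts -= pts.mean(axis=0)
    return pts / math.sqrt(float(np.sum(pts ** 2)))


@dataclass
class StudyFixture:
    """Deterministic synthetic bundle mirroring the study design."""

    schemes: dict[str, LandmarkScheme]
    configurations: dict[str, list[Configuration]]
    classifiers: pd.DataFrame
    covariates: pd.DataFrame
    tree: dendropy.Tree
    newick: str
    truth: dict

    @property
    def n_specimens(self) -> int:
        return len(self.classifiers)

    @property
    def total_landmarks(self) -> int:
        return sum(s.k for s in self.schemes.values())


_SPECIES = ("vernalis", "europensis", "robustus", "americanus")
_LOCALITIES = tuple(f"loc{i}" for i in range(1, 8))

# 100 females + 47 males = 147 specimens over 4 species x up to 7 localities
_FEMALES_PER_SPECIES = (25, 25, 25, 25)
_MALES_PER_SPECIES = (12, 12, 12, 11)


def _design() -> dict[tuple[str, str, str], int]:
    cells: dict[tuple[str, str, str], int] = {}
    for si, species in enumerate(_SPECIES):
        for sex, total in (("female", _FEMALES_PER_SPECIES[si]),
                           ("male", _MALES_PER_SPECIES[si])):
            locs = _LOCALITIES[si: si + 4]        # each species spans 4 localities
            base, extra = divmod(total, len(locs))
            for li, loc in enumerate(locs):
                n = base + (1 if li < extra else 0)
                if n:
                    cells[(species, sex, loc)] = n
    return cells


def study_fixture(seed: int = 1729) -> StudyFixture:
    """Synthetic five-structure dataset with the study's sampling design.

    Effect magnitudes are ordered as the study reports: species > sex >
    locality for systematic effects and individual > FA > imaging >
    digitizing for the variance components.  The object-symmetric genital
    somite is scored for females only; the paired structures carry matching
    symmetry with two imaging replicates (plus duplicate digitization for
    P4Enp3 only).
    """
    rng = np.random.default_rng(seed)
    schemes = study_schemes()
    design = _design()
    female_design = {cell: n for cell, n in design.items() if cell[1] == "female"}

    loc_mult = {loc: float(m) for loc, m in
                zip(_LOCALITIES, 1.0 + 0.05 * rng.standard_normal(len(_LOCALITIES)))}
    # latent individual factor shared by the two distal leg segments, giving
    # them correlated shape variation (the study's strongest RV pair)
    ids: list[str] = []
    counters: dict[tuple[str, str], int] = {}
    for (species, sex, _loc), n in design.items():
        for _ in range(n):
            idx = counters.get((species, sex), 0) + 1
            counters[(species, sex)] = idx
            ids.append(f"{species}-{sex[0]}{idx:02d}")
    factor_values = {i: float(v) for i, v in
                     zip(ids, 0.025 * rng.standard_normal(len(ids)))}
    configurations: dict[str, list[Configuration]] = {}
    classifiers: pd.DataFrame | None = None
    covariates = pd.DataFrame()
    truth: dict = {"seed": seed, "locality_size_mult": loc_mult}

    for name, scheme in schemes.items():
        k = scheme.k
        object_sym = scheme.symmetry == "object"
        base = _gs_base_shape(scheme) if object_sym else _ellipse_shape(k, rng=rng)
        means = {}
        for species in _SPECIES:
            m = base + rng.normal(0.0, 0.05, (k, 2))
            if object_sym:
                m = _symmetrize(m, scheme)
            m -= m.mean(axis=0)
            means[species] = m / math.sqrt(float(np.sum(m ** 2)))
        sex_offset = rng.normal(0.0, 0.02, (k, 2))
        allom = rng.normal(0.0, 1.0, (k, 2))
        allom = 7e-4 * allom / np.linalg.norm(allom)      # ~10-20% of shape variance
        # a pure shape direction: orthogonal to the similarity directions at
        # the mean, so directional asymmetry shows in shape but not in size
        # (the pattern reported for these structures) and its norm is fully
        # recoverable after superimposition
        da = 0.01 * tangent_direction(rng.normal(0.0, 1.0, (k, 2)), base)
        spin = ({"alpha": (4.0, 0.05, 1.0), "beta": (6.0, 0.04, 1.0),
                 "gamma": (5.0, 0.05, 1.0), "delta": (7.0, 0.03, 1.0),
                 "epsilon": (8.0, 0.06, 1.0), "zeta": (6.0, 0.05, 1.0),
                 "La": (10.0, 0.08, 1.5)}
                if name == "P4CxBp" else {})
        fvec = None
        if name in ("P4Exp3", "P4Enp3"):
            fvec = rng.normal(0.0, 1.0, (k, 2))
            fvec /= np.linalg.norm(fvec)
        spec = SimulationSpec(
            scheme=scheme,
            species_means=means,
            n_per_cell=female_design if object_sym else design,
            sex_shape_offset=None if object_sym else sex_offset,
            sex_size_ratio=0.8,
            locality_size_mult=loc_mult,
            allometry_vector=allom,
            da_vector=None if object_sym else da,
            sigma2_individual=1e-4,
            sigma2_fa=1.6e-5,
            sigma2_imaging=1.6e-6,
            sigma2_digitizing=1.6e-7 if name == "P4Enp3" else 0.0,
            size_log_mean=math.log(150.0),
            size_log_sd=0.15,
            factor_vector=fvec,
            factor_values=factor_values if fvec is not None else {},
            n_sides=1 if object_sym else 2,
            n_images=2,
            n_digits=2 if name == "P4Enp3" else 1,
            spinule_rows=spin,
            seed=int(rng.integers(2**31)),
        )
        configs, cls, cov, t = simulate_dataset(spec)
        configurations[name] = configs
        truth[name] = t
        truth[name]["species_means"] = means
        if object_sym is False and classifiers is None:
            classifiers = cls
        if not cov.empty:
            covariates = cov
    tree = read_newick(STUDY_TREE_NEWICK)
    return StudyFixture(schemes=schemes, configurations=configurations,
                        classifiers=classifiers, covariates=covariates,
                        tree=tree, newick=STUDY_TREE_NEWICK, truth=truth)
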