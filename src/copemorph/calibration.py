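"""Closed-loop calibration and recovery studies.

Each routine here generates data with the synthetic generator under known
conditions, pushes it through the full pipeline (superimposition first, then
the statistic under study), and returns the quantity a correctly implemented
method must reproduce: type-I error rates of the permutation tests under
null simulations, and recovery of injected effect sizes (directional
asymmetry, allometry percentage, variance-component ratios, modular
structure) under alternatives.

These functions back both the acceptance checks and the analysis drivers;
problem sizes are chosen so a full sweep runs in minutes on one core.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .allometry import regress_shape_on_covariate
from .anova import procrustes_anova_shape
from .integration import modularity_test, pls_two_block
from .io import Configuration, read_newick
from .ordination import dfa_pairwise
from .phylo import phylo_signal_test
from .schemes import LandmarkScheme
from .simulate import SimulationSpec, simulate_dataset, tangent_direction
from .superimpose import (assemble_matching_symmetry, gpa, procrustes_align_pair,
                          side_contrast, tangent_coordinates)

__all__ = [
    "pair_alignment_vs_grid",
    "typeI_anova_species",
    "typeI_allometry",
    "typeI_pls",
    "typeI_phylo_signal",
    "recover_da_norm",
    "recover_allometry_percent",
    "recover_variance_ratio",
    "recover_modularity",
    "dfa_separated_loo",
    "dfa_null_loo",
]


def _polygon_base(k: int, aspect: float = 0.7) -> np.ndarray:
    ang = 2 * math.pi * np.arange(k) / k
    pts = np.stack([np.cos(ang), aspect * np.sin(ang)], axis=1)
    pts -= pts.mean(axis=0)
    return pts / math.sqrt(float(np.sum(pts ** 2)))


def _scheme(k: int, name: str = "poly") -> LandmarkScheme:
    return LandmarkScheme(name=name, k=k, symmetry="matching")


# ---------------------------------------------------------------------------
# pairwise alignment vs brute-force rotation grid
# ---------------------------------------------------------------------------

def pair_alignment_vs_grid(n_shapes: int = 100, step_deg: float = 0.001,
                           seed: int = 0) -> float:
    """Max |analytic residual - grid-search residual| over random triangles.

    The oracle scans rotation angles in ``step_deg`` increments using the
    closed form ||A R(t) - B||^2 = 2 - 2 (p cos t + q sin t) for centred
    unit-centroid-size planar shapes.
    """
    rng = np.random.default_rng(seed)
    thetas = np.deg2rad(np.arange(0.0, 360.0, step_deg))
    cos_t, sin_t = np.cos(thetas), np.sin(thetas)
    worst = 0.0
    for _ in range(n_shapes):
        a = rng.normal(size=(3, 2))
        b = rng.normal(size=(3, 2))
        fit = procrustes_align_pair(a, b)
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        ac /= np.linalg.norm(ac)
        bc /= np.linalg.norm(bc)
        p = float(np.sum(ac * bc))
        q = float(ac[:, 0] @ bc[:, 1] - ac[:, 1] @ bc[:, 0])
        grid_min = math.sqrt(max(float((2.0 - 2.0 * (p * cos_t + q * sin_t)).min()),
                                 0.0))
        worst = max(worst, abs(fit.residual - grid_min))
    return worst


# ---------------------------------------------------------------------------
# type-I calibration under null simulations
# ---------------------------------------------------------------------------

def typeI_anova_species(n_reps: int = 500, n_perm: int = 199,
                        n_per_species: int = 20, k: int = 8,
                        alpha: float = 0.05, seed: int = 0) -> float:
    """Rejection rate of the species effect when both species share one mean."""
    base = _polygon_base(k)
    scheme = _scheme(k)
    rejections = 0
    master = np.random.default_rng(seed)
    for _ in range(n_reps):
        s = int(master.integers(2**31))
        spec = SimulationSpec(
            scheme=scheme, species_means={"A": base, "B": base},
            n_per_cell={("A", "female", "l"): n_per_species,
                        ("B", "female", "l"): n_per_species},
            sigma2_individual=1e-4, n_sides=1, seed=s)
        configs, cls, _, _ = simulate_dataset(spec)
        aligned = gpa(configs)
        tan = tangent_coordinates(aligned)
        table = procrustes_anova_shape(tan, aligned.meta, cls[["species"]],
                                       aligned.tangent_dim, n_perm=n_perm,
                                       seed=s ^ 0x5DEECE)
        p = table.table.set_index("effect").loc["species", "P"]
        rejections += p <= alpha
    return rejections / n_reps


def typeI_allometry(n_reps: int = 500, n_perm: int = 199, n: int = 100,
                    k: int = 7, alpha: float = 0.05, seed: int = 0) -> float:
    """Rejection rate of the shape-on-size regression with no allometry."""
    base = _polygon_base(k)
    scheme = _scheme(k)
    rejections = 0
    master = np.random.default_rng(seed)
    for _ in range(n_reps):
        s = int(master.integers(2**31))
        spec = SimulationSpec(
            scheme=scheme, species_means={"A": base},
            n_per_cell={("A", "female", "l"): n},
            sigma2_individual=1e-4, n_sides=1,
            size_log_mean=math.log(150.0), size_log_sd=0.15, seed=s)
        configs, _, _, _ = simulate_dataset(spec)
        aligned = gpa(configs)
        tan = tangent_coordinates(aligned)
        res = regress_shape_on_covariate(tan, aligned.centroid_sizes,
                                         n_perm=n_perm, seed=s ^ 0xA5A5A5)
        rejections += res.p_value <= alpha
    return rejections / n_reps


def typeI_pls(n_reps: int = 500, n_perm: int = 199, n: int = 50,
              alpha: float = 0.05, seed: int = 0) -> float:
    """Rejection rate of the PLS RV test for two independent structures."""
    base1, base2 = _polygon_base(7), _polygon_base(10, aspect=0.5)
    sch1, sch2 = _scheme(7, "s1"), _scheme(10, "s2")
    rejections = 0
    master = np.random.default_rng(seed)
    for _ in range(n_reps):
        s = int(master.integers(2**31))
        blocks = []
        for j, (sch, b) in enumerate(((sch1, base1), (sch2, base2))):
            spec = SimulationSpec(
                scheme=sch, species_means={"A": b},
                n_per_cell={("A", "female", "l"): n},
                sigma2_individual=1e-4, n_sides=1, seed=s + j)
            configs, _, _, _ = simulate_dataset(spec)
            aligned = gpa(configs)
            tan = tangent_coordinates(aligned)
            order = np.argsort(aligned.meta["specimen_id"].to_numpy())
            blocks.append(tan[order])
        res = pls_two_block(blocks[0], blocks[1], n_perm=n_perm, seed=s ^ 0x3C3C3C)
        rejections += res.p_value <= alpha
    return rejections / n_reps


def typeI_phylo_signal(n_reps: int = 500, n_perm: int = 199, n_tips: int = 16,
                       dim: int = 4, alpha: float = 0.05, seed: int = 0) -> float:
    """Rejection rate of the signal test for i.i.d. (signal-free) tip shapes."""
    master = np.random.default_rng(seed)
    # an asymmetric ladder tree so tree length actually depends on the
    # tip assignment
    newick = ""
    for i in range(n_tips - 1, 0, -1):
        inner = newick if newick else f"t{n_tips - 1}:1"
        newick = f"(t{i - 1}:{1 + 0.3 * i},{inner}):0.5"
    tree = read_newick(newick + ";")
    rejections = 0
    for _ in range(n_reps):
        s = int(master.integers(2**31))
        rng = np.random.default_rng(s)
        tips = {f"t{i}": rng.normal(size=dim) for i in range(n_tips)}
        res = phylo_signal_test(tree, tips, n_perm=n_perm, seed=s ^ 0x717171)
        rejections += res.p_value <= alpha
    return rejections / n_reps


# ---------------------------------------------------------------------------
# recovery of injected effects
# ---------------------------------------------------------------------------

def recover_da_norm(n_individuals: int = 50, da_norm: float = 0.02,
                    k: int = 8, seed: int = 0) -> tuple[float, float]:
    """(recovered, injected) directional-asymmetry norm via matching symmetry."""
    base = _polygon_base(k)
    rng = np.random.default_rng(seed)
    da = da_norm * tangent_direction(rng.normal(size=(k, 2)), base)
    spec = SimulationSpec(
        scheme=_scheme(k), species_means={"A": base},
        n_per_cell={("A", "female", "l"): n_individuals},
        sigma2_individual=1e-4, sigma2_fa=1e-5, da_vector=da,
        n_sides=2, seed=int(rng.integers(2**31)))
    configs, _, _, truth = simulate_dataset(spec)
    _, decomp = assemble_matching_symmetry(configs, spec.scheme)
    return float(np.linalg.norm(side_contrast(decomp))), truth["da_norm"]


def recover_allometry_percent(target_pct: float = 30.0, n: int = 100,
                              k: int = 7, n_reps: int = 20,
                              seed: int = 0) -> float:
    """Mean recovered percent-predicted for allometry injected at ``target_pct``.

    The allometry vector is scaled so that, in expectation, the size signal
    accounts for ``target_pct`` percent of the tangent-space variance:
    B / (B + (2k - 4) sigma^2) with B = |b|^2 Var(size).
    """
    base = _polygon_base(k)
    sigma2 = 1e-4
    log_sd, log_mean = 0.15, math.log(150.0)
    mean_size = math.exp(log_mean + log_sd ** 2 / 2)
    var_size = (math.exp(log_sd ** 2) - 1) * mean_size ** 2
    noise_ss = (2 * k - 4) * sigma2
    b_sq = (target_pct / (100.0 - target_pct)) * noise_ss / var_size
    master = np.random.default_rng(seed)
    estimates = []
    for _ in range(n_reps):
        s = int(master.integers(2**31))
        rng = np.random.default_rng(s)
        bvec = math.sqrt(b_sq) * tangent_direction(rng.normal(size=(k, 2)), base)
        spec = SimulationSpec(
            scheme=_scheme(k), species_means={"A": base},
            n_per_cell={("A", "female", "l"): n},
            sigma2_individual=sigma2, allometry_vector=bvec, n_sides=1,
            size_log_mean=log_mean, size_log_sd=log_sd, seed=s)
        configs, _, _, _ = simulate_dataset(spec)
        aligned = gpa(configs)
        tan = tangent_coordinates(aligned)
        res = regress_shape_on_covariate(tan, aligned.centroid_sizes)
        estimates.append(res.percent_predicted)
    return float(np.mean(estimates))


def recover_variance_ratio(ratio: float = 10.0, n_individuals: int = 50,
                           k: int = 8, seed: int = 0) -> float:
    """Estimate sigma^2_FA : sigma^2_imaging injected at ``ratio``.

    Uses the moment estimator (MS_FA - MS_imaging / m) / MS_imaging with
    m imaging replicates per side.
    """
    base = _polygon_base(k)
    s2_img = 1e-6
    spec = SimulationSpec(
        scheme=_scheme(k), species_means={"A": base},
        n_per_cell={("A", "female", "l"): n_individuals},
        sigma2_individual=1e-4, sigma2_fa=ratio * s2_img, sigma2_imaging=s2_img,
        n_sides=2, n_images=2, seed=seed)
    configs, _, _, _ = simulate_dataset(spec)
    aligned, _ = assemble_matching_symmetry(configs, spec.scheme)
    tan = tangent_coordinates(aligned)
    table = procrustes_anova_shape(tan, aligned.meta, None,
                                   aligned.tangent_dim, n_perm=0, seed=0)
    t = table.table.set_index("effect")
    ms_fa = t.loc["fluctuating asymmetry", "MS"]
    ms_img = t.loc["imaging", "MS"]
    return float((ms_fa - ms_img / spec.n_images) / ms_img)


def _module_direction(base: np.ndarray, landmarks, rng) -> np.ndarray:
    """Unit k x 2 direction supported on ``landmarks`` only, orthogonal to the
    similarity directions (translation/rotation/scale) at ``base``.

    The orthogonalization is solved within the support, so superimposition
    neither removes the module's variation nor spreads it onto the other
    landmarks.
    """
    k = base.shape[0]
    cols = np.concatenate([(2 * np.asarray(landmarks)),
                           (2 * np.asarray(landmarks) + 1)])
    cols = np.sort(cols)
    b = base.reshape(-1)
    rot = np.stack([-base[:, 1], base[:, 0]], axis=1).reshape(-1)
    tx = np.tile([1.0, 0.0], k)
    ty = np.tile([0.0, 1.0], k)
    constraints = np.stack([b, rot, tx, ty])[:, cols]       # 4 x |support|
    w = rng.normal(size=len(cols))
    coef, *_ = np.linalg.lstsq(constraints.T, w, rcond=None)
    w = w - constraints.T @ coef
    v = np.zeros(2 * k)
    v[cols] = w / np.linalg.norm(w)
    return v.reshape(k, 2)


def recover_modularity(n: int = 60, k: int = 10, n_alternatives: int = 500,
                       seed: int = 0) -> float:
    """Proportion of alternative partitions with RV <= observed when the data
    really contain two independent landmark modules matching the hypothesis."""
    rng = np.random.default_rng(seed)
    base = _polygon_base(k)
    half1, half2 = list(range(k // 2)), list(range(k // 2, k))
    # two independent factors, each moving only its own module along
    # directions invisible to the superimposition
    v1 = np.stack([_module_direction(base, half1, rng) for _ in range(2)])
    v2 = np.stack([_module_direction(base, half2, rng) for _ in range(2)])
    configs = []
    for i in range(n):
        coords = base + rng.normal(0, 0.005, (k, 2))
        coords += rng.normal(0, 0.05) * v1[0] + rng.normal(0, 0.05) * v1[1]
        coords += rng.normal(0, 0.05) * v2[0] + rng.normal(0, 0.05) * v2[1]
        configs.append(Configuration(f"s{i}", "poly", "none", 1, 1, coords))
    aligned = gpa(configs)
    tan = tangent_coordinates(aligned)
    res = modularity_test(tan, (half1, half2), n_alternatives=n_alternatives,
                          seed=seed)
    return res.proportion_leq


# ---------------------------------------------------------------------------
# discriminant sanity
# ---------------------------------------------------------------------------

def _two_species_shapes(mean_offset: float, n_per_species: int, k: int,
                        seed: int) -> tuple[np.ndarray, np.ndarray]:
    base = _polygon_base(k)
    rng = np.random.default_rng(seed)
    other = base + mean_offset * tangent_direction(rng.normal(size=(k, 2)), base)
    spec = SimulationSpec(
        scheme=_scheme(k), species_means={"A": base, "B": other},
        n_per_cell={("A", "female", "l"): n_per_species,
                    ("B", "female", "l"): n_per_species},
        sigma2_individual=1e-4, n_sides=1, seed=seed)
    configs, cls, _, _ = simulate_dataset(spec)
    aligned = gpa(configs)
    tan = tangent_coordinates(aligned)
    labels = cls.loc[aligned.meta["specimen_id"], "species"].to_numpy()
    return tan, labels


def dfa_separated_loo(mean_offset: float = 0.1, n_per_species: int = 15,
                      k: int = 8, seed: int = 0) -> float:
    """Mean leave-one-out percent correct for well-separated species."""
    tan, labels = _two_species_shapes(mean_offset, n_per_species, k, seed)
    res = dfa_pairwise(tan, labels, cv="loo")
    return float(np.mean(list(res.percent_correct_cv.values())))


def dfa_null_loo(n_per_species: int = 30, k: int = 8, seed: int = 0) -> float:
    """Mean leave-one-out percent correct when both groups share one mean."""
    tan, labels = _two_species_shapes(0.0, n_per_species, k, seed)
    res = dfa_pairwise(tan, labels, cv="loo")
    return float(np.mean(list(res.percent_correct_cv.values())))
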