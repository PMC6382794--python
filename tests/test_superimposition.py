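"""GPA, pairwise alignment, sliding and symmetry decomposition.

Brute-force oracles: a 0.001-degree rotation grid for pairwise alignment, a
Monte-Carlo consensus search for GPA minimality, and a 1D position grid for
semilandmark sliding.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from copemorph import (Configuration, LandmarkScheme, centroid_size, gpa,
                       procrustes_align_pair, slide_semilandmarks,
                       decompose_object_symmetry, assemble_matching_symmetry,
                       tangent_coordinates, side_contrast)
from copemorph.superimpose import procrustes_ss

from conftest import octagon, random_config, similarity_transform


def grid_rotation_residual(a, b, step_deg=0.001):
    """Min over a rotation grid of ||unit(a) R(theta) - unit(b)||."""
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    ac /= np.linalg.norm(ac)
    bc /= np.linalg.norm(bc)
    thetas = np.deg2rad(np.arange(0.0, 360.0, step_deg))
    # ||A R - B||^2 = 2 - 2 (p cos t + q sin t) for unit-size planar shapes
    p = float(np.sum(ac * bc))
    q = float(ac[:, 0] @ bc[:, 1] - ac[:, 1] @ bc[:, 0])
    vals = 2.0 - 2.0 * (p * np.cos(thetas) + q * np.sin(thetas))
    return math.sqrt(max(float(vals.min()), 0.0))


class TestCentroidSize:
    def test_unit_square(self):
        coords = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        assert centroid_size(coords) == pytest.approx(math.sqrt(2.0))

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(deadline=None)
    def test_scale_equivariance(self, c):
        coords = octagon()
        assert centroid_size(c * coords) == pytest.approx(c * centroid_size(coords))

    def test_matches_direct_formula(self, rng):
        coords = rng.normal(size=(10, 2))
        direct = math.sqrt(sum((coords[i] - coords.mean(axis=0)) @
                               (coords[i] - coords.mean(axis=0))
                               for i in range(10)))
        assert centroid_size(coords) == pytest.approx(direct, abs=1e-12)

    def test_degenerate_raises(self):
        with pytest.raises(ValueError, match="degenerate|identical"):
            Configuration("s", "t", "none", 1, 1, np.ones((4, 2)))


class TestPairAlignment:
    def test_exact_rotation_recovery(self):
        coords = octagon()
        rotated = similarity_transform(coords, math.radians(37.0), 1.0, (0, 0))
        fit = procrustes_align_pair(coords, rotated)
        assert fit.residual == pytest.approx(0.0, abs=1e-10)
        assert math.degrees(fit.angle) % 360 == pytest.approx(37.0, abs=1e-8)

    def test_reflection_flag(self, rng):
        coords = rng.normal(size=(6, 2))
        mirrored = coords * np.array([-1.0, 1.0])
        no_ref = procrustes_align_pair(coords, mirrored, allow_reflection=False)
        with_ref = procrustes_align_pair(coords, mirrored, allow_reflection=True)
        assert no_ref.residual > 1e-3
        assert with_ref.residual == pytest.approx(0.0, abs=1e-10)

    def test_residual_matches_rotation_grid_oracle(self, rng):
        for _ in range(25):
            a = rng.normal(size=(3, 2))
            b = rng.normal(size=(3, 2))
            fit = procrustes_align_pair(a, b)
            assert fit.residual == pytest.approx(grid_rotation_residual(a, b),
                                                 abs=1e-6)

    def test_transform_maps_moving_onto_target(self, rng):
        a = rng.normal(size=(5, 2))
        b = similarity_transform(a, 0.8, 2.5, (3.0, -1.0))
        fit = procrustes_align_pair(a, b)
        np.testing.assert_allclose(fit.scale * a @ fit.rotation + fit.translation,
                                   b, atol=1e-9)


class TestGpa:
    def test_copies_under_similarity_transforms_collapse(self, rng):
        base = octagon()
        configs = []
        for i in range(6):
            coords = similarity_transform(base, rng.uniform(0, 2 * math.pi),
                                          rng.uniform(0.5, 3.0),
                                          rng.uniform(-5, 5, 2))
            configs.append(Configuration(f"s{i}", "oct", "none", 1, 1, coords))
        aligned = gpa(configs)
        d = aligned.procrustes_coords - aligned.procrustes_coords[0]
        assert np.abs(d).max() < 1e-8

    def test_aligned_set_invariants(self, rng):
        configs = [random_config(rng, k=8, name=f"s{i}") for i in range(7)]
        aligned = gpa(configs)
        cs = np.sqrt((aligned.procrustes_coords ** 2).sum(axis=(1, 2)))
        np.testing.assert_allclose(cs, 1.0, atol=1e-9)
        centroids = aligned.procrustes_coords.mean(axis=1)
        assert np.abs(centroids).max() < 1e-9
        assert aligned.tangent_dim == 2 * 8 - 4
        mean = aligned.procrustes_coords.mean(axis=0)
        mean /= np.linalg.norm(mean)
        assert np.abs(mean - aligned.consensus).max() < 1e-6

    def test_two_configurations_consensus_equidistant(self, rng):
        configs = [random_config(rng, k=6, name=f"s{i}") for i in range(2)]
        aligned = gpa(configs)
        d = np.linalg.norm(aligned.procrustes_coords - aligned.consensus, axis=(1, 2))
        assert d[0] == pytest.approx(d[1], rel=1e-6)

    def test_result_invariant_under_input_similarity_transform(self, rng):
        configs = [random_config(rng, k=8, name=f"s{i}") for i in range(5)]
        moved = [Configuration(c.specimen_id, c.structure, c.side, c.image_rep,
                               c.digit_rep,
                               similarity_transform(c.coords,
                                                    rng.uniform(0, 2 * math.pi),
                                                    rng.uniform(0.5, 2.0),
                                                    rng.uniform(-3, 3, 2)))
                 for c in configs]
        a1, a2 = gpa(configs), gpa(moved)
        # consensus orientation is arbitrary; compare after pairwise alignment
        fit = procrustes_align_pair(a2.consensus, a1.consensus)
        for x1, x2 in zip(a1.procrustes_coords, a2.procrustes_coords):
            np.testing.assert_allclose(x2 @ fit.rotation, x1, atol=1e-6)

    def test_consensus_minimizes_summed_squared_distance(self, rng):
        configs = [random_config(rng, k=5, name=f"s{i}") for i in range(5)]
        aligned = gpa(configs)
        best = procrustes_ss(aligned)
        x = aligned.procrustes_coords
        for _ in range(10_000):
            cand = aligned.consensus + rng.normal(0, 0.05, aligned.consensus.shape)
            cand -= cand.mean(axis=0)
            cand /= np.linalg.norm(cand)
            ss = sum(min(np.sum((xi @ procrustes_align_pair(xi, cand).rotation
                                 - cand) ** 2),
                         np.sum((xi - cand) ** 2)) for xi in x)
            assert ss >= best - 1e-8

    def test_degenerate_input_rejected(self, rng):
        good = random_config(rng, k=4, name="g")
        with pytest.raises(ValueError):
            gpa([good, Configuration("b", "oct", "none", 1, 1,
                                     np.ones((4, 2)) + np.array([[0, 1e-30]] * 4))])


def curved_scheme():
    """Six landmarks: anchors 0 and 5, sliders 1-4 on the arc between them."""
    return LandmarkScheme(name="curve", k=6,
                          slider_curves=((0, 1, 2, 3, 4, 5),))


def arc_coords(jitter=None, rng=None):
    t = np.linspace(0.0, math.pi, 6)
    pts = np.stack([np.cos(t), np.sin(t) * 0.8 + 0.1], axis=1)
    if jitter is not None:
        pts = pts + rng.normal(0, jitter, pts.shape)
    return pts


class TestSliding:
    def test_sliders_at_optimum_do_not_move(self):
        scheme = curved_scheme()
        base = arc_coords()
        configs = [Configuration(f"s{i}", "curve", "none", 1, 1, base.copy())
                   for i in range(4)]
        aligned = gpa(configs)
        slid = slide_semilandmarks(aligned, scheme, n_cycles=2)
        np.testing.assert_allclose(slid.procrustes_coords,
                                   aligned.procrustes_coords, atol=1e-9)

    def test_in_tangent_perturbation_is_removed(self):
        scheme = curved_scheme()
        base = arc_coords()
        perturbed = base.copy()
        tangent = base[3] - base[1]
        tangent /= np.linalg.norm(tangent)
        perturbed[2] += 0.08 * tangent
        configs = [Configuration("clean0", "curve", "none", 1, 1, base.copy()),
                   Configuration("clean1", "curve", "none", 1, 1, base.copy()),
                   Configuration("pert", "curve", "none", 1, 1, perturbed)]
        aligned = gpa(configs)
        before = procrustes_ss(aligned)
        slid = slide_semilandmarks(aligned, scheme, n_cycles=4)
        after = procrustes_ss(slid)
        assert after < 0.05 * before

    def test_single_slider_matches_grid_search(self, rng):
        scheme = LandmarkScheme(name="one", k=5, slider_curves=((1, 2, 3),))
        base = np.array([[0.0, 1.0], [-1.0, 0.0], [0.0, 0.05], [1.0, 0.0],
                         [0.0, -1.0]])
        pert = base.copy()
        pert[2] += np.array([0.3, 0.0])
        configs = [Configuration("a", "one", "none", 1, 1, base.copy()),
                   Configuration("b", "one", "none", 1, 1, base.copy()),
                   Configuration("c", "one", "none", 1, 1, pert)]
        aligned = gpa(configs)
        # oracle: grid over slider positions along its tangent, one sliding
        # step without re-superimposition
        x = aligned.procrustes_coords[2]
        t = x[3] - x[1]
        t /= np.linalg.norm(t)
        shifts = np.linspace(-0.5, 0.5, 20001)
        cands = x[2][None, :] + shifts[:, None] * t[None, :]
        d2 = ((cands - aligned.consensus[2]) ** 2).sum(axis=1)
        best_shift = shifts[np.argmin(d2)]
        slid = slide_semilandmarks(aligned, scheme, n_cycles=1)
        # the slid configuration must equal the grid optimum as a *shape*
        # (the refit only changes pose, not shape)
        manual = x.copy()
        manual[2] = x[2] + best_shift * t
        fit = procrustes_align_pair(manual, slid.procrustes_coords[2])
        assert fit.residual < 1e-4

    def test_sliding_never_increases_procrustes_ss(self, rng):
        scheme = curved_scheme()
        configs = [Configuration(f"s{i}", "curve", "none", 1, 1,
                                 arc_coords(jitter=0.05, rng=rng))
                   for i in range(8)]
        aligned = gpa(configs)
        prev = procrustes_ss(aligned)
        for _ in range(4):
            aligned = slide_semilandmarks(aligned, scheme, n_cycles=1)
            cur = procrustes_ss(aligned)
            assert cur <= prev + 1e-10
            prev = cur

    def test_scheme_without_sliders_rejected(self, rng, octagon_scheme):
        configs = [random_config(rng, name=f"s{i}") for i in range(3)]
        with pytest.raises(ValueError, match="slid"):
            slide_semilandmarks(gpa(configs), octagon_scheme, 1)


def symmetric_scheme():
    """k=5 object symmetry: pairs (0,1), (2,3), midline 4."""
    return LandmarkScheme(name="sym", k=5, symmetry="object",
                          pairing=((0, 1), (2, 3)), midline=(4,))


def symmetric_coords():
    return np.array([[-1.0, 1.0], [1.0, 1.0], [-0.8, -0.5], [0.8, -0.5],
                     [0.0, 0.2]])


class TestObjectSymmetry:
    def test_symmetric_config_has_zero_asymmetry(self, rng):
        scheme = symmetric_scheme()
        configs = [Configuration(f"s{i}", "sym", "none", 1, 1,
                                 similarity_transform(symmetric_coords(),
                                                      rng.uniform(0, 6.28),
                                                      rng.uniform(0.5, 2),
                                                      rng.uniform(-3, 3, 2)))
                   for i in range(4)]
        _, decomp = decompose_object_symmetry(configs, scheme)
        assert np.abs(decomp.asymmetric).max() < 1e-10

    def test_single_landmark_offset_splits_evenly(self):
        scheme = symmetric_scheme()
        base = symmetric_coords()
        delta = np.array([0.0, 0.04])
        pert = base.copy()
        pert[0] += delta
        configs = [Configuration("s0", "sym", "none", 1, 1, pert)]
        configs += [Configuration(f"s{i}", "sym", "none", 1, 1, base.copy())
                    for i in (1, 2)]
        _, decomp = decompose_object_symmetry(configs, scheme)
        asym = decomp.asymmetric[0]
        # the offset splits +/- delta/2 between the paired landmarks, up to
        # the (small) realignment of the joint fit
        split = asym[0] - asym[1]
        assert np.linalg.norm(split - delta / centroid_size(pert)) < 0.01
        assert np.linalg.norm(asym[0] + asym[1]) < 5e-3

    def test_reconstruction_identity_and_orthogonality(self, rng):
        scheme = symmetric_scheme()
        configs = [Configuration(f"s{i}", "sym", "none", 1, 1,
                                 symmetric_coords() + rng.normal(0, 0.05, (5, 2)))
                   for i in range(6)]
        aligned, decomp = decompose_object_symmetry(configs, scheme)
        n = len(configs)
        np.testing.assert_allclose(decomp.symmetric + decomp.asymmetric,
                                   aligned.procrustes_coords[:n], atol=1e-12)
        # total SS around the consensus splits into symmetric + asymmetric parts
        dev = aligned.procrustes_coords - aligned.consensus
        total = float(np.sum(dev ** 2))
        sym_part = 2.0 * float(np.sum((decomp.symmetric - aligned.consensus) ** 2))
        asym_part = 2.0 * float(np.sum(decomp.asymmetric ** 2))
        assert total == pytest.approx(sym_part + asym_part, abs=1e-8)

    def test_unpaired_landmark_rejected(self):
        with pytest.raises(ValueError, match="unpaired"):
            LandmarkScheme(name="bad", k=5, symmetry="object",
                           pairing=((0, 1),), midline=(4,))


class TestMatchingSymmetry:
    def _paired_configs(self, rng, offset=None, n_ind=10):
        base = octagon()
        configs = []
        for i in range(n_ind):
            ind = base + rng.normal(0, 0.02, base.shape)
            left = ind.copy()
            right = ind.copy()
            if offset is not None:
                left = left + offset / 2
                right = right - offset / 2
            right = right * np.array([-1.0, 1.0])      # digitized mirrored
            for side, coords in (("left", left), ("right", right)):
                configs.append(Configuration(
                    f"i{i}", "oct", side, 1, 1,
                    similarity_transform(coords, rng.uniform(0, 6.28),
                                         rng.uniform(0.8, 1.2),
                                         rng.uniform(-2, 2, 2))))
        return configs

    def test_identical_sides_have_zero_deviation(self, rng, octagon_scheme):
        configs = self._paired_configs(rng)
        _, decomp = assemble_matching_symmetry(configs, octagon_scheme)
        assert np.abs(decomp.asymmetric).max() < 1e-8

    def test_injected_directional_asymmetry_recovered(self, rng, octagon_scheme):
        offset = np.zeros((8, 2))
        offset[0] = (0.0, 0.05)
        offset[4] = (0.0, -0.05)
        configs = self._paired_configs(rng, offset=offset, n_ind=25)
        aligned, decomp = assemble_matching_symmetry(configs, octagon_scheme)
        contrast = side_contrast(decomp)
        # the aligned frame has arbitrary orientation: rotate the contrast
        # back into the frame of the generating base shape
        base = octagon()
        scale = centroid_size(base)
        fit = procrustes_align_pair(aligned.consensus, base / scale)
        contrast = contrast @ fit.rotation
        # superimposition removes the offset's similarity components, so the
        # recoverable part is its projection onto the tangent space at the base
        b = (base / scale).reshape(-1)
        rot = (np.stack([-base[:, 1], base[:, 0]], axis=1) / scale).reshape(-1)
        tx = np.tile([1.0, 0.0], 8) / math.sqrt(8)
        ty = np.tile([0.0, 1.0], 8) / math.sqrt(8)
        expected = offset.reshape(-1) / scale
        for direction in (b, rot, tx, ty):
            expected = expected - (expected @ direction) * direction
        cos = (contrast.reshape(-1) @ expected
               / (np.linalg.norm(contrast) * np.linalg.norm(expected)))
        assert cos > 0.95
        assert np.linalg.norm(contrast) == pytest.approx(
            np.linalg.norm(expected), rel=0.2)

    def test_side_relabeling_leaves_distances_unchanged(self, rng, octagon_scheme):
        configs = self._paired_configs(rng, n_ind=6)
        flipped = [Configuration(c.specimen_id, c.structure,
                                 {"left": "right", "right": "left"}[c.side],
                                 c.image_rep, c.digit_rep, c.coords)
                   for c in configs]
        a1, _ = assemble_matching_symmetry(configs, octagon_scheme)
        a2, _ = assemble_matching_symmetry(flipped, octagon_scheme)
        d1 = np.linalg.norm(a1.procrustes_coords - a1.consensus, axis=(1, 2))
        d2 = np.linalg.norm(a2.procrustes_coords - a2.consensus, axis=(1, 2))
        np.testing.assert_allclose(np.sort(d1), np.sort(d2), atol=1e-6)


def test_tangent_dimension_is_2k_minus_4(rng):
    configs = [random_config(rng, k=45, name=f"s{i}") for i in range(4)]
    aligned = gpa(configs)
    assert aligned.tangent_dim == 86
    tan = tangent_coordinates(aligned)
    assert tan.shape == (4, 90)
    c = aligned.consensus.reshape(-1)
    # projection removed the component along the consensus
    assert np.abs((tan - c) @ c).max() < 1e-10
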