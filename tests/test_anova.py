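"""Goodall's F, hierarchical Procrustes ANOVA and size ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from copemorph import (LandmarkScheme, SimulationSpec, anova_size,
                       assemble_matching_symmetry, goodall_f,
                       procrustes_anova_shape, simulate_dataset,
                       tangent_coordinates, study_schemes, gpa)

from conftest import octagon


class TestGoodallF:
    def test_equal_mean_squares_give_one(self):
        assert goodall_f(3.0, 5, 3.0, 5) == pytest.approx(1.0)

    def test_shape_df_arithmetic(self):
        # df already carry the tangent-dimension multiplier (86 for k=45)
        assert goodall_f(2.0, 1 * 86, 1.0, 2 * 86) == pytest.approx(4.0)

    def test_matches_independent_recomputation(self, rng):
        for _ in range(20):
            ss_e, ss_err = rng.uniform(0.1, 5, 2)
            df_e, df_err = rng.integers(1, 50, 2)
            expected = (ss_e / df_e) / (ss_err / df_err)
            assert goodall_f(ss_e, int(df_e), ss_err, int(df_err)) == \
                pytest.approx(expected, rel=1e-12)

    def test_zero_error_flags_infinite(self):
        assert goodall_f(1.0, 2, 0.0, 4) == float("inf")


def _simulate_two_species(seed, mean_offset=0.0, n_per_species=20, k=8):
    scheme = LandmarkScheme(name="oct", k=k, symmetry="matching",
                            adjacency=tuple((i, (i + 1) % k) for i in range(k)))
    base = octagon()
    base = base / np.linalg.norm(base)
    mean_b = base.copy()
    if mean_offset:
        rng = np.random.default_rng(seed + 1_000_000)
        direction = rng.normal(size=(k, 2))
        direction /= np.linalg.norm(direction)
        mean_b = mean_b + mean_offset * direction
    spec = SimulationSpec(
        scheme=scheme,
        species_means={"A": base, "B": mean_b},
        n_per_cell={("A", "female", "l1"): n_per_species,
                    ("B", "female", "l1"): n_per_species},
        sigma2_individual=1e-4,
        sigma2_fa=1.6e-5,
        sigma2_imaging=1.6e-6,
        n_sides=2,
        n_images=2,
        seed=seed,
    )
    return simulate_dataset(spec), scheme


class TestShapeAnova:
    def test_strong_species_effect_tops_table(self):
        (configs, cls, _, _), scheme = _simulate_two_species(3, mean_offset=0.1)
        aligned, _ = assemble_matching_symmetry(configs, scheme)
        tan = tangent_coordinates(aligned)
        table = procrustes_anova_shape(tan, aligned.meta, cls,
                                       aligned.tangent_dim, n_perm=99, seed=0)
        t = table.table.set_index("effect")
        assert t.loc["species", "F"] == t["F"].max()
        assert t.loc["species", "P"] == pytest.approx(1 / 100)

    def test_observed_f_beyond_all_permutations_gives_plus_one_p(self):
        (configs, cls, _, _), scheme = _simulate_two_species(4, mean_offset=0.2)
        aligned, _ = assemble_matching_symmetry(configs, scheme)
        tan = tangent_coordinates(aligned)
        table = procrustes_anova_shape(tan, aligned.meta, cls,
                                       aligned.tangent_dim, n_perm=49, seed=0)
        t = table.table.set_index("effect")
        assert t.loc["species", "P"] == pytest.approx(1 / 50)

    def test_identical_seed_gives_identical_table(self):
        (configs, cls, _, _), scheme = _simulate_two_species(5, mean_offset=0.02)
        aligned, _ = assemble_matching_symmetry(configs, scheme)
        tan = tangent_coordinates(aligned)
        t1 = procrustes_anova_shape(tan, aligned.meta, cls,
                                    aligned.tangent_dim, n_perm=49, seed=7)
        t2 = procrustes_anova_shape(tan, aligned.meta, cls,
                                    aligned.tangent_dim, n_perm=49, seed=7)
        pd.testing.assert_frame_equal(t1.table, t2.table)

    def test_p_values_within_valid_range(self):
        (configs, cls, _, _), scheme = _simulate_two_species(6)
        aligned, _ = assemble_matching_symmetry(configs, scheme)
        tan = tangent_coordinates(aligned)
        table = procrustes_anova_shape(tan, aligned.meta, cls,
                                       aligned.tangent_dim, n_perm=49, seed=1)
        p = table.table["P"].dropna()
        assert ((p >= 1 / 50) & (p <= 1.0)).all()

    def test_single_level_effect_omitted_with_warning(self):
        (configs, cls, _, _), scheme = _simulate_two_species(8)
        aligned, _ = assemble_matching_symmetry(configs, scheme)
        tan = tangent_coordinates(aligned)
        with pytest.warns(UserWarning, match="single level"):
            table = procrustes_anova_shape(tan, aligned.meta, cls,
                                           aligned.tangent_dim, n_perm=9, seed=1)
        assert "sex" not in set(table.table["effect"])

    def test_variance_component_ratio_recovered(self):
        # injected sigma2_FA : sigma2_imaging = 10 with 50 individuals; the
        # FA and imaging mean squares estimate it within +/-30%
        scheme = LandmarkScheme(name="oct", k=8, symmetry="matching")
        base = octagon()
        base = base / np.linalg.norm(base)
        spec = SimulationSpec(
            scheme=scheme, species_means={"A": base},
            n_per_cell={("A", "female", "l1"): 50},
            sigma2_individual=1e-4, sigma2_fa=1.0e-5, sigma2_imaging=1.0e-6,
            n_sides=2, n_images=2, seed=11)
        configs, cls, _, truth = simulate_dataset(spec)
        aligned, _ = assemble_matching_symmetry(configs, scheme)
        tan = tangent_coordinates(aligned)
        table = procrustes_anova_shape(tan, aligned.meta, None,
                                       aligned.tangent_dim, n_perm=0, seed=0)
        t = table.table.set_index("effect")
        ms_fa, ms_img = t.loc["fluctuating asymmetry", "MS"], t.loc["imaging", "MS"]
        # E[MS_FA] = s2_FA + s2_img / n_images, E[MS_img] = s2_img
        ratio = (ms_fa - ms_img / 2) / ms_img
        assert ratio == pytest.approx(10.0, rel=0.3)


class TestSizeAnova:
    def test_all_equal_sizes_flagged(self):
        meta = pd.DataFrame({
            "specimen_id": [f"s{i}" for i in range(6) for _ in range(2)],
            "side": ["left", "right"] * 6,
            "image_rep": 1, "digit_rep": 1})
        cls = pd.DataFrame({"species": ["A"] * 3 + ["B"] * 3,
                            "locality": "l1", "sex": "female"},
                           index=pd.Index([f"s{i}" for i in range(6)]))
        table = anova_size(np.ones(12), meta, cls, n_perm=9, seed=0)
        t = table.table.set_index("effect")
        assert t.loc["species", "F"] == 0.0 or np.isnan(t.loc["species", "F"])

    def test_injected_sex_effect_detected(self):
        rng = np.random.default_rng(0)
        n = 30
        sexes = ["female"] * n + ["male"] * n
        sizes = np.where(np.array(sexes) == "male", 10.0, 12.0) + rng.normal(0, 1.0, 2 * n)
        meta = pd.DataFrame({"specimen_id": [f"s{i}" for i in range(2 * n)],
                             "side": "none", "image_rep": 1, "digit_rep": 1})
        cls = pd.DataFrame({"species": "A", "locality": "l1", "sex": sexes},
                           index=pd.Index([f"s{i}" for i in range(2 * n)]))
        with pytest.warns(UserWarning, match="single level"):
            table = anova_size(sizes, meta, cls, n_perm=199, seed=1)
        t = table.table.set_index("effect")
        assert t.loc["sex", "F"] > 10
        assert t.loc["sex", "P"] == pytest.approx(1 / 200)

    def test_balanced_two_group_f_matches_classical_anova(self):
        # one observation per individual: the species row must equal the
        # classical one-way F computed by an independent implementation
        rng = np.random.default_rng(42)
        n = 15
        sizes = np.concatenate([rng.normal(10, 1, n), rng.normal(11, 1, n)])
        ids = [f"s{i}" for i in range(2 * n)]
        meta = pd.DataFrame({"specimen_id": ids, "side": "none",
                             "image_rep": 1, "digit_rep": 1})
        cls = pd.DataFrame({"species": ["A"] * n + ["B"] * n,
                            "locality": "l1", "sex": "female"},
                           index=pd.Index(ids))
        with pytest.warns(UserWarning):
            table = anova_size(sizes, meta, cls, n_perm=0, seed=0)
        t = table.table.set_index("effect")
        f_classical = stats.f_oneway(sizes[:n], sizes[n:]).statistic
        assert t.loc["species", "F"] == pytest.approx(f_classical, abs=1e-10)


def test_component_ss_sum_to_total_within_strata():
    (configs, cls, _, _), scheme = _simulate_two_species(9, mean_offset=0.03)
    aligned, _ = assemble_matching_symmetry(configs, scheme)
    tan = tangent_coordinates(aligned)
    table = procrustes_anova_shape(tan, aligned.meta, cls,
                                   aligned.tangent_dim, n_perm=0, seed=0)
    t = table.table.set_index("effect")
    # the side-mean stratum decomposes exactly: individual + DA + FA = total
    meta = aligned.meta
    cell = meta["specimen_id"] + "|" + meta["side"]
    z = pd.DataFrame(tan).groupby(cell.values).mean()
    ids = [c.split("|")[0] for c in z.index]
    sides = [c.split("|")[1] for c in z.index]
    zc = z.values - z.values.mean(axis=0)
    total = float(np.sum(zc ** 2))
    ss_sum = (t.loc["individual", "SS"] + t.loc["directional asymmetry", "SS"]
              + t.loc["fluctuating asymmetry", "SS"])
    assert ss_sum == pytest.approx(total, abs=1e-8)
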