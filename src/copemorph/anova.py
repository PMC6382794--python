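"""Hierarchical Procrustes ANOVA of shape and ANOVA of centroid size.

Variation is decomposed over the strata of the measurement design — species,
locality and sex among individuals; individuals; side (directional
asymmetry); the individual x side interaction (fluctuating asymmetry);
imaging replicates; digitizing replicates — and each effect is tested
one-way with Goodall's F against the mean square of the stratum directly
below it:

    species/locality/sex -> individuals (within the effect's levels)
    individual           -> fluctuating asymmetry
    side (DA)            -> fluctuating asymmetry
    fluctuating asymmetry -> imaging
    imaging              -> digitizing

Goodall's F assumes isotropic landmark variation; for shape the degrees of
freedom of each stratum are multiplied by the tangent-space dimension
(2k - 4).  Significance comes from a randomized permutation procedure whose
exchangeable unit is the experimental unit of the denominator stratum (whole
individuals across species, side means across individuals, sign of the side
contrast within individuals, replicate means across cells), with the +1
finite-sample correction P = (#{F* >= F} + 1)/(n_perm + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AnovaTable", "goodall_f", "procrustes_anova_shape", "anova_size"]


def goodall_f(ss_effect: float, df_effect: int, ss_error: float, df_error: int) -> float:
    """Goodall's F: ratio of Procrustes mean squares.

    Degrees of freedom must already include the tangent-dimension multiplier
    for shape data.  A zero error sum of squares yields ``inf`` (flagged, not
    an exception).
    """
    if df_effect <= 0 or df_error <= 0:
        raise ValueError("degrees of freedom must be positive")
    ms_e = ss_effect / df_effect
    ms_err = ss_error / df_error
    if ms_err == 0.0:
        return float("inf") if ms_e > 0 else 0.0
    return float(ms_e / ms_err)


@dataclass
class AnovaTable:
    """Rows of (effect, SS, df, MS, F, P) plus permutation metadata."""

    table: pd.DataFrame
    n_perm: int
    seed: int
    denominators: dict[str, str]

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.table.to_string(index=False)


def _codes(labels) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(labels))
    return codes.astype(np.intp), len(uniques)


def _group_means(values: np.ndarray, codes: np.ndarray, n_groups: int
                 ) -> tuple[np.ndarray, np.ndarray]:
    sums = np.zeros((n_groups, values.shape[1]))
    np.add.at(sums, codes, values)
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    return sums / counts[:, None], counts


def _one_way_ss(units: np.ndarray, codes: np.ndarray, n_levels: int
                ) -> tuple[float, float]:
    """(between-SS, within-SS) of units grouped by codes."""
    grand = units.mean(axis=0)
    means, counts = _group_means(units, codes, n_levels)
    ss_b = float(np.sum(counts[:, None] * (means - grand) ** 2))
    ss_w = float(np.sum((units - means[codes]) ** 2))
    return ss_b, ss_w


def _interaction_ss(z: np.ndarray, spec_codes: np.ndarray, n_spec: int,
                    side_codes: np.ndarray, n_side: int) -> float:
    m_spec, _ = _group_means(z, spec_codes, n_spec)
    m_side, _ = _group_means(z, side_codes, n_side)
    grand = z.mean(axis=0)
    resid = z - m_spec[spec_codes] - m_side[side_codes] + grand
    return float(np.sum(resid ** 2))


def _ms_ratio(ms_num: float, ms_den: float) -> float:
    """Zero-safe mean-square ratio: flags degenerate strata as inf/0."""
    if ms_den == 0.0:
        return float("inf") if ms_num > 0 else 0.0
    return float(ms_num / ms_den)


def _perm_p(f_obs: float, f_perm: list[float], n_perm: int) -> float:
    count = sum(1 for f in f_perm if f >= f_obs)
    return (count + 1) / (n_perm + 1)


def _hierarchical_anova(values: np.ndarray, meta: pd.DataFrame,
                        classifiers: pd.DataFrame | None, df_mult: int,
                        n_perm: int, seed: int) -> AnovaTable:
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    rng = np.random.default_rng(seed)
    meta = meta.reset_index(drop=True)

    # ---- hierarchical means: digit -> image -> side -> individual ----------
    ism_key = (meta["specimen_id"].astype(str) + "|" + meta["side"].astype(str)
               + "|" + meta["image_rep"].astype(str))
    ism_codes, n_ism = _codes(ism_key)
    w, _ = _group_means(values, ism_codes, n_ism)                # image-cell means
    ism_meta = meta.loc[~ism_key.duplicated()].copy()
    ism_meta["__cell"] = ism_key[~ism_key.duplicated()].to_numpy()
    order = pd.factorize(ism_key)[1]
    ism_meta = ism_meta.set_index("__cell").loc[order]

    is_key = (ism_meta["specimen_id"].astype(str) + "|" + ism_meta["side"].astype(str))
    ism_to_is, n_is = _codes(is_key)
    z, _ = _group_means(w, ism_to_is, n_is)                      # side-cell means
    is_meta = ism_meta.loc[~is_key.duplicated(), ["specimen_id", "side"]].reset_index(drop=True)

    is_to_spec, n_spec_all = _codes(is_meta["specimen_id"])
    m, _ = _group_means(z, is_to_spec, n_spec_all)               # individual means
    spec_ids = pd.unique(is_meta["specimen_id"])

    sides_present = sorted(set(meta["side"])) not in ([["none"]], ["none"])
    has_sides = set(meta["side"]) >= {"left", "right"}
    has_imaging = n_ism > n_is
    has_digitizing = len(meta) > n_ism

    rows: list[dict] = []
    denominators: dict[str, str] = {}

    # ---- error strata ------------------------------------------------------
    ss_img = float(np.sum((w - z[ism_to_is]) ** 2)) if has_imaging else 0.0
    df_img = (n_ism - n_is) * df_mult
    ss_dig = float(np.sum((values - w[ism_codes]) ** 2)) if has_digitizing else 0.0
    df_dig = (len(meta) - n_ism) * df_mult

    # ---- side / interaction strata (complete individuals only) -------------
    ss_fa = df_fa = ss_side = df_side = None
    complete_mask = None
    if has_sides:
        side_count = is_meta.groupby("specimen_id")["side"].nunique()
        complete_specs = set(side_count.index[side_count == 2])
        dropped = sorted(set(spec_ids) - complete_specs)
        if dropped:
            warnings.warn(f"{len(dropped)} individual(s) lack a side and are excluded "
                          f"from the asymmetry strata: {dropped[:5]}...")
        complete_mask = is_meta["specimen_id"].isin(complete_specs).to_numpy()
        zc = z[complete_mask]
        spec_c, n_spec_c = _codes(is_meta.loc[complete_mask, "specimen_id"])
        side_c, n_side_c = _codes(is_meta.loc[complete_mask, "side"])
        if n_spec_c >= 2 and n_side_c == 2:
            ss_ind_b, _ = _one_way_ss(zc, spec_c, n_spec_c)
            df_ind = (n_spec_c - 1) * df_mult
            ss_side, _ = _one_way_ss(zc, side_c, n_side_c)
            df_side = (n_side_c - 1) * df_mult
            ss_fa = _interaction_ss(zc, spec_c, n_spec_c, side_c, n_side_c)
            df_fa = (n_spec_c - 1) * (n_side_c - 1) * df_mult
    if ss_fa is None:
        # no side structure: the individual stratum sits directly on imaging
        ss_ind_b, _ = _one_way_ss(z, is_to_spec, n_spec_all)
        df_ind = (n_spec_all - 1) * df_mult

    ms_fa = (ss_fa / df_fa) if ss_fa is not None and df_fa > 0 else None
    ms_img = (ss_img / df_img) if has_imaging and df_img > 0 else None
    ms_dig = (ss_dig / df_dig) if has_digitizing and df_dig > 0 else None

    # ---- classifier effects over individual means ---------------------------
    if classifiers is not None:
        for effect in ("species", "locality", "sex"):
            if effect not in classifiers.columns:
                continue
            labels = classifiers.loc[spec_ids, effect]
            codes, n_levels = _codes(labels)
            if n_levels < 2:
                warnings.warn(f"effect {effect!r} has a single level; row omitted")
                continue
            if n_spec_all - n_levels <= 0:
                raise ValueError(f"effect {effect!r}: zero degrees of freedom "
                                 "in the individual stratum")
            ss_b, ss_w = _one_way_ss(m, codes, n_levels)
            df_b = (n_levels - 1) * df_mult
            df_w = (n_spec_all - n_levels) * df_mult
            f_obs = goodall_f(ss_b, df_b, ss_w, df_w)
            f_perm = []
            for _ in range(n_perm):
                pc = rng.permutation(codes)
                pb, pw = _one_way_ss(m, pc, n_levels)
                f_perm.append(goodall_f(pb, df_b, pw, df_w))
            rows.append(dict(effect=effect, SS=ss_b, df=df_b, MS=ss_b / df_b,
                             F=f_obs, P=_perm_p(f_obs, f_perm, n_perm)))
            denominators[effect] = "individual"

    # ---- individual --------------------------------------------------------
    ind_den = ms_fa if ms_fa is not None else (ms_img if ms_img is not None else ms_dig)
    ind_den_name = ("fluctuating asymmetry" if ms_fa is not None
                    else "imaging" if ms_img is not None
                    else "digitizing" if ms_dig is not None else None)
    if df_ind > 0 and ind_den is not None:
        f_obs = _ms_ratio(ss_ind_b / df_ind, ind_den)
        f_perm = []
        if ss_fa is not None:
            zc = z[complete_mask]
            spec_c, n_spec_c = _codes(is_meta.loc[complete_mask, "specimen_id"])
            side_c, n_side_c = _codes(is_meta.loc[complete_mask, "side"])
            for _ in range(n_perm):
                idx = rng.permutation(len(zc))
                zp = zc[idx]
                pb, _ = _one_way_ss(zp, spec_c, n_spec_c)
                pfa = _interaction_ss(zp, spec_c, n_spec_c, side_c, n_side_c)
                f_perm.append(goodall_f(pb, df_ind, pfa, df_fa))
        else:
            for _ in range(n_perm):
                idx = rng.permutation(len(z))
                pb, _ = _one_way_ss(z[idx], is_to_spec, n_spec_all)
                den_ss = ss_img if ms_img is not None else ss_dig
                den_df = df_img if ms_img is not None else df_dig
                f_perm.append(goodall_f(pb, df_ind, den_ss, den_df))
        rows.append(dict(effect="individual", SS=ss_ind_b, df=df_ind,
                         MS=ss_ind_b / df_ind, F=f_obs,
                         P=_perm_p(f_obs, f_perm, n_perm)))
        denominators["individual"] = ind_den_name

    # ---- directional asymmetry (side) and fluctuating asymmetry -------------
    if ss_fa is not None:
        zc = z[complete_mask]
        spec_c, n_spec_c = _codes(is_meta.loc[complete_mask, "specimen_id"])
        side_c, n_side_c = _codes(is_meta.loc[complete_mask, "side"])
        f_obs = goodall_f(ss_side, df_side, ss_fa, df_fa)
        f_perm = []
        for _ in range(n_perm):
            flip = rng.random(n_spec_c) < 0.5
            side_p = np.where(flip[spec_c], 1 - side_c, side_c)
            pb, _ = _one_way_ss(zc, side_p, n_side_c)
            pfa = _interaction_ss(zc, spec_c, n_spec_c, side_p, n_side_c)
            f_perm.append(goodall_f(pb, df_side, pfa, df_fa))
        rows.append(dict(effect="directional asymmetry", SS=ss_side, df=df_side,
                         MS=ss_side / df_side, F=f_obs,
                         P=_perm_p(f_obs, f_perm, n_perm)))
        denominators["directional asymmetry"] = "fluctuating asymmetry"

        fa_den = ms_img if ms_img is not None else ms_dig
        fa_den_name = ("imaging" if ms_img is not None
                       else "digitizing" if ms_dig is not None else None)
        f_fa = p_fa = None
        if fa_den is not None:
            f_fa = _ms_ratio(ms_fa, fa_den)
            cm_ism = is_meta["specimen_id"].to_numpy()[ism_to_is]
            keep_w = np.isin(cm_ism, list(set(is_meta.loc[complete_mask, "specimen_id"])))
            wc = w[keep_w]
            ism_to_is_c, n_is_c = _codes(pd.Series(is_key.to_numpy()[keep_w]))
            sub_is_meta = ism_meta.loc[keep_w, ["specimen_id", "side"]].reset_index(drop=True)
            sub_is = sub_is_meta.loc[~pd.Series(is_key.to_numpy()[keep_w]).duplicated()]
            spec_w, n_spec_w = _codes(sub_is["specimen_id"])
            side_w, n_side_w = _codes(sub_is["side"])
            df_img_c = (len(wc) - n_is_c) * df_mult
            f_perm = []
            if df_img_c > 0:
                for _ in range(n_perm):
                    wp = wc[rng.permutation(len(wc))]
                    zp, _ = _group_means(wp, ism_to_is_c, n_is_c)
                    pfa = _interaction_ss(zp, spec_w, n_spec_w, side_w, n_side_w)
                    pimg = float(np.sum((wp - zp[ism_to_is_c]) ** 2))
                    f_perm.append(goodall_f(pfa, df_fa, pimg, df_img_c))
                p_fa = _perm_p(f_fa, f_perm, n_perm)
        rows.append(dict(effect="fluctuating asymmetry", SS=ss_fa, df=df_fa,
                         MS=ms_fa, F=f_fa, P=p_fa))
        denominators["fluctuating asymmetry"] = fa_den_name

    # ---- measurement-error strata ------------------------------------------
    if has_imaging:
        f_img = p_img = None
        if ms_dig is not None:
            f_img = _ms_ratio(ms_img, ms_dig)
            f_perm = []
            for _ in range(n_perm):
                yp = values[rng.permutation(len(values))]
                wp, _ = _group_means(yp, ism_codes, n_ism)
                zp, _ = _group_means(wp, ism_to_is, n_is)
                pimg = float(np.sum((wp - zp[ism_to_is]) ** 2))
                pdig = float(np.sum((yp - wp[ism_codes]) ** 2))
                f_perm.append(goodall_f(pimg, df_img, pdig, df_dig))
            p_img = _perm_p(f_img, f_perm, n_perm)
        rows.append(dict(effect="imaging", SS=ss_img, df=df_img, MS=ms_img,
                         F=f_img, P=p_img))
        denominators["imaging"] = "digitizing" if ms_dig is not None else None
    if has_digitizing:
        rows.append(dict(effect="digitizing", SS=ss_dig, df=df_dig, MS=ms_dig,
                         F=None, P=None))

    table = pd.DataFrame(rows, columns=["effect", "SS", "df", "MS", "F", "P"])
    return AnovaTable(table=table, n_perm=n_perm, seed=seed, denominators=denominators)


def procrustes_anova_shape(tangent: np.ndarray, meta: pd.DataFrame,
                           classifiers: pd.DataFrame | None, tangent_dim: int,
                           n_perm: int = 999, seed: int = 0) -> AnovaTable:
    """Procrustes ANOVA of shape (tangent coordinates, one row per configuration).

    ``tangent_dim`` (2k - 4) multiplies every stratum's degrees of freedom.
    For object-symmetric structures pass the symmetric component (side label
    ``"none"``); directional/fluctuating asymmetry rows then do not apply.
    """
    return _hierarchical_anova(tangent, meta, classifiers, tangent_dim, n_perm, seed)


def anova_size(centroid_sizes: np.ndarray, meta: pd.DataFrame,
               classifiers: pd.DataFrame | None, n_perm: int = 999,
               seed: int = 0) -> AnovaTable:
    """Univariate ANOVA of centroid size with the same strata and permutations."""
    sizes = np.asarray(centroid_sizes, dtype=float)[:, None]
    return _hierarchical_anova(sizes, meta, classifiers, 1, n_perm, seed)
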