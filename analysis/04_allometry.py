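#!/usr/bin/env python
"""Allometry, size correction and spinule-count regressions.

Regresses per-individual symmetric shape on centroid size (pooled within
species x sex), reports the percent of shape variance predicted by size
with a permutation P, writes size-corrected residual shapes under
results/aligned/ (suffix `_sizecorrected`), and regresses each spinule-count
row on centroid size.
"""

from pathlib import Path

import pandas as pd

from copemorph import (read_classifier_table, read_covariate_table,
                       regress_count_on_size, regress_shape_on_covariate,
                       size_correct, study_schemes)

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
ALIGNED = ROOT / "results" / "aligned"
OUT = ROOT / "results" / "allometry"
SEED = 20260930


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    classifiers = read_classifier_table(DATA / "classifiers.csv")
    rows = []
    for name in study_schemes():
        ind = pd.read_csv(ALIGNED / f"{name}_individuals.csv",
                          index_col="specimen_id")
        sizes = ind.pop("centroid_size")
        cls = classifiers.loc[ind.index]
        groups = (cls["species"] + "|" + cls["sex"]).to_numpy()
        res = regress_shape_on_covariate(ind.values, sizes.values,
                                         groups=groups, n_perm=999, seed=SEED)
        rows.append(dict(structure=name, percent_predicted=res.percent_predicted,
                         P=res.p_value, n=res.n, pooling=res.pooling))
        resid = size_correct(ind.values, sizes.values, groups=groups)
        out = pd.DataFrame(resid, index=ind.index, columns=ind.columns)
        out["centroid_size"] = sizes
        out.to_csv(ALIGNED / f"{name}_individuals_sizecorrected.csv")
    allo = pd.DataFrame(rows)
    allo.to_csv(OUT / "allometry.csv", index=False)
    print("Allometry (shape on centroid size, pooled within species x sex):")
    print(allo.to_string(index=False, float_format=lambda v: f"{v:.4g}"))

    counts = read_covariate_table(DATA / "spinule_counts.csv")
    sizes = pd.read_csv(ALIGNED / "P4CxBp_individuals.csv",
                        index_col="specimen_id")["centroid_size"]
    common = counts.index.intersection(sizes.index)
    spin_rows = []
    for col in counts.columns:
        slope, r2, p = regress_count_on_size(counts.loc[common, col].values,
                                             sizes.loc[common].values,
                                             n_perm=999, seed=SEED)
        spin_rows.append(dict(row=col, slope=slope, r2=r2, P=p))
    spin = pd.DataFrame(spin_rows)
    spin.to_csv(OUT / "spinule_regressions.csv", index=False)
    print("\nSpinule counts on centroid size:")
    print(spin.to_string(index=False, float_format=lambda v: f"{v:.4g}"))


if __name__ == "__main__":
    main()
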