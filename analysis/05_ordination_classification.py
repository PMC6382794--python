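#!/usr/bin/env python
"""Species delimitation in morphospace: PCA and pairwise discriminant analysis.

For each structure, runs PCA of the size-corrected per-individual symmetric
shapes, writes eigenvalue shares, scores and (PC1, PC2) convex hulls per
species, then classifies every species pair by linear discriminant analysis
with leave-one-out cross-validation (sexes pooled and separate).
"""

import itertools
from pathlib import Path

import numpy as np
import pandas as pd

from copemorph import (dfa_pairwise, group_hulls, pca_shapes,
                       read_classifier_table, study_schemes)

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
ALIGNED = ROOT / "results" / "aligned"
OUT = ROOT / "results" / "ordination"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    classifiers = read_classifier_table(DATA / "classifiers.csv")
    dfa_rows = []
    for name in study_schemes():
        ind = pd.read_csv(ALIGNED / f"{name}_individuals_sizecorrected.csv",
                          index_col="specimen_id")
        ind = ind.drop(columns="centroid_size")
        cls = classifiers.loc[ind.index]
        pca = pca_shapes(ind.values)
        pd.DataFrame({
            "eigenvalue": pca.eigenvalues,
            "percent_variance": pca.percent_variance,
        }).to_csv(OUT / f"{name}_pca_eigen.csv", index=False)
        scores = pd.DataFrame(pca.scores[:, :4], index=ind.index,
                              columns=["PC1", "PC2", "PC3", "PC4"])
        scores.join(cls[["species", "sex"]]).to_csv(OUT / f"{name}_pca_scores.csv")
        hulls = group_hulls(pca.scores[:, :2], cls["species"].to_numpy())
        hull_rows = [dict(species=sp, PC1=float(v[0]), PC2=float(v[1]))
                     for sp, verts in hulls.items() for v in verts]
        pd.DataFrame(hull_rows).to_csv(OUT / f"{name}_pca_hulls.csv", index=False)
        print(f"{name}: PC1+PC2 explain "
              f"{pca.percent_variance[:2].sum():.1f}% of variance")

        for a, b in itertools.combinations(sorted(set(cls["species"])), 2):
            for sexes in ("pooled", "female", "male"):
                sel = cls["species"].isin([a, b])
                if sexes != "pooled":
                    sel &= cls["sex"] == sexes
                labels = cls.loc[sel, "species"].to_numpy()
                if min((labels == a).sum(), (labels == b).sum()) < 3:
                    continue
                res = dfa_pairwise(ind.values[sel.to_numpy()], labels, cv="loo")
                dfa_rows.append(dict(
                    structure=name, pair=f"{a}-{b}", sexes=sexes,
                    loo_pct_a=res.percent_correct_cv[a],
                    loo_pct_b=res.percent_correct_cv[b]))
    dfa = pd.DataFrame(dfa_rows)
    dfa.to_csv(OUT / "dfa_pairwise.csv", index=False)
    perfect = ((dfa["loo_pct_a"] == 100) & (dfa["loo_pct_b"] == 100)).mean()
    print(f"\nDFA: {len(dfa)} species-pair analyses; "
          f"{100 * perfect:.0f}% with perfect leave-one-out classification")
    worst = dfa.assign(worst=dfa[["loo_pct_a", "loo_pct_b"]].min(axis=1)) \
               .nsmallest(5, "worst")
    print(worst.to_string(index=False))


if __name__ == "__main__":
    main()
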