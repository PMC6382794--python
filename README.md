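# copemorph

Landmark-based geometric morphometrics for delimiting closely related
species, built around the analysis design used for the *Acanthocyclops
vernalis* species complex: four cyclopoid copepod species digitized on five
rigid structures (the genital somite Gs, caudal ramus Cr, and three segments
of the fourth leg — P4Exp3, P4Enp3, P4CxBp; 84 landmarks in total over 147
specimens), with duplicate imaging and digitization so measurement error can
be separated from biological asymmetry.

The package is for systematists and evolutionary biologists who want a
tested, scriptable version of this pipeline: read TPS/CSV/Newick inputs,
superimpose, decompose symmetry, and run the inferential battery — without a
GUI in the loop.

## What it computes

* **Generalized Procrustes analysis.** Configurations of k planar landmarks
  are centred, scaled to unit centroid size
  CS = √Σᵢ‖xᵢ − x̄‖², and rotated to a consensus; shape lives in the tangent
  space of dimension 2k − 4 (86 for the 45-landmark Gs scheme).
  Semilandmarks slide along their curve tangents to minimize Procrustes
  distance to the consensus.
* **Symmetry decomposition.** Object symmetry (a structure with an internal
  midline) is handled by including a reflected-and-relabeled copy of every
  configuration in the fit; matching symmetry (left/right copies of a paired
  structure) by reflecting one side. Symmetric component = average over the
  (reflected) copies; asymmetric component = the remainder, exactly.
* **Hierarchical Procrustes ANOVA.** Goodall's F = (SS₁/df₁)/(SS₂/df₂) on
  Procrustes sums of squares, each effect tested one-way against the stratum
  below it (species/locality/sex → individual; individual and directional
  asymmetry → fluctuating asymmetry; FA → imaging → digitizing), with
  stratum-respecting permutation P values. A univariate twin handles
  centroid size.
* **Allometry.** Multivariate regression of shape on centroid size (pooled
  within species × sex), percent predicted = 100·SS_pred/SS_total, and
  size correction via residuals; OLS of spinule counts on size.
* **Ordination and classification.** PCA of per-individual symmetric shapes
  with convex hulls per species, and pairwise linear discriminant analysis
  with leave-one-out cross-validation (rank-controlled for p ≫ n).
* **Integration and modularity.** Two-block PLS (SVD of the between-block
  covariance) with Escoufier's RV = tr(S₁₂S₂₁)/√(tr S₁₁² · tr S₂₂²) and a
  permutation test; matrix correlation between individual-variation and FA
  covariance matrices (with/without within-landmark blocks); RV-based
  modularity tests of landmark partitions against enumerated or sampled
  alternatives, optionally contiguity-constrained on the scheme's adjacency
  graph.
* **Phylogenetic signal.** Squared-change parsimony: ancestral shapes
  minimize Σ_branches ‖Δx‖²/ℓ, solved exactly through the weighted tree
  Laplacian; signal is tested by permuting tip shapes (all 4! = 24
  assignments enumerated for the 4-taxon tree).
* **Synthetic data.** A seeded generator produces landmark datasets with the
  full study structure — species/sex/locality effects, allometry,
  directional and fluctuating asymmetry, nested imaging/digitizing error,
  random digitization poses — plus Brownian-motion tip shapes, so every
  estimator is validated closed-loop against known truth.

## Worked example

```python
import copemorph as cm

fx = cm.study_fixture()                      # deterministic synthetic bundle
scheme = fx.schemes["P4Enp3"]                # 7 landmarks, matching symmetry
aligned, decomp = cm.assemble_matching_symmetry(fx.configurations["P4Enp3"], scheme)
tan = cm.tangent_coordinates(aligned)
table = cm.procrustes_anova_shape(tan, aligned.meta, fx.classifiers,
                                  aligned.tangent_dim, n_perm=999, seed=0)
print(table.table)
```

prints (seed 0, 999 permutations):

```
               effect        SS   df        MS     F     P
              species     1.779   30   0.05931 284.5 0.001
             locality     0.421   60  0.007017 5.932 0.001
                  sex   0.06337   10  0.006337 4.562 0.009
           individual     4.154 1460  0.002846 169.8 0.001
directional asymmetry  0.007358   10 0.0007358  43.9 0.001
fluctuating asymmetry   0.02447 1460 1.676e-05 9.879 0.001
              imaging  0.004989 2940 1.697e-06 10.32 0.001
           digitizing 0.0009665 5880 1.644e-07   NaN   NaN
```

Species is by far the largest effect (F ≈ 285), sex and locality are
significant but an order of magnitude smaller, directional asymmetry is
small but real, and the FA : imaging and imaging : digitizing mean-square
ratios sit near the injected 10 : 1 — the variance ordering the generator
was asked to produce. The digitizing row is the bottom error stratum, so it
has no F of its own.

## The analysis

Numbered drivers under `analysis/` rebuild the whole study on the synthetic
bundle and write tables under `results/`:

```
python analysis/01_simulate_dataset.py        # TPS + CSV + tree
python analysis/02_superimpose.py             # GPA, sliding, symmetry split
python analysis/03_variation_anova.py         # Goodall's F tables, shape & size
python analysis/04_allometry.py               # % predicted, size correction, spinules
python analysis/05_ordination_classification.py   # PCA hulls, pairwise DFA (LOO)
python analysis/06_integration_modularity.py  # PLS/RV, matrix correlation, modularity
python analysis/07_phylo_signal.py            # squared-change parsimony, 24-way test
```

On the shipped fixture: PC1+PC2 carry 71–80% of variance per structure, 98%
of species-pair discriminant analyses classify perfectly under leave-one-out,
the two distal leg segments show the strongest between-structure covariation
(RV = 0.353, P = 0.001; all other pairs RV < 0.2 and non-significant), and no
modularity or phylogenetic signal is detected — none was injected.

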