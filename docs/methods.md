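# Methods

This note documents the statistical models behind `copemorph`, the choices
made where the literature leaves room, and what the synthetic validation
does and does not establish.

## Shape space and superimposition

A configuration is k labelled planar landmarks. Size is centroid size
(root summed squared deviation from the centroid); shape is what remains
after removing position, scale and orientation. Generalized Procrustes
analysis (GPA) iterates (i) optimal rotation of each centred,
unit-centroid-size configuration onto the current consensus (2×2 SVD with
the determinant constrained to +1, so reflections are never introduced
silently) and (ii) consensus update as the renormalized mean, itself
rotated onto the previous consensus to prevent orientation drift.
Convergence is declared when the consensus moves less than 1e-10 in
Procrustes norm; the cap is 100 iterations (typical datasets converge in
5–7). Statistics operate on tangent coordinates: aligned configurations
orthogonally projected onto the tangent space at the consensus, of
dimension 2k − 4.

The pairwise alignment routine returns the full similarity transform and a
residual defined as the Frobenius distance between unit-size, centred,
optimally rotated shapes. This is the quantity the brute-force rotation
grid in the tests reproduces to 1e-6.

**Semilandmark sliding.** Sliders are interior points of declared curves
with fixed anchor landmarks at both ends. Each slider moves along the chord
between its curve neighbours by the projection of its deviation from the
consensus — the minimum-Procrustes-distance criterion. Sliding alternates
with re-superimposition for a configurable number of cycles (default 3);
each cycle weakly decreases the total Procrustes sum of squares, which the
suite asserts. Bending-energy sliding is deliberately out of scope: the
Procrustes-distance criterion needs no thin-plate-spline machinery and is a
documented default in the field's software.

**Symmetry.** For object symmetry every configuration is paired with a
mirrored copy whose landmarks are relabeled by the scheme's left/right
pairing *before* the joint GPA; after alignment the copies are comparable
landmark-by-landmark, so the symmetric component is simply their average
and the asymmetric component the remainder (reconstruction is exact by
construction, and the symmetric/asymmetric split of the total sum of
squares is an algebraic identity). No post-alignment reflection is applied
— the consensus symmetry axis need not coincide with any coordinate axis.
For matching symmetry, right-side configurations are reflected about the
y-axis (any fixed axis works; relabeling invariance is property-tested),
all sides and replicates enter one GPA, and an individual's symmetric
component is the mean of its aligned configurations.

## Hierarchical ANOVA

Each effect is tested one-way with Goodall's F under the isotropic model:
shape degrees of freedom are the categorical df times the tangent dimension
2k − 4. Values are reduced to hierarchical means (digitization → image →
side → individual) and each effect's mean square is compared with the
stratum directly below it:

| effect | units | denominator |
|---|---|---|
| species, locality, sex | individual means | individuals within levels |
| individual | side means | individual × side (FA) |
| side (directional asymmetry) | side means | FA |
| individual × side (FA) | side cells | imaging |
| imaging | image means | digitizing |

Permutations respect the error stratum: whole individuals are shuffled
across species/locality/sex levels; side means are shuffled across
individuals; side labels are swapped within individuals for the DA test;
replicate means are shuffled across cells for the error strata. P values
carry the +1 correction, P = (#{F\* ≥ F} + 1)/(n_perm + 1), so P ∈
[1/(n_perm+1), 1] and the test is exact under exchangeability. Individuals
missing a side are excluded from the asymmetry strata only (the
completeness audit in `validate_dataset` reports them); the error-stratum
sums of squares assume the replicate design is balanced within cells, which
is how the data were collected (everything digitized "twice"). A
crossed mixed model with REML variance components is a non-goal.

The moment estimator used for the variance-component check is
σ̂²_FA = MS_FA − MS_imaging/m (m imaging replicates per side), whose ratio
to MS_imaging recovers the injected 10 : 1 within ±30% at 50 individuals.

## Allometry

Shape is regressed on raw centroid size (not log size: sizes span a narrow
range here and the raw covariate keeps percent-predicted interpretable
against the generator's linear model). Default pooling is within
species × sex cells — covariate and shapes centred per cell, one common
slope — matching how the covariation analyses are pooled; total-sample
regression is available by passing no groups. Size correction subtracts the
fitted allometric component and keeps cell means, so residuals remain
coordinates near the consensus and the operation is idempotent. One
consequence worth knowing: within-species pooling preserves species means
exactly, so analyses that only consume species means (e.g. the
phylogenetic-signal mapping) are identical on corrected and uncorrected
data; differences appear only under total-sample pooling.

## Ordination and discriminant analysis

PCA is an eigendecomposition of the sample covariance of per-individual
(symmetric, optionally size-corrected) tangent coordinates; axis signs are
fixed by making each axis's largest-magnitude loading positive. Pairwise
LDA first projects onto the principal subspace of the total covariance,
keeping eigenvalues above 1e-12 of the maximum *and at most n − 2 axes* —
the rank of the pooled within-group covariance for two groups — so the
within-group matrix stays invertible when coordinates outnumber specimens.
The discriminant is oriented so group 1 scores above group 0, scores are
thresholded at the midpoint of the projected group means (equal priors),
and leave-one-out refits the whole pipeline (subspace included) without the
held-out individual.

## Integration and modularity

RV is computed from cross-product matrices of centred blocks; PLS is the
SVD of the between-block covariance, with per-axis percent covariance
s²ᵢ/Σs². Blocks from different structures are superimposed separately and
matched by specimen; pooling centres both blocks within species × sex cells
and the permutation test shuffles one block's individuals within cells.
Matrix correlation between two 2k × 2k covariance matrices is the Pearson
correlation over upper-triangle entries, optionally excluding each
landmark's own 2×2 block (two sample covariance matrices always correlate
through their variances, so the excluded version is the informative
independence check); its permutation test relabels whole landmarks.

The modularity test compares the observed between-subset RV with same-size
alternative partitions: exhaustively enumerated (hypothesis included, so
the support proportion is bounded below by 1/N) whenever their number does
not exceed the requested 10,000, otherwise sampled uniformly without
duplicates. Contiguity constraints keep only partitions whose subsets
induce connected subgraphs of the scheme's adjacency graph. Support for
modularity is the proportion of alternatives with RV ≤ observed; small
values support the hypothesized modules.

## Phylogenetic signal

Squared-change parsimony minimizes Σ ‖Δx‖²/ℓ over internal-node values —
a quadratic solved exactly via the weighted tree Laplacian (branch-length
weighting is the default; unweighted mode sets all weights to 1; zero
branches are floored at 1e-9 with a warning). The objective separates over
coordinates, so the multivariate tree length is the sum of 1D tree lengths
— asserted as a property. For the permutation test the tree length is
evaluated through the Schur complement of the Laplacian onto the tips
(length = Σ_c x_cᵀ M x_c), so permuted assignments cost a matrix product
rather than a solve; the two routes are cross-checked. With four taxa the
test enumerates all 24 assignments and P moves in steps of 1/24 — reported
with that caveat, since 0.042 is the smallest attainable value.

## The synthetic generator

The generator works in the coordinate space of a unit-centroid-size mean
shape, so variances are in squared Procrustes units:

* species (and sex) mean shapes; additive individual deviations
  N(0, σ²_ind) per coordinate;
* allometry as a tangent-space direction times (size − mean size), sizes
  log-normal with multiplicative sex (0.8 for males) and locality
  (±5%) factors;
* side values = individual ± DA/2 plus FA noise; image and digitization
  replicates add their own noise; right sides are emitted mirrored, in
  random rotation/translation, scaled multiplicatively by size so landmark
  noise propagates into measured centroid size as it does in digitized
  drawings;
* spinule counts as rounded linear functions of size plus noise.

Injected directions (DA, allometry, module factors) are projected onto the
tangent space at the mean — orthogonal to translation, rotation and scale —
so their norms are fully recoverable after superimposition and, for DA,
invisible to the size ANOVA (the shape-not-size asymmetry pattern the
analysis highlights). Module factors used in the modularity validation are
additionally orthogonalized *within their landmark support*, otherwise the
superimposition itself would smear each module's variation across all
landmarks and manufacture spurious integration.

The deterministic study fixture reproduces the design: five schemes with
k = {45, 7, 10, 7, 15} (84 landmarks), 147 specimens (100 female, 47 male)
of 4 species over 7 localities, object symmetry with 26 sliding
semilandmarks on the genital somite (females only), matching symmetry
elsewhere, duplicate imaging everywhere and duplicate digitization for
P4Enp3 (8 digitizations per individual), the 4-taxon tree, and effect
magnitudes ordered species > sex > locality and FA > imaging > digitizing
(σ² = 1e-4, 1.6e-5, 1.6e-6, 1.6e-7). A latent individual factor shared by
the two distal leg segments gives that pair strong covariation
(RV ≈ 0.35); all other pairs are independent. Magnitudes are declared
choices, not estimates from any real dataset.

What passing tests show — and what they do not. The closed-loop checks
establish that each estimator recovers what this generative model injects:
isotropic Gaussian tangent noise, linear allometry, a single shared factor,
balanced replicates. Real landmark data have anisotropic, landmark-correlated
error, curved allometric trajectories, and missingness; calibration under
the isotropic model does not guarantee nominal error rates there, though
the permutation machinery (which only assumes exchangeability of the
permuted units) is expected to remain valid.

## Problem sizes and numerics

Monte-Carlo calibrations use 500 null replicates with 199 permutations at
α = 0.05 (rejection regions are exact multiples of the permutation
granularity: P ≤ 0.05 ⇔ the observed statistic ranks in the top 10 of 200).
Analysis drivers use 999 permutations; the modularity driver uses 10,000
alternatives (full enumeration when fewer exist). GPA tolerance is 1e-10
with max 100 iterations; PCA/PLS use LAPACK eigh/SVD; eigenvalues are
clipped at zero before percentages are formed; degenerate inputs
(all-identical landmarks, zero-variance covariates or blocks, single-level
factors) raise or are flagged rather than propagating NaNs. All randomness
flows from explicit seeds through `numpy.random.default_rng`; identical
seeds give identical tables and byte-identical TPS output.

## Known limitations

* 2D landmarks only; no missing-landmark estimation; no bending-energy
  sliding; no NTS/Morphologika dialects.
* The ANOVA is a set of one-way stratum tests, not a crossed mixed model;
  unbalanced replicate designs within cells are not reweighted.
* Canonical variates for more than two groups and between-group PCA are out
  of scope; so are CR-coefficient modularity statistics and more than two
  modules.
* Sizes are drawn independently per structure for the same individual, so
  between-structure size correlation is not emulated.
* With four taxa the phylogenetic-signal test is intrinsically
  low-resolution; it is reported, not relied upon.
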