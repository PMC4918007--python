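# Methods

This note documents the statistical machinery of `sulfidiv`, the
choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Geometric morphometrics

Configurations of k = 13 two-dimensional landmarks are superimposed by
generalized Procrustes analysis: each configuration is centred, scaled
to unit centroid size, and rotated to the running consensus; the
consensus is re-estimated and renormalized until it moves by less than
`tol` (default 1e-10). This is *full* Procrustes superimposition; the
optimal two-dimensional rotation is computed in closed form from the
cross-covariance sums. Reflections are disallowed by default because
all specimens are digitized in the same lateral orientation; a flag
enables reflection matching for other datasets.

Relative warps are principal components of the aligned shapes after
orthogonal projection into the tangent space at the consensus (the
component along the consensus direction is removed). Together with
centring and the rotation-optimality constraint — which in two
dimensions holds exactly, not just to first order — this leaves the
shapes in an exactly (2k − 4)-dimensional subspace, so at most 22
eigenvalues are non-negligible for 13 landmarks. Uniform and
non-uniform variation are decomposed together with equal landmark
weighting (no bending-energy re-weighting), the common default of
landmark-digitizing software families. Seven warps are retained by
default. Sign convention: each axis is oriented so its
largest-magnitude loading coefficient is positive. Centroid size (used
as the allometry covariate of the shape model) is recorded before
scaling; the pipeline uses its log10.

## Multivariate linear models

All (M)AN(C)OVAs are fixed-effects least-squares fits with sum-to-zero
contrasts. Covariates are centred at their training means, which keeps
main effects interpretable in the presence of covariate-by-factor
interactions. The random "site nested within clade-by-habitat" term of
the source design is represented by sum-coded site contrasts within
each clade × habitat cell.

Each term's hypothesis SSCP H is Type-III: the residual SSCP of the
model without that term's columns minus the full-model residual SSCP E.
Type-III was chosen (over sequential SS) because the designs are
unbalanced. Wilks' Λ = det(E)/det(H + E) is converted to an F statistic
with Rao's approximation, which is exact when the number of responses
or the hypothesis degrees of freedom is at most two — which covers the
habitat term (1 df) in every model. Effect size is partial
η² = 1 − Λ^(1/s), s = min(p, dfh); *relative variance* is a term's
partial variance divided by the maximum partial variance in its model,
so the strongest term scores 1.

**Pruning.** Starting from all two- and three-way interactions, the
highest-order interaction with P > 0.1 is dropped (largest P first) and
the model refitted, except that a term is retained whenever a retained
higher-order interaction containing it has P < 0.1. Main effects,
covariates and the site term are never dropped.

**Site-level tests.** For the between-site factors (clade, habitat,
clade × habitat) the individual-level residual is the wrong error
stratum. The package tests these against the variation among sites:
responses are adjusted for the model covariates using the pooled
within-site regression, site mean vectors are computed, and a MANOVA of
the full clade × habitat factorial is run on those means, giving
n_sites − n_cells error degrees of freedom. This treats the site as
the unit of replication; it is a deliberate, fully specifiable
approximation of a REML mixed-model F-test with adjusted degrees of
freedom, and is labelled as such in all output. Cells containing a
single site trigger a warning (reduced replication).

**Estimated marginal means.** Predictions on the full grid of factor
levels — covariates at their means unless overridden, site contrasts
zeroed (i.e. the average site of each cell) — are averaged with equal
weight over the non-focal factors. Standard errors use the coefficient
covariance with per-response residual variance E_rr/dfe. Requests
outside the observed covariate range warn.

## Divergence vectors

The canonical axis of the habitat term is the leading eigenvector of
E⁻¹H (computed as a symmetric-definite generalized eigenproblem), unit
normalized, oriented so the pooled sulfidic mean score is the larger.
For a pure two-group design this is the Fisher discriminant direction.

Scores are the projections of responses adjusted for the *nuisance*
terms only: covariates and fixed effects that do not involve the focal
factor. The focal term, interactions containing it, and the nested
site term are deliberately left in the scores. The alternative —
residualizing on every non-focal term including site — collapses each
site's mean score onto its clade × habitat cell mean and erases exactly
the between-system variation in divergence strength that the
system-level analyses consume; the convention used here keeps per-site
mean scores interpretable as positions along the divergence axis.
New individuals (e.g. a second genus measured on the same transformed
variables) are projected with the stored eigenvector coefficients after
centring at the training grand mean.

## Trait transformations

Lengths and masses are log10-transformed, counts square-root
transformed, proportions arcsine-square-root transformed, and every
transformed variable is then z-standardized; the mapping and scaling
constants are recorded so the transformation can be inverted. Values
outside the domain of a transform raise immediately.

## Population genetics

Pairwise differentiation is the Weir–Cockerham (1984) θ for two
populations: per allele and locus the variance components a (among
populations), b (among individuals within populations) and c (within
individuals) are accumulated, and the multilocus estimate is
Σa / Σ(a + b + c). Negative per-locus components are retained in the
ratio of sums rather than truncated, matching the estimator's
definition; a comparison with no variation at any locus is undefined
and returned as missing with a warning. Missing genotypes are handled
per locus, complete cases within each pairwise comparison. Unbiased
expected heterozygosity uses the (2n/(2n − 1)) small-sample factor.

Mantel tests correlate upper-triangle entries and permute rows and
columns of the first matrix simultaneously; one-tailed p-values use the
add-one convention (hits + 1)/(n_perm + 1), so p is never 0. The
partial Mantel test residualizes both focal matrices element-wise on
the covariate matrix and permutes the residualized dependent matrix
(the residual-matrix scheme). A constant covariate matrix falls back to
the simple test with a warning.

## Integration

Per-system divergence is the mean non-sulfidic site-mean score minus
the sulfidic site-mean score (per-site means first, then averaged
across non-sulfidic sites). Because divergence vectors are oriented
sulfidic-positive, this signed difference is systematically negative;
the summary reports both the signed value and its magnitude, and the
two-measure PCA operates on magnitudes so the expected sign of the
divergence–H₂S correlation is unambiguous. For two standardized
measures with correlation r the leading eigenvalue of the correlation
matrix is 1 + |r| and PC1 explains (1 + |r|)/2 of the variance; this
closed form is checked against a generic eigensolver in the tests.

One-tailed correlation p-values default to the t approximation
t = |r|√((n − 2)/(1 − r²)) on n − 2 df, one tail in the direction of
the observed sign (this reproduces printed values such as p = 0.002 for
ρ = 0.85 at n = 9 and p = 0.001 for r = 0.45 at n = 44); exact
enumeration over all n! rank permutations is available for n ≤ 10.
Each system's genetic-differentiation partner is its geographically
closest non-sulfidic site by great-circle distance, overridable by an
explicit pairing table; systems without genotype data are dropped from
the F_ST correlation only.

## Synthetic data generator

The generator defines the study conditions under which the pipeline is
exercised and validated:

- **Design.** Five clades × two sulfide systems × (1 sulfidic + 2
  non-sulfidic sites), i.e. ten sulfidic systems and thirty sites, with
  H₂S concentrations drawn uniformly from 20–200 µM — the range spanned
  by natural sulfide springs inhabited by these fishes. 24 individuals
  per site by default (half female, all females pregnant).
- **Habitat effects.** At the 100 µM reference concentration, sulfidic
  females carry embryos 1.52 mg heavier (1.52 → 3.04 mg lean weight)
  and 5.89 fewer offspring (14.98 → 9.09); anterior landmarks are
  displaced 0.03 Procrustes units away from the head centroid (larger
  heads). All effects scale linearly with H₂S by default; a saturating
  option (1 − e^(−H₂S/H₂S_ref)) is provided but off, since intermediate
  concentrations that would distinguish the two are rarely observable.
- **Trait error model.** Gaussian on the transformed scale, so
  back-transformed traits are positive and skewed. Generator means are
  bias-corrected (lognormal mean correction; sqrt-scale variance
  correction) so the configured raw-scale habitat means are matched in
  expectation.
- **Structure.** Fecundity correlates with log standard length at
  r = 0.67 (allometry); an offspring size–number trade-off is imposed
  through a shared latent allocation variable (weight 0.3, implying a
  within-site size–number correlation of about −0.09); females are
  larger than males (27.5 vs 20.8 mm baseline); clade offsets and
  site-level random effects (sd 0.05 on the transformed scale) create
  the nested structure the models assume.
- **Genetics.** Population allele frequencies follow the
  Balding–Nichols beta/Dirichlet model around clade-level ancestral
  frequencies, because its F parameter is the direct estimand of
  Weir–Cockerham θ — making parameter recovery a clean validation. By
  default F scales with the H₂S contrast (sulfidic sites
  F·(0.25 + 0.75·scaling), non-sulfidic F·0.25, base F = 0.15), so
  neutral differentiation increases with divergence strength. The
  generator parameterizes differentiation directly rather than
  demographically (no migration rates or census sizes are modelled).

What the generator does **not** emulate: temporal sampling, linkage or
null alleles at the microsatellites, measurement error in H₂S,
phylogenetic non-independence among clades beyond clade-level mean
offsets, missing data patterns, or asymmetric migration. Passing tests
therefore demonstrate that the estimators and the pipeline recover
known structure of this idealized design, not that any particular field
system behaves this way.

## Numerical choices and problem sizes

Determinants of SSCP matrices use log-determinants; Λ is clipped to
(0, 1]. A singular residual SSCP raises with advice to reduce the
response set. Generalized eigenproblems use the symmetric-definite
solver. GPA convergence tolerance is 1e-10 on the consensus shift.
Permutation p-values use the add-one convention. All randomness flows
through `numpy.random.default_rng` seeded from user-supplied seeds, so
identical configurations and seeds produce byte-identical outputs.

Validation problem sizes were chosen to keep every check fast while
leaving comfortable statistical margins: θ recovery uses 50 replicates
of 2 × 25 diploids at 10 loci; the null-uniformity check fits 200
seeded null studies of 8 sites × 8 individuals; EMM recovery averages
20 studies of 8 sites × 30; the end-to-end detection check runs the
full default ten-system pipeline on 20 seeds.

## Known limitations

- The site-level test is a site-means approximation, not REML; with
  very unequal site sizes it weights sites equally rather than by
  information.
- Rao's F is approximate when both the response count and the
  hypothesis df exceed two (all printed habitat tests are exact).
- Relative-warp reconstruction is exact in tangent coordinates; the
  (fourth-order) radial component discarded by the tangent projection
  is not recoverable.
- The exact-permutation correlation is limited to n ≤ 10 by factorial
  growth.
- Thin-plate-spline deformation grids, semilandmarks, 3-D landmarks,
  Bayesian population-structure clustering and migrant assignment are
  out of scope.
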