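# Methods

This note documents the statistical model behind `fasym`, the numerical
choices in its implementation, what the synthetic-data generator does and
does not emulate, and the design decisions taken where the methodology left
room for judgement.

## Object symmetry and the superimposition

A structure with object symmetry (one structure with an internal midline) is
analysed by comparing every configuration with its *reflected and
relabelled* copy: the reflection negates one coordinate axis and the
relabelling swaps each bilateral landmark with its partner, so that the
mirror is again a valid configuration of the same landmark scheme. Which
plane the raw data are reflected through is immaterial, because the
superimposition removes orientation; the mirror only needs to be *a*
reflection. `fasym` negates the x axis, and the synthetic generator builds
templates whose midline lies on x = 0 so that constructions are easy to
reason about.

All `n·r` original configurations and their `n·r` mirrors enter a single
generalized Procrustes analysis. Each configuration is centred, scaled to
unit centroid size, and rotated to the evolving consensus by least-squares
(proper rotations only, determinant +1 — reflection enters the analysis
solely through the explicit mirrors). The consensus is the mean of the
aligned set, re-scaled to unit size and kept exactly reflection-invariant by
averaging with its own relabelled reflection; because the aligned mirror of
every observation is exactly the reflection of its aligned original (the
Procrustes rotation of a mirrored shape is the conjugated rotation of the
original), this averaging reproduces what the joint mean does anyway and
merely pins it to machine precision.

Numerical settings: iteration stops when the consensus root-mean-square
change falls below 1e-10, with a cap of 100 iterations (typical data
converge in well under 10); configurations with zero centroid size raise an
error. The initial consensus is the first configuration rotated so that its
best mirror plane is x = 0. That canonicalizing rotation sends the axis
along which the shape is least congruent with its relabelled mirror
(smallest eigenvalue of the symmetrized cross-product matrix) to x and
completes the basis by Gram–Schmidt against the identity, so a shape that is
already in a mirror-canonical frame is left essentially fixed.

### Symmetric / asymmetric components

For each (specimen, replicate) couple with aligned original X and aligned
mirror M:

* symmetric component = ½(X + M) − consensus,
* asymmetric component = ½(X − M).

These are orthogonal projections onto complementary subspaces of the centred
coordinate space (dimensions `d_sym = 3p + 2u − 4` and
`d_asym = 3p + u − 3` after removal of the four symmetric and three
asymmetric similarity directions), so the squared deviation of every
observation splits exactly (Pythagoras) — the test suite asserts this at
1e-9.

Deviations are used directly in the aligned coordinate space with no formal
tangent-space projection. At the asymmetry magnitudes this package is built
for (Procrustes FA scores of order 0.01–0.02 on unit-size shapes) the
curvature of shape space contributes relative errors of order 1e-4, well
below every quoted statistic; this is an approximation and is documented as
such.

### Directional asymmetry and FA scores

The DA vector is the mean asymmetric component over the original
(non-mirror) observations — over originals and mirrors jointly it would be
identically zero, since mirror components are negated. The per-individual
Procrustes FA score is

```
fa_score_i = || mean_r(asymmetric_ij) − DA ||
```

the Frobenius (Procrustes-distance) norm of the replicate-averaged
individual asymmetry after removing DA. No degrees-of-freedom or
replicate-count normalization is applied; published score tables from other
software do not document their exact normalization, so this package states
its own definition and uses it consistently. The scale is cross-checked
against deposited score summaries (mean ≈ 0.015) by the calibration of the
default generator, not by formula.

## Procrustes ANOVA

Sums of squares, computed in the joint aligned space without small-sample
bias corrections:

```
SS_individual = r · Σ_i || mean symmetric deviation of individual i ||²
SS_side       = n · r · || DA ||²
SS_interaction= r · Σ_i || mean asymmetry of i − DA ||²
SS_error      = Σ_ij ( || s_ij − s̄_i ||² + || a_ij − ā_i ||² )
```

with the degrees of freedom in the README table. The identity
`Σ df = n·r·(d_sym + d_asym) − d_sym` holds for every design and is
property-tested over randomized designs.

F ratios pair each effect with the stratum beneath it: individual and side
are tested over the interaction (FA) mean square, and the interaction over
error — the pairing that makes the FA-over-error ratio the signal-to-noise
measure for FA studies. p-values are parametric, from the F distribution at
the Procrustes df (the default Goodall-style test); permutation tests are
out of scope.

**Percent variation** is reported as each effect's share of the total sum of
squares, `100 · SS_effect / Σ SS`. Some methodological texts describe the
percent-variation computation in terms of mean squares, but published
four-effect tables of this kind are SS shares, and that is what this package
reproduces; the discrepancy in wording is noted here deliberately.

Degenerate input (all observations identical) yields an all-zero table with
a warning and undefined p-values. A single digitization per specimen
(r = 1) is rejected with an explicit message: without replicates the error
stratum is empty and FA cannot be separated from measurement error.

## Mixed models of FA scores

Per-individual scores are modelled as
`fa_score ~ fixed effects + (1 | matriline)`; the maternal-lineage random
intercept absorbs relatedness among specimens. Four standard variants are
provided: (1) all individuals with a binary exposure term, (2) the
never-exposed subset without an exposure term, (3) all individuals with the
number of exposures as a 0/1/2 categorical factor, and (4) the exposed
subset with developmental stage at exposure (fetal / juvenile / adult,
fetal reference). Covariate coding: age at death in years (continuous); sex
with female reference; decade of birth as a single numeric trend in decade
units anchored at 1950 — a deliberate interpretation, since a single
coefficient (not level-wise contrasts) is the quantity of interest.

Fitting is REML through `statsmodels.MixedLM`. The response is standardized
internally before optimization (FA scores are O(1e-2), and the raw scale
upsets line searches) and the variance components are converted back; the
optimizer falls back through BFGS, Powell and Nelder–Mead. When the
matriline variance collapses to the boundary (ratio to residual variance
below 1e-8) it is clamped to zero with a logged note and residual degrees of
freedom are used. A `df_method="residual"` flag forces that fallback
explicitly. A response that is an exact linear function of the design is
returned as an exact interpolation (zero variance components) rather than
fed to the optimizer.

**Satterthwaite degrees of freedom** for a fixed-effect contrast c are

```
df = 2 (c' V c)² / ( g' A g )
```

where `V(θ) = (X' Σ(θ)⁻¹ X)⁻¹` at the REML variance estimates
θ = (σ²_matriline, σ²_residual), g is the finite-difference gradient of
`c'Vc` in θ (relative step 1e-4, one-sided at the boundary), and A is the
inverse observed information of the restricted log-likelihood (central
finite-difference Hessian). The restricted likelihood itself is evaluated
with per-group Woodbury identities, so the computation is linear in the
number of individuals. Against R's `lmerTest` on identical data the
estimates and SEs agree to ~1e-5 relative and the dfs to ~1e-4 (asserted in
the test suite); on a balanced one-way design the intercept df reproduces
the textbook between-group value g − 1.

**Post hoc contrasts** of a fitted factor are all pairwise level
differences, tested as z statistics on the fitted coefficient covariance
(the usual large-sample treatment of pairwise comparisons on mixed models)
with Bonferroni–Holm stepdown over the contrast family (via
`statsmodels.stats.multitest`). For developmental stage at exposure the
family is the three pairwise contrasts. A joint Wald chi-square test of all
coefficients of a factor is also available, since a single "factor effect"
statistic and per-level t tests answer different questions.

**Power analysis** is simulation-based: scores are regenerated over the real
(or simulated) metadata from specified variance components, an effect of
size e% of the baseline mean FA is added to the target group, the model is
refit, and power is the rejection fraction at α. Effect sizes are
parameterized as percent change in mean FA score — the natural scale for a
norm-valued response; this is an interpretive choice and is stated as such.
The grid, α, simulation count and seed are all explicit.

## The synthetic-data generator

`simulate_dataset` draws, per individual, a deviation in the symmetric
subspace (SD `sigma_sym` per component), a deviation in the asymmetric
subspace (SD `sigma_fa`, multiplied by the exposure-group inflation κ_g)
plus a fixed DA field of norm `da_magnitude`; per replicate, i.i.d. noise
`sigma_err` on every coordinate; and finally an independent random rotation,
translation and scaling per configuration, which the superimposition must
remove (an invariance asserted at 1e-6 on FA scores). Subspace conventions
are chosen so symmetric draws are reflection-invariant and asymmetric draws
change sign under reflection; the two are orthogonal by construction and
their post-projection ranks equal `d_sym` and `d_asym` (tested).

Metadata mirrors the emulated cohort: 275 individuals (154 F / 121 M), 174
never exposed and 101 exposed to at least one of two hurricanes (1989,
1998) — 10 as fetuses, 50 as juveniles, 41 as adults, 23 of them exposed
twice — with birth years 1951–2005, ages drawn to respect skeletal maturity
at exposure (males mature at 8 yr, females at 15 yr), and ~30 matrilines.
One external source prints the female count as 157; the constituent counts
used here are the ones that sum to the stated total (154 + 121 = 275), and
the discrepancy is simply noted.

### Calibration of the default magnitudes

No study publishes its per-stratum landmark variances, so the defaults are a
documented *calibration*, not measurements. With the template centroid size
set to 100 (nominal mm), `sigma_sym = 0.80`, `da_magnitude = 0.45`,
`sigma_fa = 0.096` and `sigma_err = 0.26` were derived once, in closed form,
from two requirements: (i) the four variance shares of the default cohort
sit at the values replicate cranial digitizing studies report (individual
≈ 91%, DA ≈ 0.3%, FA ≈ 3.6%, error ≈ 5%, FA-over-error F ≈ 1.54), and (ii)
the mean Procrustes FA score is ≈ 0.015. A default full-scale run lands at
90.9 / 0.33 / 3.64 / 5.14, F = 1.54, mean score 0.0150. The default fetal
inflation κ_fetal = 1.4 is the minimal mechanism consistent with a reported
fetal-exposure elevation of ~0.006–0.007 on that mean.

What the generator does **not** emulate: anatomically realistic cranial
geometry (the template is a random symmetric point cloud); growth or
age-structured shape change; landmark-specific error variances;
between-individual heterogeneity in FA *magnitude* beyond the exposure
groups — real deposited scores have SD ≈ 0.004 where the generator, with a
single `sigma_fa` per group, produces ≈ 0.0016, because the norm of a
fixed-variance Gaussian in ~44 dimensions is concentrated. Matriline
affects scores only (a random intercept at the score level), not landmark
geometry, keeping the landmark and score generators composable. Passing
tests on synthetic data therefore demonstrate the correctness and
calibration of the estimators under the assumed variance structure, not the
biological realism of any particular dataset.

## Problem sizes in the test suite

Statistical tests run at sizes chosen to make Monte-Carlo error small
relative to the asserted tolerances while keeping the suite quick: the
null-FA F calibration uses 200 replicates of a 12-individual, 5-landmark
design (the F ratio's null expectation depends only on its df); mixed-model
type-I error uses 1000 score-level simulations at n = 100; parameter
recovery uses 200 simulations at n = 300 with 20 matrilines; and the
end-to-end fetal-inflation detection runs 60 full-pipeline replicates at the
complete 275 × 2 × 34 design, where detection is deliberately strict — both
Holm-adjusted fetal contrasts significant at α = 0.05.

## Known limitations

* No missing-landmark handling: incomplete configurations are rejected, not
  imputed.
* Procrustes FA scores only; Mahalanobis-type FA scores (which need large
  samples for a stable covariance estimate) and matching asymmetry of
  paired separate structures are out of scope, as are sliding
  semilandmarks and allometry corrections.
* Parametric F tests only in the Procrustes ANOVA; no permutation tests.
* The mixed models support a single random intercept (the grouping factor
  the analysis calls matriline); crossed or nested random effects are not
  implemented.
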