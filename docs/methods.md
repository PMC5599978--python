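# Methods

This note documents the statistical models implemented in `nutriqg`, the
choices made where the design was genuinely open, what the synthetic-data
generators do and do not emulate, and the package's known limitations.

## Standardization and intake bookkeeping

Ingested protein and carbohydrate are the consumed dry diet mass multiplied
by the diet's nutrient fractions; the data model stores net consumption only
(spillage and feces correction are assumed applied upstream).  Analyses run
on the z-scale: intakes and traits are transformed to mean 0, SD 1 with the
sample (n−1) SD.  Standardization is per sex by default, since single-group
surfaces are fitted within sex; the between-group comparison standardizes
within group first and then pools, which reproduces the error-df pattern of
a 430-row pooled fit (424 / 420 / 418 across tiers).  A pooled option
exists.  Stored (mean, SD) factors make the transform invertible to 1e−10.

## Response surfaces

For trait z on standardized intakes, estimation is two-stage:

* linear gradients β = (β_P, β_C) from `z ~ 1 + P + C` (residual df n − 3);
* quadratic and correlational gradients from the full second-order model
  `z ~ 1 + P + C + P² + C² + P·C` (residual df n − 6).

Quadratic coefficients are reported raw — no γ/2 doubling convention.  Each
coefficient carries its SE and a two-sided t-test.  A deliberate consequence
of the two-stage scheme: when the true surface is curved, the first-order β
estimates the surface's best linear approximation *under the observed intake
distribution*, not the coefficients of the generating polynomial.  Parameter
-recovery tests therefore check β on linear surfaces and γ on full surfaces,
where both are exactly identified (to 1e−8 in the noiseless limit).
Rank-deficient designs (e.g. every observation on one nutritional rail) are
rejected with a message naming the collinearity.

Landscapes use a thin-plate spline with basis r²·log r plus an affine null
space, penalty chosen by generalized cross-validation over a log-spaced grid
(λ ∈ 10⁻⁸…10²) unless given.  The prediction grid is rectangular over the
observed intake bounding box and masked to the convex hull of the data;
values outside the hull are never reported as supported, and a regulated
intake point outside the hull is flagged as extrapolation rather than
evaluated.

## Sequential surface comparison and the vector angle

Two groups (each standardized within group) are pooled with a group
indicator; a group main effect (intercept shift) is always present so the
tests target gradients, not elevations.  Tiers are nested in the order
linear → quadratic → correlational, retaining group-specific lower-tier
terms when testing higher tiers:

| tier | added group-specific terms | df1 |
|---|---|---|
| linear | g·P, g·C | 2 |
| quadratic | g·P², g·C² | 2 |
| correlational | g·P·C | 1 |

Each tier's partial F is ((SS_R − SS_C)/df1)/(SS_C/df2) with df2 the
complete-model residual df.  Note the reduced model of each tier adds the
*common* higher-order terms, so a tier's SS_C does not carry over as the
next tier's SS_R.  Significant multi-df tiers get single-df follow-ups per
nutrient.  Displayed p-values floor at 0.0001.

The angle between two linear gradient vectors is
θ = arccos(a·b/(‖a‖‖b‖)) in degrees, clamped against rounding overflow;
0° means the two optima lie in the same direction of nutrient space.  Its
uncertainty comes from a Bayesian linear model per group,
`z = β_P P + β_C C + ε` (no intercept — all variables are centered by the
z-transform), sampled by a conjugate Gibbs chain: β | σ² is normal around
the least-squares solution, σ² | β inverse-gamma with a scaled
inverse-chi-square prior (default V = 1, ν = 0.02, relatively
uninformative).  θ is computed per paired draw across the two independent
chains (seeds derived deterministically from the user seed) and summarized
by the posterior mean and the 95% shortest-interval HPD (ties broken toward
the lower bound).  The default chain (20,000 iterations, 2,000 burn-in,
thin 10) gives 1,800 draws; the publication-scale setting
(400,000 / 20,000 / 25 → 15,200 draws) is `ANGLE_PUBLISHED_SETTINGS`.  With a
near-zero prior scale and noiseless data the posterior collapses onto the
plug-in angle; with the default prior the prior scale (νV) sets a small
variance floor.

## The sex-limited animal model

Traits are (Pm, Cm, Pf, Cf); individual i of sex s expresses its sex's two:

```
y_i = μ_s + Z_s a_i + e_i,   a ~ N(0, A ⊗ G),   e_i ~ N(0, R_s)
```

A is the numerator relationship matrix; its sparse inverse is assembled by
Henderson's rules assuming non-inbred known parents (Mendelian-sampling
variance ½ with both parents known, ¾ with one, 1 with none).  Pedigrees
are canonically ordered (depth, then id), which makes fits invariant to
input row permutation, bitwise, at fixed seed.

Gibbs updates per iteration: (1) single-site blocked draws of each
individual's 4-trait breeding value from its full conditional (sparse-A⁻¹
prior part plus the sex's 2×2 residual-precision data part) — this loop is
numba-compiled, with all normals drawn from one seeded generator outside the
kernel; (2) conjugate normal draws of the trait means (the only fixed
effects; diet pair is deliberately excluded by default so the genetic
parameters describe regulated intake across diet pairs — an optional flag
adds it for sensitivity runs); (3) G from an inverse-Wishart with scale
νV·I₄ + aᵀA⁻¹a and df ν + N (default V = diag, ν = 1.002, mirroring the
relatively flat additive prior); (4) each sex's 2×2 residual block from the
analogous inverse-Wishart.  Cross-sex residual covariances are structurally
zero: no individual expresses both sexes' traits, so they are inestimable
and fixing them at zero matches what any estimator could identify.

Every retained G draw is symmetric positive definite by construction
(inverse-Wishart).  Derived per draw: Gm, Gf, the between-sex block B,
heritabilities Va/(Va+Ve) (≈ Va on variance-standardized traits), r_M, r_F
and r_MF per nutrient as cov/√(v₁v₂), with zero-variance draws excluded and
counted.  Effective sample sizes of the four genetic variances are estimated
by the initial-positive-sequence method; ESS < 50 triggers a recorded
warning, never a silent pass.  The default chain is test-scale
(20,000 / 2,000 / 10); `ANIMAL_PUBLISHED_SETTINGS` (250,000 / 100 / 50 → 4,998
draws) reproduces the publication-scale run.  At the full 2160-offspring
design the test-scale chain takes on the order of two minutes on one CPU,
which is the problem size used throughout the test suite.

## Predicted response and the R constraint metric

With G in trait order (Pm, Cm, Pf, Cf) and β the stacked per-sex linear
gradients for one trait, the one-generation response is Δz̄ = ½ G β; the ½
reflects equal autosomal contributions of the two parents and is applied
exactly once.  β is stacked by *label*, never by position, because printed
conventions disagree on whether males or females come first; a label
mismatch raises.  The counterfactual Δz̄_{B=0} zeroes the off-diagonal 2×2
blocks; R is the elementwise ratio.

The default mode is per-draw: one G draw and one β draw enter the equation
together; Δz̄, Δz̄_{B=0} and R are summarized afterwards (posterior mean and
95% HPD).  The posterior mean of a ratio is not the ratio of posterior
means; plug-in mode exists as a documented cross-check and the test suite
asserts the two diverge on a skewed posterior, guarding against the wrong
implementation.  Ratio draws with |Δz̄_{B=0}| < 1e−8 are excluded, not
winsorized, and exclusion counts are always reported.  Classification:
HPD entirely above 1 → accelerated, below 1 → constrained, spanning 1 →
neutral.

## Choice analysis

Diet preference is a two-sided paired t-test of per-individual high-C minus
high-P consumption per diet pair; exact ties are flagged rather than
erroring.  The sex × diet-pair MANOVA of (P, C) intake uses Pillai's trace
from partial (type-III-style) hypothesis SSCP matrices under sum-to-zero
coding — conventions coincide on balanced designs — with the standard
approximate-F transformation; with a single response it reduces exactly to
the univariate ANOVA F.  Univariate follow-ups use statsmodels type-III
tables; Fisher's LSD orderings are computed only after a significant
omnibus pair effect.

The RIP per sex is the mean of per-diet-pair mean intakes (robust to pair
attrition; identical to the pooled mean when balanced), with SEs from the
pooled individual SD.  The RIP sex test is the ANCOVA
`C ~ sex + P + sex×P` with type-III tests: a significant interaction means
the sexes regulate along lines of different slope.  P intake and the
interaction are ordinary fixed effects — a random slope would be
unidentifiable with one observation per individual.

## Synthetic data: what it emulates and what it does not

The generators reproduce the three designs' statistical structure with
known truth:

* **No-choice:** a log-spaced 6 × 4 diet grid between rails 5P:1C and
  1P:8C (total nutrient fraction ≤ 0.9); each individual's intake sits on
  its diet's rail with log-normal total consumption (mean 600 mg, CV 0.35);
  traits follow the specified quadratic surface on the z-scale plus Gaussian
  noise (default residual SD 0.9, which puts linear-gradient SEs at the
  study's ~0.06 for n ≈ 220).  Default gradients are the published per-sex
  point estimates.
* **Half-sib choice:** founder breeding values MVN(0, G), offspring =
  mid-parent + MVN(0, ½G) Mendelian deviation (non-inbred founders, as in
  the study pedigree); sex-limited expression; residual blocks complete the
  phenotypic variance to 1 on the standardized scale with moderate residual
  correlations; phenotypes are placed on a mg scale with study-like means
  and SDs.  Default design 30 × 3 × 24 = 2160 with balanced diet-pair
  allocation; default G is the published point matrix, so recovery tests run
  at the study's own effect sizes.
* **Outbred choice:** (P, C) drawn around the sex's RIP with the dispersion
  long axis along the regulation line (total intake varies, the defended
  ratio is tight: 25% vs 3% of the RIP norm), independent of diet pair by
  default (perfect regulation; configurable pair offsets).  Per-diet
  consumed masses are back-solved from intake and the pair's compositions,
  yielding the paired-preference columns.

Not emulated: mortality/censoring, egg-counting or call-monitoring error
beyond the Gaussian trait residual, diet hygroscopy, feces mass, or
repeated-measures structure within the 21-day feeding period (totals per
individual are the analysis unit).  Passing tests therefore certify the
estimators under these idealized conditions, not robustness to the omitted
features of real feeding data.

## Numerical choices and degenerate inputs

Seeds are explicit everywhere; all generators and samplers are
bit-reproducible at fixed seed and library versions.  OLS uses the normal
equations with a condition-number guard (> 1e10 → collinearity error);
constant traits return zero gradients with p = 1.  The TPS system is solved
as a bordered linear system with a least-squares fallback.  HPD intervals
use the shortest contiguous window over sorted draws.  Infinite partial F
(zero complete-model RSS) is flagged with a warning rather than silently
returned.  The angle is undefined for zero gradient vectors and raises.

## Known limitations

* No REML estimator; the animal model is Bayesian-only, additive and
  autosomal (no dominance, maternal effects or X-linkage).
* The angle machinery is two-nutrient; the geometry generalizes but is not
  implemented for > 2 nutrients.
* Single-generation response prediction only; the breeder's equation is not
  iterated.
* Published posterior-mean response tables cannot be reproduced exactly from
  point estimates alone — per-draw averaging over the original chains
  (unavailable) differs from plug-in products by design; the package
  reports both routes and documents their divergence.
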