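# Methods

## The two traits

All analyses start from vial-level CAFE assays: groups of 8 same-sex,
same-line flies drinking 4% sucrose from capillaries for 24 h, with
fly-free vials in the same humid chamber measuring evaporation. The
analyzable observation is the adjusted per-fly intake

    y = (total consumed − mean evaporation of the vial's batch) / flies alive.

Negative adjusted values are retained and flagged, never floored:
flooring would bias low-consumption lines upward. Per line × sex the
vials reduce to a replicate count, mean, sample SD (n−1 denominator)
and CV_E = 100·SD/mean. CV_E cells need a positive mean and at least
`min_reps` replicates (default 3; the assay design uses 6).

## Mixed model and REML

Pooled across sexes the model is `Y = μ + S + L + S×L + E` with sex
fixed and line / sex-by-line random; per sex it reduces to
`Y = μ + L + E`. Both random factors are nested within line, so the
marginal covariance is block-diagonal by line and the restricted
likelihood is evaluated block-wise, batching lines with identical
replication patterns (a balanced 182-line panel needs one 12×12
inverse per iteration).

The optimizer takes average-information (AI) Newton steps; any step
that would reduce the restricted likelihood (or leave the positive
orthant) is replaced by the monotone EM update, and components are
projected to a non-negative floor, so the restricted likelihood is
non-decreasing by construction. Convergence is declared at relative
parameter change < 1e-10 (default; tight enough that balanced-design
estimates agree with the closed-form ANOVA moment estimators to
better than 1e-8), with a 200-iteration cap and an explicit
non-convergence error carrying the iteration trace. Standard errors
come from the inverse AI matrix at the optimum. Data with no residual
variation at all short-circuit to all-zero components.

The ANOVA table uses Type III sums of squares from sum-to-zero-coded
least squares. For the random terms and the fixed sex effect the
F denominator is synthesized from MS(S×L) and MS(E) to match the
σ²_SL coefficient of the null expected mean square (coefficients
computed from QR projections of the indicator matrices), with
Satterthwaite degrees of freedom. For balanced data this reduces to
the classical ratios; for unbalanced data it is one reasonable
convention among several, and the variance components — not the F
statistics — are the quantities the package stands behind.

Broad-sense heritability is `(σ²_L + σ²_SL)/(σ²_L + σ²_SL + σ²_E)`
pooled and `σ²_L/(σ²_L + σ²_E)` per sex. The cross-sex genetic
correlation is reported in two conventions: the primary estimate
divides the sample covariance of female and male line means by the
per-sex REML among-line SDs (it can leave [−1, 1] because numerator
and denominators come from different estimators; it is then clamped
with a warning and the raw value kept), and a plain Pearson
correlation of line means is reported alongside (downward-biased by
within-line noise, upward-bounded by it too — the two bracket the
truth in practice).

## Variance heterogeneity and CV_E

Genetic control of micro-environmental variance is tested by one-way
ANOVA of absolute deviations of each vial from its line's center:
mean (Levene) or median (Brown-Forsythe; medians use the midpoint
convention for even counts). Lines with a single vial carry no
variance information and are dropped with a warning.

Both tests are asymptotic. With very few replicates per line the
F reference is a poor approximation: at 6 vials per line and ~180
lines the mean-centred variant rejects a true null far above the
nominal rate while the median-centred variant is deeply conservative
(a property of the tests, observable in any implementation). Type-I
calibration is therefore verified in a large-replicate regime
(15 lines × 60 vials in the acceptance checks), and study-scale
P-values from the 6-replicate design should be read as orderings more
than exact tail probabilities — the median-centred test being the
safer of the two.

Pearson correlations of line-level quantities report the t-based
two-sided P (n−2 df) and the Fisher-z 95% CI
`tanh(atanh r ± 1.96/√(n−3))`; pairs with missing values are dropped
and n is always reported, cross-trait tables add a Benjamini-Hochberg
column but the primary P-values are deliberately unadjusted (nominal
reporting).

## Association scan

Traits are line-level: mean and CV_E for females, males, their
average, and the female−male difference (formally the sex-by-line
interaction). Two-step adjustment:

1. Ordinary least squares of the trait on Wolbachia infection and
   inversion-karyotype covariates; per-term Type III F tests; the
   adjusted trait is residuals + grand mean. Single-level covariates
   drop out (identity adjustment); rank-deficient designs raise an
   error naming the aliased terms.
2. A relatedness matrix K = McMc′/(m·mean variant variance) from
   centred 0/2 genotypes (diagonal mean exactly 1, PSD by
   construction). The null model `y = μ + g + e`, `g ~ N(0, σ²_g K)`,
   is fitted once by REML on K's eigensystem (bounded scalar search
   over the variance ratio), and every variant is then tested by
   generalized least squares under that fixed covariance — the
   population-parameters-previously-estimated scheme. With K = I the
   scan is exactly ordinary least squares.

Genotypes are 0/2 (inbred homozygotes); the reported effect is per
allele, i.e. half the homozygous-class difference — the convention
matters when comparing with validation crosses. P-values use the t
reference with n−2 df (small panels). Missing genotypes drop the line
for that variant only. Variants with MAF < 0.05 (boundary inclusive)
or excess missingness are excluded before scanning. Flags: `top` for
P < 1e-5, `bonferroni` for P < 0.05/(number tested). A variant is
assigned every gene whose span, widened by 1 kb on each side, covers
its position (1-based inclusive; GFF3 input).

One caveat measured during development: when the relatedness matrix is
estimated from only a few hundred variants, each tested variant is a
visible fraction of its own K and the scan becomes slightly
conservative. Calibration checks therefore use ≥800 variants per
panel; real studies with millions of variants are in the many-variant
limit where this vanishes.

## Validation statistics

Dunnett many-to-one comparisons pool the within-group variance across
all groups; the adjusted P for statistic t is P(max_j |T_j| ≥ t) under
the joint null. The many-to-one correlation structure is always
one-factor (ρ_ij = λ_i λ_j, λ_i = √(n_i/(n_i+n_0))), so conditioning
on the control variate and the pooled-SD variate turns the tail into a
two-dimensional integral, evaluated by 96-point Gauss-Hermite ×
160-point Gauss-Legendre quadrature — deterministic, exact for any
(unbalanced) sample sizes, agreeing with Monte-Carlo references to
~1e-4 and with the k=1 pooled t-test (special-cased exactly).

Pairwise variance validation uses the two-group mean-centred Levene
test. The SNP-cross contrast treats the F1 genotype, not the vial, as
the experimental unit (class means over genotype means, two-sample
pooled t-test per sex); with a single genotype per class it falls back
to vial level with a warning and a flag. The Beavis report divides the
validated effect by the GWA effect — estimates selected for passing a
significance threshold are upward-biased, so ratios well below 1 are
expected — and flags sign discordance.

## The synthetic generator

The generator inverts the analysis model. Per-fly intake for line l,
sex s is `grand_mean ± sex_effect/2 + L_ls + wolbachia + ε`,
ε ~ N(0, σ²_ls); the recorded vial value is intake × flies alive plus
a batch evaporation offset (shared per-batch constant plus small
noise, mirrored by control vials), so the reduction path is exercised
end to end. Defaults are the study's design: 182 lines × 2 sexes × 6
vials of 8 flies, σ²_L = 8.21, σ²_SL = 1.92, mean σ²_E = 12.66.

Choices where the generative form was open:

* **Within-line SDs** are log-normal per line (positivity guaranteed);
  `cve_heritability` scales a per-line log-SD effect shared between
  the sexes (variance `h·τ²` with τ = `cve_dispersion`, default 0.3),
  and the log-mean is set so E[σ²] equals `var_error_mean` exactly.
  The non-heritable share of observed log-SD variance is carried by
  the sampling noise of a 6-replicate SD itself; at h = 0 all lines
  share one true σ, which is what lets type-I calibration of the
  Levene tests be checked against this generator.
* **Cross-sex structure**: line effects are bivariate normal with
  correlation `cross_sex_line_corr` (default 1, the classic shared
  main effect); setting it below 1 with σ²_SL = 0 plants an exact
  cross-sex genetic correlation for recovery tests.
* **Scale**: the paper-scale variance components (σ_E ≈ 3.6 per fly)
  force a grand mean around 12 intake-score units for line means to
  stay positive (CV_E needs a positive mean); the default sex
  difference is 0.9 (females higher). The generator reproduces the
  study's variance structure, not capillary physics — per-fly volumes
  this large would overflow real 5 µL capillaries.
* **Genotypes** are biallelic, independent (no linkage
  disequilibrium, no demography), homozygous 0/2 with allele
  frequencies uniform on `maf_range`; a mean-QTL adds its
  allele-substitution effect × dose to line means (sex patterns:
  both / female / male / opposite), a variance-QTL multiplies the
  within-line SD of minor-allele homozygotes. Wolbachia infection is
  assigned independently of genotype.
* **Random streams** are split per component (line effects, SDs,
  genotypes, covariates, evaporation, vial noise), so enlarging the
  variant panel never perturbs phenotypes and identical seeds are
  bit-identical.

What passing tests on this generator do *not* show about real data:
no linkage disequilibrium or population structure among lines (a
separate family-structured construction is used to test that the
relatedness adjustment controls confounding), no genotype-covariate
correlation, Gaussian vial noise, and a mean–CV_E coupling that is
purely mechanical (SD independent of mean ⇒ negative mean–CV_E
correlation); real panels may couple mean and variance biologically.

## Problem sizes in the checks

Acceptance-style checks run at: 200 study-scale panels for
variance-component recovery (Monte-Carlo SEs ≈ 0.03–0.08 per
component), 500 panels of 15 lines × 60 vials for variance-test
calibration, 12 × 800-variant panels for null-scan uniformity, 100
seeds for planted-variant power, and 500 ten-treatment panels for
Dunnett family-wise error, with a 1e6-draw Monte-Carlo oracle for the
k = 2 adjusted P.

## Known limitations

* Type III F statistics for random terms under unbalance follow one
  synthesized-denominator convention; other software may print
  different F values for identical variance components.
* The LMM scan estimates the polygenic variance once on the null
  model; per-variant re-estimation (or leave-one-chromosome-out
  schemes) is out of scope.
* CV_E is a summary statistic; no double-GLM / DHGLM modelling of
  variance effects.
* The Dunnett quadrature assumes the homoscedastic pooled-variance
  model; no Welch-type extension.
* r_GS mixes moment and REML estimators and can exceed 1 in small
  panels (reported raw and clamped).
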