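# Methods

This note documents the statistical model the package implements, the
choices made where a design was genuinely open, the defaults of the
synthetic-data generator, and the limits of what the test suite can show.

## 1. Measurement model and parameterization

Items are modelled through latent responses `y* = Λη + ε`. Three-category
ordinal items (coded 1–3) are observed via two strictly increasing
thresholds on the latent-normal scale; continuous 0–10 items are observed
directly. Identification follows the convention that reproduces the
published degrees of freedom exactly for every single-group structure:

* factor variances fixed at 1, all pattern loadings free, factor means 0;
* ordinal items carry unit total latent variance with the residual variance
  *derived*, not free (delta-style parameterization), so each contributes
  two free thresholds;
* continuous items contribute a free intercept and residual variance;
* residual correlations are parameterized on the correlation scale, so a
  residual-pair parameter adds to the implied inter-item correlation
  exactly (for continuous items the covariance contribution is scaled by
  the implied SDs).

Counting: with `p` items (`p_o` ordinal, `p_c` continuous), the statistic
vector has `2·p_o + 2·p_c + p(p−1)/2` entries. For the 19-item structure
(15 ordinal, 4 continuous, 4 residual pairs) this yields df 145
(correlated factors), 129 (bifactor), 133 (S-1 with wellbeing as
reference), 138 (S-1 with internalising as reference), and 113/121 for the
two reduced models with non-invariant items removed. In bifactor-family
models all factor covariances are fixed at zero; in S-1 models the
remaining specific factors stay mutually orthogonal (freeing their
correlation breaks the df accounting for the wellbeing-referenced model).

## 2. Sample statistics

Margins are estimated first (thresholds as inverse-normal cumulative
proportions; continuous means/variances), then each correlation by a
one-dimensional likelihood maximization with margins fixed (two-step
estimation): bivariate-normal contingency likelihood for ordinal pairs
(polychoric), conditional likelihood of categories given the standardized
continuous score for mixed pairs (polyserial), and Pearson for continuous
pairs. Two-step rather than joint ML is the standard choice in this
estimator family and is orders of magnitude faster; its effect on the
estimates is far below sampling noise at the sample sizes involved. All
statistics use pairwise-complete observations, which is the natural match
for limited-information estimation under the small missingness rates the
generator emulates (0.6–2.6% per item, MCAR).

The asymptotic covariance `Γ̂` of the stacked statistics comes from
per-observation influence functions of the estimating equations, including
the first-step correction for estimated margins (computed from
finite-difference derivatives of the mean score, so it does not rely on
the information identity). A seeded nonparametric bootstrap of the whole
statistic vector serves as an independent oracle in the tests; the two
agree within 25% on variances at n = 2000 — comfortably enough, since
only the diagonal of `Γ̂` enters the point estimates.

Numerical choices: the correlation search runs on `[−.999, .999]` with
tolerance 1e−8 and clamps (with a boundary flag) at ±.999; bivariate
normal rectangle probabilities use a vectorized 20-node Gauss–Legendre
implementation of the Drezner–Wesolowsky/Genz scheme, chosen over the
general-purpose SciPy integrator for speed on threshold grids and verified
against it to ~1e−6 or better in the tests; cell probabilities are floored
at 1e−300 before logs.

## 3. DWLS estimation and the adjusted test statistic

The fit function is `F(θ) = (s − σ(θ))' W⁻¹ (s − σ(θ))` with
`W = diag(Γ̂)`. In single-group models the margins are saturated, so they
are profiled at their sample values and the quasi-Newton search (L-BFGS-B,
gradient tolerance 1e−6, up to 3 seeded jittered restarts) runs over the
structural parameters only; starting values are .5 for general/domain
loadings, .3 for specific loadings, 0 for factor and residual
correlations. A soft penalty keeps ordinal communalities below 0.98
(Heywood guard); continuous items with implied negative residual variance
are flagged rather than silently truncated.

The test statistic is the scaled-and-shifted transform of `T = F_min`:
with `U` the DWLS residual projector and `M = UΓ̂`,
`T* = √(df/tr(M²))·(T − tr(M)) + df`, matching the mean and variance of a
χ²(df). The mean-only scaling `T·df/tr(M)` is available behind a flag for
sensitivity checks. Standard errors use the full sandwich with `Γ̂`.
Fit indices: RMSEA with `n−1` in the denominator (both `n` and `n−1`
round to the published three-decimal values, so the choice is cosmetic)
and a 90% CI from noncentral-χ² inversion; CFI/TLI against the
independence-with-free-margins baseline, the conventional choice.
Modification indices are score tests in the residual metric with the
sampling variance `(UΓ̂U)` — under the null each index is χ²(1) to a good
approximation (empirically: mean ≈ 1.1, 1% tail ≈ 1.3% at n = 2000).
Nested models are compared with a scaled difference built from the same
trace machinery applied to the difference of the two projectors; a
negative scaled difference (a known pathology) is reported as 0 with a
flag. Nesting is asserted from the model algebra of the structures
involved, not tested empirically.

The wellbeing instrument alone has no ordinal items, and is fitted by
normal-theory ML on the sample covariance matrix (means saturated), with
likelihood-ratio-based modification indices. Its χ² is unadjusted.

Cluster sampling is quantified (one-way ANOVA ICC per item) but the
test-statistic correction for clustering is not implemented; with item
ICCs in the .004–.067 band the unadjusted statistics are mildly liberal at
worst, and all calibration tests generate independent respondents.

## 4. Multigroup invariance

The categorical three-step scheme: (1) per-group baselines; (2) configural
— identical structure, every parameter group-specific, scale factors 1 and
factor means 0 in both groups, statistically identical to two separate
fits and assembled on the stacked statistic space; (3) scalar — loadings
and thresholds/intercepts equated, in exchange for free group-2 factor
means, factor variances, and ordinal scale (delta) factors. Continuous
residual variances and residual correlations stay group-specific at every
level. These identification details are the conventional delta-scheme
choices; only the three steps themselves are fixed by the study design.

Scalar-vs-configural uses the scaled difference test at α = .05. On
rejection, the partial-invariance search computes a block modification
index per still-invariant item (group-2 deviations of its thresholds/
intercept and loadings; directions already spanned by free parameters are
absorbed by the projector and a pseudo-inverse), frees the whole
measurement block of the top item — ties break toward the item earlier in
the model's item order — refits, and stops when the test is
non-significant or a freed-item cap (default 3) is reached; hitting the
cap while still significant yields the verdict "rejected".

Negative continuous residual variances surface as parameters pinned at
their lower bound; the policy recomputes the unconstrained one-step
estimate and its sandwich SE, fixes the variance to zero when the estimate
is non-significantly negative (recording the fix), and fails loudly when
it is significantly negative, since that indicates real misspecification.

Covariate associations with binary gender/income are estimated one
covariate at a time as the group-2 factor-mean differences of the fully
scalar-invariant two-group model — for a binary regressor this is exactly
the latent regression of each factor on the covariate in probit form. The
reported coefficient is the group difference in reference-group factor-SD
units; a correlation-metric standardization (rescaling by the covariate SD
and the marginal factor SD) is reported alongside, since the scale of such
coefficients is a genuine reporting ambiguity.

## 5. Dimensionality indices

ECV is computed from completely standardized loadings as
`Σλ²_general / (Σλ²_general + Σλ²_specific)`; PUC from group sizes as
`1 − Σ n_k(n_k−1)/2 ÷ p(p−1)/2` (S-1 reference-domain items count as
singleton groups). The unidimensionality screen — PUC > .80 *and*
ECV > .60, both strict — is advisory text, never an automatic model
selection, because the underlying recommendation is itself a heuristic.
The vanishing-factor diagnostic flags a specific factor when at least half
its loadings fall strictly below .3 (both configurable), or when an
explicitly supplied freed-variance estimate falls below .15; loadings
exactly at the threshold do not count. The reported collapsed pattern
(.28/.15/.18/.08 on a four-loading factor) fires the loading rule.

A caution about ECV from fitted bifactor models on (nearly) unidimensional
categorical data: because ordinal items carry no fitted variance statistic
in the delta parameterization, a *single* specific loading per factor
changes no implied correlation when the factor's other loadings are near
zero — a flat ridge of the DWLS fit function. Sampling noise pushes one
loading up that ridge, which deflates ECV without reflecting any real
specific covariance; the identified part of the specific structure (the
loading *products*) does vanish. This is the estimator-level face of the
vanishing-factor/empirical-underidentification phenomenon, and the reason
the test suite checks the identified specific covariance (second-largest
loading per specific factor) rather than a raw ECV cutoff on
unidimensional simulations.

## 6. The synthetic generator

The generator is the package's stand-in for the undeposited survey; its
defaults are the study conditions. What the paper fixes is used directly:
9/6/4 items on the three instruments' scales, factor correlations +.58
(internalising–externalising), −.58 (internalising–wellbeing), −.42
(externalising–wellbeing), the wellbeing residual pair at .26, loadings
within [.43, .80], per-item missingness within [.006, .026], 59 clusters,
N = 1982, covariate prevalences .47 (girls) and .43 (ever-FSM). Where only
constraints are printed, the shipped defaults are fixed assumptions,
documented here and in the config file:

* loadings drawn once from [.43, .80] and frozen as constants;
* symptom thresholds at cumulative probabilities ≈ (.55, .90) — a floor
  effect — with small per-item offsets; the re-reversed calm item at
  ≈ (.25, .75); the reverse-keyed item is emitted already re-coded;
* the three symptom residual pairs at .20/.25/.30;
* wellbeing intercept 7.5 and total SD 1.5 on the 0–10 scale, giving a
  mild ceiling (~5% of responses at the maximum);
* covariate effects with the reported association signs (girls: higher
  internalising, lower externalising; ever-FSM: higher externalising) and
  modest assumed magnitudes (.15/−.30 and .05/.25/−.05 factor-SD per
  unit), set to zero in null-calibration tests;
* clustering as a normal random intercept on each factor, variance solved
  so the *average* item ICC hits the .03 target (per-item ICCs then span a
  band, as in real data); an ICC calibration test checks an item at the
  mean communality.

Covariate and cluster variance shares are subtracted from the
within-person factor covariance so the marginal latent correlation matrix
equals the configured `Φ` exactly; since cluster intercepts are normal,
only the binary covariates make latent margins non-normal, and their
effect on category probabilities is O(10⁻³). The [0, 10] clipping of
continuous items is the one deliberate deviation between the generative
process and the analysis model: at the default ceiling it attenuates
wellbeing correlations by ≲ .005, inside the .02 moment-fidelity band the
tests enforce. What passing tests therefore show is recovery under a
correctly specified latent-normal world with mild realistic violations
(clipping, binary-covariate mixtures); they do not speak to robustness
under strong non-normality, informative missingness, or informative
cluster sampling.

## 7. Problem sizes used in testing

Calibration suites are run at reduced but non-trivial sizes chosen to keep
the full suite reproducible on one CPU: latent-correlation recovery at
n = 2000 over 10 seeds; loading recovery at n = 5000 over 10 seeds;
invariance null calibration on a compact one-factor instrument (3 ordinal
+ 2 continuous items) with 800 per group over 200 replicates; scaled-
difference type-I calibration on a 6-item instrument at n = 1000 over 200
replicates; orthant and missingness checks at n = 50 000 and entrywise
moment fidelity at n = 200 000, where the band is sharp against the max
over all 171 correlations. Stochastic
suites use fixed seed blocks; the spec-level tolerance of each check is
stated in the corresponding test.

## 8. Known limitations

* No cluster-robust correction of test statistics or standard errors.
* Exactly two groups in invariance testing; freeing is whole-item.
* The S-1(internalising) full-model df computed here is 138 under the
  stated convention; reduced-model counts match the published 121 exactly.
* Γ̂ uses the empirical-moment form of the information matrices inside
  influence functions; with heavy boundary clamping (|ρ̂| at .999) its
  variances for those entries are approximations (flagged pairs are
  reported).
* The ML route for continuous-only instruments reports unadjusted χ²
  (plain normal-theory ML), appropriate only for roughly symmetric
  continuous items like the generated wellbeing scores.
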