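# Methods

`latentchange` implements the latent-variable analysis of co-developing
constructs measured at two waves: a longitudinal confirmatory factor
analysis (CFA) with measurement-invariance testing, a multiple-indicator
bivariate latent change score model (LCSM), multi-group equality-constraint
comparisons, and a synthetic-cohort generator that makes the whole pipeline
runnable without access-restricted data. This note records the models, the
conventions, and the design choices a maintainer would want to know.

## The model family

All models live in LISREL-style all-latent parameter matrices
(Λ loadings, B directed paths among latents, Ψ latent residual
covariances, Θ observed residual covariances, ν observed intercepts,
α latent intercepts), with implied moments

    Σ = Λ (I − B)⁻¹ Ψ (I − B)⁻ᵀ Λᵀ + Θ,     μ = ν + Λ (I − B)⁻¹ α.

Each cell is fixed or carries a free-parameter label; cells sharing a label
share a value, which is how across-wave and across-group equality
constraints are expressed. Observed variables that enter the structural
part directly (cortical thickness; all variables of the "separate
indicator" models) get unit-loading latent proxies with zero residuals, so
the LCSM's unit-weight paths are expressible for them too.

**Latent change score structure.** For each construct, wave 2 is defined
as wave 1 plus a latent change factor through fixed unit paths
(`t2 ← t1 = 1`, `t2 ← Δ = 1`) and a zero wave-2 residual, so the change
factor Δ carries its own intercept, variance, and regressions. The
bivariate model frees exactly thirteen structural parameters: baseline
means and variances of the social-experiences factor (PSE) and cortical
thickness (CT), change intercepts, change residual variances, two
self-feedback paths (ΔPSE ← PSE₁, ΔCT ← CT₁), the coupling ΔCT ← PSE₁,
the change–change covariance φ, and the baseline covariance. The reverse
coupling (ΔPSE ← CT₁) exists behind a flag and is off by default, matching
the unidirectional published specification.

**Identification.** Marker-variable convention: the marker indicator
(school environment by default — the highest-loading indicator; the
published report does not name its marker, so this is configurable) has
its loading fixed to 1 and intercept to 0, and latent means are free.
The factor therefore takes the 0–100 indicator metric, which is what makes
a latent mean like 80.74 interpretable.

**Invariance levels.** Configural frees loadings and intercepts per wave;
weak equates loadings across waves; strong also equates intercepts;
partial is strong with a named subset of wave-2 intercepts released
(default: family cohesion and number of close friends — two indicators,
chosen so the partial CFA has df = 79; the published report does not name
the freed pair). Across-wave residual covariances for same-named
indicators are always free. Free-parameter counts for 7 indicators × 2
waves: configural 50, weak 44, strong 38, partial 38 + k. The single-group
LCSM uses the strong measurement model (df = 106 with 46 free parameters).

## Estimation

**FIML.** Rows are grouped by missingness pattern; each pattern
contributes through its count, mean, and scatter, so one likelihood
evaluation costs O(#patterns · p³) independent of n, and on complete data
the value equals the complete-data multivariate-normal log-likelihood
exactly. Rows with no observed variables are dropped with a warning. A
non-positive-definite sub-block returns −∞ to the optimizer (a rejected
step), never an exception.

**Optimization.** L-BFGS with an analytic adjoint-propagated gradient,
followed by Fisher-scoring polish (expected information, ridge fallback,
backtracking line search) to a gradient max-norm of 1e-6 on the
per-observation log-likelihood. Starting values are moments-informed:
free loadings 1, residual variances at half the sample variance, latent
means/variances from marker columns, plus up to two jittered restarts if
needed. Variance parameters are unconstrained; negative estimates are
flagged as Heywood cases, not barred, matching common SEM-software
behavior. Non-convergence is flagged on the result, not raised.

**Standard errors.** The default "robust" flavor is the sandwich
estimator: observed information (finite differences of the analytic
gradient) as bread, the outer product of casewise score contributions as
meat. Plain observed-information SEs are available. No Satorra–Bentler
style scaled χ² is computed: the quantities this package is accountable
for (parameter recovery, df bookkeeping, Δχ² arithmetic) do not involve
the scaling constant, and sandwich SEs cover the robustness role.

**Saturated and baseline models.** The saturated log-likelihood under
missingness comes from an EM algorithm for the unstructured MVN (closed
form on complete data); the independence baseline factorizes per column
into observed-case means and variances.

## Fit indices and decisions

χ² = 2(ℓ_saturated − ℓ_model), clamped at zero if optimizer noise makes it
negative. CFI uses the independence baseline. RMSEA uses the N − 1
denominator with a 90% CI from noncentral-χ² inversion (bisection,
tolerance 1e-8); these conventions are unstated in the source report and
follow dominant SEM practice. SRMR averages squared standardized
residuals over unique covariance *and mean* elements (all models here have
mean structures), with sample-side moments taken from the saturated (EM)
estimates so the index is defined under missingness.

Nested comparisons report Δχ² (clamped at 0 with a warning if negative),
Δdf, p, ΔCFI and ΔRMSEA. The retention rule is a disjunction, as
published: retain the constrained model if p > .05, or the RMSEA increase
is < .015, or the CFI decrease is < .010; ties favor parsimony. One
consequence worth knowing: a moderate loading violation can be decisively
significant by Δχ² yet still "retained" because the RMSEA barely moves —
the rule is deliberately lenient, and the ladder reports both the test and
the decision so users can see when they disagree.

## Standardized solution

The standardized column of the published parameter table mixes two
conventions, and the implementation reproduces exactly that mix:

* loadings, directed paths, and intercepts/means are rescaled by
  model-implied **total** standard deviations of their connected variables
  (so a standardized change variance of .91 means 91% of the implied total
  change variance is residual);
* variance parameters are reported as **proportions** of the implied total
  variance of their variable;
* covariance parameters are reported as the **correlation of the
  corresponding residual terms** (for exogenous variables the residual is
  the total, so this is the plain correlation). This is what reproduces a
  standardized change–change covariance of ≈ .08 from
  2.62/√(31.26 · 35.28); scaling by total SDs would give ≈ .065 and can
  exceed 1 in pathological cases, while the residual-correlation form is
  bounded in [−1, 1].

## The synthetic cohort generator

The generator is a forward model of the LCSM path diagram in the scaled
0–100 metric: baseline (PSE₁, CT₁) are bivariate normal; change scores
follow their regressions with correlated residuals; wave 2 = wave 1 +
change; seven indicators load on the PSE factor at each wave with
across-wave-correlated residuals (correlation .3 by default). Canonical
structural defaults are the published estimates (φ = 2.62, self-feedbacks
−.51 and −.16, coupling −.01, baseline covariance −.18, change intercepts
43.38 and 5.16, baseline means 80.74 and 57.14, change variances 31.26 and
35.28; where the running text and the table disagree in the last digit,
the running text is used). Baseline variances are back-solved so the
standardized change-variance proportions equal .74 and .91, and
measurement parameters are back-solved so fully standardized wave-1
loadings hit .10 (friends), .20 (neighborhood safety), .26 (family
cohesion) and .50 elsewhere, every indicator sharing the marker's total
observed variance. Demographics (sex, puberty stage with the published
group frequencies, parental education with median 16 years, MRI QC fields)
are generated independently of the outcome model unless per-group
structural overrides are requested.

**Missingness.** Wave-2 cortical thickness is deleted at a 20% marginal
rate, modulated logistically (slope .5 on the z-scored observed wave-1
indicator mean) so adolescents with lower observed baseline social scores
are more likely to miss the second scan — missing at random by
construction, because the modulator is observed. The logistic intercept is
solved numerically so the realized marginal rate matches the target.
Wave-2 indicators are deleted completely at random at 10%; wave 1 is
complete by default. The true missingness mechanism of the real cohort is
unknown; MAR is assumed because that is the assumption under which FIML is
justified.

**What the generator does not emulate.** Indicators are Gaussian, not
discretized Likert items (so reverse-scaled native tables can spill
slightly past theoretical scale bounds); friend counts are not counts;
demographics carry no real covariance with the outcome process; QC flags
are independent noise. Passing tests therefore demonstrate that the
*estimator and decision machinery* behave correctly under the model's own
assumptions — they do not validate distributional robustness on real
cohort data.

## Monte-Carlo recovery and known small-sample behavior

`recovery_study` simulates replicates, refits, and reports per-parameter
mean estimate, bias, Monte-Carlo SE, empirical SD vs mean model SE, and
95% coverage; replicates that fail to converge are excluded and counted,
and more than 20% failures abort the study. The acceptance surface uses
n = 5,000 with 20 replicates (tests) and 30 replicates (acceptance
script) — sizes chosen to pin Monte-Carlo error well below the published
standard errors while keeping a desk-scale runtime.

A property worth documenting: at n = 5,000 the ML estimate of the
change–change covariance φ is mildly right-skewed (skew ≈ .25 across
replicates) and its replicate mean can sit a tenth or two above the
generating 2.62 depending on the seed batch; multistart refits confirm
these are global optima, and at n = 100,000 all structural parameters are
unbiased (φ mean 2.600 ± .023 over 30 replicates). This is ordinary
finite-sample behavior of ML in a weak-indicator latent model, not an
estimator defect.

## Preprocessing conventions

Order of operations: truncate friend counts at 100 → blank brain values
failing QC (recommendation flag set, or clinical score > 2) → cell-wise
±5 z-score rule per variable and wave, computed on the post-truncation
column; cells exactly at |z| = 5 are retained. The z-rule blanks the
offending cell only, not the participant, because variable-specific
exclusion counts are what the source reports. The rule is single-pass;
strict idempotence holds when a second pass flags nothing new, which is
the case for the generator's Gaussian data. Scaling is percent of maximum
possible on theoretical scale ranges (not observed min/max), keeping the
metric comparable across waves and samples; the thickness range defaults
to 1.0–4.5 mm and is configurable. SES splits parental education years at
the sample median with ties assigned high (configurable). The 20/80
exploratory/confirmatory split utility floors the first part's size and is
seeded.

## Numerical details and degenerate inputs

Gradient tolerance 1e-6 (max-norm, per-observation log-likelihood); EM
tolerance 1e-9 relative; RMSEA CI bisection 1e-8. χ² and Δχ² are clamped
at 0 with warnings. df = 0 yields CFI 1 and undefined RMSEA, flagged.
Zero implied variances make standardized values undefined (NaN), flagged.
A singular (I − B) raises a structural-cycle error; a non-PD generating
covariance raises at construction, never silently. Multi-group fits
require every named group non-empty; rows with missing group labels are
excluded from multi-group stages.

## Limitations

Two waves only (no three-wave or dual change score extensions);
continuous-normal estimators only (no WLSMV/categorical, no Bayesian
fitting); no modification-index search (the partial-invariance freed set
is user-specified); no scaled-χ² robust test statistics. The six-group
puberty stratification is expressible via the multi-group builder, but no
degrees-of-freedom claim is made for it: the published parameter count for
that model cannot be reconciled without knowing its exact per-group
constraint set.
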