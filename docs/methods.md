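# Methods

This note documents the statistical models implemented in `spiral_alt`, the
assumptions they make, the synthetic data-generating process used to test
them, and the numerical and design choices that were genuinely open.

## Scientific setting

Experience-sampling (ESM) trials prompt participants several times a day
("beeps") to rate momentary mood and cognition on 7-point Likert scales.
The design handled here is a two-arm randomized trial (mindfulness-based
cognitive therapy, `mbct`, n = 64 vs waitlist `control`, n = 66) with two
assessment periods (pre / post treatment), each comprising six consecutive
days with ten 90-minute beep blocks per day — at most 60 beeps per
participant per period.  Two constructs are scored per beep: **positive
affect (PA)**, the unit-weight mean of the mood adjectives retained by a
principal-component loading cutoff, and **positive cognition (PC)**, the
rated pleasantness of the current thought.  The scientific question is
whether treatment raises these quantities and whether day-to-day dynamics
(autoregression within a construct, cross-lagged coupling between
constructs) sustain the gains — an "upward spiral".

## Preprocessing

* **Validity filter.** Reports completed more than 15 minutes after the
  beep are excluded; the boundary is inclusive (delay ≤ 15 min is valid)
  because the exclusion rule targets reports *not* filled in within 15
  minutes.  Never-completed reports are removed.  The filter is idempotent
  and order-invariant.
* **PA composite.** A principal component analysis of the beep-level
  adjective correlation matrix (complete cases, pooled across subjects and
  periods; a period-restricted analysis is available via a flag).
  Components with eigenvalue > 1 are extracted; with two or more, an
  oblique (quartimin) rotation is applied and the component with the
  largest squared-loading sum is taken — with a single component the
  rotation is a no-op and is skipped.  Items with |loading| < 0.6 are
  dropped; Cronbach's alpha is reported for the retained set.  Beep scores
  are unit-weight means of retained items, missing when fewer than 4 of
  the items were answered (the majority of 7; the instrument gives no rule
  for partial response).
* **Likert coding** is fixed at 1–7.  A rating of 0 is treated as
  out-of-range (set missing with a warning), not silently recoded: the
  instrument description is internally contradictory on this point and the
  conservative choice does not manufacture data.
* **Daily aggregation.** Valid beep scores are averaged into per-subject
  daily means of PA and PC.  Any day with at least one contributing beep
  yields a mean; contributing counts are recorded so users can impose a
  stricter threshold downstream.

## Mixed model for momentary outcomes

The treatment-effect model for a beep-level outcome is

y = b0 + b1·time + b2·condition + b3·(condition×time) + u_subject + e,

with u ~ N(0, σ²_u) and AR(1) residuals: corr(e_i, e_j) = ρ^d over the
ordered beep sequence within subject × period, where d is the difference
in scheduled beep positions (so skipped beeps widen the gap); the
correlation does not bridge the pre/post boundary, and no clock-time gap
model is attempted because only the block schedule is defined.  b3 is the
difference-in-differences of interest.

The marginal likelihood is evaluated exactly in O(n) per evaluation: the
Markov structure of the AR(1) chain gives a banded whitening transform,
and the random intercept enters by a rank-one Woodbury update per subject;
fixed effects are profiled out by GLS.  Estimation is ML by default (so
nested fixed-effect likelihood-ratio tests remain valid; REML available).
Wald tests use a normal reference — beep counts per cell are in the
thousands, so the df refinement is immaterial.  The random-intercept
variance is reported with a one-sided z test from the observed information
of the profiled likelihood.  The implementation is verified against a
dense multivariate-normal oracle to ~1e-9.

## Path-model engine

Models are parameter tables over observed and latent variables compiled to
RAM matrices: Σ = F(I−A)⁻¹S(I−A)⁻ᵀFᵀ, μ = F(I−A)⁻¹M.

* **Estimators.** Covariance ML minimizes the normal-theory discrepancy
  F = ln|Σ| − ln|S| + tr(SΣ⁻¹) − p + (x̄−μ)ᵀΣ⁻¹(x̄−μ) on complete-case
  moments; FIML maximizes the casewise Gaussian likelihood over each
  case's observed subvector (valid under missing-at-random data), grouped
  by missingness pattern for speed.  Analytic gradients are propagated
  through the RAM structure for both.
* **Chi-square conventions.** Covariance ML: χ² = (N − ddof)·F̂ with
  ddof = 1 by default (the convention of the commercial SEM packages this
  mirrors).  With ddof = 0 the statistic is the pure likelihood-ratio
  statistic and coincides *exactly* with the FIML chi-square on complete
  data — the identity the test suite asserts.  FIML: χ² = 2(llsat − ll),
  with the saturated model fitted by EM for the multivariate normal with
  missing data (closed form when complete).  EM was chosen over running
  the quasi-Newton optimizer on the ~p(p+3)/2-parameter saturated problem
  because it is exact ML, monotone, and has no convergence knobs.
* **Optimization.** L-BFGS-B on the unconstrained natural parameters
  (variances are not log-transformed, because trajectory-model residual
  covariances legitimately sit near zero and may cross it during
  iteration; positive definiteness of Σ is enforced by a penalty wall and
  checked at the solution).  Start values: sample means/variances for
  measurement parameters, 0.1 for structural paths, half the average
  variance for latent variances.  A full-memory BFGS polish runs after
  line-search stalls, and up to 5 jittered restarts after failures; a
  solution with max |gradient| < 1e-3 (which moves χ² by < 1e-6) counts as
  converged.
* **Standard errors** come from the observed information (central-
  difference Hessian of the objective); a near-singular information matrix
  flags under-identification and switches to a pseudo-inverse.
* **Fit evaluation.** df = p(p+3)/2 moments per group minus distinct free
  parameters after equality-label merging (verified against a brute-force
  census); relative χ²/df ratio; CFI and IFI against the independence
  baseline (free means and variances only — their standard definition);
  RMSEA = √(max(χ²−df,0)/(df(n−1))) with a 90% interval from noncentral
  chi-square inversion, lower bound floored at zero.  Worked example: at
  the printed statistics χ² = 14.57, df = 12 and n = 126 these give
  RMSEA = 0.04 (0.00, 0.10); the point estimate is stable over n 121–130,
  the interval's upper bound rounds to 0.10 from n ≈ 126 up.
* **Equality constraints** are enforced exactly by parameter sharing
  (within and across groups via labels), never by penalty.  Multi-group
  fits sum one objective over disjoint groups.

## ALT model family

The autoregressive latent trajectory (ALT) model hybridizes a latent
state–trait/growth model with a cross-lagged panel model.  The
"predetermined" parameterization treats day 1 as exogenous (free mean and
variance, covarying with the latent factors), which prevents bias from
dynamics that started before the series was observed.  Per construct: a
trait intercept factor loading 1 on days 2–6 (free mean/variance), an
optional linear slope factor with loadings 1–5, free lag-1 autoregressive
paths (optionally equality-constrained across the five lags), day-2..6
intercepts fixed at zero, free residual variances.

The multivariate form adds all four pairwise covariances among the two
intercept factors and the two day-1 measures, optional bidirectional
cross-lagged paths for all five lags, and same-day residual covariances
for days 2–6 (on by default; the daily constructs are strongly coupled
within day).  The conditional form regresses both intercept factors *and*
both day-1 measures on the covariates (treatment dummy, pre-period mean
PA/PC) so that baseline differences propagate to day 1; this identifying
choice is flagged in the parameter table.  The two-group form drops the
treatment dummy (condition becomes the grouping variable), retains the
pre-period covariates, labels dynamics per group, and supports cross-group
equality labels for formal equivalence tests.

Degree-of-freedom arithmetic of the family (analytic, verified by census):
AR equality in a univariate 6-day model frees 4 df; a slope factor costs
4; bidirectional cross-lags cost 10; joint AR + cross-lag equality in the
multivariate/conditional model gains 16.

### The model ladder

`run_model_ladder` executes the nested sequence — univariate PA (base,
+slope, AR equality), univariate PC, multivariate (base, +cross-lags,
joint constraints), conditional, two-group — with the reporting decision
rules: a constraint is retained when its Δχ² p ≥ 0.05 (so a marginal
p = 0.05 retains); the slope factor is retained only when it improves fit
at p < 0.05 or its mean is significant.  Comparisons are made only between
structurally nested neighbours, which the code verifies at the free-slot
level before fitting.  The cross-group equivalence test shares the
labelled dynamics parameters across arms and is run whenever the final
structure carries equality labels.

## Synthetic data generator

The generator *is* the multivariate ALT process, so the models above are
correctly specified for it (this is what makes χ² calibration and coverage
tests meaningful).  Per subject × period, traits (η_PA, η_PC) are
bivariate normal; day 1 = offset + η + correlated residual; days 2–6
follow the AR/cross-lagged recursion with correlated innovations.  Post-
period treated-arm trait means are shifted by (τ_PA, τ_PC).  Traits share
70% of their variance across the two periods (`trait_stability`) so the
pre-period means are informative covariates, as in real panels.

Defaults (all overridable) are set to the study's reported regime and
7-point scale: steady-state daily means ≈ 3.3 with SD ≈ 1.0–1.1, daily PA
autocorrelation ρ_PA = 0.25, cross-lag γ_PA→PC = 0.17 with no reverse
coupling, ρ_PC = 0.05, same-day residual correlation ≈ 0.78, τ_PA = 0.15
and τ_PC = 0.2065.  τ_PC was calibrated by simulation so the *realized*
mixed-model interaction on momentary positive cognition is 0.230 ± 0.005
(600 replicates), matching the reported effect; the Likert measurement
layer attenuates latent effects by a few percent.  Item loadings put the
PA composite's alpha near 0.89 with "relaxed" at 0.25, well under the 0.6
retention cutoff.  An optional per-arm override `gamma_pa_pc_control`
supports probe designs in which only the treated arm carries the
cross-lag.

The beep layer adds momentary noise (SD 0.8) on the daily latent, maps
adjectives through their loadings with item noise, and discretizes by
rounding and clipping to 1–7 (a flag yields continuous items for
exact-recovery tests).  Completion delays are exponential (mean 4 min,
truncated at 15) with a late mass (probability `p_late`) shifted beyond
the 15-minute validity limit; beeps are independently unanswered with
probability `p_miss`, optionally increasing over days (MAR mode) to
exercise full-information estimation.

### What the generator does not emulate

Real ESM data have circadian structure, serially correlated and
outcome-dependent missingness, non-normal and floor/ceiling-compressed
responses, and treatment effects that need not enter through trait means.
Passing recovery and calibration tests therefore demonstrates correctness
of the estimators under the assumed model class, not robustness to these
violations.  One such violation is deliberately present: under the full
generator the mixed model's AR(1)+random-intercept covariance understates
between-period trait variation, so its standard errors for the interaction
are optimistic there; calibration tests for the mixed model use data
simulated from its own process, while the full-pipeline test checks
centering only.

## Problem sizes used by the test suite

Monte-Carlo sizes were chosen so that tolerance bands sit several standard
errors away from the truth under a correct implementation: the moment
oracle compares implied to empirical moments at 20 000 subjects (max
absolute deviation < 0.05 ≈ 4σ of Monte-Carlo noise), large-n recovery
runs at 40 000 subjects, calibration of Δχ² and Wald type-I error uses 500
replicates at the study scale of 130 subjects, and sampling-distribution
checks use 200–300 replicates.  The end-to-end ladder check runs three
independent probe panels of 600 subjects per arm (treated-arm-only
cross-lag, no slope, equal ARs) and requires each structural decision to
be recovered in at least two of three panels — individual retention
decisions carry exactly the 5% error their α = 0.05 rule implies, so a
single-panel criterion would fail a correct implementation roughly a
quarter of the time.

## Known limitations

* Ordinal Likert data are modeled as Gaussian throughout (as is standard
  for 7-point ESM composites); no polychoric/limited-information option.
* No robust (sandwich / Satorra–Bentler) corrections or bootstrap CIs.
* The mixed model supports a random intercept only (no random slopes),
  and the AR(1) index ignores clock-time gaps within a block schedule.
* FIML assumes MAR; missingness mechanisms depending on the unobserved
  response are out of scope.
* Absolute df values of the fitted ALT models follow this package's
  parameter census; published tables from other software may differ in
  their absolute df (different implicit parameterizations) while agreeing
  on all df *differences*, which is what the ladder's decisions use.
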