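# Methods

`trialcea` implements a within-trial economic evaluation of the kind run
alongside pragmatic randomised trials in child mental health: a
two-arm comparison (a modular, therapist-delivered psychological
intervention added to usual care, versus assessment-enhanced usual care
alone) over a one-year horizon, from a health- and social-care
perspective. Because participant-level trial data of this kind are not
publicly shareable, the package pairs the analysis machinery with a
synthetic-trial generator calibrated to the published summary
statistics, so every stage is exercisable and testable end to end.

## Costing

Service use is recorded as (participant, period, category, quantity)
with periods `baseline_3m` (3-month recall before randomisation),
`m0_6` and `m6_12`. Costs are quantity x unit cost, summed per
participant-period. Unit costs are a user input (category, unit,
unit cost, price year); the bundled table is illustrative with
realistic 2020/21-style magnitudes. Record-level costing is carried
out in exact integer pence (unit costs are validated to whole pence),
so category costs and totals are exact at the 0.01 GBP resolution;
the only rounding, half-even to pence, happens at report time.

The intervention is micro-costed bottom-up:

    session cost = rate_therapist x ff_hours x (1 + r_indirect)
                 + sup_hours x rate_supervisor / sessions_pp
                 + training_total / (n_amortised x sessions_pp)

where `r_indirect` is indirect (non-face-to-face) hours per
face-to-face hour, supervision and training are per-participant
overheads spread over `sessions_pp` sessions, and training is amortised
equally over `n_amortised` participants (defaulting to the intervention
arm size; no published allocation rule exists, so equal division is a
design choice). Per-participant intervention cost is sessions attended
x session cost x a substitution scaling factor in (0, 1]: 1.0 treats
the intervention as fully additional to usual care, 0.75 is the
sensitivity scenario in which delivery partly substitutes for standard
clinic contact. The factor applies to the whole per-participant
intervention total (not to training alone), matching the "75% of the
full cost" framing. The shipped micro-costing configuration is a
synthetic illustration that lands at ~80.41 GBP/session and, over a
mean 18.23 sessions, ~1466 GBP/participant; the true line items behind
those published figures are not public.

## Outcomes

SDQ total difficulties scores (integer 0-40, lower = better) are used
directly at the requested endpoint, no interpolation. QALYs are the
area under the utility curve at 0, 0.5 and 1.0 years assuming linear
change: `q = 0.25 u0 + 0.5 u6 + 0.25 u12`. A QALY is complete only when
all three utilities are observed. Utilities live in [0, 1] by default;
a config flag widens the floor to -0.594 for EQ-5D-5L-style
worse-than-dead valuations. Combined child+caregiver QALYs are the
arithmetic sum of the two individual QALYs -- no standard combination
rule exists across populations and instruments, and the sum is the
usual total-QALY-gain convention; it is a single, swappable function.

## Estimation

Every outcome (costs, SDQ, QALYs) is analysed with a linear model of
the outcome on arm, baseline covariates (baseline 3-month cost,
baseline SDQ, and the outcome's own baseline utility where applicable)
and the four minimisation factors (primary disorder, age band, autism,
intellectual disability; treatment-coded with references anxiety, <11,
no, no), with a random intercept for recruiting site. The arm
coefficient is the adjusted intervention-minus-control difference.
Wald 95% intervals use the mixed-model asymptotics (n in the hundreds;
reported intervals are symmetric). Complete-case rows are defined per
analysis, not listwise. Fitting uses L-BFGS with a Powell retry; a
degenerate fit (boundary variance, non-finite SE) or a single site
falls back to OLS with a log message -- for the arm contrast this is a
benign change of weighting, not of estimand. A rank-deficient design
raises, naming the collinear columns. Unadjusted per-arm means come
with Welch t-tests: parametric comparison of arithmetic means is
standard for cost data even when skewed, because the mean is the
decision-relevant statistic.

## Decision analysis

ICERs are delta-cost / delta-effect with the usual plane quadrants
(NE/SW trade-off, SE dominant, NW dominated); a zero effect difference
yields an undefined-ratio marker carrying the cost sign. Net monetary
benefit is `lambda x effect - cost`. Uncertainty comes from a
non-parametric bootstrap: participants are resampled with replacement
stratified by arm, and three adjusted models are refit per resample --
cost excluding the intervention, intervention cost, and effect -- so
each replicate is a joint (dC_excl, dI, dE) triple. Degenerate
resamples (singular designs) are redrawn, erroring above 10% redraws.
Storing the intervention component separately means costing scenarios
(e.g. 75%) reuse identical replicates with only `dC = dC_excl + f x dI`
changed, which makes intervention-cost scaling exactly monotone on
every CEAC point and keeps scenarios comparable under one seed.

The CEAC at each lambda is the fraction of replicates with
`lambda x dE - dC > 0`, ties at exactly zero counted one half
(measure-zero in practice; fixed for determinism on toy data). For SDQ
the effect enters as the *reduction* in score (control minus
intervention), so the curve reads per unit improvement. Default grids:
0-1000 GBP step 1 for SDQ; 0-50,000 GBP step 500 for QALYs, with the
20,000-30,000 NICE band reported. The default replicate budget is
B = 5000; the analysis scripts use B = 500 with the mixed estimator,
which resolves CEAC probabilities to about +/-0.02.

## Missing data

Follow-up missingness is handled by multiple imputation with chained
equations, m = 31 datasets, predictive mean matching. Incomplete
variables (period costs, SDQ at 6/12 months, child and caregiver
QALYs -- QALYs are imputed directly, not their constituent utilities)
are visited in ascending order of missingness fraction. Each
univariate step regresses the observed part on the fixed predictor set
(arm, the four minimisation factors, baseline cost/SDQ/utilities) plus
current values of the other incomplete variables; type-1 matching draws
the regression parameters from their approximate posterior, predicts
missing rows with the draw and observed rows with the least-squares
fit, and imputes each missing value with the observed value of one of
its k = 5 nearest-prediction donors (uniform among the k). Imputed
values therefore always lie in the observed support (integer SDQ stays
integer). Categorical predictors are never imputed (always observed at
baseline in this design). Default 10 chain iterations; because
missingness is confined to outcomes and predictors are complete, the
chain is insensitive to iteration count and the Monte-Carlo tests use
3-5 iterations.

Pooling follows Rubin's rules: `q_bar = mean(q_i)`,
`T = w_bar + (1 + 1/m) B` with the small-sample degrees of freedom
`(m-1)(1 + w_bar / ((1+1/m)B))^2`. CEACs under imputation nest the
bootstrap within each completed dataset (B/m replicates each from one
master seed) and pool the replicate clouds before computing one curve,
preserving the joint cost-effect dependence while propagating
imputation uncertainty; a Rubin-pooled per-lambda NMB-regression
variant (OLS within datasets, pooled Wald statistic mapped through the
t CDF) is available behind `method="rubin_nmb"` for comparison -- the
two agree closely for these linear models.

## The synthetic-trial generator

Defaults encode the study conditions: n = 334 randomised 1:1 (167/167
by permuted blocks; minimisation itself is a trial-conduct detail and
is not re-implemented -- the published 166/168 split arises only if
configured explicitly) across 13 sites, four minimisation factors with
plausible prevalences (55/15/30% disorder mix, 35% autism, 55% under
11, 30% intellectual disability -- illustrative, as the joint baseline
distribution is not published).

Treatment effects are specified as *conditional* (covariate-adjusted)
differences and hold exactly in expectation by construction:

* **Costs.** Baseline service-use counts are Poisson with a
  gamma-frailty intensity (negative binomial marginally: non-negative,
  right-skewed), scaled per arm to means 1602 / 2076 GBP
  (intervention / control) -- a deliberate chance-imbalance so the
  adjustment machinery has work to do. Follow-up count intensities
  share a common multiplier linear in the *realised* baseline cost and
  arm: expected follow-up cost = F0 + 1.3228 x baseline + theta x arm,
  with theta = -796 GBP and F0 set so the control marginal mean is
  7845 GBP. The slope 1.3228 is exactly the value that reconciles the
  published observed (-1423 GBP) and adjusted (-796 GBP) cost
  differences given the baseline imbalance (-474 GBP); the generator's
  default cost geometry is therefore self-consistent with all four
  published cost figures simultaneously. A mean-one gamma frailty on
  follow-up intensity and a mean-one lognormal site multiplier add
  overdispersion and clustering without moving conditional means.
  Costed totals on the wide table equal pricing the long service-use
  table to < 0.01 GBP (tested). Optional per-category zero inflation
  preserves category means.
* **SDQ.** Baseline ~ N(19.7, 3.5) rounded and clipped to [0, 40]
  (entry thresholds are not enforced); follow-ups are an AR(1)-style
  pull (persistence 0.55) toward control means 19.6 / 18.8 at 6 / 12
  months plus arm effects (-2.0 / -2.021) and N(0, 4.5) noise, rounded
  and clipped. With these means the clip boundaries sit > 3 SD away,
  so rounding/clipping bias on the arm contrast is far below
  Monte-Carlo resolution.
* **Utilities.** Latent normal: per-timepoint means ~0.70-0.72 (both
  roles), a person-level random effect (SD 0.05), site effect
  (SD 0.02) and noise (SD 0.05), clipped to [0, 1]. The arm effect is a
  constant latent shift at 6 and 12 months of size (QALY effect)/0.75,
  which the 0.25/0.5/0.25 trapezoid weights turn into exactly the
  configured QALY difference (0.023 child, 0.070 caregiver, 0.093
  combined). The ceiling sits > 3 SD above the treated means, so
  clipping attenuation is ~1e-5 QALY -- negligible at every tolerance
  used. At extreme configured means this bias grows; that is a known
  limitation of the clipped-normal choice.
* **Sessions.** Intervention-arm session counts are 23 - Binomial(21,
  p) with p chosen so the mean is exactly 18.23: integer support
  {2..23} and a long left tail mimicking early drop-out. Control arm
  is identically zero. Intervention cost is sessions x 80.41 GBP.
* **Missingness.** MAR by default: masking probability is logistic in
  standardised baseline SDQ and log baseline cost (both coefficients
  0.5 -- sicker, costlier participants are more often lost), with the
  intercept solved numerically so the mean probability equals the
  configured rate. Default rates give ~84%/78% SDQ completeness at
  6/12 months and ~67% complete QALYs (per-timepoint utility masking at
  18%). MCAR is available for unbiasedness and coverage tests.
  Baseline is never masked. Whether real attrition is MAR is not
  knowable from the data; MAR is assumed for MI validity, never
  asserted.

Everything is deterministic given the config seed (byte-identical
files on re-run).

What the generator does *not* emulate: minimisation-induced covariate
balance beyond randomisation, informative (MNAR) drop-out,
within-participant correlation between cost and outcome trajectories
beyond what baseline cost induces, COVID-era service-use shocks, and
the true joint distribution of the minimisation factors. Passing tests
therefore certify the estimators and pipeline under a plausible
data-generating process, not the published point estimates themselves.

## Verification strategy and problem sizes

Published results cannot be recomputed without the participant-level
data, so verification is three-layered:

1. **Worked examples** on published summary figures (arm-mean cost
   difference of 43 GBP; 18.23 sessions x 80.41 GBP/session vs the
   published per-participant total; the adjusted differences including
   and excluding the intervention differing by the per-participant
   intervention cost).
2. **Calibrated recovery**: 500 simulated trials of n = 334; the
   Monte-Carlo mean of the adjusted estimates must sit within 3
   Monte-Carlo SEs of the configured truths for SDQ, CYP QALYs,
   combined QALYs, and cost including/excluding the intervention.
   `scripts/acceptance.py` reruns exactly this from a single seed.
3. **Property suites**: trapezoid-vs-numerical-integration agreement at
   1e-12, the constant-utility identity, the exact Rubin variance
   identity, PMM support membership, CEAC range/monotonicity,
   exact per-replicate monotonicity under intervention-cost scaling,
   identity-resample bootstrap recovery of point estimates, and exact
   sign-flip under arm relabelling.

Monte-Carlo problem sizes in the test suite (500 recovery trials; 200
replicates for the MI unbiasedness and coverage loops with 3 chain
iterations; 100 replicates for the adjustment-efficacy check under an
exaggerated 1000/3000 GBP baseline imbalance; 50/30/15 replicates at
n = 200/800/3200 for consistency) were chosen so each check resolves
its target effect with comfortable margin while the whole suite runs
in minutes.

## Known limitations

* The mixed model assumes Gaussian errors; cost residuals are skewed.
  This matches the published analytic choice (means of skewed costs,
  parametric inference) but GLM-gamma alternatives are out of scope.
* The generator's conditional-linearity construction makes adjusted
  estimates exactly unbiased by design; it cannot probe robustness to
  non-linear confounding.
* The illustrative unit costs and micro-costing line items are
  synthetic; all costing outputs on bundled defaults are demonstrations,
  not reproductions of published cost tables.
* CEAC probabilities from B = 500 carry ~0.02 Monte-Carlo noise;
  decision-grade runs should use the B = 5000 default.
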