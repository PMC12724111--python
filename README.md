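# trialcea

Within-trial cost-effectiveness analysis for a two-arm randomised trial
of a modular psychological intervention for children and young people
with epilepsy and common mental-health difficulties, evaluated against
assessment-enhanced usual care over a one-year horizon.

The package is aimed at health economists and trial statisticians. It
implements the full economic-evaluation pipeline as a tested library
with thin command-line and script drivers:

* **Costing** — unit costs applied to service-use records (exact to the
  penny), plus bottom-up micro-costing of the multi-session
  intervention (therapist time inflated for indirect activity,
  supervision, amortised training) and a substitution scaling scenario
  (75% of full intervention cost).
* **Outcomes** — SDQ endpoints and QALYs as the area under the utility
  curve, `q = 0.25·u₀ + 0.5·u₆ + 0.25·u₁₂`, for children (CHU9D-derived
  utilities), caregivers (EQ-5D-5L-derived) and both combined.
* **Estimation** — adjusted between-arm differences from mixed-effects
  linear regression: outcome ~ arm + baseline cost/SDQ/utility +
  minimisation factors, with a site random intercept and Wald 95% CIs.
* **Decision analysis** — ICERs with quadrant labels, net monetary
  benefit `λ·ΔE − ΔC`, a stratified non-parametric bootstrap of joint
  incremental (ΔC, ΔE) pairs refitting the adjusted models per
  resample, and cost-effectiveness acceptability curves over
  willingness-to-pay grids.
* **Missing data** — multiple imputation by chained equations with
  predictive mean matching (m = 31, k = 5 donors), Rubin's-rules
  pooling, and MI-aware CEACs (bootstrap nested within imputations).
* **Synthetic trial generator** — because participant-level trial data
  are not public, a calibrated generator reproduces the statistical
  structure of the study (n = 334, 1:1 across 13 sites, right-skewed
  costs with baseline imbalance, utility trajectories in [0, 1], 2–23
  intervention sessions with mean 18.23, MAR follow-up attrition) with
  configured *conditional* treatment effects that hold exactly in
  expectation. See `docs/methods.md` for the model and its limits.

## Worked example

```python
from trialcea import (default_config, generate_trial, apply_missingness,
                      add_qaly_columns, AdjustmentSpec, adjusted_difference,
                      Scenario, run_scenarios)

ds  = apply_missingness(generate_trial(default_config(seed=42)))
df  = add_qaly_columns(ds.participants)

est = adjusted_difference(df, AdjustmentSpec(
    outcome="sdq_12", baseline_covariates=["cost_baseline_3m", "sdq_0"]))
print(f"adjusted SDQ difference {est.estimate:.3f} "
      f"(95% CI {est.ci_low:.3f} to {est.ci_high:.3f}, n={est.n_used})")

table, curves = run_scenarios(
    df, [Scenario("sdq_12m"), Scenario("sdq_12m", intervention_scaling=0.75)],
    B=500, seed=42)
print(table[["scenario", "delta_cost", "delta_effect", "icer",
             "ceac_crossing_lambda"]].round(2).to_string())
```

prints (seed 42):

```
adjusted SDQ difference -2.683 (95% CI -3.828 to -1.538, n=277)
                       scenario  delta_cost  delta_effect    icer  ceac_crossing_lambda
0         sdq_12m_complete_case      842.54          2.68  314.03                 280.0
1  sdq_12m_complete_case_cost75      473.18          2.68  176.37                 143.0
```

Read: on this synthetic trial the intervention improves 12-month SDQ by
2.7 points at an extra £843, i.e. £314 per point of improvement; the
CEAC first exceeds 50% at a willingness-to-pay of £280 per point, and
costing the intervention at 75% (partial substitution for usual care)
moves that threshold down to £143. The same machinery reports CYP,
caregiver and combined QALY scenarios against the £20,000–£30,000 per
QALY band.

The numbered drivers under `analysis/` run the whole evaluation in
sequence (`01_simulate_trial.py` → `06_calibration_check.py`), writing
tables and CEAC curves to `results/`; an equivalent CLI is available as
`trialcea simulate|cost|outcomes|analyse|ceac|impute`.

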