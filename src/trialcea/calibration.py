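"""Monte-Carlo recovery of the generator's calibrated treatment effects.

Simulates many independent trials at the study conditions (n=334, 1:1,
13 sites), fits the adjusted mixed model for each headline outcome in
each trial, and averages the arm-coefficient estimates.  If generator
and estimator are both correct, each average matches the configured
conditional effect to within Monte-Carlo error:

* 12-month SDQ difference (calibrated to -2.021 points),
* CYP QALY difference (0.023), combined CYP+caregiver QALYs (0.093),
* total 12-month cost including the intervention, and the
  control-minus-intervention cost difference excluding it
  (calibrated so excluding-intervention difference is -796 GBP;
  including it, -796 + mean sessions x per-session cost).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from trialcea.config import GeneratorConfig, default_config
from trialcea.estimate import AdjustmentSpec, adjusted_difference
from trialcea.outcomes import add_qaly_columns
from trialcea.simulate import generate_trial

#: outcome -> (column, baseline covariates, report sign)
#: cost_excl is reported control-minus-intervention (positive = saving)
CALIBRATION_OUTCOMES = {
    "sdq_12m": ("sdq_12", ["cost_baseline_3m", "sdq_0"], 1.0),
    "qaly_cyp": ("qaly_cyp", ["cost_baseline_3m", "sdq_0", "utility_cyp_0"], 1.0),
    "qaly_combined": (
        "qaly_combined",
        ["cost_baseline_3m", "sdq_0", "utility_cyp_0", "utility_caregiver_0"],
        1.0,
    ),
    "cost_total_incl": ("cost_total", ["cost_baseline_3m", "sdq_0"], 1.0),
    "cost_excl_control_minus_int": ("cost_followup_excl", ["cost_baseline_3m", "sdq_0"], -1.0),
}


def calibrated_truths(config: GeneratorConfig) -> dict:
    """The true conditional effects implied by a generator config."""
    mean_intervention_cost = config.session_count_mean * config.intervention_cost_per_session
    return {
        "sdq_12m": config.effect_sdq_12m,
        "qaly_cyp": config.effect_qaly_cyp,
        "qaly_combined": config.effect_qaly_cyp + config.effect_qaly_caregiver,
        "cost_total_incl": config.effect_cost_excl_intervention + mean_intervention_cost,
        "cost_excl_control_minus_int": -config.effect_cost_excl_intervention,
    }


@dataclass
class CalibrationResult:
    estimates: pd.DataFrame  # one row per simulated trial
    truths: dict

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in CALIBRATION_OUTCOMES:
            est = self.estimates[name]
            mc_se = est.std(ddof=1) / np.sqrt(len(est))
            rows.append(
                {
                    "outcome": name,
                    "mean_estimate": est.mean(),
                    "mc_se": mc_se,
                    "truth": self.truths[name],
                    "abs_error": abs(est.mean() - self.truths[name]),
                    "within_3_mc_se": abs(est.mean() - self.truths[name]) <= 3 * mc_se,
                    "n_trials": len(est),
                }
            )
        return pd.DataFrame(rows)


def run_calibration_study(
    n_trials: int = 500,
    seed: int = 1,
    config: GeneratorConfig | None = None,
    estimator: str = "mixed_random_intercept",
) -> CalibrationResult:
    """Simulate ``n_trials`` fully observed trials and fit all outcomes."""
    base = config or default_config()
    trial_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_trials)
    rows = []
    for s in trial_seeds:
        ds = generate_trial(base.replace(seed=int(s)), include_service_use=False)
        df = add_qaly_columns(ds.participants, utility_floor=base.utility_floor)
        row = {}
        for name, (col, covs, sign) in CALIBRATION_OUTCOMES.items():
            spec = AdjustmentSpec(outcome=col, baseline_covariates=covs, estimator=estimator)
            row[name] = sign * adjusted_difference(df, spec).estimate
        rows.append(row)
    return CalibrationResult(estimates=pd.DataFrame(rows), truths=calibrated_truths(base))
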