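"""Synthetic-trial generator.

Generates participant-level datasets with the statistical structure the
downstream economic evaluation assumes, calibrated so that configured
*conditional* treatment effects hold exactly in expectation:

* 1:1 permuted-block allocation across sites (minimisation is a
  trial-conduct detail and is not re-implemented);
* minimisation factors (primary disorder, autism, age band,
  intellectual disability) as always-observed baseline categoricals;
* service-use quantities as integer counts: baseline counts are
  gamma-Poisson (negative binomial -- right-skewed, non-negative),
  follow-up count intensities are linear in the *realised* baseline cost
  and in arm, so the covariate-adjusted arm difference in costed totals
  equals the configured effect;
* SDQ scores integer in [0, 40] with an AR(1)-style dependence on
  baseline; utilities on a latent normal scale clipped to [0, 1]
  (clipping bias is negligible at the default means, > 3 SD from the
  ceiling);
* session counts for the intervention arm on {min..max} with the
  configured mean, via a reflected binomial;
* MAR or MCAR follow-up missingness with a logistic link on baseline
  SDQ and log baseline cost.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from trialcea.config import MISSINGNESS_KEYS, ConfigError, GeneratorConfig
from trialcea.costing import DEFAULT_UNIT_COSTS, UnitCostTable, default_unit_cost_table

#: share of total period cost attributed to each service category; the
#: generator converts shares to expected counts via the unit costs
CATEGORY_COST_SHARES = {
    "outpatient_epilepsy": 0.22,
    "outpatient_other": 0.12,
    "outpatient_mental_health": 0.02,
    "inpatient_epilepsy": 0.18,
    "inpatient_other": 0.12,
    "a_and_e": 0.04,
    "ambulance": 0.02,
    "gp": 0.04,
    "community_nurse": 0.06,
    "community_paediatrician": 0.03,
    "camhs": 0.03,
    "clinical_psychologist": 0.02,
    "speech_language_therapist": 0.02,
    "educational_psychologist": 0.02,
    "counselling": 0.01,
    "medication_epilepsy": 0.03,
    "medication_other": 0.01,
    "medication_mental_health": 0.01,
}

ARM_INTERVENTION = "intervention"
ARM_CONTROL = "control"

#: columns that can be masked at follow-up: (measure, timepoint) -> column
MASKABLE = {
    ("sdq", "m6"): "sdq_6",
    ("sdq", "m12"): "sdq_12",
    ("utility_cyp", "m6"): "utility_cyp_6",
    ("utility_cyp", "m12"): "utility_cyp_12",
    ("utility_caregiver", "m6"): "utility_caregiver_6",
    ("utility_caregiver", "m12"): "utility_caregiver_12",
    ("cost", "m0_6"): "cost_m0_6",
    ("cost", "m6_12"): "cost_m6_12",
}


@dataclass
class TrialDataset:
    """A generated trial: wide participant table + long service-use table."""

    participants: pd.DataFrame
    service_use: Optional[pd.DataFrame]
    config: GeneratorConfig

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.participants.to_csv(outdir / "participants.csv", index=False)
        if self.service_use is not None:
            self.service_use.to_csv(outdir / "service_use.csv", index=False)
        self.config.to_yaml(outdir / "config.yaml")

    @classmethod
    def read(cls, outdir) -> "TrialDataset":
        outdir = Path(outdir)
        participants = pd.read_csv(outdir / "participants.csv")
        su_path = outdir / "service_use.csv"
        service_use = pd.read_csv(su_path) if su_path.exists() else None
        config = GeneratorConfig.from_yaml(outdir / "config.yaml")
        return cls(participants=participants, service_use=service_use, config=config)


def _session_counts(rng, n, lo, hi, mean):
    # hi - Binomial(hi-lo, p) has support {lo..hi} and mean hi - (hi-lo)p;
    # the long left tail mimics early drop-out from a near-complete course
    span = hi - lo
    p = (hi - mean) / span
    return hi - rng.binomial(span, p, size=n)


def _draw_counts(rng, intensity, zero_inflation_pi=0.0):
    """Poisson counts; optional zero inflation preserving the mean."""
    if zero_inflation_pi > 0.0:
        keep = rng.random(intensity.shape) >= zero_inflation_pi
        lam = np.where(keep, intensity / (1.0 - zero_inflation_pi), 0.0)
    else:
        lam = intensity
    return rng.poisson(lam)


def generate_trial(
    config: GeneratorConfig,
    unit_costs: Optional[UnitCostTable] = None,
    include_service_use: bool = True,
) -> TrialDataset:
    """Generate a fully observed trial dataset.

    The wide cost columns are the priced sums of the generated
    service-use counts (identical, to < 0.01 GBP, to pricing the long
    table through :func:`trialcea.costing.cost_service_use`).
    """
    config.validate()
    if unit_costs is None:
        unit_costs = default_unit_cost_table()
    cats = list(CATEGORY_COST_SHARES)
    missing_cats = set(cats) - set(unit_costs.categories)
    if missing_cats:
        raise ConfigError(f"unit-cost table lacks generator categories: {sorted(missing_cats)}")
    shares = np.array([CATEGORY_COST_SHARES[c] for c in cats])
    units = np.array([unit_costs.unit_cost(c) for c in cats])

    n = config.n_participants
    rng = np.random.default_rng(config.seed)

    # --- allocation and baseline structure --------------------------------
    n_int, n_ctrl = config.allocation_ratio
    arm = np.array([1] * n_int + [0] * n_ctrl)
    rng.shuffle(arm)
    site = rng.integers(1, config.n_sites + 1, size=n)
    disorder = rng.choice(
        ["anxiety", "depression", "disruptive"], size=n, p=[0.55, 0.15, 0.30]
    )
    asd = rng.binomial(1, 0.35, size=n)
    age_group = np.where(rng.random(n) < 0.55, "<11", ">=11")
    intellectual_disability = rng.binomial(1, 0.30, size=n)

    # per-site offsets (clusters for the mixed models)
    site_sdq = rng.normal(0.0, config.site_sd_sdq, size=config.n_sites)[site - 1]
    site_util = rng.normal(0.0, config.site_sd_utility, size=config.n_sites)[site - 1]
    # multiplicative, mean-one site offset on cost intensities
    s = config.site_sd_cost
    sigma_ln = np.sqrt(np.log1p(s**2)) if s > 0 else 0.0
    site_cost_raw = rng.normal(0.0, 1.0, size=config.n_sites)
    site_cost = np.exp(sigma_ln * site_cost_raw - 0.5 * sigma_ln**2)[site - 1]

    # --- baseline (3-month recall) service use and cost -------------------
    b_mean = np.where(arm == 1, *config.baseline_cost_mean_by_arm)
    frailty = rng.gamma(config.cost_shape, 1.0 / config.cost_shape, size=n)
    base_intensity = (
        b_mean[:, None] * shares[None, :] / units[None, :]
    ) * (frailty * site_cost)[:, None]
    q_base = np.empty((n, len(cats)), dtype=np.int64)
    for j, c in enumerate(cats):
        q_base[:, j] = _draw_counts(rng, base_intensity[:, j], config.zero_inflation.get(c, 0.0))
    cost_baseline = q_base @ units

    # --- follow-up service use: intensity linear in realised baseline cost
    gamma = config.cost_baseline_slope
    theta = config.effect_cost_excl_intervention
    f0 = config.followup_cost_mean_control - gamma * config.baseline_cost_mean_by_arm[1]
    target = np.maximum(f0 + gamma * cost_baseline + theta * arm, 0.0)
    h = rng.gamma(
        config.followup_dispersion_shape, 1.0 / config.followup_dispersion_shape, size=n
    )
    q_fu = {}
    costs_fu = {}
    for period in ("m0_6", "m6_12"):
        intensity = (
            (target / 2.0)[:, None] * shares[None, :] / units[None, :]
        ) * (h * site_cost)[:, None]
        qp = np.empty((n, len(cats)), dtype=np.int64)
        for j, c in enumerate(cats):
            qp[:, j] = _draw_counts(rng, intensity[:, j], config.zero_inflation.get(c, 0.0))
        q_fu[period] = qp
        costs_fu[period] = qp @ units

    # --- SDQ (integer, 0-40) ----------------------------------------------
    sdq0_lat = rng.normal(config.sdq_mean_baseline, config.sdq_baseline_sd, size=n) + site_sdq
    sdq_0 = np.clip(np.rint(sdq0_lat), 0, 40).astype(np.int64)
    dev0 = sdq_0 - config.sdq_mean_baseline
    rho = config.sdq_persistence
    sdq6_lat = (
        config.sdq_mean_6m_control
        + rho * dev0
        + config.effect_sdq_6m * arm
        + site_sdq
        + rng.normal(0.0, config.sdq_noise_sd, size=n)
    )
    sdq12_lat = (
        config.sdq_mean_12m_control
        + rho * dev0
        + config.effect_sdq_12m * arm
        + site_sdq
        + rng.normal(0.0, config.sdq_noise_sd, size=n)
    )
    sdq_6 = np.clip(np.rint(sdq6_lat), 0, 40).astype(np.int64)
    sdq_12 = np.clip(np.rint(sdq12_lat), 0, 40).astype(np.int64)

    # --- utilities (latent normal, clipped) -------------------------------
    floor = config.utility_floor
    util = {}
    for role, qaly_effect in (
        ("cyp", config.effect_qaly_cyp),
        ("caregiver", config.effect_qaly_caregiver),
    ):
        mu = config.utility_means[role]
        # effect applied at both follow-ups; AUC weights 0.25/0.5/0.25
        # turn a per-timepoint shift d into a QALY shift of 0.75 d
        delta = qaly_effect / 0.75
        person = rng.normal(0.0, config.utility_person_sd, size=n)
        for t_idx, t_label in enumerate(("0", "6", "12")):
            shift = delta * arm if t_idx > 0 else 0.0
            lat = (
                mu[t_idx]
                + shift
                + person
                + site_util
                + rng.normal(0.0, config.utility_noise_sd, size=n)
            )
            util[f"utility_{role}_{t_label}"] = np.clip(lat, floor, 1.0)

    # --- intervention delivery --------------------------------------------
    lo, hi = config.session_count_range
    sessions = np.where(
        arm == 1, _session_counts(rng, n, lo, hi, config.session_count_mean), 0
    )
    cost_intervention = sessions * config.intervention_cost_per_session

    # --- assemble ----------------------------------------------------------
    pid = np.array([f"P{i:04d}" for i in range(1, n + 1)])
    participants = pd.DataFrame(
        {
            "participant_id": pid,
            "arm": np.where(arm == 1, ARM_INTERVENTION, ARM_CONTROL),
            "site_id": site,
            "disorder": disorder,
            "asd": asd,
            "age_group": age_group,
            "intellectual_disability": intellectual_disability,
            "sdq_0": sdq_0,
            "sdq_6": sdq_6.astype(float),
            "sdq_12": sdq_12.astype(float),
            "utility_cyp_0": util["utility_cyp_0"],
            "utility_cyp_6": util["utility_cyp_6"],
            "utility_cyp_12": util["utility_cyp_12"],
            "utility_caregiver_0": util["utility_caregiver_0"],
            "utility_caregiver_6": util["utility_caregiver_6"],
            "utility_caregiver_12": util["utility_caregiver_12"],
            "cost_baseline_3m": cost_baseline,
            "cost_m0_6": costs_fu["m0_6"],
            "cost_m6_12": costs_fu["m6_12"],
            "sessions_attended": sessions,
            "cost_intervention": cost_intervention,
        }
    )
    participants["cost_followup_excl"] = (
        participants["cost_m0_6"] + participants["cost_m6_12"]
    )
    participants["cost_total"] = (
        participants["cost_followup_excl"] + participants["cost_intervention"]
    )
    for (measure, tp), col in MASKABLE.items():
        participants[f"obs_{col}"] = True

    service_use = None
    if include_service_use:
        frames = []
        for period, q in (("baseline_3m", q_base), ("m0_6", q_fu["m0_6"]), ("m6_12", q_fu["m6_12"])):
            ii, jj = np.nonzero(q)
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": pid[ii],
                        "period": period,
                        "category": np.array(cats)[jj],
                        "quantity": q[ii, jj],
                    }
                )
            )
        service_use = (
            pd.concat(frames, ignore_index=True)
            .sort_values(["participant_id", "period", "category"], kind="stable")
            .reset_index(drop=True)
        )

    return TrialDataset(participants=participants, service_use=service_use, config=config)


# ---------------------------------------------------------------------------
# missingness


def _mar_probabilities(df: pd.DataFrame, rate: float) -> np.ndarray:
    """Logistic MAR link: miss probability rises with baseline SDQ and cost.

    p_i = expit(alpha + 0.5 z(sdq_0) + 0.5 z(log1p(cost_baseline_3m))),
    with alpha solved so the mean probability equals ``rate``.
    """
    z1 = df["sdq_0"].to_numpy(dtype=float)
    z1 = (z1 - z1.mean()) / (z1.std() or 1.0)
    z2 = np.log1p(df["cost_baseline_3m"].to_numpy(dtype=float))
    z2 = (z2 - z2.mean()) / (z2.std() or 1.0)
    lin = 0.5 * z1 + 0.5 * z2
    if rate <= 0.0:
        return np.zeros(len(df))
    if rate >= 1.0:
        return np.ones(len(df))
    alpha = brentq(lambda a: expit(a + lin).mean() - rate, -30.0, 30.0)
    return expit(alpha + lin)


def apply_missingness(dataset: TrialDataset, config: Optional[GeneratorConfig] = None) -> TrialDataset:
    """Mask follow-up measurements per the configured rates and mechanism.

    Baseline measurements are never masked.  Masked cells become NaN and
    their ``obs_*`` flag False; derived cost columns are recomputed so
    missingness propagates (a participant with either follow-up cost
    period missing has missing follow-up and total costs).  Deterministic
    given the config seed (independent stream from generation).
    """
    if config is None:
        config = dataset.config
    config.validate()
    df = dataset.participants.copy()
    rng = np.random.default_rng([config.seed, 977])

    for measure, tps in MISSINGNESS_KEYS.items():
        for tp in tps:
            rate = config.missingness_rates.get(measure, {}).get(tp, 0.0)
            col = MASKABLE[(measure, tp)]
            if config.missingness_mechanism == "MAR":
                p = _mar_probabilities(df, rate)
            else:
                p = np.full(len(df), rate)
            mask = rng.random(len(df)) < p
            df.loc[mask, col] = np.nan
            df[f"obs_{col}"] = ~mask & df[f"obs_{col}"]

    df["cost_followup_excl"] = df["cost_m0_6"] + df["cost_m6_12"]
    df["cost_total"] = df["cost_followup_excl"] + df["cost_intervention"]
    return TrialDataset(participants=df, service_use=dataset.service_use, config=config)
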