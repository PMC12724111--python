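"""Generator configuration for the synthetic trial.

The defaults encode the study conditions of a 334-participant, 1:1,
13-site trial of a modular psychological intervention for children with
epilepsy and common mental-health difficulties: right-skewed service
costs with a chance baseline imbalance between arms, SDQ total
difficulties scores (0-40, lower = better), child and caregiver utility
trajectories on [0, 1], 2-23 delivered sessions (mean 18.23), and
missing-at-random follow-up attrition.  Treatment effects are specified
as *conditional* (covariate-adjusted) arm differences, which is what the
estimation module targets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml


class ConfigError(ValueError):
    """A generator configuration violates one of its invariants."""


#: measures that can be masked at follow-up, with their timepoint keys
MISSINGNESS_KEYS = {
    "sdq": ("m6", "m12"),
    "utility_cyp": ("m6", "m12"),
    "utility_caregiver": ("m6", "m12"),
    "cost": ("m0_6", "m6_12"),
}


def _default_missingness() -> dict:
    # SDQ economic data ~84% / ~78% complete at 6 / 12 months; QALY
    # completeness ~65% arises from per-timepoint utility masking.
    return {
        "sdq": {"m6": 0.16, "m12": 0.22},
        "utility_cyp": {"m6": 0.18, "m12": 0.18},
        "utility_caregiver": {"m6": 0.18, "m12": 0.18},
        "cost": {"m0_6": 0.16, "m6_12": 0.22},
    }


def _default_utility_means() -> dict:
    # latent means per role at 0 / 6 / 12 months, kept >3 SD below the
    # ceiling so [0,1] clipping is negligible for calibration
    return {
        "cyp": (0.70, 0.71, 0.72),
        "caregiver": (0.70, 0.71, 0.71),
    }


@dataclass
class GeneratorConfig:
    """Full parameterisation of the synthetic-trial generator.

    Monetary fields are GBP; effects are intervention-minus-control
    conditional differences (negative SDQ effect = benefit).
    """

    n_participants: int = 334
    allocation_ratio: tuple = (167, 167)  # (intervention, control)
    n_sites: int = 13
    seed: int = 0

    # conditional treatment effects
    effect_sdq_12m: float = -2.021
    effect_sdq_6m: float = -2.0
    effect_qaly_cyp: float = 0.023
    effect_qaly_caregiver: float = 0.070  # combined = cyp + caregiver = 0.093
    effect_cost_excl_intervention: float = -796.0

    # cost model
    baseline_cost_mean_by_arm: tuple = (1602.0, 2076.0)  # (intervention, control)
    followup_cost_mean_control: float = 7845.0
    cost_baseline_slope: float = 1.3228  # GBP follow-up per GBP baseline
    cost_shape: float = 1.5  # gamma frailty shape for baseline skew
    followup_dispersion_shape: float = 5.0  # gamma frailty on follow-up intensity
    zero_inflation: dict = field(default_factory=dict)  # category -> extra P(zero)

    # outcomes
    utility_means: dict = field(default_factory=_default_utility_means)
    utility_person_sd: float = 0.05
    utility_noise_sd: float = 0.05
    utility_floor: float = 0.0  # set to -0.594 to admit worse-than-dead states
    sdq_mean_baseline: float = 19.7
    sdq_baseline_sd: float = 3.5
    sdq_mean_6m_control: float = 19.6
    sdq_mean_12m_control: float = 18.8
    sdq_persistence: float = 0.55
    sdq_noise_sd: float = 4.5

    # intervention delivery
    session_count_range: tuple = (2, 23)
    session_count_mean: float = 18.23
    intervention_cost_per_session: float = 80.41

    # clustering
    site_sd_sdq: float = 1.0
    site_sd_utility: float = 0.02
    site_sd_cost: float = 0.05  # SD of the multiplicative site offset on cost

    # missingness
    missingness_rates: dict = field(default_factory=_default_missingness)
    missingness_mechanism: str = "MAR"  # or "MCAR"

    def validate(self) -> "GeneratorConfig":
        if self.n_participants < 2:
            raise ConfigError("n_participants must be at least 2")
        if len(self.allocation_ratio) != 2 or any(
            int(a) != a or a < 1 for a in self.allocation_ratio
        ):
            raise ConfigError("allocation_ratio must be a pair of positive counts")
        if sum(self.allocation_ratio) != self.n_participants:
            raise ConfigError(
                "allocation_ratio must sum to n_participants "
                f"(got {sum(self.allocation_ratio)} != {self.n_participants})"
            )
        if self.n_sites < 1:
            raise ConfigError("n_sites must be positive")
        if self.cost_shape <= 0:
            raise ConfigError("cost_shape must be positive")
        if any(b < 0 for b in self.baseline_cost_mean_by_arm):
            raise ConfigError("baseline_cost_mean_by_arm entries must be >= 0")
        if self.followup_cost_mean_control <= 0:
            raise ConfigError("followup_cost_mean_control must be positive")
        for role, means in self.utility_means.items():
            if role not in ("cyp", "caregiver"):
                raise ConfigError(f"unknown utility role {role!r}")
            if any(not (0.0 <= u <= 1.0) for u in means):
                raise ConfigError(f"utility_means[{role!r}] must lie in [0, 1]")
        lo, hi = self.session_count_range
        if not (int(lo) == lo and int(hi) == hi and 0 <= lo < hi):
            raise ConfigError("session_count_range must be increasing integers")
        if not (lo <= self.session_count_mean <= hi):
            raise ConfigError("session_count_mean must lie within session_count_range")
        if self.missingness_mechanism not in ("MAR", "MCAR"):
            raise ConfigError("missingness_mechanism must be 'MAR' or 'MCAR'")
        for measure, keys in self.missingness_rates.items():
            if measure not in MISSINGNESS_KEYS:
                raise ConfigError(f"unknown missingness measure {measure!r}")
            for tp, rate in keys.items():
                if tp not in MISSINGNESS_KEYS[measure]:
                    raise ConfigError(f"unknown timepoint {tp!r} for measure {measure!r}")
                if not (0.0 <= rate <= 1.0):
                    raise ConfigError(
                        f"missingness_rates[{measure!r}][{tp!r}] must be in [0, 1]"
                    )
        for cat, pi in self.zero_inflation.items():
            if not (0.0 <= pi < 1.0):
                raise ConfigError(f"zero_inflation[{cat!r}] must be in [0, 1)")
        if not (0.0 <= self.utility_person_sd and 0.0 <= self.utility_noise_sd):
            raise ConfigError("utility SDs must be non-negative")
        return self

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["allocation_ratio"] = list(self.allocation_ratio)
        d["baseline_cost_mean_by_arm"] = list(self.baseline_cost_mean_by_arm)
        d["session_count_range"] = list(self.session_count_range)
        d["utility_means"] = {k: list(v) for k, v in self.utility_means.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key in ("allocation_ratio", "baseline_cost_mean_by_arm", "session_count_range"):
            if key in d:
                d[key] = tuple(d[key])
        if "utility_means" in d:
            d["utility_means"] = {k: tuple(v) for k, v in d["utility_means"].items()}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration fields: {sorted(unknown)}")
        return cls(**d).validate()

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs).validate()


def default_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """The trial-calibrated study conditions (n=334, 1:1, 13 sites)."""
    return GeneratorConfig(seed=seed).replace(**overrides) if overrides else GeneratorConfig(
        seed=seed
    ).validate()
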