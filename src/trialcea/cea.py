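"""Incremental cost-effectiveness: ICERs, net benefit, bootstrap, CEACs.

Decision uncertainty is propagated by non-parametric bootstrap: resample
participants with replacement within arm, refit the adjusted cost and
effect models on each resample, and keep the joint (delta-cost,
delta-effect) pair.  A cost-effectiveness acceptability curve (CEAC)
evaluates, for each willingness-to-pay lambda on a grid, the fraction of
replicates with positive incremental net monetary benefit
lambda * dE - dC (ties at exactly zero count one half).

The cost replicates are stored decomposed into an
excluding-intervention component and an intervention component, so
intervention-cost scaling scenarios (e.g. 75% substitution costing)
reuse the *same* replicates with only the intervention share rescaled --
scaling down can then never lower a CEAC probability, replicate by
replicate, and scenarios stay seed-comparable.

Effect direction: for SDQ the effect enters as the *reduction* in score
(control-minus-intervention adjusted difference), so larger = better
and the CEAC reads per unit improvement; QALYs enter as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from trialcea.estimate import (
    AdjustmentSpec,
    SingularDesignError,
    adjusted_difference,
)

NICE_QALY_BAND = (20_000.0, 30_000.0)


@dataclass
class WTPGrid:
    """Increasing grid of willingness-to-pay values (GBP per effect unit)."""

    values: np.ndarray
    effect_label: str = "QALY"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("willingness-to-pay grid is empty")
        if (self.values < 0).any() or not np.all(np.diff(self.values) > 0):
            raise ValueError("grid must be non-negative and strictly increasing")


def sdq_wtp_grid(step: float = 1.0, top: float = 1000.0) -> WTPGrid:
    return WTPGrid(np.arange(0.0, top + step / 2, step), "SDQ point improvement")


def qaly_wtp_grid(step: float = 500.0, top: float = 50_000.0) -> WTPGrid:
    return WTPGrid(np.arange(0.0, top + step / 2, step), "QALY")


def icer(delta_cost: float, delta_effect: float) -> dict:
    """Incremental cost-effectiveness ratio with plane-quadrant label.

    Quadrants (x = dE, y = dC): NE trade-off (dearer, better), SE
    dominant (cheaper-or-equal, better), NW dominated (dearer, worse),
    SW trade-off (cheaper, worse).  dE = 0 yields an undefined-ratio
    marker carrying the sign of dC.
    """
    if delta_effect == 0:
        return {
            "ratio": float("nan"),
            "quadrant": "undefined",
            "delta_cost_sign": int(np.sign(delta_cost)),
        }
    if delta_effect > 0:
        quadrant = "trade-off NE" if delta_cost > 0 else "dominant SE"
    else:
        quadrant = "dominated NW" if delta_cost > 0 else "trade-off SW"
    return {"ratio": delta_cost / delta_effect, "quadrant": quadrant, "delta_cost_sign": int(np.sign(delta_cost))}


def net_monetary_benefit(effect, cost, wtp: float):
    """NMB = lambda x effect - cost (vectorised; per participant or incremental)."""
    return wtp * np.asarray(effect, dtype=float) - np.asarray(cost, dtype=float)


@dataclass
class IncrementalDistribution:
    """B joint bootstrap replicates of incremental cost and effect.

    ``delta_cost_excl`` and ``delta_intervention`` decompose the cost
    difference; ``delta_cost`` applies the current
    ``intervention_scaling``.
    """

    delta_cost_excl: np.ndarray
    delta_intervention: np.ndarray
    delta_effect: np.ndarray
    effect_label: str
    seed: Optional[int] = None
    intervention_scaling: float = 1.0
    point: dict = field(default_factory=dict)  # point estimates at scaling 1.0
    n_redraws: int = 0

    def __post_init__(self):
        for a in (self.delta_cost_excl, self.delta_intervention, self.delta_effect):
            if len(a) < 1:
                raise ValueError("need at least one bootstrap replicate")
        if not (len(self.delta_cost_excl) == len(self.delta_intervention) == len(self.delta_effect)):
            raise ValueError("replicate arrays must share length")

    @property
    def B(self) -> int:
        return len(self.delta_effect)

    @property
    def delta_cost(self) -> np.ndarray:
        return self.delta_cost_excl + self.intervention_scaling * self.delta_intervention

    def scaled(self, factor: float) -> "IncrementalDistribution":
        if not (0.0 < factor <= 1.0):
            raise ValueError("intervention scaling factor must lie in (0, 1]")
        return replace(self, intervention_scaling=factor)

    @staticmethod
    def pool(dists: list) -> "IncrementalDistribution":
        first = dists[0]
        return IncrementalDistribution(
            delta_cost_excl=np.concatenate([d.delta_cost_excl for d in dists]),
            delta_intervention=np.concatenate([d.delta_intervention for d in dists]),
            delta_effect=np.concatenate([d.delta_effect for d in dists]),
            effect_label=first.effect_label,
            seed=first.seed,
            intervention_scaling=first.intervention_scaling,
            point=first.point,
            n_redraws=sum(d.n_redraws for d in dists),
        )


def _stratified_indices(rng, arm_idx: dict) -> np.ndarray:
    parts = [rng.choice(idx, size=len(idx), replace=True) for idx in arm_idx.values()]
    return np.concatenate(parts)


def bootstrap_incrementals(
    dataset: pd.DataFrame,
    cost_spec: AdjustmentSpec,
    effect_spec: AdjustmentSpec,
    B: int,
    seed: int,
    effect_sign: float = 1.0,
    effect_label: str = "QALY",
    intervention_spec: Optional[AdjustmentSpec] = None,
    resampler=None,
) -> IncrementalDistribution:
    """Joint bootstrap of adjusted incremental cost and effect.

    Participants are resampled with replacement stratified by arm; the
    adjusted cost model (excluding intervention), the adjusted
    intervention-cost model and the adjusted effect model are refit on
    each resample and the triple stored.  Replicates whose refits hit a
    singular design are redrawn (counted); more than 10% redraws raises.
    ``resampler(rng, arm_idx) -> row positions`` may replace the default
    stratified scheme (e.g. the identity for testing).
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    if intervention_spec is None:
        intervention_spec = replace(cost_spec, outcome="cost_intervention")
    rng = np.random.default_rng(seed)
    df = dataset.reset_index(drop=True)
    arm_idx = {a: g.index.to_numpy() for a, g in df.groupby("arm")}
    if resampler is None:
        resampler = _stratified_indices

    point = {
        "delta_cost_excl": adjusted_difference(df, cost_spec).estimate,
        "delta_intervention": adjusted_difference(df, intervention_spec).estimate,
        "delta_effect": effect_sign * adjusted_difference(df, effect_spec).estimate,
    }

    dc, di, de = np.empty(B), np.empty(B), np.empty(B)
    redraws = 0
    b = 0
    while b < B:
        sample = df.iloc[resampler(rng, arm_idx)]
        try:
            dc[b] = adjusted_difference(sample, cost_spec).estimate
            di[b] = adjusted_difference(sample, intervention_spec).estimate
            de[b] = effect_sign * adjusted_difference(sample, effect_spec).estimate
        except (SingularDesignError, ValueError):
            redraws += 1
            if redraws > max(1, 0.1 * B):
                raise RuntimeError(
                    f"more than 10% of bootstrap resamples were degenerate ({redraws} redraws)"
                )
            continue
        b += 1

    return IncrementalDistribution(
        delta_cost_excl=dc,
        delta_intervention=di,
        delta_effect=de,
        effect_label=effect_label,
        seed=seed,
        point=point,
        n_redraws=redraws,
    )


@dataclass
class CEACCurve:
    grid: WTPGrid
    probability: np.ndarray
    crossing_lambda: Optional[float]  # first grid value with P >= 0.5
    scenario: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lambda": self.grid.values,
                "probability": self.probability,
                "scenario": self.scenario,
            }
        )


def ceac(dist: IncrementalDistribution, grid: WTPGrid, scenario: str = "") -> CEACCurve:
    """Probability cost-effective at each willingness-to-pay value.

    P(lambda) = fraction of replicates with lambda*dE - dC > 0, ties at
    exactly zero counted as half (measure-zero in practice, fixed for
    determinism on toy data).
    """
    dc = dist.delta_cost
    de = dist.delta_effect
    nmb = grid.values[:, None] * de[None, :] - dc[None, :]
    prob = (nmb > 0).mean(axis=1) + 0.5 * (nmb == 0).mean(axis=1)
    above = np.nonzero(prob >= 0.5)[0]
    crossing = float(grid.values[above[0]]) if above.size else None
    return CEACCurve(grid=grid, probability=prob, crossing_lambda=crossing, scenario=scenario)


# ---------------------------------------------------------------------------
# scenarios

#: outcome token -> (outcome column, baseline covariates, sign, label, grid)
SCENARIO_OUTCOMES = {
    "sdq_12m": ("sdq_12", ["cost_baseline_3m", "sdq_0"], -1.0, "SDQ point improvement"),
    "sdq_6m": ("sdq_6", ["cost_baseline_3m", "sdq_0"], -1.0, "SDQ point improvement"),
    "qaly_cyp": ("qaly_cyp", ["cost_baseline_3m", "sdq_0", "utility_cyp_0"], 1.0, "QALY"),
    "qaly_caregiver": (
        "qaly_caregiver",
        ["cost_baseline_3m", "sdq_0", "utility_caregiver_0"],
        1.0,
        "QALY",
    ),
    "qaly_combined": (
        "qaly_combined",
        ["cost_baseline_3m", "sdq_0", "utility_cyp_0", "utility_caregiver_0"],
        1.0,
        "QALY",
    ),
}

COST_BASELINE_COVARIATES = ["cost_baseline_3m", "sdq_0"]


@dataclass
class Scenario:
    """One analysis cell: outcome x missing-data handling x costing."""

    outcome: str  # token in SCENARIO_OUTCOMES
    missing_data: str = "complete_case"  # or "imputed"
    intervention_scaling: float = 1.0

    def __post_init__(self):
        if self.outcome not in SCENARIO_OUTCOMES:
            raise ValueError(
                f"unknown scenario outcome {self.outcome!r}; "
                f"choose from {sorted(SCENARIO_OUTCOMES)}"
            )
        if self.missing_data not in ("complete_case", "imputed"):
            raise ValueError(f"unknown missing-data handling {self.missing_data!r}")
        if not (0.0 < self.intervention_scaling <= 1.0):
            raise ValueError("intervention_scaling must lie in (0, 1]")

    @property
    def tag(self) -> str:
        pieces = [self.outcome, self.missing_data]
        if self.intervention_scaling != 1.0:
            pieces.append(f"cost{int(round(self.intervention_scaling * 100))}")
        return "_".join(pieces)


def specs_for_outcome(outcome: str, estimator: str = "mixed_random_intercept"):
    """(cost_spec, effect_spec, effect_sign, effect_label) for a scenario outcome."""
    col, covs, sign, label = SCENARIO_OUTCOMES[outcome]
    cost_spec = AdjustmentSpec(
        outcome="cost_followup_excl",
        baseline_covariates=list(COST_BASELINE_COVARIATES),
        estimator=estimator,
    )
    effect_spec = AdjustmentSpec(outcome=col, baseline_covariates=list(covs), estimator=estimator)
    return cost_spec, effect_spec, sign, label


def default_grid_for(outcome: str) -> WTPGrid:
    return sdq_wtp_grid() if outcome.startswith("sdq") else qaly_wtp_grid()


def run_scenarios(
    dataset: pd.DataFrame,
    scenarios: list,
    B: int = 5000,
    seed: int = 0,
    estimator: str = "mixed_random_intercept",
    grids: Optional[dict] = None,
    imputation_config=None,
) -> tuple:
    """Estimates + CEAC per scenario, sharing seeds and bootstrap draws.

    Scenarios differing only in intervention scaling share the same
    bootstrap replicates (only the intervention cost share is rescaled);
    all scenarios derive their randomness from the single ``seed``.
    Returns ``(table, curves)``: a tidy DataFrame of adjusted estimates,
    ICERs and CEAC summaries, and a dict scenario-tag -> CEACCurve.
    """
    from trialcea import impute as impute_mod  # local import; impute depends on cea

    rows = []
    curves = {}
    dist_cache: dict = {}
    imputed_cache: dict = {}

    for sc in scenarios:
        grid = (grids or {}).get(sc.outcome, default_grid_for(sc.outcome))
        cost_spec, effect_spec, sign, label = specs_for_outcome(sc.outcome, estimator)
        cache_key = (sc.outcome, sc.missing_data)
        if cache_key not in dist_cache:
            if sc.missing_data == "complete_case":
                dist_cache[cache_key] = bootstrap_incrementals(
                    dataset, cost_spec, effect_spec, B=B, seed=seed,
                    effect_sign=sign, effect_label=label,
                )
            else:
                if "imputed" not in imputed_cache:
                    cfg = imputation_config or impute_mod.ImputationConfig(seed=seed)
                    imputed_cache["imputed"] = impute_mod.mice_impute(dataset, cfg)
                dist_cache[cache_key] = impute_mod.bootstrap_incrementals_mi(
                    imputed_cache["imputed"], cost_spec, effect_spec,
                    B=B, seed=seed, effect_sign=sign, effect_label=label,
                )
        dist = dist_cache[cache_key].scaled(sc.intervention_scaling)
        curve = ceac(dist, grid, scenario=sc.tag)
        curves[sc.tag] = curve

        point_dc = dist.point["delta_cost_excl"] + sc.intervention_scaling * dist.point["delta_intervention"]
        point_de = dist.point["delta_effect"]
        ic = icer(point_dc, point_de)
        band = (
            (NICE_QALY_BAND if not sc.outcome.startswith("sdq") else (0.0, grid.values[-1]))
        )
        in_band = (grid.values >= band[0]) & (grid.values <= band[1])
        rows.append(
            {
                "scenario": sc.tag,
                "outcome": sc.outcome,
                "missing_data": sc.missing_data,
                "intervention_scaling": sc.intervention_scaling,
                "delta_cost": point_dc,
                "delta_effect": point_de,
                "icer": ic["ratio"],
                "quadrant": ic["quadrant"],
                "ceac_crossing_lambda": curve.crossing_lambda,
                "prob_ce_band_low": float(curve.probability[in_band][0]),
                "prob_ce_band_high": float(curve.probability[in_band][-1]),
                "B": dist.B,
                "seed": seed,
            }
        )

    return pd.DataFrame(rows), curves
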