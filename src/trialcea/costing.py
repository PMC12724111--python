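"""Costing: unit-cost application to service use and intervention micro-costing.

Service-use records (contacts, nights, prescription-months) are priced
against a user-supplied unit-cost table.  The multi-session intervention
is micro-costed bottom-up from therapist time (inflated for indirect,
non-face-to-face activity), supervision and amortised training, with a
substitution scaling factor for the scenario in which the intervention
partly replaces rather than adds to standard care.

Money is handled as exact integer pence throughout record-level costing
(unit costs are validated to whole pence), so category costs and totals
are exact at the 0.01 GBP resolution; rounding to pence, where a
fractional intermediate arises in the micro-costing model, is half-even.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

PERIODS = ("baseline_3m", "m0_6", "m6_12")


class UnknownCategoryError(KeyError):
    """A service-use record references a category absent from the table."""


def _to_pence(x: float, what: str) -> int:
    p = round(float(x) * 100)
    if abs(p - float(x) * 100) > 1e-6:
        raise ValueError(f"{what} must be a whole number of pence, got {x!r}")
    if p < 0:
        raise ValueError(f"{what} must be non-negative, got {x!r}")
    return int(p)


@dataclass
class UnitCostTable:
    """Map service category -> (unit cost in GBP, unit kind).

    ``entries`` maps category token to ``(unit_cost, unit)`` with
    ``unit`` one of contact / night / item.  ``currency_year`` labels
    the price year of the costs (e.g. "2020/21").
    """

    entries: dict
    currency_year: str = "2020/21"

    def __post_init__(self):
        self._pence = {}
        for cat, (cost, unit) in self.entries.items():
            if unit not in ("contact", "night", "item"):
                raise ValueError(f"unknown unit {unit!r} for category {cat!r}")
            self._pence[cat] = _to_pence(cost, f"unit cost for {cat!r}")

    def unit_cost(self, category: str) -> float:
        if category not in self._pence:
            raise UnknownCategoryError(category)
        return self._pence[category] / 100.0

    def unit_cost_pence(self, category: str) -> int:
        if category not in self._pence:
            raise UnknownCategoryError(category)
        return self._pence[category]

    @property
    def categories(self):
        return list(self.entries)

    def to_csv(self, path) -> None:
        rows = [
            {"category": c, "unit": u, "unit_cost": cost, "year": self.currency_year}
            for c, (cost, u) in self.entries.items()
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "UnitCostTable":
        df = pd.read_csv(path)
        if df["category"].duplicated().any():
            dupes = df.loc[df["category"].duplicated(), "category"].tolist()
            raise ValueError(f"duplicate categories in unit-cost table: {dupes}")
        year = str(df["year"].iloc[0]) if "year" in df else "unknown"
        entries = {
            r.category: (float(r.unit_cost), r.unit) for r in df.itertuples(index=False)
        }
        return cls(entries=entries, currency_year=year)


#: Illustrative NHS-style unit costs (GBP per contact/night/item).  These
#: stand in for nationally applicable published unit costs, which are a
#: user input; the values here are synthetic but of realistic magnitude
#: for the 2020/21 price year.
DEFAULT_UNIT_COSTS = {
    "outpatient_epilepsy": (223.0, "contact"),
    "outpatient_other": (186.0, "contact"),
    "outpatient_mental_health": (229.0, "contact"),
    "inpatient_epilepsy": (676.0, "night"),
    "inpatient_other": (645.0, "night"),
    "a_and_e": (180.0, "contact"),
    "ambulance": (292.0, "contact"),
    "gp": (39.0, "contact"),
    "community_nurse": (42.0, "contact"),
    "community_paediatrician": (108.0, "contact"),
    "camhs": (235.0, "contact"),
    "clinical_psychologist": (108.0, "contact"),
    "speech_language_therapist": (98.0, "contact"),
    "educational_psychologist": (105.0, "contact"),
    "counselling": (55.0, "contact"),
    "medication_epilepsy": (30.0, "item"),
    "medication_other": (12.0, "item"),
    "medication_mental_health": (25.0, "item"),
}


def default_unit_cost_table() -> UnitCostTable:
    return UnitCostTable(entries=dict(DEFAULT_UNIT_COSTS), currency_year="2020/21")


# ---------------------------------------------------------------------------
# service-use costing


@dataclass
class CostSummary:
    """Per participant-period costs, decomposed by category.

    ``cost_total = cost_excl_intervention + scaling_factor * cost_intervention``
    holds exactly at pence resolution by construction.
    """

    participant_id: str
    period: str
    cost_by_category: dict = field(default_factory=dict)  # category -> GBP
    cost_intervention: float = 0.0
    scaling_factor: float = 1.0

    @property
    def cost_excl_intervention(self) -> float:
        return round(sum(self.cost_by_category.values()), 2)

    @property
    def cost_total(self) -> float:
        return round(
            self.cost_excl_intervention
            + round(self.scaling_factor * self.cost_intervention, 2),
            2,
        )


def cost_service_use(
    records: pd.DataFrame,
    table: UnitCostTable,
    participant_ids=None,
    periods=PERIODS,
) -> pd.DataFrame:
    """Price a long service-use table; one output row per participant-period.

    ``records`` needs columns participant_id, period, category, quantity.
    Participants listed in ``participant_ids`` but absent from
    ``records`` receive explicit zero-cost rows rather than going
    missing.  Unknown categories raise, naming the category and the
    participants carrying it.
    """
    req = {"participant_id", "period", "category", "quantity"}
    if not req.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(req)}")
    if (records["quantity"] < 0).any():
        bad = records.loc[records["quantity"] < 0, "participant_id"].tolist()
        raise ValueError(f"negative quantities for participants {bad}")

    unknown = set(records["category"]) - set(table.categories)
    if unknown:
        offenders = (
            records[records["category"].isin(unknown)]
            .groupby("category")["participant_id"]
            .apply(lambda s: sorted(set(s))[:5])
            .to_dict()
        )
        raise UnknownCategoryError(
            f"categories not in unit-cost table: {offenders}"
        )

    if participant_ids is None:
        participant_ids = sorted(set(records["participant_id"]))

    pence = records["quantity"].to_numpy(dtype=np.int64) * np.array(
        [table.unit_cost_pence(c) for c in records["category"]], dtype=np.int64
    )
    priced = records[["participant_id", "period", "category"]].copy()
    priced["pence"] = pence
    wide = (
        priced.pivot_table(
            index=["participant_id", "period"],
            columns="category",
            values="pence",
            aggfunc="sum",
            fill_value=0,
        )
        .reindex(columns=table.categories, fill_value=0)
    )
    full_index = pd.MultiIndex.from_product(
        [participant_ids, list(periods)], names=["participant_id", "period"]
    )
    wide = wide.reindex(full_index, fill_value=0).astype(np.int64)
    out = wide / 100.0
    out["cost_excl_intervention"] = wide.sum(axis=1) / 100.0
    return out.reset_index()


# ---------------------------------------------------------------------------
# intervention micro-costing


@dataclass
class InterventionCostModel:
    """Bottom-up cost model for a multi-session therapist-delivered intervention.

    Delivery staff time is costed per face-to-face hour and inflated by
    ``indirect_to_face_ratio`` (indirect hours -- preparation,
    administration, supervision attendance -- per face-to-face hour).
    Supervision and training are overheads per participant, spread over
    ``sessions_per_participant`` sessions; training is amortised equally
    over ``training_amortisation_n`` participants.  ``scaling_factor``
    scales the per-participant intervention total (1.0 = fully
    additional to usual care, 0.75 = partial substitution scenario).
    """

    therapist_cost_per_hour: float
    face_to_face_hours_per_session: float
    indirect_to_face_ratio: float = 0.0
    supervisor_cost_per_hour: float = 0.0
    supervision_hours_per_participant: float = 0.0
    training_cost_total: float = 0.0
    training_amortisation_n: int = 1
    sessions_per_participant: float = 1.0
    scaling_factor: float = 1.0

    def __post_init__(self):
        for name in (
            "therapist_cost_per_hour",
            "indirect_to_face_ratio",
            "supervisor_cost_per_hour",
            "supervision_hours_per_participant",
            "training_cost_total",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.face_to_face_hours_per_session <= 0:
            raise ValueError("face_to_face_hours_per_session must be positive")
        if self.training_amortisation_n < 1:
            raise ValueError("training_amortisation_n must be a positive count")
        if self.sessions_per_participant <= 0:
            raise ValueError("sessions_per_participant must be positive")
        if not (0.0 < self.scaling_factor <= 1.0):
            raise ValueError("scaling_factor must lie in (0, 1]")


@dataclass
class SessionCost:
    """Per-session intervention cost with auditable components (GBP)."""

    delivery: float
    supervision: float
    training: float

    @property
    def total(self) -> float:
        return self.delivery + self.supervision + self.training


def cost_intervention_session(model: InterventionCostModel) -> SessionCost:
    """Cost of one delivered session, decomposed into components."""
    delivery = (
        model.therapist_cost_per_hour
        * model.face_to_face_hours_per_session
        * (1.0 + model.indirect_to_face_ratio)
    )
    supervision = (
        model.supervision_hours_per_participant
        * model.supervisor_cost_per_hour
        / model.sessions_per_participant
    )
    training = model.training_cost_total / (
        model.training_amortisation_n * model.sessions_per_participant
    )
    return SessionCost(delivery=delivery, supervision=supervision, training=training)


def cost_intervention_total(sessions_attended: float, model: InterventionCostModel) -> float:
    """Per-participant intervention cost: sessions x session cost x scaling."""
    if sessions_attended < 0:
        raise ValueError("sessions_attended must be non-negative")
    return sessions_attended * cost_intervention_session(model).total * model.scaling_factor


def scale_intervention(summary: CostSummary, factor: float) -> CostSummary:
    """Apply a substitution scaling factor to the intervention component only."""
    if not (0.0 < factor <= 1.0):
        raise ValueError("scaling factor must lie in (0, 1]")
    return replace(summary, scaling_factor=factor)


def example_intervention_model() -> InterventionCostModel:
    """Synthetic illustrative micro-costing configuration.

    The line items (Band-5 delivery time inflated for indirect activity,
    Band-7/8a supervision, amortised training) are invented but chosen
    so the per-session total lands at ~80.41 GBP and, over a mean of
    18.23 sessions, ~1466 GBP per participant -- the scale reported for
    comparable modular interventions.  The real inputs to such a costing
    are trial records and published staff costs; this fixture only
    demonstrates the model's structure.
    """
    return InterventionCostModel(
        therapist_cost_per_hour=37.0,
        face_to_face_hours_per_session=0.7,
        indirect_to_face_ratio=1.0,
        supervisor_cost_per_hour=54.0,
        supervision_hours_per_participant=5.0,
        training_cost_total=41759.0,
        training_amortisation_n=166,
        sessions_per_participant=18.23,
    )
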