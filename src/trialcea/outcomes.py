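"""SDQ endpoints and QALYs from utility trajectories.

QALYs over the one-year trial horizon are the area under the utility
curve defined by measurements at 0, 6 and 12 months, assuming linear
change between timepoints (trapezoid rule).  A QALY is complete only
when all three constituent utilities are observed; otherwise it is
missing (complete-case rule -- imputation handles the rest).  Combined
child+caregiver QALYs are the arithmetic sum of the two individual
QALYs, the standard total-QALY-gain convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: measurement times in years and the implied trapezoid weights
QALY_TIMES = (0.0, 0.5, 1.0)


def _trapezoid_weights(times=QALY_TIMES) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if not np.all(np.diff(t) > 0):
        raise ValueError("measurement times must be strictly increasing")
    w = np.zeros_like(t)
    w[:-1] += np.diff(t) / 2.0
    w[1:] += np.diff(t) / 2.0
    return w


@dataclass
class QALYResult:
    participant_id: str
    role: str
    qaly: float  # NaN when incomplete
    complete: bool


def qaly_auc(
    utilities,
    times=QALY_TIMES,
    participant_id: str = "",
    role: str = "",
    utility_floor: float = 0.0,
) -> QALYResult:
    """Area-under-the-curve QALY for one utility trajectory.

    With the default times (0, 0.5, 1.0 years) this is
    0.5*(u0+u6)/2 + 0.5*(u6+u12)/2.  Any missing utility makes the QALY
    missing.  Utilities outside [utility_floor, 1] raise; the floor may
    be lowered below zero to admit worse-than-dead valuations.
    """
    u = np.asarray(utilities, dtype=float)
    w = _trapezoid_weights(times)
    if u.shape != w.shape:
        raise ValueError(f"expected {len(w)} utilities, got {u.shape}")
    if np.isnan(u).any():
        return QALYResult(participant_id, role, float("nan"), complete=False)
    if ((u < utility_floor) | (u > 1.0)).any():
        raise ValueError(f"utilities outside [{utility_floor}, 1]: {u}")
    return QALYResult(participant_id, role, float(w @ u), complete=True)


def combine_qalys(cyp: QALYResult, caregiver: QALYResult) -> float:
    """Total QALY gain across child and caregiver; missing propagates."""
    if cyp.role and caregiver.role and cyp.role == caregiver.role:
        raise ValueError("combine_qalys expects one CYP and one caregiver result")
    if not (cyp.complete and caregiver.complete):
        return float("nan")
    return cyp.qaly + caregiver.qaly


def sdq_endpoint(series, timepoint: int):
    """The recorded SDQ total at 6 or 12 months; no interpolation.

    ``series`` maps timepoint (months) to score, e.g. {0: 19, 6: 18, 12: 16}
    or a 3-sequence ordered (0, 6, 12).
    """
    if timepoint not in (6, 12):
        raise ValueError(f"SDQ endpoint must be 6 or 12 months, got {timepoint}")
    if not isinstance(series, dict):
        series = dict(zip((0, 6, 12), series))
    value = series.get(timepoint, float("nan"))
    return float("nan") if pd.isna(value) else value


def add_qaly_columns(participants: pd.DataFrame, utility_floor: float = 0.0) -> pd.DataFrame:
    """Vectorised QALY construction on the wide participant table.

    Adds qaly_cyp, qaly_caregiver and qaly_combined; any missing
    constituent utility yields a missing QALY for that role, and a
    missing combined QALY if either role is incomplete.
    """
    df = participants.copy()
    w = _trapezoid_weights()
    for role in ("cyp", "caregiver"):
        cols = [f"utility_{role}_{t}" for t in ("0", "6", "12")]
        u = df[cols].to_numpy(dtype=float)
        observed = ~np.isnan(u)
        if ((u < utility_floor) | (u > 1.0))[observed].any():
            raise ValueError(f"{role} utilities outside [{utility_floor}, 1]")
        df[f"qaly_{role}"] = u @ w
    df["qaly_combined"] = df["qaly_cyp"] + df["qaly_caregiver"]
    return df
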