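"""Ventilator mechanics: mechanical power, P/F ratio, MP aggregates, VFD28.

Mechanical power (MP) is the energy the ventilator delivers to the
respiratory system per minute, here computed with the simplified
pressure-volume formula

    MP (J/min) = 0.098 · Vt · RR · (PEEP + P_insp),    P_insp = Ppeak − PEEP,

so MP reduces algebraically to 0.098 · Vt · RR · Ppeak.  Vt is tidal volume
in litres, RR respiratory rate in breaths/min, pressures in cmH2O.  The
0.098 factor converts L·cmH2O/min to J/min.

Ventilator-free days at day 28 (VFD28) is the standard composite outcome:
death on or before day 28 scores 0; otherwise 28 minus whole days spent on
the ventilator, floored at 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "mechanical_power",
    "pf_ratio",
    "normalize_fio2",
    "vfd28",
    "aggregate_mp",
    "VentSummary",
    "InsufficientDataError",
]

MP_INPUT_COLUMNS = ("vt", "rr", "peep", "p_peak")


class InsufficientDataError(ValueError):
    """No complete ventilator hour available in the requested window."""


@dataclass(frozen=True)
class VentSummary:
    """Per-admission ventilator aggregates over a stated window."""

    admission_id: object
    mp_median: float
    mp_max: float
    mp_min: float
    driving_pressure_mean: float
    minute_ventilation_mean: float
    n_hours_used: int

    def __post_init__(self) -> None:
        if not (self.mp_min <= self.mp_median <= self.mp_max):
            raise ValueError("MP aggregates must satisfy min <= median <= max")
        if self.n_hours_used < 1:
            raise ValueError("n_hours_used must be >= 1")


def mechanical_power(vt, rr, peep, p_peak):
    """Mechanical power in J/min from tidal volume (L), rate, PEEP and peak pressure.

    Accepts scalars or numpy arrays.  Raises ``ValueError`` on non-positive
    tidal volume, negative rate, or peak pressure below PEEP.
    """
    vt = np.asarray(vt, dtype=float)
    rr = np.asarray(rr, dtype=float)
    peep = np.asarray(peep, dtype=float)
    p_peak = np.asarray(p_peak, dtype=float)
    if np.any(vt <= 0):
        raise ValueError("tidal volume must be positive (litres)")
    if np.any(rr < 0):
        raise ValueError("respiratory rate must be non-negative")
    if np.any(peep < 0):
        raise ValueError("PEEP must be non-negative")
    if np.any(p_peak < peep):
        raise ValueError("peak pressure must be >= PEEP")
    # PEEP + (Ppeak − PEEP) = Ppeak; kept explicit to mirror the definition.
    out = 0.098 * vt * rr * (peep + (p_peak - peep))
    return float(out) if out.ndim == 0 else out


def normalize_fio2(fio2):
    """Return FiO2 as a fraction, accepting the percent dialect.

    Values in (1, 100] are interpreted as percent and divided by 100; values
    in [0.21, 1] pass through.  Anything below 0.21 after normalization is
    physiologically impossible on a ventilator and raises ``ValueError``.
    """
    f = np.asarray(fio2, dtype=float)
    f = np.where(f > 1.0, f / 100.0, f)
    if np.any(f < 0.21) or np.any(f > 1.0):
        raise ValueError("FiO2 must lie in [0.21, 1.0] after normalization")
    return float(f) if f.ndim == 0 else f


def pf_ratio(pao2, fio2):
    """PaO2/FiO2 ratio (oxygenation severity marker), FiO2 percent-tolerant."""
    p = np.asarray(pao2, dtype=float)
    if np.any(p <= 0):
        raise ValueError("PaO2 must be positive")
    out = p / normalize_fio2(fio2)
    return float(out) if out.ndim == 0 else out


def vfd28(intubation_duration_hours: float, death_day: float | None = None) -> int:
    """Ventilator-free days at day 28.

    Death on or before day 28 scores 0 regardless of ventilation time;
    survivors score ``max(0, 28 − ceil(duration/24))``.
    """
    if intubation_duration_hours < 0:
        raise ValueError("intubation duration must be non-negative")
    if death_day is not None and not (isinstance(death_day, float) and math.isnan(death_day)):
        if death_day < 0:
            raise ValueError("death day must be non-negative")
        if death_day <= 28:
            return 0
    return max(0, 28 - math.ceil(intubation_duration_hours / 24.0))


def vfd28_series(duration_hours: pd.Series, death_day: pd.Series) -> pd.Series:
    """Vectorised :func:`vfd28` over aligned pandas Series (NaN death = alive)."""
    days_vent = np.ceil(np.asarray(duration_hours, dtype=float) / 24.0)
    out = np.maximum(0, 28 - days_vent)
    dd = np.asarray(death_day, dtype=float)
    out[~np.isnan(dd) & (dd <= 28)] = 0
    if np.any(np.asarray(duration_hours, dtype=float) < 0):
        raise ValueError("intubation duration must be non-negative")
    return pd.Series(out.astype(int), index=getattr(duration_hours, "index", None))


def hourly_mp(hourly: pd.DataFrame) -> pd.Series:
    """MP per row of an hourly table; NaN where any of the four inputs is missing."""
    ok = hourly[list(MP_INPUT_COLUMNS)].notna().all(axis=1)
    mp = pd.Series(np.nan, index=hourly.index, dtype=float)
    if ok.any():
        sub = hourly.loc[ok]
        mp.loc[ok] = mechanical_power(
            sub["vt"].to_numpy(), sub["rr"].to_numpy(),
            sub["peep"].to_numpy(), sub["p_peak"].to_numpy(),
        )
    return mp


def aggregate_mp(records: pd.DataFrame, window_hours: int = 24) -> VentSummary:
    """Median/max/min MP plus driving-pressure and minute-ventilation means.

    ``records`` holds the hourly rows of a single admission with columns
    ``hour, vt, rr, peep, p_peak``.  Only complete hours in
    ``[0, window_hours)`` contribute; with none, raises
    :class:`InsufficientDataError` so the caller can exclude the admission.
    """
    win = records[records["hour"] < window_hours]
    complete = win[win[list(MP_INPUT_COLUMNS)].notna().all(axis=1)]
    if complete.empty:
        raise InsufficientDataError(
            "no hour with complete MP inputs in window [0, %d)" % window_hours
        )
    mp = mechanical_power(
        complete["vt"].to_numpy(), complete["rr"].to_numpy(),
        complete["peep"].to_numpy(), complete["p_peak"].to_numpy(),
    )
    mp = np.atleast_1d(mp)
    adm = records["admission_id"].iloc[0] if "admission_id" in records else None
    return VentSummary(
        admission_id=adm,
        mp_median=float(np.median(mp)),
        mp_max=float(np.max(mp)),
        mp_min=float(np.min(mp)),
        driving_pressure_mean=float((complete["p_peak"] - complete["peep"]).mean()),
        minute_ventilation_mean=float((complete["vt"] * complete["rr"]).mean()),
        n_hours_used=int(len(complete)),
    )
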