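"""Supply calendars and proportion-of-days-covered (PDC) computation.

Fills are turned into a daily coverage calendar with full carry-forward
stockpiling: a fill's supply starts at the later of its fill day and the end
of the supply already on hand, so overlapping supply is deferred, never lost
(except by truncation at the horizon). Monthly PDC uses fixed 30-day months;
an indicator of 1 means monthly PDC >= 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FillRecord",
    "SupplyCalendar",
    "AdherenceSeries",
    "build_supply_calendar",
    "monthly_pdc",
    "dichotomize",
    "overall_pdc",
    "adherence_series",
    "panel_from_fills",
    "DEFAULT_HORIZON",
    "MONTH_DAYS",
    "ADHERENCE_THRESHOLD",
]

DEFAULT_HORIZON = 360
MONTH_DAYS = 30
ADHERENCE_THRESHOLD = 0.8


@dataclass(frozen=True)
class FillRecord:
    """One dispensing event: day offset from index and days of supply."""

    day: int
    days_supply: int

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError(f"fill day must be >= 0, got {self.day}")
        if self.days_supply < 1:
            raise ValueError(f"days_supply must be >= 1, got {self.days_supply}")


@dataclass
class SupplyCalendar:
    """Boolean daily coverage over ``[0, horizon)`` for one patient."""

    covered: np.ndarray
    horizon: int = DEFAULT_HORIZON
    patient_id: object = None

    def __post_init__(self) -> None:
        self.covered = np.asarray(self.covered, dtype=bool)
        if self.covered.shape != (self.horizon,):
            raise ValueError("covered length must equal horizon")

    @property
    def covered_days(self) -> int:
        return int(self.covered.sum())


@dataclass
class AdherenceSeries:
    """Monthly PDC fractions, binary indicators, and overall PDC."""

    monthly_pdc: np.ndarray
    indicators: np.ndarray
    overall_pdc: float
    patient_id: object = None


def _coerce_fills(fills: Iterable) -> list[FillRecord]:
    out = []
    for f in fills:
        if isinstance(f, FillRecord):
            out.append(f)
        else:
            day, supply = f
            out.append(FillRecord(int(day), int(supply)))
    return out


def build_supply_calendar(
    fills: Iterable,
    horizon: int = DEFAULT_HORIZON,
    patient_id: object = None,
) -> SupplyCalendar:
    """Build the daily coverage calendar with full carry-forward stockpiling.

    Fills are processed in ascending day order; each fill's supply begins at
    ``max(fill day, end of supply on hand)`` and runs for ``days_supply``
    consecutive days, truncated at ``horizon``. Same-day fills merge
    additively into the queue, so their order is irrelevant.
    """
    recs = sorted(_coerce_fills(fills), key=lambda r: r.day)
    covered = np.zeros(horizon, dtype=bool)
    pointer = 0  # first day not yet covered by supply on hand
    for rec in recs:
        start = max(rec.day, pointer)
        end = start + rec.days_supply
        covered[min(start, horizon) : min(end, horizon)] = True
        pointer = end
    return SupplyCalendar(covered=covered, horizon=horizon, patient_id=patient_id)


def monthly_pdc(calendar: SupplyCalendar, n_months: int = 12) -> np.ndarray:
    """Per 30-day month, covered days / 30. Month m covers days [30(m-1), 30m)."""
    if calendar.horizon < n_months * MONTH_DAYS:
        raise ValueError(
            f"horizon {calendar.horizon} too short for {n_months} 30-day months"
        )
    chunks = calendar.covered[: n_months * MONTH_DAYS].reshape(n_months, MONTH_DAYS)
    return chunks.sum(axis=1) / MONTH_DAYS


def dichotomize(pdc: Sequence[float], threshold: float = ADHERENCE_THRESHOLD) -> np.ndarray:
    """Binary indicators: 1 iff monthly PDC >= threshold (boundary inclusive)."""
    arr = np.asarray(pdc, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("PDC fractions must lie in [0, 1]")
    return (arr >= threshold).astype(int)


def overall_pdc(calendar: SupplyCalendar) -> float:
    """Covered days divided by the horizon length."""
    return calendar.covered_days / calendar.horizon


def adherence_series(
    fills: Iterable,
    horizon: int = DEFAULT_HORIZON,
    n_months: int = 12,
    threshold: float = ADHERENCE_THRESHOLD,
    patient_id: object = None,
) -> AdherenceSeries:
    cal = build_supply_calendar(fills, horizon=horizon, patient_id=patient_id)
    pdc = monthly_pdc(cal, n_months=n_months)
    return AdherenceSeries(
        monthly_pdc=pdc,
        indicators=dichotomize(pdc, threshold=threshold),
        overall_pdc=overall_pdc(cal),
        patient_id=patient_id,
    )


def panel_from_fills(
    fills: pd.DataFrame,
    horizon: int = DEFAULT_HORIZON,
    n_months: int = 12,
    threshold: float = ADHERENCE_THRESHOLD,
    drug: str | None = "nintedanib",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute per-patient adherence from a fills table.

    Parameters
    ----------
    fills
        Table with columns ``patient_id``, ``day``, ``days_supply`` and
        optionally ``drug`` (filtered to ``drug`` when present).

    Returns
    -------
    (long, panel)
        ``long`` has one row per patient-month (patient_id, month, pdc,
        adherent) plus a per-patient ``overall_pdc`` column; ``panel`` is the
        wide N x n_months 0/1 indicator table indexed by patient_id.
    """
    required = {"patient_id", "day", "days_supply"}
    missing = required - set(fills.columns)
    if missing:
        raise KeyError(f"fills table missing column(s): {sorted(missing)}")
    df = fills
    if drug is not None and "drug" in df.columns:
        df = df[df["drug"] == drug]
    rows = []
    wide = {}
    for pid, grp in df.groupby("patient_id", sort=True):
        series = adherence_series(
            zip(grp["day"], grp["days_supply"]),
            horizon=horizon,
            n_months=n_months,
            threshold=threshold,
            patient_id=pid,
        )
        wide[pid] = series.indicators
        for m in range(n_months):
            rows.append(
                {
                    "patient_id": pid,
                    "month": m + 1,
                    "pdc": series.monthly_pdc[m],
                    "adherent": int(series.indicators[m]),
                    "overall_pdc": series.overall_pdc,
                }
            )
    long = pd.DataFrame(
        rows, columns=["patient_id", "month", "pdc", "adherent", "overall_pdc"]
    )
    panel = pd.DataFrame.from_dict(
        wide, orient="index", columns=[f"m{m}" for m in range(1, n_months + 1)]
    )
    panel.index.name = "patient_id"
    return long, panel
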