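"""Inclusion/exclusion filters over claims-shaped tables, with attrition.

Time is measured in integer day offsets from each patient's index day (day
of the first qualifying drug fill). Baseline is [-360, -1], follow-up
[0, 359]; enrollment must cover [-360, 360). Filters are conjunctive
predicates applied sequentially in a configurable order, so the final
patient set is order-invariant even though per-step counts are not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adherence import build_supply_calendar

__all__ = ["FilterConfig", "FilterResult", "SchemaError", "identify_index",
           "apply_filters", "FILTER_ORDER"]


class SchemaError(KeyError):
    pass


FILTER_ORDER = (
    "age",
    "enrollment",
    "diagnosis",
    "baseline_antifibrotic",
    "excluded_care",
    "comorbid_exclusion",
    "pirfenidone_overlap",
    "death",
)

_CARE_FLAGS = ("lung_transplant", "snf", "ltc", "hospice", "dual_eligible")
_EXCLUDED_DX = ("LUNG_CANCER", "AUTOIMMUNE")


@dataclass(frozen=True)
class FilterConfig:
    index_drug: str = "nintedanib"
    overlap_drug: str = "pirfenidone"
    min_age: int = 66
    baseline_days: int = 360
    followup_days: int = 360
    dx_gap_days: int = 14  # inclusive: exactly 14 days apart qualifies
    order: tuple = FILTER_ORDER


@dataclass
class FilterResult:
    steps: list  # (filter name, n_before, n_excluded, n_after)
    final_ids: list

    def __post_init__(self):
        for name, before, excluded, after in self.steps:
            if after != before - excluded or min(before, excluded, after) < 0:
                raise ValueError(f"inconsistent attrition row for {name!r}")

    @property
    def attrition(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.steps, columns=["filter", "n_before", "n_excluded", "n_after"]
        )


def _require(df: pd.DataFrame, table: str, cols: set) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise SchemaError(f"{table} table missing column(s): {sorted(missing)}")


def identify_index(fills: pd.DataFrame, drug: str = "nintedanib") -> pd.Series:
    """Earliest qualifying fill day per patient; patients without one dropped."""
    _require(fills, "fills", {"patient_id", "day"})
    df = fills
    if "drug" in df.columns:
        df = df[df["drug"] == drug]
    if df.empty:
        return pd.Series(dtype=float, name="index_day")
    idx = df.groupby("patient_id")["day"].min()
    idx.name = "index_day"
    return idx


# --- individual predicates: return the set of patient ids that PASS ----------

def _pass_age(tables, index, cfg):
    cov = tables["covariates"]
    _require(cov, "covariates", {"patient_id", "age"})
    ok = cov.loc[cov["age"] >= cfg.min_age, "patient_id"]
    return set(ok) & set(index.index)


def _pass_enrollment(tables, index, cfg):
    enr = tables["enrollment"]
    _require(enr, "enrollment", {"patient_id", "start_day", "end_day"})
    parts = [c for c in ("part_a", "part_b", "part_d") if c in enr.columns]
    passed = set()
    for pid, grp in enr.groupby("patient_id"):
        if pid not in index.index:
            continue
        if parts:
            grp = grp[(grp[parts] == 1).all(axis=1)]
        lo, hi = -cfg.baseline_days, cfg.followup_days
        covered = np.zeros(hi - lo, dtype=bool)
        for _, row in grp.iterrows():
            a = max(int(row["start_day"]), lo)
            b = min(int(row["end_day"]), hi)
            if b > a:
                covered[a - lo : b - lo] = True
        if covered.all():
            passed.add(pid)
    return passed


def _pass_diagnosis(tables, index, cfg):
    dx = tables["diagnoses"]
    _require(dx, "diagnoses", {"patient_id", "day", "code", "setting"})
    base = dx[(dx["code"] == "IPF") & (dx["day"] >= -cfg.baseline_days)
              & (dx["day"] <= -1)]
    passed = set()
    for pid, grp in base.groupby("patient_id"):
        if (grp["setting"] == "inpatient").any():
            passed.add(pid)
            continue
        days = np.sort(grp.loc[grp["setting"] == "outpatient", "day"].to_numpy())
        if days.size >= 2 and days[-1] - days[0] >= cfg.dx_gap_days:
            passed.add(pid)
    return passed & set(index.index)


def _pass_baseline_antifibrotic(tables, index, cfg):
    fills = tables["fills"]
    _require(fills, "fills", {"patient_id", "day", "drug"})
    anti = fills[fills["drug"].isin([cfg.index_drug, cfg.overlap_drug])]
    bad = set()
    for pid, grp in anti.groupby("patient_id"):
        if pid not in index.index:
            continue
        rel = grp["day"] - index[pid]
        if ((rel >= -cfg.baseline_days) & (rel <= -1)).any():
            bad.add(pid)
    return set(index.index) - bad


def _pass_excluded_care(tables, index, cfg):
    cov = tables["covariates"]
    _require(cov, "covariates", {"patient_id", *_CARE_FLAGS})
    ok = cov.loc[(cov[list(_CARE_FLAGS)] == 0).all(axis=1), "patient_id"]
    return set(ok) & set(index.index)


def _pass_comorbid_exclusion(tables, index, cfg):
    dx = tables["diagnoses"]
    _require(dx, "diagnoses", {"patient_id", "day", "code"})
    bad = dx[dx["code"].isin(_EXCLUDED_DX) & (dx["day"] >= -cfg.baseline_days)
             & (dx["day"] <= -1)]
    return set(index.index) - set(bad["patient_id"])


def _pass_pirfenidone_overlap(tables, index, cfg):
    """Exclude follow-up fills of the alternative drug whose supply interval
    overlaps the index drug's stockpiled coverage."""
    fills = tables["fills"]
    _require(fills, "fills", {"patient_id", "day", "days_supply", "drug"})
    bad = set()
    for pid, grp in fills.groupby("patient_id"):
        if pid not in index.index:
            continue
        rel = grp.assign(rel=grp["day"] - index[pid])
        nint = rel[(rel["drug"] == cfg.index_drug) & (rel["rel"] >= 0)
                   & (rel["rel"] < cfg.followup_days)]
        alt = rel[(rel["drug"] == cfg.overlap_drug) & (rel["rel"] >= 0)
                  & (rel["rel"] < cfg.followup_days)]
        if alt.empty or nint.empty:
            continue
        cal = build_supply_calendar(
            zip(nint["rel"], nint["days_supply"]), horizon=cfg.followup_days
        )
        for _, row in alt.iterrows():
            a = int(row["rel"])
            b = min(a + int(row["days_supply"]), cfg.followup_days)
            if cal.covered[a:b].any():
                bad.add(pid)
                break
    return set(index.index) - bad


def _pass_death(tables, index, cfg):
    cov = tables["covariates"]
    _require(cov, "covariates", {"patient_id"})
    if "death_day" not in cov.columns:
        return set(index.index)
    dd = cov.set_index("patient_id")["death_day"]
    bad = dd[dd.notna() & (dd < cfg.followup_days)].index
    return set(index.index) - set(bad)


_PREDICATES = {
    "age": _pass_age,
    "enrollment": _pass_enrollment,
    "diagnosis": _pass_diagnosis,
    "baseline_antifibrotic": _pass_baseline_antifibrotic,
    "excluded_care": _pass_excluded_care,
    "comorbid_exclusion": _pass_comorbid_exclusion,
    "pirfenidone_overlap": _pass_pirfenidone_overlap,
    "death": _pass_death,
}


def apply_filters(tables: dict, config: FilterConfig = FilterConfig()) -> FilterResult:
    """Apply the configured filter sequence; emit one attrition row per filter.

    ``tables`` must hold ``fills``, ``enrollment``, ``diagnoses`` and
    ``covariates`` DataFrames. The starting population is every patient with
    a qualifying index fill.
    """
    for key in ("fills", "enrollment", "diagnoses", "covariates"):
        if key not in tables:
            raise SchemaError(f"missing table: {key!r}")
    index = identify_index(tables["fills"], drug=config.index_drug)
    current = set(index.index)
    steps = []
    for name in config.order:
        if name not in _PREDICATES:
            raise KeyError(f"unknown filter: {name!r}")
        passed = _PREDICATES[name](tables, index, config)
        before = len(current)
        current = current & passed
        steps.append((name, before, before - len(current), len(current)))
    return FilterResult(steps=steps, final_ids=sorted(current))
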