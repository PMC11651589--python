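"""Time-stratified case-crossover design: referents, lags, matched sets.

Each case day is matched to every other day in the same calendar month and
year that falls on the same day of the week (3–4 referents, before and
after the case day).  Because case and referent days share the month and
weekday, anything constant within a district-month — demography, regional
wealth, seasonality, long-term trends, weekday patterns — cancels out of
the conditional likelihood; only covariates that vary day to day within
the stratum (the lagged exposure metric, temperature, holidays) remain.

Exposure lag convention: lag k is k days *before* the member day, applied
identically to case and referent days.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LagSpec",
    "PanelGapError",
    "enumerate_referents",
    "lagged_exposure",
    "build_matched_sets",
    "validate_panel",
]

logger = logging.getLogger(__name__)

PANEL_COLUMNS = ("district_id", "date", "pm25", "temperature", "holiday")
CASE_COLUMNS = ("case_id", "event_date", "district_id")


class PanelGapError(KeyError):
    """A required (district, date) row is absent from the exposure panel."""


@dataclass(frozen=True)
class LagSpec:
    """Which backward lag window summarises PM2.5 for a member day.

    ``moving_average`` averages PM2.5 over the given contiguous lags
    (default lags 0–2: the event day and the two preceding days);
    ``single`` picks one lag day.
    """

    kind: str = "moving_average"
    lags: tuple[int, ...] = (0, 1, 2)

    def __post_init__(self) -> None:
        if self.kind not in ("moving_average", "single"):
            raise ValueError(f"unknown lag kind {self.kind!r}")
        if not self.lags or any(l < 0 for l in self.lags):
            raise ValueError("lags must be a non-empty set of non-negative integers")
        if self.kind == "single" and len(self.lags) != 1:
            raise ValueError("single-lag spec takes exactly one lag")
        if self.kind == "moving_average":
            ordered = sorted(self.lags)
            if ordered != list(range(ordered[0], ordered[-1] + 1)):
                raise ValueError("moving-average lags must be contiguous")

    @property
    def max_lag(self) -> int:
        return max(self.lags)

    @property
    def label(self) -> str:
        if self.kind == "single":
            return f"lag{self.lags[0]}"
        return f"ma{min(self.lags)}-{max(self.lags)}"

    @classmethod
    def parse(cls, text: str) -> "LagSpec":
        """Parse compact CLI form: ``ma:0-2`` or ``single:1``."""
        kind, _, arg = text.partition(":")
        if kind in ("ma", "moving_average"):
            lo, _, hi = arg.partition("-")
            return cls("moving_average", tuple(range(int(lo), int(hi) + 1)))
        if kind == "single":
            return cls("single", (int(arg),))
        raise ValueError(f"cannot parse lag spec {text!r}")


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Check panel invariants; returns the panel with parsed dates.

    Requires columns district_id, date, pm25, temperature, holiday;
    (district, date) unique; no calendar gaps per district; pm25 >= 0.
    """
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"panel missing columns {missing}")
    panel = panel.copy()
    panel["date"] = pd.to_datetime(panel["date"])
    if panel.duplicated(["district_id", "date"]).any():
        raise ValueError("duplicate (district_id, date) rows in panel")
    if (panel["pm25"] < 0).any():
        raise ValueError("negative pm25 in panel")
    for district, grp in panel.groupby("district_id", sort=False):
        dates = grp["date"].sort_values()
        span = pd.date_range(dates.iloc[0], dates.iloc[-1])
        if len(dates) != len(span):
            raise ValueError(f"calendar gaps in panel for district {district!r}")
    return panel


def enumerate_referents(event_date) -> list[pd.Timestamp]:
    """All days of the event's month sharing its weekday, minus the event day.

    Bidirectional (before and after the case day), ascending order.
    """
    d = pd.Timestamp(event_date)
    month = pd.date_range(d.replace(day=1), d.replace(day=d.days_in_month))
    return [day for day in month if day.dayofweek == d.dayofweek and day != d]


def lagged_exposure(panel: pd.DataFrame, district, date, spec: LagSpec) -> float:
    """PM2.5 summary over the backward lag window for one district-day.

    Raises :class:`PanelGapError` naming the district and missing date —
    never silently imputes.
    """
    date = pd.Timestamp(date)
    sub = panel.loc[panel["district_id"] == district]
    series = pd.Series(
        sub["pm25"].to_numpy(), index=pd.DatetimeIndex(pd.to_datetime(sub["date"]))
    )
    values = []
    for lag in spec.lags:
        day = date - pd.Timedelta(days=lag)
        if day not in series.index:
            raise PanelGapError(
                f"no exposure for district {district!r} on {day.date()} "
                f"(lag {lag} of {date.date()})"
            )
        values.append(float(series.loc[day]))
    return float(np.mean(values)) if spec.kind == "moving_average" else values[0]


def _attach_lagged(members: pd.DataFrame, panel: pd.DataFrame, lag: int,
                   columns: dict[str, str]) -> pd.DataFrame:
    """Merge panel values at ``member_date - lag`` onto the member table."""
    shifted = panel[["district_id", "date", *columns]].rename(
        columns={"date": "_lag_date", **columns}
    )
    members = members.assign(_lag_date=members["member_date"] - pd.Timedelta(days=lag))
    out = members.merge(shifted, on=["district_id", "_lag_date"], how="left")
    return out.drop(columns="_lag_date")


def build_matched_sets(
    cases: pd.DataFrame,
    panel: pd.DataFrame,
    lag_spec: LagSpec | None = None,
    temp_lags: int = 2,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Construct the long-format matched-set table.

    One matched set per case (set_id == case_id): the case day plus its
    same-weekday referent days in the same calendar month, each carrying
    the lagged PM2.5 metric, temperatures at lags 0..temp_lags, and the
    holiday flag.

    Member days whose lag window leaves the panel are dropped; a whole set
    is dropped when its *case* day lacks a complete window or fewer than
    one referent survives.  Counts are returned (and logged).

    Returns
    -------
    sets : DataFrame with columns set_id, case_id, district_id,
        member_date, is_case, pm, temp_lag_0..temp_lag_L, holiday.
    dropped : dict with keys ``cases_dropped`` and ``referent_days_dropped``.
    """
    lag_spec = lag_spec or LagSpec()
    panel = validate_panel(panel)
    cases = cases.copy()
    cases["event_date"] = pd.to_datetime(cases["event_date"])
    missing = [c for c in CASE_COLUMNS if c not in cases.columns]
    if missing:
        raise ValueError(f"case table missing columns {missing}")
    unknown = set(cases["district_id"]) - set(panel["district_id"])
    if unknown:
        raise ValueError(f"case districts absent from panel: {sorted(unknown)!r}")

    # Same-weekday days of the month are exactly those whose day-of-month is
    # congruent to the event's day-of-month mod 7.
    day = cases["event_date"].dt.day.to_numpy()
    days_in_month = cases["event_date"].dt.days_in_month.to_numpy()
    first = (day - 1) % 7 + 1
    n_members = (days_in_month - first) // 7 + 1
    idx = np.repeat(np.arange(len(cases)), n_members)
    occurrence = np.arange(n_members.sum()) - np.repeat(
        np.cumsum(n_members) - n_members, n_members
    )
    member_day = first[idx] + 7 * occurrence
    month_start = (
        cases["event_date"] - pd.to_timedelta(day - 1, unit="D")
    ).to_numpy()
    members = pd.DataFrame(
        {
            "set_id": cases["case_id"].to_numpy()[idx],
            "district_id": cases["district_id"].to_numpy()[idx],
            "member_date": month_start[idx]
            + (member_day - 1).astype("timedelta64[D]"),
            "is_case": member_day == day[idx],
        }
    )
    members["case_id"] = members["set_id"]

    for lag in sorted({*lag_spec.lags, *range(temp_lags + 1), 0}):
        cols: dict[str, str] = {}
        if lag in lag_spec.lags:
            cols["pm25"] = f"pm_lag_{lag}"
        if lag <= temp_lags:
            cols["temperature"] = f"temp_lag_{lag}"
        if lag == 0:
            cols["holiday"] = "holiday"
        if cols:
            members = _attach_lagged(members, panel, lag, cols)

    pm_cols = [f"pm_lag_{l}" for l in lag_spec.lags]
    temp_cols = [f"temp_lag_{l}" for l in range(temp_lags + 1)]
    complete = members[pm_cols + temp_cols + ["holiday"]].notna().all(axis=1)

    # Case day incomplete -> whole set dropped (lag window exits the panel).
    bad_case_sets = set(members.loc[members["is_case"] & ~complete, "set_id"])
    n_ref_dropped = int((~complete & ~members["set_id"].isin(bad_case_sets)).sum())
    members = members[complete & ~members["set_id"].isin(bad_case_sets)]
    # A set needs at least one surviving referent to be informative.
    sizes = members.groupby("set_id")["is_case"].agg(["size", "sum"])
    keep = sizes.index[(sizes["size"] >= 2) & (sizes["sum"] == 1)]
    n_cases_dropped = len(cases) - len(keep)
    members = members[members["set_id"].isin(keep)].reset_index(drop=True)

    if lag_spec.kind == "moving_average":
        members["pm"] = members[pm_cols].mean(axis=1)
    else:
        members["pm"] = members[pm_cols[0]]
    members["holiday"] = members["holiday"].astype(bool)

    dropped = {"cases_dropped": int(n_cases_dropped),
               "referent_days_dropped": n_ref_dropped}
    if n_cases_dropped or n_ref_dropped:
        logger.info(
            "matched sets: dropped %d cases and %d referent days at panel boundary",
            n_cases_dropped, n_ref_dropped,
        )
    out_cols = ["set_id", "case_id", "district_id", "member_date", "is_case",
                "pm", *temp_cols, "holiday"]
    return members[out_cols], dropped
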