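"""Stratified refits and Wald contrasts between subgroup estimates.

Each subgroup level gets its own case-crossover dataset (matched sets are
rebuilt from that level's cases alone) and an independent refit of the
main model; subgroup pairs are then compared with a Wald difference test
that treats the two estimates as independent:

    z = (b1 - b2) / sqrt(se1^2 + se2^2),   p = 2 * (1 - Phi(|z|)).

Season is assigned from the case day's month (warm: April–September,
cold: October–March); referent days share the month by construction, so
no matched set straddles a season boundary.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .basis import CrossBasisSpec, SplineSpec
from .clogit import FitResult, build_design, fit, or_per_increment
from .design import LagSpec, build_matched_sets

__all__ = [
    "WARM_MONTHS",
    "season_of",
    "split_levels",
    "stratified_fits",
    "wald_difference_test",
    "pairwise_wald",
    "SubgroupResult",
]

logger = logging.getLogger(__name__)

WARM_MONTHS = frozenset(range(4, 10))  # April .. September

FACTORS = ("sex", "age_group", "age_band", "urban", "grdp_high", "season")

_LEVEL_LABELS = {
    "urban": {True: "urban", False: "rural"},
    "grdp_high": {True: "grdp_high", False: "grdp_low"},
}


@dataclass
class SubgroupResult:
    level: str
    n_cases: int
    fit: FitResult | None
    or_per_10: dict[str, float] | None


def season_of(dates) -> pd.Series:
    """'warm' (April–September) or 'cold' (October–March) per date."""
    months = pd.DatetimeIndex(pd.to_datetime(dates)).month
    return pd.Series(np.where(np.isin(months, list(WARM_MONTHS)), "warm", "cold"))


def _factor_values(cases: pd.DataFrame, factor: str) -> pd.Series:
    if factor == "season":
        return season_of(cases["event_date"]).set_axis(cases.index)
    if factor not in cases.columns:
        raise KeyError(f"unknown subgroup factor {factor!r}")
    values = cases[factor]
    if factor in _LEVEL_LABELS:
        values = values.map(_LEVEL_LABELS[factor])
    return values.astype(str)


def split_levels(cases: pd.DataFrame, factor: str | tuple[str, ...]) -> dict[str, pd.DataFrame]:
    """Partition cases by a factor or a crossing of factors.

    Crossing levels are labelled ``"<level1>:<level2>"`` (e.g.
    ``"cold:65+"`` for season crossed with age group).
    """
    factors = (factor,) if isinstance(factor, str) else tuple(factor)
    labels = _factor_values(cases, factors[0])
    for f in factors[1:]:
        labels = labels.str.cat(_factor_values(cases, f), sep=":")
    return {str(level): sub for level, sub in cases.groupby(labels, sort=True)}


def stratified_fits(
    cases: pd.DataFrame,
    panel: pd.DataFrame,
    factor: str | tuple[str, ...],
    lag_spec: LagSpec | None = None,
    temp: CrossBasisSpec | None = CrossBasisSpec(),
    pm: str | SplineSpec = "linear",
    holiday: bool = True,
    temp_lags: int | None = None,
) -> dict[str, SubgroupResult]:
    """Rebuild matched sets and refit the main model per subgroup level.

    Levels with no informative matched sets are reported with
    ``fit=None`` (absent, not zero) and a logged warning.
    """
    lag_spec = lag_spec or LagSpec()
    if temp_lags is None:
        temp_lags = temp.lag_range[1] if temp is not None else lag_spec.max_lag
    out: dict[str, SubgroupResult] = {}
    for level, sub in split_levels(cases, factor).items():
        sets, _ = build_matched_sets(sub, panel, lag_spec, temp_lags=temp_lags)
        informative = not sets.empty and sets.groupby("set_id")["pm"].nunique().gt(1).any()
        if not informative:
            logger.warning("subgroup level %r has no informative matched sets", level)
            out[level] = SubgroupResult(level, len(sub), None, None)
            continue
        dm = build_design(sets, pm=pm, temp=temp, holiday=holiday)
        res = fit(dm)
        or10 = None
        if pm == "linear" and not res.separation:
            or10 = or_per_increment(res)
        out[level] = SubgroupResult(level, len(sub), res, or10)
    return out


def wald_difference_test(est1: float, se1: float, est2: float, se2: float):
    """Two-sided Wald z-test for a difference of independent log-ORs."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    z = (est1 - est2) / np.hypot(se1, se2)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def pairwise_wald(results: dict[str, SubgroupResult]) -> pd.DataFrame:
    """All pairwise Wald contrasts between fitted subgroup levels."""
    rows = []
    fitted = {k: r for k, r in results.items() if r.or_per_10 is not None}
    for a, b in itertools.combinations(fitted, 2):
        ra, rb = fitted[a].or_per_10, fitted[b].or_per_10
        z, p = wald_difference_test(
            ra["log_or_per_unit"], ra["se_per_unit"],
            rb["log_or_per_unit"], rb["se_per_unit"],
        )
        rows.append({"level_1": a, "level_2": b, "z": z, "p": p})
    return pd.DataFrame(rows, columns=["level_1", "level_2", "z", "p"])
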