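"""Descriptive summaries of case records (counts and percentages)."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

__all__ = ["summarize", "to_markdown"]


def _percent(count: int, total: int) -> float:
    """count/total * 100 rounded half-up to one decimal (display convention)."""
    if total == 0:
        return 0.0
    value = Decimal(count) * 100 / Decimal(total)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


_FACTOR_ORDERS = {
    "sex": ["male", "female"],
    "age_group": ["0-64", "65+"],
    "age_band": ["0-19", "20-39", "40-64", "65-79", "80+"],
    "holiday": [True, False],
    "urban": [True, False],
    "grdp_high": [True, False],
}

_LEVEL_LABELS = {
    "holiday": {True: "yes", False: "no"},
    "urban": {True: "urban", False: "rural"},
    "grdp_high": {True: "high", False: "low"},
}


def summarize(cases: pd.DataFrame, panel: pd.DataFrame | None = None) -> pd.DataFrame:
    """Counts and one-decimal percentages per factor level, plus a total row.

    Covers sex, coarse and fine age bands, urban/rural and the regional
    wealth stratum; when an exposure panel is supplied, a holiday factor
    is derived from the case day's flag.
    """
    if cases.empty:
        raise ValueError("no case records to summarise")
    cases = cases.copy()
    if panel is not None:
        flags = panel[["district_id", "date", "holiday"]].copy()
        flags["date"] = pd.to_datetime(flags["date"])
        cases["event_date"] = pd.to_datetime(cases["event_date"])
        cases = cases.merge(
            flags, left_on=["district_id", "event_date"],
            right_on=["district_id", "date"], how="left",
        )

    total = len(cases)
    rows = [("total", "", total, 100.0)]
    for factor, order in _FACTOR_ORDERS.items():
        if factor not in cases.columns:
            continue
        counts = cases[factor].value_counts()
        for level in order:
            if level not in counts.index:
                continue
            label = _LEVEL_LABELS.get(factor, {}).get(level, str(level))
            rows.append((factor, label, int(counts[level]), _percent(int(counts[level]), total)))
    return pd.DataFrame(rows, columns=["factor", "level", "count", "percent"])


def to_markdown(table: pd.DataFrame) -> str:
    """Render the summary as a GitHub-style markdown table."""
    lines = ["| Factor | Level | N | % |", "| --- | --- | ---: | ---: |"]
    for _, r in table.iterrows():
        lines.append(f"| {r['factor']} | {r['level']} | {r['count']} | {r['percent']:.1f} |")
    return "\n".join(lines)
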