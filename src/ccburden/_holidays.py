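"""Synthetic stand-in holiday calendar.

A fixed list of recurring (month, day) public-holiday dates applied to
every year of a generated panel.  The list is *synthetic*: it is not the
official Korean holiday calendar (lunar holidays move between years),
but its density — 14 dates, about 3.8% of days — matches the share of
holidays a national injury survey sees.
"""

from __future__ import annotations

import pandas as pd

DEFAULT_HOLIDAYS: tuple[tuple[int, int], ...] = (
    (1, 1),    # new year
    (2, 10), (2, 11),          # lunar new year stand-in
    (3, 1),    # independence movement day
    (5, 5),    # children's day
    (5, 19),   # buddha's birthday stand-in
    (6, 6),    # memorial day
    (8, 15),   # liberation day
    (9, 20), (9, 21), (9, 22),  # harvest festival stand-in
    (10, 3),   # national foundation day
    (10, 9),   # hangul day
    (12, 25),  # christmas
)


def holiday_mask(dates: pd.DatetimeIndex | pd.Series,
                 holidays: tuple[tuple[int, int], ...] = DEFAULT_HOLIDAYS):
    """Boolean mask of which dates fall on a (recurring) holiday."""
    dates = pd.DatetimeIndex(dates)
    keys = set(holidays)
    return pd.Series(
        [(m, d) in keys for m, d in zip(dates.month, dates.day)],
        index=range(len(dates)),
    ).to_numpy()
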