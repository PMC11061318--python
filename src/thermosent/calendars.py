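"""Calendar labels used as time fixed effects.

Besides day-of-week, the panel models can absorb the 24 solar terms of
the traditional Chinese calendar — roughly fortnight-long divisions of
the solar year (Start of Spring, Rain Water, ..., Major Cold) whose
boundaries track the sun's ecliptic longitude.  The packaged table
holds the approximate Gregorian start dates (month, day), which drift
by at most a day across recent decades; callers may override it with
exact dates for a specific year.
"""

from __future__ import annotations

import datetime as dt

import pandas as pd

#: (term index 1..24, name, approximate Gregorian start (month, day)).
#: Term 1 is Start of Spring; the year wraps through Minor/Major Cold.
SOLAR_TERMS: list[tuple[int, str, tuple[int, int]]] = [
    (1, "start_of_spring", (2, 4)),
    (2, "rain_water", (2, 19)),
    (3, "awakening_of_insects", (3, 5)),
    (4, "spring_equinox", (3, 20)),
    (5, "clear_and_bright", (4, 4)),
    (6, "grain_rain", (4, 20)),
    (7, "start_of_summer", (5, 5)),
    (8, "grain_full", (5, 21)),
    (9, "grain_in_ear", (6, 5)),
    (10, "summer_solstice", (6, 21)),
    (11, "minor_heat", (7, 7)),
    (12, "major_heat", (7, 22)),
    (13, "start_of_autumn", (8, 7)),
    (14, "end_of_heat", (8, 23)),
    (15, "white_dew", (9, 7)),
    (16, "autumn_equinox", (9, 23)),
    (17, "cold_dew", (10, 8)),
    (18, "frost_descent", (10, 23)),
    (19, "start_of_winter", (11, 7)),
    (20, "minor_snow", (11, 22)),
    (21, "major_snow", (12, 7)),
    (22, "winter_solstice", (12, 21)),
    (23, "minor_cold", (1, 5)),
    (24, "major_cold", (1, 20)),
]

SUPPORTED_YEARS = range(1900, 2101)


def solar_term_of(date, table=None) -> int:
    """Solar-term index (1..24) containing ``date``; start dates inclusive.

    Jan 1 up to the Minor Cold boundary still belongs to the Winter
    Solstice term of the preceding year.
    """
    d = pd.Timestamp(date)
    if d.year not in SUPPORTED_YEARS:
        raise ValueError(f"date {d.date()} outside supported years")
    table = table or SOLAR_TERMS
    starts = sorted(
        (dt.date(d.year, m, day), idx) for idx, _, (m, day) in table
    )
    current = None
    for start, idx in starts:
        if d.date() >= start:
            current = idx
    if current is None:  # before Minor Cold: previous year's Winter Solstice
        current = 22
    return current


def solar_terms_of(dates: pd.Series, table=None) -> pd.Series:
    """Vectorized :func:`solar_term_of` over a date series."""
    uniq = {d: solar_term_of(d, table) for d in pd.unique(dates)}
    return pd.Series(pd.Series(dates).map(uniq).to_numpy(), index=dates.index)
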