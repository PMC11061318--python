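"""Percentile-threshold extreme-temperature indices.

A city-day is "extremely hot" relative to its own calendar-day
climatology: the 95th percentile of that city's daily maxima on that
day-of-year over a 20-year reference period is the warm standard, and
the signed gap between today's maximum and that standard is the extreme
high temperature index

    EHT = MAXT - Max_q ,

with the cold-side mirror  ELT = Min_q - MINT  (so more extreme cold is
a larger ELT).  Apparent variants subtract the square root of wind
speed; difference variants apply the same construction to the
day-over-day temperature change.  Annual counts of threshold
exceedances give the Warm Day Index (WDI) and Cold Night Index (CNI).

Quantiles use linear interpolation between order statistics (position
1 + (n-1)q), the numpy default, pinned for reproducibility.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger("thermosent")

WEATHER_FIELDS = ["tmax", "tmin", "wind", "precip"]

#: canonical city-day column names
CITYDAY_COLUMNS = ["city_id", "date", "MAXT", "MINT", "WS", "P"]

INDEX_COLUMNS = ["EHT", "ELT", "EHAT", "ELAT", "EHTD", "ELTD", "EHATD", "ELATD"]


def day_of_year_key(dates: pd.Series) -> pd.Series:
    """Calendar-day key, with Feb 29 mapped to the Feb 28 cell.

    The key is the day-of-year in a non-leap calendar so that e.g.
    Mar 1 shares one cell across leap and common years.
    """
    d = pd.DatetimeIndex(dates)
    month, day = d.month.to_numpy(), d.day.to_numpy()
    day = np.where((month == 2) & (day == 29), 28, day)
    cum = np.array([0, 31, 59, 90, 120, 151, 181, 212, 243, 273, 304, 334])
    return pd.Series(cum[month - 1] + day, index=dates.index if hasattr(dates, "index") else None)


def aggregate_stations(station_days: pd.DataFrame,
                       city_map: dict | None = None) -> pd.DataFrame:
    """Collapse station-day records to city-day weather by averaging.

    Each weather field is the arithmetic mean over the stations reporting
    that field that day; a field no station reports stays missing.  If
    ``city_map`` (station → city) is given it overrides the file's city
    column; a station mapped to no city raises.
    """
    df = station_days.copy()
    if city_map is not None:
        unmapped = set(df["station_id"]) - set(city_map)
        if unmapped:
            raise ValueError(f"stations mapped to no city: {sorted(unmapped)}")
        df["city_id"] = df["station_id"].map(city_map)
    if df["city_id"].isna().any():
        bad = df.loc[df["city_id"].isna(), "station_id"].unique()
        raise ValueError(f"stations mapped to no city: {sorted(bad)}")
    out = (
        df.groupby(["city_id", "date"], as_index=False, sort=True)[WEATHER_FIELDS]
        .mean()
        .rename(columns={"tmax": "MAXT", "tmin": "MINT", "wind": "WS", "precip": "P"})
    )
    return out


def _day_over_day(df: pd.DataFrame, col: str) -> pd.Series:
    """Signed change col_t - col_{t-1} within city; gaps break the series."""
    df = df.sort_values(["city_id", "date"])
    diff = df.groupby("city_id")[col].diff()
    gap = df.groupby("city_id")["date"].diff() != pd.Timedelta(days=1)
    n_gaps = int((gap & diff.notna()).sum())
    if n_gaps:
        log.warning("%d non-contiguous day gaps treated as series breaks", n_gaps)
    return diff.where(~gap)


def compute_thresholds(ref_weather: pd.DataFrame, q_upper: float = 0.95,
                       q_lower: float = 0.05, window: int = 0) -> pd.DataFrame:
    """Build the per-(city, day-of-year) percentile threshold table.

    For each city and calendar day, ``Max_q`` is the empirical
    ``q_upper`` quantile of MAXT over the reference years pooled across
    ``doy ± window`` (with wraparound), ``Min_q`` the ``q_lower``
    quantile of MINT, and ``MaxTD_q`` / ``MinTD_q`` the analogous
    quantiles of the signed day-over-day changes.

    Raises if any cell has fewer than two observations.
    """
    if not (0 < q_lower < 1 and 0 < q_upper < 1):
        raise ValueError("quantiles must lie in (0, 1)")
    years = pd.DatetimeIndex(ref_weather["date"]).year
    if years.nunique() < 2:
        raise ValueError("reference period must span at least 2 years")

    df = ref_weather.sort_values(["city_id", "date"]).reset_index(drop=True)
    df["MAXTD"] = _day_over_day(df, "MAXT").to_numpy()
    df["MINTD"] = _day_over_day(df, "MINT").to_numpy()
    df["doy"] = day_of_year_key(df["date"]).to_numpy()

    if window > 0:
        frames = []
        for off in range(-window, window + 1):
            g = df.copy()
            g["doy"] = (g["doy"] - 1 + off) % 365 + 1
            frames.append(g)
        pooled = pd.concat(frames, ignore_index=True)
    else:
        pooled = df

    g = pooled.groupby(["city_id", "doy"], sort=True)
    pieces = {}
    for col, q, name in (
        ("MAXT", q_upper, "Max_q"),
        ("MINT", q_lower, "Min_q"),
        ("MAXTD", q_upper, "MaxTD_q"),
        ("MINTD", q_lower, "MinTD_q"),
    ):
        counts = g[col].count()
        if (counts < 2).any():
            if col in ("MAXT", "MINT"):
                cid, doy = counts.idxmin()
                raise ValueError(
                    f"threshold cell (city {cid}, doy {doy}) has "
                    f"{int(counts.min())} observation(s) of {col}; need >= 2"
                )
            # change series can be legitimately sparse (non-contiguous
            # reference data); those cells get missing diff thresholds
            log.warning("%d (city, doy) cells have <2 %s observations; "
                        "their difference thresholds are missing",
                        int((counts < 2).sum()), col)
        quant = g[col].quantile(q)  # linear order-statistic interpolation
        pieces[name] = quant.where(counts >= 2)
    thr = pd.DataFrame(pieces).reset_index()
    thr.attrs.update(
        q_upper=q_upper, q_lower=q_lower, window=window,
        reference_years=sorted(years.unique().tolist()),
    )
    return thr


def compute_eht(maxt, max_q, clamp: bool = False):
    """Extreme high temperature: MAXT - Max_q (floored at 0 if clamped)."""
    out = np.asarray(maxt, dtype=float) - np.asarray(max_q, dtype=float)
    return np.maximum(out, 0.0) if clamp else out


def compute_elt(mint, min_q, clamp: bool = False):
    """Extreme low temperature: Min_q - MINT (floored at 0 if clamped)."""
    out = np.asarray(min_q, dtype=float) - np.asarray(mint, dtype=float)
    return np.maximum(out, 0.0) if clamp else out


def compute_apparent(index, ws):
    """Wind-adjusted (apparent) index: index - sqrt(WS).  Requires WS >= 0."""
    ws = np.asarray(ws, dtype=float)
    if np.any(ws < 0):
        raise ValueError("wind speed must be non-negative")
    return np.asarray(index, dtype=float) - np.sqrt(ws)


def compute_indices(weather: pd.DataFrame, thresholds: pd.DataFrame,
                    clamp: bool = False) -> pd.DataFrame:
    """Compute every extreme index for each city-day of ``weather``.

    Returns a frame keyed by (city_id, date) with EHT, ELT, their
    apparent variants (EHAT, ELAT), the day-over-day difference indices
    (EHTD, ELTD) and the apparent difference variants (EHATD, ELATD).
    The first day of each city's series has missing difference indices.
    Clamping, when requested, floors each index at zero before the
    apparent adjustment is applied.
    """
    df = weather.sort_values(["city_id", "date"]).reset_index(drop=True)
    df["MAXTD"] = _day_over_day(df, "MAXT").to_numpy()
    df["MINTD"] = _day_over_day(df, "MINT").to_numpy()
    df["doy"] = day_of_year_key(df["date"]).to_numpy()
    merged = df.merge(thresholds, on=["city_id", "doy"], how="left", validate="m:1")

    out = merged[["city_id", "date"]].copy()
    out["EHT"] = compute_eht(merged["MAXT"], merged["Max_q"])
    out["ELT"] = compute_elt(merged["MINT"], merged["Min_q"])
    out["EHTD"] = merged["MAXTD"] - merged["MaxTD_q"]
    out["ELTD"] = merged["MinTD_q"] - merged["MINTD"]
    ws = merged["WS"]
    for src, dst in (("EHT", "EHAT"), ("ELT", "ELAT"),
                     ("EHTD", "EHATD"), ("ELTD", "ELATD")):
        app = pd.Series(compute_apparent(out[src], ws.fillna(0.0)), index=out.index)
        out[dst] = app.where(ws.notna())
    if clamp:  # clamped index == max(0, continuous index), all variants
        for col in INDEX_COLUMNS:
            out[col] = out[col].clip(lower=0.0)
    n_missing = int(out[["EHT", "ELT"]].isna().any(axis=1).sum())
    if n_missing:
        log.info("%d city-days with missing EHT/ELT (missing inputs propagated)",
                 n_missing)
    return out[["city_id", "date"] + INDEX_COLUMNS]


def count_extreme_days(year_weather: pd.DataFrame,
                       thresholds: pd.DataFrame) -> pd.DataFrame:
    """Annual Warm Day Index and Cold Night Index per city.

    WDI counts days with MAXT strictly above the warm standard, CNI days
    with MINT strictly below the cold standard; ties at the threshold
    are not extreme.  Days missing the relevant temperature are excluded
    from that count and reported in ``n_missing_maxt`` / ``n_missing_mint``.
    """
    df = year_weather.copy()
    df["doy"] = day_of_year_key(df["date"]).to_numpy()
    df["year"] = pd.DatetimeIndex(df["date"]).year
    m = df.merge(thresholds, on=["city_id", "doy"], how="left", validate="m:1")
    m["warm"] = m["MAXT"] > m["Max_q"]
    m["cold"] = m["MINT"] < m["Min_q"]
    out = (
        m.groupby(["city_id", "year"], as_index=False, sort=True)
        .agg(
            WDI=("warm", "sum"),
            CNI=("cold", "sum"),
            n_missing_maxt=("MAXT", lambda s: int(s.isna().sum())),
            n_missing_mint=("MINT", lambda s: int(s.isna().sum())),
        )
    )
    out["WDI"] = out["WDI"].astype(int)
    out["CNI"] = out["CNI"].astype(int)
    return out
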