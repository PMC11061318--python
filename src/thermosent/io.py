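"""Readers and writers for the pipeline's delimited-text tables.

All ingestion converts to one canonical unit regime — °C, m/s, mm —
so every downstream formula sees a single system.  Logs go to standard
error (via :mod:`logging`); results only to files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .config import ConfigError

log = logging.getLogger("thermosent")

#: columns a station-day table must provide (canonical names)
STATION_COLUMNS = ["station_id", "city_id", "date", "tmax", "tmin", "wind", "precip"]
POST_COLUMNS = ["post_id", "city_id", "date", "text", "score"]

_TEMP_UNITS = {"C", "F"}
_WIND_UNITS = {"m/s", "knots"}
_PRECIP_UNITS = {"mm", "in"}

KNOT_MS = 0.514444
INCH_MM = 25.4


@dataclass
class StationDialect:
    """Column mapping and units of a station-day file.

    ``columns`` maps canonical names (see :data:`STATION_COLUMNS`) to the
    file's column headers; identity by default.  Units are declared per
    quantity; unknown labels are a configuration error.
    """

    columns: Mapping[str, str] = field(default_factory=dict)
    temp_unit: str = "C"
    wind_unit: str = "m/s"
    precip_unit: str = "mm"
    sep: str = ","

    def __post_init__(self) -> None:
        if self.temp_unit not in _TEMP_UNITS:
            raise ConfigError(f"unknown temperature unit {self.temp_unit!r}")
        if self.wind_unit not in _WIND_UNITS:
            raise ConfigError(f"unknown wind unit {self.wind_unit!r}")
        if self.precip_unit not in _PRECIP_UNITS:
            raise ConfigError(f"unknown precipitation unit {self.precip_unit!r}")


def fahrenheit_to_celsius(x):
    return (np.asarray(x, dtype=float) - 32.0) * 5.0 / 9.0


def read_station_daily(path, dialect: StationDialect | None = None) -> pd.DataFrame:
    """Read a station-day weather file into canonical units.

    Returns a frame with :data:`STATION_COLUMNS`; temperatures in °C,
    wind in m/s, precipitation in mm.  Rows with unparseable dates are
    dropped with a logged count; missing numeric cells stay missing.
    Duplicate (station, date) rows raise.
    """
    dialect = dialect or StationDialect()
    raw = pd.read_csv(path, sep=dialect.sep)
    if raw.empty:
        log.warning("station file %s is empty", path)
        return pd.DataFrame(columns=STATION_COLUMNS)

    rename = {src: canon for canon, src in dialect.columns.items()}
    df = raw.rename(columns=rename)
    missing = [c for c in STATION_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"station file lacks columns {missing}")
    df = df[STATION_COLUMNS].copy()

    dates = pd.to_datetime(df["date"], errors="coerce", format="ISO8601")
    bad = dates.isna() & df["date"].notna()
    if bad.any():
        log.warning("rejected %d rows with unparseable dates", int(bad.sum()))
    df = df.loc[~bad].copy()
    df["date"] = dates.loc[~bad].dt.normalize()

    dup = df.duplicated(subset=["station_id", "date"], keep=False)
    if dup.any():
        first = df.loc[dup, ["station_id", "date"]].iloc[0]
        raise ValueError(
            f"duplicate station-day rows; first offender: "
            f"station {first['station_id']} on {first['date'].date()}"
        )

    for col in ("tmax", "tmin", "wind", "precip"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if dialect.temp_unit == "F":
        df["tmax"] = fahrenheit_to_celsius(df["tmax"])
        df["tmin"] = fahrenheit_to_celsius(df["tmin"])
    if dialect.wind_unit == "knots":
        df["wind"] = df["wind"] * KNOT_MS
    if dialect.precip_unit == "in":
        df["precip"] = df["precip"] * INCH_MM
    return df.reset_index(drop=True)


def read_posts(path) -> pd.DataFrame:
    """Read a post table (post_id, city_id, date, text, score).

    Scores must lie in the closed interval [0, 100]; offenders raise a
    validation error listing their ids.  Text is kept verbatim —
    deduplication happens downstream.
    """
    df = pd.read_csv(path, dtype={"text": str})
    missing = [c for c in POST_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"post file lacks columns {missing}")
    df = df[POST_COLUMNS].copy()
    df["date"] = pd.to_datetime(df["date"]).dt.normalize()
    df["score"] = pd.to_numeric(df["score"])
    out = (df["score"] < 0) | (df["score"] > 100)
    if out.any():
        ids = df.loc[out, "post_id"].tolist()
        raise ValueError(f"sentiment scores outside [0, 100] for posts: {ids}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Write a tidy table as CSV with full float precision (round-trips)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_table(path, parse_dates: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    for c in parse_dates or []:
        df[c] = pd.to_datetime(df[c])
    return df


def write_results(results: Mapping[str, "object"], out_dir, *,
                  config=None, seed: int | None = None) -> dict:
    """Write fitted-model coefficient tables plus a run manifest.

    ``results`` maps names to fitted results (anything exposing
    ``to_frame()``).  Each becomes ``<name>.csv`` with term, estimate,
    clustered SE, p-value plus N and R² columns; the manifest (JSON)
    records the config hash, seed and table checksums.  Output is
    deterministic bytes under a fixed config and seed.
    """
    if not results:
        raise ValueError("empty result bundle: nothing to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": seed,
        "config_hash": config.hash() if config is not None else None,
        "tables": {},
    }
    for name, res in sorted(results.items()):
        frame = res.to_frame() if hasattr(res, "to_frame") else pd.DataFrame(res)
        p = out_dir / f"{name}.csv"
        frame.to_csv(p, index=False)
        import hashlib

        manifest["tables"][name] = hashlib.sha256(p.read_bytes()).hexdigest()
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
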