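"""Neighbor-city instruments for the extreme-temperature indices.

Weather in a bordering city moves with the target city's weather (a
shared regional system) but should not affect the target's residents
through any channel other than temperature itself — the classic
exclusion argument.  Each city's instrument is therefore the mean of
its neighbors' index values after harmonizing altitudes with the
standard environmental lapse rate, 0.6 °C per 100 m:

    NEHT_it = mean_j [ EHT_jt - 0.6 (Al_j - Al_i) / 100 ] ,

and likewise NELT from neighbors' ELT.  Adjacency is supplied as data
(an administrative edge list), never computed from geometry.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger("thermosent")

LAPSE_RATE_PER_100M = 0.6

META_COLUMNS = ["city_id", "altitude", "region", "PCDI"]


def altitude_adjust(index_j, al_j, al_i):
    """Shift a neighbor's index to the target city's altitude.

    Subtracts ``0.6 * (Al_j - Al_i) / 100`` — a neighbor sitting higher
    (colder) than the target has its index raised to the target's level.
    """
    delta = (np.asarray(al_j, dtype=float) - np.asarray(al_i, dtype=float))
    return np.asarray(index_j, dtype=float) - LAPSE_RATE_PER_100M * delta / 100.0


def validate_adjacency(adjacency: pd.DataFrame, cities=None) -> pd.DataFrame:
    """Check the neighbor relation: symmetric, no self-loops, no isolates."""
    adj = adjacency[["city_id", "neighbor_id"]].drop_duplicates()
    if (adj["city_id"] == adj["neighbor_id"]).any():
        raise ValueError("adjacency contains self-neighbors")
    pairs = set(map(tuple, adj.to_numpy()))
    asym = [p for p in pairs if (p[1], p[0]) not in pairs]
    if asym:
        raise ValueError(f"adjacency not symmetric, e.g. {asym[0]}")
    if cities is not None:
        isolated = set(cities) - set(adj["city_id"])
        if isolated:
            raise ValueError(f"cities with zero neighbors: {sorted(isolated)}")
    return adj


def synthesize_instruments(indices: pd.DataFrame, meta: pd.DataFrame,
                           adjacency: pd.DataFrame,
                           cols: tuple[str, str] = ("EHT", "ELT")) -> pd.DataFrame:
    """Build NEHT/NELT per city-day from neighbors' indices.

    For each (city, date), the instrument is the equal-weight mean over
    bordering cities of their altitude-adjusted index value; neighbors
    missing that day are dropped from the mean and counted.  Returns a
    frame keyed by (city_id, date) with NEHT, NELT, n_neighbors_used;
    city-days where no neighbor reports are absent (logged).
    """
    adj = validate_adjacency(adjacency, cities=indices["city_id"].unique())
    alt = meta.set_index("city_id")["altitude"]
    hi, lo = cols

    nb = adj.merge(
        indices[["city_id", "date", hi, lo]].rename(
            columns={"city_id": "neighbor_id", hi: "_hi", lo: "_lo"}),
        on="neighbor_id", how="inner",
    )
    al_i = nb["city_id"].map(alt).to_numpy()
    al_j = nb["neighbor_id"].map(alt).to_numpy()
    nb["_hi"] = altitude_adjust(nb["_hi"], al_j, al_i)
    nb["_lo"] = altitude_adjust(nb["_lo"], al_j, al_i)

    nb = nb.dropna(subset=["_hi", "_lo"], how="all")
    out = (
        nb.groupby(["city_id", "date"], as_index=False, sort=True)
        .agg(NEHT=("_hi", "mean"), NELT=("_lo", "mean"),
             n_neighbors_used=("_hi", "count"))
    )
    out = out[out["n_neighbors_used"] >= 1]
    n_expected = indices[["city_id", "date"]].drop_duplicates().shape[0]
    if len(out) < n_expected:
        log.warning("%d city-days have no reporting neighbor; instrument missing",
                    n_expected - len(out))
    return out
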