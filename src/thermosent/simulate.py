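"""Synthetic study generator.

Emulates every input the pipeline consumes, with a known data-generating
process so that estimates can be checked against stored truth:

* a per-city daily temperature climatology — seasonal sinusoid plus an
  AR(1) anomaly — over a 20-year reference period and a 366-day study
  year, observed by several noisy stations per city;
* spatial correlation: every city's anomaly loads on a shared regional
  factor (neighbor correlation ~0.95 by default), which is what makes
  the neighbor-city instrument strong;
* city metadata (altitude, north/south region, per-capita disposable
  income) and a symmetric neighbor graph (ring by default);
* city-day covariates (wind, precipitation, PM2.5, cumulative and new
  COVID-19 case counts);
* post-level sentiment scores generated linearly from the pipeline's
  OWN extreme-temperature indices (the generator never recomputes the
  index formulas), city fixed effects, day-of-week effects and noise,
  truncated to [0, 100].

An optional unobserved city-day confounder — an urban heat-island
shock — enters sentiment directly and correlates with the city's own
*idiosyncratic* temperature anomaly, biasing OLS while leaving the
neighbor instrument valid.  A "broken-IV" variant instead correlates
the confounder with the *shared* regional anomaly, which contaminates
the neighbors too; it exists to demonstrate what the diagnostics and
estimates do when the exclusion restriction fails, and is expected to
fail recovery.

Every output is a pure function of (scenario, seed).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger("thermosent")


@dataclass
class SimScenario:
    """Generator settings.  Defaults mirror the study's scale: 49 cities,
    a 20-year reference climatology, a 366-day study year, and 1-50
    posts per city-day."""

    n_cities: int = 49
    n_ref_years: int = 20
    study_year: int = 2020
    stations_per_city: int = 3
    neighbor_graph: str | list[tuple[str, str]] = "ring"
    altitude_range: tuple[float, float] = (0.0, 1500.0)

    mean_temp: float = 16.0          # °C national mean of daily maxima
    north_south_offset: float = 3.0  # °C south warmer / north colder
    seasonal_amplitude: float = 12.0  # °C peak-to-mean seasonal swing
    ar1: float = 0.7                 # day-to-day anomaly persistence
    anomaly_sd: float = 3.0          # °C stationary anomaly sd
    neighbor_corr: float = 0.95      # anomaly correlation between cities
    station_noise_sd: float = 0.5    # °C per-station measurement noise
    diurnal_mean: float = 9.0        # °C mean tmax - tmin
    diurnal_sd: float = 1.5

    wind_shape: float = 2.0          # gamma; mean = shape*scale = 3.3 m/s
    wind_scale: float = 1.65
    precip_prob: float = 0.3
    pm25_median: float = 15.0        # µg/m³ (the heterogeneity threshold)
    pm25_sigma: float = 0.5

    beta0: float = 60.0
    beta_eht: float = -0.16          # sentiment units per °C of EHT
    beta_elt: float = -0.27
    beta_pm25: float = 0.015
    beta_ws: float = 0.158
    beta_p: float = -0.052
    beta_ccd: float = -0.0175
    gamma_sd: float = 2.0            # city fixed-effect sd
    dow_effects: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0, 0.0, 1.0, 1.0)

    posts_min: int = 1
    posts_max: int = 50
    score_noise_sd: float = 10.0
    spam_rate: float = 0.0           # duplicate-post injection probability

    confound_rho: float = 0.0        # corr(confounder, temperature anomaly)
    confound_scale: float = 4.0      # sentiment units per confounder sd
    broken_iv: bool = False          # confounder loads on the shared anomaly

    #: (beta_elt_poor, beta_elt_rich) override for heterogeneity tests
    income_group_beta_elt: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_cities < 2:
            raise ValueError("need at least 2 cities")
        if not -1 < self.ar1 < 1:
            raise ValueError("AR(1) coefficient must lie in (-1, 1)")
        if not 0 <= self.confound_rho <= 1:
            raise ValueError("confound_rho must lie in [0, 1]")
        if self.posts_min < 0 or self.posts_max < self.posts_min:
            raise ValueError("invalid post-count range")

    @property
    def ref_years(self) -> range:
        return range(self.study_year - self.n_ref_years, self.study_year)


@dataclass
class World:
    """Fixed geography: metadata, adjacency, stations, latent city traits."""

    meta: pd.DataFrame          # city_id, altitude, region, PCDI
    adjacency: pd.DataFrame     # city_id, neighbor_id (symmetric)
    station_map: dict[str, str]  # station_id -> city_id
    base_temp: np.ndarray       # per-city mean of daily maxima, °C
    gamma: np.ndarray           # per-city sentiment fixed effect

    @property
    def cities(self) -> list[str]:
        return self.meta["city_id"].tolist()


def generate_world(scenario: SimScenario, rng: np.random.Generator) -> World:
    """Draw geography: altitudes, income, region flags, neighbor graph."""
    n = scenario.n_cities
    cities = [f"C{i + 1:03d}" for i in range(n)]
    lo, hi = scenario.altitude_range
    altitude = rng.uniform(lo, hi, size=n).round(1)
    pcdi = rng.lognormal(mean=np.log(40_000.0), sigma=0.3, size=n).round(0)
    region = np.where(np.arange(n) < n // 2, "north", "south")
    base = (scenario.mean_temp
            + np.where(region == "north", -1, 1) * scenario.north_south_offset
            + rng.normal(0.0, 1.0, size=n))
    gamma = rng.normal(0.0, scenario.gamma_sd, size=n)

    if scenario.neighbor_graph == "ring":
        edges = [(cities[i], cities[(i + 1) % n]) for i in range(n)]
    else:
        edges = [tuple(e) for e in scenario.neighbor_graph]
    sym = sorted({(a, b) for a, b in edges} | {(b, a) for a, b in edges})
    adjacency = pd.DataFrame(sym, columns=["city_id", "neighbor_id"])
    isolated = set(cities) - set(adjacency["city_id"])
    if isolated:
        raise ValueError(f"neighbor graph leaves cities isolated: {sorted(isolated)}")

    meta = pd.DataFrame({"city_id": cities, "altitude": altitude,
                         "region": region, "PCDI": pcdi})
    station_map = {f"S{c}_{k + 1}": c for c in cities
                   for k in range(scenario.stations_per_city)}
    return World(meta=meta, adjacency=adjacency, station_map=station_map,
                 base_temp=base, gamma=gamma)


def _ar1(rng: np.random.Generator, shape: tuple[int, ...], phi: float) -> np.ndarray:
    """Stationary unit-variance AR(1) along the last axis."""
    out = np.empty(shape)
    out[..., 0] = rng.normal(size=shape[:-1])
    innov_sd = np.sqrt(1.0 - phi ** 2)
    eps = rng.normal(scale=innov_sd, size=shape)
    for t in range(1, shape[-1]):
        out[..., t] = phi * out[..., t - 1] + eps[..., t]
    return out


def generate_climate(scenario: SimScenario, world: World,
                     rng: np.random.Generator, start_year: int,
                     end_year: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Station-day weather records for [start_year, end_year].

    Returns ``(station_days, truth)``:  station_days holds station_id,
    city_id, date, tmax, tmin, wind, precip in canonical units; truth
    holds the latent standardized shared and idiosyncratic anomaly
    components per city-day (needed by the confounder and by tests).
    """
    dates = pd.date_range(f"{start_year}-01-01", f"{end_year}-12-31", freq="D")
    T, C = len(dates), scenario.n_cities

    shared = _ar1(rng, (T,), scenario.ar1)
    idio = _ar1(rng, (C, T), scenario.ar1)
    w = scenario.neighbor_corr
    anomaly = scenario.anomaly_sd * (np.sqrt(w) * shared[None, :]
                                     + np.sqrt(1.0 - w) * idio)

    doy = dates.dayofyear.to_numpy()
    seasonal = scenario.seasonal_amplitude * np.cos(2 * np.pi * (doy - 200) / 365.25)
    tmax = world.base_temp[:, None] + seasonal[None, :] + anomaly
    m, s = scenario.diurnal_mean, scenario.diurnal_sd
    diurnal = rng.gamma(shape=(m / s) ** 2, scale=s ** 2 / m, size=(C, T))
    tmin = tmax - diurnal
    wind = rng.gamma(scenario.wind_shape, scenario.wind_scale, size=(C, T))
    precip = np.where(rng.random((C, T)) < scenario.precip_prob,
                      rng.gamma(2.0, 5.0, size=(C, T)), 0.0)

    S = scenario.stations_per_city
    frames = []
    cities = np.asarray(world.cities)
    for k in range(S):
        noise_mx = rng.normal(0.0, scenario.station_noise_sd, size=(C, T))
        noise_mn = rng.normal(0.0, scenario.station_noise_sd, size=(C, T))
        frames.append(pd.DataFrame({
            "station_id": np.repeat([f"S{c}_{k + 1}" for c in cities], T),
            "city_id": np.repeat(cities, T),
            "date": np.tile(dates, C),
            "tmax": (tmax + noise_mx).ravel(),
            "tmin": (tmin + noise_mn).ravel(),
            "wind": np.clip(wind + rng.normal(0, 0.1, size=(C, T)), 0, None).ravel(),
            "precip": precip.ravel(),
        }))
    station_days = pd.concat(frames, ignore_index=True)

    truth = pd.DataFrame({
        "city_id": np.repeat(cities, T),
        "date": np.tile(dates, C),
        "z_shared": np.tile(shared, C),
        "z_idio": idio.ravel(),
        "anomaly": anomaly.ravel(),
    })
    return station_days, truth


def generate_covariates(scenario: SimScenario, world: World,
                        rng: np.random.Generator, year: int) -> pd.DataFrame:
    """City-day PM2.5 and COVID-19 case counts for the study year.

    PM2.5 is lognormal around the configured median; each city gets one
    outbreak window of Poisson daily new cases, cumulated into CCD.
    """
    dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    T, C = len(dates), scenario.n_cities
    pm25 = rng.lognormal(np.log(scenario.pm25_median), scenario.pm25_sigma,
                         size=(C, T))
    start = rng.integers(30, 90, size=C)
    length = rng.integers(40, 80, size=C)
    t_idx = np.arange(T)[None, :]
    in_window = (t_idx >= start[:, None]) & (t_idx < (start + length)[:, None])
    newc = rng.poisson(0.8, size=(C, T)) * in_window
    ccd = np.cumsum(newc, axis=1)
    return pd.DataFrame({
        "city_id": np.repeat(world.cities, T),
        "date": np.tile(dates, C),
        "PM25": pm25.ravel(),
        "CCD": ccd.ravel().astype(float),
        "NEWC": newc.ravel().astype(float),
    })


def latent_sentiment(scenario: SimScenario, world: World, panel: pd.DataFrame,
                     rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    """Latent city-day mean sentiment from the structural model.

    ``panel`` must carry EHT, ELT (the pipeline's own indices), the
    controls PM25/WS/P/CCD, and the latent anomaly components z_idio /
    z_shared.  Returns the latent mean per row and the truth record.
    """
    cities = world.cities
    gamma = dict(zip(cities, world.gamma))
    beta_elt = np.full(len(panel), scenario.beta_elt)
    rich_by_city: dict[str, bool] = {}
    if scenario.income_group_beta_elt is not None:
        poor_b, rich_b = scenario.income_group_beta_elt
        cut = world.meta["PCDI"].median()
        rich_by_city = dict(zip(world.meta["city_id"], world.meta["PCDI"] > cut))
        is_rich = panel["city_id"].map(rich_by_city).to_numpy()
        beta_elt = np.where(is_rich, rich_b, poor_b)

    dow = pd.DatetimeIndex(panel["date"]).dayofweek.to_numpy()
    z = panel["z_shared" if scenario.broken_iv else "z_idio"].to_numpy()
    rho = scenario.confound_rho
    if rho > 0:  # switchable: the clean scenario has no heat-island shock
        conf = rho * z + np.sqrt(1.0 - rho ** 2) * rng.normal(size=len(panel))
    else:
        conf = np.zeros(len(panel))

    latent = (scenario.beta0
              + scenario.beta_eht * panel["EHT"].to_numpy()
              + beta_elt * panel["ELT"].to_numpy()
              + scenario.beta_pm25 * panel["PM25"].to_numpy()
              + scenario.beta_ws * panel["WS"].to_numpy()
              + scenario.beta_p * panel["P"].to_numpy()
              + scenario.beta_ccd * panel["CCD"].to_numpy()
              + panel["city_id"].map(gamma).to_numpy()
              + np.asarray(scenario.dow_effects)[dow]
              + scenario.confound_scale * conf)
    frac_out = float(((latent < 5) | (latent > 95)).mean())
    if frac_out > 0.01:
        log.warning("latent sentiment outside [5, 95] for %.1f%% of city-days; "
                    "truncation may bias recovery", 100 * frac_out)
    truth = {
        "beta0": scenario.beta0, "beta_eht": scenario.beta_eht,
        "beta_elt": scenario.beta_elt,
        "beta_pm25": scenario.beta_pm25, "beta_ws": scenario.beta_ws,
        "beta_p": scenario.beta_p, "beta_ccd": scenario.beta_ccd,
        "gamma": gamma, "dow_effects": list(scenario.dow_effects),
        "confound_rho": rho, "confound_scale": scenario.confound_scale,
        "broken_iv": scenario.broken_iv,
        "income_group_beta_elt": scenario.income_group_beta_elt,
        "rich_by_city": {k: bool(v) for k, v in rich_by_city.items()},
        "scenario": dataclasses.asdict(scenario),
    }
    return latent, truth


def generate_posts(scenario: SimScenario, world: World, panel: pd.DataFrame,
                   rng: np.random.Generator, with_text: bool = True
                   ) -> tuple[pd.DataFrame, dict]:
    """Post-level scores around the latent city-day mean.

    Post counts are uniform on [posts_min, posts_max]; scores are the
    latent mean plus Gaussian noise, truncated to [0, 100].  With
    ``with_text``, each post gets a unique synthetic token text and —
    at the configured spam rate — may instead duplicate the text of an
    earlier post in the same city, to exercise deduplication.
    """
    latent, truth = latent_sentiment(scenario, world, panel, rng)
    n_posts = rng.integers(scenario.posts_min, scenario.posts_max + 1,
                           size=len(panel))
    row = np.repeat(np.arange(len(panel)), n_posts)
    scores = np.clip(latent[row] + rng.normal(0, scenario.score_noise_sd,
                                              size=len(row)), 0.0, 100.0)
    posts = pd.DataFrame({
        "post_id": [f"p{i:08d}" for i in range(len(row))],
        "city_id": panel["city_id"].to_numpy()[row],
        "date": panel["date"].to_numpy()[row],
        "score": scores,
    })
    if with_text:
        texts = np.array([f"w{i}" for i in range(len(posts))], dtype=object)
        if scenario.spam_rate > 0:
            spam = rng.random(len(posts)) < scenario.spam_rate
            n_injected = 0
            for city, idx in posts.groupby("city_id").indices.items():
                hit = idx[spam[idx] & (idx > idx[0])]
                for j in hit:  # copy an earlier post's text within the city
                    src = idx[rng.integers(0, np.searchsorted(idx, j))]
                    texts[j] = texts[src]
                n_injected += len(hit)
            truth["n_spam_injected"] = n_injected
        posts["text"] = texts
    posts = posts[["post_id", "city_id", "date", "text", "score"]
                  if with_text else ["post_id", "city_id", "date", "score"]]
    truth["n_posts_total"] = int(len(posts))
    return posts, truth
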