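import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, max_examples=25, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_panel(n_cities=5, n_days=30, seed=0, beta_eht=-0.3, beta_elt=-0.5,
               noise_sd=1.0, start="2020-03-02"):
    """Small estimation panel with a known linear model and city/dow effects.

    Built directly (not through build_panel) so panel-model tests are
    independent of the assembly code.
    """
    rng = np.random.default_rng(seed)
    dates = pd.date_range(start, periods=n_days, freq="D")
    cities = [f"C{i}" for i in range(n_cities)]
    gamma = rng.normal(0, 2, n_cities)
    dow_eff = rng.normal(0, 0.5, 7)
    rows = []
    for ci, c in enumerate(cities):
        eht = rng.normal(0, 2, n_days)
        elt = rng.normal(0, 2, n_days)
        pm = rng.lognormal(np.log(15), 0.4, n_days)
        ws = rng.gamma(2, 1.65, n_days)
        p = np.where(rng.random(n_days) < 0.3, rng.gamma(2, 5, n_days), 0)
        ccd = np.cumsum(rng.poisson(0.5, n_days)).astype(float)
        dow = dates.dayofweek.to_numpy()
        y = (60 + beta_eht * eht + beta_elt * elt + 0.02 * pm + 0.15 * ws
             - 0.05 * p - 0.01 * ccd + gamma[ci] + dow_eff[dow]
             + rng.normal(0, noise_sd, n_days))
        rows.append(pd.DataFrame({
            "city_id": c, "date": dates, "sentiment": y, "EHT": eht,
            "ELT": elt, "PM25": pm, "WS": ws, "P": p, "CCD": ccd,
            "dow": dow, "weekend": (dow >= 5).astype(int),
        }))
    df = pd.concat(rows, ignore_index=True)
    df.attrs["truth"] = {"beta_eht": beta_eht, "beta_elt": beta_elt}
    return df


@pytest.fixture
def toy_panel():
    return make_panel()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
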