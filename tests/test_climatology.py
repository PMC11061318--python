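import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from thermosent.climatology import (
    aggregate_stations,
    compute_apparent,
    compute_eht,
    compute_elt,
    compute_indices,
    compute_thresholds,
    count_extreme_days,
    day_of_year_key,
)


def station_frame(rows):
    df = pd.DataFrame(rows, columns=["station_id", "city_id", "date",
                                     "tmax", "tmin", "wind", "precip"])
    df["date"] = pd.to_datetime(df["date"])
    return df


def ref_weather(values, city="c1", month=6, day=15, col="MAXT"):
    """One observation per reference year on a fixed calendar day."""
    other = "MINT" if col == "MAXT" else "MAXT"
    offset = -10 if col == "MAXT" else 10
    return pd.DataFrame({
        "city_id": city,
        "date": pd.to_datetime([f"{2000 + i}-{month:02d}-{day:02d}"
                                for i in range(len(values))]),
        col: values, other: np.asarray(values) + offset,
        "WS": 1.0, "P": 0.0,
    })


class TestAggregateStations:
    def test_single_station_identity(self):
        df = station_frame([["s1", "c1", "2020-01-01", 31.0, 20.0, 3.0, 0.0]])
        out = aggregate_stations(df)
        assert out.loc[0, "MAXT"] == 31.0

    def test_two_stations_mean(self):
        df = station_frame([["s1", "c1", "2020-01-01", 30.0, 20.0, 3.0, 0.0],
                            ["s2", "c1", "2020-01-01", 34.0, 22.0, 5.0, 2.0]])
        out = aggregate_stations(df)
        assert out.loc[0, "MAXT"] == 32.0 and out.loc[0, "WS"] == 4.0

    def test_mean_over_reporting_stations_only(self):
        df = station_frame([["s1", "c1", "2020-01-01", 30.0, 20, 3, 0],
                            ["s2", "c1", "2020-01-01", 32.0, 20, 3, 0],
                            ["s3", "c1", "2020-01-01", np.nan, 20, 3, 0]])
        assert aggregate_stations(df).loc[0, "MAXT"] == 31.0

    def test_all_missing_field_stays_missing(self):
        df = station_frame([["s1", "c1", "2020-01-01", np.nan, 20, 3, 0]])
        assert np.isnan(aggregate_stations(df).loc[0, "MAXT"])

    def test_unmapped_station_raises(self):
        df = station_frame([["s1", "c1", "2020-01-01", 30, 20, 3, 0]])
        with pytest.raises(ValueError, match="s1"):
            aggregate_stations(df, city_map={"s2": "c1"})


class TestComputeThresholds:
    def test_constant_series_any_quantile(self):
        thr = compute_thresholds(ref_weather([20.0] * 20), 0.95, 0.05)
        assert thr.loc[0, "Max_q"] == 20.0

    def test_order_statistic_interpolation_upper(self):
        # 1..20 at q=0.95: position 1+19*0.95 = 19.05 -> 19.05
        thr = compute_thresholds(ref_weather(list(range(1, 21))), 0.95, 0.05)
        assert thr.loc[0, "Max_q"] == pytest.approx(19.05, abs=1e-12)

    def test_order_statistic_interpolation_lower(self):
        thr = compute_thresholds(
            ref_weather(list(range(1, 21)), col="MINT"), 0.95, 0.05)
        assert thr.loc[0, "Min_q"] == pytest.approx(1.95, abs=1e-12)

    def test_row_order_invariance(self, rng):
        base = ref_weather(rng.normal(20, 5, 20).tolist())
        shuffled = base.sample(frac=1, random_state=1).reset_index(drop=True)
        a = compute_thresholds(base)
        b = compute_thresholds(shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_understocked_cell_errors_with_name(self):
        w = ref_weather([20.0, 21.0])
        w.loc[1, "MAXT"] = np.nan
        with pytest.raises(ValueError, match="c1"):
            compute_thresholds(w)

    def test_max_q_above_min_q(self, rng):
        w = ref_weather(rng.normal(25, 3, 20).tolist())
        thr = compute_thresholds(w)
        assert (thr["Max_q"] > thr["Min_q"]).all()

    def test_single_year_reference_rejected(self):
        w = ref_weather([20.0])
        with pytest.raises(ValueError, match="2 years"):
            compute_thresholds(w)

    def test_pooling_window_merges_adjacent_days(self):
        frames = [ref_weather([10.0 + i] * 3, day=d) for i, d in enumerate((14, 15, 16))]
        w = pd.concat(frames, ignore_index=True)
        thr0 = compute_thresholds(w, window=0)
        thr1 = compute_thresholds(w, window=1)
        cell0 = thr0[thr0["doy"] == day_of_year_key(pd.Series(pd.to_datetime(["2020-06-15"])))[0]]
        cell1 = thr1[thr1["doy"] == cell0["doy"].iloc[0]]
        assert cell1["Max_q"].iloc[0] > cell0["Max_q"].iloc[0]  # pools day 16


def test_quantile_matches_brute_force_oracle(rng):
    """Thresholds equal a sort-and-interpolate oracle on random series."""
    def oracle(x, q):
        x = np.sort(np.asarray(x, float))
        pos = (len(x) - 1) * q
        lo, g = int(np.floor(pos)), pos - np.floor(pos)
        return x[lo] if g == 0 else (1 - g) * x[lo] + g * x[min(lo + 1, len(x) - 1)]

    for _ in range(200):
        n = int(rng.integers(5, 40))
        vals = rng.normal(15, 8, n)
        q = float(rng.uniform(0.5, 0.99))
        thr = compute_thresholds(ref_weather(vals.tolist()), q, 1 - q)
        assert abs(thr.loc[0, "Max_q"] - oracle(vals, q)) < 1e-10
        assert abs(thr.loc[0, "Min_q"] - oracle(vals - 10, 1 - q)) < 1e-10


class TestIndexAlgebra:
    @pytest.mark.parametrize("maxt,max_q,clamp,expected", [
        (35.0, 33.0, False, 2.0),
        (33.0, 33.0, False, 0.0),
        (30.0, 33.0, False, -3.0),
        (30.0, 33.0, True, 0.0),
    ])
    def test_eht(self, maxt, max_q, clamp, expected):
        assert compute_eht(maxt, max_q, clamp) == expected

    @pytest.mark.parametrize("mint,min_q,clamp,expected", [
        (-5.0, -2.0, False, 3.0),
        (-2.0, -2.0, False, 0.0),
        (1.0, -2.0, False, -3.0),
    ])
    def test_elt(self, mint, min_q, clamp, expected):
        assert compute_elt(mint, min_q, clamp) == expected

    @pytest.mark.parametrize("index,ws,expected", [
        (2.0, 4.0, 0.0),
        (3.0, 0.0, 3.0),
        (1.5, 2.25, 0.0),
    ])
    def test_apparent(self, index, ws, expected):
        assert compute_apparent(index, ws) == expected

    def test_apparent_negative_wind_rejected(self):
        with pytest.raises(ValueError):
            compute_apparent(2.0, -1.0)

    @given(st.floats(-30, 45), st.floats(-30, 45))
    def test_eht_clamp_dominance(self, maxt, max_q):
        cont = compute_eht(maxt, max_q, clamp=False)
        assert compute_eht(maxt, max_q, clamp=True) == max(0.0, cont)


def _study_weather(maxt, city="c1", start="2020-06-10", mint=None, ws=1.0):
    dates = pd.date_range(start, periods=len(maxt), freq="D")
    return pd.DataFrame({
        "city_id": city, "date": dates, "MAXT": maxt,
        "MINT": np.asarray(maxt) - 10 if mint is None else mint,
        "WS": ws, "P": 0.0,
    })


def _flat_thresholds(cities, max_q, min_q, maxtd_q=5.0, mintd_q=-5.0):
    rows = [{"city_id": c, "doy": d, "Max_q": max_q, "Min_q": min_q,
             "MaxTD_q": maxtd_q, "MinTD_q": mintd_q}
            for c in cities for d in range(1, 366)]
    return pd.DataFrame(rows)


class TestTempDiffIndices:
    def test_ehtd_arithmetic(self):
        w = _study_weather([20.0, 28.0])  # MAXTD day2 = 8.0
        thr = _flat_thresholds(["c1"], 30.0, 5.0, maxtd_q=6.0)
        idx = compute_indices(w, thr)
        assert idx.loc[1, "EHTD"] == pytest.approx(2.0)

    def test_eltd_arithmetic(self):
        w = _study_weather([20.0, 10.0])  # MINTD day2 = -10
        thr = _flat_thresholds(["c1"], 30.0, 5.0, mintd_q=-7.0)
        idx = compute_indices(w, thr)
        assert idx.loc[1, "ELTD"] == pytest.approx(3.0)

    def test_first_day_of_series_missing(self):
        idx = compute_indices(_study_weather([20.0, 21.0]),
                              _flat_thresholds(["c1"], 30.0, 5.0))
        assert np.isnan(idx.loc[0, "EHTD"]) and np.isnan(idx.loc[0, "ELTD"])

    def test_date_gap_breaks_series(self, caplog):
        w = pd.concat([_study_weather([20.0, 21.0], start="2020-06-10"),
                       _study_weather([22.0], start="2020-06-14")],
                      ignore_index=True)
        with caplog.at_level("WARNING", logger="thermosent"):
            idx = compute_indices(w, _flat_thresholds(["c1"], 30.0, 5.0))
        assert np.isnan(idx.loc[2, "EHTD"])
        assert "gap" in caplog.text

    def test_apparent_variants_subtract_sqrt_wind(self):
        w = _study_weather([35.0], ws=4.0)
        idx = compute_indices(w, _flat_thresholds(["c1"], 33.0, 5.0))
        assert idx.loc[0, "EHT"] == 2.0 and idx.loc[0, "EHAT"] == 0.0


class TestShiftEquivariance:
    def test_constant_shift_cancels_exactly(self, rng):
        # 21 reference values put the 95th/5th percentiles exactly on an
        # order statistic (positions 20 and 2), so the shift is bitwise.
        vals = rng.integers(10, 30, 21).astype(float)
        c = 8.0
        w_ref, w_ref_c = ref_weather(vals.tolist()), ref_weather((vals + c).tolist())
        t0, t1 = compute_thresholds(w_ref), compute_thresholds(w_ref_c)
        study = _study_weather([25.0], start="2020-06-15")
        study_c = study.assign(MAXT=study["MAXT"] + c, MINT=study["MINT"] + c)
        i0 = compute_indices(study, t0)
        i1 = compute_indices(study_c, t1)
        assert i0.loc[0, "EHT"] == i1.loc[0, "EHT"]
        assert i0.loc[0, "ELT"] == i1.loc[0, "ELT"]


class TestCountExtremeDays:
    def _year(self, exceed_days, city="c1"):
        dates = pd.date_range("2020-01-01", "2020-12-31", freq="D")
        maxt = np.full(len(dates), 25.0)
        maxt[:exceed_days] = 35.0
        mint = maxt - 10
        return pd.DataFrame({"city_id": city, "date": dates, "MAXT": maxt,
                             "MINT": mint, "WS": 1.0, "P": 0.0})

    def _thr(self, max_q=30.0, min_q=10.0):
        return pd.DataFrame([{"city_id": "c1", "doy": d, "Max_q": max_q,
                              "Min_q": min_q, "MaxTD_q": 5.0, "MinTD_q": -5.0}
                             for d in range(1, 366)])

    def test_constructed_exceedance_count(self):
        counts = count_extreme_days(self._year(12), self._thr())
        assert counts.loc[0, "WDI"] == 12

    def test_all_below_threshold_zero(self):
        counts = count_extreme_days(self._year(0), self._thr())
        assert counts.loc[0, "WDI"] == 0

    def test_tie_at_threshold_not_counted(self):
        w = self._year(0)
        w.loc[0, "MAXT"] = 30.0  # exactly the standard
        assert count_extreme_days(w, self._thr()).loc[0, "WDI"] == 0

    def test_missing_days_excluded_and_reported(self):
        w = self._year(5)
        w.loc[0, "MAXT"] = np.nan  # was an exceedance day
        counts = count_extreme_days(w, self._thr())
        assert counts.loc[0, "WDI"] == 4
        assert counts.loc[0, "n_missing_maxt"] == 1

    def test_wdi_monotone_in_quantile(self, rng):
        """Looser (90th) standards flag at least as many warm days as 95th."""
        years = [ref_weather(rng.normal(25, 4, 20).tolist(), day=d)
                 for d in range(1, 29)]
        w = pd.concat(years, ignore_index=True)
        thr95 = compute_thresholds(w, 0.95, 0.05)
        thr90 = compute_thresholds(w, 0.90, 0.10)
        dates = pd.date_range("2020-06-01", "2020-06-28", freq="D")
        study = pd.DataFrame({"city_id": "c1", "date": dates,
                              "MAXT": rng.normal(27, 4, len(dates)),
                              "MINT": rng.normal(17, 4, len(dates)),
                              "WS": 1.0, "P": 0.0})
        c95 = count_extreme_days(study, thr95)
        c90 = count_extreme_days(study, thr90)
        assert c90.loc[0, "WDI"] >= c95.loc[0, "WDI"]
        assert c90.loc[0, "CNI"] >= c95.loc[0, "CNI"]


def test_feb29_maps_to_feb28_cell():
    d = pd.Series(pd.to_datetime(["2020-02-28", "2020-02-29", "2020-03-01",
                                  "2019-03-01"]))
    k = day_of_year_key(d)
    assert k[0] == k[1]
    assert k[2] == k[3]
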