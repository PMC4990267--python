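import io
import math

import numpy as np
import pandas as pd
import pytest

from fleetrum.features import (
    DEFAULT_THRESHOLDS,
    EnvGrid,
    PriceSeries,
    QuartileThresholds,
    TripState,
    build_choice_occasions,
    compute_reference_quartiles,
    env_quartile_counts,
    lagged_cpue,
    lagged_rpue,
    region_month_stats,
    seasonal_and_climate_covariates,
    update_trip_state,
)
from fleetrum.regions import GeoPoint


def _prices(months=("2001-05", "2001-06"), yft=1000.0, skj=900.0):
    idx = pd.PeriodIndex(months, freq="M")
    return PriceSeries(pd.DataFrame({"YFTP": yft, "SKJP": skj}, index=idx))


class TestReferenceQuartiles:
    def test_constant_sample(self):
        th = compute_reference_quartiles({"SST": [5, 5, 5, 5]})
        assert th["SST"] == (5.0, 5.0)

    def test_linear_interpolation_convention(self):
        # order statistics 1..8: Q1 = 2.75, Q3 = 6.25 under type-7 quantiles
        th = compute_reference_quartiles({"MLD": list(range(1, 9))})
        assert th["MLD"] == pytest.approx((2.75, 6.25))

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match=">= 4"):
            compute_reference_quartiles({"O2": [1.0, 2.0]})

    def test_published_defaults(self):
        assert DEFAULT_THRESHOLDS["SST"] == (26.8, 28.7)
        assert DEFAULT_THRESHOLDS["SSH"] == (0.6, 0.7)
        assert DEFAULT_THRESHOLDS["MLD"] == (18.6, 38.8)
        assert DEFAULT_THRESHOLDS["O2"] == (0.4, 1.0)

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            QuartileThresholds({"SST": (3.0, 2.0)})


class TestQuartileCounts:
    def _grid(self, values, var="SST", month="2001-06"):
        cells = {}
        # cells inside toy region 2 ([0,10]x[0,10])
        for i, v in enumerate(values):
            cells[(1 + i, 2)] = v
        return EnvGrid(month=pd.Period(month, freq="M"), values={var: cells})

    def test_counts_with_published_sst_thresholds(self, toy_rs):
        grid = self._grid([26.0, 27.5, 29.0])
        out = env_quartile_counts(grid, 2, toy_rs, DEFAULT_THRESHOLDS)
        assert out["SST"] == (1, 1)

    def test_region_without_cells(self, toy_rs):
        grid = self._grid([26.0, 27.5, 29.0])
        assert env_quartile_counts(grid, 1, toy_rs, DEFAULT_THRESHOLDS)["SST"] == (0, 0)

    def test_boundary_is_greater_or_equal(self, toy_rs):
        grid = self._grid([28.7, 28.7, 28.7, 28.7])
        assert env_quartile_counts(grid, 2, toy_rs, DEFAULT_THRESHOLDS)["SST"] == (0, 4)

    def test_missing_values_excluded_and_partition(self, toy_rs):
        vals = [25.0, 27.0, 29.5, float("nan"), 26.8, 30.1]
        grid = self._grid(vals)
        lo, hi = env_quartile_counts(grid, 2, toy_rs, DEFAULT_THRESHOLDS)["SST"]
        finite = [v for v in vals if math.isfinite(v)]
        mid = sum(1 for v in finite if 26.8 <= v < 28.7)
        assert lo + mid + hi == len(finite)


class TestLaggedCpueRpue:
    def test_zero_catch_forced_floor(self):
        assert lagged_cpue({}, 1.0) == pytest.approx(math.log(1e-4), abs=1e-12)

    def test_direct_evaluation(self):
        val = lagged_cpue({"YFT": 4.0, "SKJ": 5.0, "BET": 1.0}, 5.0)
        assert val == pytest.approx(math.log(10.0 / 5.0001 + 1e-4), abs=1e-12)
        assert val == pytest.approx(0.6932, abs=5e-4)

    def test_rpue_direct_evaluation(self):
        val = lagged_rpue(
            {"YFT": 1.0, "BET": 1.0, "SKJ": 1.0},
            1.0,
            _prices(),
            pd.Period("2001-05", freq="M"),
        )
        # 1000 + (900+100) + 900 = 2900 over 1.00001 days
        assert val == pytest.approx(math.log(2900.0 / 1.00001), abs=1e-12)
        assert val == pytest.approx(7.9724, abs=5e-4)

    def test_rpue_zero_revenue_floor(self):
        val = lagged_rpue({}, 1.0, _prices(), pd.Period("2001-05", freq="M"))
        assert val == pytest.approx(math.log(1e-12), abs=1e-12)

    def test_rpue_price_homogeneity(self):
        catch = {"YFT": 2.0, "SKJ": 3.0}
        m = pd.Period("2001-05", freq="M")
        v1 = lagged_rpue(catch, 2.0, _prices(yft=1000, skj=900), m)
        v2 = lagged_rpue(catch, 2.0, _prices(yft=2000, skj=1800), m)
        # doubling all prices (incl. the BET premium's base) shifts by ~ln 2;
        # the fixed +100 premium breaks exact homogeneity only via BET catch
        assert v2 - v1 == pytest.approx(math.log(2.0), abs=1e-12)

    def test_rpue_missing_price_month(self):
        with pytest.raises(KeyError):
            lagged_rpue({"YFT": 1.0}, 1.0, _prices(), pd.Period("1990-01", freq="M"))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            lagged_cpue({"YFT": -1.0}, 1.0)


class TestSeasonalCovariates:
    @pytest.mark.parametrize(
        "date,expected",
        [("2001-01-15", 1), ("2001-03-31", 1), ("2001-04-01", 0), ("2001-07-15", 0),
         ("2001-10-01", 1), ("2001-12-25", 1)],
    )
    def test_oct_mar_dummy(self, date, expected):
        mei = pd.Series(
            0.3, index=pd.period_range("2001-01", "2001-12", freq="M")
        )
        oct_mar, val = seasonal_and_climate_covariates(date, mei)
        assert oct_mar == expected
        assert val == 0.3

    def test_missing_mei_month(self):
        mei = pd.Series(0.1, index=pd.period_range("2001-01", "2001-02", freq="M"))
        with pytest.raises(KeyError):
            seasonal_and_climate_covariates("2002-06-15", mei)


def _rec(date, lon, lat, ht=0.0, hs=0.0, hf=0.0, sets=(0, 0, 0), catch=(0, 0, 0)):
    return {
        "date": date,
        "lon": lon,
        "lat": lat,
        "hours_travel": ht,
        "hours_search": hs,
        "hours_fish": hf,
        "sets_DEL": sets[0],
        "sets_OBJ": sets[1],
        "sets_NOA": sets[2],
        "catch_SKJ_t": catch[0],
        "catch_YFT_t": catch[1],
        "catch_BET_t": catch[2],
    }


class TestTripState:
    def test_departure_day_all_zero(self):
        s = TripState.initial("T1", "V1", GeoPoint(-5.5, 2.5), "2001-06-01")
        assert s.dist_since_dep == 0 and s.days_since_dep == 0
        assert s.catch_total() == 0 and s.current_region is None

    def test_three_day_hand_summation(self, toy_rs):
        # day 1: travel east 2 deg on the equator-ish parallel within region 1
        # day 2: fish in region 1; day 3: cross into region 2 and fish
        s = TripState.initial("T1", "V1", GeoPoint(-7.5, 2.5), "2001-06-01")
        s = update_trip_state(
            s, _rec("2001-06-02", -5.5, 2.5, ht=20.0, hs=4.0), toy_rs
        )
        s = update_trip_state(
            s,
            _rec("2001-06-03", -5.5, 2.5, ht=2.0, hs=10.0, hf=12.0,
                 sets=(0, 2, 0), catch=(12.0, 3.0, 1.0)),
            toy_rs,
        )
        s = update_trip_state(
            s,
            _rec("2001-06-04", 1.5, 2.5, ht=10.0, hs=6.0, hf=8.0,
                 sets=(0, 0, 1), catch=(5.0, 0.0, 0.0)),
            toy_rs,
        )
        from fleetrum.regions import geodesic_km

        d12 = geodesic_km(GeoPoint(-7.5, 2.5), GeoPoint(-5.5, 2.5))
        d34 = geodesic_km(GeoPoint(-5.5, 2.5), GeoPoint(1.5, 2.5))
        assert s.dist_since_dep == pytest.approx(d12 + d34, abs=1e-9)
        assert s.days_since_dep == 3
        assert s.travel_days_since_dep == pytest.approx((20 + 2 + 10) / 24)
        assert s.search_days_since_dep == pytest.approx((4 + 10 + 6) / 24)
        assert s.catch_since_dep == pytest.approx((17.0, 3.0, 1.0))
        # the region changed on day 3: last-region block holds only day 3
        assert s.current_region == 2
        assert s.travel_days_last == pytest.approx(10 / 24)
        assert s.search_days_last == pytest.approx(6 / 24)
        assert s.sets_last == pytest.approx((0.0, 0.0, 1.0))
        assert s.catch_last == pytest.approx((5.0, 0.0, 0.0))

    def test_activity_days_bounded_by_duration(self, toy_rs):
        s = TripState.initial("T1", "V1", GeoPoint(-5.5, 2.5), "2001-06-01")
        for d in range(2, 6):
            s = update_trip_state(
                s, _rec(f"2001-06-{d:02d}", -5.5, 2.5, ht=6.0, hs=10.0, hf=8.0), toy_rs
            )
        assert s.days_since_dep == 4
        assert s.travel_days_since_dep + s.search_days_since_dep <= s.days_since_dep + 1e-9

    def test_out_of_order_record_rejected(self, toy_rs):
        s = TripState.initial("T1", "V1", GeoPoint(-5.5, 2.5), "2001-06-05")
        with pytest.raises(ValueError, match="out-of-order"):
            update_trip_state(s, _rec("2001-06-05", -5.5, 2.5), toy_rs)


class TestBuildOccasions:
    def test_counts_and_uniqueness(self, compact_ds):
        occs = compact_ds.occasions()
        n_trips = compact_ds.logs["trip_id"].nunique()
        first = [o for o in occs if o.stage == "first"]
        assert len(first) == n_trips  # every trip makes at least one set
        # switch occasions: one per set day after the first set day
        logs = compact_ds.logs
        sets = logs[["sets_DEL", "sets_OBJ", "sets_NOA"]].sum(axis=1)
        n_set_days = int((sets > 0).sum())
        assert len(occs) == n_set_days  # first day + later set days
        for o in occs:
            assert 1 <= o.chosen <= compact_ds.region_set.R

    def test_single_set_trip(self, compact_ds):
        logs = compact_ds.logs
        trip_id = logs["trip_id"].iloc[0]
        trip = logs[logs["trip_id"] == trip_id].copy()
        sets = trip[["sets_DEL", "sets_OBJ", "sets_NOA"]].sum(axis=1)
        first_set_idx = sets[sets.values > 0].index[0]
        truncated = trip.loc[:first_set_idx]
        occs = build_choice_occasions(
            truncated,
            compact_ds.region_set,
            compact_ds.grids,
            compact_ds.stats,
            compact_ds.prices,
            compact_ds.mei,
            compact_ds.registry,
            thresholds=compact_ds.thresholds,
            feature_config=compact_ds.scenario.feature_config,
            env_counts=compact_ds.env_counts,
        )
        assert len(occs) == 1 and occs[0].stage == "first"

    def test_trip_without_sets_skipped_with_warning(self, compact_ds):
        logs = compact_ds.logs
        trip_id = logs["trip_id"].iloc[0]
        trip = logs[logs["trip_id"] == trip_id].copy()
        for col in ("sets_DEL", "sets_OBJ", "sets_NOA"):
            trip[col] = 0
        with pytest.warns(UserWarning, match="no sets"):
            occs = build_choice_occasions(
                trip,
                compact_ds.region_set,
                compact_ds.grids,
                compact_ds.stats,
                compact_ds.prices,
                compact_ds.mei,
                compact_ds.registry,
                thresholds=compact_ds.thresholds,
                feature_config=compact_ds.scenario.feature_config,
                env_counts=compact_ds.env_counts,
            )
        assert occs == []

    def test_csv_round_trip_is_bit_identical(self, compact_ds):
        csv = compact_ds.logs_csv()
        logs2 = pd.read_csv(io.StringIO(csv))
        occs1 = compact_ds.occasions()
        occs2 = build_choice_occasions(
            logs2,
            compact_ds.region_set,
            compact_ds.grids,
            compact_ds.stats,
            compact_ds.prices,
            compact_ds.mei,
            compact_ds.registry,
            thresholds=compact_ds.thresholds,
            feature_config=compact_ds.scenario.feature_config,
            env_counts=compact_ds.env_counts,
        )
        assert len(occs1) == len(occs2)
        for a, b in zip(occs1, occs2):
            assert a.occasion_id == b.occasion_id and a.chosen == b.chosen
            assert np.array_equal(a.X, b.X) and np.array_equal(a.Z, b.Z)


class TestRegionMonthStats:
    def test_permutation_invariance(self, toy_rs):
        prices = _prices()
        rows = [
            _rec("2001-05-03", -5.5, 2.5, hf=12.0, catch=(10, 2, 0)) | {"trip_id": "A", "vessel_id": "V1"},
            _rec("2001-05-10", -4.5, 3.5, hf=24.0, catch=(4, 4, 1)) | {"trip_id": "B", "vessel_id": "V2"},
            _rec("2001-05-20", -3.5, 1.5, hf=6.0, catch=(0, 8, 0)) | {"trip_id": "C", "vessel_id": "V3"},
        ]
        df = pd.DataFrame(rows)
        s1 = region_month_stats(df, toy_rs, prices)
        s2 = region_month_stats(df.iloc[::-1].reset_index(drop=True), toy_rs, prices)
        pd.testing.assert_frame_equal(
            s1.sort_values(["month", "region_id"]).reset_index(drop=True),
            s2.sort_values(["month", "region_id"]).reset_index(drop=True),
        )

    def test_lag_attachment(self, toy_rs):
        prices = _prices()
        df = pd.DataFrame(
            [_rec("2001-05-03", -5.5, 2.5, hf=24.0, catch=(10, 0, 0))
             | {"trip_id": "A", "vessel_id": "V1"}]
        )
        stats = region_month_stats(df, toy_rs, prices)
        assert list(stats["month"].astype(str)) == ["2001-06"]
        assert stats["cpue_lag1"].iloc[0] == pytest.approx(
            math.log(10.0 / 1.0001 + 1e-4)
        )


class TestPriceSeries:
    def test_bet_premium(self):
        p = _prices()
        yftp, skjp, betp = p.get(pd.Period("2001-05", freq="M"))
        assert betp == skjp + 100.0

    def test_nonpositive_prices_rejected(self):
        idx = pd.PeriodIndex(["2001-05"], freq="M")
        with pytest.raises(ValueError):
            PriceSeries(pd.DataFrame({"YFTP": [0.0], "SKJP": [900.0]}, index=idx))
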