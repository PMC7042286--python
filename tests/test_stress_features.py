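"""Unit and property tests of the stage-windowed stress features."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from maizestress import stress_features as sf
from .conftest import make_weather


def _day(offset, base=dt.date(2015, 5, 1)):
    return base + dt.timedelta(days=offset)


class TestSplitStages:
    @pytest.mark.parametrize(
        "gsl, bounds",
        [
            (100, (0, 30, 50, 75, 100)),
            (170, (0, 51, 85, 128, 170)),  # 127.5 rounds half-to-even
            (4, (0, 1, 2, 3, 4)),
        ],
    )
    def test_boundaries_at_stage_fractions(self, gsl, bounds):
        windows = sf.split_stages(_day(0), _day(gsl))
        assert windows.bounds == bounds

    def test_too_short_season_rejected(self):
        with pytest.raises(ValueError, match="four stages"):
            sf.split_stages(_day(0), _day(3))

    @given(gsl=st.integers(min_value=4, max_value=400))
    def test_windows_partition_the_season(self, gsl):
        windows = sf.split_stages(_day(0), _day(gsl))
        assert sum(windows.lengths) == gsl
        assert all(length >= 1 for length in windows.lengths)
        starts_ends = list(windows)
        assert starts_ends[0][0] == 0 and starts_ends[-1][1] == gsl
        for (_, e_prev), (s_next, _) in zip(starts_ends, starts_ends[1:]):
            assert e_prev == s_next


def _brute_force_longest_run(mask):
    best = run = 0
    for value in mask:
        run = run + 1 if value else 0
        best = max(best, run)
    return best


class TestLongestRun:
    @pytest.mark.parametrize(
        "mask, expected",
        [
            ([False, True, True, False, True, True, True], 3),
            ([False] * 6, 0),
            ([True] * 9, 9),
            ([], 0),
        ],
    )
    def test_known_series(self, mask, expected):
        assert sf.longest_run(mask) == expected

    @given(st.lists(st.booleans(), max_size=80))
    def test_matches_brute_force_enumeration(self, mask):
        assert sf.longest_run(mask) == _brute_force_longest_run(mask)


class TestEdd:
    def test_hand_sum_of_exceedances(self):
        assert sf.edd([32.0, 31.0, 29.0]) == pytest.approx(3.0)

    def test_no_exceedance_gives_zero(self):
        assert sf.edd([30.0, 25.0, 18.0]) == 0.0

    def test_linearity_above_threshold(self):
        tmax = np.array([33.0, 29.0, 31.0, 35.0, 30.0])
        hot = tmax > 30.0
        bumped = np.where(hot, tmax + 1.0, tmax)
        assert sf.edd(bumped) == pytest.approx(sf.edd(tmax) + hot.sum())


class TestHtc:
    def test_stated_formula_hand_value(self):
        # 60 mm over 30 days at constant Tavg 20 C: 60 / (0.1 * 600) = 1
        precip = np.full(30, 2.0)
        tavg = np.full(30, 20.0)
        assert sf.htc(precip, tavg) == pytest.approx(1.0)

    def test_zero_precipitation(self):
        assert sf.htc(np.zeros(10), np.full(10, 15.0)) == 0.0

    def test_undefined_when_no_warm_days(self):
        assert np.isnan(sf.htc(np.full(10, 3.0), np.full(10, 8.0)))

    def test_strictly_increasing_in_precip_sum(self):
        tavg = np.full(20, 18.0)
        low = sf.htc(np.full(20, 1.0), tavg)
        high = sf.htc(np.full(20, 1.5), tavg)
        assert high > low


class TestVpd:
    def test_saturated_air_gives_zero(self):
        tmax, tmin = np.full(5, 30.0), np.full(5, 20.0)
        ea = sf.saturation_vapour_pressure((tmax + tmin) / 2)
        assert sf.vpd(tmax, tmin, ea) == 0.0

    def test_magnus_hand_value(self):
        # Tmean 25 C: es = 610.78*exp(17.27*25/262.3) = 3167.67 Pa
        out = sf.vpd(np.full(4, 30.0), np.full(4, 20.0), np.full(4, 2000.0))
        assert out == pytest.approx(11.6767, abs=1e-3)

    def test_drier_air_never_decreases_vpd(self):
        tmax, tmin = np.full(6, 28.0), np.full(6, 16.0)
        ea = np.full(6, 2400.0)
        assert sf.vpd(tmax, tmin, ea / 2) >= sf.vpd(tmax, tmin, ea)

    def test_monotone_in_tmax(self):
        ea = np.full(6, 1500.0)
        cool = sf.vpd(np.full(6, 27.0), np.full(6, 15.0), ea)
        warm = sf.vpd(np.full(6, 29.0), np.full(6, 15.0), ea)
        assert warm >= cool


class TestExtractFeatures:
    SOIL = dict(sand=30.0, clay=30.0, silt=40.0, ph=6.5, om=2.0, cec=15.0,
                awc=0.12, ksat=10.0)

    def test_benign_season_zeroes_all_stress(self):
        # cool, saturated, daily-rain season: every stress metric vanishes
        n = 40
        tmax = np.full(n, 24.0)
        tmin = np.full(n, 14.0)
        ea = sf.saturation_vapour_pressure((tmax + tmin) / 2)
        weather = make_weather("2015-05-01", tmax, tmin,
                               precip=np.full(n, 5.0), vapour_pressure=ea)
        fv = sf.extract_features(weather, _day(0), _day(n), self.SOIL)
        for stage in range(1, 5):
            for metric in ("EDD", "CTD", "CTN", "CDD", "VPD"):
                assert fv[f"{metric}{stage}"] == 0.0

    def test_feature_vector_layout(self):
        weather = make_weather("2015-05-01", np.full(30, 26.0))
        fv = sf.extract_features(weather, _day(0), _day(30), self.SOIL)
        assert list(fv.index) == sf.ALL_FEATURES
        assert len(sf.MET_FEATURES) == 26
        assert len(fv) == 34

    def test_toy_season_matches_independent_recomputation(self):
        # 20-day season, stages [0,6), [6,10), [10,15), [15,20)
        rng = np.random.default_rng(42)
        tmax = rng.uniform(24.0, 36.0, 20)
        tmin = tmax - rng.uniform(8.0, 14.0, 20)
        precip = np.where(rng.random(20) < 0.5, rng.uniform(0.0, 12.0, 20), 0.0)
        ea = rng.uniform(800.0, 2500.0, 20)
        weather = make_weather("2015-06-01", tmax, tmin, precip, ea)
        fv = sf.extract_features(
            weather, dt.date(2015, 6, 1), dt.date(2015, 6, 21), self.SOIL
        )
        bounds = [0, 6, 10, 15, 20]
        for stage in range(4):
            s, e = bounds[stage], bounds[stage + 1]
            assert fv[f"EDD{stage+1}"] == pytest.approx(
                sum(max(0.0, t - 30.0) for t in tmax[s:e]))
            assert fv[f"CTD{stage+1}"] == _brute_force_longest_run(
                list(tmax[s:e] > 30.0))
            assert fv[f"CTN{stage+1}"] == _brute_force_longest_run(
                list(tmin[s:e] > 20.0))
            assert fv[f"PS{stage+1}"] == pytest.approx(precip[s:e].sum())
            assert fv[f"CDD{stage+1}"] == _brute_force_longest_run(
                list(precip[s:e] < 1.0))
            tmean = (tmax[s:e] + tmin[s:e]) / 2.0
            es = 610.78 * np.exp(17.27 * tmean / (tmean + 237.3))
            assert fv[f"VPD{stage+1}"] == pytest.approx(
                np.clip(es - ea[s:e], 0, None).mean() / 100.0)
            if stage + 1 in (2, 3):
                warm = tmean[tmean > 10.0]
                assert fv[f"HTC{stage+1}"] == pytest.approx(
                    precip[s:e].sum() / (0.1 * warm.sum()))

    def test_weather_gap_is_reported(self):
        weather = make_weather("2015-05-01", np.full(30, 26.0))
        weather = weather.drop(index=[10, 11])
        with pytest.raises(sf.MissingWeatherError, match="2015-05-11"):
            sf.extract_features(weather, _day(0), _day(30), self.SOIL)

    def test_missing_soil_descriptor_rejected(self):
        weather = make_weather("2015-05-01", np.full(30, 26.0))
        soil = {k: v for k, v in self.SOIL.items() if k != "ph"}
        with pytest.raises(KeyError, match="ph"):
            sf.extract_features(weather, _day(0), _day(30), soil)


class TestImputeMissing:
    def test_htc_imputed_with_column_median(self):
        table = pd.DataFrame({"HTC2": [1.0, np.nan, 3.0], "PS1": [1.0, 2.0, 3.0]})
        out = sf.impute_missing(table)
        assert out["HTC2"].tolist() == [1.0, 2.0, 3.0]
        assert not out.isna().any().any()
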