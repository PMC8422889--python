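import calendar

import numpy as np
import pandas as pd
import pytest

from ringsense.climate import (
    MonthlyClimate,
    count_spring_frost,
    monthly_aggregate,
    seasonal_covariates,
    spei,
    thornthwaite_pet,
)
from ringsense.ring_io import DailyClimate
from ringsense.synthetic_data import generate_climate

from conftest import make_monthly_frame


def daily_frame(year, month, tmin, tmean, precip):
    ndays = calendar.monthrange(year, month)[1]
    dates = pd.date_range(f"{year}-{month:02d}-01", periods=ndays, freq="D")
    return pd.DataFrame(
        {"date": dates, "tmin": np.resize(tmin, ndays),
         "tmean": np.resize(tmean, ndays), "precip": np.resize(precip, ndays)}
    )


class TestMonthlyAggregate:
    def test_no_frost_above_zero(self):
        daily = DailyClimate(daily_frame(2000, 1, 1.0, 3.0, 0.0))
        m = monthly_aggregate(daily)
        assert m.frame.loc[0, "frost_days"] == 0

    def test_exactly_zero_is_not_frost(self):
        daily = DailyClimate(daily_frame(2000, 1, 0.0, 2.0, 0.0))
        m = monthly_aggregate(daily)
        assert m.frame.loc[0, "frost_days"] == 0

    def test_hand_computed_fixture(self):
        tmin = np.full(31, 2.0)
        tmin[:5] = -2.0
        precip = np.zeros(31)
        precip[[3, 10, 20]] = [4.0, 2.5, 1.5]
        daily = DailyClimate(daily_frame(2000, 1, tmin, np.full(31, 5.0), precip))
        m = monthly_aggregate(daily)
        row = m.frame.iloc[0]
        assert row["frost_days"] == 5
        assert row["precip"] == pytest.approx(8.0)
        assert row["tmean"] == pytest.approx(5.0)

    def test_incomplete_month_rejected(self):
        frame = daily_frame(2000, 1, 1.0, 2.0, 0.0).iloc[:20]
        with pytest.raises(ValueError, match="2000-01"):
            monthly_aggregate(DailyClimate(frame))

    def test_frost_translation_covariance(self):
        tmin = np.full(31, -1.0)
        daily = DailyClimate(daily_frame(2000, 1, tmin, np.full(31, 1.0), 0.0))
        assert monthly_aggregate(daily).frame.loc[0, "frost_days"] == 31
        shifted = DailyClimate(daily_frame(2000, 1, tmin + 10, np.full(31, 11.0), 0.0))
        assert monthly_aggregate(shifted).frame.loc[0, "frost_days"] == 0


class TestSpringFrost:
    def test_march_plus_april(self):
        df = make_monthly_frame([2000])
        df.loc[df["month"] == 3, "frost_days"] = 3
        df.loc[df["month"] == 4, "frost_days"] = 2
        out = count_spring_frost(MonthlyClimate(df))
        assert out[2000] == 5

    def test_frost_free_year_is_zero(self):
        out = count_spring_frost(MonthlyClimate(make_monthly_frame([2000])))
        assert out[2000] == 0

    def test_missing_month_omits_year_with_warning(self):
        df = make_monthly_frame([2000])
        df = df[df["month"] != 4]
        with pytest.warns(UserWarning, match="2000"):
            out = count_spring_frost(MonthlyClimate(df))
        assert 2000 not in out.index


# frozen hand evaluation of the closed form: T=10 degC all year, lat 52.25
_PET_ORACLE = {
    1: 33.5799, 2: 36.3877, 3: 48.4764, 4: 55.6113, 5: 65.1580, 6: 67.2671,
    7: 67.7068, 8: 60.8926, 9: 50.4503, 10: 43.4405, 11: 34.4192, 12: 31.5156,
}


class TestThornthwaite:
    def test_subzero_months_have_zero_pet(self):
        df = make_monthly_frame([2001], tmean=-5.0)
        df.loc[df["month"].isin([6, 7]), "tmean"] = 15.0  # keep heat index > 0
        out = thornthwaite_pet(MonthlyClimate(df), 52.25)
        cold = out.frame[out.frame["tmean"] < 0]
        assert (cold["pet"] == 0).all()

    def test_equator_varies_only_with_month_length(self):
        df = make_monthly_frame([2001], tmean=20.0)
        out = thornthwaite_pet(MonthlyClimate(df), 0.0)
        pet = out.frame.set_index("month")["pet"]
        days = {m: calendar.monthrange(2001, m)[1] for m in range(1, 13)}
        per_day = np.array([pet[m] / days[m] for m in range(1, 13)])
        assert np.allclose(per_day, per_day[0], rtol=1e-6)

    def test_matches_hand_oracle(self):
        df = make_monthly_frame([2001], tmean=10.0)
        out = thornthwaite_pet(MonthlyClimate(df), 52.25)
        pet = out.frame.set_index("month")["pet"]
        for m, expect in _PET_ORACLE.items():
            assert pet[m] == pytest.approx(expect, abs=1e-3)

    def test_monotone_in_temperature(self):
        base = make_monthly_frame([2001], tmean=10.0)
        warm = make_monthly_frame([2001], tmean=12.0)
        p0 = thornthwaite_pet(MonthlyClimate(base), 52.25).frame["pet"]
        p1 = thornthwaite_pet(MonthlyClimate(warm), 52.25).frame["pet"]
        assert (p1 >= p0).all()

    def test_all_cold_year_warns(self):
        df = make_monthly_frame([2001], tmean=-3.0)
        with pytest.warns(UserWarning, match="PET = 0"):
            out = thornthwaite_pet(MonthlyClimate(df), 52.25)
        assert (out.frame["pet"] == 0).all()


def synthetic_monthly(seed=3, years=(1974, 2017)):
    rng = np.random.default_rng(seed)
    rows = []
    for yr in range(years[0], years[1] + 1):
        for mo in range(1, 13):
            precip = rng.gamma(4.0, 18.0)
            pet = max(30 + 25 * np.cos(2 * np.pi * (mo - 7) / 12) + rng.normal(0, 5), 0)
            rows.append({"year": yr, "month": mo, "tmean": 10.0, "precip": precip,
                         "frost_days": 0, "pet": pet, "d": precip - pet})
    return MonthlyClimate(pd.DataFrame(rows))


class TestSpei:
    def test_calibration_mean_zero_sd_one(self):
        mc = synthetic_monthly()
        s = spei(mc, 3, (1974, 2017)).dropna()
        g = s.groupby(s.index.get_level_values(1))
        assert (g.mean().abs() < 0.05).all()
        assert ((g.std(ddof=1) - 1).abs() < 0.05).all()

    def test_three_month_window_locality(self):
        mc = synthetic_monthly()
        s0 = spei(mc, 3, (1974, 2017))
        df = mc.frame.copy()
        may = (df["year"] == 1990) & (df["month"] == 5)
        df.loc[may, "precip"] += 100.0
        df.loc[may, "d"] += 100.0
        s1 = spei(MonthlyClimate(df), 3, (1974, 2017))
        assert s1[(1990, 8)] == pytest.approx(s0[(1990, 8)])
        assert s1[(1990, 7)] != pytest.approx(s0[(1990, 7)])

    def test_monotone_in_summer_balance(self):
        # perturb a year outside the calibration window so the fitted
        # distribution (and hence every other year's index) is unchanged
        mc = synthetic_monthly(years=(1974, 2018))
        s0 = spei(mc, 3, (1974, 2017))
        df = mc.frame.copy()
        sel = (df["year"] == 2018) & (df["month"].isin([6, 7, 8]))
        df.loc[sel, "precip"] += 30.0
        df.loc[sel, "d"] += 30.0
        s1 = spei(MonthlyClimate(df), 3, (1974, 2017))
        assert s1[(2018, 8)] > s0[(2018, 8)]
        assert s1[(2017, 8)] == pytest.approx(s0[(2017, 8)])

    def test_location_shift_invariance(self):
        mc = synthetic_monthly()
        s0 = spei(mc, 3, (1974, 2017))
        df = mc.frame.copy()
        df["d"] += 55.0
        df["precip"] += 55.0  # keep d = precip - pet consistent
        s1 = spei(MonthlyClimate(df), 3, (1974, 2017))
        pd.testing.assert_series_equal(s0.dropna(), s1.dropna(), atol=1e-8, rtol=0)

    def test_leading_window_undefined(self):
        mc = synthetic_monthly()
        s = spei(mc, 3)
        assert s[(1974, 1)] != s[(1974, 1)]  # NaN
        assert np.isfinite(s[(1974, 3)])

    def test_constant_balance_rejected(self):
        df = make_monthly_frame([2000, 2001, 2002, 2003, 2004], pet=20.0)
        with pytest.raises(ValueError, match="constant"):
            spei(MonthlyClimate(df), 3)


class TestSeasonalCovariates:
    def test_previous_summer_is_lagged_current(self):
        mc = synthetic_monthly()
        s = spei(mc, 3, (1974, 2017))
        cov = seasonal_covariates(mc, s)
        df = cov.frame.set_index("year")
        assert df.loc[1975, "prev_summer_spei"] == pytest.approx(
            df.loc[1974, "summer_spei"]
        )

    def test_winter_temperature_day_weighted(self):
        df = make_monthly_frame([2001])  # non-leap year
        df.loc[df["month"] == 1, "tmean"] = 0.0
        df.loc[df["month"] == 2, "tmean"] = 0.0
        df.loc[df["month"] == 3, "tmean"] = 3.0
        mc = MonthlyClimate(df)
        fake_spei = pd.Series(0.0, index=mc.series("tmean").index)
        cov = seasonal_covariates(mc, fake_spei)
        wt = cov.frame.set_index("year").loc[2001, "winter_temp"]
        assert wt == pytest.approx(93.0 / 90.0)

    def test_first_year_flagged_incomplete(self):
        mc = synthetic_monthly()
        s = spei(mc, 3, (1974, 2017))
        cov = seasonal_covariates(mc, s)
        first = cov.frame.iloc[0]
        assert not first["complete"]
        assert cov.frame.iloc[1]["complete"]

    def test_generator_frost_bookkeeping(self):
        daily = generate_climate((1990, 1995), seed=5)
        m = monthly_aggregate(daily)
        df = daily.frame
        df = df[(df["date"].dt.year == 1992) & (df["date"].dt.month.isin([3, 4]))]
        planted = int((df["tmin"] < 0).sum())
        out = count_spring_frost(m)
        assert out[1992] == planted
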