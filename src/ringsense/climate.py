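"""Climate covariates for climate-growth analysis.

From a validated daily station record this module derives, in order:

1. monthly aggregates (mean temperature, precipitation total, frost-day
   count, with frost defined strictly as ``tmin < 0`` degC);
2. monthly potential evapotranspiration (PET) by the Thornthwaite
   temperature/daylength method;
3. the climate-water balance ``d = precip - pet`` (mm) and its k-month
   standardized index (SPEI), fitted per calendar month with a
   three-parameter log-logistic distribution by unbiased probability-
   weighted moments and mapped to a standard normal scale;
4. the four per-year seasonal regression covariates: spring frost-day
   count (March-April), current and previous summer 3-month SPEI (the
   June-August balance, read at August), and mean winter temperature
   (January-March, day-weighted).

Season boundaries, SPEI scale and calibration window are all arguments so
monthly exploratory analyses are not constrained by the seasonal defaults.
"""

from __future__ import annotations

import calendar
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ring_io import DailyClimate, SchemaError

__all__ = [
    "MonthlyClimate",
    "SeasonalCovariates",
    "monthly_aggregate",
    "count_spring_frost",
    "daylength_hours",
    "thornthwaite_pet",
    "add_pet",
    "spei",
    "seasonal_covariates",
    "derive_covariates",
]


@dataclass
class MonthlyClimate:
    """Monthly climate table indexed by (year, month).

    Columns: ``tmean`` (degC), ``precip`` (mm/month), ``frost_days``
    (count of days with tmin < 0 degC), and once PET has been attached,
    ``pet`` (mm/month) and ``d`` = precip - pet (mm).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        for col in ("year", "month", "tmean", "precip", "frost_days"):
            if col not in df.columns:
                raise SchemaError(f"monthly climate missing column {col!r}")
        if "pet" in df.columns:
            if (df["pet"] < 0).any():
                raise ValueError("PET must be non-negative")
            if "d" in df.columns and not np.allclose(df["d"], df["precip"] - df["pet"]):
                raise ValueError("d must equal precip - pet exactly")
        self.frame = df.reset_index(drop=True)

    def series(self, col: str) -> pd.Series:
        """Column as a Series indexed by (year, month)."""
        return self.frame.set_index(["year", "month"])[col]

    @property
    def years(self) -> np.ndarray:
        return np.unique(self.frame["year"].to_numpy())


# ---------------------------------------------------------------------------
# Monthly aggregation
# ---------------------------------------------------------------------------

def monthly_aggregate(daily: DailyClimate, missing_tolerance: int = 0) -> MonthlyClimate:
    """Aggregate a daily record to calendar months.

    ``tmean`` is the mean of daily means, ``precip`` the monthly total and
    ``frost_days`` the count of days whose minimum dropped strictly below
    0 degC (a day at exactly 0 is not a frost day).  Months missing more
    than ``missing_tolerance`` days are rejected.
    """
    df = daily.frame.copy()
    df["year"] = df["date"].dt.year
    df["month"] = df["date"].dt.month
    rows = []
    for (yr, mo), grp in df.groupby(["year", "month"], sort=True):
        ndays = calendar.monthrange(int(yr), int(mo))[1]
        if ndays - len(grp) > missing_tolerance:
            raise ValueError(
                f"month {int(yr)}-{int(mo):02d} has {len(grp)} of {ndays} days"
            )
        rows.append(
            {
                "year": int(yr),
                "month": int(mo),
                "tmean": float(grp["tmean"].mean()),
                "precip": float(grp["precip"].sum()),
                "frost_days": int((grp["tmin"] < 0.0).sum()),
            }
        )
    return MonthlyClimate(pd.DataFrame(rows))


def count_spring_frost(
    monthly: MonthlyClimate, months: tuple[int, ...] = (3, 4)
) -> pd.Series:
    """Per-year frost-day count summed over the given months (default Mar+Apr).

    Years missing any of the requested months are omitted with a warning.
    """
    df = monthly.frame
    out = {}
    for yr in monthly.years:
        sub = df[(df["year"] == yr) & (df["month"].isin(months))]
        if len(sub) < len(months):
            warnings.warn(f"year {yr}: spring months incomplete, omitted", stacklevel=2)
            continue
        out[int(yr)] = int(sub["frost_days"].sum())
    return pd.Series(out, name="spring_frost", dtype=int)


# ---------------------------------------------------------------------------
# Thornthwaite PET
# ---------------------------------------------------------------------------

def daylength_hours(month: int, latitude_deg: float, year: int = 2001) -> float:
    """Mean daylength (h) for a month from solar declination at mid-month."""
    ndays = calendar.monthrange(year, month)[1]
    doy = int(sum(calendar.monthrange(year, m)[1] for m in range(1, month)) + ndays / 2)
    decl = np.deg2rad(23.45) * np.sin(2.0 * np.pi * (284 + doy) / 365.0)
    lat = np.deg2rad(latitude_deg)
    cos_h = -np.tan(lat) * np.tan(decl)
    cos_h = min(1.0, max(-1.0, float(cos_h)))
    return 24.0 / np.pi * np.arccos(cos_h)


def thornthwaite_pet(monthly: MonthlyClimate, latitude_deg: float) -> MonthlyClimate:
    """Attach Thornthwaite monthly PET and the climate-water balance.

    For each calendar year the annual heat index is
    ``I = sum((T_m/5)**1.514)`` over months with ``T_m > 0``; the exponent
    is ``a = 6.75e-7*I**3 - 7.71e-5*I**2 + 1.792e-2*I + 0.49239``; then
    ``PET_m = 16*(10*T_m/I)**a * daylength/12 * days/30`` mm, and PET = 0
    for months at or below freezing.  Requires complete 12-month years.
    """
    if abs(latitude_deg) >= 66.5:
        raise ValueError("Thornthwaite daylength geometry requires |latitude| < 66.5 deg")
    df = monthly.frame.copy()
    counts = df.groupby("year")["month"].count()
    bad = counts[counts != 12]
    if len(bad):
        raise ValueError(f"incomplete year(s) for PET: {bad.index.tolist()}")
    pet = np.zeros(len(df))
    for yr, grp in df.groupby("year"):
        t = grp["tmean"].to_numpy(dtype=float)
        months = grp["month"].to_numpy(dtype=int)
        pos = t > 0.0
        heat = float(np.sum((t[pos] / 5.0) ** 1.514))
        if heat == 0.0:
            warnings.warn(f"year {yr}: all months at or below 0 degC; PET = 0", stacklevel=2)
            continue
        a = 6.75e-7 * heat**3 - 7.71e-5 * heat**2 + 1.792e-2 * heat + 0.49239
        for i, (tm, mo) in enumerate(zip(t, months)):
            if tm <= 0.0:
                continue
            ndays = calendar.monthrange(int(yr), int(mo))[1]
            dl = daylength_hours(int(mo), latitude_deg, int(yr))
            pet[grp.index[i]] = 16.0 * (10.0 * tm / heat) ** a * (dl / 12.0) * (ndays / 30.0)
    df["pet"] = pet
    df["d"] = df["precip"] - df["pet"]
    return MonthlyClimate(df)


add_pet = thornthwaite_pet


# ---------------------------------------------------------------------------
# SPEI
# ---------------------------------------------------------------------------

def _unbiased_pwm(x: np.ndarray) -> tuple[float, float, float]:
    """First three unbiased probability-weighted moments b0, b1, b2."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    i = np.arange(1, n + 1, dtype=float)
    b0 = x.mean()
    b1 = float(np.sum((i - 1) / (n - 1) * x) / n)
    b2 = float(np.sum((i - 1) * (i - 2) / ((n - 1) * (n - 2)) * x) / n)
    return b0, b1, b2


def _loglogistic_params(x: np.ndarray) -> tuple[float, float, float]:
    """Fit the three-parameter log-logistic by unbiased PWMs / L-moments.

    The generalized-logistic parameterization ``(kappa, alpha, xi)`` is
    used (Hosking's L-moment fit: ``kappa = -tau3``), which is the
    log-logistic for positively skewed samples and extends it smoothly to
    the occasional left-skewed monthly balance sample.  Returns
    ``(kappa, alpha, xi)``.
    """
    b0, b1, b2 = _unbiased_pwm(x)
    l1 = b0
    l2 = 2.0 * b1 - b0
    l3 = 6.0 * b2 - 6.0 * b1 + b0
    if l2 <= 0:
        raise ValueError("degenerate sample for log-logistic fit (L-scale <= 0)")
    kappa = -l3 / l2
    if abs(kappa) >= 1.0:
        raise ValueError(f"L-skewness {l3 / l2:.3f} outside the fittable range")
    if abs(kappa) < 1e-8:
        return 0.0, l2, l1  # logistic limit
    gk = kappa * np.pi / np.sin(kappa * np.pi)  # = Gamma(1+k)Gamma(1-k)
    alpha = l2 / gk
    xi = l1 - alpha * (1.0 / kappa - gk / kappa)
    return kappa, alpha, xi


def _loglogistic_cdf(x: np.ndarray, kappa: float, alpha: float, xi: float) -> np.ndarray:
    """CDF of the generalized-logistic / log-logistic distribution."""
    x = np.asarray(x, dtype=float)
    if kappa == 0.0:
        y = (x - xi) / alpha
    else:
        t = 1.0 - kappa * (x - xi) / alpha
        y = np.empty_like(x)
        pos = t > 0
        y[pos] = -np.log(t[pos]) / kappa
        y[~pos] = np.inf if kappa > 0 else -np.inf
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-y))


def _normal_quantile(p: np.ndarray) -> np.ndarray:
    """Standard normal quantile by the classical rational approximation."""
    p = np.asarray(p, dtype=float)
    lower = p <= 0.5
    pp = np.where(lower, p, 1.0 - p)
    pp = np.clip(pp, 1e-12, 0.5)
    w = np.sqrt(-2.0 * np.log(pp))
    num = 2.515517 + 0.802853 * w + 0.010328 * w**2
    den = 1.0 + 1.432788 * w + 0.189269 * w**2 + 0.001308 * w**3
    z = w - num / den
    return np.where(lower, -z, z)


def spei(
    monthly: MonthlyClimate,
    scale_months: int = 3,
    calibration: tuple[int, int] | None = None,
) -> pd.Series:
    """k-month standardized precipitation-evapotranspiration index.

    The balance ``d = precip - pet`` is summed over the ``scale_months``
    window ending at each month; for each calendar month separately a
    three-parameter log-logistic distribution is fitted to the calibration
    years by unbiased PWMs, and its CDF values are mapped through the
    standard normal quantile.  Within the calibration period each calendar
    month's index then has mean ~0 and sd ~1 by construction.

    Returns a Series indexed by (year, month); the first ``scale_months-1``
    months of the record, where the window is incomplete, are NaN.
    """
    if scale_months < 1:
        raise ValueError("scale_months must be >= 1")
    d = monthly.series("d").sort_index()
    vals = d.to_numpy(dtype=float)
    if len(vals) < scale_months:
        raise ValueError("record shorter than the aggregation scale")
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    agg = np.full(len(vals), np.nan)
    agg[scale_months - 1 :] = csum[scale_months:] - csum[: -scale_months]
    dk = pd.Series(agg, index=d.index, name=f"d{scale_months}")

    years = dk.index.get_level_values(0)
    if calibration is None:
        calibration = (int(years.min()), int(years.max()))
    out = pd.Series(np.nan, index=dk.index, name="spei")
    for mo in range(1, 13):
        mask = dk.index.get_level_values(1) == mo
        if not mask.any():
            continue
        sub = dk[mask].dropna()
        cal = sub[
            (sub.index.get_level_values(0) >= calibration[0])
            & (sub.index.get_level_values(0) <= calibration[1])
        ]
        if len(cal) < 4:
            raise ValueError(f"calendar month {mo}: fewer than 4 calibration values")
        if np.ptp(cal.to_numpy()) == 0:
            raise ValueError(f"calendar month {mo}: constant aggregated balance")
        kappa, alpha, xi = _loglogistic_params(cal.to_numpy())
        cdf = _loglogistic_cdf(sub.to_numpy(dtype=float), kappa, alpha, xi)
        cdf = np.clip(cdf, 1e-6, 1.0 - 1e-6)
        out.loc[sub.index] = _normal_quantile(cdf)
    return out


# ---------------------------------------------------------------------------
# Seasonal covariates
# ---------------------------------------------------------------------------

@dataclass
class SeasonalCovariates:
    """Per-year regression covariates.

    Columns: ``spring_frost`` (days), ``summer_spei`` and
    ``prev_summer_spei`` (dimensionless), ``winter_temp`` (degC),
    ``complete`` (False where any covariate is undefined, e.g. the first
    year's previous-summer index).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"year", "spring_frost", "summer_spei", "prev_summer_spei", "winter_temp"}
        missing = need - set(self.frame.columns)
        if missing:
            raise SchemaError(f"seasonal covariates missing: {sorted(missing)}")
        if "complete" not in self.frame.columns:
            self.frame = self.frame.assign(
                complete=~self.frame[list(need - {"year"})].isna().any(axis=1)
            )
        self.frame = self.frame.reset_index(drop=True)

    def over(self, period: tuple[int, int]) -> pd.DataFrame:
        df = self.frame
        return df[(df["year"] >= period[0]) & (df["year"] <= period[1])].reset_index(drop=True)


def seasonal_covariates(
    monthly: MonthlyClimate,
    spei_series: pd.Series,
    frost_months: tuple[int, ...] = (3, 4),
    winter_months: tuple[int, ...] = (1, 2, 3),
    summer_month: int = 8,
) -> SeasonalCovariates:
    """Assemble the per-year seasonal covariate table.

    Winter temperature is the mean of the winter months' ``tmean`` weighted
    by days in month; the summer index is the k-month SPEI read at
    ``summer_month`` (August by default, i.e. the June-August balance).
    """
    df = monthly.frame
    tmean = monthly.series("tmean")
    rows = []
    for yr in monthly.years:
        yr = int(yr)
        frost = np.nan
        sub = df[(df["year"] == yr) & (df["month"].isin(frost_months))]
        if len(sub) == len(frost_months):
            frost = float(sub["frost_days"].sum())
        wt = np.nan
        if all((yr, m) in tmean.index for m in winter_months):
            wdays = np.array([calendar.monthrange(yr, m)[1] for m in winter_months], float)
            wvals = np.array([tmean.loc[(yr, m)] for m in winter_months], float)
            wt = float(np.sum(wvals * wdays) / wdays.sum())
        ss = float(spei_series.get((yr, summer_month), np.nan))
        rows.append(
            {"year": yr, "spring_frost": frost, "summer_spei": ss, "winter_temp": wt}
        )
    out = pd.DataFrame(rows).sort_values("year").reset_index(drop=True)
    out["prev_summer_spei"] = out["summer_spei"].shift(1)
    out = out[["year", "spring_frost", "summer_spei", "prev_summer_spei", "winter_temp"]]
    return SeasonalCovariates(out)


def derive_covariates(
    daily: DailyClimate,
    latitude_deg: float,
    scale_months: int = 3,
    calibration: tuple[int, int] | None = None,
) -> tuple[MonthlyClimate, pd.Series, SeasonalCovariates]:
    """Daily record -> (monthly with PET, SPEI series, seasonal covariates)."""
    monthly = thornthwaite_pet(monthly_aggregate(daily), latitude_deg)
    s = spei(monthly, scale_months=scale_months, calibration=calibration)
    return monthly, s, seasonal_covariates(monthly, s)
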