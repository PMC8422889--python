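"""Bootstrapped monthly climate-growth correlations.

For each species chronology, every monthly climate variable from June of
the year before ring formation through September of the formation year
(16 lagged months) is paired with the ring-width index, and the Pearson
correlation of each pair is bootstrapped (years resampled with
replacement).  A cell is flagged significant when the percentile
confidence interval excludes zero, the standard convention for
dendroclimatic correlation screens.

Month columns are labelled lower-case for previous-year months and
upper-case for current-year months (``jun .. dec, JAN .. SEP``).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate import MonthlyClimate
from .detrend import Chronology

__all__ = [
    "WINDOW_MONTHS",
    "GRID_VARIABLES",
    "CorrelationGrid",
    "align_window",
    "bootstrap_correlation",
    "correlation_grid",
    "species_rng",
]

#: (calendar month, lag in years, label); previous June through current September.
WINDOW_MONTHS: list[tuple[int, int, str]] = [
    *[(m, -1, lab) for m, lab in zip(range(6, 13), ["jun", "jul", "aug", "sep", "oct", "nov", "dec"])],
    *[(m, 0, lab) for m, lab in zip(range(1, 10), ["JAN", "FEB", "MAR", "APR", "MAY", "JUN", "JUL", "AUG", "SEP"])],
]

GRID_VARIABLES = ("frost_days", "tmean", "pet", "precip", "spei")


@dataclass
class CorrelationGrid:
    """Bootstrap correlation summary per (climate variable, window month)."""

    species_code: str
    frame: pd.DataFrame  # variable, month_label, r_mean, ci_low, ci_high, significant

    def __post_init__(self) -> None:
        df = self.frame.dropna(subset=["r_mean"])  # degenerate cells carry NaN
        if not ((df["ci_low"] <= df["r_mean"] + 1e-12) & (df["r_mean"] <= df["ci_high"] + 1e-12)).all():
            raise ValueError("confidence bounds must bracket the bootstrap mean")

    def cell(self, variable: str, month_label: str) -> pd.Series:
        df = self.frame
        row = df[(df["variable"] == variable) & (df["month_label"] == month_label)]
        if row.empty:
            raise KeyError((variable, month_label))
        return row.iloc[0]


def align_window(
    chronology: Chronology,
    monthly: MonthlyClimate,
    spei_series: pd.Series | None = None,
    variables: tuple[str, ...] = GRID_VARIABLES,
) -> tuple[np.ndarray, np.ndarray, dict[tuple[str, str], np.ndarray]]:
    """Pair chronology years with the 16 lagged monthly values per variable.

    Returns ``(years, tri, columns)`` where ``columns`` maps
    ``(variable, month_label)`` to the aligned value vector.  Only years
    with a complete window for every requested variable are kept.
    """
    tables: dict[str, pd.Series] = {}
    for var in variables:
        if var == "spei":
            if spei_series is None:
                raise ValueError("spei requested but no SPEI series supplied")
            tables[var] = spei_series
        else:
            tables[var] = monthly.series(var)

    rows: list[int] = []
    cols: dict[tuple[str, str], list[float]] = {
        (var, lab): [] for var in variables for _, _, lab in WINDOW_MONTHS
    }
    for i, yr in enumerate(chronology.years):
        yr = int(yr)
        vals: dict[tuple[str, str], float] = {}
        ok = True
        for var in variables:
            tab = tables[var]
            for mo, lag, lab in WINDOW_MONTHS:
                key = (yr + lag, mo)
                v = tab.get(key, np.nan)
                if v is None or (isinstance(v, float) and np.isnan(v)):
                    ok = False
                    break
                vals[(var, lab)] = float(v)
            if not ok:
                break
        if ok:
            rows.append(i)
            for key, v in vals.items():
                cols[key].append(v)
    if len(rows) < 10:
        raise ValueError(
            f"{chronology.species_code}: only {len(rows)} complete chronology/climate "
            "years; need at least 10"
        )
    years = chronology.years[rows]
    tri = chronology.tri_mean[rows]
    return years, tri, {k: np.asarray(v) for k, v in cols.items()}


def bootstrap_correlation(
    x: np.ndarray,
    y: np.ndarray,
    n_boot: int = 1000,
    level: float = 0.95,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float, float, bool]:
    """Bootstrap the Pearson correlation of paired samples.

    Pairs are resampled with replacement ``n_boot`` times; returns the
    bootstrap mean r, the percentile interval at ``level`` and whether the
    interval excludes zero.  Degenerate resamples (zero variance, possible
    for sparse count variables) yield no correlation and are dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in correlation input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in correlation input")
    rng = np.random.default_rng(rng)
    idx = rng.integers(0, n, size=(n_boot, n))
    xs, ys = x[idx], y[idx]
    xs = xs - xs.mean(axis=1, keepdims=True)
    ys = ys - ys.mean(axis=1, keepdims=True)
    denom = np.sqrt((xs**2).sum(axis=1) * (ys**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xs * ys).sum(axis=1) / denom
    r = r[np.isfinite(r)]
    if len(r) == 0:
        raise ValueError("all bootstrap resamples degenerate")
    alpha = 1.0 - level
    lo, hi = np.quantile(r, [alpha / 2.0, 1.0 - alpha / 2.0])
    r_mean = float(r.mean())
    significant = bool(lo > 0.0 or hi < 0.0)
    return r_mean, float(lo), float(hi), significant


def species_rng(seed: int, species_code: str) -> np.random.Generator:
    """Deterministic per-species random stream (order-independent runs)."""
    return np.random.default_rng([seed, zlib.crc32(species_code.encode())])


def correlation_grid(
    chronology: Chronology,
    monthly: MonthlyClimate,
    spei_series: pd.Series | None = None,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    variables: tuple[str, ...] = GRID_VARIABLES,
) -> CorrelationGrid:
    """Bootstrap correlation grid: ``variables`` x 16 window months."""
    _, tri, cols = align_window(chronology, monthly, spei_series, variables)
    rng = species_rng(seed, chronology.species_code)
    records = []
    for var in variables:
        for _, _, lab in WINDOW_MONTHS:
            x = cols[(var, lab)]
            if np.ptp(x) == 0:
                # e.g. a frost-free summer month: no variation, no correlation
                records.append(
                    dict(variable=var, month_label=lab, r_mean=np.nan,
                         ci_low=np.nan, ci_high=np.nan, significant=False)
                )
                continue
            r_mean, lo, hi, sig = bootstrap_correlation(x, tri, n_boot, level, rng)
            records.append(
                dict(variable=var, month_label=lab, r_mean=r_mean,
                     ci_low=lo, ci_high=hi, significant=sig)
            )
    return CorrelationGrid(chronology.species_code, pd.DataFrame(records))
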