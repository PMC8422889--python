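"""Age-detrending of ring-width series and chronology building.

The non-climatic age/size trend of each ring-width series is estimated with
a cubic smoothing spline whose frequency response passes 50 % of a signal's
amplitude at a chosen period (default 15 years).  Dividing raw widths by the
fitted trend gives the dimensionless tree-ring index (TRI), centred near 1.
Per-species chronologies are the year-by-year Tukey biweight robust mean of
the individual TRI series, which strengthens the shared climatic signal
while damping tree-level noise.

Spline parameterization
-----------------------
A penalized natural cubic smoothing spline on the integer year grid acts as
a linear low-pass filter.  For penalty weight ``lam`` its amplitude response
at angular frequency ``w = 2*pi/period`` is, away from the edges,

    A(w) = 1 / (1 + lam * 3 * (2 - 2*cos w)**2 / (2 + cos w))

(the discrete symbol of the integrated-squared-curvature penalty).  The
smoothing weight is therefore solved in closed form so that
``A(2*pi/cutoff) = response`` — the contract is the transfer function, not a
particular stiffness constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solveh_banded

from .ring_io import RingSeries

__all__ = [
    "TriSeries",
    "Chronology",
    "spline_lambda",
    "fit_spline_trend",
    "detrend_ratio",
    "biweight_mean",
    "combine_cores",
    "build_chronology",
    "detrend_series",
]


@dataclass
class TriSeries:
    """Dimensionless ring-width index for one core or tree (mean ~ 1)."""

    series_id: str
    years: np.ndarray
    tri: np.ndarray
    species_code: str = ""
    tree_id: str = ""

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.tri = np.asarray(self.tri, dtype=float)
        if self.years.shape != self.tri.shape:
            raise ValueError("years and tri must have equal length")
        if not np.all(np.isfinite(self.tri)) or np.any(self.tri < 0):
            raise ValueError("tri values must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.years)


@dataclass
class Chronology:
    """Per-species mean TRI time series with sample depth.

    ``sd_tri`` — the standard deviation of the chronology over a stated
    period — is carried as a summary of the species' overall year-to-year
    growth variability (an omnibus indicator of climate sensitivity).
    """

    species_code: str
    years: np.ndarray
    tri_mean: np.ndarray
    sample_depth: np.ndarray
    sd_tri: float = float("nan")
    sd_period: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.tri_mean = np.asarray(self.tri_mean, dtype=float)
        self.sample_depth = np.asarray(self.sample_depth, dtype=int)
        if not (len(self.years) == len(self.tri_mean) == len(self.sample_depth)):
            raise ValueError("chronology columns must have equal length")
        if np.any(self.sample_depth < 1):
            raise ValueError("sample depth must be >= 1")

    def __len__(self) -> int:
        return len(self.years)


# ---------------------------------------------------------------------------
# Smoothing spline
# ---------------------------------------------------------------------------

def spline_lambda(cutoff_years: float, response: float = 0.5) -> float:
    """Penalty weight giving amplitude ``response`` at period ``cutoff_years``."""
    if cutoff_years < 2:
        raise ValueError("cutoff must be >= 2 years")
    if not 0 < response < 1:
        raise ValueError("response must be in (0, 1)")
    w = 2.0 * np.pi / cutoff_years
    symbol = 3.0 * (2.0 - 2.0 * np.cos(w)) ** 2 / (2.0 + np.cos(w))
    return (1.0 - response) / response / symbol


def fit_spline_trend(
    series: RingSeries,
    cutoff_years: float = 15.0,
    response: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit the age trend of a ring-width series.

    Returns ``(trend, flagged_years)``: the fitted per-year trend (mm) and
    the calendar years (possibly empty) where the fit is non-positive and
    the ratio index is undefined.
    """
    if len(series) < 4:
        raise ValueError(f"{series.series_id}: need >= 4 rings to fit a trend")
    lam = spline_lambda(cutoff_years, response)
    trend = _smooth(series.trw, lam)
    flagged = series.years[trend <= 0]
    return trend, flagged


def _smooth(y: np.ndarray, lam: float) -> np.ndarray:
    """Natural cubic smoothing spline values on the unit grid (Reinsch form).

    Solves ``min ||y - s||^2 + lam * s' Q R^-1 Q' s`` via the Woodbury
    identity ``s = y - lam Q (R + lam Q'Q)^-1 Q'y``; the inner matrix is
    symmetric pentadiagonal, solved in banded form.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    # Q'y: second differences of y
    qty = y[:-2] - 2.0 * y[1:-1] + y[2:]
    m = n - 2
    ab = np.zeros((3, m))
    ab[0, 2:] = lam                       # second superdiagonal of R + lam Q'Q
    ab[1, 1:] = 1.0 / 6.0 - 4.0 * lam     # first superdiagonal
    ab[2, :] = 2.0 / 3.0 + 6.0 * lam      # diagonal
    u = solveh_banded(ab, qty)
    s = y.copy()
    s[:-2] -= lam * u
    s[1:-1] += 2.0 * lam * u
    s[2:] -= lam * u
    return s


def detrend_ratio(series: RingSeries, trend: np.ndarray) -> TriSeries:
    """Divide raw widths by the fitted trend, giving the TRI series."""
    trend = np.asarray(trend, dtype=float)
    if trend.shape != series.trw.shape:
        raise ValueError("trend and series must cover the same years")
    bad = series.years[trend <= 0]
    if len(bad):
        raise ValueError(
            f"{series.series_id}: non-positive trend in year(s) "
            + ", ".join(str(y) for y in bad)
        )
    return TriSeries(
        series_id=series.series_id,
        years=series.years,
        tri=series.trw / trend,
        species_code=series.species_code,
        tree_id=series.tree_id,
    )


def detrend_series(
    series: RingSeries,
    cutoff_years: float = 15.0,
    response: float = 0.5,
) -> TriSeries:
    """Fit the spline trend and return the ratio index, dropping flagged years.

    Years where the fitted trend is non-positive (possible near suppressed
    series ends) are removed with a warning rather than clamped.
    """
    trend, flagged = fit_spline_trend(series, cutoff_years, response)
    if len(flagged):
        warnings.warn(
            f"{series.series_id}: dropping {len(flagged)} year(s) with "
            f"non-positive spline trend: {flagged.tolist()}",
            stacklevel=2,
        )
        keep = trend > 0
        return TriSeries(
            series_id=series.series_id,
            years=series.years[keep],
            tri=series.trw[keep] / trend[keep],
            species_code=series.species_code,
            tree_id=series.tree_id,
        )
    return detrend_ratio(series, trend)


# ---------------------------------------------------------------------------
# Robust averaging
# ---------------------------------------------------------------------------

def biweight_mean(values, c: float = 9.0, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Tukey biweight robust location estimate.

    Iterates the biweight-weighted mean from a median start, with the scale
    fixed at ``c`` times the median absolute deviation about the median.
    Falls back to the median when the MAD is zero (no scale information).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("biweight_mean of empty input")
    if not np.all(np.isfinite(x)):
        raise ValueError("biweight_mean requires finite values")
    if x.size == 1:
        return float(x[0])
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    if mad == 0.0:
        return med
    scale = c * mad
    loc = med
    for _ in range(max_iter):
        u = (x - loc) / scale
        w = np.zeros_like(x)
        inside = np.abs(u) < 1.0
        w[inside] = (1.0 - u[inside] ** 2) ** 2
        new = float(np.sum(w * x) / np.sum(w))
        if abs(new - loc) < tol:
            loc = new
            break
        loc = new
    return loc


def combine_cores(tris: list[TriSeries], tree_id: str | None = None) -> TriSeries:
    """Average a tree's per-core TRI series into one tree-level series.

    Cores are detrended individually *before* averaging; the tree-level
    index in any year is the plain mean of the cores present that year.
    """
    if not tris:
        raise ValueError("no core series to combine")
    if len(tris) == 1:
        t = tris[0]
        return TriSeries(t.series_id, t.years, t.tri, t.species_code, tree_id or t.tree_id)
    years = np.unique(np.concatenate([t.years for t in tris]))
    acc = np.zeros(len(years))
    cnt = np.zeros(len(years), dtype=int)
    for t in tris:
        idx = np.searchsorted(years, t.years)
        acc[idx] += t.tri
        cnt[idx] += 1
    tid = tree_id or tris[0].tree_id
    return TriSeries(
        series_id=tid,
        years=years,
        tri=acc / cnt,
        species_code=tris[0].species_code,
        tree_id=tid,
    )


def build_chronology(
    tris: list[TriSeries],
    species_code: str | None = None,
    c: float = 9.0,
    sd_period: tuple[int, int] | None = None,
) -> Chronology:
    """Build a species chronology as the per-year biweight mean of TRI series.

    ``sd_period`` selects the years over which the chronology's standard
    deviation (``sd_tri``) is computed; by default the period where every
    contributing series overlaps (falling back to the full span when the
    series do not all overlap).
    """
    if not tris:
        raise ValueError("no TRI series supplied")
    species = species_code or tris[0].species_code
    years = np.unique(np.concatenate([t.years for t in tris]))
    per_year: dict[int, list[float]] = {int(y): [] for y in years}
    for t in tris:
        for y, v in zip(t.years, t.tri):
            per_year[int(y)].append(float(v))
    if len(tris) > 1:
        overlap = [y for y in years if len(per_year[int(y)]) > 1]
        if not overlap:
            raise ValueError(f"{species}: series share no overlapping years")
    tri_mean = np.array([biweight_mean(per_year[int(y)], c=c) for y in years])
    depth = np.array([len(per_year[int(y)]) for y in years], dtype=int)

    if sd_period is None:
        full = depth == len(tris)
        sel = full if full.any() else np.ones(len(years), bool)
        period = (int(years[sel][0]), int(years[sel][-1]))
    else:
        period = (int(sd_period[0]), int(sd_period[1]))
    in_period = (years >= period[0]) & (years <= period[1])
    sd = float(np.std(tri_mean[in_period], ddof=1)) if in_period.sum() > 1 else float("nan")
    return Chronology(
        species_code=species,
        years=years,
        tri_mean=tri_mean,
        sample_depth=depth,
        sd_tri=sd,
        sd_period=period,
    )
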