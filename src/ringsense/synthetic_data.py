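"""Synthetic study-system generator with known ground truth.

Emulates the data a multi-species common-garden tree-ring study rests on,
so every pipeline stage can be exercised end to end with no external data:

* a daily maritime-temperate climate record (annual temperature sinusoid
  with AR(1) weather noise, seasonal diurnal range so frost days cluster
  in late winter/early spring, gamma-distributed rainfall tuned to about
  10 degC and 830 mm per year);
* ring-width panels for a list of species with a declining age trend
  (modified negative exponential), species-specific linear responses to
  the standardized seasonal climate covariates on the log scale, per-tree
  random effects, multiplicative year noise and two cores per tree;
* Brownian-motion traits on a phylogeny, and random ultrametric trees.

Every generated dataset carries a :class:`SyntheticTruth` record of the
parameters that produced it, and regeneration from the same (config, seed)
is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .climate import SeasonalCovariates, derive_covariates
from .phylosignal import PhyloCov, phylo_vcv
from .ring_io import (
    DailyClimate,
    PhyloTree,
    RingSeries,
    read_newick,
    write_daily_climate,
    write_newick,
    write_rwl,
)

__all__ = [
    "ClimateParams",
    "SpeciesSpec",
    "SyntheticTruth",
    "generate_climate",
    "generate_rings",
    "simulate_bm_traits",
    "random_ultrametric_newick",
    "generate_study_fixture",
]


# ---------------------------------------------------------------------------
# Climate
# ---------------------------------------------------------------------------

@dataclass
class ClimateParams:
    """Daily climate model parameters (defaults approximate the study region)."""

    mean_temp: float = 10.1          # degC, annual mean
    seasonal_amp: float = 7.5        # degC, sinusoid amplitude (peak mid-July)
    peak_doy: float = 200.0
    ar1_phi: float = 0.7             # day-to-day persistence of weather noise
    ar1_sd: float = 1.8              # innovation sd, degC
    diurnal_base: float = 2.5        # tmean - tmin offset, degC
    diurnal_amp: float = 2.0         # extra offset in winter (peak mid-Jan)
    diurnal_peak_doy: float = 15.0
    tmin_noise_sd: float = 1.5       # half-normal extra depression of tmin
    wet_prob: float = 0.60
    rain_shape: float = 2.0
    rain_scale: float = 1.9          # mm; annual total ~ 365*0.6*2*1.9 ~ 830


def generate_climate(
    years: tuple[int, int],
    seed: int | np.random.Generator = 0,
    params: ClimateParams | None = None,
) -> DailyClimate:
    """Generate a daily climate record for calendar years ``years`` inclusive."""
    p = params or ClimateParams()
    if years[1] - years[0] < 1:
        raise ValueError("need at least 2 years of climate")
    if not (0 <= p.wet_prob <= 1) or p.rain_shape <= 0 or p.rain_scale <= 0:
        raise ValueError("invalid precipitation parameters")
    rng = np.random.default_rng(seed)
    dates = pd.date_range(f"{years[0]}-01-01", f"{years[1]}-12-31", freq="D")
    doy = dates.day_of_year.to_numpy(dtype=float)
    n = len(dates)

    season = p.mean_temp + p.seasonal_amp * np.cos(
        2.0 * np.pi * (doy - p.peak_doy) / 365.25
    )
    noise = np.empty(n)
    innov = rng.normal(0.0, p.ar1_sd, size=n)
    noise[0] = innov[0] / np.sqrt(max(1.0 - p.ar1_phi**2, 1e-9))
    for i in range(1, n):
        noise[i] = p.ar1_phi * noise[i - 1] + innov[i]
    tmean = season + noise

    offset = p.diurnal_base + p.diurnal_amp * np.cos(
        2.0 * np.pi * (doy - p.diurnal_peak_doy) / 365.25
    )
    tmin = tmean - np.maximum(offset, 0.0) - np.abs(rng.normal(0.0, p.tmin_noise_sd, n))

    wet = rng.random(n) < p.wet_prob
    precip = np.where(wet, rng.gamma(p.rain_shape, p.rain_scale, size=n), 0.0)

    return DailyClimate(
        pd.DataFrame(
            {
                "date": dates,
                "tmin": np.round(tmin, 2),
                "tmean": np.round(tmean, 2),
                "precip": np.round(precip, 2),
            }
        )
    )


# ---------------------------------------------------------------------------
# Ring widths
# ---------------------------------------------------------------------------

@dataclass
class SpeciesSpec:
    """Ground-truth growth model for one species.

    ``betas`` are log-scale responses per standard deviation of each
    seasonal covariate (so TRI ~ exp(beta * z) ~ 1 + beta * z for the
    magnitudes used here); the age trend is
    ``trend(age) = a * exp(-b * age) + c`` mm.
    """

    code: str
    betas: dict[str, float]
    trend_a: float = 2.5
    trend_b: float = 0.06
    trend_c: float = 0.8

    def trend(self, age: np.ndarray) -> np.ndarray:
        return self.trend_a * np.exp(-self.trend_b * np.asarray(age, float)) + self.trend_c


@dataclass
class SyntheticTruth:
    """Record of every parameter behind a generated dataset."""

    seed: int
    species: list[SpeciesSpec]
    sigma_tree: float
    sigma_year: float
    sigma_core: float
    tree_effects: dict[str, float] = field(default_factory=dict)
    z_covariates: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "sigma_tree": self.sigma_tree,
            "sigma_year": self.sigma_year,
            "sigma_core": self.sigma_core,
            "species": [dataclasses.asdict(s) for s in self.species],
            "tree_effects": self.tree_effects,
            "extra": self.extra,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _zscore_covariates(covariates: SeasonalCovariates, years: np.ndarray) -> pd.DataFrame:
    cols = ["spring_frost", "summer_spei", "prev_summer_spei", "winter_temp"]
    df = covariates.frame
    df = df[df["year"].isin(years)].dropna(subset=cols).reset_index(drop=True)
    missing = sorted(set(years) - set(df["year"]))
    if missing:
        raise ValueError(f"covariates do not cover ring years: {missing}")
    z = df[["year"]].copy()
    for c in cols:
        sd = df[c].std(ddof=1)
        if sd == 0:
            raise ValueError(f"covariate {c} constant over simulation years")
        z[c] = (df[c] - df[c].mean()) / sd
    return z


def generate_rings(
    species_specs: list[SpeciesSpec],
    n_trees: int,
    years: tuple[int, int],
    covariates: SeasonalCovariates,
    seed: int | np.random.Generator = 0,
    sigma_tree: float = 0.10,
    sigma_year: float = 0.08,
    sigma_core: float | None = None,
    cores_per_tree: int = 2,
) -> tuple[list[RingSeries], SyntheticTruth]:
    """Simulate ring-width cores with known climate responses.

    ``log TRW(t) = log(trend(age)) + sum_k beta_k z_k(t) + u_tree + eps(t)``
    with ``u_tree ~ N(0, sigma_tree^2)`` and ``eps ~ N(0, sigma_year^2)``;
    each of the ``cores_per_tree`` cores adds independent multiplicative
    noise of sd ``sigma_core`` (default a tenth of ``sigma_year``).
    """
    rng = np.random.default_rng(seed)
    if sigma_core is None:
        sigma_core = 0.1 * sigma_year
    yr = np.arange(years[0], years[1] + 1)
    z = _zscore_covariates(covariates, yr)
    zmat = z.set_index("year").loc[yr, ["spring_frost", "summer_spei", "prev_summer_spei", "winter_temp"]].to_numpy()
    ages = np.arange(1, len(yr) + 1)

    series: list[RingSeries] = []
    tree_effects: dict[str, float] = {}
    for spec in species_specs:
        beta = np.array(
            [
                spec.betas.get("spring_frost", 0.0),
                spec.betas.get("summer_spei", 0.0),
                spec.betas.get("prev_summer_spei", 0.0),
                spec.betas.get("winter_temp", 0.0),
            ]
        )
        signal = zmat @ beta
        log_trend = np.log(spec.trend(ages))
        for t in range(1, n_trees + 1):
            tree_id = f"{spec.code}{t:02d}"
            u = rng.normal(0.0, sigma_tree)
            tree_effects[tree_id] = u
            eps = rng.normal(0.0, sigma_year, size=len(yr))
            log_tree = log_trend + signal + u + eps
            for c in range(cores_per_tree):
                core_noise = rng.normal(0.0, sigma_core, size=len(yr))
                trw = np.exp(log_tree + core_noise)
                series.append(
                    RingSeries(
                        series_id=f"{tree_id}{chr(ord('A') + c)}",
                        years=yr,
                        trw=np.round(trw, 3),
                        species_code=spec.code,
                        tree_id=tree_id,
                        to_pith=True,
                    )
                )
    truth = SyntheticTruth(
        seed=int(seed) if isinstance(seed, (int, np.integer)) else -1,
        species=list(species_specs),
        sigma_tree=sigma_tree,
        sigma_year=sigma_year,
        sigma_core=sigma_core,
        tree_effects=tree_effects,
        z_covariates=z,
    )
    return series, truth


# ---------------------------------------------------------------------------
# Phylogeny and traits
# ---------------------------------------------------------------------------

def random_ultrametric_newick(
    labels: list[str],
    rng: np.random.Generator | int | None = None,
    depth: float = 100.0,
) -> str:
    """Random binary ultrametric tree over ``labels`` (root-to-tip = depth)."""
    rng = np.random.default_rng(rng)
    nodes: list[tuple[str, float]] = [(lab, 0.0) for lab in labels]  # (newick, height)
    height = 0.0
    while len(nodes) > 1:
        height += float(rng.exponential(1.0))
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (nwk_j, h_j) = nodes.pop(j)
        (nwk_i, h_i) = nodes.pop(i)
        merged = f"({nwk_i}:{height - h_i:.6f},{nwk_j}:{height - h_j:.6f})"
        nodes.append((merged, height))
    nwk, h = nodes[0]
    scale = depth / h
    # rescale by rewriting branch lengths
    import re

    nwk = re.sub(r":(\d+\.\d+)", lambda m: f":{float(m.group(1)) * scale:.6f}", nwk)
    return nwk + ";"


def simulate_bm_traits(
    tree: PhyloTree | PhyloCov,
    sigma2: float = 1.0,
    n_reps: int = 1,
    seed: int | np.random.Generator = 0,
) -> tuple[list[str], np.ndarray]:
    """Simulate Brownian-motion traits: rows ~ MVN(0, sigma2 * C).

    Returns ``(species_order, traits)`` with ``traits`` of shape
    ``(n_reps, n_tips)``.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    cov = tree if isinstance(tree, PhyloCov) else phylo_vcv(tree)
    rng = np.random.default_rng(seed)
    n = len(cov.species)
    if sigma2 == 0:
        return cov.species, np.zeros((n_reps, n))
    L = np.linalg.cholesky(sigma2 * cov.C)
    Z = rng.standard_normal((n_reps, n))
    return cov.species, Z @ L.T


# ---------------------------------------------------------------------------
# Full fixture bundle
# ---------------------------------------------------------------------------

def _default_species_specs(n_species: int, rng: np.random.Generator) -> list[SpeciesSpec]:
    codes = [f"SP{chr(ord('A') + i)}{chr(ord('A') + i)}" for i in range(n_species)]
    specs = []
    for code in codes:
        betas = {
            "spring_frost": float(rng.uniform(-0.10, 0.02)),
            "summer_spei": float(rng.uniform(0.02, 0.08)),
            "prev_summer_spei": float(rng.uniform(-0.03, 0.06)),
            "winter_temp": float(rng.uniform(-0.04, 0.10)),
        }
        specs.append(
            SpeciesSpec(
                code=code,
                betas=betas,
                trend_a=float(rng.uniform(1.8, 3.2)),
                trend_b=float(rng.uniform(0.04, 0.09)),
                trend_c=float(rng.uniform(0.6, 1.2)),
            )
        )
    return specs


def generate_study_fixture(
    seed: int,
    outdir: str | Path,
    scale: str = "small",
    latitude: float = 52.25,
) -> dict:
    """Write a complete synthetic study bundle to ``outdir``.

    ``scale='small'`` gives 6 species x 5 trees x 50 years,
    ``scale='full'`` 19 species x 10 trees x 60 years.  Files written:
    ``rings.rwl``, ``daily_climate.csv``, ``tree.nwk`` (species tips plus
    an ``OUTG`` outgroup), ``wood_density.csv`` and ``truth.json``.
    Returns a manifest dict with paths and the in-memory objects.
    """
    if scale == "small":
        n_species, n_trees, n_years = 6, 5, 50
    elif scale == "full":
        n_species, n_trees, n_years = 19, 10, 60
    else:
        raise ValueError("scale must be 'small' or 'full'")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(seed)
    s_clim, s_rings, s_tree, s_dens = master.spawn(4)

    ring_years = (2018 - n_years + 1, 2018)
    clim_years = (ring_years[0] - 2, ring_years[1])
    daily = generate_climate(clim_years, seed=np.random.default_rng(s_clim))
    _, _, covs = derive_covariates(daily, latitude)

    rng_rings = np.random.default_rng(s_rings)
    specs = _default_species_specs(n_species, rng_rings)
    series, truth = generate_rings(
        specs, n_trees, ring_years, covs, seed=rng_rings
    )
    truth.seed = seed

    codes = [sp.code for sp in specs]
    nwk = random_ultrametric_newick(codes + ["OUTG"], rng=np.random.default_rng(s_tree))

    rng_dens = np.random.default_rng(s_dens)
    density = pd.DataFrame(
        {"species_code": codes, "density": np.round(rng_dens.uniform(350, 650, n_species), 1)}
    )

    paths = {
        "rwl": outdir / "rings.rwl",
        "daily": outdir / "daily_climate.csv",
        "tree": outdir / "tree.nwk",
        "density": outdir / "wood_density.csv",
        "truth": outdir / "truth.json",
    }
    write_rwl(series, paths["rwl"], precision=0.001)
    write_daily_climate(daily, paths["daily"])
    paths["tree"].write_text(nwk + "\n")
    density.to_csv(paths["density"], index=False)
    truth.extra = {
        "scale": scale,
        "latitude": latitude,
        "ring_years": list(ring_years),
        "climate_years": list(clim_years),
        "n_trees": n_trees,
        "outgroup": "OUTG",
    }
    truth.to_json(paths["truth"])
    return {
        "paths": {k: str(v) for k, v in paths.items()},
        "series": series,
        "daily": daily,
        "covariates": covs,
        "truth": truth,
        "species_codes": codes,
    }
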