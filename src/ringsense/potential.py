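"""Growth-potential proxies and their correlation with climate sensitivity.

Three per-species proxies of inherent growth capacity:

* **diameter growth** (cm/yr): twice the species' fixed radius-vs-cambial-age
  slope over the first 20 years, from a random-slope mixed model (per-tree
  random age slopes);
* **area growth** (cm2/yr): mean basal area increment,
  ``BAI_t = pi * (r_t^2 - r_{t-1}^2)`` assuming a circular cross-section;
* **mass growth** (kg/yr per metre of stem): area growth (m2/yr) times wood
  density (kg/m3).

The proxies are then correlated (Pearson, species as the unit) with the
species' standardized climate-sensitivity coefficients and with the
standard deviation of their chronologies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .detrend import Chronology
from .ring_io import RingSeries
from .sensitivity import SensitivityTable

__all__ = [
    "GrowthPotential",
    "cumulative_radius",
    "growth_potential_slope",
    "basal_area_increment",
    "stem_mass_growth",
    "growth_potential_table",
    "sensitivity_potential_correlation",
]

MM_PER_CM = 10.0
CM2_PER_M2 = 1e4


@dataclass
class GrowthPotential:
    """Per-species growth-potential proxies (all non-negative)."""

    frame: pd.DataFrame  # species_code, diameter_growth, area_growth, mass_growth

    def __post_init__(self) -> None:
        if "species_code" not in self.frame.columns:
            raise ValueError("species_code column required")
        num = self.frame.select_dtypes("number")
        if (num < 0).any().any():
            raise ValueError("growth-potential proxies must be non-negative")
        self.frame = self.frame.reset_index(drop=True)


def cumulative_radius(series: RingSeries) -> pd.DataFrame:
    """Per-year estimated stem radius (mm) and cambial age from summed widths.

    If the series does not reach the pith the radius is offset by the
    unknown missed length; a flag column records this.
    """
    radius = np.cumsum(series.trw)
    return pd.DataFrame(
        {
            "series_id": series.series_id,
            "species_code": series.species_code,
            "tree_id": series.tree_id,
            "year": series.years,
            "age": np.arange(1, len(series) + 1),
            "radius_mm": radius,
            "to_pith": series.to_pith,
        }
    )


def growth_potential_slope(
    series_list: list[RingSeries],
    first_n: int = 20,
    allow_partial: bool = True,
) -> pd.DataFrame:
    """Species diameter growth (cm/yr) over the first ``first_n`` cambial years.

    Fits ``radius ~ species + species:age`` with a per-tree random age slope
    (REML); the species fixed slope (mm radius per year) is doubled and
    converted to cm to give diameter growth.  Trees without ``first_n``
    rings contribute their available early ages when ``allow_partial``;
    species with no usable tree are omitted with a warning.
    """
    frames = []
    for s in series_list:
        cr = cumulative_radius(s)
        cr = cr[cr["age"] <= first_n]
        if len(cr) < first_n and not allow_partial:
            continue
        if len(cr) >= 3:
            frames.append(cr)
    if not frames:
        raise ValueError("no series with usable early-age windows")
    df = pd.concat(frames, ignore_index=True)

    usable = df.groupby("species_code")["tree_id"].nunique()
    species = sorted(usable.index)
    if not species:
        raise ValueError("no species with usable trees")

    fe = _fit_radius_model(df)
    rows = []
    for sp in species:
        slope_mm = float(fe[f"C(species_code)[{sp}]:age"])
        rows.append(
            {
                "species_code": sp,
                "radius_slope_mm": slope_mm,
                "diameter_growth": max(0.0, 2.0 * slope_mm / MM_PER_CM),
                "n_trees": int(usable[sp]),
            }
        )
    return pd.DataFrame(rows)


def _fit_radius_model(df: pd.DataFrame) -> pd.Series:
    """Fixed effects of ``radius ~ species + species:age`` with per-tree
    random age slopes.

    When the between-tree slope variance is (numerically) zero the REML
    fit can become singular; in that case the model degenerates to
    ordinary least squares on the same fixed-effect design, which is then
    used directly.
    """
    formula = "radius_mm ~ 0 + C(species_code) + C(species_code):age"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(formula, df, groups=df["tree_id"], re_formula="0 + age")
            fit = model.fit(reml=True)
            if np.all(np.isfinite(fit.fe_params.to_numpy())):
                return fit.fe_params
        except (np.linalg.LinAlgError, ValueError):
            pass
    warnings.warn(
        "random-slope fit singular (no between-tree slope variance); "
        "falling back to the fixed-effect least-squares solution",
        stacklevel=3,
    )
    return smf.ols(formula, df).fit().params


def basal_area_increment(
    series: RingSeries, window: tuple[int, int] | None = None
) -> tuple[pd.DataFrame, float]:
    """Per-year basal area increment (cm2/yr) and its mean over a window.

    ``BAI_t = pi * (r_t^2 - r_{t-1}^2)`` with radii in cm; for a series
    reaching the pith the increments sum exactly to ``pi * r_final^2``.
    """
    if not series.to_pith:
        warnings.warn(
            f"{series.series_id}: series does not reach the pith; BAI computed "
            "inside-out from the first measured ring (biased low near the pith)",
            stacklevel=2,
        )
    r_cm = np.cumsum(series.trw) / MM_PER_CM
    r_prev = np.concatenate([[0.0], r_cm[:-1]])
    bai = np.pi * (r_cm**2 - r_prev**2)
    df = pd.DataFrame({"year": series.years, "bai": bai})
    if window is not None:
        sel = (df["year"] >= window[0]) & (df["year"] <= window[1])
        mean_bai = float(df.loc[sel, "bai"].mean()) if sel.any() else float("nan")
    else:
        mean_bai = float(df["bai"].mean())
    return df, mean_bai


def stem_mass_growth(area_growth_cm2: float, wood_density_kg_m3: float) -> float:
    """Stem mass growth (kg/yr per m stem): area growth (m2/yr) x density."""
    if wood_density_kg_m3 <= 0:
        raise ValueError("wood density must be positive")
    return area_growth_cm2 / CM2_PER_M2 * wood_density_kg_m3


def growth_potential_table(
    series_list: list[RingSeries],
    wood_density: pd.DataFrame | None = None,
    first_n: int = 20,
    bai_window: tuple[int, int] | None = None,
) -> GrowthPotential:
    """Assemble the species growth-potential table from cores.

    ``wood_density`` is a per-species table (``species_code, density``,
    kg/m3); species without a density get NaN mass growth with a warning.
    Mean BAI is averaged over trees within species (tree-level BAI first,
    to match a per-tree sampling design).
    """
    slope = growth_potential_slope(series_list, first_n=first_n)

    per_tree: dict[tuple[str, str], list[RingSeries]] = {}
    for s in series_list:
        per_tree.setdefault((s.species_code, s.tree_id), []).append(s)
    rows = []
    for (sp, tree), cores in per_tree.items():
        vals = [basal_area_increment(c, window=bai_window)[1] for c in cores]
        vals = [v for v in vals if np.isfinite(v)]
        if vals:
            rows.append({"species_code": sp, "tree_id": tree, "mean_bai": np.mean(vals)})
    bai_sp = (
        pd.DataFrame(rows).groupby("species_code", as_index=False)["mean_bai"].mean()
        .rename(columns={"mean_bai": "area_growth"})
    )

    out = slope.merge(bai_sp, on="species_code", how="outer")
    if wood_density is not None:
        dens = wood_density.set_index("species_code")["density"]
        mass = []
        for _, row in out.iterrows():
            sp = row["species_code"]
            if sp in dens.index and np.isfinite(row.get("area_growth", np.nan)):
                mass.append(stem_mass_growth(float(row["area_growth"]), float(dens[sp])))
            else:
                if sp not in dens.index:
                    warnings.warn(f"{sp}: no wood density; mass growth omitted", stacklevel=2)
                mass.append(np.nan)
        out["mass_growth"] = mass
    else:
        out["mass_growth"] = np.nan
    cols = ["species_code", "diameter_growth", "area_growth", "mass_growth",
            "radius_slope_mm", "n_trees"]
    return GrowthPotential(out[cols])


def sensitivity_potential_correlation(
    sens: SensitivityTable,
    potential: GrowthPotential,
    sd_tri: pd.Series | None = None,
) -> pd.DataFrame:
    """Cross-species Pearson correlations: sensitivity measures x proxies.

    Rows are the four sensitivity coefficients plus (optionally) the
    chronology standard deviation; columns are r and two-sided p for each
    growth-potential proxy.  The unit of analysis is the species.
    """
    sens_df = sens.coefficients.set_index("species_code")
    measures = {
        "spring_frost": sens_df["beta_frost"],
        "current_spei": sens_df["beta_spei_cur"],
        "previous_spei": sens_df["beta_spei_prev"],
        "winter_temp": sens_df["beta_winter"],
    }
    if sd_tri is not None:
        measures["sd_tri"] = sd_tri
    pot_df = potential.frame.set_index("species_code")
    proxies = ["diameter_growth", "area_growth", "mass_growth"]

    rows = []
    for mname, mvals in measures.items():
        row: dict[str, object] = {"sensitivity": mname}
        for proxy in proxies:
            pair = pd.concat([mvals, pot_df[proxy]], axis=1, join="inner").dropna()
            if len(pair) < 3:
                row[f"r_{proxy}"] = np.nan
                row[f"p_{proxy}"] = np.nan
                continue
            a = pair.iloc[:, 0].to_numpy(float)
            b = pair.iloc[:, 1].to_numpy(float)
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                raise ValueError(f"constant column in correlation ({mname} vs {proxy})")
            r, p = stats.pearsonr(a, b)
            row[f"r_{proxy}"] = float(r)
            row[f"p_{proxy}"] = float(p)
            row[f"n_{proxy}"] = len(pair)
        rows.append(row)
    return pd.DataFrame(rows)
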