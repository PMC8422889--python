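"""Species-specific climate sensitivity from a linear mixed model.

Tree-level ring-width index (TRI) is regressed on the four standardized
seasonal climate covariates with species-by-covariate interactions as
fixed effects and a random intercept per tree, fitted by REML.  Cell-means
coding (one intercept and one slope per species and covariate, no
reference level) makes every coefficient directly a species' growth
sensitivity: the expected TRI change per standard deviation of the
covariate.  The response is left unstandardized, so coefficients live on
the TRI scale (typically 0.01-0.13 in magnitude).

Model summaries include per-coefficient Wald tests (normal approximation),
variance inflation factors of the covariates, the marginal and conditional
R2 of the variance-partition formulation, and per-species R2 as the
squared correlation of fixed-effect predictions with observations at both
the individual tree-year and the yearly species-mean (chronology) level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .climate import SeasonalCovariates

__all__ = [
    "COVARIATES",
    "GrowthPanel",
    "SensitivityTable",
    "Standardizer",
    "standardize_covariates",
    "vif",
    "filter_outliers",
    "fit_sensitivity_model",
    "species_r2",
]

COVARIATES = ("spring_frost", "summer_spei", "prev_summer_spei", "winter_temp")

#: short coefficient names used in output tables, keyed by covariate column
BETA_NAMES = {
    "spring_frost": "beta_frost",
    "summer_spei": "beta_spei_cur",
    "prev_summer_spei": "beta_spei_prev",
    "winter_temp": "beta_winter",
}


@dataclass
class GrowthPanel:
    """Long table of tree-level TRI: (species_code, tree_id, year, tri)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        need = {"species_code", "tree_id", "year", "tri"}
        missing = need - set(df.columns)
        if missing:
            raise ValueError(f"growth panel missing column(s): {sorted(missing)}")
        if df.duplicated(["tree_id", "year"]).any():
            raise ValueError("duplicate (tree_id, year) rows in growth panel")
        if (df["tri"] <= 0).any() or not np.all(np.isfinite(df["tri"])):
            raise ValueError("tri must be finite and > 0")
        self.frame = df.reset_index(drop=True)

    def over(self, period: tuple[int, int]) -> "GrowthPanel":
        df = self.frame
        return GrowthPanel(
            df[(df["year"] >= period[0]) & (df["year"] <= period[1])].copy()
        )

    @property
    def species(self) -> list[str]:
        return sorted(self.frame["species_code"].unique())


@dataclass
class SensitivityTable:
    """Per-species standardized coefficients plus fit-level summaries."""

    coefficients: pd.DataFrame  # species_code, beta_*, se_*, p_*, sig_*
    r2_marginal: float
    r2_conditional: float
    var_random: float
    var_residual: float
    vif: pd.Series | None = None
    species_r2: pd.DataFrame | None = None
    residuals: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.coefficients["species_code"].duplicated().any():
            raise ValueError("one row per species expected")
        for r2 in (self.r2_marginal, self.r2_conditional):
            if not (0.0 <= r2 <= 1.0 + 1e-12):
                raise ValueError(f"R2 out of [0, 1]: {r2}")
        if self.r2_marginal > self.r2_conditional + 1e-12:
            raise ValueError("marginal R2 cannot exceed conditional R2")

    def beta(self, species: str, name: str) -> float:
        row = self.coefficients.set_index("species_code").loc[species]
        return float(row[name])


# ---------------------------------------------------------------------------
# Covariate preparation
# ---------------------------------------------------------------------------

@dataclass
class Standardizer:
    """Stored z-score transform (mean, sd per covariate) with inverse."""

    means: pd.Series
    sds: pd.Series

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for col in self.means.index:
            out[col] = (df[col] - self.means[col]) / self.sds[col]
        return out

    def inverse(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for col in self.means.index:
            out[col] = df[col] * self.sds[col] + self.means[col]
        return out


def standardize_covariates(
    covariates: SeasonalCovariates | pd.DataFrame,
    columns: tuple[str, ...] = COVARIATES,
) -> tuple[pd.DataFrame, Standardizer]:
    """Z-score the covariate columns (exact mean 0, sd 1; ddof = 1)."""
    df = covariates.frame if isinstance(covariates, SeasonalCovariates) else covariates
    df = df.dropna(subset=list(columns)).reset_index(drop=True)
    if len(df) < 3:
        raise ValueError("need at least 3 complete years to standardize")
    means = df[list(columns)].mean()
    sds = df[list(columns)].std(ddof=1)
    zero = sds[sds == 0]
    if len(zero):
        raise ValueError(f"constant covariate(s): {', '.join(zero.index)}")
    scaler = Standardizer(means, sds)
    return scaler.transform(df), scaler


def vif(covariates: pd.DataFrame, columns: tuple[str, ...] | None = None) -> pd.Series:
    """Variance inflation factor per covariate: 1 / (1 - R2_j | others)."""
    cols = list(columns) if columns else list(covariates.columns)
    if len(cols) < 2:
        raise ValueError("VIF needs at least two covariates")
    X = covariates[cols].to_numpy(dtype=float)
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more observations than covariates")
    out = {}
    for j, col in enumerate(cols):
        y = X[:, j]
        others = np.column_stack([np.ones(len(X)), np.delete(X, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        if r2 >= 1.0 - 1e-12:
            warnings.warn(f"perfect collinearity for {col}; VIF infinite", stacklevel=2)
            out[col] = np.inf
        else:
            out[col] = 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def filter_outliers(panel: GrowthPanel, k: float = 4.0) -> GrowthPanel:
    """Optional ring screen: drop rows with |TRI - 1| > k * sd(TRI).

    Off by default in the pipeline; the retained/removed counts are logged
    by the caller.
    """
    df = panel.frame
    sd = float(df["tri"].std(ddof=1))
    keep = (df["tri"] - 1.0).abs() <= k * sd
    return GrowthPanel(df[keep].copy())


# ---------------------------------------------------------------------------
# Mixed model
# ---------------------------------------------------------------------------

def fit_sensitivity_model(
    panel: GrowthPanel,
    z_covariates: pd.DataFrame,
    covariate_columns: tuple[str, ...] = COVARIATES,
    alpha: float = 0.05,
) -> SensitivityTable:
    """Fit the random-intercept species-by-climate mixed model by REML.

    ``z_covariates`` must contain ``year`` plus the standardized covariate
    columns.  Species observed in different year windows are handled by the
    merge (each species' rows keep only its own years).
    """
    df = panel.frame.merge(
        z_covariates[["year", *covariate_columns]], on="year", how="inner"
    ).dropna(subset=list(covariate_columns))
    n_species = df["species_code"].nunique()
    if n_species < 2:
        raise ValueError("need at least 2 species")
    trees_per_species = df.groupby("species_code")["tree_id"].nunique()
    if (trees_per_species < 2).any():
        raise ValueError("need at least 2 trees per species")

    terms = " + ".join(f"C(species_code):{c}" for c in covariate_columns)
    formula = f"tri ~ 0 + C(species_code) + {terms}"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["tree_id"])
        fit = model.fit(reml=True)

    fe = fit.fe_params
    se = fit.bse_fe
    pvals = fit.pvalues[fe.index]

    species = sorted(df["species_code"].unique())
    rows = []
    for sp in species:
        row: dict[str, object] = {"species_code": sp}
        row["intercept"] = float(fe[f"C(species_code)[{sp}]"])
        for col in covariate_columns:
            key = f"C(species_code)[{sp}]:{col}"
            bname = BETA_NAMES.get(col, f"beta_{col}")
            row[bname] = float(fe[key])
            row[f"se_{bname[5:]}"] = float(se[key])
            row[f"p_{bname[5:]}"] = float(pvals[key])
            row[f"sig_{bname[5:]}"] = bool(pvals[key] < alpha)
        rows.append(row)
    coef_table = pd.DataFrame(rows)

    # variance partition R2: fixed / (fixed + random + residual)
    X = model.exog
    fixed_pred = X @ fe.to_numpy()
    var_f = float(np.var(fixed_pred))
    var_re = float(np.asarray(fit.cov_re)[0, 0]) if fit.cov_re.size else 0.0
    var_e = float(fit.scale)
    total = var_f + var_re + var_e
    r2m = var_f / total
    r2c = (var_f + var_re) / total

    df_out = df.copy()
    df_out["predicted"] = fixed_pred
    df_out["residual"] = df_out["tri"] - fixed_pred
    sp_r2 = species_r2(df_out)

    return SensitivityTable(
        coefficients=coef_table,
        r2_marginal=r2m,
        r2_conditional=r2c,
        var_random=var_re,
        var_residual=var_e,
        vif=vif(z_covariates.dropna(subset=list(covariate_columns)), covariate_columns),
        species_r2=sp_r2,
        residuals=df_out[["species_code", "tree_id", "year", "tri", "predicted", "residual"]],
    )


def species_r2(predicted_panel: pd.DataFrame, min_obs: int = 3) -> pd.DataFrame:
    """Squared correlation of predicted vs observed TRI per species.

    Computed (a) over all tree-years of the species ("individual") and
    (b) over yearly species means ("chronology"); species with fewer than
    ``min_obs`` observations are omitted with a warning.
    """
    rows = []
    for sp, grp in predicted_panel.groupby("species_code"):
        if len(grp) < min_obs:
            warnings.warn(f"{sp}: fewer than {min_obs} observations; omitted", stacklevel=2)
            continue
        r_ind = _corr_or_nan(grp["predicted"], grp["tri"])
        by_year = grp.groupby("year")[["predicted", "tri"]].mean()
        r_chr = _corr_or_nan(by_year["predicted"], by_year["tri"])
        rows.append(
            {
                "species_code": sp,
                "r2_individual": r_ind**2 if np.isfinite(r_ind) else np.nan,
                "r2_chronology": r_chr**2 if np.isfinite(r_chr) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _corr_or_nan(a: pd.Series, b: pd.Series) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(stats.pearsonr(a, b)[0])
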