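"""End-to-end orchestration: raw inputs to the five output tables.

``run_full_analysis`` wires the stages together: read ring widths and
climate, detrend and build chronologies, derive climate covariates,
bootstrap the monthly correlation grids, fit the sensitivity mixed model,
compute growth-potential proxies and their cross-species correlations,
and test phylogenetic signal.  Outputs are plain CSVs with the full run
configuration echoed as ``#`` header lines for provenance, so every table
is traceable to the (config, seed) pair that produced it; a run is fully
deterministic given its seeds.

Each stage writes and reads only documented file schemas, so stages can
equally be run one at a time from the command line.
"""

from __future__ import annotations

import dataclasses
import warnings
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import climate as climate_mod
from . import climgrowth, detrend, phylosignal, potential, sensitivity
from .ring_io import (
    read_daily_climate,
    read_newick,
    read_rwl,
    write_table,
)

__all__ = ["RunConfig", "run_full_analysis", "build_growth_panel"]


@dataclass
class RunConfig:
    """Flat run configuration (YAML-serializable key/value document)."""

    rwl: str
    daily_climate: str
    outdir: str
    tree: str | None = None
    wood_density: str | None = None
    outgroup: str | None = None
    latitude: float = 52.25
    common_period: tuple[int, int] = (1974, 2017)
    spline_cutoff: float = 15.0
    spline_response: float = 0.5
    spei_scale: int = 3
    calibration: tuple[int, int] | None = None
    n_boot: int = 1000
    n_perm: int = 999
    seed: int = 0
    outlier_k: float | None = None
    first_n: int = 20

    def __post_init__(self) -> None:
        self.common_period = (int(self.common_period[0]), int(self.common_period[1]))
        if self.common_period[0] >= self.common_period[1]:
            raise ValueError("common_period start must precede end")
        if self.calibration is not None:
            self.calibration = (int(self.calibration[0]), int(self.calibration[1]))

    def as_header(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: v for k, v in d.items() if v is not None}

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        from .ring_io import read_config

        return cls(**read_config(path))


def build_growth_panel(
    series_list,
    cutoff: float = 15.0,
    response: float = 0.5,
) -> tuple[sensitivity.GrowthPanel, dict[str, list[detrend.TriSeries]]]:
    """Detrend cores, average per tree, and stack into the long TRI panel.

    Returns the panel and the per-species tree-level TRI series used for
    chronology building.
    """
    by_tree: dict[str, list] = {}
    for s in series_list:
        by_tree.setdefault(s.tree_id, []).append(s)
    species_tris: dict[str, list[detrend.TriSeries]] = {}
    rows = []
    for tree_id, cores in sorted(by_tree.items()):
        core_tris = [detrend.detrend_series(c, cutoff, response) for c in cores]
        tri = detrend.combine_cores(core_tris, tree_id=tree_id)
        species_tris.setdefault(tri.species_code, []).append(tri)
        for y, v in zip(tri.years, tri.tri):
            rows.append(
                {
                    "species_code": tri.species_code,
                    "tree_id": tree_id,
                    "year": int(y),
                    "tri": float(v),
                }
            )
    return sensitivity.GrowthPanel(pd.DataFrame(rows)), species_tris


def run_full_analysis(config: RunConfig) -> dict[str, Path]:
    """Run every stage and write the output tables under ``config.outdir``.

    Outputs: ``chronologies.csv``, ``grid.csv``, ``table2.csv`` (species
    sensitivity coefficients), ``table3.csv`` (sensitivity-potential
    correlations), ``table4.csv`` (phylogenetic signal, when a tree is
    given), ``potential.csv``, ``residuals.csv`` and ``run_log.txt``.
    On any stage failure the partially written outputs are removed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = config.as_header()
    written: list[Path] = []
    log: list[str] = []

    def emit(name: str, df: pd.DataFrame) -> Path:
        path = outdir / name
        write_table(df, path, header=header)
        written.append(path)
        return path

    try:
        # --- stage: ring input + detrending -------------------------------
        series = read_rwl(config.rwl)
        log.append(f"rings: {len(series)} series, {sum(len(s) for s in series)} rings")
        panel, species_tris = build_growth_panel(
            series, config.spline_cutoff, config.spline_response
        )
        period = config.common_period
        span = (int(panel.frame["year"].min()), int(panel.frame["year"].max()))
        if period[0] > span[1] or period[1] < span[0]:
            raise ValueError(
                f"common period {period} lies outside the ring data span {span}"
            )
        chronos = {
            sp: detrend.build_chronology(tris, species_code=sp, sd_period=period)
            for sp, tris in sorted(species_tris.items())
        }
        chron_rows = []
        for sp, ch in chronos.items():
            for y, m, d in zip(ch.years, ch.tri_mean, ch.sample_depth):
                chron_rows.append(
                    {"species_code": sp, "year": int(y), "tri_mean": m, "sample_depth": d}
                )
        emit("chronologies.csv", pd.DataFrame(chron_rows))

        # --- stage: climate covariates ------------------------------------
        daily = read_daily_climate(config.daily_climate)
        calib = config.calibration or period
        monthly, spei_series, covs = climate_mod.derive_covariates(
            daily, config.latitude, config.spei_scale, calib
        )
        log.append(f"climate: {len(daily)} days -> {len(monthly.frame)} months")

        # --- stage: bootstrap correlation grids ---------------------------
        grid_frames = []
        for sp, ch in chronos.items():
            grid = climgrowth.correlation_grid(
                ch,
                monthly,
                spei_series,
                n_boot=config.n_boot,
                seed=config.seed,
            )
            gf = grid.frame.copy()
            gf.insert(0, "species_code", sp)
            grid_frames.append(gf)
        emit("grid.csv", pd.concat(grid_frames, ignore_index=True))

        # --- stage: sensitivity mixed model -------------------------------
        panel_cp = panel.over(period)
        n_before = len(panel_cp.frame)
        if config.outlier_k is not None:
            panel_cp = sensitivity.filter_outliers(panel_cp, k=config.outlier_k)
            log.append(
                f"outlier filter (k={config.outlier_k}): {n_before} -> "
                f"{len(panel_cp.frame)} rings"
            )
        z, _scaler = sensitivity.standardize_covariates(covs.over(period))
        fit = sensitivity.fit_sensitivity_model(panel_cp, z)
        log.append(
            f"sensitivity: {len(panel_cp.frame)} tree-year rows, "
            f"R2m={fit.r2_marginal:.3f} R2c={fit.r2_conditional:.3f}, "
            f"VIF max={fit.vif.max():.2f}"
        )
        t2 = fit.coefficients.copy()
        t2["r2_marginal"] = fit.r2_marginal
        t2["r2_conditional"] = fit.r2_conditional
        t2 = t2.merge(fit.species_r2, on="species_code", how="left")
        emit("table2.csv", t2)
        emit("residuals.csv", fit.residuals)

        # --- stage: growth potential --------------------------------------
        density = None
        if config.wood_density:
            density = pd.read_csv(config.wood_density, comment="#")
        pot = potential.growth_potential_table(
            series, wood_density=density, first_n=config.first_n
        )
        emit("potential.csv", pot.frame)
        sd_tri = pd.Series({sp: ch.sd_tri for sp, ch in chronos.items()}, name="sd_tri")
        t3 = potential.sensitivity_potential_correlation(fit, pot, sd_tri=sd_tri)
        emit("table3.csv", t3)

        # --- stage: phylogenetic signal -----------------------------------
        if config.tree:
            ptree = read_newick(config.tree)
            if config.outgroup and config.outgroup in ptree.tip_labels:
                ptree = ptree.drop_tip(config.outgroup)
            cov = phylosignal.phylo_vcv(ptree)
            traits = {
                "sensitivity_spring_frost": fit.coefficients.set_index("species_code")["beta_frost"],
                "sensitivity_current_spei": fit.coefficients.set_index("species_code")["beta_spei_cur"],
                "sensitivity_previous_spei": fit.coefficients.set_index("species_code")["beta_spei_prev"],
                "sensitivity_winter_temp": fit.coefficients.set_index("species_code")["beta_winter"],
                "diameter_growth": pot.frame.set_index("species_code")["diameter_growth"],
                "area_growth": pot.frame.set_index("species_code")["area_growth"],
                "mass_growth": pot.frame.set_index("species_code")["mass_growth"],
            }
            t4_rows = []
            for name, tr in traits.items():
                tr = tr.dropna()
                common = [s for s in cov.species if s in tr.index]
                if len(common) < 3:
                    warnings.warn(f"{name}: fewer than 3 species on the tree; skipped")
                    continue
                sub = cov.reorder(common)
                x = tr.loc[common].to_numpy(dtype=float)
                rng = np.random.default_rng([config.seed, zlib.crc32(name.encode())])
                k, p = phylosignal.k_significance(x, sub, n_perm=config.n_perm, rng=rng)
                t4_rows.append({"trait": name, "K": k, "p": p, "n_species": len(common)})
            emit("table4.csv", pd.DataFrame(t4_rows))

        log_path = outdir / "run_log.txt"
        log_path.write_text("\n".join(log) + "\n")
        written.append(log_path)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    return {p.stem: p for p in written}
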