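import numpy as np
import pandas as pd
import pytest

from ringsense.sensitivity import (
    COVARIATES,
    GrowthPanel,
    fit_sensitivity_model,
    filter_outliers,
    species_r2,
    standardize_covariates,
    vif,
)


def covariate_table(years, seed=0):
    rng = np.random.default_rng(seed)
    n = len(years)
    return pd.DataFrame(
        {
            "year": list(years),
            "spring_frost": rng.poisson(6, n).astype(float),
            "summer_spei": rng.normal(0, 1, n),
            "prev_summer_spei": rng.normal(0, 1, n),
            "winter_temp": rng.normal(3, 1.5, n),
        }
    )


def make_panel(betas_by_species, z, n_trees=4, sigma_tree=0.0, sigma_eps=0.05, seed=0):
    """Panel with TRI = 1 + X @ beta + u_tree + eps (linear in covariates)."""
    rng = np.random.default_rng(seed)
    zmat = z[list(COVARIATES)].to_numpy()
    rows = []
    for sp, betas in betas_by_species.items():
        signal = zmat @ np.asarray(betas)
        for t in range(n_trees):
            u = rng.normal(0, sigma_tree) if sigma_tree > 0 else 0.0
            eps = rng.normal(0, sigma_eps, len(z)) if sigma_eps > 0 else 0.0
            tri = 1.0 + signal + u + eps
            for yr, v in zip(z["year"], tri):
                rows.append(
                    {"species_code": sp, "tree_id": f"{sp}{t:02d}",
                     "year": int(yr), "tri": float(max(v, 1e-6))}
                )
    return GrowthPanel(pd.DataFrame(rows))


@pytest.fixture(scope="module")
def zcov():
    z, _ = standardize_covariates(covariate_table(range(1974, 2018)))
    return z


class TestStandardize:
    def test_exact_zscores_and_inverse(self):
        raw = covariate_table(range(1974, 2018))
        z, scaler = standardize_covariates(raw)
        assert np.allclose(z[list(COVARIATES)].mean(), 0, atol=1e-12)
        assert np.allclose(z[list(COVARIATES)].std(ddof=1), 1, atol=1e-12)
        back = scaler.inverse(z)
        for c in COVARIATES:
            assert np.allclose(back[c], raw[c], atol=1e-12)

    def test_constant_column_rejected(self):
        raw = covariate_table(range(1974, 2018))
        raw["winter_temp"] = 3.0
        with pytest.raises(ValueError, match="winter_temp"):
            standardize_covariates(raw)


class TestVif:
    def test_orthogonal_covariates(self):
        n = 40
        x = np.zeros((n, 2))
        x[: n // 2, 0] = 1
        x[::2, 1] = 1  # orthogonal-in-correlation design
        df = pd.DataFrame({"a": x[:, 0] - x[:, 0].mean(), "b": x[:, 1] - x[:, 1].mean()})
        out = vif(df)
        assert np.allclose(out, 1.0, atol=1e-10)

    def test_two_correlated_covariates_closed_form(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=5000)
        e = rng.normal(size=5000)
        a = a - a.mean()
        e = e - e.mean()
        e = e - a * (a @ e) / (a @ a)  # exactly orthogonal, centered
        a /= np.linalg.norm(a)
        e /= np.linalg.norm(e)
        b = 0.9 * a + np.sqrt(1 - 0.81) * e  # sample correlation exactly 0.9
        df = pd.DataFrame({"a": a, "b": b})
        out = vif(df)
        assert out["a"] == pytest.approx(1 / (1 - 0.81), rel=1e-6)

    def test_seasonal_covariates_not_collinear(self, zcov):
        out = vif(zcov, COVARIATES)
        assert (out < 5).all()

    def test_perfect_collinearity_flagged_infinite(self):
        a = np.arange(20.0)
        df = pd.DataFrame({"a": a, "b": 2 * a})
        with pytest.warns(UserWarning, match="collinearity"):
            out = vif(df)
        assert np.isinf(out).all()


class TestMixedModel:
    def test_null_panel_coefficients_near_zero(self, zcov):
        # betas = 0: each estimate should sit within 3 SEs of zero almost
        # always (normal-theory coverage), over 100 seeded replicates
        species = {f"S{i}": [0, 0, 0, 0] for i in range(4)}
        ok = total = 0
        for seed in range(100):
            panel = make_panel(species, zcov, n_trees=3, sigma_tree=0.03,
                               sigma_eps=0.08, seed=seed)
            fit = fit_sensitivity_model(panel, zcov)
            for _, row in fit.coefficients.iterrows():
                for name in ("frost", "spei_cur", "spei_prev", "winter"):
                    total += 1
                    ok += abs(row[f"beta_{name}"]) < 3 * row[f"se_{name}"]
        assert ok / total >= 0.95

    def test_planted_betas_recovered(self, zcov):
        species = {
            "AAAA": [-0.05, 0.06, 0.02, 0.04],
            "BBBB": [-0.02, 0.03, 0.00, -0.03],
            "CCCC": [0.01, 0.08, 0.05, 0.10],
        }
        panel = make_panel(species, zcov, n_trees=10, sigma_tree=0.03,
                           sigma_eps=0.08, seed=1)
        fit = fit_sensitivity_model(panel, zcov)
        inside = total = 0
        for sp, betas in species.items():
            for truth, name in zip(betas, ("frost", "spei_cur", "spei_prev", "winter")):
                est = fit.coefficients.set_index("species_code").loc[sp]
                lo = est[f"beta_{name}"] - 1.96 * est[f"se_{name}"]
                hi = est[f"beta_{name}"] + 1.96 * est[f"se_{name}"]
                total += 1
                inside += lo <= truth <= hi
        assert inside / total >= 0.8

    def test_noise_free_panel_perfect_fit(self, zcov):
        species = {"AAAA": [-0.05, 0.06, 0.02, 0.04], "BBBB": [0.02, 0.03, -0.01, 0.0]}
        panel = make_panel(species, zcov, n_trees=2, sigma_tree=0.0,
                           sigma_eps=1e-8, seed=0)
        fit = fit_sensitivity_model(panel, zcov)
        assert fit.r2_marginal == pytest.approx(fit.r2_conditional, abs=1e-6)
        assert (fit.species_r2["r2_individual"] > 0.999).all()
        assert (fit.species_r2["r2_chronology"] > 0.999).all()

    def test_affine_equivariance(self, zcov):
        species = {"AAAA": [-0.05, 0.06, 0.02, 0.04], "BBBB": [0.02, 0.03, -0.01, 0.0]}
        panel = make_panel(species, zcov, n_trees=3, sigma_eps=0.06, seed=2)
        fit1 = fit_sensitivity_model(panel, zcov)
        doubled = GrowthPanel(panel.frame.assign(tri=panel.frame["tri"] * 2))
        fit2 = fit_sensitivity_model(doubled, zcov)
        c1 = fit1.coefficients.set_index("species_code")
        c2 = fit2.coefficients.set_index("species_code")
        for name in ("frost", "spei_cur", "spei_prev", "winter"):
            assert np.allclose(c2[f"beta_{name}"], 2 * c1[f"beta_{name}"], atol=1e-6)
            assert np.allclose(c2[f"p_{name}"], c1[f"p_{name}"], atol=1e-6)
        assert fit2.r2_marginal == pytest.approx(fit1.r2_marginal, abs=1e-6)

    def test_species_order_invariance(self, zcov):
        species = {"AAAA": [-0.05, 0.06, 0.02, 0.04], "BBBB": [0.02, 0.03, -0.01, 0.0]}
        panel = make_panel(species, zcov, n_trees=3, sigma_eps=0.06, seed=3)
        shuffled = GrowthPanel(
            panel.frame.sort_values("year", kind="stable").reset_index(drop=True)
        )
        f1 = fit_sensitivity_model(panel, zcov)
        f2 = fit_sensitivity_model(shuffled, zcov)
        pd.testing.assert_frame_equal(
            f1.coefficients, f2.coefficients, atol=1e-8, rtol=0
        )

    def test_matches_per_species_ols_when_no_random_variance(self, zcov):
        species = {"AAAA": [-0.05, 0.06, 0.02, 0.04], "BBBB": [0.02, 0.03, -0.01, 0.0]}
        panel = make_panel(species, zcov, n_trees=2, sigma_tree=0.0,
                           sigma_eps=0.05, seed=4)
        fit = fit_sensitivity_model(panel, zcov)
        zmat = np.column_stack([np.ones(len(zcov)), zcov[list(COVARIATES)].to_numpy()])
        for sp in species:
            sub = panel.frame[panel.frame["species_code"] == sp].merge(zcov, on="year")
            X = np.column_stack([np.ones(len(sub)), sub[list(COVARIATES)].to_numpy()])
            beta_ols, *_ = np.linalg.lstsq(X, sub["tri"].to_numpy(), rcond=None)
            est = fit.coefficients.set_index("species_code").loc[sp]
            got = [est["intercept"], est["beta_frost"], est["beta_spei_cur"],
                   est["beta_spei_prev"], est["beta_winter"]]
            assert np.allclose(got, beta_ols, atol=1e-4)

    def test_requires_two_species_and_trees(self, zcov):
        one_sp = make_panel({"AAAA": [0, 0, 0, 0]}, zcov, n_trees=3)
        with pytest.raises(ValueError, match="2 species"):
            fit_sensitivity_model(one_sp, zcov)


class TestSpeciesR2:
    def test_pure_noise_species_r2_near_zero(self):
        r2s = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 44 * 5
            df = pd.DataFrame(
                {
                    "species_code": "NOIS",
                    "tree_id": np.repeat([f"T{i}" for i in range(5)], 44),
                    "year": np.tile(np.arange(1974, 2018), 5),
                    "tri": np.abs(rng.normal(1, 0.1, n)),
                    "predicted": rng.normal(1, 0.02, n),
                }
            )
            out = species_r2(df)
            r2s.append(float(out["r2_individual"].iloc[0]))
        assert np.median(r2s) < 0.1

    def test_chronology_level_at_least_individual_on_shared_signal(self):
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            signal = rng.normal(1, 0.08, 44)
            rows = []
            for t in range(8):
                obs = signal + rng.normal(0, 0.1, 44)
                for yr, o, p in zip(range(1974, 2018), obs, signal):
                    rows.append({"species_code": "SHRD", "tree_id": f"T{t}",
                                 "year": yr, "tri": o, "predicted": p})
            out = species_r2(pd.DataFrame(rows))
            wins += out["r2_chronology"].iloc[0] >= out["r2_individual"].iloc[0]
        assert wins >= 95

    def test_too_few_observations_omitted(self):
        df = pd.DataFrame(
            {"species_code": ["A", "A"], "tree_id": ["T", "T"],
             "year": [2000, 2001], "tri": [1.0, 1.1], "predicted": [1.0, 1.1]}
        )
        with pytest.warns(UserWarning, match="fewer than"):
            out = species_r2(df)
        assert out.empty


class TestOutlierFilter:
    def test_extreme_rings_removed(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {"species_code": "A", "tree_id": [f"T{i}" for i in range(50)],
             "year": 2000, "tri": np.abs(rng.normal(1, 0.05, 50))}
        )
        df.loc[0, "tri"] = 5.0
        out = filter_outliers(GrowthPanel(df), k=4.0)
        assert len(out.frame) == 49
        assert 5.0 not in out.frame["tri"].values
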