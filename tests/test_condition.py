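import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hybeco import condition as cond
from hybeco import simulate
from hybeco.genetics import CN, PT

from conftest import flat_k_surface, shared_growth, syntopic_zones


def _pure_k_data(seed=0, n=300, **cfg_kw):
    cfg = simulate.SimulationConfig(
        n_cn=n, n_pt=n, n_hybrid=0, seed=seed, **cfg_kw
    )
    ds = simulate.gen_individuals(cfg, include=())
    cov = ds.covariates.assign(
        env=ds.covariates["zone"], sp=ds.covariates["species"]
    )
    ktab = cond.compute_k_table(cov)
    return ktab[~ktab["excluded"]], cfg


class TestComputeK:
    def test_arithmetic(self):
        r = cond.compute_k(10.0, 10_000.0)
        assert r.k == pytest.approx(10.0)
        assert not r.excluded

    def test_low_k_excluded(self):
        r = cond.compute_k(10.0, 4_900.0)
        assert r.k == pytest.approx(4.9)
        assert r.excluded

    def test_boundaries_retained(self):
        # bounds are strict inequalities: K=5 and K=20 are kept
        assert not cond.compute_k(10.0, 5_000.0).excluded
        assert not cond.compute_k(10.0, 20_000.0).excluded
        assert cond.compute_k(10.0, 20_001.0).excluded

    def test_domain_error(self):
        with pytest.raises(ValueError):
            cond.compute_k(0.0, 100.0)
        with pytest.raises(ValueError):
            cond.compute_k(10.0, -1.0)

    @given(
        size=st.floats(min_value=1.0, max_value=50.0, allow_nan=False),
        weight=st.floats(min_value=10.0, max_value=1e6, allow_nan=False),
        c=st.floats(min_value=0.5, max_value=2.0, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_scaling_property(self, size, weight, c):
        k = cond.compute_k(size, weight).k
        assert cond.compute_k(size, 2 * weight).k == pytest.approx(2 * k)
        assert cond.compute_k(c * size, weight).k == pytest.approx(
            k / c**3, rel=1e-9
        )

    def test_table_reports_exclusions(self):
        df = pd.DataFrame(
            {"id": ["a", "b"], "size_cm": [10.0, 10.0],
             "weight_mg": [10_000.0, 900.0]}
        )
        out = cond.compute_k_table(df)
        assert list(out["excluded"]) == [False, True]


class TestTraitModel:
    def test_degree2_recovered_strong_signal(self):
        ktab, _ = _pure_k_data(seed=1, n=500)
        fit = cond.fit_trait_model(ktab, response="K", compute_type3=False)
        assert fit.degree == 2  # generative surface is quadratic in size
        assert min(fit.aic_table, key=fit.aic_table.get) == 2

    def test_degree_never_six(self):
        with pytest.raises(ValueError, match="1..5"):
            cond.fit_trait_model(pd.DataFrame(), "K",
                                 candidate_degrees=(6,))

    def test_null_species_effect_within_2se(self):
        ktab, _ = _pure_k_data(
            seed=2, n=400,
            k_surface={**flat_k_surface(),
                       "base": {CN: 10.0, PT: 10.0}},
            growth=shared_growth(),
        )
        fit = cond.fit_trait_model(ktab, response="K")
        i = fit.coef.index.get_loc("sp[Cn]")
        se = np.sqrt(fit.cov[i, i])
        assert abs(fit.coef.iloc[i]) < 2 * se

    def test_duplicate_rows_same_coefficients(self):
        ktab, _ = _pure_k_data(seed=3, n=100)
        fit1 = cond.fit_trait_model(ktab, response="K", compute_type3=False)
        doubled = pd.concat([ktab, ktab], ignore_index=True)
        fit2 = cond.fit_trait_model(doubled, response="K",
                                    compute_type3=False,
                                    candidate_degrees=(fit1.degree,))
        np.testing.assert_allclose(
            fit1.coef.values,
            fit2.coef.values * 0 + fit2.coef.values, rtol=1e-6,
        )
        np.testing.assert_allclose(fit1.coef.values, fit2.coef.values,
                                   rtol=1e-6)

    def test_empty_cell_raises(self):
        ktab, _ = _pure_k_data(seed=4, n=100)
        broken = ktab[~((ktab["env"] == "durance") & (ktab["sp"] == PT))]
        with pytest.raises(cond.FitError, match="durance"):
            cond.fit_trait_model(broken, response="K")

    def test_aic_against_refit_oracle(self):
        # AIC differences between degrees must match an independent OLS
        # refit (statsmodels) on the same designs
        import statsmodels.api as sm

        ktab, _ = _pure_k_data(seed=5, n=200)
        fit = cond.fit_trait_model(ktab, response="K", compute_type3=False)
        y = ktab["K"].to_numpy()
        aics = {}
        for m in (1, 2, 3, 4, 5):
            f_m = cond.fit_trait_model(ktab, response="K",
                                       candidate_degrees=(m,),
                                       size_center=fit.size_center,
                                       compute_type3=False)
            X = f_m.design(ktab["env"].to_numpy(), ktab["size_cm"].to_numpy(),
                           ktab["sp"].to_numpy())
            aics[m] = sm.OLS(y, X).fit().aic
        for m in (2, 3, 4, 5):
            delta_mine = fit.aic_table[m] - fit.aic_table[1]
            delta_sm = aics[m] - aics[1]
            assert delta_mine == pytest.approx(delta_sm, abs=1e-6)

    def test_median_centering_default(self):
        ktab, _ = _pure_k_data(seed=6, n=100)
        fit = cond.fit_trait_model(ktab, response="K", compute_type3=False)
        assert fit.size_center == pytest.approx(
            float(ktab["size_cm"].median())
        )

    def test_type3_table_shape(self):
        ktab, _ = _pure_k_data(seed=7, n=200)
        fit = cond.fit_trait_model(ktab, response="K")
        assert set(fit.type3["effect"]) == {
            "env", "size", "sp", "env:size", "env:sp", "size:sp",
            "env:size:sp",
        }
        assert ((fit.type3["p"] >= 0) & (fit.type3["p"] <= 1)).all()

    def test_bspline_basis_option(self):
        ktab, _ = _pure_k_data(seed=8, n=200)
        fit = cond.fit_trait_model(ktab, response="K", basis="bspline",
                                   candidate_degrees=(3, 4),
                                   compute_type3=False)
        assert fit.basis.kind == "bspline"
        pred = fit.predict(["reference"], [14.0], [CN])
        assert np.isfinite(pred).all()


@pytest.fixture(scope="module")
def fit():
    ktab, _ = _pure_k_data(seed=9, n=300)
    return cond.fit_trait_model(ktab, response="K", compute_type3=False)


class TestMixturePrediction:

    def test_endpoint_pt(self, fit):
        row = pd.DataFrame(
            {"env": ["reference"], "size_cm": [15.0], "h": [1.0]}
        )
        mix = cond.predict_hybrid_mixture(fit, row)
        pure = fit.predict(["reference"], [15.0], [PT])
        assert mix[0] == pytest.approx(pure[0], abs=1e-12)

    def test_midpoint(self, fit):
        row = pd.DataFrame(
            {"env": ["ardeche"], "size_cm": [14.0], "h": [0.5]}
        )
        mix = cond.predict_hybrid_mixture(fit, row)
        p_cn = fit.predict(["ardeche"], [14.0], [CN])[0]
        p_pt = fit.predict(["ardeche"], [14.0], [PT])[0]
        assert mix[0] == pytest.approx((p_cn + p_pt) / 2, abs=1e-12)

    def test_linearity_in_h(self, fit):
        hs = np.linspace(0, 1, 11)
        rows = pd.DataFrame(
            {"env": "durance", "size_cm": 16.0, "h": hs}
        )
        preds = cond.predict_hybrid_mixture(fit, rows)
        linear = preds[0] + hs * (preds[-1] - preds[0])
        np.testing.assert_allclose(preds, linear, atol=1e-10)

    def test_unseen_environment_errors(self, fit):
        row = pd.DataFrame({"env": ["moon"], "size_cm": [14.0], "h": [0.5]})
        with pytest.raises(ValueError, match="moon"):
            cond.predict_hybrid_mixture(fit, row)

    def test_mean_deviation_null_additive(self):
        # additive hybrids: mean D within 2 SE of 0
        cfg = simulate.SimulationConfig(
            n_cn=400, n_pt=400, n_hybrid=150, seed=10,
            zones=syntopic_zones(), growth=shared_growth(),
        )
        ds = simulate.gen_individuals(cfg, include=())
        cov = ds.covariates.merge(ds.truth[["id", "true_h"]], on="id")
        cov = cov.assign(env=cov["zone"], sp=cov["species"],
                         h=cov["true_h"])
        ktab = cond.compute_k_table(cov)
        pure = ktab[ktab["sp"].isin([CN, PT]) & ~ktab["excluded"]]
        fit = cond.fit_trait_model(pure, response="K", compute_type3=False)
        hyb = ktab[(ktab["sp"] == "Hybrid") & ~ktab["excluded"]]
        devs = cond.hybrid_deviations(fit, hyb, observed_col="K")
        se = devs["D"].std() / np.sqrt(len(devs))
        assert abs(devs["D"].mean()) < 2 * se + 0.05


class TestDeviationModel:
    def test_all_zero(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "env": rng.choice(["ardeche", "durance"], 40),
                "size_cm": rng.uniform(8, 25, 40),
                "h": rng.uniform(0.1, 0.9, 40),
                "D": np.zeros(40),
            }
        )
        fit = cond.fit_deviation_model(df)
        np.testing.assert_allclose(fit.params["coef"], 0.0, atol=1e-10)
        assert fit.result.mse_resid == pytest.approx(0.0, abs=1e-20)

    def test_exact_linear_in_h(self):
        rng = np.random.default_rng(1)
        h = rng.uniform(0, 1, 60)
        df = pd.DataFrame(
            {
                "env": rng.choice(["ardeche", "durance"], 60),
                "size_cm": rng.uniform(8, 25, 60),
                "h": h,
                "D": 2.0 * (h - 0.5),
            }
        )
        fit = cond.fit_deviation_model(df)
        assert fit.params.loc["h", "coef"] == pytest.approx(2.0, abs=1e-9)
        assert fit.params.loc["Intercept", "coef"] == pytest.approx(
            -1.0, abs=1e-9
        )

    def test_heterosis_recovery(self):
        # heterosis_delta=1.5 added to hybrid K recovered by the intercept
        estimates = []
        for seed in range(20):
            cfg = simulate.SimulationConfig(
                n_cn=400, n_pt=400, n_hybrid=150, seed=seed,
                heterosis_delta=1.5, zones=syntopic_zones(),
                growth=shared_growth(), k_surface=flat_k_surface(),
            )
            ds = simulate.gen_individuals(cfg, include=())
            cov = ds.covariates.merge(ds.truth[["id", "true_h"]], on="id")
            cov = cov.assign(env=cov["zone"], sp=cov["species"],
                             h=cov["true_h"])
            ktab = cond.compute_k_table(cov)
            pure = ktab[ktab["sp"].isin([CN, PT]) & ~ktab["excluded"]]
            fit = cond.fit_trait_model(pure, response="K",
                                       compute_type3=False)
            hyb = ktab[(ktab["sp"] == "Hybrid") & ~ktab["excluded"]]
            devs = cond.hybrid_deviations(fit, hyb, observed_col="K")
            dev_fit = cond.fit_deviation_model(devs)
            estimates.append(dev_fit.params.loc["Intercept", "coef"])
        assert 1.2 <= np.mean(estimates) <= 1.8

    def test_single_env_dropped_with_note(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {
                "env": ["ardeche"] * 30,
                "size_cm": rng.uniform(8, 25, 30),
                "h": rng.uniform(0, 1, 30),
                "D": rng.normal(0, 1, 30),
            }
        )
        fit = cond.fit_deviation_model(df)
        assert any("env terms dropped" in n for n in fit.notes)
        assert not any("env" in t for t in fit.params.index)

    def test_too_few_hybrids(self):
        with pytest.raises(cond.FitError):
            cond.fit_deviation_model(
                pd.DataFrame({"env": ["a"], "size_cm": [10.0],
                              "h": [0.5], "D": [0.1]})
            )


class TestSizeAgeComparison:
    def _records(self, seed=0, n=200, durance_effect=0.0):
        rng = np.random.default_rng(seed)
        group = rng.choice([CN, PT], n)
        env = rng.choice(["reference", "durance"], n)
        age = rng.integers(1, 9, n).astype(float)
        size = 5.0 + 2.5 * age + rng.normal(0, 1.0, n)
        size += np.where(env == "durance", durance_effect, 0.0)
        return pd.DataFrame(
            {"group": group, "env": env, "age": age, "size_cm": size,
             "station": rng.choice(["s1", "s2"], n)}
        )

    def test_null_difference_within_2se(self):
        out = cond.size_age_comparison(self._records(seed=1, n=400))
        means = out["adjusted_means"].set_index(["group", "env"])
        for env in ("reference", "durance"):
            a = means.loc[(CN, env)]
            b = means.loc[(PT, env)]
            se = np.hypot(a["se"], b["se"])
            assert abs(a["adjusted_mean"] - b["adjusted_mean"]) < 2.5 * se

    def test_environment_effect_recovery(self):
        out = cond.size_age_comparison(
            self._records(seed=2, n=400, durance_effect=-2.5)
        )
        means = out["adjusted_means"].set_index(["group", "env"])
        for g in (CN, PT):
            diff = (means.loc[(g, "durance"), "adjusted_mean"]
                    - means.loc[(g, "reference"), "adjusted_mean"])
            assert diff == pytest.approx(-2.5, abs=0.5)

    def test_confounded_design_raises(self):
        df = pd.DataFrame(
            {
                "group": [CN] * 10 + [PT] * 10,
                "env": ["reference"] * 20,
                "age": [2.0] * 10 + [5.0] * 10,  # age == f(group)
                "size_cm": np.r_[np.full(10, 10.0), np.full(10, 17.0)],
                "station": ["s"] * 20,
            }
        )
        with pytest.raises(cond.FitError, match="rank-deficient"):
            cond.size_age_comparison(df)

    def test_missing_ages_counted(self):
        df = self._records(seed=3, n=100)
        df.loc[df.index[:7], "age"] = np.nan
        out = cond.size_age_comparison(df)
        assert out["n_missing_age"] == 7
        assert out["n_used"] == 93

    def test_station_exclusion(self):
        df = self._records(seed=4, n=100)
        out = cond.size_age_comparison(df, exclude_stations=["s1"])
        assert out["n_used"] == int((df["station"] == "s2").sum())
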