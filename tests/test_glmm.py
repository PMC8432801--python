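"""Mixed-model engine: GLM equivalence, recovery, prediction, bootstrap."""

import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from patsy import dmatrix

from birdindex import glmm
from birdindex.glmm import ConvergenceError, GlmmSpec


def _inv_logit(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_binomial(n, seed, n_towns=1, n_obs=1, town_sd=0.0, obs_sd=0.0,
                      year_effects=(0.0,)):
    rng = np.random.default_rng(seed)
    years = 2005 + np.arange(len(year_effects))
    df = pd.DataFrame({
        "year": rng.choice(years, n),
        "doy_c": rng.normal(0, 10, n),
        "start_c": rng.normal(0, 0.1, n),
        "list_length": rng.integers(5, 25, n).astype(float),
        "protocol": rng.choice(["stationary", "traveling"], n),
        "town": rng.choice([f"T{i}" for i in range(n_towns)], n),
        "observer_id": rng.choice([f"o{i}" for i in range(n_obs)], n),
    })
    u_t = dict(zip(sorted(df["town"].unique()), rng.normal(0, town_sd, n_towns)))
    u_o = dict(zip(sorted(df["observer_id"].unique()), rng.normal(0, obs_sd, n_obs)))
    ye = dict(zip(years, year_effects))
    eta = (-2.0 + df["year"].map(ye) + 0.02 * df["doy_c"] - 0.001 * df["doy_c"] ** 2
           + 0.08 * df["list_length"] + 0.3 * (df["protocol"] == "traveling")
           + df["town"].map(u_t) + df["observer_id"].map(u_o))
    df["response"] = (rng.random(n) < _inv_logit(eta)).astype(int)
    return df


class TestFitGlmm:
    def test_zero_variance_data_match_plain_glm(self):
        """Single town + single observer: PIRLS must reproduce ordinary IRLS."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        df = simulate_binomial(5000, seed=1, year_effects=(0.0, 0.3, -0.2))
        fit = glmm.fit_glmm(df, GlmmSpec("binomial", "L"))
        assert fit.sigma == {"town": 0.0, "observer_id": 0.0}
        oracle = smf.glm("response ~ " + fit.spec.formula(), df,
                         family=sm.families.Binomial()).fit()
        assert np.max(np.abs(fit.beta.to_numpy() - oracle.params.to_numpy())) < 1e-6

    def test_intercept_only_coin_flip(self):
        rng = np.random.default_rng(2)
        d = pd.DataFrame({"response": (rng.random(10_000) < 0.5).astype(int),
                          "town": "T", "year": 2005})
        fit = glmm.fit_glmm(d, GlmmSpec("binomial", None, re_factors=(),
                                        formula_override="1"))
        se = np.sqrt(fit.vcov_beta[0, 0])
        assert abs(fit.beta.iloc[0]) < 3 * se

    def test_year_effect_recovery_with_random_intercepts(self):
        df = simulate_binomial(20_000, seed=3, n_towns=5, n_obs=30,
                               town_sd=0.3, obs_sd=0.4,
                               year_effects=(0.0, 0.3, -0.2))
        fit = glmm.fit_glmm(df, GlmmSpec("binomial", "L"))
        for term, truth in (("C(year)[T.2006]", 0.3), ("C(year)[T.2007]", -0.2)):
            i = list(fit.beta.index).index(term)
            se = np.sqrt(fit.vcov_beta[i, i])
            assert abs(fit.beta[term] - truth) < 3 * se

    def test_matches_lme4_glmer_nagq0(self, tmp_path):
        """Independent oracle: R lme4 with nAGQ=0 on a small crossed design."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        rng = np.random.default_rng(42)
        n = 600
        towns = [f"T{i}" for i in range(4)]
        obs = [f"o{i}" for i in range(8)]
        df = pd.DataFrame({
            "year": rng.choice([2005, 2006, 2007, 2008], n),
            "town": rng.choice(towns, n),
            "observer_id": rng.choice(obs, n),
        })
        u_t = dict(zip(towns, rng.normal(0, 0.5, 4)))
        u_o = dict(zip(obs, rng.normal(0, 0.7, 8)))
        eta = (-0.5 + 0.4 * (df.year == 2006) - 0.3 * (df.year == 2007)
               + 0.1 * (df.year == 2008) + df.town.map(u_t) + df.observer_id.map(u_o))
        df["response"] = (rng.random(n) < _inv_logit(eta)).astype(int)
        csv = tmp_path / "fixture.csv"
        df.to_csv(csv, index=False)
        fit = glmm.fit_glmm(df, GlmmSpec("binomial", None))
        r_code = f'''
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m <- glmer(response ~ factor(year) + (1|town) + (1|observer_id),
                   data=d, family=binomial, nAGQ=0)
        cat(jsonlite::toJSON(list(beta=fixef(m), sd=sqrt(unlist(VarCorr(m)))), digits=10))
        '''
        out = subprocess.run(["Rscript", "-e", r_code], capture_output=True, text=True)
        assert out.returncode == 0, out.stderr[-800:]
        res = json.loads(out.stdout)
        assert np.max(np.abs(fit.beta.to_numpy() - np.asarray(res["beta"]))) < 1e-3
        assert abs(sorted(fit.sigma.values())[-1] - max(res["sd"])) < 1e-2

    def test_quasipoisson_phi_near_one_on_poisson_data(self):
        rng = np.random.default_rng(4)
        n = 10_000
        d = pd.DataFrame({"year": rng.choice([2005, 2006], n),
                          "town": rng.choice(["T1", "T2"], n),
                          "observer_id": rng.choice(["a", "b", "c"], n)})
        mu = np.exp(0.2 + 0.3 * (d["year"] == 2006))
        d["response"] = rng.poisson(mu)
        fit = glmm.fit_glmm(d, GlmmSpec("quasipoisson", None))
        assert abs(fit.phi - 1.0) < 0.1

    def test_quasipoisson_phi_scales_beta_ses(self):
        rng = np.random.default_rng(5)
        n = 4000
        d = pd.DataFrame({"year": rng.choice([2005, 2006], n), "town": "T",
                          "observer_id": "o"})
        lam = rng.gamma(0.5, 2.0, n)  # overdispersed mixture
        d["response"] = rng.poisson(lam)
        fit = glmm.fit_glmm(d, GlmmSpec("quasipoisson", None))
        assert fit.phi > 1.5  # mixture variance inflates Pearson dispersion

    def test_binomial_requires_binary_response(self):
        d = pd.DataFrame({"response": [0, 1, 2], "town": "T", "year": 2005,
                          "observer_id": "o"})
        with pytest.raises(ValueError):
            glmm.fit_glmm(d, GlmmSpec("binomial", None))

    def test_complete_separation_raises(self):
        rng = np.random.default_rng(6)
        n = 400
        d = pd.DataFrame({
            "year": rng.choice([2005, 2006], n),
            "doy_c": rng.normal(0, 5, n), "start_c": rng.normal(0, 0.1, n),
            "list_length": rng.integers(5, 25, n).astype(float),
            "protocol": "traveling", "town": "T", "observer_id": "o",
        })
        d["response"] = (d["list_length"] > 12).astype(int)
        with pytest.raises(ConvergenceError):
            glmm.fit_glmm(d, GlmmSpec("binomial", "L"))


class TestEffortFormSelection:
    @pytest.mark.parametrize("gen_form,expected", [("L", "L"), ("logL", "logL")])
    def test_selects_generating_form(self, gen_form, expected):
        rng = np.random.default_rng(11)
        n = 6000
        d = pd.DataFrame({
            "year": rng.choice([2005, 2006], n),
            "doy_c": rng.normal(0, 5, n), "start_c": rng.normal(0, 0.1, n),
            "list_length": np.exp(rng.uniform(np.log(5), np.log(60), n)).round(),
            "protocol": rng.choice(["stationary", "traveling"], n),
            "town": rng.choice(["T1", "T2", "T3"], n),
            "observer_id": rng.choice([f"o{i}" for i in range(10)], n),
        })
        if gen_form == "L":
            eta = -3.0 + 0.12 * d["list_length"]
        else:
            eta = -5.0 + 1.8 * np.log(d["list_length"])
        d["response"] = (rng.random(n) < _inv_logit(eta)).astype(int)
        form, _ = glmm.select_effort_form(d)
        assert form == expected

    def test_tie_breaks_toward_untransformed(self, monkeypatch):
        class Stub:
            loglik = -100.0
            spec = GlmmSpec("binomial", "L")

        monkeypatch.setattr(glmm, "fit_glmm", lambda det, spec: Stub())
        form, _ = glmm.select_effort_form(pd.DataFrame())
        assert form == "L"


def _handmade_fit(eta_value, family="binomial"):
    """Intercept-only GlmmFit with a chosen linear predictor."""
    d = pd.DataFrame({"x": [1.0, 1.0]})
    dm = dmatrix("1", d, return_type="dataframe")
    return glmm.GlmmFit(
        spec=GlmmSpec(family, None, re_factors=(), formula_override="1"),
        design_info=dm.design_info,
        beta=pd.Series([eta_value], index=["Intercept"]),
        vcov_beta=np.eye(1), sigma={}, u={}, phi=1.0, centering={},
        deviance=0.0, loglik=0.0, converged=True, n_iter=1,
    )


class TestPredictStandardized:
    def test_all_zero_coefficients_give_half(self):
        grid = pd.DataFrame({"town": ["T"], "year": [2005]})
        out = glmm.predict_standardized(_handmade_fit(0.0), grid)
        assert np.isclose(out["estimate"].iloc[0], 0.5)

    def test_logit_arithmetic(self):
        grid = pd.DataFrame({"town": ["T"], "year": [2005]})
        out = glmm.predict_standardized(_handmade_fit(np.log(4.0)), grid)
        assert np.isclose(out["estimate"].iloc[0], 0.8, atol=1e-9)

    def test_log_link_zero_predictor_gives_unit_rate(self):
        grid = pd.DataFrame({"town": ["T"], "year": [2005]})
        out = glmm.predict_standardized(_handmade_fit(0.0, "quasipoisson"), grid)
        assert np.isclose(out["estimate"].iloc[0], 1.0)

    def test_unseen_town_rejected(self):
        df = simulate_binomial(800, seed=7, n_towns=3, n_obs=5, town_sd=0.3,
                               obs_sd=0.3, year_effects=(0.0, 0.2))
        fit = glmm.fit_glmm(df, GlmmSpec("binomial", None))
        grid = pd.DataFrame({"town": ["ELSEWHERE"], "year": [2005]})
        with pytest.raises(KeyError):
            glmm.predict_standardized(fit, grid)

    def test_detection_estimates_inside_unit_interval(self):
        df = simulate_binomial(1500, seed=8, n_towns=3, n_obs=8, town_sd=0.4,
                               obs_sd=0.4, year_effects=(0.0, 0.2, -0.1))
        fit = glmm.fit_glmm(df, GlmmSpec("binomial", "L"))
        grid = glmm.make_prediction_grid(_with_grid_columns(df))
        out = glmm.predict_standardized(fit, grid)
        assert ((out["estimate"] > 0) & (out["estimate"] < 1)).all()


def _with_grid_columns(df):
    d = df.copy()
    d["doy"] = d["doy_c"] + 160.0
    d["start_time"] = d["start_c"] + 0.3
    d.attrs["doy_mean"] = 160.0
    d.attrs["start_mean"] = 0.3
    return d


class TestPredictionGrid:
    def test_covariates_identical_across_towns(self):
        df = _with_grid_columns(simulate_binomial(
            1000, seed=9, n_towns=4, n_obs=6, year_effects=(0.0, 0.1)))
        grid = glmm.make_prediction_grid(df)
        assert grid.groupby("year")["doy_c"].nunique().eq(1).all()
        assert (grid["protocol"] == "traveling").all()
        assert len(grid) == 4 * 2


class TestBootstrapSe:
    def test_deterministic_under_seed(self):
        df = simulate_binomial(600, seed=10, n_towns=3, n_obs=6, town_sd=0.3,
                               obs_sd=0.3, year_effects=(0.0, 0.2))
        fit = glmm.fit_glmm(df, GlmmSpec("binomial", None))
        grid = pd.DataFrame({"town": ["T0", "T1"], "year": [2005, 2005]})
        a = glmm.bootstrap_se(fit, df, grid, B=15, seed=5, refit_theta=False)
        b = glmm.bootstrap_se(fit, df, grid, B=15, seed=5, refit_theta=False)
        assert np.array_equal(a["se"], b["se"])
        assert (a["se"] > 0).all()

    def test_invalid_b_rejected(self):
        fit = _handmade_fit(0.0)
        with pytest.raises(ValueError):
            glmm.bootstrap_se(fit, pd.DataFrame({"response": [0, 1]}),
                              pd.DataFrame({"town": ["T"], "year": [2005]}), B=1)
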