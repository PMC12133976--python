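"""Gamma mixed model: model set, fitting, comparison, inference, prediction."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from perohr import glmm
from perohr.glmm import (GlmmFit, ModelSpec, aic_weights, build_design,
                         build_model_set, fit_glmm, habitat_contrasts,
                         predict_response, wald_anova)
from perohr.synthetic import DEFAULT_COEFFICIENTS, simulate_analysis_table


class TestModelSet:
    def test_twelve_candidates(self):
        assert len(build_model_set()) == 12

    def test_full_model_has_the_ten_reported_terms(self):
        top = build_model_set()[-1]
        assert top.fixed_terms == (
            "sex", "condition", "habitat", "latitude", "density",
            "sex:condition", "habitat:latitude", "latitude:density",
            "habitat:density", "habitat:latitude:density")

    def test_every_spec_respects_marginality(self):
        # construction itself enforces the hierarchy; a violating spec raises
        for spec in build_model_set():
            ModelSpec(spec.name, spec.fixed_terms)  # re-validates
        with pytest.raises(ValueError, match="lower-order"):
            ModelSpec("bad", ("sex", "habitat:latitude"))


@pytest.fixture(scope="module")
def sim_fit():
    df, truth = simulate_analysis_table(n=900, n_sites=18, n_years=8, rng=21)
    spec = build_model_set()[-1]
    return df, truth, fit_glmm(df, spec, standardize=False)


class TestFitGlmm:
    def test_zero_variance_limit_matches_gamma_glm(self):
        import statsmodels.api as sm
        df, _ = simulate_analysis_table(n=500, n_sites=10, n_years=5,
                                        sigma_site=0.0, sigma_year=0.0, rng=7)
        spec = build_model_set()[2]  # mains + sex:condition
        fit = fit_glmm(df, spec, standardize=False, fix_variances=(0.0, 0.0))
        X, names, _ = build_design(df, spec, {})
        ref = sm.GLM(df["area50_m2"], X,
                     family=sm.families.Gamma(sm.families.links.Log())).fit()
        rel = np.abs(fit.coef.to_numpy() - ref.params.to_numpy())
        rel = rel / np.abs(ref.params.to_numpy())
        assert rel.max() < 1e-3

    def test_free_fit_finds_small_variances_when_truth_is_zero(self):
        df, _ = simulate_analysis_table(n=800, n_sites=15, n_years=6,
                                        sigma_site=0.0, sigma_year=0.0, rng=8)
        fit = fit_glmm(df, build_model_set()[1], standardize=False)
        assert fit.sigma_site < 0.1 and fit.sigma_year < 0.15

    def test_intercept_only_recovers_log_mean(self):
        rng = np.random.default_rng(9)
        mu, shape = 1500.0, 2.0
        df = pd.DataFrame({
            "area50_m2": rng.gamma(shape, mu / shape, 2000),
            "sex": "female", "condition": 0.0, "habitat": "forest",
            "latitude": 0.0, "density": 0.0,
            "site_id": rng.integers(0, 10, 2000), "year": rng.integers(0, 5, 2000),
        })
        fit = fit_glmm(df, build_model_set()[0], standardize=False)
        # mean of the gamma: se(log mean) ~ 1/sqrt(n*shape) ~ 0.016
        assert fit.coef["(Intercept)"] == pytest.approx(np.log(mu), abs=0.06)
        assert fit.shape == pytest.approx(shape, rel=0.15)

    def test_nonpositive_response_raises_naming_rows(self):
        df, _ = simulate_analysis_table(n=50, n_sites=4, n_years=3, rng=10)
        df.loc[3, "area50_m2"] = -1.0
        with pytest.raises(ValueError, match="3"):
            fit_glmm(df, build_model_set()[0])

    def test_nested_model_never_loses_loglik(self, sim_fit):
        df, _, full = sim_fit
        mains = fit_glmm(df, build_model_set()[1], standardize=False)
        assert full.loglik >= mains.loglik - 1e-4

    def test_aic_counts_fixed_effects_variances_and_shape(self, sim_fit):
        _, _, fit = sim_fit
        k = fit.n_fixed + 2 + 1
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * k)

    def test_standardized_fit_predicts_like_unstandardized(self, sim_fit):
        df, _, fit_raw = sim_fit
        fit_std = fit_glmm(df, fit_raw.spec, standardize=True)
        nd = df.head(20)[["sex", "condition", "habitat", "latitude", "density"]]
        p1 = predict_response(fit_raw, nd)["mu"].to_numpy()
        p2 = predict_response(fit_std, nd)["mu"].to_numpy()
        assert np.allclose(p1, p2, rtol=2e-2)

    def test_matches_glmmtmb_reference(self, tmp_path):
        df, _ = simulate_analysis_table(n=500, n_sites=12, n_years=6, rng=11)
        spec = build_model_set()[2]
        fit = fit_glmm(df, spec, standardize=False)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(f'''
            suppressMessages(library(glmmTMB))
            d <- read.csv("{csv}")
            d$sex <- relevel(factor(d$sex), ref="female")
            m <- glmmTMB(area50_m2 ~ sex + condition + habitat + latitude
                         + density + sex:condition + (1|site_id) + (1|year),
                         data=d, family=Gamma(link="log"))
            fe <- fixef(m)$cond
            vc <- VarCorr(m)$cond
            cat(paste(fe, collapse=","), "\\n")
            cat(sqrt(vc$site_id[1,1]), sqrt(vc$year[1,1]),
                as.numeric(logLik(m)), "\\n")
        ''')
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr[-800:]
        lines = [ln for ln in out.stdout.strip().splitlines() if ln.strip()]
        ref_coef = np.array([float(v) for v in lines[0].split(",")])
        sd_site, sd_year, ll = (float(v) for v in lines[1].split())
        assert np.allclose(fit.coef.to_numpy(), ref_coef, rtol=1e-2, atol=6e-3)
        assert fit.sigma_site == pytest.approx(sd_site, abs=5e-3)
        assert fit.sigma_year == pytest.approx(sd_year, abs=5e-3)
        assert fit.loglik == pytest.approx(ll, abs=0.05)


class TestAicWeights:
    def test_closed_form_pair(self):
        w = aic_weights(np.array([100.0, 102.0]))["weight"].to_numpy()
        assert np.allclose(sorted(w, reverse=True), [0.7311, 0.2689], atol=5e-5)

    def test_identical_aics_share_weight_equally(self):
        w = aic_weights(np.array([50.0, 50.0, 50.0]))["weight"]
        assert np.allclose(w, 1 / 3)

    def test_sum_to_one_and_shift_invariant(self):
        rng = np.random.default_rng(12)
        aics = rng.uniform(1000, 1020, 12)
        w1 = aic_weights(aics).sort_values("model")["weight"].to_numpy()
        w2 = aic_weights(aics + 57.3).sort_values("model")["weight"].to_numpy()
        assert w1.sum() == pytest.approx(1.0)
        assert np.allclose(w1, w2)


def toy_fit(coef, cov, terms):
    names = list(coef)
    return GlmmFit(
        spec=ModelSpec("toy", tuple(terms)),
        coef=pd.Series(coef),
        cov=pd.DataFrame(cov, index=names, columns=names),
        sigma_site=0.0, sigma_year=0.0, shape=1.0, loglik=0.0, aic=0.0,
        n_obs=0, term_slices={t: [names.index(c) for c in cols]
                              for t, cols in terms.items()},
        scaler={}, ranef={}, covariate_ranges={})


class TestWaldAnova:
    def test_zero_coefficients_give_zero_chisq_p_one(self):
        fit = toy_fit({"(Intercept)": 5.0, "sex[male]": 0.0},
                      np.eye(2) * 0.01, {"sex": ["sex[male]"]})
        tab = wald_anova(fit).set_index("term")
        assert tab.loc["sex", "chisq"] == 0.0
        assert tab.loc["sex", "p_value"] == 1.0

    def test_single_df_term_equals_squared_z(self, sim_fit):
        _, _, fit = sim_fit
        tab = wald_anova(fit).set_index("term")
        se = np.sqrt(fit.cov.loc["sex[male]", "sex[male]"])
        z = fit.coef["sex[male]"] / se
        assert tab.loc["sex", "chisq"] == pytest.approx(z ** 2, rel=1e-8)
        assert tab.loc["sex", "df"] == 1

    def test_multi_df_term_block(self, sim_fit):
        _, _, fit = sim_fit
        tab = wald_anova(fit).set_index("term")
        assert tab.loc["habitat", "df"] == 2
        assert tab.loc["habitat:latitude:density", "df"] == 2


class TestHabitatContrasts:
    def test_contrast_equals_prediction_difference(self, sim_fit):
        df, _, fit = sim_fit
        tab = habitat_contrasts(fit).set_index("contrast")
        rows = []
        for hab in ("grassland", "forest"):
            nd = pd.DataFrame({"habitat": [hab], "condition": [0.0],
                               "latitude": [0.0], "density": [0.0]})
            mu_f = predict_response(fit, nd.assign(sex="female"))["mu"][0]
            mu_m = predict_response(fit, nd.assign(sex="male"))["mu"][0]
            rows.append(0.5 * (np.log(mu_f) + np.log(mu_m)))
        assert tab.loc["grassland - forest", "estimate"] == \
            pytest.approx(rows[0] - rows[1], abs=1e-10)

    def test_equal_true_effects_share_a_letter(self):
        coef = dict(DEFAULT_COEFFICIENTS)
        for k in list(coef):
            if "habitat" in k:
                coef[k] = 0.0
        df, _ = simulate_analysis_table(n=1200, n_sites=20, n_years=6,
                                        coefficients=coef, rng=13)
        fit = fit_glmm(df, build_model_set()[1], standardize=False)
        tab = habitat_contrasts(fit)
        letters = tab.attrs["letters"]
        assert len(set(letters.values())) == 1

    def test_divergent_group_gets_distinct_letter(self):
        coef = dict(DEFAULT_COEFFICIENTS)
        for k in list(coef):
            if "habitat" in k:
                coef[k] = 0.0
        coef["habitat[grassland]"] = 1.5
        df, _ = simulate_analysis_table(n=1500, n_sites=20, n_years=6,
                                        coefficients=coef, rng=14)
        fit = fit_glmm(df, build_model_set()[1], standardize=False)
        letters = habitat_contrasts(fit).attrs["letters"]
        assert letters["grassland"] != letters["forest"]
        assert letters["forest"] == letters["shrubland"]


class TestPredictResponse:
    def test_intercept_only_predicts_exp_b0(self):
        fit = toy_fit({"(Intercept)": 7.0}, np.eye(1) * 1e-4, {})
        out = predict_response(fit, pd.DataFrame({"density": [0.0]}))
        assert out["mu"][0] == pytest.approx(np.exp(7.0))
        assert out["lo"][0] < out["mu"][0] < out["hi"][0]

    def test_monotone_in_uninteracted_covariate(self):
        fit = toy_fit({"(Intercept)": 7.0, "density": -0.02},
                      np.eye(2) * 1e-4, {"density": ["density"]})
        out = predict_response(fit, pd.DataFrame({"density": [0.0, 10.0, 20.0]}))
        assert out["mu"].is_monotonic_decreasing

    def test_extrapolation_warns(self, sim_fit):
        df, _, fit = sim_fit
        nd = pd.DataFrame({"sex": ["female"], "condition": [0.0],
                           "habitat": ["forest"], "latitude": [0.0],
                           "density": [df["density"].max() + 50.0]})
        with pytest.warns(UserWarning, match="extrapolat"):
            predict_response(fit, nd)

    def test_recovers_simulated_three_way_crossing(self):
        df, truth = simulate_analysis_table(n=2500, n_sites=30, n_years=8, rng=15)
        fit = fit_glmm(df, build_model_set()[-1], standardize=False)
        # density slope in grasslands steepens (more negative) at high latitude
        true_mod = (truth["latitude:density"]
                    + truth["habitat[grassland]:latitude:density"])
        fit_mod = (fit.coef["latitude:density"]
                   + fit.coef["habitat[grassland]:latitude:density"])
        assert np.sign(fit_mod) == np.sign(true_mod)
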