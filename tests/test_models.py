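import numpy as np
import pandas as pd
import pytest
from scipy import stats

from saplingshift import models
from saplingshift.models import (
    collinearity_screen,
    fit_cwm_lm,
    fit_endozoochory_lmm,
    fit_recruitment_glmm,
    fit_st_lmm,
    hp_slopes_at_sl,
    marginal_effects,
    mode_hp_slopes,
    nakagawa_r2,
    pairwise_mode_tests,
    significance_stars,
    trait_correlations,
)

from conftest import simulate_study


class TestCollinearity:
    def test_duplicate_flagged(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4], "c": [4.0, 1, 3, 2]})
        corr, flags = collinearity_screen(df)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert ("a", "b", pytest.approx(1.0)) in [(x, y, r) for x, y, r in flags]

    def test_sign_flip_flagged(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 5], "y": [-1.0, -2, -3, -5]})
        corr, flags = collinearity_screen(df)
        assert corr.loc["x", "y"] == pytest.approx(-1.0)
        assert len(flags) == 1

    def test_independent_large_sample_unflagged(self, rng):
        df = pd.DataFrame(rng.standard_normal((10_000, 3)), columns=list("abc"))
        corr, flags = collinearity_screen(df)
        off = corr.to_numpy()[~np.eye(3, dtype=bool)]
        assert (np.abs(off) < 0.05).all()
        assert flags == []

    def test_constant_covariate_reported_absent(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "k": [2.0, 2, 2, 2]})
        corr, flags = collinearity_screen(df)
        assert np.isnan(corr.loc["a", "k"])
        assert flags == []


class TestNakagawaR2:
    def test_closed_form(self):
        # var(fixed)=1, var(random)=1, var(resid)=2 -> R2m=.25, R2c=.50
        fit = models.FitResult(
            params=pd.Series([0.0]),
            bse=pd.Series([1.0]),
            pvalues=pd.Series([1.0]),
            cov_params=pd.DataFrame([[1.0]]),
            varcomps={"species": 1.0},
            resid_var=2.0,
            loglik=0.0,
            residuals=pd.Series([0.0]),
            linpred_marginal=np.array([-1.0, 1.0]),
            converged=True,
            family="gaussian",
            link="identity",
            design=None,
        )
        r2m, r2c = nakagawa_r2(fit)
        assert (r2m, r2c) == (pytest.approx(0.25), pytest.approx(0.50))

    def test_no_random_variance_collapses(self):
        fit = models.FitResult(
            params=pd.Series([0.0]),
            bse=pd.Series([1.0]),
            pvalues=pd.Series([1.0]),
            cov_params=pd.DataFrame([[1.0]]),
            varcomps={},
            resid_var=1.0,
            loglik=0.0,
            residuals=pd.Series([0.0]),
            linpred_marginal=np.array([-1.0, 1.0]),
            converged=True,
            family="gaussian",
            link="identity",
            design=None,
        )
        r2m, r2c = nakagawa_r2(fit)
        assert r2m == r2c

    def test_binomial_null_fixed_effects(self):
        fit = models.FitResult(
            params=pd.Series([0.0]),
            bse=pd.Series([1.0]),
            pvalues=pd.Series([1.0]),
            cov_params=pd.DataFrame([[1.0]]),
            varcomps={"species": 0.5},
            resid_var=None,
            loglik=0.0,
            residuals=pd.Series([0.0]),
            linpred_marginal=np.zeros(10),
            converged=True,
            family="binomial",
            link="logit",
            design=None,
        )
        r2m, r2c = nakagawa_r2(fit)
        assert r2m == 0.0
        assert r2c == pytest.approx(0.5 / (0.5 + np.pi**2 / 3))

    def test_ordering_on_real_fit(self, effect_study):
        *_, rec = effect_study
        fit = fit_recruitment_glmm(rec)
        r2m, r2c = nakagawa_r2(fit)
        assert 0.0 <= r2m <= r2c <= 1.0


class TestMixedModels:
    def test_glmm_recovers_opposing_slope_signs(self, effect_study):
        *_, rec = effect_study
        fit = fit_recruitment_glmm(rec)
        slopes = mode_hp_slopes(fit).set_index("dispersal_mode")["slope"]
        assert slopes["endozoochory"] < 0 < slopes["abiotic"]

    def test_st_lmm_location_equivariance(self, null_study):
        *_, rec = null_study
        base = fit_st_lmm(rec)
        shifted = rec.copy()
        shifted["st_ratio"] = shifted["st_ratio"] + 2.5
        shift = fit_st_lmm(shifted)
        diff = (shift.params - base.params).abs()
        assert shift.params["Intercept"] - base.params["Intercept"] == pytest.approx(2.5, abs=1e-6)
        assert diff.drop("Intercept").max() < 1e-6

    def test_reml_matches_balanced_anova_components(self, rng):
        # balanced one-way layout: REML variance components equal the
        # classical ANOVA estimators sigma_b^2=(MSB-MSW)/n, sigma_w^2=MSW
        k, n = 30, 8
        g = np.repeat(np.arange(k), n)
        u = rng.normal(0, 1.3, k)
        y = 5.0 + u[g] + rng.normal(0, 0.9, k * n)
        df = pd.DataFrame(
            {
                "st_ratio": y,
                "species": [f"s{i}" for i in g],
                "hp": 0.0,
                "cec": 0.0,
                "vdnd": 0.0,
                "n_adults": 0.0,
                "dispersal_mode": "abiotic",
                "sapling_present": 1,
            }
        )
        fit = fit_st_lmm(df, standardize=False)
        means = pd.Series(y).groupby(g).mean()
        msb = n * ((means - y.mean()) ** 2).sum() / (k - 1)
        msw = sum(((y[g == i] - means[i]) ** 2).sum() for i in range(k)) / (k * (n - 1))
        assert fit.resid_var == pytest.approx(msw, rel=1e-4)
        assert fit.varcomps["species"] == pytest.approx((msb - msw) / n, rel=1e-3)

    def test_endo_lmm_slope_identity_and_null_interaction(self):
        # slopes at different seed lengths differ exactly by the fitted
        # interaction times the z-difference; with no injected interaction
        # the interaction stays within noise of zero
        *_, rec = simulate_study(1311, n_species=250)
        endo = rec[rec["dispersal_mode"] == "endozoochory"].rename(columns={"sl_mm": "sl"})
        endo = endo.dropna(subset=["sl", "st_ratio"])
        fit = fit_endozoochory_lmm(endo)
        sl = hp_slopes_at_sl(fit, [1.0, 18.0, 50.0]).set_index("sl_mm")
        mean, sd = fit.design.scalers["sl"]
        b = fit.params["hp:sl"]
        expect_diff = b * ((50.0 - mean) / sd - (1.0 - mean) / sd)
        assert sl.loc[50.0, "slope"] - sl.loc[1.0, "slope"] == pytest.approx(expect_diff)
        assert abs(b) < 3.5 * fit.bse["hp:sl"]

    def test_endo_lmm_interaction_sign_pattern(self, effect_study):
        # negative HP x SL interaction: HP slope declines from small- to
        # large-seeded species
        *_, rec = effect_study
        endo = rec[rec["dispersal_mode"] == "endozoochory"].copy()
        endo["sl"] = endo["true_sl_mm"]
        endo = endo.dropna(subset=["sl", "st_ratio"])
        fit = fit_endozoochory_lmm(endo)
        sl = hp_slopes_at_sl(fit, [1.0, 50.0]).set_index("sl_mm")
        assert sl.loc[1.0, "slope"] > sl.loc[50.0, "slope"]
        assert fit.params["hp:sl"] < 0

    def test_endo_lmm_single_family_degenerates(self, null_study):
        *_, rec = null_study
        endo = rec[rec["dispersal_mode"] == "endozoochory"].rename(columns={"sl_mm": "sl"})
        endo = endo.dropna(subset=["sl", "st_ratio"]).copy()
        endo["family"] = "onlyfam"
        fit = fit_endozoochory_lmm(endo)
        assert set(fit.varcomps) == {"species"}

    def test_glmm_single_species_degenerate(self, null_study):
        *_, rec = null_study
        one = rec[rec["species"] == rec["species"].mode()[0]].copy()
        if one["sapling_present"].nunique() < 2:  # ensure both outcomes occur
            one.iloc[0, one.columns.get_loc("sapling_present")] = (
                1 - one["sapling_present"].iloc[0]
            )
        fit = fit_recruitment_glmm(one[
            ["sapling_present", "hp", "cec", "vdnd", "n_adults", "dispersal_mode", "species"]
        ])
        assert fit.converged
        assert fit.varcomps["species"] < 1.0


class TestCWMLinearModels:
    @staticmethod
    def _cwm_frame(rng, stage_offset=0.0):
        plots = [f"P{i}" for i in range(30)]
        hp = np.linspace(2.4, 13.8, 30)
        rows = []
        for stage in ("adult", "sapling"):
            for p, h in zip(plots, hp):
                rows.append(
                    {
                        "plot_id": p,
                        "life_stage": stage,
                        "trait": "wd",
                        "cwm": 0.6
                        + (stage_offset if stage == "sapling" else 0.0)
                        + rng.normal(0, 0.02),
                        "hp": h,
                        "vdnd": rng.uniform(0, 50),
                        "cec": rng.uniform(0.1, 4),
                    }
                )
        return pd.DataFrame(rows)

    def test_identical_stages_zero_stage_effect(self, rng):
        df = self._cwm_frame(rng)
        sap = df[df["life_stage"] == "adult"].copy()
        sap["life_stage"] = "sapling"
        both = pd.concat([df[df["life_stage"] == "adult"], sap])
        fit = fit_cwm_lm(both, "wd")
        assert fit.params["stage[sapling]"] == pytest.approx(0.0, abs=1e-12)
        assert fit.params["hp:stage[sapling]"] == pytest.approx(0.0, abs=1e-12)

    def test_injected_stage_offset_recovered(self, rng):
        df = self._cwm_frame(rng, stage_offset=-0.07)
        fit = fit_cwm_lm(df, "wd", standardize=False)
        assert fit.params["stage[sapling]"] == pytest.approx(-0.07, abs=0.02)

    def test_null_hp_effect_rarely_significant(self):
        hits = 0
        reps = 40
        for r in range(reps):
            df = self._cwm_frame(np.random.default_rng(r))
            fit = fit_cwm_lm(df, "wd")
            hits += fit.pvalues["hp"] < 0.05
        assert hits / reps <= 0.15  # ~5% nominal


class TestMarginalEffects:
    def test_matches_design_matrix_prediction(self, effect_study):
        *_, rec = effect_study
        fit = fit_recruitment_glmm(rec)
        grid = np.linspace(3, 13, 7)
        out = marginal_effects(fit, grid, mode="endozoochory")
        beta = fit.params.to_numpy()
        for hp, eta in zip(out["hp"], out["linpred"]):
            row = fit.design.row(hp=hp, mode="endozoochory")
            assert eta == pytest.approx(float(row @ beta))
        assert out["predicted"].between(0, 1).all()

    def test_linear_model_margins_reproduce_coefficients(self, rng):
        df = TestCWMLinearModels._cwm_frame(rng)
        fit = fit_cwm_lm(df, "wd", standardize=False)
        out = marginal_effects(fit, np.array([5.0, 6.0]), stage="adult")
        slope = out["predicted"].iloc[1] - out["predicted"].iloc[0]
        assert slope == pytest.approx(fit.params["hp"])

    def test_extrapolation_flagged_not_refused(self, effect_study):
        *_, rec = effect_study
        fit = fit_recruitment_glmm(rec)
        out = marginal_effects(fit, np.array([0.5, 5.0, 99.0]), mode="abiotic")
        assert list(out["extrapolated"]) == [True, False, True]


class TestCorrelationsAndTests:
    def test_perfectly_linear(self):
        df = pd.DataFrame(
            {"species": list("abcde"), "x": [1.0, 2, 3, 4, 5], "y": [2.0, 4, 6, 8, 10]}
        )
        out = trait_correlations(df, ["x", "y"])
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_permutation_null(self, rng):
        n = 10_000
        x = rng.standard_normal(n)
        y = rng.permutation(x)
        df = pd.DataFrame({"species": [f"s{i}" for i in range(n)], "x": x, "y": y})
        out = trait_correlations(df, ["x", "y"])
        assert abs(out.loc[0, "r"]) < 0.05

    def test_too_few_pairs_absent(self):
        df = pd.DataFrame({"species": ["a", "b"], "x": [1.0, 2.0], "y": [1.0, np.nan]})
        out = trait_correlations(df, ["x", "y"])
        assert np.isnan(out.loc[0, "r"])
        assert out.loc[0, "n"] == 1

    @pytest.mark.parametrize(
        "p, stars",
        [
            (0.03, "*"),
            (0.0005, "***"),
            (0.2, "n.s."),
            (0.05, "*"),  # boundary
            (1e-4, "****"),
            (0.01, "**"),
            (np.nan, "n.s."),
        ],
    )
    def test_star_mapping(self, p, stars):
        assert significance_stars(p) == stars

    def test_identical_samples_ns(self):
        df = pd.DataFrame(
            {
                "species": [f"s{i}" for i in range(8)],
                "dispersal_mode": ["abiotic"] * 4 + ["endozoochory"] * 4,
                "wd": [0.5, 0.6, 0.7, 0.8] * 2,
            }
        )
        out = pairwise_mode_tests(df, "wd")
        assert out.loc[0, "p"] == pytest.approx(1.0)
        assert out.loc[0, "stars"] == "n.s."

    def test_three_sd_gap_power(self, rng):
        a = rng.normal(0, 1, 200)
        b = rng.normal(3, 1, 200)
        df = pd.DataFrame(
            {
                "species": [f"s{i}" for i in range(400)],
                "dispersal_mode": ["abiotic"] * 200 + ["endozoochory"] * 200,
                "wd": np.concatenate([a, b]),
            }
        )
        out = pairwise_mode_tests(df, "wd")
        assert out.loc[0, "stars"] == "****"

    def test_small_mode_skipped(self):
        df = pd.DataFrame(
            {
                "species": ["a", "b", "c"],
                "dispersal_mode": ["abiotic", "abiotic", "endozoochory"],
                "wd": [0.4, 0.6, 0.5],
            }
        )
        out = pairwise_mode_tests(df, "wd")
        assert out.empty


class TestNullCalibrationLMM:
    def test_st_interaction_p_uniform_under_null(self):
        # Wald p for the HP x mode interaction under a null generator should
        # be approximately uniform
        ps = []
        for r in range(60):
            *_, rec = simulate_study(40_000 + r, n_species=100)
            fit = fit_st_lmm(rec)
            names = [c for c in fit.params.index if c.startswith("hp:mode")]
            _, _, p = fit.wald_test(names)
            ps.append(p)
        stat, p_ks = stats.kstest(ps, "uniform")
        assert p_ks > 0.01
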