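"""Binomial GLMM: design building, likelihood oracles, LRT, BLUPs, VIF."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import commvar as cv
from commvar.errors import DesignError, FitError, UsageError
from commvar.glmm import (
    GlmmFit,
    GlmmSpec,
    build_design,
    fit_glmm,
    lrt,
    marginal_loglik,
    predict_reaction_norms,
    vif,
)

from _oracles import agq_loglik, irls_logistic, per_group_logit_mle
from conftest import TRUE_BETA


def _single_factor_fixture():
    """10 groups x 20 observations, one random intercept, one covariate.

    Frozen reference values for this exact fixture were computed with
    lme4::glmer (Laplace, nAGQ=1): logLik = -117.3104,
    beta = (-0.679596, 0.6161325), sd(intercept) = 0.9647399.
    """
    rng = np.random.default_rng(42)
    G, m = 10, 20
    grp = np.repeat(np.arange(G), m)
    x1 = rng.standard_normal(G * m)
    u = rng.normal(0, 0.8, G)
    eta = -0.3 + 0.6 * x1 + u[grp]
    y = (rng.random(G * m) < expit(eta)).astype(int)
    ev = pd.DataFrame(
        {
            "mother_id": [f"g{k}" for k in grp],
            "group_id": "one",
            "infant_age": x1,
            "redo": y,
        }
    )
    spec = GlmmSpec(response="redo", fixed_terms=("infant_age",), group_intercept=False)
    return build_design(ev, spec), grp, x1, y


GLMER_LL = -117.3104
GLMER_BETA = (-0.679596, 0.6161325)
GLMER_SD = 0.9647399


class TestDesign:
    def test_study_design_has_six_columns(self, sat_design):
        assert sat_design.colnames == [
            "intercept", "setting_wild", "species_sumatran",
            "infant_age", "parity", "context_binary",
        ]
        assert sat_design.X.shape[1] == 6
        assert sat_design.n_mothers == 26
        assert sat_design.n_groups == 7

    def test_direction_filter_row_count(self, study_sim):
        events = study_sim["events"]
        sub = events.query("direction == 'mother_to_infant'")
        d = build_design(sub, GlmmSpec(response="redo"))
        assert d.n_obs == len(sub)

    def test_single_level_factor_raises(self, study_sim):
        events = study_sim["events"].copy()
        events["context_binary"] = 1
        with pytest.raises(DesignError, match="context"):
            build_design(events, GlmmSpec(response="redo"))

    def test_missing_column_raises(self, study_sim):
        events = study_sim["events"].drop(columns=["parity"])
        with pytest.raises(DesignError, match="parity"):
            build_design(events, GlmmSpec(response="redo"))

    def test_slope_requires_intercept(self):
        with pytest.raises(UsageError):
            GlmmSpec(mother_intercept=False, mother_slope=True).validate()


class TestLikelihoodOracles:
    def test_collapse_to_plain_logistic(self):
        """With no random structure the fit is ordinary logistic
        regression; compare against IRLS and statsmodels oracles."""
        rng = np.random.default_rng(8)
        n = 600
        x = rng.standard_normal(n)
        y = (rng.random(n) < expit(-0.4 + 0.9 * x)).astype(int)
        ev = pd.DataFrame(
            {"mother_id": "m", "group_id": "g", "infant_age": x, "redo": y}
        )
        spec = GlmmSpec(
            response="redo", fixed_terms=("infant_age",),
            mother_intercept=False, group_intercept=False,
        )
        d = build_design(ev, spec)
        fit = fit_glmm(d)
        X = np.column_stack([np.ones(n), x])
        np.testing.assert_allclose(
            fit.beta.to_numpy(), irls_logistic(X, y), atol=1e-4
        )
        sm = pytest.importorskip("statsmodels.api")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.beta.to_numpy(), res.params, atol=1e-4)
        assert fit.loglik == pytest.approx(res.llf, abs=1e-6)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.k)

    def test_laplace_equals_one_node_quadrature(self):
        """The Laplace marginal likelihood is adaptive GH quadrature with a
        single node; the independent scalar-quadrature oracle must agree to
        numerical precision at the fitted parameters."""
        d, grp, x1, y = _single_factor_fixture()
        fit = fit_glmm(d)
        beta = fit.beta.to_numpy()
        s2 = fit.varcomps["sigma2_id"]
        eta_fixed = beta[0] + beta[1] * x1
        oracle = agq_loglik(y, eta_fixed, grp, s2, nodes=1)
        ours = marginal_loglik(d, beta, {"sigma2_id": s2})
        assert ours == pytest.approx(oracle, abs=1e-6)
        assert fit.loglik == pytest.approx(ours, abs=1e-6)

    def test_matches_frozen_glmer_reference(self):
        """Same fixture fitted by lme4::glmer (Laplace): estimates agree."""
        d, *_ = _single_factor_fixture()
        fit = fit_glmm(d)
        assert fit.loglik == pytest.approx(GLMER_LL, abs=5e-3)
        np.testing.assert_allclose(fit.beta.to_numpy(), GLMER_BETA, atol=5e-3)
        assert np.sqrt(fit.varcomps["sigma2_id"]) == pytest.approx(GLMER_SD, abs=5e-3)

    def test_sigma2_recovery_200_mothers(self):
        """200 mothers x 50 events at sigma2_id = 1: the estimate lands
        within +-0.2 of truth."""
        cfg = cv.PopulationConfig.from_cell_counts(
            {("bornean", "wild"): 200}, events_per_mother=50.0, seed=31
        )
        truth = cv.TruthParameters(
            sigma2_id=1.0, sigma2_group=0.0, sigma2_slope=0.0, rho=0.0
        )
        roster = cv.generate_population(cfg)
        events, _ = cv.generate_events(roster, truth, cfg)
        spec = GlmmSpec(
            response="satisfactory",
            fixed_terms=("infant_age", "parity", "context_binary"),
            group_intercept=False,
        )
        fit = fit_glmm(build_design(events, spec))
        assert fit.converged
        assert fit.varcomps["sigma2_id"] == pytest.approx(1.0, abs=0.2)

    def test_constant_response_raises(self):
        ev = pd.DataFrame(
            {"mother_id": list("aabb"), "group_id": "g",
             "infant_age": [1, 2, 3, 4], "redo": [1, 1, 1, 1]}
        )
        spec = GlmmSpec(response="redo", fixed_terms=("infant_age",),
                        group_intercept=False)
        with pytest.raises(FitError):
            fit_glmm(build_design(ev, spec))


class TestNestingAndLrt:
    def test_loglik_monotone_in_nesting(self, sat_fit, sat_fit_reduced, sat_fit_slope):
        assert sat_fit.loglik >= sat_fit_reduced.loglik - 1e-4
        assert sat_fit_slope.loglik >= sat_fit.loglik - 1e-4
        for f in (sat_fit, sat_fit_reduced, sat_fit_slope):
            assert f.aic == pytest.approx(-2 * f.loglik + 2 * f.k)

    def test_identical_models_give_null_result(self, sat_fit):
        res = lrt(sat_fit, sat_fit)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    @pytest.mark.parametrize(
        "stat,expected,tol",
        [(10.236, 0.001376, 1e-4), (3.841, 0.05, 5e-4), (15.065, 1.04e-4, 2e-5)],
    )
    def test_chi_square_tail(self, sat_fit, stat, expected, tol):
        """1-df tail probabilities at reference statistics."""
        reduced = dataclasses.replace(
            sat_fit, loglik=sat_fit.loglik - stat / 2.0, k=sat_fit.k - 1
        )
        res = lrt(sat_fit, reduced)
        assert res.df == 1
        assert res.p_value == pytest.approx(expected, abs=tol)
        assert "boundary" in res.note

    def test_mother_identity_significant_at_study_scale(
        self, sat_fit, sat_fit_reduced
    ):
        res = lrt(sat_fit, sat_fit_reduced)
        assert res.df == 1
        assert res.statistic > 0
        assert res.p_value < 0.05

    def test_non_nested_specs_raise(self, sat_fit, study_sim):
        other = build_design(
            study_sim["events"].query("direction == 'infant_to_mother'"),
            GlmmSpec(response="satisfactory", fixed_terms=("infant_age",)),
        )
        fit_other = fit_glmm(other)
        with pytest.raises(UsageError):
            lrt(sat_fit, fit_other)


class TestBlups:
    def test_shrinkage_vs_per_group_mle(self):
        """Strongly separated balanced groups: conditional modes shrink
        toward zero relative to the unpooled per-group logit MLEs."""
        rng = np.random.default_rng(6)
        mothers = np.repeat([f"m{i}" for i in range(6)], 40)
        probs = np.repeat([0.85, 0.8, 0.75, 0.25, 0.2, 0.15], 40)
        y = (rng.random(len(mothers)) < probs).astype(int)
        ev = pd.DataFrame(
            {"mother_id": mothers, "group_id": "g", "infant_age": 1.0, "redo": y}
        )
        spec = GlmmSpec(response="redo", fixed_terms=(), group_intercept=False)
        fit = fit_glmm(build_design(ev, spec))
        mles = per_group_logit_mle(y, mothers)
        centered = {k: v - np.mean(list(mles.values())) for k, v in mles.items()}
        for m, blup in fit.blups["mother_intercept"].items():
            assert abs(blup) < abs(centered[m])
            assert np.sign(blup) == np.sign(centered[m])

    def test_no_clustering_shrinks_to_zero(self):
        """Unclustered data: the variance collapses and BLUPs vanish."""
        rng = np.random.default_rng(13)
        n = 2000
        ev = pd.DataFrame(
            {
                "mother_id": rng.choice([f"m{i}" for i in range(20)], n),
                "group_id": "g",
                "infant_age": rng.standard_normal(n),
                "redo": (rng.random(n) < 0.4).astype(int),
            }
        )
        spec = GlmmSpec(response="redo", fixed_terms=("infant_age",),
                        group_intercept=False)
        fit = fit_glmm(build_design(ev, spec))
        assert fit.varcomps["sigma2_id"] < 0.05
        assert fit.blups["mother_intercept"].abs().max() < 0.1

    def test_blups_track_true_intercepts(self, sat_fit, study_sim):
        truth = study_sim["effects"].mother.set_index("mother_id")["intercept"]
        est = sat_fit.blups["mother_intercept"]
        joined = pd.concat([truth, est], axis=1, join="inner")
        rho = joined.corr(method="spearman").iloc[0, 1]
        assert rho > 0.3


class TestVif:
    def test_orthogonal_predictors_unit_vif(self):
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        ev = pd.DataFrame(
            {"mother_id": "m", "group_id": "g", "infant_age": x1, "parity": x2,
             "redo": np.tile([0, 1], n // 2)}
        )
        spec = GlmmSpec(response="redo", fixed_terms=("infant_age", "parity"),
                        mother_intercept=False, group_intercept=False)
        res = vif(build_design(ev, spec))
        np.testing.assert_allclose(res.values.to_numpy(), 1.0, atol=1e-10)
        assert not res.collinear

    def test_correlated_pair_closed_form_and_oracle(self):
        """r = 0.9 gives VIF = 1/(1-0.81); a random third predictor matches
        a direct least-squares R^2 oracle."""
        rng = np.random.default_rng(21)
        n = 4000
        x1 = rng.standard_normal(n)
        x2 = 0.9 * x1 + np.sqrt(1 - 0.81) * rng.standard_normal(n)
        x3 = rng.standard_normal(n)
        ev = pd.DataFrame(
            {"mother_id": "m", "group_id": "g", "infant_age": x1, "parity": x2,
             "context_binary": x3, "redo": (rng.random(n) < 0.5).astype(int)}
        )
        spec = GlmmSpec(
            response="redo", fixed_terms=("infant_age", "parity", "context_binary"),
            mother_intercept=False, group_intercept=False,
        )
        d = build_design(ev, spec)
        res = vif(d)
        assert res.values["infant_age"] == pytest.approx(1 / (1 - 0.81), rel=0.05)
        # oracle for one predictor: R^2 from lstsq of x2 on (1, x1, x3)
        A = np.column_stack([np.ones(n), x1, x3])
        coef, *_ = np.linalg.lstsq(A, x2, rcond=None)
        r2 = 1 - np.sum((x2 - A @ coef) ** 2) / np.sum((x2 - x2.mean()) ** 2)
        assert res.values["parity"] == pytest.approx(1 / (1 - r2), rel=1e-6)

    def test_collinear_flagged_infinite(self):
        x = np.arange(10.0)
        ev = pd.DataFrame(
            {"mother_id": "m", "group_id": "g", "infant_age": x, "parity": 2 * x,
             "redo": np.tile([0, 1], 5)}
        )
        spec = GlmmSpec(response="redo", fixed_terms=("infant_age", "parity"),
                        mother_intercept=False, group_intercept=False)
        res = vif(build_design(ev, spec))
        assert res.collinear
        assert np.isinf(res.max_vif)

    def test_study_design_no_collinearity(self, sat_design):
        res = vif(sat_design)
        assert res.max_vif < 5.0


class TestReactionNormPredictions:
    def test_intercept_model_parallel_on_logit_scale(self, sat_fit):
        pred = predict_reaction_norms(sat_fit)
        wide = pred.pivot(index="mother_id", columns="context_binary", values="eta")
        diffs = wide[1] - wide[0]
        np.testing.assert_allclose(
            diffs.to_numpy(), sat_fit.beta["context_binary"], atol=1e-10
        )
        assert pred["prob"].between(0, 1).all()
        np.testing.assert_allclose(
            pred["prob"], expit(pred["eta"]), atol=1e-12
        )

    def test_slope_model_lines_diverge(self, sat_fit_slope):
        pred = predict_reaction_norms(sat_fit_slope)
        wide = pred.pivot(index="mother_id", columns="context_binary", values="eta")
        diffs = (wide[1] - wide[0]).to_numpy()
        assert np.std(diffs) > 1e-4
        slope_blups = sat_fit_slope.blups["mother_slope"]
        expected = sat_fit_slope.beta["context_binary"] + slope_blups
        np.testing.assert_allclose(
            np.sort(diffs), np.sort(expected.to_numpy()), atol=1e-8
        )


class TestWaldCoverage:
    def test_context_effect_coverage_near_nominal(self, recovery_study):
        """95% Wald intervals for the within-individual context effect hit
        close to nominal coverage; cluster-level covariates (setting,
        species) under-cover with 26 clusters, a known property of
        theta-conditional Wald intervals."""
        reps = recovery_study[0.0]
        hits = {name: 0 for name in TRUE_BETA}
        for rep in reps:
            for name, true in TRUE_BETA.items():
                if abs(rep["beta"][name] - true) <= 1.96 * rep["se"][name]:
                    hits[name] += 1
        n = len(reps)
        assert hits["context_binary"] / n >= 0.88
        assert np.mean([h / n for h in hits.values()]) >= 0.72
        for name in ("setting_wild", "species_sumatran"):
            assert hits[name] / n >= 0.55
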