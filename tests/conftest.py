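"""Shared fixtures: study-shaped simulations and fitted models.

Expensive objects (GLMM fits, the 50-replicate recovery study) are
session-scoped so several tests can interrogate the same computation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

import commvar as cv
from commvar.glmm import GlmmSpec, build_design, fit_glmm
from commvar.reaction_norms import LOGIT_RESIDUAL_VARIANCE, compare_models, repeatability

#: true fixed effects of the default synthetic truth, keyed by design column
TRUE_BETA = {
    "intercept": -1.0,
    "setting_wild": -0.3,
    "species_sumatran": 0.2,
    "infant_age": 0.05,
    "parity": -0.05,
    "context_binary": 0.8,
}


@pytest.fixture(scope="session")
def study_sim():
    """One study-shaped dataset (26 mothers, 7 groups) with known truth."""
    cfg = dataclasses.replace(cv.PopulationConfig(), seed=7)
    truth = cv.TruthParameters()
    roster = cv.generate_population(cfg)
    events, effects = cv.generate_events(
        roster, truth, cfg, dataclasses.replace(cv.RepertoireConfig(), seed=7)
    )
    return {"config": cfg, "truth": truth, "roster": roster,
            "events": events, "effects": effects}


@pytest.fixture(scope="session")
def sat_design(study_sim):
    sub = study_sim["events"].query("direction == 'infant_to_mother'")
    return build_design(sub, GlmmSpec(response="satisfactory"))


@pytest.fixture(scope="session")
def sat_fit(sat_design):
    return fit_glmm(sat_design)


@pytest.fixture(scope="session")
def sat_fit_slope(sat_design, sat_fit):
    spec = dataclasses.replace(sat_design.spec, mother_slope=True)
    return fit_glmm(sat_design.with_spec(spec), start=sat_fit.varcomps)


@pytest.fixture(scope="session")
def sat_fit_reduced(sat_design):
    spec = dataclasses.replace(sat_design.spec, mother_intercept=False)
    return fit_glmm(sat_design.with_spec(spec))


def _recovery_rep(seed: int, sigma2_slope: float) -> dict:
    """One replicate of the study-scale parameter-recovery simulation.

    Truth places latent individual repeatability at exactly 0.10:
    sigma2_id = 0.10/0.90 * (sigma2_group + pi^2/3).
    """
    s2_group = 0.15
    s2_id = 0.10 / 0.90 * (s2_group + LOGIT_RESIDUAL_VARIANCE)
    truth = cv.TruthParameters(
        sigma2_id=s2_id, sigma2_group=s2_group, sigma2_slope=sigma2_slope, rho=0.0
    )
    cfg = dataclasses.replace(cv.PopulationConfig(), seed=seed)
    roster = cv.generate_population(cfg)
    events, _ = cv.generate_events(roster, truth, cfg)
    sub = events.query("direction == 'infant_to_mother'")
    design = build_design(sub, GlmmSpec(response="satisfactory"))
    fit_int = fit_glmm(design)
    fit_slope = fit_glmm(
        design.with_spec(dataclasses.replace(design.spec, mother_slope=True)),
        start=fit_int.varcomps,
    )
    comp = compare_models(fit_int, fit_slope)
    return {
        "R": repeatability(fit_int, "individual").R,
        "delta_aic": comp.delta_aic,
        "beta": fit_int.beta,
        "se": fit_int.se,
        "n_obs": design.n_obs,
        "converged": fit_int.converged and fit_slope.converged,
    }


@pytest.fixture(scope="session")
def recovery_study():
    """50 replicates x 2 slope-variance conditions at study scale
    (26 mothers, ~3500 infant-request events per replicate)."""
    return {
        sigma2_slope: [_recovery_rep(1000 + i, sigma2_slope) for i in range(50)]
        for sigma2_slope in (0.0, 1.5)
    }
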