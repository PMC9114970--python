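"""Latent-scale repeatability (ICC) and random-regression model selection.

For a binomial-logit mixed model the residual variance on the latent scale
is pi^2/3, so the adjusted repeatability at a grouping level is

    R_level = sigma2_level / (sigma2_id + sigma2_group + pi^2/3)

(fixed effects are in the model but their variance is excluded from the
denominator).  Uncertainty comes from a parametric bootstrap — simulate
from the fitted model, refit, recompute R — and the p-value from a
likelihood-ratio test dropping the focal variance component (naive 1-df
chi-square reference, conservative on the boundary).  The two procedures
differ, which is how a confidence interval touching 0 can coexist with a
small p-value.

Random-intercept versus random-slope (random regression) models are
compared on AIC: the slope model is preferred only when its AIC is more
than 7 units lower.  Under random slopes repeatability is context
dependent; the reported R refers to the reference context (slope term 0).
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .errors import UsageError
from .glmm import GlmmFit, GlmmSpec, fit_glmm, lrt, simulate_response

#: residual variance of the logistic latent scale
LOGIT_RESIDUAL_VARIANCE = float(np.pi**2 / 3.0)

LEVELS = ("individual", "group")

#: the slope model must beat the intercept model by more than this
DELTA_AIC_THRESHOLD = 7.0

_LEVEL_VARCOMP = {"individual": "sigma2_id", "group": "sigma2_group"}


@dataclass
class RepeatabilityResult:
    """Variance-standardized repeatability with optional uncertainty."""

    R: float
    level: str
    se: float | None = None
    ci: tuple[float, float] | None = None
    p_value: float | None = None
    lrt_statistic: float | None = None
    n_boot: int = 0
    seed: int | None = None
    n_boot_failed: int = 0
    high_failure_rate: bool = False
    note: str = ""


@dataclass
class ModelComparison:
    """AIC comparison of random-intercept vs random-slope models."""

    aic_intercept: float
    aic_slope: float
    delta_aic: float
    preferred: str
    threshold: float = DELTA_AIC_THRESHOLD
    lrt_statistic: float | None = None
    lrt_df: int | None = None
    lrt_p: float | None = None


def _check_level(fit: GlmmFit, level: str) -> str:
    if level not in LEVELS:
        raise UsageError(f"unknown level {level!r}; expected one of {LEVELS}")
    comp = _LEVEL_VARCOMP[level]
    present = fit.spec.mother_intercept if level == "individual" else fit.spec.group_intercept
    if not present:
        raise UsageError(f"level {level!r} is not among the fit's random terms")
    return comp


def _point_R(varcomps: dict[str, float], comp: str) -> float:
    denom = (
        varcomps.get("sigma2_id", 0.0)
        + varcomps.get("sigma2_group", 0.0)
        + LOGIT_RESIDUAL_VARIANCE
    )
    return float(varcomps.get(comp, 0.0) / denom)


def repeatability(fit: GlmmFit, level: str = "individual") -> RepeatabilityResult:
    """Point estimate of the latent-scale adjusted repeatability."""
    comp = _check_level(fit, level)
    if not fit.converged:
        raise UsageError("repeatability requested from a non-converged fit")
    note = ""
    if fit.spec.mother_slope:
        note = "random-slope model: R refers to the reference context (slope term = 0)"
    return RepeatabilityResult(R=_point_R(fit.varcomps, comp), level=level, note=note)


def _reduced_spec(spec: GlmmSpec, level: str) -> GlmmSpec:
    if level == "individual":
        return dc_replace(spec, mother_intercept=False, mother_slope=False)
    return dc_replace(spec, group_intercept=False)


def repeatability_uncertainty(
    fit: GlmmFit,
    level: str = "individual",
    n_boot: int = 1000,
    seed: int | None = 0,
) -> RepeatabilityResult:
    """Repeatability with parametric-bootstrap se/CI and an LRT p-value.

    Bootstrap: simulate responses from the fitted model (fresh random
    effects and Bernoulli noise), refit the same specification, recompute
    R; se is the bootstrap standard deviation, the CI the 2.5/97.5
    percentile interval truncated at 0.  ``n_boot=0`` returns the point
    estimate only.  The p-value is computed on the original data by
    refitting without the focal random term.  Replicates whose refit fails
    or does not converge are dropped; a failure rate above 20% sets
    ``high_failure_rate``.
    """
    comp = _check_level(fit, level)
    result = repeatability(fit, level)
    design = fit.design
    if design is None:
        raise UsageError("fit carries no design; cannot bootstrap")

    reduced = fit_glmm(design.with_spec(_reduced_spec(fit.spec, level)))
    test = lrt(fit, reduced)
    result.p_value = test.p_value
    result.lrt_statistic = test.statistic

    if n_boot <= 0:
        return result

    rng = np.random.default_rng(seed)
    beta = fit.beta.to_numpy()
    draws = []
    failed = 0
    for _ in range(int(n_boot)):
        y_star = simulate_response(design, beta, fit.varcomps, rng)
        if y_star.min() == y_star.max():
            failed += 1
            continue
        try:
            refit = fit_glmm(design.with_response(y_star), start=fit.varcomps)
        except Exception:
            failed += 1
            continue
        if not refit.converged:
            failed += 1
            continue
        draws.append(_point_R(refit.varcomps, comp))

    result.n_boot = int(n_boot)
    result.seed = seed
    result.n_boot_failed = failed
    result.high_failure_rate = failed > 0.2 * n_boot
    if draws:
        arr = np.asarray(draws)
        result.se = float(arr.std(ddof=1)) if len(arr) > 1 else None
        lo, hi = np.percentile(arr, [2.5, 97.5])
        result.ci = (float(max(0.0, lo)), float(max(0.0, hi)))
    return result


def compare_models(fit_intercept: GlmmFit, fit_slope: GlmmFit) -> ModelComparison:
    """AIC comparison with the strict delta-AIC > 7 preference rule."""
    if fit_intercept.spec.mother_slope or not fit_slope.spec.mother_slope:
        raise UsageError("expected (intercept-only fit, random-slope fit)")
    if fit_intercept.fingerprint != fit_slope.fingerprint:
        raise UsageError("model comparison across different data (fingerprint mismatch)")
    delta = fit_intercept.aic - fit_slope.aic
    preferred = "slope" if delta > DELTA_AIC_THRESHOLD else "intercept"
    test = lrt(fit_slope, fit_intercept)
    return ModelComparison(
        aic_intercept=fit_intercept.aic,
        aic_slope=fit_slope.aic,
        delta_aic=float(delta),
        preferred=preferred,
        lrt_statistic=test.statistic,
        lrt_df=test.df,
        lrt_p=test.p_value,
    )
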