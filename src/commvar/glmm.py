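"""Binomial logit mixed models via Laplace-approximated maximum likelihood.

The model for a binary response y_i is

    y_i ~ Bernoulli(expit(eta_i))
    eta  = X beta + u[mother] + v[group] + s[mother] * context

with crossed random intercepts u ~ N(0, sigma2_id), v ~ N(0, sigma2_group)
and, optionally, individual random slopes s over the binary social context,
where (u, s) are bivariate normal with correlation rho (a random-regression
/ behavioural-reaction-norm model).  The marginal likelihood integrates the
random effects out with a Laplace approximation: the conditional mode b-hat
is found by a penalized Newton inner loop, and the outer optimizer runs
over the fixed effects plus variance parameters (standard deviations on the
log scale, the correlation through an unconstrained tanh parameter, i.e. a
Cholesky factor of the 2x2 intercept/slope covariance).

No restricted likelihood is attempted (REML is undefined here) and no
priors or penalties are applied; boundary estimates (a variance pinned at
0) are reported as such rather than hidden.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import chi2

from .errors import DesignError, FitError, UsageError

RESPONSES = ("redo", "satisfactory")

#: fixed-effect terms of the study's full model, in order
DEFAULT_FIXED_TERMS = ("setting", "species", "infant_age", "parity", "context_binary")

_BINARY_FACTORS = {
    "setting": ("setting_wild", "wild"),
    "species": ("species_sumatran", "sumatran"),
}

#: |beta| beyond this on the logit scale flags (quasi-)complete separation
SEPARATION_BOUND = 15.0

_LOG_SD_BOUNDS = (-7.0, 3.0)
_ZRHO_BOUND = 5.0


@dataclass
class GlmmSpec:
    """Model specification: response, fixed terms and random structure."""

    response: str = "redo"
    fixed_terms: tuple[str, ...] = DEFAULT_FIXED_TERMS
    mother_intercept: bool = True
    group_intercept: bool = True
    mother_slope: bool = False
    slope_term: str = "context_binary"

    def validate(self) -> None:
        if self.mother_slope and not self.mother_intercept:
            raise UsageError("a mother random slope requires the mother intercept")
        if self.mother_slope and self.slope_term not in self.fixed_terms:
            raise UsageError("the random-slope term must also be a fixed term")

    @property
    def has_random(self) -> bool:
        return self.mother_intercept or self.group_intercept

    def theta_names(self) -> tuple[str, ...]:
        names = []
        if self.mother_intercept:
            names.append("log_sd_id")
        if self.group_intercept:
            names.append("log_sd_group")
        if self.mother_slope:
            names += ["log_sd_slope", "z_rho"]
        return tuple(names)


@dataclass
class Design:
    """Model matrices plus grouping indices for one response analysis."""

    X: np.ndarray
    y: np.ndarray
    colnames: list[str]
    spec: GlmmSpec
    mother_codes: np.ndarray
    mother_levels: list[str]
    group_codes: np.ndarray
    group_levels: list[str]
    ctx: np.ndarray
    frame: pd.DataFrame
    fingerprint: str = ""

    def __post_init__(self) -> None:
        if not self.fingerprint:
            h = hashlib.sha256()
            h.update(self.X.tobytes())
            h.update(self.y.tobytes())
            h.update(self.spec.response.encode())
            self.fingerprint = h.hexdigest()[:16]

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_mothers(self) -> int:
        return len(self.mother_levels)

    @property
    def n_groups(self) -> int:
        return len(self.group_levels)

    def with_response(self, y: np.ndarray) -> "Design":
        return replace(self, y=np.asarray(y, dtype=float), fingerprint="")

    def with_spec(self, spec: GlmmSpec) -> "Design":
        """Same data, different random structure (fixed part unchanged)."""
        spec.validate()
        return replace(self, spec=spec)


def build_design(events: pd.DataFrame, spec: GlmmSpec) -> Design:
    """Build dense fixed-effect and sparse random-effect structures.

    Binary factors get treatment coding (wild = 1, sumatran = 1); the
    covariates infant_age and parity enter untransformed.  A factor with a
    single observed level is a design error naming the factor.
    """
    spec.validate()
    if events.empty:
        raise DesignError("event table is empty")
    needed = {"mother_id", "group_id", spec.response} | set(spec.fixed_terms)
    missing = sorted(needed - set(events.columns))
    if missing:
        raise DesignError(f"missing column(s): {missing}")

    n = len(events)
    cols = [np.ones(n)]
    names = ["intercept"]
    for term in spec.fixed_terms:
        if term in _BINARY_FACTORS:
            colname, ref1 = _BINARY_FACTORS[term]
            levels = set(events[term].unique())
            if len(levels) < 2:
                raise DesignError(f"factor {term!r} has a single level: {levels}")
            cols.append((events[term] == ref1).to_numpy(dtype=float))
            names.append(colname)
        elif term == "context_binary":
            vals = set(pd.unique(events[term]))
            if len(vals) < 2:
                raise DesignError(f"factor 'context_binary' has a single level: {vals}")
            cols.append(events[term].to_numpy(dtype=float))
            names.append(term)
        else:
            cols.append(events[term].to_numpy(dtype=float))
            names.append(term)
    X = np.column_stack(cols)
    y = events[spec.response].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise DesignError(f"response {spec.response!r} must be binary 0/1")

    mother = pd.Categorical(events["mother_id"].astype(str))
    group = pd.Categorical(events["group_id"].astype(str))
    ctx = (
        events[spec.slope_term].to_numpy(dtype=float)
        if spec.slope_term in events.columns
        else np.zeros(n)
    )
    return Design(
        X=X,
        y=y,
        colnames=names,
        spec=spec,
        mother_codes=np.asarray(mother.codes, dtype=np.int64),
        mother_levels=list(mother.categories),
        group_codes=np.asarray(group.codes, dtype=np.int64),
        group_levels=list(group.categories),
        ctx=ctx,
        frame=events.reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# variance parameterization


def varcomps_from_theta(theta: np.ndarray, spec: GlmmSpec) -> dict[str, float]:
    out = {"sigma2_id": 0.0, "sigma2_group": 0.0, "sigma2_slope": 0.0, "rho": 0.0}
    i = 0
    if spec.mother_intercept:
        out["sigma2_id"] = float(np.exp(2 * theta[i])); i += 1
    if spec.group_intercept:
        out["sigma2_group"] = float(np.exp(2 * theta[i])); i += 1
    if spec.mother_slope:
        out["sigma2_slope"] = float(np.exp(2 * theta[i])); i += 1
        out["rho"] = float(np.tanh(theta[i])); i += 1
    return out


def theta_from_varcomps(vc: dict[str, float], spec: GlmmSpec) -> np.ndarray:
    lo = _LOG_SD_BOUNDS[0]

    def _log_sd(v: float) -> float:
        return max(lo, 0.5 * np.log(max(v, 1e-12)))

    theta = []
    if spec.mother_intercept:
        theta.append(_log_sd(vc.get("sigma2_id", 0.0)))
    if spec.group_intercept:
        theta.append(_log_sd(vc.get("sigma2_group", 0.0)))
    if spec.mother_slope:
        theta.append(_log_sd(vc.get("sigma2_slope", 0.0)))
        theta.append(float(np.arctanh(np.clip(vc.get("rho", 0.0), -0.9999, 0.9999))))
    return np.asarray(theta, dtype=float)


def _precision(theta: np.ndarray, design: Design) -> tuple[np.ndarray, float]:
    """Dense precision matrix of the stacked random effects and log|P|."""
    spec = design.spec
    M, G = design.n_mothers, design.n_groups
    vc = varcomps_from_theta(np.asarray(theta, dtype=float), spec)
    blocks_dim = (M if spec.mother_intercept else 0) + (
        G if spec.group_intercept else 0
    ) + (M if spec.mother_slope else 0)
    P = np.zeros((blocks_dim, blocks_dim))
    logdet = 0.0
    off = 0
    mother_off = None
    if spec.mother_intercept:
        mother_off = off
        off += M
    group_off = None
    if spec.group_intercept:
        group_off = off
        off += G
    slope_off = None
    if spec.mother_slope:
        slope_off = off
        off += M

    if spec.mother_slope:
        s1, s3, r = vc["sigma2_id"], vc["sigma2_slope"], vc["rho"]
        cov = np.array(
            [[s1, r * np.sqrt(s1 * s3)], [r * np.sqrt(s1 * s3), s3]]
        )
        prec2 = np.linalg.inv(cov)
        sign, ld = np.linalg.slogdet(prec2)
        idx = np.arange(M)
        P[mother_off + idx, mother_off + idx] = prec2[0, 0]
        P[slope_off + idx, slope_off + idx] = prec2[1, 1]
        P[mother_off + idx, slope_off + idx] = prec2[0, 1]
        P[slope_off + idx, mother_off + idx] = prec2[1, 0]
        logdet += M * ld
    elif spec.mother_intercept:
        idx = np.arange(M)
        P[mother_off + idx, mother_off + idx] = 1.0 / vc["sigma2_id"]
        logdet += -M * np.log(vc["sigma2_id"])
    if spec.group_intercept:
        idx = np.arange(G)
        P[group_off + idx, group_off + idx] = 1.0 / vc["sigma2_group"]
        logdet += -G * np.log(vc["sigma2_group"])
    return P, float(logdet)


# ---------------------------------------------------------------------------
# likelihood machinery


def _bern_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _plain_logistic(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Newton (IRLS) logistic regression; returns (beta, cov, loglik)."""
    beta = np.zeros(X.shape[1])
    for _ in range(100):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = sla.solve(H, grad, assume_a="pos")
        except sla.LinAlgError as exc:
            raise FitError(f"singular fixed-effects design: {exc}") from exc
        f0 = _bern_loglik(y, eta)
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            if _bern_loglik(y, X @ cand) >= f0 - 1e-12:
                break
            t *= 0.5
        beta = beta + t * step
        if np.max(np.abs(grad)) < 1e-10 * (1 + abs(f0)):
            break
    eta = X @ beta
    mu = expit(eta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    H = (X * w[:, None]).T @ X
    return beta, np.linalg.inv(H), _bern_loglik(y, eta)


class _LaplaceObjective:
    """Negative Laplace marginal log-likelihood over (beta, theta).

    Exploits the indicator structure of the random-effect design: Z-products
    reduce to index gathers and bincounts, and the penalized Hessian is
    assembled block-wise, so each objective evaluation costs O(n) plus one
    dense Cholesky of the (small) random-effect dimension.  The conditional
    mode is warm-started across evaluations so the finite-difference
    gradients of the outer optimizer stay cheap and consistent.
    """

    def __init__(self, design: Design):
        self.design = design
        self.X = design.X
        self.y = design.y
        spec = design.spec
        self.m = design.mother_codes
        self.g = design.group_codes
        self.ctx = design.ctx.astype(float)
        self.M = design.n_mothers
        self.G = design.n_groups
        off = 0
        self.u_off = self.v_off = self.s_off = None
        if spec.mother_intercept:
            self.u_off = off
            off += self.M
        if spec.group_intercept:
            self.v_off = off
            off += self.G
        if spec.mother_slope:
            self.s_off = off
            off += self.M
        self.q = off
        self.b = np.zeros(self.q)
        # flat indices for the crossed mother x group Hessian block
        self._mg = self.m * self.G + self.g
        self._gm = self.g * self.M + self.m

    def eta_random(self, b: np.ndarray) -> np.ndarray:
        eta = np.zeros(len(self.y))
        if self.u_off is not None:
            eta += b[self.u_off + self.m]
        if self.v_off is not None:
            eta += b[self.v_off + self.g]
        if self.s_off is not None:
            eta += b[self.s_off + self.m] * self.ctx
        return eta

    def _grad_random(self, r: np.ndarray) -> np.ndarray:
        parts = []
        if self.u_off is not None:
            parts.append(np.bincount(self.m, weights=r, minlength=self.M))
        if self.v_off is not None:
            parts.append(np.bincount(self.g, weights=r, minlength=self.G))
        if self.s_off is not None:
            parts.append(np.bincount(self.m, weights=r * self.ctx, minlength=self.M))
        return np.concatenate(parts)

    def _hessian(self, w: np.ndarray, P: np.ndarray) -> np.ndarray:
        """Dense Z'WZ + P assembled from its diagonal and crossed blocks."""
        H = P.copy()
        M, G = self.M, self.G
        uo, vo, so = self.u_off, self.v_off, self.s_off
        if uo is not None:
            d = np.bincount(self.m, weights=w, minlength=M)
            H[uo + np.arange(M), uo + np.arange(M)] += d
        if vo is not None:
            d = np.bincount(self.g, weights=w, minlength=G)
            H[vo + np.arange(G), vo + np.arange(G)] += d
        if uo is not None and vo is not None:
            B = np.bincount(self._mg, weights=w, minlength=M * G).reshape(M, G)
            H[uo:uo + M, vo:vo + G] += B
            H[vo:vo + G, uo:uo + M] += B.T
        if so is not None:
            wc = w * self.ctx
            d = np.bincount(self.m, weights=wc * self.ctx, minlength=M)
            H[so + np.arange(M), so + np.arange(M)] += d
            dc = np.bincount(self.m, weights=wc, minlength=M)
            H[uo + np.arange(M), so + np.arange(M)] += dc
            H[so + np.arange(M), uo + np.arange(M)] += dc
            if vo is not None:
                C = np.bincount(self._gm, weights=wc, minlength=G * M).reshape(G, M)
                H[vo:vo + G, so:so + M] += C
                H[so:so + M, vo:vo + G] += C.T
        return H

    def _mode(
        self, eta_fixed: np.ndarray, P: np.ndarray, b0: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, float]:
        """Penalized Newton for the conditional mode; returns (b, chol(H), f)."""
        y = self.y
        b = b0.copy()
        eta = eta_fixed + self.eta_random(b)
        f = _bern_loglik(y, eta) - 0.5 * b @ (P @ b)
        chol = None
        for _ in range(100):
            mu = expit(eta)
            grad = self._grad_random(y - mu) - P @ b
            w = np.clip(mu * (1 - mu), 1e-10, None)
            H = self._hessian(w, P)
            try:
                chol = sla.cho_factor(H, check_finite=False)
            except sla.LinAlgError:
                chol = sla.cho_factor(H + 1e-8 * np.eye(self.q), check_finite=False)
            step = sla.cho_solve(chol, grad, check_finite=False)
            t = 1.0
            for _ in range(30):
                cand = b + t * step
                eta_c = eta_fixed + self.eta_random(cand)
                f_c = _bern_loglik(y, eta_c) - 0.5 * cand @ (P @ cand)
                if f_c >= f - 1e-12:
                    break
                t *= 0.5
            b, eta, f = cand, eta_c, f_c
            if np.max(np.abs(grad)) < 1e-10 * (1 + abs(f)):
                break
        # refresh the factor at the accepted mode
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        H = self._hessian(w, P)
        try:
            chol = sla.cho_factor(H, check_finite=False)
        except sla.LinAlgError:
            chol = sla.cho_factor(H + 1e-8 * np.eye(self.q), check_finite=False)
        return b, chol, f

    def loglik(self, beta: np.ndarray, theta: np.ndarray) -> float:
        P, logdetP = _precision(theta, self.design)
        eta_fixed = self.X @ beta
        b, chol, f = self._mode(eta_fixed, P, self.b)
        self.b = b
        logdetH = 2.0 * float(np.sum(np.log(np.diag(chol[0]))))
        return f + 0.5 * logdetP - 0.5 * logdetH

    def __call__(self, x: np.ndarray) -> float:
        p = self.X.shape[1]
        ll = self.loglik(x[:p], x[p:])
        return -ll if np.isfinite(ll) else 1e12

    def beta_cov(self, beta: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """Fixed-effect covariance conditional on theta (Schur complement
        of the joint penalized Hessian at the mode, the standard GLMM
        Wald covariance)."""
        P, _ = _precision(theta, self.design)
        eta_fixed = self.X @ beta
        b, chol, _ = self._mode(eta_fixed, P, self.b)
        eta = eta_fixed + self.eta_random(b)
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        XW = self.X * w[:, None]
        XWX = XW.T @ self.X
        XWZ = np.column_stack([self._grad_random(XW[:, j]) for j in range(XW.shape[1])]).T
        info = XWX - XWZ @ sla.cho_solve(chol, XWZ.T, check_finite=False)
        return np.linalg.inv(info)


@dataclass
class GlmmFit:
    """A fitted binomial mixed model."""

    spec: GlmmSpec
    beta: pd.Series
    se: pd.Series
    varcomps: dict[str, float]
    loglik: float
    k: int
    aic: float
    blups: dict[str, pd.Series]
    converged: bool
    n_obs: int
    boundary: dict[str, bool] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    theta: np.ndarray | None = None
    design: Design | None = None
    fingerprint: str = ""


def marginal_loglik(design: Design, beta: np.ndarray, varcomps: dict[str, float]) -> float:
    """Laplace marginal log-likelihood at given parameters (no fitting)."""
    spec = design.spec
    if not spec.has_random:
        return _bern_loglik(design.y, design.X @ np.asarray(beta, dtype=float))
    obj = _LaplaceObjective(design)
    theta = theta_from_varcomps(varcomps, spec)
    return obj.loglik(np.asarray(beta, dtype=float), theta)


def fit_glmm(design: Design, start: dict | None = None) -> GlmmFit:
    """Maximum-likelihood fit of the specified binomial mixed model.

    The outer optimization (L-BFGS-B with finite-difference gradients) runs
    over fixed effects and log-scale variance parameters jointly; the inner
    Newton loop profiles out the random-effect modes.  A stalled optimizer
    yields ``converged=False`` rather than an exception; a variance pinned
    at its lower bound is flagged in ``boundary``.
    """
    spec = design.spec
    spec.validate()
    y = design.y
    if y.min() == y.max():
        raise FitError(f"response {spec.response!r} is constant (separation)")

    warnings: list[str] = []

    if not spec.has_random:
        beta, cov, ll = _plain_logistic(design.X, y)
        se = np.sqrt(np.diag(cov))
        k = len(beta)
        fit = GlmmFit(
            spec=spec,
            beta=pd.Series(beta, index=design.colnames),
            se=pd.Series(se, index=design.colnames),
            varcomps={"sigma2_id": 0.0, "sigma2_group": 0.0, "sigma2_slope": 0.0, "rho": 0.0},
            loglik=ll,
            k=k,
            aic=-2 * ll + 2 * k,
            blups={},
            converged=True,
            n_obs=design.n_obs,
            theta=np.empty(0),
            design=design,
            fingerprint=design.fingerprint,
        )
        _check_separation(fit)
        return fit

    for name, levels in (
        ("mother_id", design.n_mothers if spec.mother_intercept else 2),
        ("group_id", design.n_groups if spec.group_intercept else 2),
    ):
        if levels < 2:
            raise FitError(f"random factor {name!r} needs >= 2 levels")

    p = design.X.shape[1]
    beta0, _, _ = _plain_logistic(design.X, y)
    if start is not None:
        # keep warm starts off the boundary: a start pinned at sigma = 0
        # makes the outer optimizer crawl along the constraint
        clean = {
            k: max(float(v), 0.02)
            for k, v in start.items()
            if k.startswith("sigma2")
        }
        clean["rho"] = float(np.clip(start.get("rho", 0.0), -0.8, 0.8))
        theta0 = theta_from_varcomps(clean, spec)
    else:
        theta0 = theta_from_varcomps(
            dict.fromkeys(("sigma2_id", "sigma2_group", "sigma2_slope"), 0.25), spec
        )
    x0 = np.concatenate([beta0, theta0])

    obj = _LaplaceObjective(design)
    bounds = [(-30.0, 30.0)] * p
    for name in spec.theta_names():
        bounds.append(
            (-_ZRHO_BOUND, _ZRHO_BOUND) if name == "z_rho" else _LOG_SD_BOUNDS
        )
    res = minimize(
        obj,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={
            "maxiter": 1000,
            "ftol": 1e-11,
            "gtol": 1e-6,
            "maxfun": 100000,
            "eps": 1e-6,
        },
    )
    converged = bool(res.success)
    if not converged:
        # Nelder-Mead polish from the stall point, then accept if improved
        res2 = minimize(
            obj, res.x, method="Nelder-Mead",
            options={"maxiter": 4000, "fatol": 1e-10, "xatol": 1e-8},
        )
        if res2.fun <= res.fun + 1e-9:
            res = res2
            converged = bool(res2.success)
        if not converged:
            warnings.append("outer optimizer did not meet its tolerance")

    x = res.x
    beta_hat, theta_hat = x[:p], x[p:]
    ll = -float(res.fun)
    vc = varcomps_from_theta(theta_hat, spec)

    boundary = {}
    for name, comp in zip(spec.theta_names(), theta_hat):
        if name.startswith("log_sd") and comp <= _LOG_SD_BOUNDS[0] + 1e-6:
            key = {"log_sd_id": "sigma2_id", "log_sd_group": "sigma2_group",
                   "log_sd_slope": "sigma2_slope"}[name]
            boundary[key] = True
            vc[key] = 0.0

    try:
        cov_beta = obj.beta_cov(beta_hat, theta_hat)
        se = np.sqrt(np.clip(np.diag(cov_beta), 0, None))
    except Exception:
        se = np.full(p, np.nan)
        warnings.append("fixed-effect covariance not available")

    # conditional modes at the optimum
    P, _ = _precision(theta_hat, design)
    b, _, _ = obj._mode(design.X @ beta_hat, P, obj.b)
    blups: dict[str, pd.Series] = {}
    off = 0
    if spec.mother_intercept:
        blups["mother_intercept"] = pd.Series(
            b[off:off + design.n_mothers], index=design.mother_levels
        )
        off += design.n_mothers
    if spec.group_intercept:
        blups["group_intercept"] = pd.Series(
            b[off:off + design.n_groups], index=design.group_levels
        )
        off += design.n_groups
    if spec.mother_slope:
        blups["mother_slope"] = pd.Series(
            b[off:off + design.n_mothers], index=design.mother_levels
        )

    k = p + len(theta_hat)
    fit = GlmmFit(
        spec=spec,
        beta=pd.Series(beta_hat, index=design.colnames),
        se=pd.Series(se, index=design.colnames),
        varcomps=vc,
        loglik=ll,
        k=k,
        aic=-2 * ll + 2 * k,
        blups=blups,
        converged=converged,
        n_obs=design.n_obs,
        boundary=boundary,
        warnings=warnings,
        theta=theta_hat,
        design=design,
        fingerprint=design.fingerprint,
    )
    _check_separation(fit)
    return fit


def _check_separation(fit: GlmmFit) -> None:
    if np.max(np.abs(fit.beta.to_numpy())) > SEPARATION_BOUND:
        fit.converged = False
        fit.warnings.append(
            f"|beta| exceeds {SEPARATION_BOUND}: possible complete separation"
        )


@dataclass
class LrtResult:
    """Likelihood ratio test of nested fits (naive chi-square reference)."""

    statistic: float
    df: int
    p_value: float
    note: str = (
        "chi-square reference with df = parameter difference; conservative "
        "when the tested variance component sits on the boundary of its space"
    )


def lrt(full: GlmmFit, reduced: GlmmFit) -> LrtResult:
    """LRT of ``reduced`` (nested) against ``full``."""
    if full.fingerprint and reduced.fingerprint and (
        full.n_obs != reduced.n_obs
    ):
        raise UsageError("models were fitted to different data")
    if reduced.k > full.k:
        raise UsageError("the reduced model has more parameters than the full one")
    if list(reduced.beta.index) != list(full.beta.index):
        raise UsageError("models differ in fixed effects; not nested")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    df = max(1, full.k - reduced.k)
    return LrtResult(statistic=stat, df=df, p_value=float(chi2.sf(stat, df)))


def blups(fit: GlmmFit) -> dict[str, pd.Series]:
    """Conditional modes (BLUPs) per random-effect level."""
    if not fit.converged:
        raise UsageError("BLUPs requested from a non-converged fit")
    return fit.blups


@dataclass
class VifResult:
    values: pd.Series
    max_vif: float
    collinear: bool


def vif(design: Design) -> VifResult:
    """Variance inflation factors of the fixed-effect predictors.

    VIF_j = 1 / (1 - R^2_j) with R^2_j from the least-squares regression of
    predictor j on the remaining predictors (plus intercept).  A perfectly
    collinear predictor reports an infinite VIF and sets the flag.
    """
    names = [c for c in design.colnames if c != "intercept"]
    if len(names) < 2:
        raise DesignError("VIF needs at least two non-intercept predictors")
    idx = [design.colnames.index(c) for c in names]
    X = design.X[:, idx]
    out = {}
    collinear = False
    for j, name in enumerate(names):
        others = np.column_stack(
            [np.ones(len(X))] + [X[:, m] for m in range(X.shape[1]) if m != j]
        )
        target = X[:, j]
        coefs, *_ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ coefs
        sst = float(np.sum((target - target.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 1.0
        if r2 >= 1.0 - 1e-12:
            out[name] = np.inf
            collinear = True
        else:
            out[name] = 1.0 / (1.0 - r2)
    values = pd.Series(out)
    return VifResult(values=values, max_vif=float(values.max()), collinear=collinear)


def predict_reaction_norms(fit: GlmmFit, per_individual: bool = True) -> pd.DataFrame:
    """Predicted response probability per individual in each context.

    Uses each mother's own covariates and conditional modes; on the logit
    scale the per-individual lines are parallel under a random-intercept
    model and non-parallel only when random slopes are fitted (the
    back-transformed probability lines are never strictly parallel).
    """
    design = fit.design
    if design is None:
        raise UsageError("fit carries no design; cannot predict")
    spec = fit.spec
    if "context_binary" not in spec.fixed_terms:
        raise UsageError("prediction requires the binary context term")
    ctx_col = design.colnames.index("context_binary")
    rows = []
    frame = design.frame
    first = frame.drop_duplicates("mother_id")
    for i, rec in zip(first.index.to_numpy(), first.itertuples(index=False)):
        x = design.X[int(i)].copy()
        u = fit.blups.get("mother_intercept", pd.Series(dtype=float)).get(rec.mother_id, 0.0)
        v = fit.blups.get("group_intercept", pd.Series(dtype=float)).get(rec.group_id, 0.0)
        s = fit.blups.get("mother_slope", pd.Series(dtype=float)).get(rec.mother_id, 0.0)
        for ctx in (0.0, 1.0):
            x[ctx_col] = ctx
            eta = float(x @ fit.beta.to_numpy())
            if per_individual:
                eta += float(u) + float(v) + float(s) * ctx
            rows.append(
                {
                    "mother_id": rec.mother_id,
                    "group_id": rec.group_id,
                    "context_binary": int(ctx),
                    "eta": eta,
                    "prob": float(expit(eta)),
                }
            )
    return pd.DataFrame(rows)


def simulate_response(
    design: Design,
    beta: np.ndarray,
    varcomps: dict[str, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw a new binary response vector from the model at given parameters
    (fresh random effects each call; used by the parametric bootstrap)."""
    spec = design.spec
    eta = design.X @ np.asarray(beta, dtype=float)
    if spec.has_random:
        M, G = design.n_mothers, design.n_groups
        s1 = varcomps.get("sigma2_id", 0.0)
        s3 = varcomps.get("sigma2_slope", 0.0)
        r = varcomps.get("rho", 0.0)
        if spec.mother_slope:
            off = r * np.sqrt(s1 * s3)
            cov = np.array([[s1, off], [off, s3]])
            us = rng.multivariate_normal(np.zeros(2), cov, size=M, method="eigh")
            u, s = us[:, 0], us[:, 1]
        else:
            u = rng.normal(0.0, np.sqrt(s1), size=M) if spec.mother_intercept else np.zeros(M)
            s = np.zeros(M)
        v = (
            rng.normal(0.0, np.sqrt(varcomps.get("sigma2_group", 0.0)), size=G)
            if spec.group_intercept
            else np.zeros(G)
        )
        if spec.mother_intercept:
            eta = eta + u[design.mother_codes]
        if spec.group_intercept:
            eta = eta + v[design.group_codes]
        if spec.mother_slope:
            eta = eta + s[design.mother_codes] * design.ctx
    return (rng.random(design.n_obs) < expit(eta)).astype(float)
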