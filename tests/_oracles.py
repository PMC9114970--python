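"""Independent oracles used by the test suite.

Everything here is deliberately written without reusing the package's
computation paths: brute-force set arithmetic, exhaustive enumeration,
scalar quadrature and textbook IRLS, so agreement with the package is a
genuine dual-route check.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import expit, logsumexp


def dice_bruteforce(types_a, types_b) -> float:
    """Dice coefficient by explicit element counting."""
    shared = 0
    for t in set(types_a):
        if t in set(types_b):
            shared += 1
    return 2.0 * shared / (len(set(types_a)) + len(set(types_b)))


def within_between_stat(values: np.ndarray, labels: list[str]) -> float:
    """mean(within-label dyads) - mean(between-label dyads), by loops."""
    within, between = [], []
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            (within if labels[i] == labels[j] else between).append(values[i, j])
    return float(np.mean(within) - np.mean(between))


def enumerate_permutation_p(values: np.ndarray, labels: list[str]) -> float:
    """Exact permutation p over all distinct label assignments.

    p = #{assignments with statistic >= observed} / #assignments, the
    identity assignment included in the null set.
    """
    observed = within_between_stat(values, labels)
    classes = sorted(set(labels))
    n_a = labels.count(classes[0])
    n = len(labels)
    count = total = 0
    for pos in itertools.combinations(range(n), n_a):
        lab = [classes[0] if i in pos else classes[1] for i in range(n)]
        total += 1
        if within_between_stat(values, lab) >= observed - 1e-12:
            count += 1
    return count / total


def agq_loglik(
    y: np.ndarray,
    eta_fixed: np.ndarray,
    groups: np.ndarray,
    sigma2: float,
    nodes: int = 50,
) -> float:
    """Adaptive Gauss-Hermite marginal log-likelihood, one scalar random
    intercept per group; per-group mode by bounded scalar minimization."""
    xg, wg = np.polynomial.hermite.hermgauss(nodes)
    total = 0.0
    for k in np.unique(groups):
        mask = groups == k
        yk, ek = y[mask], eta_fixed[mask]

        def neg_joint(b):
            e = ek + b
            ll = np.sum(yk * e - np.logaddexp(0.0, e))
            return -(ll - 0.5 * b * b / sigma2 - 0.5 * np.log(2 * np.pi * sigma2))

        res = minimize_scalar(
            neg_joint, bounds=(-8, 8), method="bounded", options={"xatol": 1e-12}
        )
        bhat = res.x
        mu = expit(ek + bhat)
        shat = 1.0 / np.sqrt(np.sum(mu * (1 - mu)) + 1.0 / sigma2)
        bs = bhat + np.sqrt(2.0) * shat * xg
        gvals = np.array([-neg_joint(b) for b in bs])
        total += logsumexp(np.log(wg) + xg**2 + gvals) + np.log(np.sqrt(2.0) * shat)
    return float(total)


def irls_logistic(X: np.ndarray, y: np.ndarray, tol=1e-12, maxiter=200) -> np.ndarray:
    """Textbook iteratively reweighted least squares for logistic regression."""
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-12, None)
        z = eta + (y - mu) / w
        beta_new = np.linalg.solve((X * w[:, None]).T @ X, (X * w[:, None]).T @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    return beta


def per_group_logit_mle(y: np.ndarray, groups: np.ndarray) -> dict:
    """Separate logit(mean) per group, the unpooled fixed-effect MLE."""
    out = {}
    for k in np.unique(groups):
        p = y[groups == k].mean()
        p = min(max(p, 1e-9), 1 - 1e-9)
        out[k] = float(np.log(p / (1 - p)))
    return out
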