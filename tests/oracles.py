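"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own E-step/M-step code paths:
inclusion probabilities come from exhaustive enumeration over indicator
configurations, mixing-weight updates from numeric maximization, and
M-step minimizers from a generic quasi-Newton optimizer.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import minimize, minimize_scalar


def norm_pdf(x: float, var: float) -> float:
    return math.exp(-0.5 * x * x / var) / math.sqrt(2.0 * math.pi * var)


def enumerate_common(beta_s: float, pi1: float, v0: float, v1: float) -> float:
    """P(gamma_s = 1 | beta_s) by direct Bayes' rule over gamma in {0, 1}."""
    a = pi1 * norm_pdf(beta_s, v1)
    b = (1.0 - pi1) * norm_pdf(beta_s, v0)
    return a / (a + b)


def enumerate_region(
    alpha_r: np.ndarray, pi2: float, pi3: float, v2: float, v3: float
) -> tuple[float, np.ndarray]:
    """(P(eta_r = 1 | alpha_r), P(lambda_rj = 1 | eta_r = 1, alpha_r)) by
    enumeration over all (eta, lambda_1..J) configurations.

    When eta = 0 the lambda's are degenerate at 0 (point mass).
    """
    J = len(alpha_r)
    weights: dict[tuple[int, ...], float] = {}
    total = 0.0
    for eta in (0, 1):
        for lam in itertools.product((0, 1), repeat=J):
            if eta == 0:
                p_lam = 1.0 if all(l == 0 for l in lam) else 0.0
            else:
                p_lam = math.prod(pi3 if l else (1.0 - pi3) for l in lam)
            if p_lam == 0.0:
                continue
            dens = math.prod(
                norm_pdf(a, v3 if (eta and l) else v2) for a, l in zip(alpha_r, lam)
            )
            w = (pi2 if eta else (1.0 - pi2)) * p_lam * dens
            weights[(eta, *lam)] = weights.get((eta, *lam), 0.0) + w
            total += w
    g = sum(w for cfg, w in weights.items() if cfg[0] == 1) / total
    denom_eta1 = sum(w for cfg, w in weights.items() if cfg[0] == 1)
    q = np.array(
        [
            sum(w for cfg, w in weights.items() if cfg[0] == 1 and cfg[1 + j] == 1) / denom_eta1
            for j in range(J)
        ]
    )
    return g, q


def numeric_pi1(p_s: np.ndarray, S: int, a: float, b: float) -> float:
    """argmax of the pi1 component of the expected complete-data log-posterior."""

    def neg(pi):
        return -(
            (p_s.sum() + a - 1.0) * math.log(pi) + (S - p_s.sum() + b - 1.0) * math.log(1.0 - pi)
        )

    res = minimize_scalar(neg, bounds=(1e-9, 1 - 1e-9), method="bounded",
                          options={"xatol": 1e-12})
    return float(res.x)


def numeric_pi3(q_rj_by_region: list[np.ndarray], g_r: np.ndarray, L: int, a: float, b: float) -> float:
    """argmax of the pi3 component: sum_r g_r sum_j [q log pi + (1-q) log(1-pi)]
    plus the Beta prior.  Excluded regions (eta = 0) carry point-mass
    lambda's and contribute no pi3 term."""
    gq = sum(g * q.sum() for g, q in zip(g_r, q_rj_by_region))
    gJ = sum(g * len(q) for g, q in zip(g_r, q_rj_by_region))

    def neg(pi):
        return -((gq + a - 1.0) * math.log(pi) + (gJ - gq + b - 1.0) * math.log(1.0 - pi))

    res = minimize_scalar(neg, bounds=(1e-9, 1 - 1e-9), method="bounded",
                          options={"xatol": 1e-12})
    return float(res.x)


def mstep_objective(X: np.ndarray, penalty: np.ndarray, omega: np.ndarray) -> float:
    Z = (X @ omega).reshape(-1, 3)
    loss = np.log1p(np.exp(-Z).sum(axis=1)).sum()
    return float(loss + 0.5 * (penalty * omega**2).sum())


def mstep_oracle(X: np.ndarray, penalty: np.ndarray) -> np.ndarray:
    """Generic minimizer of the penalized matched-set logistic objective."""
    p = X.shape[1]
    res = minimize(
        lambda w: mstep_objective(X, penalty, w),
        np.zeros(p),
        method="L-BFGS-B",
        options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 5000},
    )
    return res.x


def observed_log_posterior(
    X: np.ndarray,
    S: int,
    regions: list[list[int]],
    omega: np.ndarray,
    pis: tuple[float, float, float],
    v: tuple[float, float, float, float],
    beta_hyper: tuple[tuple[float, float], ...] = ((1, 1), (1, 1), (1, 1)),
) -> float:
    """Direct marginalization over all indicators of the joint log posterior
    (up to the Beta normalizing constants), for tiny instances.

    ``regions`` lists, per region, the indices of its rare coefficients
    within the alpha block.
    """
    v0, v1, v2, v3 = v
    pi1, pi2, pi3 = pis
    Z = (X @ omega).reshape(-1, 3)
    ll = float(-np.log1p(np.exp(-Z).sum(axis=1)).sum())
    beta, alpha = omega[:S], omega[S:]
    for b in beta:
        ll += math.log(pi1 * norm_pdf(b, v1) + (1 - pi1) * norm_pdf(b, v0))
    for idx in regions:
        a_r = alpha[idx]
        total = 0.0
        for eta in (0, 1):
            for lam in itertools.product((0, 1), repeat=len(idx)):
                if eta == 0 and any(lam):
                    continue
                p_lam = 1.0 if eta == 0 else math.prod(pi3 if l else 1 - pi3 for l in lam)
                dens = math.prod(norm_pdf(a, v3 if (eta and l) else v2) for a, l in zip(a_r, lam))
                total += (pi2 if eta else 1 - pi2) * p_lam * dens
        ll += math.log(total)
    for pi, (a, b) in zip(pis, beta_hyper):
        ll += (a - 1.0) * math.log(pi) + (b - 1.0) * math.log(1.0 - pi)
    return ll
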