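"""Solvers for the penalized M-step.

The M-step minimizes the strongly convex objective

    f(w) = sum_n log(1 + sum_{i=1..3} exp(-x_in . w)) + (1/2) w' P w

with P a strictly positive diagonal penalty, so the minimizer is unique
and any convergent solver is acceptable.  Two are provided:

* :func:`newton_solve` — damped Newton with backtracking line search,
  deterministic, used by default;
* :func:`sdca_solve` — stochastic dual coordinate ascent over per-family
  dual blocks (the dual of the 1:3 matched-set loss is a negative
  entropy over the four transmission configurations), kept as an
  independent cross-check and for very large p.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .likelihood import ContrastMatrix, softmax_weights


class SolverError(RuntimeError):
    def __init__(self, message: str, grad_norm: float):
        super().__init__(f"{message} (final gradient norm {grad_norm:.3e})")
        self.grad_norm = grad_norm


def _objective(X: np.ndarray, penalty: np.ndarray, omega: np.ndarray) -> float:
    Z = (X @ omega).reshape(-1, 3)
    A = np.concatenate([np.zeros((Z.shape[0], 1)), -Z], axis=1)
    m = A.max(axis=1, keepdims=True)
    loss = (m.ravel() + np.log(np.exp(A - m).sum(axis=1))).sum()
    return float(loss + 0.5 * (penalty * omega**2).sum())


def _grad(X: np.ndarray, penalty: np.ndarray, omega: np.ndarray, U: np.ndarray) -> np.ndarray:
    return -(X.T @ U.reshape(-1)) + penalty * omega


def mstep_tolerance(n_families: int, tol: float = 1e-8) -> float:
    """Gradient-infinity-norm stopping threshold, relative to problem scale.

    Scales with sqrt(N) (the natural score scale) so that the residual
    objective error stays far below the EM ascent tolerance.
    """
    return tol * max(1.0, float(n_families)) ** 0.5


def newton_solve(
    contrasts: ContrastMatrix,
    penalty: np.ndarray,
    omega_init: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> np.ndarray:
    """Damped Newton minimization of the penalized M-step objective."""
    X = contrasts.X.astype(float)
    penalty = np.asarray(penalty, dtype=float)
    if np.any(penalty <= 0):
        raise ValueError("penalty diagonal must be strictly positive")
    omega = np.array(omega_init, dtype=float).copy()
    gtol = mstep_tolerance(contrasts.n_families, tol)
    f = _objective(X, penalty, omega)
    Xf = X.reshape(contrasts.n_families, 3, -1) if contrasts.n_families else X.reshape(0, 3, X.shape[1])
    for _ in range(max_iter):
        U = softmax_weights(contrasts, omega)
        g = _grad(X, penalty, omega, U)
        if np.abs(g).max() <= gtol:
            return omega
        # Hessian of the loss: X' diag(u) X - sum_n m_n m_n', m_n = sum_i u_in x_in
        H = (X * U.reshape(-1)[:, None]).T @ X
        M = np.einsum("nij,ni->nj", Xf, U)
        H -= M.T @ M
        H[np.diag_indices_from(H)] += penalty
        try:
            step = -cho_solve(cho_factor(H), g)
        except np.linalg.LinAlgError:
            step = -g / penalty
        # backtracking line search on the objective; near machine precision
        # the Armijo decrease is unresolvable, so a non-increasing step is
        # accepted (Newton's full step is then essentially exact)
        t = 1.0
        gTs = float(g @ step)
        f_eps = 8.0 * np.finfo(float).eps * max(1.0, abs(f))
        for _ in range(50):
            cand = omega + t * step
            fc = _objective(X, penalty, cand)
            if fc <= f + 1e-4 * t * gTs or fc <= f + f_eps:
                omega, f = cand, fc
                break
            t *= 0.5
        else:  # pragma: no cover - step rejected entirely
            omega = omega - g / penalty
            f = _objective(X, penalty, omega)
    U = softmax_weights(contrasts, omega)
    g = _grad(X, penalty, omega, U)
    if np.abs(g).max() <= gtol:
        return omega
    raise SolverError("Newton M-step failed to converge", float(np.abs(g).max()))


def _entropy(u: np.ndarray) -> float:
    """Entropy of the 4-point configuration distribution (u1,u2,u3, u0=1-sum)."""
    u0 = 1.0 - u.sum()
    parts = np.append(u, u0)
    parts = parts[parts > 0]
    return float(-(parts * np.log(parts)).sum())


def sdca_solve(
    contrasts: ContrastMatrix,
    penalty: np.ndarray,
    omega_init: np.ndarray | None = None,
    tol: float = 1e-8,
    max_epochs: int = 500,
    seed: int = 0,
    inner_iter: int = 40,
) -> np.ndarray:
    """Stochastic dual coordinate ascent over per-family dual blocks.

    Each family holds a dual vector u_n on the 4-configuration simplex
    (the conjugate of its log-sum-exp loss is the negative entropy).
    One epoch visits families in a seeded random order and re-optimizes
    each block by damped fixed-point iteration on the stationarity map
    u = softmax(-(K u + c)); the primal iterate is w = P^{-1} sum A_n' u_n.
    Terminates on a primal-dual gap below the same scale-relative
    tolerance as the Newton solver.
    """
    X = contrasts.X.astype(float)
    penalty = np.asarray(penalty, dtype=float)
    if np.any(penalty <= 0):
        raise ValueError("penalty diagonal must be strictly positive")
    N = contrasts.n_families
    p = contrasts.p
    if N == 0:
        return np.zeros(p)
    gap_tol = mstep_tolerance(N, tol)
    rng = np.random.default_rng(seed)
    A = X.reshape(N, 3, p)
    Ainvp = A / penalty  # A_n P^{-1}
    K = np.einsum("nip,njp->nij", Ainvp, A)  # per-family 3x3 Gram in P^{-1} metric
    U = np.full((N, 3), 0.25)  # uniform start (u0 = 0.25)
    v = np.einsum("nij,ni->j", A, U)
    for _ in range(max_epochs):
        for n in rng.permutation(N):
            u = U[n]
            r = v - A[n].T @ u  # contribution of the other families
            c = Ainvp[n] @ r
            for _ in range(inner_iter):
                z = K[n] @ u + c
                e = np.exp(-z + min(0.0, z.min()))
                u_new = e / (np.exp(min(0.0, z.min())) + e.sum())
                step = u_new - u
                u = u + 0.5 * step
                if np.abs(step).max() < 1e-12:
                    break
            v = r + A[n].T @ u
            U[n] = u
        omega = v / penalty
        primal = _objective(X, penalty, omega)
        dual = sum(_entropy(U[n]) for n in range(N)) - 0.5 * float(v @ (v / penalty))
        if primal - dual <= gap_tol:
            return omega
    raise SolverError("SDCA M-step failed to converge", float(primal - dual))


def mstep_coefficients(
    contrasts: ContrastMatrix,
    penalty: np.ndarray,
    omega_init: np.ndarray,
    method: str = "newton",
    tol: float = 1e-8,
    seed: int = 0,
) -> np.ndarray:
    """Minimize the penalized conditional-logistic objective (M-step).

    ``method`` selects :func:`newton_solve` (default) or :func:`sdca_solve`;
    both converge to the same unique minimizer.
    """
    if method == "newton":
        return newton_solve(contrasts, penalty, omega_init, tol=tol)
    if method == "sdca":
        return sdca_solve(contrasts, penalty, omega_init, tol=tol, seed=seed)
    raise ValueError(f"unknown M-step solver {method!r}")
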