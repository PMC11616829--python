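"""EM / deterministic-annealing engine for spike-and-slab trio selection.

The E-step computes exact conditional inclusion probabilities — p_s for
common variants, g_r for regions, and q_rj for rare variants given their
region is included — from the current coefficients and mixing weights.
The M-step re-fits the coefficients under the resulting diagonal ridge
penalty and updates the mixing weights in closed form.  Deterministic
annealing tempers the E-step probabilities with an exponent t that is
ramped from 0.1 to 1, flattening the posterior early on to avoid poor
local modes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .likelihood import ContrastMatrix, conditional_log_likelihood
from .priors import AnnealingSchedule, ConvergenceSpec, PriorSpec
from .solvers import mstep_coefficients
from .variants import ModelLayout, Variant

log = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


def _norm_logpdf(x: np.ndarray, var: float) -> np.ndarray:
    return -0.5 * (_LOG2PI + np.log(var) + np.square(x) / var)


def _tempered_sigmoid(log_num: np.ndarray, log_den: np.ndarray, t: float) -> np.ndarray:
    """sigma(t * (log_num - log_den)), the annealed two-way posterior."""
    with np.errstate(invalid="ignore"):
        d = log_num - log_den
    # -inf - -inf cannot occur: both branches have positive density
    return expit(t * d)


def estep_common(beta: np.ndarray, pi1: float, prior: PriorSpec, t: float = 1.0) -> np.ndarray:
    """Inclusion probabilities p_s of the common variants.

    p_s = a_s^t / (a_s^t + b_s^t) with a_s = pi1 N(beta_s; 0, v1) and
    b_s = (1 - pi1) N(beta_s; 0, v0); evaluated in log space.
    """
    beta = np.asarray(beta, dtype=float)
    with np.errstate(divide="ignore"):
        la = np.log(pi1) + _norm_logpdf(beta, prior.v1)
        lb = np.log1p(-pi1) + _norm_logpdf(beta, prior.v0)
    return _tempered_sigmoid(la, lb, t)


def estep_rare(alpha: np.ndarray, pi3: float, prior: PriorSpec, t: float = 1.0) -> np.ndarray:
    """Within-region inclusion probabilities q_rj, conditional on eta_r = 1.

    q_rj = c^t / (c^t + d^t) with c = pi3 N(alpha; 0, v3) and
    d = (1 - pi3) N(alpha; 0, v2).
    """
    alpha = np.asarray(alpha, dtype=float)
    with np.errstate(divide="ignore"):
        lc = np.log(pi3) + _norm_logpdf(alpha, prior.v3)
        ld = np.log1p(-pi3) + _norm_logpdf(alpha, prior.v2)
    return _tempered_sigmoid(lc, ld, t)


def _region_mix_logdens(alpha: np.ndarray, pi3: float, prior: PriorSpec) -> np.ndarray:
    """Per-coefficient log[pi3 N(.;0,v3) + (1-pi3) N(.;0,v2)]."""
    with np.errstate(divide="ignore"):
        lc = np.log(pi3) + _norm_logpdf(alpha, prior.v3)
        ld = np.log1p(-pi3) + _norm_logpdf(alpha, prior.v2)
    return np.logaddexp(lc, ld)


def estep_region(
    alpha: np.ndarray,
    layout: ModelLayout,
    pi2: float,
    pi3: float,
    prior: PriorSpec,
    t: float = 1.0,
) -> np.ndarray:
    """Region inclusion probabilities g_r = e_r^t / (e_r^t + f_r^t).

    e_r multiplies, over the region's rare coefficients, the slab/spike
    mixture densities (region in, each member in or out); f_r multiplies
    the pure spike densities (region out).  ``alpha`` is the full rare
    coefficient block ordered per ``layout``.
    """
    alpha = np.asarray(alpha, dtype=float)
    mix = _region_mix_logdens(alpha, pi3, prior)
    spike = _norm_logpdf(alpha, prior.v2)
    with np.errstate(divide="ignore"):
        le = np.log(pi2) + np.add.reduceat(mix, layout.group_starts)
        lf = np.log1p(-pi2) + np.add.reduceat(spike, layout.group_starts)
    return _tempered_sigmoid(le, lf, t)


def estep_region_scalar(
    alpha_r: np.ndarray, pi2: float, pi3: float, prior: PriorSpec, t: float = 1.0
) -> float:
    """g_r for a single region's coefficient vector (convenience wrapper)."""
    alpha_r = np.atleast_1d(np.asarray(alpha_r, dtype=float))
    mix = _region_mix_logdens(alpha_r, pi3, prior).sum()
    spike = _norm_logpdf(alpha_r, prior.v2).sum()
    with np.errstate(divide="ignore"):
        le = np.log(pi2) + mix
        lf = np.log1p(-pi2) + spike
    return float(_tempered_sigmoid(np.asarray(le), np.asarray(lf), t))


def build_penalty(p_s: np.ndarray, q_rj: np.ndarray, prior: PriorSpec) -> np.ndarray:
    """Diagonal of the M-step ridge penalty P^(k).

    Common entries (1 - p_s)/v0 + p_s/v1; rare entries
    (1 - q_rj)/v2 + q_rj/v3.  Every entry is >= 1/max(v1, v3) > 0, so
    the penalized objective is strongly convex.
    """
    common = (1.0 - p_s) / prior.v0 + p_s / prior.v1
    rare = (1.0 - q_rj) / prior.v2 + q_rj / prior.v3
    return np.concatenate([common, rare])


def update_pis(
    p_s: np.ndarray,
    q_rj: np.ndarray,
    g_r: np.ndarray,
    layout: ModelLayout,
    prior: PriorSpec,
    current: tuple[float, float, float],
) -> tuple[float, float, float]:
    """Closed-form M-step updates of the mixing weights.

    Generalized Beta(a, b) form (sum + a - 1) / (count + a + b - 2); at
    the defaults a = 1, b = (S, R, L) this reduces to
    pi1 = sum p_s / (2S - 1), pi2 = sum g_r / (2R - 1) and
    pi3 = sum_r g_r sum_j q_rj / (L + sum_r g_r J_r - 1).
    If a class is empty (S = 0 or R = 0) its weight is held fixed.
    """
    S, R, L = layout.S, layout.R, layout.L
    a, b = prior.a, prior.b
    pi1, pi2, pi3 = current
    if S > 0:
        pi1 = (p_s.sum() + a[0] - 1.0) / (S + a[0] + b[0] - 2.0)
    if R > 0:
        pi2 = (g_r.sum() + a[1] - 1.0) / (R + a[1] + b[1] - 2.0)
        gq = float((g_r * np.add.reduceat(q_rj, layout.group_starts)).sum())
        gJ = float((g_r * layout.J).sum())
        pi3 = (gq + a[2] - 1.0) / (gJ + a[2] + b[2] - 2.0)
    return float(pi1), float(pi2), float(pi3)


def observed_objective(
    contrasts: ContrastMatrix,
    layout: ModelLayout,
    omega: np.ndarray,
    pis: tuple[float, float, float],
    prior: PriorSpec,
) -> float:
    """Observed-data log-posterior with the indicators marginalized out
    (up to an additive constant).

    This is the quantity whose successive differences the convergence
    rule monitors; at t = 1 EM never decreases it.  The marginal prior
    factorizes: each common coefficient contributes a two-component
    normal mixture, each region a two-branch product over its members,
    and each mixing weight its Beta density.
    """
    pi1, pi2, pi3 = pis
    ll = conditional_log_likelihood(contrasts, omega)
    beta = omega[: layout.S]
    alpha = omega[layout.S :]
    with np.errstate(divide="ignore"):
        if layout.S:
            la = np.log(pi1) + _norm_logpdf(beta, prior.v1)
            lb = np.log1p(-pi1) + _norm_logpdf(beta, prior.v0)
            ll += float(np.logaddexp(la, lb).sum())
        if layout.R:
            mix = _region_mix_logdens(alpha, pi3, prior)
            spike = _norm_logpdf(alpha, prior.v2)
            le = np.log(pi2) + np.add.reduceat(mix, layout.group_starts)
            lf = np.log1p(-pi2) + np.add.reduceat(spike, layout.group_starts)
            ll += float(np.logaddexp(le, lf).sum())
        # Beta hyper-prior terms; skipped at unit hyper-parameters so a
        # boundary mixing weight (pi = 0 or 1) cannot produce 0 * -inf
        for pi, ai, bi in zip(pis, prior.a, prior.b):
            if ai != 1.0:
                ll += (ai - 1.0) * np.log(pi)
            if bi != 1.0:
                ll += (bi - 1.0) * np.log1p(-pi)
    return float(ll)


@dataclass
class ModelState:
    """Converged (or current) state of the EM run."""

    beta: np.ndarray
    alpha: np.ndarray
    pis: tuple[float, float, float]
    p_s: np.ndarray
    q_rj: np.ndarray
    g_r: np.ndarray
    t: float
    k: int
    converged: bool
    objective: float
    trace: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def omega(self) -> np.ndarray:
        return np.concatenate([self.beta, self.alpha])


def em_iteration(
    contrasts: ContrastMatrix,
    layout: ModelLayout,
    omega: np.ndarray,
    pis: tuple[float, float, float],
    prior: PriorSpec,
    t: float,
    solver: str = "newton",
    mstep_tol: float = 1e-9,
    seed: int = 0,
    penalty_form: str = "joint",
) -> tuple[np.ndarray, tuple[float, float, float], np.ndarray, np.ndarray, np.ndarray]:
    """One tempered EM sweep: E-step, penalized M-step, mixing-weight update.

    ``penalty_form`` picks the rare-coefficient penalty weight: ``"joint"``
    (default) uses the full indicator expectation E[eta lambda] = g_r q_rj,
    for which the observed-data objective is exactly non-decreasing at
    t = 1; ``"conditional"`` uses q_rj alone (conditional on region
    inclusion), which is not an exact E-step and can lose monotonicity.
    """
    beta = omega[: layout.S]
    alpha = omega[layout.S :]
    pi1, pi2, pi3 = pis
    p_s = estep_common(beta, pi1, prior, t)
    q_rj = estep_rare(alpha, pi3, prior, t)
    g_r = estep_region(alpha, layout, pi2, pi3, prior, t)
    if penalty_form == "joint":
        rare_weight = np.repeat(g_r, layout.J) * q_rj
    elif penalty_form == "conditional":
        rare_weight = q_rj
    else:
        raise ValueError(f"unknown penalty_form {penalty_form!r}")
    penalty = build_penalty(p_s, rare_weight, prior)
    omega_new = mstep_coefficients(contrasts, penalty, omega, method=solver, tol=mstep_tol, seed=seed)
    pis_new = update_pis(p_s, q_rj, g_r, layout, prior, pis)
    return omega_new, pis_new, p_s, q_rj, g_r


def run_daem(
    contrasts: ContrastMatrix,
    layout: ModelLayout,
    prior: PriorSpec,
    conv: ConvergenceSpec = ConvergenceSpec(),
    anneal: AnnealingSchedule = AnnealingSchedule(),
    omega_init: np.ndarray | float = 0.5,
    pi_init: tuple[float, float, float] | None = None,
    solver: str = "newton",
    seed: int = 0,
    keep_trace: bool = True,
    penalty_form: str = "joint",
) -> ModelState:
    """Deterministic-annealing EM to the posterior mode.

    One EM sweep is run at each annealing temperature, then iteration
    continues at t = 1 until the observed-data log-posterior moves by
    less than ``conv.epsilon`` or ``conv.max_iter`` is hit (in which
    case the best state is returned with ``converged=False``).
    Coefficients start at 0.5 by default; mixing weights start at their
    prior means.
    """
    prior = prior.resolve_hypers(layout.S, layout.R, layout.L)
    p = layout.p
    if contrasts.p != p:
        raise ValueError(f"contrast matrix has {contrasts.p} columns, layout expects {p}")
    omega = (
        np.full(p, float(omega_init)) if np.isscalar(omega_init) else np.array(omega_init, dtype=float)
    )
    pis = prior.pi_means if pi_init is None else tuple(float(x) for x in pi_init)
    rows = []
    k = 0
    p_s = q_rj = g_r = None
    for t in anneal.temperatures:
        omega, pis, p_s, q_rj, g_r = em_iteration(
            contrasts, layout, omega, pis, prior, t, solver=solver, seed=seed + k,
            penalty_form=penalty_form,
        )
        k += 1
        if keep_trace:
            obj = observed_objective(contrasts, layout, omega, pis, prior)
            rows.append((k, t, obj, *pis))
            log.info("anneal sweep k=%d t=%.2f objective=%.6f", k, t, obj)
    obj = observed_objective(contrasts, layout, omega, pis, prior)
    converged = False
    for _ in range(conv.max_iter):
        omega, pis, p_s, q_rj, g_r = em_iteration(
            contrasts, layout, omega, pis, prior, 1.0, solver=solver, seed=seed + k,
            penalty_form=penalty_form,
        )
        k += 1
        obj_new = observed_objective(contrasts, layout, omega, pis, prior)
        if keep_trace:
            rows.append((k, 1.0, obj_new, *pis))
            log.info("EM iteration k=%d objective=%.6f", k, obj_new)
        delta, obj = obj_new - obj, obj_new
        if abs(delta) < conv.epsilon:
            converged = True
            break
    if not converged:
        log.warning("EM did not converge within %d iterations", conv.max_iter)
    # final E-step so the reported probabilities match the reported coefficients
    beta, alpha = omega[: layout.S], omega[layout.S :]
    p_s = estep_common(beta, pis[0], prior, 1.0)
    q_rj = estep_rare(alpha, pis[2], prior, 1.0)
    g_r = estep_region(alpha, layout, pis[1], pis[2], prior, 1.0)
    trace = pd.DataFrame(rows, columns=["k", "t", "objective", "pi1", "pi2", "pi3"])
    return ModelState(
        beta=beta,
        alpha=alpha,
        pis=pis,
        p_s=p_s,
        q_rj=q_rj,
        g_r=g_r,
        t=1.0,
        k=k,
        converged=converged,
        objective=obj,
        trace=trace,
    )


@dataclass
class SelectionResult:
    """Per-variant and per-region selection flags with coefficients."""

    variants: pd.DataFrame  # variant_id, region_id, maf, class, coefficient, inclusion_probability, selected
    regions: pd.DataFrame  # region_id, g_r, selected
    threshold: float

    @property
    def selected_variants(self) -> set[str]:
        return set(self.variants.loc[self.variants["selected"], "variant_id"])

    @property
    def selected_regions(self) -> set[int]:
        return set(self.regions.loc[self.regions["selected"], "region_id"].astype(int))


def final_selection(
    state: ModelState,
    layout: ModelLayout,
    variants: list[Variant],
    threshold: float = 0.5,
) -> SelectionResult:
    """Threshold the posterior inclusion probabilities.

    A common variant is selected when p_s >= threshold; a rare variant
    when its joint probability g_r * q_rj >= threshold (an excluded
    region therefore suppresses its members); a region when g_r >=
    threshold or any member variant is selected.
    """
    region_g = dict(zip(layout.region_ids.tolist(), state.g_r.tolist()))
    rows = []
    for s, col in enumerate(layout.common_cols):
        v = variants[col]
        rows.append(
            (v.id, v.region_id, v.maf, "common", state.beta[s], state.p_s[s], state.p_s[s] >= threshold)
        )
    for j, col in enumerate(layout.rare_cols):
        v = variants[col]
        joint = state.g_r[np.searchsorted(layout.region_ids, layout.rare_regions[j])] * state.q_rj[j]
        rows.append((v.id, v.region_id, v.maf, "rare", state.alpha[j], joint, joint >= threshold))
    vdf = pd.DataFrame(
        rows,
        columns=["variant_id", "region_id", "maf", "class", "coefficient", "inclusion_probability", "selected"],
    )
    all_regions = sorted({v.region_id for v in variants if v.region_id > 0})
    rrows = []
    for r in all_regions:
        g = region_g.get(r, 0.0)
        member_sel = bool(vdf.loc[vdf["region_id"] == r, "selected"].any())
        rrows.append((r, g, g >= threshold or member_sel))
    rdf = pd.DataFrame(rrows, columns=["region_id", "g_r", "selected"])
    return SelectionResult(variants=vdf, regions=rdf, threshold=threshold)
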