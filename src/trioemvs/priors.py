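"""Spike-and-slab prior specification and run-control settings.

Common-variant coefficients get a two-component normal mixture
(spike variance ``v0``, slab variance ``v1``) gated by a Bernoulli
indicator with mixing weight pi1.  Rare-variant coefficients get the
dual-indicator version: a region indicator eta_r (weight pi2) gates
per-variant indicators lambda_rj (weight pi3); the coefficient variance
is ``v3`` only when both fire, else ``v2``.  Each mixing weight carries
a Beta(a_i, b_i) hyper-prior; the defaults a_i = 1 and
b = (S, R, L) penalize model size in proportion to the number of
candidate terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


#: Default spike (exclusion) variance: odds ratios inside [0.95, 1.05]
#: are treated as clinically irrelevant, so the spike's 95% prior mass
#: covers that band: sd = log(1.05)/1.96, variance ~ 6.2e-4.  The slab
#: defaults follow the same 95%-coverage device on the clinically
#: relevant side: v1 = 0.4 covers odds ratios [0.29, 3.45] (common) and
#: v3 = 0.5 covers [0.27, 4.3] (rare).  The spikes are starting values;
#: data-driven tuning of v0 and v2 (see :mod:`trioemvs.tuning`) is
#: recommended before final selection.
DEFAULT_SPIKE_VARIANCE = (np.log(1.05) / 1.96) ** 2


@dataclass(frozen=True)
class PriorSpec:
    """Spike/slab variances and Beta hyper-parameters.

    ``v0 < v1`` (common spike/slab) and ``v2 < v3`` (rare spike/slab).
    ``a`` and ``b`` hold the Beta(a_i, b_i) hyper-parameters for
    (pi1, pi2, pi3); ``b`` entries of ``None`` are resolved to
    (S, R, L) by :meth:`resolve_hypers`.
    """

    v0: float = DEFAULT_SPIKE_VARIANCE
    v1: float = 0.4
    v2: float = DEFAULT_SPIKE_VARIANCE
    v3: float = 0.5
    a: tuple[float, float, float] = (1.0, 1.0, 1.0)
    b: tuple[float | None, float | None, float | None] = (None, None, None)

    def __post_init__(self) -> None:
        if not 0 < self.v0 < self.v1:
            raise ValueError(f"need 0 < v0 < v1, got v0={self.v0}, v1={self.v1}")
        if not 0 < self.v2 < self.v3:
            raise ValueError(f"need 0 < v2 < v3, got v2={self.v2}, v3={self.v3}")
        if any(x <= 0 for x in self.a):
            raise ValueError("Beta hyper-parameters a_i must be positive")
        if any(x is not None and x <= 0 for x in self.b):
            raise ValueError("Beta hyper-parameters b_i must be positive")

    def resolve_hypers(self, S: int, R: int, L: int) -> "PriorSpec":
        """Fill unset b_i with the model-size defaults (S, R, L)."""
        defaults = (float(max(S, 1)), float(max(R, 1)), float(max(L, 1)))
        b = tuple(d if x is None else float(x) for x, d in zip(self.b, defaults))
        return replace(self, b=b)

    @property
    def pi_means(self) -> tuple[float, float, float]:
        """Prior means a_i / (a_i + b_i) of the mixing weights."""
        if any(x is None for x in self.b):
            raise ValueError("call resolve_hypers() before pi_means")
        return tuple(a / (a + b) for a, b in zip(self.a, self.b))


@dataclass(frozen=True)
class ConvergenceSpec:
    """Stop when the observed-data log-posterior moves by less than epsilon."""

    epsilon: float = 1e-4
    max_iter: int = 500

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass(frozen=True)
class AnnealingSchedule:
    """Temperatures visited before the final exact-EM stage at t = 1.

    One EM sweep is run at each listed temperature; iteration to
    convergence then happens at t = 1.  The default matches the
    recommended schedule t = 0.1, 0.2, ..., 1.0.
    """

    temperatures: tuple[float, ...] = field(
        default_factory=lambda: tuple(round(0.1 * k, 10) for k in range(1, 11))
    )

    def __post_init__(self) -> None:
        for t in self.temperatures:
            if not 0 < t <= 1:
                raise ValueError(f"temperature {t} outside (0, 1]")

    @staticmethod
    def none() -> "AnnealingSchedule":
        """Plain EM: no tempered sweeps (equivalent to starting at t = 1)."""
        return AnnealingSchedule(temperatures=())
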