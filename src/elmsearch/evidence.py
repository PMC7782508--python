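"""Leaky drift-diffusion evidence accumulation per search-field location.

Within one fixation the observer receives, every millisecond, an independent
normal evidence sample at each of the n predefined locations: mean +dt if
the target is at that location, -dt otherwise, variance 8 dt / a^2.  Samples
are integrated leakily with decay exp(-k dt) per step:

    W_{t} = dW + W_{t-dt} * exp(-k dt)

In the continuum limit the accumulated evidence at time T is normal with
mean +/- (1 - e^{-kT})/k and variance (8/a^2) (1 - e^{-2kT})/(2k), which
reproduces the visibility time course d'(T) of the visibility module as
2 * mean / sd.

The discrete-event (ELM) limit instead draws one evidence value per location
per fixation from N(+/-0.5, 1/d'^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .visibility import TemporalVisibility

__all__ = [
    "DiffusionConfig",
    "EvidenceState",
    "D_PRIME_FLOOR",
    "sample_elm_response",
    "evidence_moments",
    "step_accumulate",
    "accumulate_block",
]

# Floor on d' (and on a, via a >= floor * sqrt(k)) at extreme eccentricities:
# the exponential visibility fields never reach zero but underflow; flooring
# keeps evidence variances finite.  Locations this invisible contribute
# nothing to the posterior either way.
D_PRIME_FLOOR = 1e-4


@dataclass(frozen=True)
class DiffusionConfig:
    """Time step of the per-millisecond evidence process (seconds)."""

    dt: float = 0.001

    def __post_init__(self) -> None:
        if not (self.dt > 0):
            raise ValueError("dt must be > 0")


@dataclass
class EvidenceState:
    """Accumulated evidence for the current fixation.

    ``a`` and ``k`` are cached once per fixation (they depend only on the
    fixation location); ``W`` is the per-location accumulated evidence and
    ``T_f`` the elapsed time in the current fixation.
    """

    a: np.ndarray
    k: np.ndarray
    W: np.ndarray = field(default=None)
    T_f: float = 0.0

    def __post_init__(self) -> None:
        self.a = np.maximum(np.asarray(self.a, dtype=float),
                            D_PRIME_FLOOR * np.sqrt(self.k))
        self.k = np.asarray(self.k, dtype=float)
        if self.W is None:
            self.W = np.zeros_like(self.a)


def sample_elm_response(target_present, dprime, rng: np.random.Generator):
    """One per-fixation evidence draw per location: N(+/-0.5, 1/d'^2).

    ``target_present`` is a boolean scalar or vector; d' values below the
    floor are floored.
    """
    d = np.maximum(np.asarray(dprime, dtype=float), D_PRIME_FLOOR)
    mean = np.where(np.asarray(target_present, dtype=bool), 0.5, -0.5)
    draw = np.asarray(rng.normal(mean, 1.0 / d))
    return draw if draw.ndim else float(draw)


def evidence_moments(T: float, tv: TemporalVisibility, target_present: bool):
    """Closed-form (mean, variance) of accumulated evidence at time T.

    mean = +/- (1 - e^{-kT}) / k, variance = (8/a^2) (1 - e^{-2kT}) / (2k).
    """
    if T < 0:
        raise ValueError("T must be >= 0")
    k = tv.k
    sign = 1.0 if target_present else -1.0
    mean = sign * (-np.expm1(-k * T)) / k
    a = max(tv.a, D_PRIME_FLOOR * np.sqrt(k))
    var = (8.0 / a**2) * (-np.expm1(-2.0 * k * T)) / (2.0 * k)
    return float(mean), float(var)


def step_accumulate(
    state: EvidenceState,
    target_index: int,
    cfg: DiffusionConfig,
    rng: np.random.Generator,
    freeze_noise: bool = False,
) -> EvidenceState:
    """Advance the per-location leaky accumulators by one time step.

    Every location's W is updated by W <- dW + W * exp(-k dt) with dW drawn
    from N(+/-dt, 8 dt / a^2) (sign + at ``target_index``;
    ``target_index=None`` means the target is absent everywhere).
    ``freeze_noise`` forces dW = 0, leaving the pure exponential decay
    (testing hook).
    """
    dt = cfg.dt
    n = state.a.size
    if freeze_noise:
        dw = np.zeros(n)
    else:
        mu = np.full(n, -dt)
        if target_index is not None:
            mu[target_index] = dt
        sd = np.sqrt(8.0 * dt) / state.a
        dw = rng.normal(mu, sd)
    state.W = dw + state.W * np.exp(-state.k * dt)
    state.T_f += dt
    return state


def accumulate_block(
    state: EvidenceState,
    target_index: int,
    n_steps: int,
    rng: np.random.Generator,
    dt: float = 0.001,
) -> np.ndarray:
    """Vectorised ``n_steps`` of the leaky recursion; returns the trajectory.

    Output has shape (n_locations, n_steps); column j is W after step j + 1.
    ``state`` is advanced in place to the end of the block.  Equivalent to
    ``n_steps`` calls of :func:`step_accumulate` (same recursion, different
    random-stream consumption order).

    The exact solution of the recursion is used:
    W_t = lam^t (W_0 + sum_{s<=t} dW_s lam^{-s}), lam = exp(-k dt), computed
    with a cumulative sum.  Block lengths are kept short enough upstream that
    lam^{-t} stays well inside double range.
    """
    a, k = state.a, state.k
    n = a.size
    mu = np.full(n, -dt)
    if target_index is not None:
        mu[target_index] = dt
    sd = np.sqrt(8.0 * dt) / a
    dw = rng.standard_normal((n, n_steps)) * sd[:, None] + mu[:, None]
    growth = np.exp(np.outer(k, dt * np.arange(1, n_steps + 1)))  # lam^{-t}
    traj = (state.W[:, None] + np.cumsum(dw * growth, axis=1)) / growth
    state.W = traj[:, -1].copy()
    state.T_f += n_steps * dt
    return traj
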