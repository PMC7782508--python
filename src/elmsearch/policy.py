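"""Saccade timing, fixation-target selection, and the stopping rule.

Saccade timing uses a collapsing bound on the posterior probability at the
attended location:

    log10 theta_S(t) = q1 * exp(-(t / q2)^q3),   q1, q3 < 0, q2 > 0

which decreases from 1 (t -> 0+) to 10^q1 (t -> infinity); a saccade is
triggered as soon as the attended probability falls below the bound.  Three
percent of saccades (never the first of a trial) are instead low-latency
"express" saccades whose latency is Gamma(shape 10, scale 6.9e-3) + 30 ms
(mean 99 ms).

The next fixation is chosen among the predefined locations by maximising the
expected information gain 0.5 * sum_i P_i d'^2_{i,candidate} (the ELM rule),
optionally discounted by an amplitude penalty exp(-max(D, 1)/c) that leaves
saccades shorter than 1 degree unpenalised.

Search stops when the attended probability exceeds theta_T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .belief import PosteriorMap

__all__ = [
    "SaccadeTimingParams",
    "SelectionParams",
    "StoppingParams",
    "saccade_threshold",
    "should_saccade",
    "sample_saccade_type",
    "sample_express_latency",
    "expected_info_gain",
    "select_next_fixation",
    "check_stop",
]


@dataclass(frozen=True)
class SaccadeTimingParams:
    """Collapsing-bound shape (q1-q3), express-saccade mixture, neural lags.

    q1 (log10 units, < 0): asymptotic bound 10^q1; q2 (s, > 0): bound
    timescale; q3 (dimensionless, < 0): bound shape.  The express constants
    and the eye-brain (retina -> cortex, 60 ms) and saccade (decision -> eye,
    30 ms) lags are fixed from the literature.
    """

    q1: float
    q2: float
    q3: float
    express_fraction: float = 0.03
    express_shape: float = 10.0
    express_scale: float = 6.9e-3
    express_delay: float = 0.03
    eye_brain_lag: float = 0.06
    saccade_lag: float = 0.03

    def __post_init__(self) -> None:
        if not (self.q1 < 0 and self.q3 < 0 and self.q2 > 0):
            raise ValueError(
                f"require q1 < 0, q2 > 0, q3 < 0; got ({self.q1}, {self.q2}, {self.q3})"
            )
        if not (0.0 <= self.express_fraction <= 1.0):
            raise ValueError("express_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SelectionParams:
    """Saccade-target selection: ELM rule or amplitude-penalised ELM rule.

    ``penalty_scale`` is the c of the exponential penalty (degrees);
    ``expected_next_fixation_duration`` is the exposure at which candidate
    visibility is evaluated (0.25 s).
    """

    mode: str = "elm"  # "elm" | "penalized"
    penalty_scale: float = 2.0
    expected_next_fixation_duration: float = 0.25

    def __post_init__(self) -> None:
        if self.mode not in ("elm", "penalized"):
            raise ValueError(f"mode must be 'elm' or 'penalized', got {self.mode!r}")
        if not (self.penalty_scale > 0):
            raise ValueError("penalty_scale c must be > 0")


@dataclass(frozen=True)
class StoppingParams:
    """Target-detection threshold theta_T on the attended probability."""

    threshold: float = 0.952

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("theta_T must lie in (0, 1)")


def saccade_threshold(t, q: SaccadeTimingParams):
    """Collapsing bound theta_S(t) = 10^(q1 exp(-(t/q2)^q3)).

    Strictly decreasing from 1 at t -> 0+ to 10^q1 at t -> infinity.  t = 0 is
    handled as the limit value 1.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    with np.errstate(divide="ignore"):
        z = np.where(t > 0, (t / q.q2) ** q.q3, np.inf)
    out = 10.0 ** (q.q1 * np.exp(-z))
    return out if out.ndim else float(out)


def should_saccade(p_attend: float, t: float, q: SaccadeTimingParams) -> bool:
    """True iff the attended probability has fallen below the bound."""
    return bool(p_attend < saccade_threshold(t, q))


def sample_saccade_type(
    rng: np.random.Generator, q: SaccadeTimingParams, first: bool = False
) -> str:
    """'express' with probability ``express_fraction``; the first saccade of a
    trial is always 'normal'."""
    if first or q.express_fraction == 0.0:
        return "normal"
    return "express" if rng.random() < q.express_fraction else "normal"


def sample_express_latency(
    rng: np.random.Generator, q: SaccadeTimingParams, size: int | None = None
):
    """Express-saccade latency in seconds: Gamma(10, 6.9e-3) + 0.03."""
    draw = rng.gamma(q.express_shape, q.express_scale, size) + q.express_delay
    return draw if size is not None else float(draw)


def expected_info_gain(post: PosteriorMap, dprime_sq_candidate: np.ndarray):
    """Expected entropy reduction of fixating a candidate: 0.5 sum_i P_i d'^2_i.

    ``dprime_sq_candidate`` holds d'^2 at every location when fixating the
    candidate; a matrix (n_locations, n_candidates) yields the gain of every
    candidate at once.
    """
    d2 = np.asarray(dprime_sq_candidate, dtype=float)
    gain = 0.5 * (post.p @ d2) if d2.ndim == 2 else 0.5 * float(post.p @ d2)
    return gain


def select_next_fixation(
    post: PosteriorMap,
    current,
    sel: SelectionParams,
    dprime_sq: np.ndarray,
    candidates: np.ndarray,
) -> int:
    """Choose the next fixation among ``candidates`` (grid nodes).

    ELM mode maximises the expected information gain; penalised mode
    multiplies the gain by exp(-max(D, 1)/c) with D the distance from the
    current fixation.  Exact ties are broken by smallest distance to the
    current fixation, then lowest index, for deterministic replays.
    """
    gains = expected_info_gain(post, dprime_sq)
    dist = np.hypot(*(candidates - np.asarray(current, dtype=float)).T)
    if sel.mode == "penalized":
        scores = np.exp(-np.maximum(dist, 1.0) / sel.penalty_scale) * gains
    else:
        scores = gains
    best = scores.max()
    tied = np.flatnonzero(scores == best)
    if tied.size == 1:
        return int(tied[0])
    return int(tied[np.lexsort((tied, dist[tied]))[0]])


def check_stop(p_attend: float, stop: StoppingParams) -> bool:
    """True iff the attended probability strictly exceeds theta_T."""
    return bool(p_attend > stop.threshold)
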