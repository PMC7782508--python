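"""Bayesian posterior maps over target location.

The searcher's belief state is a probability vector over the n predefined
locations (uniform prior 1/n).  All algebra is done in log space with a
max-subtraction before exponentiation: the evidence exponents
a^2 W / (2 + 2 e^{-T k}) routinely reach hundreds.

Two update forms are provided:

* the discrete (ELM) recursion  P_i propto P_i * exp(d'_i^2 W_i), one update
  per fixation, equivalent to the batch product over all fixations;
* the continuous-time form, where each fixation f contributes the exponent
  a_{i,f}^2 W_{i,f} / (2 + 2 exp(-T_f k_{i,f})) and a memory capacity M
  restricts the sum to the last M fixations (including the current one).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math
import warnings

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "PosteriorMap",
    "FixationRecord",
    "MemoryBuffer",
    "ct_exponent",
    "posterior_elm_update",
    "posterior_ct",
    "entropy",
    "attention_probability",
]


@dataclass
class PosteriorMap:
    """Normalised posterior over the predefined locations, kept in log space."""

    log_p: np.ndarray

    def __post_init__(self) -> None:
        self.log_p = np.asarray(self.log_p, dtype=float)
        self.log_p = self.log_p - logsumexp(self.log_p)

    @classmethod
    def uniform(cls, n: int) -> "PosteriorMap":
        return cls(np.full(n, -math.log(n)))

    @classmethod
    def from_probabilities(cls, p) -> "PosteriorMap":
        p = np.asarray(p, dtype=float)
        if np.any(p < 0):
            raise ValueError("probabilities must be >= 0")
        with np.errstate(divide="ignore"):
            return cls(np.log(p / p.sum()))

    @property
    def p(self) -> np.ndarray:
        return np.exp(self.log_p)

    @property
    def n(self) -> int:
        return self.log_p.size


@dataclass
class FixationRecord:
    """Evidence bookkeeping for one fixation: where, for how long, and the
    per-location accumulated evidence and cached visibility parameters."""

    location: np.ndarray  # (2,) fixation position in degrees
    T_f: float            # accumulation time of this fixation (s)
    W: np.ndarray         # (n,) accumulated evidence
    a: np.ndarray         # (n,) cached a_i for this fixation
    k: np.ndarray         # (n,) cached k_i for this fixation


@dataclass
class MemoryBuffer:
    """The last min(F, M) fixation records; ``capacity=None`` is unlimited."""

    capacity: int | None = None
    records: list[FixationRecord] = field(default_factory=list)

    def append(self, record: FixationRecord) -> None:
        self.records.append(record)
        if self.capacity is not None and len(self.records) > self.capacity:
            del self.records[: len(self.records) - self.capacity]

    def __len__(self) -> int:
        return len(self.records)


def ct_exponent(record: FixationRecord) -> np.ndarray:
    """Per-location log-likelihood-ratio contribution of one fixation:
    a_i^2 W_i / (2 + 2 exp(-T_f k_i))."""
    return record.a**2 * record.W / (2.0 + 2.0 * np.exp(-record.T_f * record.k))


def posterior_elm_update(prev: PosteriorMap, W, dprime) -> PosteriorMap:
    """One discrete fixation update: P_i propto P_i exp(d'_i^2 W_i)."""
    W = np.asarray(W, dtype=float)
    d = np.asarray(dprime, dtype=float)
    if W.shape != prev.log_p.shape or d.shape != prev.log_p.shape:
        raise ValueError("W and dprime must match the posterior length")
    return PosteriorMap(prev.log_p + d**2 * W)


def posterior_ct(buffer: MemoryBuffer, n: int | None = None) -> PosteriorMap:
    """Posterior from the memory buffer under the continuous-time model.

    Sums the per-fixation exponents of the stored (last <= M) records on top
    of the uniform prior.
    """
    if not buffer.records:
        raise ValueError("memory buffer is empty")
    if n is None:
        n = buffer.records[0].W.size
    expo = np.zeros(n)
    for rec in buffer.records:
        expo += ct_exponent(rec)
    return PosteriorMap(expo - math.log(n))


def entropy(post: PosteriorMap) -> float:
    """Shannon entropy in nats; 0 * ln 0 is treated as 0."""
    lp = post.log_p
    p = np.exp(lp)
    h = -np.sum(p * np.where(p > 0, lp, 0.0))
    return float(max(h, 0.0))


def attention_probability(
    post: PosteriorMap,
    point,
    grid: np.ndarray,
    radius: float = 0.5,
) -> float:
    """Posterior mass attributed to an attention point.

    Sums the posterior over all predefined locations within ``radius``
    degrees (Euclidean, boundary inclusive) of ``point``.  The models that
    only fixate grid nodes use the degenerate case where the point sits on a
    node; the disc then typically covers 1-3 nodes.
    """
    point = np.asarray(point, dtype=float)
    d2 = ((grid - point) ** 2).sum(axis=1)
    mask = d2 <= radius * radius
    if not mask.any():
        warnings.warn(
            "no predefined location within the attention radius; returning 0",
            stacklevel=2,
        )
        return 0.0
    return float(np.exp(logsumexp(post.log_p[mask])))
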