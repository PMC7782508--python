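"""Saccade landing-position noise: eccentricity-dependent scatter and
undershoot bias.

Landing positions form an isotropic 2-D Gaussian around a biased mean.  Both
coefficients come from a regression on first-saccade landing data over
target eccentricities 0.5-17.5 degrees:

    sigma_s(x) = 0.0453 x + 0.364           (degrees, per axis)
    bias(x)    = -0.1195 * max(0, x - 10)   (degrees, along the saccade axis)

The bias is an undershoot: it displaces the mean landing point back toward
the current fixation, and only engages beyond 10 degrees.  The source data
were purely horizontal saccades; since the scatter is stated to be
direction-independent, the bias is applied along the saccade axis for
oblique saccades as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LandingModel", "landing_sd", "landing_bias", "sample_landing"]


@dataclass(frozen=True)
class LandingModel:
    """Coefficients of the landing-noise regressions (degrees)."""

    sd_slope: float = 0.0453
    sd_intercept: float = 0.364
    bias_slope: float = 0.1195
    bias_onset: float = 10.0

    def __post_init__(self) -> None:
        if self.sd_intercept <= 0 or self.sd_slope < 0:
            raise ValueError("landing SD must be positive at all eccentricities")


def landing_sd(ecc, lm: LandingModel = LandingModel()):
    """Per-axis landing SD at saccade-target eccentricity ``ecc`` (deg)."""
    e = np.asarray(ecc, dtype=float)
    if np.any(e < 0):
        raise ValueError("eccentricity must be >= 0")
    out = lm.sd_slope * e + lm.sd_intercept
    return out if out.ndim else float(out)


def landing_bias(ecc, lm: LandingModel = LandingModel()):
    """Signed along-axis bias (<= 0) at eccentricity ``ecc`` (deg)."""
    e = np.asarray(ecc, dtype=float)
    if np.any(e < 0):
        raise ValueError("eccentricity must be >= 0")
    out = -lm.bias_slope * np.maximum(0.0, e - lm.bias_onset)
    return out if out.ndim else float(out)


def sample_landing(
    current,
    target,
    lm: LandingModel,
    rng: np.random.Generator,
    field_radius: float | None = 7.5,
    max_tries: int = 100,
) -> np.ndarray:
    """Sample the actual landing position of a saccade.

    The mean is the target displaced by the undershoot bias along the
    saccade axis (toward the current fixation); scatter is an isotropic
    Gaussian with per-axis SD ``landing_sd(amplitude)``.  Samples outside
    the field (radius ``field_radius`` around the origin) are redrawn up to
    ``max_tries`` times, then clamped to the rim; ``field_radius=None``
    disables the constraint.
    """
    current = np.asarray(current, dtype=float)
    target = np.asarray(target, dtype=float)
    delta = target - current
    amp = float(np.hypot(*delta))
    if amp > 0:
        axis = delta / amp
        mean = target + landing_bias(amp, lm) * axis  # bias <= 0: undershoot
    else:
        mean = target
    sd = landing_sd(amp, lm)
    for _ in range(max_tries):
        landing = mean + rng.normal(0.0, sd, size=2)
        if field_radius is None or np.hypot(*landing) <= field_radius:
            return landing
    # pathological tail: clamp to the rim along the mean direction
    norm = np.hypot(*landing)
    return landing * (field_radius / norm) if norm > 0 else landing
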