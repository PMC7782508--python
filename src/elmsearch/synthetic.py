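"""Synthetic psychophysics data for exercising every fitting path offline.

Two generators emulate the detection experiments:

* contrast trials: 2IFC detection at the fovea across a contrast ladder,
  Bernoulli outcomes from a generating Weibull curve — the input to the
  psychometric fit;
* visibility trials: 2IFC detection across (location, exposure) conditions,
  with correct-response probability Phi(d'/sqrt(2)) implied by a generating
  visibility field (the equal-variance 2IFC accuracy law) — aggregated into
  weighted d' samples, the input to the visibility-field fit.

"Human-like" target eye-movement histograms for the timing fits are
produced by running the simulator itself at known parameters (see the
fitting module), so every stage of the pipeline can be tested without any
recorded data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .visibility import PsychometricCurve, VisibilityFieldParams, field_dprime

__all__ = [
    "SyntheticDetectionConfig",
    "make_contrast_trials",
    "make_detection_trials",
    "noiseless_visibility_samples",
]


def _default_eccentricities():
    return (0.0, 1.5, 3.0, 4.5, 6.0)


def _default_exposures():
    return (0.05, 0.1, 0.2, 0.4, 0.7)


@dataclass(frozen=True)
class SyntheticDetectionConfig:
    """Conditions of the synthetic detection experiment.

    Locations are placed on the four cardinal half-axes at the given
    eccentricities (plus the fovea), mirroring the cued detection blocks.
    """

    visibility: VisibilityFieldParams
    eccentricities: tuple = field(default_factory=_default_eccentricities)
    exposures: tuple = field(default_factory=_default_exposures)
    trials_per_condition: int = 50

    def __post_init__(self) -> None:
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be >= 1")


def make_contrast_trials(
    curve: PsychometricCurve,
    contrasts,
    n_per_level: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """2IFC contrast-ladder trials with hit/correct-rejection structure.

    Each trial hides the target in interval 1 or 2 at random; the response
    is correct with probability given by the Weibull curve.  Columns:
    contrast, interval_with_target, response_interval.
    """
    rows = []
    for c in np.asarray(contrasts, dtype=float):
        p = 0.5 + 0.5 * (1.0 - np.exp(-((c / curve.threshold) ** curve.steepness)))
        intervals = rng.integers(1, 3, size=n_per_level)
        correct = rng.random(n_per_level) < p
        responses = np.where(correct, intervals, 3 - intervals)
        rows.append(pd.DataFrame({
            "contrast": c,
            "interval_with_target": intervals,
            "response_interval": responses,
        }))
    return pd.concat(rows, ignore_index=True)


def make_detection_trials(
    cfg: SyntheticDetectionConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the cued detection task; return (raw trials, d' samples).

    Raw-trial columns: x_deg, y_deg, exposure_s, interval_with_target,
    response_interval.  Sample columns: x_deg, y_deg, exposure_s, dprime
    (estimated from the correct rate via d' = sqrt(2) z(rate), rates clamped
    away from 0/1 by half a trial) and weight (proportional to the trial
    count of the condition, mirroring subject-count weighting).
    """
    locs = [(0.0, 0.0)]
    for e in cfg.eccentricities:
        if e > 0:
            locs += [(e, 0.0), (-e, 0.0), (0.0, e), (0.0, -e)]
    trial_rows, sample_rows = [], []
    ntr = cfg.trials_per_condition
    for (x, y) in locs:
        for T in cfg.exposures:
            d_true = float(field_dprime(x, y, T, cfg.visibility))
            p_correct = stats.norm.cdf(d_true / np.sqrt(2.0))
            intervals = rng.integers(1, 3, size=ntr)
            correct = rng.random(ntr) < p_correct
            responses = np.where(correct, intervals, 3 - intervals)
            trial_rows.append(pd.DataFrame({
                "x_deg": x, "y_deg": y, "exposure_s": T,
                "interval_with_target": intervals,
                "response_interval": responses,
            }))
            rate = np.clip(correct.mean(), 0.5 / ntr, 1.0 - 0.5 / ntr)
            d_hat = max(np.sqrt(2.0) * stats.norm.ppf(rate), 0.0)
            sample_rows.append((x, y, T, d_hat, float(ntr)))
    trials = pd.concat(trial_rows, ignore_index=True)
    samples = pd.DataFrame(
        sample_rows, columns=["x_deg", "y_deg", "exposure_s", "dprime", "weight"]
    )
    samples["weight"] /= samples["weight"].mean()
    return trials, samples


def noiseless_visibility_samples(
    p: VisibilityFieldParams,
    eccentricities=None,
    exposures=None,
) -> pd.DataFrame:
    """Exact d' samples on the condition grid (for parameter-recovery tests)."""
    cfg = SyntheticDetectionConfig(
        visibility=p,
        eccentricities=tuple(eccentricities) if eccentricities is not None
        else _default_eccentricities(),
        exposures=tuple(exposures) if exposures is not None else _default_exposures(),
    )
    locs = [(0.0, 0.0)]
    for e in cfg.eccentricities:
        if e > 0:
            locs += [(e, 0.0), (-e, 0.0), (0.0, e), (0.0, -e)]
    rows = [
        (x, y, T, float(field_dprime(x, y, T, p)), 1.0)
        for (x, y) in locs for T in cfg.exposures
    ]
    return pd.DataFrame(rows, columns=["x_deg", "y_deg", "exposure_s", "dprime", "weight"])
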