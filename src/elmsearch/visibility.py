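"""Psychometric functions and the spatiotemporal visibility map.

Target visibility is quantified as d' (signal-detection sensitivity): the
separation between the target-present and target-absent evidence
distributions in units of their common standard deviation.  Three layers are
modelled here:

1. Contrast -> detection rate, via a Weibull psychometric function for a
   two-interval forced-choice (2IFC) task.
2. Hit / correct-rejection rates -> d', via the 2IFC signal-detection
   conversion.
3. The spatiotemporal visibility map: d' as a function of target location
   relative to fixation (x, y, in degrees) and stimulus exposure T (seconds),
   generated by a leaky evidence-accumulation process.  The time course at
   one location is

       d'(T) = a * sqrt((1 - exp(-k T)) / (k (1 + exp(-k T))))

   with asymptote a/sqrt(k), and the two per-location parameters decay
   exponentially with (anisotropic) eccentricity:

       a(x, y) = p1 * exp(-p2 * sqrt(x^2 + p5 y^2))
       k(x, y) = p3 * exp(-p4 * sqrt(x^2 + p5 y^2))

   p5 > 1 means visibility falls off faster vertically than horizontally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.stats import qmc

__all__ = [
    "PsychometricCurve",
    "TemporalVisibility",
    "VisibilityFieldParams",
    "weibull_rate",
    "fit_weibull",
    "dprime_from_rates",
    "dprime_timecourse",
    "visibility_params_at",
    "field_dprime",
    "fit_visibility_field",
]


@dataclass(frozen=True)
class PsychometricCurve:
    """Weibull psychometric curve for a 2IFC detection task.

    Parameters
    ----------
    threshold : float
        Threshold RMS contrast C_T (dimensionless, > 0).  At C = C_T the
        detection rate is 0.5 + 0.5 * (1 - 1/e) ~ 0.816.
    steepness : float
        Steepness s (dimensionless, > 0).
    """

    threshold: float
    steepness: float

    def __post_init__(self) -> None:
        if not (self.threshold > 0):
            raise ValueError(f"threshold C_T must be > 0, got {self.threshold}")
        if not (self.steepness > 0):
            raise ValueError(f"steepness s must be > 0, got {self.steepness}")


@dataclass(frozen=True)
class TemporalVisibility:
    """Per-location leaky-accumulation parameters.

    ``a`` (units s^-1/2) scales the asymptote, ``k`` (1/s) is the leak rate.
    Steady-state d' is a / sqrt(k).
    """

    a: float
    k: float

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError(f"a must be >= 0, got {self.a}")
        if not (self.k > 0):
            raise ValueError(f"k must be > 0, got {self.k}")

    @property
    def steady_state_dprime(self) -> float:
        return self.a / np.sqrt(self.k)


@dataclass(frozen=True)
class VisibilityFieldParams:
    """Five spatial-decay parameters generating the (a, k) visibility fields.

    p1: foveal a value; p2: spatial decay of a (1/deg); p3: foveal k (1/s);
    p4: spatial decay of k (1/deg); p5: vertical-anisotropy weight on y^2
    inside the radius (dimensionless).  All strictly positive, so both fields
    are maximal at the fovea and strictly decreasing with eccentricity.
    """

    p1: float
    p2: float
    p3: float
    p4: float
    p5: float

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p3", "p4", "p5"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    def as_array(self) -> np.ndarray:
        return np.array([self.p1, self.p2, self.p3, self.p4, self.p5])


def weibull_rate(contrast, curve: PsychometricCurve):
    """2IFC detection rate at RMS contrast ``contrast``.

    f(C) = 0.5 + 0.5 * (1 - exp(-(C / C_T)^s)); chance level is 0.5 and the
    curve saturates at 1.
    """
    c = np.asarray(contrast, dtype=float)
    if np.any(c < 0):
        raise ValueError("contrast must be >= 0")
    rate = 0.5 + 0.5 * (1.0 - np.exp(-((c / curve.threshold) ** curve.steepness)))
    return rate if rate.ndim else float(rate)


def fit_weibull(trials: pd.DataFrame, which: str = "hit") -> PsychometricCurve:
    """Maximum-likelihood Weibull fit to 2IFC detection trials.

    ``trials`` must have columns ``contrast``, ``interval_with_target`` (1 or
    2) and ``response_interval``.  ``which`` selects the trials entering the
    fit: ``"hit"`` uses target-in-first-interval trials (hit rate),
    ``"correct_rejection"`` target-in-second-interval trials.  Outcomes are
    Bernoulli with success probability given by the Weibull curve.
    """
    if which not in ("hit", "correct_rejection"):
        raise ValueError(f"which must be 'hit' or 'correct_rejection', got {which!r}")
    interval = 1 if which == "hit" else 2
    sub = trials[trials["interval_with_target"] == interval]
    contrast = sub["contrast"].to_numpy(dtype=float)
    correct = (sub["response_interval"] == sub["interval_with_target"]).to_numpy()
    if np.unique(contrast).size < 2:
        raise ValueError("need >= 2 distinct contrast levels to fit a Weibull curve")
    if correct.all() or (~correct).all():
        raise ValueError(
            "all outcomes identical: the Weibull likelihood is unbounded "
            "(non-identifiable)"
        )

    def nll(theta):
        ct, s = np.exp(theta)
        p = 0.5 + 0.5 * (1.0 - np.exp(-((contrast / ct) ** s)))
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        return -(np.log(p[correct]).sum() + np.log(1.0 - p[~correct]).sum())

    # multi-start over plausible thresholds; steepness starts at 2
    best = None
    for ct0 in np.quantile(contrast, [0.25, 0.5, 0.75]):
        res = optimize.minimize(
            nll, x0=[np.log(ct0), np.log(2.0)], method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    ct, s = np.exp(best.x)
    return PsychometricCurve(threshold=float(ct), steepness=float(s))


def dprime_from_rates(f_hit, f_cr, n_trials: int | None = None) -> float:
    """2IFC d' from hit and correct-rejection rates.

    d' = (z(f_H) - z(1 - f_CR)) / sqrt(2), z the inverse standard-normal CDF.
    Rates of exactly 0 or 1 are clamped to 1/(2N) and 1 - 1/(2N) (N =
    ``n_trials``) with a warning; this keeps z finite while preserving rate
    ordering.
    """
    f_hit = float(f_hit)
    f_cr = float(f_cr)
    for r in (f_hit, f_cr):
        if not (0.0 <= r <= 1.0):
            raise ValueError(f"rates must lie in [0, 1], got {r}")
    if f_hit in (0.0, 1.0) or f_cr in (0.0, 1.0):
        if n_trials is None:
            raise ValueError(
                "rate of exactly 0 or 1 requires n_trials for the 1/(2N) clamp"
            )
        lo, hi = 1.0 / (2 * n_trials), 1.0 - 1.0 / (2 * n_trials)
        warnings.warn(
            f"rate at 0/1 clamped to [{lo:.4g}, {hi:.4g}]", stacklevel=2
        )
        f_hit = min(max(f_hit, lo), hi)
        f_cr = min(max(f_cr, lo), hi)
    z = stats.norm.ppf
    return float((z(f_hit) - z(1.0 - f_cr)) / np.sqrt(2.0))


def dprime_timecourse(T, tv: TemporalVisibility):
    """d' after exposure ``T`` seconds under leaky accumulation.

    d'(T) = a sqrt((1 - e^{-kT}) / (k (1 + e^{-kT}))).  d'(0) = 0, strictly
    increasing, with limit a/sqrt(k).  As k -> 0 this approaches the
    perfect-integration growth a sqrt(T/2).
    """
    t = np.asarray(T, dtype=float)
    if np.any(t < 0):
        raise ValueError("exposure T must be >= 0")
    kt = tv.k * t
    # -expm1(-kt) is accurate for small kt; the ratio tends to T/2 as k -> 0
    ratio = -np.expm1(-kt) / (tv.k * (1.0 + np.exp(-kt)))
    d = tv.a * np.sqrt(ratio)
    return d if d.ndim else float(d)


def visibility_params_at(x, y, p: VisibilityFieldParams) -> TemporalVisibility:
    """(a, k) at location (x, y) degrees relative to fixation."""
    r = np.sqrt(float(x) ** 2 + p.p5 * float(y) ** 2)
    return TemporalVisibility(a=p.p1 * np.exp(-p.p2 * r), k=p.p3 * np.exp(-p.p4 * r))


def field_dprime(dx, dy, T, p: VisibilityFieldParams):
    """Vectorised d' for displacements (dx, dy) from fixation at exposure T."""
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    r = np.sqrt(dx**2 + p.p5 * dy**2)
    a = p.p1 * np.exp(-p.p2 * r)
    k = p.p3 * np.exp(-p.p4 * r)
    kt = k * T
    return a * np.sqrt(-np.expm1(-kt) / (k * (1.0 + np.exp(-kt))))


DEFAULT_BOUNDS = {
    "p1": (1e-3, 20.0),
    "p2": (1e-3, 5.0),
    "p3": (1e-3, 50.0),
    "p4": (1e-3, 5.0),
    "p5": (0.05, 20.0),
}


def _weighted_mse(theta, x, y, T, d, w):
    p1, p2, p3, p4, p5 = np.exp(theta)
    r = np.sqrt(x**2 + p5 * y**2)
    a = p1 * np.exp(-p2 * r)
    k = p3 * np.exp(-p4 * r)
    kt = k * T
    pred = a * np.sqrt(-np.expm1(-kt) / (k * (1.0 + np.exp(-kt))))
    return float(np.mean(w * (pred - d) ** 2))


def fit_visibility_field(
    samples: pd.DataFrame,
    n_starts: int = 32,
    bounds: dict | None = None,
    two_stage: bool = False,
    seed: int = 0,
) -> tuple[VisibilityFieldParams, float]:
    """Fit the five visibility-field parameters to measured d' samples.

    ``samples`` columns: ``x_deg``, ``y_deg``, ``exposure_s``, ``dprime``,
    ``weight`` (weight proportional to the number of contributing subjects;
    normalised to mean 1 internally).  The objective is the weighted MSE
    between predicted and sampled d'.  The default (one-stage) fit uses
    multi-start local optimisation with Latin-hypercube starts inside
    ``bounds``; ``two_stage=True`` first fits (a, k) per location and then
    the exponential fields to those per-location values.

    Returns (params, weighted-MSE at the optimum).
    """
    bounds = dict(DEFAULT_BOUNDS, **(bounds or {}))
    x = samples["x_deg"].to_numpy(dtype=float)
    y = samples["y_deg"].to_numpy(dtype=float)
    T = samples["exposure_s"].to_numpy(dtype=float)
    d = samples["dprime"].to_numpy(dtype=float)
    w = samples["weight"].to_numpy(dtype=float)
    if np.any(w <= 0) or np.any(T <= 0):
        raise ValueError("weights and exposures must be > 0")
    ecc = np.hypot(x, y)
    if np.unique(T).size < 2 or np.unique(np.round(ecc, 9)).size < 2:
        raise ValueError(
            "samples must span >= 2 exposures and >= 2 eccentricities "
            "(non-identifiable otherwise)"
        )
    w = w / w.mean()

    lo = np.log([bounds[k][0] for k in ("p1", "p2", "p3", "p4", "p5")])
    hi = np.log([bounds[k][1] for k in ("p1", "p2", "p3", "p4", "p5")])

    if two_stage:
        starts = [_two_stage_start(samples, bounds)]
        # a few extra random starts around the two-stage estimate
        rng = np.random.default_rng(seed)
        for _ in range(4):
            starts.append(np.clip(starts[0] + rng.normal(0, 0.3, 5), lo, hi))
    else:
        sampler = qmc.LatinHypercube(d=5, seed=seed)
        starts = lo + sampler.random(n_starts) * (hi - lo)

    best_x, best_f = None, np.inf
    for x0 in starts:
        res = optimize.minimize(
            _weighted_mse, x0=np.asarray(x0), args=(x, y, T, d, w),
            method="L-BFGS-B", bounds=list(zip(lo, hi)),
        )
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun
    p1, p2, p3, p4, p5 = np.exp(best_x)
    return VisibilityFieldParams(p1, p2, p3, p4, p5), float(best_f)


def _two_stage_start(samples: pd.DataFrame, bounds: dict) -> np.ndarray:
    """Stage-one estimate: per-location (a, k) fits, then the spatial fields."""
    locs = samples.groupby(["x_deg", "y_deg"])
    rows = []
    for (x0, y0), grp in locs:
        if grp["exposure_s"].nunique() < 2:
            continue
        T = grp["exposure_s"].to_numpy(dtype=float)
        d = grp["dprime"].to_numpy(dtype=float)
        wt = grp["weight"].to_numpy(dtype=float)

        def obj(th, T=T, d=d, wt=wt):
            a, k = np.exp(th)
            kt = k * T
            pred = a * np.sqrt(-np.expm1(-kt) / (k * (1.0 + np.exp(-kt))))
            return float(np.mean(wt * (pred - d) ** 2))

        res = optimize.minimize(obj, x0=[np.log(max(d.max(), 0.1) * 3), np.log(8.0)],
                                method="Nelder-Mead")
        a_hat, k_hat = np.exp(res.x)
        rows.append((x0, y0, a_hat, k_hat, wt.mean()))
    if len(rows) < 3:
        raise ValueError("two-stage fit needs >= 3 locations with >= 2 exposures")
    arr = np.array(rows)
    xs, ys, a_hat, k_hat, wt = arr.T

    def stage2(th):
        p1, p2, p3, p4, p5 = np.exp(th)
        r = np.sqrt(xs**2 + p5 * ys**2)
        return float(np.mean(wt * ((p1 * np.exp(-p2 * r) - a_hat) ** 2
                                   + (p3 * np.exp(-p4 * r) - k_hat) ** 2)))

    x0 = np.log([max(a_hat.max(), 0.1), 0.3, max(k_hat.max(), 0.5), 0.3, 1.0])
    res = optimize.minimize(stage2, x0=x0, method="Nelder-Mead",
                            options={"maxiter": 4000})
    lo = np.log([bounds[k][0] for k in ("p1", "p2", "p3", "p4", "p5")])
    hi = np.log([bounds[k][1] for k in ("p1", "p2", "p3", "p4", "p5")])
    return np.clip(res.x, lo, hi)
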