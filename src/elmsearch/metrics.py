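"""Eye-movement summary statistics and histogram goodness-of-fit.

Simulated (or recorded) search trials are reduced to named probability
histograms — fixation duration, saccade amplitude, fixation
distance-to-centre, each overall and per ordinal position, plus a smoothed
2-D fixation-location density — and compared with the Bhattacharyya
coefficient

    B_c(H1, H2) = sum_i sqrt(H1(i) H2(i)),   B_d = -ln B_c,

which is 1 iff the histograms coincide and 0 iff their supports are
disjoint.

Summary conventions: fixation durations exclude the first fixation (at the
field centre, contaminated by anticipation) and the last (ended by the
response); fixation locations and distances exclude the first fixation;
saccade amplitudes use all saccades; the fixation count per trial uses all
fixations.  Ordinal slot j (0-based, 20 slots) holds fixation j + 2 for
duration/distance and saccade j + 1 for amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
from scipy.ndimage import gaussian_filter

from .simulator import TrialResult

__all__ = [
    "BinConfig",
    "HistogramSummary",
    "bhattacharyya",
    "bhattacharyya_distance",
    "fixation_noise",
    "summarize",
    "bootstrap_bc",
]

N_ORDINALS = 20


def _default_duration_edges():
    return np.arange(0.0, 1525.0, 25.0)  # ms


def _default_amplitude_edges():
    return np.arange(0.0, 15.5, 0.5)  # deg


def _default_distance_edges():
    return np.arange(0.0, 7.75, 0.25)  # deg


@dataclass(frozen=True)
class BinConfig:
    """Bin edges for the named histograms (configurable; the comparisons are
    bin-sensitive, so both sides of any B_c must share a BinConfig).

    The raster resolution 42.857 px/deg makes the 0.35-degree Gaussian
    smoother exactly 15 pixels wide.
    """

    duration_edges_ms: np.ndarray = field(default_factory=_default_duration_edges)
    amplitude_edges: np.ndarray = field(default_factory=_default_amplitude_edges)
    distance_edges: np.ndarray = field(default_factory=_default_distance_edges)
    raster_px_per_deg: float = 300.0 / 7.0
    raster_smooth_sd_deg: float = 0.35
    field_radius: float = 7.5


@dataclass
class HistogramSummary:
    """Binned eye-movement statistics of a set of trials.

    ``counts``/``probs`` map metric name ('duration', 'amplitude',
    'distance') to arrays; ``ordinal_counts`` to (20, n_bins) arrays.
    ``location`` is the Gaussian-smoothed 2-D fixation density (sums to 1).
    ``dist_to_target_by_ordinal`` is the mean distance between fixation and
    target by ordinal; ``direction_change_mean`` and ``next_amplitude_mean``
    condition the relative angle / amplitude of saccade s + 1 on the
    amplitude bin of saccade s.
    """

    bins: BinConfig
    counts: dict
    ordinal_counts: dict
    location: np.ndarray
    n_trials: int
    fixation_counts: np.ndarray
    dist_to_target_by_ordinal: np.ndarray
    direction_change_mean: np.ndarray
    next_amplitude_mean: np.ndarray

    @property
    def probs(self) -> dict:
        out = {}
        for name, c in self.counts.items():
            tot = c.sum()
            out[name] = c / tot if tot > 0 else c.astype(float)
        return out

    def ordinal_probs(self, name: str) -> np.ndarray:
        c = self.ordinal_counts[name].astype(float)
        tot = c.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            p = np.where(tot > 0, c / np.maximum(tot, 1), 0.0)
        return p

    def to_json(self) -> str:
        payload = {
            "n_trials": self.n_trials,
            "edges": {
                "duration_ms": self.bins.duration_edges_ms.tolist(),
                "amplitude": self.bins.amplitude_edges.tolist(),
                "distance": self.bins.distance_edges.tolist(),
            },
            "counts": {k: v.tolist() for k, v in self.counts.items()},
            "ordinal_counts": {k: v.tolist() for k, v in self.ordinal_counts.items()},
            "location": self.location.tolist(),
            "fixation_counts": self.fixation_counts.tolist(),
            "dist_to_target_by_ordinal": self.dist_to_target_by_ordinal.tolist(),
            "direction_change_mean": self.direction_change_mean.tolist(),
            "next_amplitude_mean": self.next_amplitude_mean.tolist(),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "HistogramSummary":
        d = json.loads(text)
        bins = BinConfig(
            duration_edges_ms=np.asarray(d["edges"]["duration_ms"]),
            amplitude_edges=np.asarray(d["edges"]["amplitude"]),
            distance_edges=np.asarray(d["edges"]["distance"]),
        )
        return cls(
            bins=bins,
            counts={k: np.asarray(v) for k, v in d["counts"].items()},
            ordinal_counts={k: np.asarray(v) for k, v in d["ordinal_counts"].items()},
            location=np.asarray(d["location"]),
            n_trials=int(d["n_trials"]),
            fixation_counts=np.asarray(d["fixation_counts"]),
            dist_to_target_by_ordinal=np.asarray(d["dist_to_target_by_ordinal"]),
            direction_change_mean=np.asarray(d["direction_change_mean"]),
            next_amplitude_mean=np.asarray(d["next_amplitude_mean"]),
        )


def bhattacharyya(h1, h2) -> float:
    """Bhattacharyya coefficient of two probability histograms on shared bins."""
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    if h1.shape != h2.shape:
        raise ValueError(f"histogram shapes differ: {h1.shape} vs {h2.shape}")
    return float(np.sqrt(h1 * h2).sum())


def bhattacharyya_distance(h1, h2) -> float:
    """B_d = -ln B_c (infinite for disjoint histograms)."""
    bc = bhattacharyya(h1, h2)
    return float(np.inf) if bc == 0 else float(-np.log(bc))


def fixation_noise(samples: np.ndarray) -> tuple[float, float]:
    """Within-fixation noise metrics of gaze samples (N, 2).

    SD_fix is the root mean squared deviation from the mean gaze position
    (divisor N); RMS_fix the root mean square of inter-sample displacements
    (divisor N - 1).
    """
    s = np.asarray(samples, dtype=float)
    if s.ndim != 2 or s.shape[1] != 2 or s.shape[0] < 2:
        raise ValueError("need at least 2 gaze samples of shape (N, 2)")
    centred = s - s.mean(axis=0)
    sd = np.sqrt((centred**2).sum(axis=1).mean())
    diffs = np.diff(s, axis=0)
    rms = np.sqrt((diffs**2).sum(axis=1).mean())
    return float(sd), float(rms)


def summarize(results: list[TrialResult], bins: BinConfig = BinConfig()) -> HistogramSummary:
    """Reduce a batch of trials to the full histogram summary."""
    if not results:
        raise ValueError("no trials to summarize")
    nb_d = len(bins.duration_edges_ms) - 1
    nb_a = len(bins.amplitude_edges) - 1
    nb_r = len(bins.distance_edges) - 1
    cnt = {
        "duration": np.zeros(nb_d),
        "amplitude": np.zeros(nb_a),
        "distance": np.zeros(nb_r),
    }
    ocnt = {
        "duration": np.zeros((N_ORDINALS, nb_d)),
        "amplitude": np.zeros((N_ORDINALS, nb_a)),
        "distance": np.zeros((N_ORDINALS, nb_r)),
    }
    R = bins.field_radius
    npx = int(round(2 * R * bins.raster_px_per_deg))
    loc = np.zeros((npx, npx))
    tgt_sum = np.zeros(N_ORDINALS)
    tgt_n = np.zeros(N_ORDINALS)
    dc_sum = np.zeros(nb_a)
    dc_n = np.zeros(nb_a)
    na_sum = np.zeros(nb_a)

    def hist_into(acc, values, edges):
        if len(values):
            acc += np.histogram(values, bins=edges)[0]

    for r in results:
        F = r.n_fixations
        dur_ms = r.durations * 1000.0
        amps = r.amplitudes
        # overall histograms with the exclusion rules
        if F > 2:
            hist_into(cnt["duration"], dur_ms[1:-1], bins.duration_edges_ms)
        if F > 1:
            hist_into(cnt["amplitude"], amps, bins.amplitude_edges)
            dists = np.hypot(r.fix_xy[1:, 0], r.fix_xy[1:, 1])
            hist_into(cnt["distance"], dists, bins.distance_edges)
            ix = np.clip(((r.fix_xy[1:, 0] + R) * bins.raster_px_per_deg).astype(int),
                         0, npx - 1)
            iy = np.clip(((r.fix_xy[1:, 1] + R) * bins.raster_px_per_deg).astype(int),
                         0, npx - 1)
            np.add.at(loc, (iy, ix), 1.0)
        # per-ordinal histograms
        for j in range(min(N_ORDINALS, F - 2)):
            hist_into(ocnt["duration"][j], dur_ms[j + 1: j + 2], bins.duration_edges_ms)
        for j in range(min(N_ORDINALS, F - 1)):
            hist_into(ocnt["amplitude"][j], amps[j: j + 1], bins.amplitude_edges)
            d = np.hypot(*r.fix_xy[j + 1])
            hist_into(ocnt["distance"][j], [d], bins.distance_edges)
        # distance to target by ordinal (all fixations)
        tgt = r.response_xy if r.correct else None
        for j in range(min(N_ORDINALS, F)):
            if tgt is not None:
                tgt_sum[j] += np.hypot(*(r.fix_xy[j] - tgt))
                tgt_n[j] += 1
        # conditional statistics of consecutive saccades
        if F > 2:
            dirs = r.directions
            rel = np.abs(np.angle(np.exp(1j * np.diff(dirs))))  # in [0, pi]
            abins = np.clip(
                np.digitize(amps[:-1], bins.amplitude_edges) - 1, 0, nb_a - 1
            )
            np.add.at(dc_sum, abins, np.degrees(rel))
            np.add.at(na_sum, abins, amps[1:])
            np.add.at(dc_n, abins, 1.0)

    loc = gaussian_filter(loc, sigma=bins.raster_smooth_sd_deg * bins.raster_px_per_deg)
    tot = loc.sum()
    if tot > 0:
        loc = loc / tot
    with np.errstate(invalid="ignore"):
        dc_mean = np.where(dc_n > 0, dc_sum / np.maximum(dc_n, 1), np.nan)
        na_mean = np.where(dc_n > 0, na_sum / np.maximum(dc_n, 1), np.nan)
        tgt_mean = np.where(tgt_n > 0, tgt_sum / np.maximum(tgt_n, 1), np.nan)
    return HistogramSummary(
        bins=bins,
        counts=cnt,
        ordinal_counts=ocnt,
        location=loc,
        n_trials=len(results),
        fixation_counts=np.array([r.n_fixations for r in results]),
        dist_to_target_by_ordinal=tgt_mean,
        direction_change_mean=dc_mean,
        next_amplitude_mean=na_mean,
    )


def bootstrap_bc(
    results_a: list[TrialResult],
    results_b: list[TrialResult],
    metric: str = "duration",
    n_boot: int = 2000,
    seed: int = 0,
    bins: BinConfig = BinConfig(),
) -> tuple[np.ndarray, float, tuple[float, float]]:
    """Bootstrap distribution of B_c between two sets of trials.

    Trials are resampled with replacement on both sides; returns the B_c
    samples, their SD, and the 99% confidence interval mean +/- 2.576 * SD.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    bcs = np.empty(n_boot)
    for i in range(n_boot):
        sa = [results_a[j] for j in rng.integers(len(results_a), size=len(results_a))]
        sb = [results_b[j] for j in rng.integers(len(results_b), size=len(results_b))]
        ha = summarize_metric(sa, metric, bins)
        hb = summarize_metric(sb, metric, bins)
        bcs[i] = bhattacharyya(ha, hb)
    sd = float(bcs.std())
    mean = float(bcs.mean())
    return bcs, sd, (mean - 2.576 * sd, mean + 2.576 * sd)


def summarize_metric(results, metric: str, bins: BinConfig = BinConfig()) -> np.ndarray:
    """Single-metric probability histogram (cheap path for bootstraps)."""
    if metric == "duration":
        vals = np.concatenate(
            [r.durations[1:-1] * 1000.0 for r in results if r.n_fixations > 2]
            or [np.empty(0)]
        )
        edges = bins.duration_edges_ms
    elif metric == "amplitude":
        vals = np.concatenate(
            [r.amplitudes for r in results if r.n_fixations > 1] or [np.empty(0)]
        )
        edges = bins.amplitude_edges
    elif metric == "distance":
        vals = np.concatenate(
            [np.hypot(r.fix_xy[1:, 0], r.fix_xy[1:, 1]) for r in results
             if r.n_fixations > 1] or [np.empty(0)]
        )
        edges = bins.distance_edges
    else:
        raise ValueError(f"unknown metric {metric!r}")
    c = np.histogram(vals, bins=edges)[0].astype(float)
    tot = c.sum()
    return c / tot if tot > 0 else c
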