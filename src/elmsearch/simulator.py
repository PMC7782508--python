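"""Full search-trial simulation for the ELM, CTELM and CCTELM searchers.

A trial starts with the eye at the field centre and the target hidden at
one of the n predefined grid locations.  The three variants share the
visibility map and the Bayesian posterior over grid locations and differ in
their temporal and motor machinery:

* ELM: fixed 250 ms fixations, one evidence draw per location per fixation,
  next fixation = expected-information-gain argmax over the grid, stop when
  the fixated node's posterior exceeds theta_T.
* CTELM: millisecond evidence accumulation; a fixation ends when the
  posterior at the attended location falls below a collapsing bound (or an
  express-saccade timer fires); neural lags (eye-brain 60 ms, saccade 30 ms)
  shape the timing; unlimited memory; fixations land exactly on grid nodes.
* CCTELM: CTELM plus a saccade-amplitude penalty on target selection,
  Gaussian landing noise (so fixations fall anywhere in the field), a
  memory limited to the last M fixations, and attention probabilities
  summed over all grid nodes within 0.5 degrees.

Timing of the event loop (all times in integer milliseconds): when the
bound (or the express timer) triggers a saccade at time tau, the next
fixation target is selected from the posterior at tau, a fresh
saccade-decision process starts immediately at tau, the eye moves
instantaneously at tau + 30 ms (saccade lag), and evidence keeps
accumulating from the *previous* fixation location until the first
information from the new one arrives at tau + 30 + 60 ms (eye-brain lag),
at which point the previous fixation's evidence is frozen.  The collapsing
bound's clock runs from the start of the decision process, but it is only
compared against the attended probability once evidence from the attended
fixation has begun to arrive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .belief import PosteriorMap
from .evidence import D_PRIME_FLOOR
from .grid import generate_grid, rotate_points
from .oculomotor import LandingModel, sample_landing
from .policy import (
    SaccadeTimingParams,
    SelectionParams,
    StoppingParams,
    sample_express_latency,
    sample_saccade_type,
)
from .visibility import VisibilityFieldParams

__all__ = [
    "SearchFieldConfig",
    "ModelVariant",
    "TrialResult",
    "BatchSummary",
    "candidate_dprime_sq",
    "run_trial_elm",
    "run_trial_ct",
    "run_trial",
    "run_batch",
    "events_frame",
    "trials_frame",
]

_MS = 0.001


@dataclass(frozen=True)
class SearchFieldConfig:
    """Geometry of the search field and its predefined locations."""

    n_locations: int = 400
    diameter: float = 15.0
    grid_layout: str = "rings"

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    def base_grid(self) -> np.ndarray:
        return generate_grid(self.n_locations, self.radius, layout=self.grid_layout)


@dataclass(frozen=True)
class ModelVariant:
    """A fully-parameterised searcher.

    ``kind`` is 'elm', 'ctelm' or 'cctelm'.  ``memory`` is the capacity M in
    fixations including the current one (None = unlimited); the landing
    model applies to CCTELM only.  ``elm_exposure`` sets the exposure at
    which the ELM variant evaluates its per-fixation visibility (the
    nominal 250 ms fixation).
    """

    kind: str
    visibility: VisibilityFieldParams
    stopping: StoppingParams
    selection: SelectionParams
    timing: Optional[SaccadeTimingParams] = None
    landing: Optional[LandingModel] = None
    memory: Optional[int] = None
    field: SearchFieldConfig = field(default_factory=SearchFieldConfig)
    elm_fixation_duration: float = 0.25
    elm_exposure: float = 0.25
    max_fixations: int = 600
    max_fixation_ms: int = 8000  # numerical safeguard: force a saccade
    # testing hook: schedule saccades at a fixed cadence instead of the
    # collapsing bound / express mixture (used to replicate the discrete
    # searcher with the continuous-time machinery)
    forced_fixation_ms: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("elm", "ctelm", "cctelm"):
            raise ValueError(f"kind must be elm/ctelm/cctelm, got {self.kind!r}")
        if self.kind in ("ctelm", "cctelm") and self.timing is None:
            raise ValueError(f"{self.kind} requires SaccadeTimingParams")
        if self.memory is not None and self.memory < 1:
            raise ValueError("memory capacity must be >= 1")


@dataclass
class TrialResult:
    """One simulated search trial.

    Fixations are ordered; ``durations`` are seconds between successive eye
    movements (the terminal fixation ends at the response).  Saccade i
    connects fixation i to fixation i + 1.
    """

    fix_xy: np.ndarray          # (F, 2)
    durations: np.ndarray       # (F,)
    saccade_types: list[str]    # (F - 1,)
    response_xy: np.ndarray
    response_index: int
    target_index: int
    correct: bool
    truncated: bool

    @property
    def n_fixations(self) -> int:
        return len(self.fix_xy)

    @property
    def amplitudes(self) -> np.ndarray:
        d = np.diff(self.fix_xy, axis=0)
        return np.hypot(d[:, 0], d[:, 1])

    @property
    def directions(self) -> np.ndarray:
        d = np.diff(self.fix_xy, axis=0)
        return np.arctan2(d[:, 1], d[:, 0])


@dataclass
class BatchSummary:
    n_trials: int
    p_correct: float
    truncation_rate: float
    median_fix_correct: float
    median_fix_error: float
    max_fix_correct: int
    max_fix_error: int


def candidate_dprime_sq(
    grid: np.ndarray, p: VisibilityFieldParams, exposure: float = 0.25
) -> np.ndarray:
    """d'^2 at every grid node for every candidate fixation node.

    Entry (i, j): squared visibility of node i while fixating node j, for a
    fixation of ``exposure`` seconds.  Symmetric, because visibility depends
    only on the (sign-symmetric) displacement.  Computed in single
    precision: this matrix only feeds the saccade-target argmax.
    """
    g = grid.astype(np.float32)
    dx = g[:, 0][:, None] - g[:, 0][None, :]
    dy = g[:, 1][:, None] - g[:, 1][None, :]
    r = np.sqrt(dx * dx + np.float32(p.p5) * dy * dy)
    a = np.float32(p.p1) * np.exp(np.float32(-p.p2) * r)
    k = np.float32(p.p3) * np.exp(np.float32(-p.p4) * r)
    ekt = np.exp(-k * np.float32(exposure))
    d2 = a * a * (1.0 - ekt) / (k * (1.0 + ekt))
    return np.maximum(d2, np.float32(D_PRIME_FLOOR**2))


def _fields_at(grid: np.ndarray, eye: np.ndarray, p: VisibilityFieldParams):
    """Cached (a, k) per grid node for a fixation at ``eye`` (with a floor)."""
    d = grid - eye
    r = np.sqrt(d[:, 0] ** 2 + p.p5 * d[:, 1] ** 2)
    a = p.p1 * np.exp(-p.p2 * r)
    k = p.p3 * np.exp(-p.p4 * r)
    a = np.maximum(a, D_PRIME_FLOOR * np.sqrt(k))
    return a, k


def _dprime_at(grid, eye, p, exposure):
    a, k = _fields_at(grid, eye, p)
    ekt = np.exp(-k * exposure)
    return a * np.sqrt((1.0 - ekt) / (k * (1.0 + ekt)))


def _select(post_p, d2_matrix, grid, eye, sel: SelectionParams) -> int:
    """ELM / penalised argmax with deterministic tie-breaking."""
    gains = 0.5 * (post_p @ d2_matrix)
    dist = np.hypot(grid[:, 0] - eye[0], grid[:, 1] - eye[1])
    if sel.mode == "penalized":
        scores = np.exp(-np.maximum(dist, 1.0) / sel.penalty_scale) * gains
    else:
        scores = gains
    tied = np.flatnonzero(scores == scores.max())
    if tied.size == 1:
        return int(tied[0])
    return int(tied[np.lexsort((tied, dist[tied]))[0]])


def run_trial_elm(
    variant: ModelVariant,
    grid: np.ndarray,
    target_index: int,
    rng: np.random.Generator,
) -> TrialResult:
    """Simulate one discrete-time (ELM) trial on a prepared grid."""
    n = len(grid)
    theta_t = variant.stopping.threshold
    d2 = candidate_dprime_sq(grid, variant.visibility, variant.elm_exposure)
    log_p = np.full(n, -math.log(n))
    eye = np.zeros(2)
    # the centre start is generally not a grid node; attention sits on the
    # nearest node until the first saccade
    att = int(np.argmin(((grid - eye) ** 2).sum(axis=1)))
    fix_xy = [eye.copy()]
    durations = []
    types: list[str] = []
    truncated = False
    while True:
        dpr = np.maximum(_dprime_at(grid, eye, variant.visibility,
                                    variant.elm_exposure), D_PRIME_FLOOR)
        mean = np.full(n, -0.5)
        mean[target_index] = 0.5
        W = rng.normal(mean, 1.0 / dpr)
        log_p = log_p + dpr**2 * W
        log_p -= _logsumexp(log_p)
        if math.exp(log_p[att]) > theta_t:
            durations.append(variant.elm_fixation_duration)
            response = att
            break
        if len(fix_xy) >= variant.max_fixations:
            durations.append(variant.elm_fixation_duration)
            truncated = True
            response = att
            break
        nxt = _select(np.exp(log_p), d2, grid, eye, variant.selection)
        durations.append(variant.elm_fixation_duration)
        types.append("normal")
        eye = grid[nxt].copy()
        att = nxt
        fix_xy.append(eye.copy())
    correct = (not truncated) and response == target_index
    return TrialResult(
        fix_xy=np.asarray(fix_xy),
        durations=np.asarray(durations),
        saccade_types=types,
        response_xy=grid[response].copy(),
        response_index=response,
        target_index=target_index,
        correct=correct,
        truncated=truncated,
    )


def _logsumexp(x: np.ndarray) -> float:
    m = x.max()
    return m + math.log(np.exp(x - m).sum())


_CHUNK = 256  # ms of evidence simulated per vectorised block


class _LiveRecord:
    """Per-location accumulation state of the fixation currently feeding in.

    The hot loop runs in single precision: evidence samples are O(1e-3) and
    posterior exponents O(1e2), both far from float32 limits, and every
    decision is a threshold comparison with plenty of margin.  ``lam_pows``
    caches exp(-k s dt) for s = 1.._CHUNK and ``decay`` tracks
    exp(-k T_f) so no per-step exponentials are needed.
    """

    __slots__ = ("a2", "k", "W", "T_ms", "mu", "sd", "lam_pows", "inv_pows",
                 "decay")

    def __init__(self, grid, eye, p: VisibilityFieldParams, target_index, dt=_MS):
        a, k = _fields_at(grid, eye, p)
        n = len(grid)
        self.a2 = (a * a).astype(np.float32)
        self.k = k
        self.W = np.zeros(n, dtype=np.float32)
        self.T_ms = 0
        mu = np.full(n, -dt)
        mu[target_index] = dt
        self.mu = mu.astype(np.float32)
        self.sd = (np.sqrt(8.0 * dt) / a).astype(np.float32)
        expo = (-dt) * k.astype(np.float32)[:, None] * np.arange(
            1.0, _CHUNK + 1, dtype=np.float32
        )
        self.lam_pows = np.exp(expo)
        self.inv_pows = np.exp(-expo)
        self.decay = np.ones(n, dtype=np.float32)

    def exponent(self) -> np.ndarray:
        t = self.T_ms * _MS
        return self.a2 * self.W / (2.0 + 2.0 * np.exp(-t * self.k)).astype(np.float32)


def _advance(rec: _LiveRecord, steps: int, rng, past_sum):
    """Advance ``rec`` by ``steps`` <= _CHUNK ms of the leaky recursion.

    Returns (E, Z, traj): E = exp(X - colmax(X)) with X the posterior
    exponent matrix, Z the column sums of E, and the evidence trajectory.
    The attended probability over an index set S at step j is
    E[S, j].sum() / Z[j]; the full posterior at step j is E[:, j] / Z[j].
    All heavy operations run in place on single-precision buffers.
    """
    lp = rec.lam_pows[:, :steps]
    inv = rec.inv_pows[:, :steps]
    dw = rng.standard_normal((rec.a2.size, steps), dtype=np.float32)
    np.multiply(dw, rec.sd[:, None], out=dw)
    np.add(dw, rec.mu[:, None], out=dw)
    # traj = (W0 + cumsum(dw * lam^-s)) * lam^s
    np.multiply(dw, inv, out=dw)
    dw[:, 0] += rec.W
    np.cumsum(dw, axis=1, out=dw)
    traj = np.multiply(dw, lp, out=dw)
    # X = past + a2 * traj / (2 + 2 decay lam^s), built in a scratch buffer
    buf = np.multiply(rec.decay[:, None], lp)
    np.multiply(buf, 2.0, out=buf)
    np.add(buf, 2.0, out=buf)
    np.divide(traj, buf, out=buf)
    np.multiply(buf, rec.a2[:, None], out=buf)
    np.add(buf, past_sum[:, None], out=buf)
    m = buf.max(axis=0)
    np.subtract(buf, m[None, :], out=buf)
    E = np.exp(buf, out=buf)
    Z = E.sum(axis=0)
    return E, Z, traj


def _commit(rec: _LiveRecord, traj, upto: int):
    """Fold the first ``upto`` steps of a computed trajectory into ``rec``."""
    rec.W = traj[:, upto - 1].copy()
    rec.decay = rec.decay * rec.lam_pows[:, upto - 1]
    rec.T_ms += upto


def run_trial_ct(
    variant: ModelVariant,
    grid: np.ndarray,
    target_index: int,
    rng: np.random.Generator,
) -> TrialResult:
    """Simulate one continuous-time (CTELM / CCTELM) trial on a prepared grid."""
    n = len(grid)
    p_vis = variant.visibility
    q = variant.timing
    sel = variant.selection
    theta_t = variant.stopping.threshold
    cct = variant.kind == "cctelm"
    M = variant.memory
    ebl_ms = int(round(q.eye_brain_lag / _MS))
    slag_ms = int(round(q.saccade_lag / _MS))
    d2 = candidate_dprime_sq(grid, p_vis, sel.expected_next_fixation_duration)
    q1, q2, q3 = q.q1, q.q2, q.q3

    def att_indices(point):
        # constrained model: all nodes within the 0.5-degree window (an
        # empty window, possible just off the rim, carries zero attended
        # probability); grid-fixating models: the single nearest node
        if cct:
            mask = ((grid - point) ** 2).sum(axis=1) <= 0.25
            return np.flatnonzero(mask)
        return np.array([int(np.argmin(((grid - point) ** 2).sum(axis=1)))])

    # --- trial state -------------------------------------------------------
    t = 0  # ms since stimulus onset
    eye = np.zeros(2)
    frozen: list[np.ndarray] = []   # per-fixation exponent vectors
    past_sum = np.zeros(n)
    fix_xy = [eye.copy()]
    landing_ms = [0]
    durations_ms: list[int] = []
    types: list[str] = []
    truncated = False
    stopped = False
    response = -1

    live: _LiveRecord | None = None   # record currently accumulating
    # decision-process state (the first process is always a normal saccade)
    proc_start = 0
    cur_type = "normal"
    forced = variant.forced_fixation_ms
    # absolute trigger time if scheduled (express saccade or forced cadence)
    express_at: int | None = forced if forced is not None else None
    bound_from = ebl_ms               # earliest bound comparison time
    att_idx = att_indices(eye)
    att_next = att_idx
    # pending transitions (absolute ms); -1 = none
    eye_move_at = -1
    switch_at = ebl_ms                # first fixation's evidence arrival
    pending_target = eye.copy()
    forced_sacc_at = variant.max_fixation_ms  # numerical safeguard

    def refresh_past() -> np.ndarray:
        if M is None:
            use = frozen
        else:
            use = frozen[-(M - 1):] if M > 1 else []
        s = np.zeros(n, dtype=np.float32)
        for v in use:
            s += v
        return s

    def start_saccade(post_p) -> None:
        """Trigger the current decision process at time ``t``: choose the
        next fixation, schedule the eye move and evidence switch, and start
        the next decision process."""
        nonlocal proc_start, cur_type, express_at, bound_from
        nonlocal eye_move_at, switch_at, pending_target, att_next
        nonlocal forced_sacc_at
        nxt = _select(post_p, d2, grid, eye, sel)
        intended = grid[nxt]
        if cct and variant.landing is not None:
            landing = sample_landing(eye, intended, variant.landing, rng,
                                     field_radius=variant.field.radius)
        else:
            landing = intended.copy()
        types.append(cur_type)
        pending_target = landing
        eye_move_at = t + slag_ms
        switch_at = t + slag_ms + ebl_ms
        # the stop rule keeps monitoring the current fixation's window until
        # the eye actually moves; the collapsing bound is only evaluated
        # once evidence from the new fixation arrives, by which time the eye
        # (and with it the attended window) is already at the landing point
        att_next = att_indices(landing)
        # next decision process starts now
        proc_start = t
        if variant.forced_fixation_ms is not None:
            cur_type = "normal"
            express_at = t + variant.forced_fixation_ms
        else:
            cur_type = sample_saccade_type(rng, q, first=False)
            if cur_type == "express":
                latency = int(round(sample_express_latency(rng, q) / _MS))
                express_at = max(t + latency, eye_move_at + 1)
            else:
                express_at = None
        bound_from = switch_at
        forced_sacc_at = t + variant.max_fixation_ms

    def move_eye_if_due() -> None:
        """Execute a pending saccade whose time has passed (bookkeeping)."""
        nonlocal eye, att_idx, eye_move_at
        if eye_move_at != -1 and t >= eye_move_at:
            durations_ms.append(eye_move_at - landing_ms[-1])
            landing_ms.append(eye_move_at)
            eye = pending_target.copy()
            fix_xy.append(eye.copy())
            att_idx = att_next
            eye_move_at = -1

    def switch_if_due() -> None:
        """Freeze the outgoing fixation's evidence and start the new record
        once the eye-brain lag has elapsed after landing."""
        nonlocal live, past_sum, switch_at
        if switch_at != -1 and t >= switch_at:
            if live is not None:
                frozen.append(live.exponent())
            live = _LiveRecord(grid, eye, p_vis, target_index)
            past_sum = refresh_past()
            switch_at = -1

    def finish(log_post: np.ndarray, as_truncated: bool) -> None:
        # a stop during the saccade lag cancels the pending saccade: the
        # response is made from the fixation the eye is actually at
        nonlocal response, stopped, truncated
        truncated = as_truncated
        if cct or as_truncated:
            response = int(np.argmax(log_post))
        else:
            response = int(att_idx[0])
        stopped = True

    while not stopped:
        move_eye_if_due()
        switch_if_due()
        # next structural event (eye moves do not interrupt accumulation)
        horizon = min(
            x for x in (switch_at, express_at, forced_sacc_at, t + _CHUNK)
            if x is not None and x > t
        )
        steps = horizon - t
        if live is None:
            # posterior static at the uniform prior: nothing can cross the
            # stop threshold and the bound is not evaluated yet
            t = horizon
        else:
            E, Z, traj = _advance(live, steps, rng, past_sum)
            # stop-rule window, piecewise if the eye lands mid-block
            if eye_move_at != -1 and eye_move_at <= t + steps:
                j = max(eye_move_at - t - 1, 0)
                p_att = np.empty(steps, dtype=np.float32)
                p_att[:j] = E[att_idx, :j].sum(axis=0) / Z[:j]
                p_att[j:] = E[att_next, j:].sum(axis=0) / Z[j:]
            else:
                p_att = E[att_idx].sum(axis=0) / Z
            if forced is not None:
                # the discrete-replication mode checks the stop rule only at
                # fixation boundaries, like the discrete searcher
                first_stop = steps
            else:
                stop_hits = np.flatnonzero(p_att > theta_t)
                first_stop = stop_hits[0] if stop_hits.size else steps
            first_trig = steps
            if express_at is None:
                ms_abs = t + np.arange(1, steps + 1)
                rel = (ms_abs - proc_start) * _MS
                theta_s = 10.0 ** (q1 * np.exp(-((rel / q2) ** q3)))
                trig_hits = np.flatnonzero((ms_abs >= bound_from)
                                           & (p_att < theta_s))
                if trig_hits.size:
                    first_trig = trig_hits[0]
            if first_stop <= first_trig and first_stop < steps:
                _commit(live, traj, first_stop + 1)
                t = t + first_stop + 1
                move_eye_if_due()
                finish(E[:, first_stop], as_truncated=False)
                break
            if first_trig < steps:
                _commit(live, traj, first_trig + 1)
                t = t + first_trig + 1
                move_eye_if_due()
                if len(fix_xy) >= variant.max_fixations:
                    finish(E[:, first_trig], as_truncated=True)
                    break
                start_saccade(E[:, first_trig] / Z[first_trig])
                continue
            _commit(live, traj, steps)
            t = horizon

        if t == express_at or t == forced_sacc_at:
            # express timer fired, or the bound never crossed within the cap
            move_eye_if_due()
            switch_if_due()
            expo = past_sum + (live.exponent() if live is not None else 0.0)
            post_p = np.exp(expo - expo.max())
            post_p /= post_p.sum()
            if forced is not None and float(post_p[att_idx].sum()) > theta_t:
                finish(expo, as_truncated=False)
                break
            if len(fix_xy) >= variant.max_fixations:
                finish(expo, as_truncated=True)
                break
            start_saccade(post_p.astype(np.float64))
            continue

    # ---- wrap up ----------------------------------------------------------
    durations_ms.append(max(t - landing_ms[-1], 0))
    del types[max(len(fix_xy) - 1, 0):]
    if truncated:
        correct = False
    else:
        correct = response == target_index
    return TrialResult(
        fix_xy=np.asarray(fix_xy),
        durations=np.asarray(durations_ms, dtype=float) * _MS,
        saccade_types=types,
        response_xy=grid[response].copy() if response >= 0 else eye.copy(),
        response_index=response,
        target_index=target_index,
        correct=correct,
        truncated=truncated,
    )


def run_trial(
    variant: ModelVariant,
    grid: np.ndarray,
    target_index: int,
    rng: np.random.Generator,
) -> TrialResult:
    if variant.kind == "elm":
        return run_trial_elm(variant, grid, target_index, rng)
    return run_trial_ct(variant, grid, target_index, rng)


def run_batch(
    variant: ModelVariant,
    n_trials: int,
    seed: int,
    rotate: bool = True,
    offset: int = 0,
) -> tuple[list[TrialResult], BatchSummary]:
    """Simulate ``n_trials`` independent trials.

    Each trial gets its own random substream derived from ``seed``, a fresh
    uniform rotation of the predefined grid about the field centre, and a
    target drawn uniformly among the (rotated) grid locations.  Trial i uses
    substream (seed, offset + i), so a batch can be split or parallelised:
    ``run_batch(v, 1000, s, offset=1000)`` reproduces trials 1000-1999 of
    ``run_batch(v, 2000, s)`` exactly.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    base = variant.field.base_grid()
    results = []
    for i in range(n_trials):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(offset + i,))
        )
        angle = rng.uniform(0.0, 2.0 * np.pi) if rotate else 0.0
        grid_i = rotate_points(base, angle)
        target = int(rng.integers(len(grid_i)))
        results.append(run_trial(variant, grid_i, target, rng))
    return results, summarize_batch(results)


def summarize_batch(results: list[TrialResult]) -> BatchSummary:
    nfix = np.array([r.n_fixations for r in results])
    corr = np.array([r.correct for r in results])
    trunc = np.array([r.truncated for r in results])

    def med(mask):
        return float(np.median(nfix[mask])) if mask.any() else float("nan")

    def mx(mask):
        return int(nfix[mask].max()) if mask.any() else 0

    return BatchSummary(
        n_trials=len(results),
        p_correct=float(corr.mean()),
        truncation_rate=float(trunc.mean()),
        median_fix_correct=med(corr),
        median_fix_error=med(~corr),
        max_fix_correct=mx(corr),
        max_fix_error=mx(~corr),
    )


def events_frame(results: list[TrialResult], model: str = "") -> pd.DataFrame:
    """One row per fixation: positions in degrees (origin at field centre,
    +x right, +y up), onsets/durations in ms, and the type of the saccade
    that ends each fixation."""
    rows = []
    for tid, r in enumerate(results):
        onset = 0.0
        for f in range(r.n_fixations):
            nxt = r.saccade_types[f] if f < len(r.saccade_types) else "response"
            rows.append(
                (tid, model, f + 1, r.fix_xy[f, 0], r.fix_xy[f, 1],
                 onset, r.durations[f] * 1000.0, nxt)
            )
            onset += r.durations[f] * 1000.0
    return pd.DataFrame(
        rows,
        columns=["trial_id", "model", "fix_index", "x_deg", "y_deg",
                 "onset_ms", "duration_ms", "next_saccade_type"],
    )


def trials_frame(results: list[TrialResult], grid: np.ndarray | None = None) -> pd.DataFrame:
    rows = []
    for tid, r in enumerate(results):
        rows.append(
            (tid, r.response_xy[0], r.response_xy[1], r.n_fixations,
             bool(r.correct), bool(r.truncated))
        )
    return pd.DataFrame(
        rows,
        columns=["trial_id", "response_x", "response_y", "n_fixations",
                 "correct", "truncated"],
    )
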