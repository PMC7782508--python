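"""Internal-consistency experiments on the decision rules.

The saccade-target rule scores a candidate fixation by the approximate
expected information gain 0.5 * sum_i P_i d'^2_{i,c}, with candidate
visibility frozen at the expected fixation duration (0.25 s).  This module
measures how well that approximation tracks the *realized* expected entropy
reduction: for a given posterior, the true expected gain of fixating c is

    E[ H(P) - H(P') ],

with the expectation over the target location (distributed as P) and the
evidence of a 0.25-s fixation at c, and P' the updated posterior.  The
correlation of the two quantities across candidates is the figure of merit.
"""

from __future__ import annotations

import numpy as np

from .simulator import ModelVariant, _dprime_at, candidate_dprime_sq

__all__ = ["info_gain_correlation"]


def _entropy_rows(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(p > 0, p * np.log(p), 0.0)
    return -term.sum(axis=-1)


def info_gain_correlation(
    variant: ModelVariant,
    n_posteriors: int = 6,
    n_candidates: int = 60,
    n_mc: int = 256,
    n_history: int = 3,
    seed: int = 0,
) -> float:
    """Mean Pearson correlation (over posteriors) between the approximated
    and the Monte-Carlo realized expected information gain across candidate
    fixations.

    Each posterior is produced by letting the searcher accumulate
    ``n_history`` fixations of evidence from a random target; candidates
    are a random subset of the grid.  Evidence of the probe fixation is
    drawn from the closed-form per-fixation log-likelihood-ratio
    distribution N(+/- d'^2/2, d'^2).
    """
    rng = np.random.default_rng(seed)
    grid = variant.field.base_grid()
    n = len(grid)
    d2 = candidate_dprime_sq(grid, variant.visibility,
                             variant.selection.expected_next_fixation_duration
                             ).astype(np.float64)
    corrs = []
    for _ in range(n_posteriors):
        target = int(rng.integers(n))
        log_p = np.full(n, -np.log(n))
        eye = np.zeros(2)
        for _ in range(n_history):
            dpr = _dprime_at(grid, eye, variant.visibility, 0.25)
            x = rng.normal(-dpr**2 / 2.0, dpr)
            x[target] += dpr[target] ** 2
            log_p = log_p + x
            log_p -= log_p.max()
            log_p -= np.log(np.exp(log_p).sum())
            eye = grid[rng.integers(n)]  # wander; posterior is what matters
        p = np.exp(log_p)
        h0 = _entropy_rows(p[None, :])[0]

        cand = rng.choice(n, size=min(n_candidates, n), replace=False)
        approx = 0.5 * (p @ d2[:, cand])
        realized = np.empty(cand.size)
        targets = rng.choice(n, size=n_mc, p=p)
        for ci, c in enumerate(cand):
            dd = d2[:, c]
            x = rng.normal(-dd / 2.0, np.sqrt(dd), size=(n_mc, n))
            x[np.arange(n_mc), targets] += dd[targets]
            lp = log_p[None, :] + x
            lp -= lp.max(axis=1, keepdims=True)
            post = np.exp(lp)
            post /= post.sum(axis=1, keepdims=True)
            realized[ci] = h0 - _entropy_rows(post).mean()
        corrs.append(np.corrcoef(approx, realized)[0, 1])
    return float(np.mean(corrs))
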