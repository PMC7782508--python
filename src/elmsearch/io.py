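"""Reading gaze-event tables back into trial objects.

The events CSV (one row per fixation: trial_id, model, fix_index, x_deg,
y_deg, onset_ms, duration_ms, next_saccade_type) carries enough information
to rebuild the fixation/saccade structure for summarising; response fields
that the events table does not carry (correctness, target) are filled with
neutral values, so summaries built from CSV exclude the response-dependent
curves.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulator import TrialResult

__all__ = ["results_from_events"]

_REQUIRED = ["trial_id", "fix_index", "x_deg", "y_deg", "duration_ms",
             "next_saccade_type"]


def results_from_events(df: pd.DataFrame) -> list[TrialResult]:
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"events table missing columns: {missing}")
    results = []
    for _, grp in df.groupby("trial_id", sort=True):
        grp = grp.sort_values("fix_index")
        xy = grp[["x_deg", "y_deg"]].to_numpy(dtype=float)
        durations = grp["duration_ms"].to_numpy(dtype=float) / 1000.0
        types = [str(t) for t in grp["next_saccade_type"].tolist()[:-1]]
        results.append(TrialResult(
            fix_xy=xy,
            durations=durations,
            saccade_types=types,
            response_xy=xy[-1].copy(),
            response_index=-1,
            target_index=-1,
            correct=False,
            truncated=False,
        ))
    return results
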