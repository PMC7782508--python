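"""Default parameter presets for the three searcher variants.

Only a subset of the constants are printed quantities with literature
provenance (the stopping threshold 0.952 and memory capacity 8 of the
constrained model, the express-saccade mixture, the neural lags, the
landing-noise regression coefficients, the field geometry).  The remaining
parameters — the visibility field p1-p5, the collapsing-bound shape q1-q3,
and the amplitude-penalty scale c — were fitted to human data in the
original study but not printed; the presets ship documented placeholders
instead, and every parameter carries an explicit ``provenance`` tag
('paper' or 'placeholder') so simulation results are never silently
attributed to the fitted values.

The placeholder choices and their calibration targets:

* visibility (p1, p2, p3, p4, p5) = (10.392, 0.25, 12.0, 0.2, 1.4):
  foveal steady-state d' = p1/sqrt(p3) = 3.0 exactly (the task was designed
  around foveal d' = 3), foveal accumulation time constant 1/p3 ~ 83 ms,
  steady d' falling to ~1 at 7 deg eccentricity, with a mild vertical
  anisotropy;
* bound (q1, q2, q3) = (-5.0, 0.06, -1.0): the bound at first evidence
  arrival (90 ms into a decision process) sits just below the prior mass of
  an unexplored attention window, and the resulting mean fixation duration
  is ~250-280 ms;
* penalty c = 8.0 deg: yields a short-tailed, roughly exponential saccade
  amplitude distribution (median ~1.4 deg) without trapping the searcher.
"""

from __future__ import annotations

from .oculomotor import LandingModel
from .policy import SaccadeTimingParams, SelectionParams, StoppingParams
from .simulator import ModelVariant, SearchFieldConfig
from .visibility import VisibilityFieldParams

__all__ = ["default_presets", "PRESET_PROVENANCE"]

_PLACEHOLDER_VIS = dict(p1=10.392304845413264, p2=0.25, p3=12.0, p4=0.2, p5=1.4)
_PLACEHOLDER_Q = dict(q1=-5.0, q2=0.06, q3=-1.0)
_PENALTY_C = 8.0

PRESET_PROVENANCE = {
    "visibility.p1": "placeholder",
    "visibility.p2": "placeholder",
    "visibility.p3": "placeholder",
    "visibility.p4": "placeholder",
    "visibility.p5": "placeholder",
    "timing.q1": "placeholder",
    "timing.q2": "placeholder",
    "timing.q3": "placeholder",
    "timing.express_fraction": "paper",
    "timing.express_shape": "paper",
    "timing.express_scale": "paper",
    "timing.express_delay": "paper",
    "timing.eye_brain_lag": "paper",
    "timing.saccade_lag": "paper",
    "selection.mode": "paper",
    "selection.penalty_scale": "placeholder",
    "selection.expected_next_fixation_duration": "paper",
    "stopping.threshold.cctelm": "paper",
    "stopping.threshold.elm": "placeholder",
    "stopping.threshold.ctelm": "placeholder",
    "landing.sd_slope": "paper",
    "landing.sd_intercept": "paper",
    "landing.bias_slope": "paper",
    "landing.bias_onset": "paper",
    "memory": "paper",
    "field.n_locations": "paper",
    "field.diameter": "paper",
}


def default_presets() -> dict[str, ModelVariant]:
    """Presets ``elm-default``, ``ctelm-default``, ``cctelm-default``."""
    vis = VisibilityFieldParams(**_PLACEHOLDER_VIS)
    q = SaccadeTimingParams(**_PLACEHOLDER_Q)
    fieldcfg = SearchFieldConfig()
    return {
        "elm-default": ModelVariant(
            kind="elm",
            visibility=vis,
            stopping=StoppingParams(0.952),
            selection=SelectionParams(mode="elm"),
            field=fieldcfg,
        ),
        "ctelm-default": ModelVariant(
            kind="ctelm",
            visibility=vis,
            stopping=StoppingParams(0.952),
            selection=SelectionParams(mode="elm"),
            timing=q,
            field=fieldcfg,
        ),
        "cctelm-default": ModelVariant(
            kind="cctelm",
            visibility=vis,
            stopping=StoppingParams(0.952),
            selection=SelectionParams(mode="penalized", penalty_scale=_PENALTY_C),
            timing=q,
            landing=LandingModel(),
            memory=8,
            field=fieldcfg,
        ),
    }
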