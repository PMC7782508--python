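"""YAML model-configuration files.

A config file captures everything needed to reproduce a simulation: the
model kind, every parameter block, the field geometry, and a per-parameter
``provenance`` map marking each value as a printed constant ('paper') or a
documented placeholder.  Loading validates every block through the
dataclass invariants before any simulation runs, and round-trips
losslessly.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .oculomotor import LandingModel
from .policy import SaccadeTimingParams, SelectionParams, StoppingParams
from .presets import PRESET_PROVENANCE, default_presets
from .simulator import ModelVariant, SearchFieldConfig
from .visibility import VisibilityFieldParams

__all__ = ["variant_to_dict", "variant_from_dict", "load_config", "save_config"]

_BLOCKS = {
    "visibility": VisibilityFieldParams,
    "timing": SaccadeTimingParams,
    "selection": SelectionParams,
    "stopping": StoppingParams,
    "landing": LandingModel,
    "field": SearchFieldConfig,
}


def variant_to_dict(variant: ModelVariant, provenance: dict | None = None) -> dict:
    out: dict = {"model": variant.kind, "memory": variant.memory}
    for name in ("visibility", "timing", "selection", "stopping", "landing", "field"):
        block = getattr(variant, name)
        out[name] = None if block is None else asdict(block)
    out["elm_fixation_duration"] = variant.elm_fixation_duration
    out["elm_exposure"] = variant.elm_exposure
    out["max_fixations"] = variant.max_fixations
    out["provenance"] = dict(provenance if provenance is not None else PRESET_PROVENANCE)
    return out


def variant_from_dict(cfg: dict) -> ModelVariant:
    if not isinstance(cfg, dict):
        raise ValueError("config root must be a mapping")
    try:
        kind = cfg["model"]
    except KeyError as exc:
        raise ValueError("config is missing the 'model' field") from exc
    blocks = {}
    for name, cls in _BLOCKS.items():
        raw = cfg.get(name)
        if raw is None:
            blocks[name] = None
            continue
        if not isinstance(raw, dict):
            raise ValueError(f"config block {name!r} must be a mapping")
        try:
            blocks[name] = cls(**raw)
        except TypeError as exc:
            raise ValueError(f"config block {name!r}: unknown or missing field ({exc})")
        except ValueError as exc:
            raise ValueError(f"config block {name!r}: {exc}")
    if blocks["visibility"] is None:
        raise ValueError("config block 'visibility' is required")
    if blocks["stopping"] is None:
        raise ValueError("config block 'stopping' is required")
    if blocks["selection"] is None:
        raise ValueError("config block 'selection' is required")
    kwargs = dict(
        kind=kind,
        visibility=blocks["visibility"],
        stopping=blocks["stopping"],
        selection=blocks["selection"],
        timing=blocks["timing"],
        landing=blocks["landing"],
        memory=cfg.get("memory"),
    )
    if blocks["field"] is not None:
        kwargs["field"] = blocks["field"]
    for opt in ("elm_fixation_duration", "elm_exposure", "max_fixations"):
        if opt in cfg and cfg[opt] is not None:
            kwargs[opt] = cfg[opt]
    return ModelVariant(**kwargs)


def save_config(variant: ModelVariant, path, provenance: dict | None = None) -> None:
    payload = variant_to_dict(variant, provenance)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_config(path) -> ModelVariant:
    raw = yaml.safe_load(Path(path).read_text())
    return variant_from_dict(raw)


def load_preset_or_config(model: str, config_path=None) -> ModelVariant:
    """CLI helper: a preset name ('elm', 'ctelm', 'cctelm') or a YAML path."""
    if config_path is not None:
        return load_config(config_path)
    presets = default_presets()
    key = f"{model}-default"
    if key not in presets:
        raise ValueError(f"unknown model {model!r}; expected elm, ctelm or cctelm")
    return presets[key]
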