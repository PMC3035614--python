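"""Flat key-value (de)serialization of scenario parameter sets.

Configs are JSON or YAML mappings whose keys mirror the parameter dataclass
fields, plus a ``scenario`` tag; per-resource values are arrays.  Round
trips are lossless and unknown keys are rejected, so a config written by
one run reproduces the next exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .models import (
    AdditionalResourcesParams,
    InterstageSharingParams,
    MultipleHabitatsParams,
    ScenarioParams,
)

__all__ = [
    "params_to_dict",
    "params_from_dict",
    "load_params",
    "save_params",
    "config_hash",
]

_CLASSES = {
    "additional": AdditionalResourcesParams,
    "multiple": MultipleHabitatsParams,
    "sharing": InterstageSharingParams,
}


def _jsonable(value):
    if isinstance(value, np.ndarray):
        return [bool(v) if value.dtype == bool else float(v) for v in value]
    if isinstance(value, (np.floating, np.integer)):
        return float(value)
    return value


def params_to_dict(params: ScenarioParams) -> dict:
    """Flat dict representation, suitable for JSON/YAML."""
    out = {"scenario": params.scenario}
    for f in dataclasses.fields(params):
        val = getattr(params, f.name)
        if val is None:
            continue
        out[f.name] = _jsonable(val)
    return out


def params_from_dict(data: dict) -> ScenarioParams:
    """Rebuild a parameter set from :func:`params_to_dict` output.

    Unknown keys raise ``ValueError`` so typos in configs fail loudly.
    """
    data = dict(data)
    scenario = data.pop("scenario", None)
    if scenario not in _CLASSES:
        raise ValueError(f"config must set scenario to one of {sorted(_CLASSES)}")
    cls = _CLASSES[scenario]
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys for scenario {scenario!r}: {sorted(unknown)}")
    return cls(**data)


def save_params(params: ScenarioParams, path) -> None:
    path = Path(path)
    data = params_to_dict(params)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=True))
    else:
        path.write_text(json.dumps(data, indent=2, sort_keys=True))


def load_params(path) -> ScenarioParams:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must contain a mapping")
    return params_from_dict(data)


def config_hash(params: ScenarioParams) -> str:
    """Stable short hash identifying a parameter set in output provenance."""
    canonical = json.dumps(params_to_dict(params), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
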