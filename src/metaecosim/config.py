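"""Run-configuration files (YAML/JSON) with strict key checking.

A config has up to four sections: ``params`` (flat key-value, see
:meth:`metaecosim.model.ModelParams.from_dict`), ``topology`` (either a
builder recipe or explicit connectivity matrices), ``settle``
(classification protocol constants) and ``sweep`` (grid axes, ensemble
size, seed).  Unknown keys raise immediately, guarding against silent
typos in parameter names.
"""

from __future__ import annotations

import json
from dataclasses import fields as dc_fields
from pathlib import Path

import numpy as np
import yaml

from .classify import SettleSettings
from .model import ModelParams
from .topology import (
    MetaTopology,
    fully_connected_resource_topology,
    nested_topology,
)

__all__ = [
    "load_config",
    "save_config",
    "build_params",
    "build_topology",
    "build_settle",
]

_SECTIONS = {"params", "topology", "settle", "sweep"}
_BUILDERS = {
    "nested": nested_topology,
    "fully_connected": fully_connected_resource_topology,
}


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    data = (
        json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    )
    if not isinstance(data, dict):
        raise ValueError(f"config {path} is not a mapping")
    unknown = set(data) - _SECTIONS
    if unknown:
        raise KeyError(f"unknown config section(s): {sorted(unknown)}")
    return data


def save_config(config: dict, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(config, indent=2))
    else:
        path.write_text(yaml.safe_dump(config, sort_keys=False))


def build_params(config: dict) -> ModelParams:
    return ModelParams.from_dict(config.get("params", {}))


def build_topology(config: dict) -> MetaTopology:
    block = dict(config.get("topology", {"builder": "nested"}))
    if "builder" in block:
        name = block.pop("builder")
        if name not in _BUILDERS:
            raise KeyError(
                f"unknown topology builder {name!r}; "
                f"options: {sorted(_BUILDERS)}"
            )
        allowed = {"n_locations", "flow_normalization"}
        unknown = set(block) - allowed
        if unknown:
            raise KeyError(f"unknown topology key(s): {sorted(unknown)}")
        return _BUILDERS[name](**block)
    return MetaTopology.from_config_block(block)


def build_settle(config: dict) -> SettleSettings:
    block = dict(config.get("settle", {}))
    allowed = {f.name for f in dc_fields(SettleSettings)}
    unknown = set(block) - allowed
    if unknown:
        raise KeyError(f"unknown settle key(s): {sorted(unknown)}")
    return SettleSettings(**block)


def axis_values(spec) -> np.ndarray:
    """Parse a grid axis: list of values or {start, stop, step} mapping."""
    if isinstance(spec, dict):
        unknown = set(spec) - {"start", "stop", "step"}
        if unknown:
            raise KeyError(f"unknown axis key(s): {sorted(unknown)}")
        start, stop, step = spec["start"], spec["stop"], spec["step"]
        if step <= 0:
            raise ValueError("axis step must be > 0")
        n = int(round((stop - start) / step))
        return np.round(start + step * np.arange(n + 1), 10)
    return np.asarray(list(spec), dtype=float)
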