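"""Plain-text persistence: YAML configs, CSV tables, JSON reports."""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd
import yaml

from .online import OnlineConfig, RadiusMap
from .simulate import SimulationConfig
from .study import StudyConfig


def _plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def save_config(config: StudyConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(config), fh, sort_keys=False)


def load_config(path) -> StudyConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    sim = raw.pop("sim")
    sim["channels"] = tuple(sim.get("channels", ()))
    sim["conditions"] = tuple(sim.get("conditions", ()))
    online_cfg = raw.pop("online_cfg")
    rmap = raw.pop("radius_map")
    return StudyConfig(sim=SimulationConfig(**sim),
                       online_cfg=OnlineConfig(**online_cfg),
                       radius_map=RadiusMap(**rmap), **raw)


def save_band_powers(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def load_band_powers(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_trace(trace, path) -> None:
    pd.DataFrame({"time_s": trace.update_times,
                  "alpha_db": trace.alpha_db,
                  "radius_px": trace.radius_px}).to_csv(path, index=False)


def save_ground_truth(truth, path) -> None:
    truth.trial_table().to_csv(path, index=False)


def save_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(_plain(obj), fh, indent=2)
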