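"""Run configuration: flat key/value text (a YAML-compatible subset).

Reserved keys: ``stage``, ``seed``, ``out_dir``.  Keys prefixed ``input.``
name input files; every other key is a stage parameter.  Example::

    stage: dwi-adc
    seed: 7
    out_dir: runs/adc01
    input.volumes: volumes.csv
    input.bvalues: bvalues.csv
    input.roi_labels: roi_labels.nii
    time_spacing_s: 300
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    stage: str
    inputs: dict[str, str] = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "aquaflux_out"

    def require_input(self, key: str) -> Path:
        if key not in self.inputs:
            raise KeyError(f"config is missing required input key 'input.{key}'")
        return Path(self.inputs[key])

    def param(self, key: str, default=None):
        return self.params.get(key, default)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat key/value mapping")
    if "stage" not in raw:
        raise ValueError(f"{path}: config is missing the 'stage' key")
    cfg = RunConfig(stage=str(raw.pop("stage")))
    cfg.seed = int(raw.pop("seed", 0))
    cfg.out_dir = str(raw.pop("out_dir", cfg.out_dir))
    for key, val in raw.items():
        if key.startswith("input."):
            cfg.inputs[key[len("input.") :]] = str(val)
        else:
            cfg.params[key] = val
    return cfg
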