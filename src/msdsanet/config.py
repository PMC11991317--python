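"""Run configuration: flat-namespaced YAML keys mirroring the pipeline knobs.

A RunConfig fully determines a run given the same inputs: saving one and
reloading it reproduces the run. Keys are dotted ("synthetic.n_trials",
"training.lr") so config files diff cleanly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .model import ModelConfig
from .evaluation import TrainingConfig


@dataclass
class RunConfig:
    preset: str = "deap-like"            # synthetic preset for simulate
    dimension: str = "valence"
    threshold: float | None = None       # None -> from the preset's rating scale
    window_s: float = 1.0
    stride_s: float = 1.0
    layout_path: str | None = None
    model_size: str = "reduced"          # "reduced" or "full"
    k_folds: int = 10
    snr_list: tuple = (10.0, 0.0, -5.0)
    ablation: str = "full"
    seed: int = 0
    out_dir: str = "runs"
    verbosity: int = 1
    synthetic: dict = field(default_factory=dict)   # overrides for the preset
    model: dict = field(default_factory=dict)       # overrides for ModelConfig
    training: dict = field(default_factory=dict)    # overrides for TrainingConfig

    def model_config(self, n_eeg: int, n_periph: int,
                     window_samples: int) -> ModelConfig:
        kw = dict(self.model)
        kw.setdefault("seed", self.seed)
        base = dict(n_eeg=n_eeg, n_periph=n_periph, window_samples=window_samples)
        if self.model_size == "reduced":
            return ModelConfig.reduced(**base, **kw)
        return ModelConfig(**base, **kw)

    def training_config(self) -> TrainingConfig:
        kw = dict(self.training)
        kw.setdefault("seed", self.seed)
        if self.model_size == "reduced":
            return TrainingConfig.reduced(**kw)
        return TrainingConfig(**kw)


def _flatten(d: dict, prefix: str = "") -> dict:
    out = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, f"{key}."))
        else:
            out[key] = list(v) if isinstance(v, tuple) else v
    return out


def _unflatten(flat: dict) -> dict:
    out: dict = {}
    for key, v in flat.items():
        parts = key.split(".")
        node = out
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = v
    return out


def save_run_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_flatten(asdict(cfg)), fh, sort_keys=True)


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        flat = yaml.safe_load(fh) or {}
    d = _unflatten(flat)
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(d) - known
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}; "
                       f"valid keys: {sorted(known)}")
    if "snr_list" in d:
        d["snr_list"] = tuple(d["snr_list"])
    return RunConfig(**d)
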