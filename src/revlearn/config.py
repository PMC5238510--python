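"""Run configuration (YAML) and reproducibility manifest helpers."""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .models import ModelParams, MODEL_NAMES

__all__ = ["RunConfig", "load_config", "write_manifest", "derive_subseeds"]

DEFAULT_CONDITIONS = {
    "control": {
        "model": "FW+Decay",
        "params": {"eta": 0.561, "beta": 2.18, "alpha": 0.44, "omega": 1.043},
        "n_sessions": 19,
        "blocks_per_session": 8,
    },
    "drug": {
        "model": "FW+Decay",
        "params": {"eta": 0.648, "beta": 2.12, "alpha": 0.41, "omega": 1.179},
        "n_sessions": 19,
        "blocks_per_session": 8,
    },
}


@dataclass
class RunConfig:
    seed: int = 0
    conditions: dict = field(default_factory=lambda: json.loads(json.dumps(DEFAULT_CONDITIONS)))
    models: list = field(default_factory=lambda: list(MODEL_NAMES))
    fit: dict = field(default_factory=lambda: {"n_starts": 5, "nm_maxiter": 20})
    cv: dict = field(default_factory=lambda: {"n_reps": 100, "train_frac": 0.8})
    perm: dict = field(default_factory=lambda: {"n_perm": 1000, "level": 0.95})
    observer: dict = field(default_factory=lambda: {"level": 0.95, "chance": 0.5})
    lapse_rate: float = 0.0

    def __post_init__(self):
        for name, spec in self.conditions.items():
            if spec["model"] not in MODEL_NAMES:
                raise ValueError(f"unknown model {spec['model']!r} for condition {name!r}")
            if spec.get("n_sessions", 1) < 1 or spec.get("blocks_per_session", 1) < 1:
                raise ValueError("n_sessions and blocks_per_session must be positive")
        for m in self.models:
            if m not in MODEL_NAMES:
                raise ValueError(f"unknown model {m!r}")

    def agent_params(self, condition: str) -> ModelParams:
        return ModelParams(**self.conditions[condition].get("params", {}))

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "conditions": self.conditions,
            "models": list(self.models),
            "fit": self.fit,
            "cv": self.cv,
            "perm": self.perm,
            "observer": self.observer,
            "lapse_rate": self.lapse_rate,
        }


def load_config(path=None, seed=None) -> RunConfig:
    """Load a YAML run configuration; missing keys fall back to defaults."""
    raw = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    cfg = RunConfig(**raw)
    if seed is not None:
        cfg.seed = int(seed)
    return cfg


def derive_subseeds(seed: int, stages) -> dict:
    """Deterministic per-stage sub-seeds spawned from the run seed."""
    children = np.random.SeedSequence(seed).spawn(len(stages))
    return {stage: int(child.generate_state(1)[0]) for stage, child in zip(stages, children)}


def write_manifest(out_dir, config: RunConfig, subseeds: dict) -> Path:
    """Write a manifest sufficient to reproduce the run exactly."""
    import revlearn

    cfg = config.to_dict()
    digest = hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()
    manifest = {
        "config": cfg,
        "config_sha256": digest,
        "subseeds": subseeds,
        "versions": {
            "revlearn": revlearn.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
    }
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return path
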