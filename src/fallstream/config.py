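"""Layered run configuration: defaults < YAML file < dotted CLI overrides."""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Dict, Iterable, Optional

import yaml

DEFAULTS: Dict[str, Any] = {
    "seed": 0,
    "data": {
        "target_fs": 50.0,
        "cutoff_hz": 20.0,
        "window_s": 12.0,
        "split": {"ratio": 0.8, "seed": 0},
        "sisfall": {"acc_range_g": 16.0, "acc_bits": 13, "gyro_range_dps": 2000.0, "gyro_bits": 16},
        "synthetic": {
            "n_subjects": 10,
            "falls_per_subject": 50,
            "adls_per_subject": 50,
            "duration_s": 12.0,
        },
    },
    "model": {
        "attention_mode": "vector",
        "pooling": "avg",
        "temperature": None,
        "dropout": 0.5,
    },
    "train": {
        "max_epochs": 300,
        "batch_size": 128,
        "initial_lr": 0.001,
        "lr_decay_epochs": [100, 200],
        "lr_decay_factor": 0.1,
        "epoch_unit": "epoch",
        "class_weighting": False,
    },
    "eval": {
        "cv_k": 5,
        "ablation_rates": [50.0, 10.0, 5.0],
        "stream": {"window_s": 8.0, "hop_s": 0.5},
    },
}


class ConfigError(ValueError):
    pass


def _merge(base: Dict[str, Any], update: Dict[str, Any], path: str = "") -> Dict[str, Any]:
    out = copy.deepcopy(base)
    for key, value in update.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown config key: {here}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"{here} must be a mapping")
            out[key] = _merge(base[key], value, here)
        else:
            out[key] = value
    return out


def _apply_override(cfg: Dict[str, Any], dotted: str) -> None:
    if "=" not in dotted:
        raise ConfigError(f"override {dotted!r} must look like key.path=value")
    key_path, raw = dotted.split("=", 1)
    keys = key_path.strip().split(".")
    node = cfg
    for key in keys[:-1]:
        if not isinstance(node, dict) or key not in node:
            raise ConfigError(f"unknown config key: {key_path}")
        node = node[key]
    leaf = keys[-1]
    if not isinstance(node, dict) or leaf not in node:
        raise ConfigError(f"unknown config key: {key_path}")
    if isinstance(node[leaf], dict):
        raise ConfigError(f"{key_path} is a section, not a value")
    node[leaf] = yaml.safe_load(raw)


def load_config(
    path: Optional[str | Path] = None, overrides: Iterable[str] = ()
) -> Dict[str, Any]:
    """Resolve the configuration tree; precedence CLI > file > defaults."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        loaded = yaml.safe_load(path.read_text()) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        cfg = _merge(cfg, loaded)
    for item in overrides:
        _apply_override(cfg, item)
    return cfg


def save_snapshot(cfg: Dict[str, Any], out_dir: str | Path) -> Path:
    """Write the resolved configuration beside a run's outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "config.resolved.yaml"
    path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    return path
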