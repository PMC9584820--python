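"""Run configuration: YAML schema, validation and artifact provenance."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

__all__ = ["DEFAULT_CONFIG", "load_run_config", "config_hash", "write_provenance"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "out",
    "game": {
        "k": 4,
        "r": 1.6,
        "n_rounds": 10,
        "endowments": [10, 2, 2, 2],
        "bonus_rounds": 4,
    },
    "players": {
        "mixture": {"conditional_cooperator": 0.5, "free_rider": 0.25,
                    "full_contributor": 0.15, "noisy_uniform": 0.1},
        "n_games": 500,
        "imitation": {"n_updates": 30000, "batch_size": 512, "lr": 0.0004,
                      "entropy_weight": 0.1, "l2_weight": 0.00001},
        "rational": {"n_updates": 500, "batch_size": 128, "lr": 0.003},
    },
    "voting": {"slope": 1.4},
    "designer": {
        "n_updates": 10000,
        "batch_size": 512,
        "lr": 0.0004,
        "opponent": "canonical:liberal_egalitarian",
    },
    "tournament": {"n_v": 10, "n_w": 10, "n_per_cell": 20},
    "analysis": {"n_shuffles": 10000, "beach_resolution": 21},
    "simulate": {"mechanism_a": "canonical:liberal_egalitarian",
                 "mechanism_b": "canonical:libertarian",
                 "n_sessions": 1, "order": "AB"},
}


def _validate(section: dict, defaults: dict, path: str = "") -> None:
    for key in section:
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ValueError(f"unknown config key {where!r}; known keys at this "
                             f"level: {sorted(defaults)}")
        if isinstance(defaults[key], dict) and isinstance(section[key], dict) \
                and key != "mixture":
            _validate(section[key], defaults[key], where)


def _merge(defaults: dict, overrides: dict) -> dict:
    out = {}
    for key, value in defaults.items():
        if key in overrides and isinstance(value, dict) and key != "mixture":
            out[key] = _merge(value, overrides[key])
        elif key in overrides:
            out[key] = overrides[key]
        else:
            out[key] = value
    return out


def load_run_config(path: str | Path | None) -> dict:
    """Load a YAML run config, validating keys and filling defaults."""
    if path is None:
        return json.loads(json.dumps(DEFAULT_CONFIG))
    with open(path) as fh:
        overrides = yaml.safe_load(fh) or {}
    if not isinstance(overrides, dict):
        raise ValueError(f"config at {path} must be a YAML mapping")
    _validate(overrides, DEFAULT_CONFIG)
    return _merge(DEFAULT_CONFIG, overrides)


def config_hash(config: dict) -> str:
    """Stable short hash identifying a config (for artifact provenance)."""
    blob = json.dumps(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_provenance(out_dir: str | Path, config: dict, seed: int) -> Path:
    """Record the config, its hash and the seed next to the artifacts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config_hash(config), "seed": seed, "config": config}
    path = out / "provenance.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(meta, fh)
    return path
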