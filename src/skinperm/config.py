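"""Layered configuration: built-in defaults < config file < CLI flags.

The configuration is a plain nested dict (YAML on disk).  Unknown keys are
tolerated with a warning (forward compatibility); missing *required* keys
fail hard with every missing key listed at once.  A canonical SHA-256 hash
of the resolved configuration goes into the run manifest so a run can be
reproduced from the manifest alone.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

__all__ = ["DEFAULTS", "load_config", "resolve_config", "config_hash"]

DEFAULTS: dict = {
    "seed": 0,
    "ph": [7.4],
    "permeant": {
        "preset": "acid_like",
        # or explicitly: name, pka, acid_class, dg_hyd_neutral, dg_hyd_charged
    },
    "environment": {
        "temperature": 305.15,
        "n_layers": 30,
        "n_layers_spread": 6,
        "z1": -5.2,
        "z2": 5.2,
        "spacing": 0.01,
    },
    "preprocessing": {
        "symmetrize": False,
        "median_width": 0.2,
        "edge_points": 2,
        "spacing": 0.01,
    },
    "combination": {
        "mode": "boltzmann",
        "rezero": False,
    },
    "synth": {
        "enabled": True,
        "replicates": 5,
    },
    "inputs": {},   # per-state profile paths when synth is disabled
    "output": {"dir": "skinperm_out"},
}

_REQUIRED = ("permeant", "ph", "environment")


def _deep_merge(base: dict, override: dict, path="", warnings=None) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        full = f"{path}{key}"
        if key not in base and warnings is not None and path == "":
            warnings.append(f"unknown configuration key: {full!r}")
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val, full + ".", warnings)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path) -> dict:
    with Path(path).open() as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return data


def resolve_config(
    file_config: dict | None = None,
    cli_overrides: dict | None = None,
) -> tuple[dict, list[str]]:
    """Merge defaults, file and CLI layers; return (config, warnings).

    Raises ValueError listing *all* missing required keys at once.
    """
    warnings: list[str] = []
    cfg = DEFAULTS
    if file_config:
        cfg = _deep_merge(cfg, file_config, warnings=warnings)
    if cli_overrides:
        cfg = _deep_merge(cfg, cli_overrides, warnings=warnings)
    missing = [k for k in _REQUIRED if not cfg.get(k)]
    if missing:
        raise ValueError(
            "missing required configuration keys: " + ", ".join(missing)
        )
    return cfg, warnings


def config_hash(cfg: dict) -> str:
    """SHA-256 of the canonical JSON form of the configuration."""
    canon = json.dumps(cfg, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()
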