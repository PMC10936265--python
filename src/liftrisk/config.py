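"""Configuration loading.

All physical parameters of the human, box and exoskeleton models, the
lumbar coupling, the cost weights and the solver settings live in one YAML
document.  :func:`default_config` returns the packaged defaults; user files
are deep-merged on top, so a study config only needs to list overrides.
"""

from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path

import yaml


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def default_config() -> dict:
    text = (
        resources.files("liftrisk").joinpath("data/default_config.yaml").read_text()
    )
    return yaml.safe_load(text)


def load_config(path: str | Path | None = None) -> dict:
    """Packaged defaults, optionally overlaid with a user YAML file."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        cfg = _deep_merge(cfg, user)
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
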