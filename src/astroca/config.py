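"""Load and merge the package's structured configuration.

The reference configuration ships as ``data/defaults.yaml``; user files only
need the keys they override. Nested dictionaries are merged recursively.
"""

from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path

import yaml


def default_config() -> dict:
    """Return a deep copy of the packaged reference configuration."""
    text = resources.files("astroca").joinpath("data/defaults.yaml").read_text()
    return yaml.safe_load(text)


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load a configuration file on top of the packaged defaults."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, user)
    return cfg
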