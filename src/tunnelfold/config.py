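"""Default parameter tables (residues, geometry, tunnel) and YAML overrides."""
from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path

import yaml

_DEFAULTS = None


def load_defaults() -> dict:
    """Return the packaged default configuration as a fresh dict."""
    global _DEFAULTS
    if _DEFAULTS is None:
        text = resources.files("tunnelfold.data").joinpath("defaults.yaml").read_text()
        _DEFAULTS = yaml.safe_load(text)
    return copy.deepcopy(_DEFAULTS)


def load_config(path: str | Path | None = None) -> dict:
    """Defaults, deep-updated with an optional user YAML file."""
    cfg = load_defaults()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _deep_update(cfg, user)
    return cfg


def _deep_update(base: dict, extra: dict) -> dict:
    for key, val in extra.items():
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], val)
        else:
            base[key] = val
    return base
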