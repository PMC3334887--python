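"""Experiment configuration files.

A config file is YAML with the same structure as the packaged defaults
(morphology, passive, spine, calcium, sites, electrical blocks); any subset
of keys may be given and is deep-merged over the defaults.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .morphology import default_morphology_config


def deep_merge(base: dict, override: dict) -> dict:
    """Recursively merge ``override`` into a copy of ``base``."""
    out = copy.deepcopy(base)
    for key, val in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(val, dict):
            out[key] = deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Packaged defaults, optionally overridden by a user YAML file."""
    base = default_morphology_config()
    if path is None:
        return base
    with open(path) as fh:
        override = yaml.safe_load(fh) or {}
    if not isinstance(override, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return deep_merge(base, override)
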