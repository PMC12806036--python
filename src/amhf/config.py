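"""Run configuration: nested defaults, YAML overrides, strict key checking.

A run config has three sections: ``seed``, ``synthetic`` (dataset
generation) and ``model`` (estimator parameters, named exactly as the
constructor arguments of
:class:`amhf.model.MultiFunctionPeptideClassifier`).  Unknown keys are
rejected so typos fail loudly; every CLI run logs the fully resolved
config to stderr.
"""

from __future__ import annotations

import copy
import inspect

import yaml

from .io import LABEL_NAMES
from .model import MultiFunctionPeptideClassifier

__all__ = ["default_config", "load_config", "resolve_config"]

_MODEL_KEYS = [
    p.name
    for p in inspect.signature(MultiFunctionPeptideClassifier.__init__).parameters.values()
    if p.name != "self"
]

_DEFAULTS = {
    "seed": 0,
    "synthetic": {
        "n_classes": len(LABEL_NAMES),
        "n_samples": 1000,
        "label_rate": 1.3,
        "noise_rate": 0.05,
        "length_min": 5,
        "length_max": 50,
    },
    "model": {k: None for k in _MODEL_KEYS},  # None = estimator default
}


def default_config() -> dict:
    return copy.deepcopy(_DEFAULTS)


def _merge(base: dict, override: dict, path: str = "") -> dict:
    for key, value in override.items():
        where = f"{path}{key}"
        if key not in base:
            raise ValueError(f"unknown config key: {where!r}")
        if isinstance(base[key], dict) and key != "model":
            if not isinstance(value, dict):
                raise ValueError(f"config key {where!r} must be a mapping")
            _merge(base[key], value, where + ".")
        elif key == "model":
            if not isinstance(value, dict):
                raise ValueError("config key 'model' must be a mapping")
            for mk, mv in value.items():
                if mk not in base["model"]:
                    raise ValueError(f"unknown config key: 'model.{mk}'")
                base["model"][mk] = mv
        else:
            base[key] = value
    return base


def resolve_config(overrides: dict | None) -> dict:
    """Defaults merged with overrides; unknown keys raise ``ValueError``."""
    cfg = default_config()
    if overrides:
        _merge(cfg, overrides)
    return cfg


def load_config(path: str | None) -> dict:
    """Resolve a YAML config file (or just the defaults when path is None)."""
    overrides = None
    if path is not None:
        with open(path) as fh:
            overrides = yaml.safe_load(fh) or {}
    return resolve_config(overrides)


def model_kwargs(cfg: dict) -> dict:
    """Estimator keyword arguments from a resolved config (drop the Nones)."""
    return {k: v for k, v in cfg["model"].items() if v is not None}


__all__.append("model_kwargs")
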