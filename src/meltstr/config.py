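"""One YAML config controlling every threshold in the pipeline.

The file has one block per stage; any subset may be present and
overrides the defaults below.  ``meltstr.config.default_config()``
returns the full dictionary, which also serves as the schema.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Mapping

import yaml

from .melt_io import ContractError

__all__ = ["default_config", "load_config", "ConfigError"]


class ConfigError(ContractError):
    """Invalid or unknown configuration values."""


_DEFAULTS: dict[str, Any] = {
    "locus": "D5S818",
    "features": {
        "smoothing_window": 11,
        "smoothing_degree": 3,
        "melt_window": [70.0, 90.0],
        "prominence_frac": 0.05,
        "terrace_frac": 0.15,
    },
    "lda": {
        "priors": "uniform",
        "ridge": 1e-6,
    },
    "pca": {
        "components": 2,
        "typing_quantile": 0.999,
        "melt_window": [70.0, 90.0],
    },
    "simulation": {
        "tm_coeffs": [67.0, 41.0, 675.0],
        "transition_slope": 0.30,
        "amplitude": 1000.0,
        "baseline_intercept": 100.0,
        "baseline_slope": -0.5,
        "heteroduplex": False,
        "heteroduplex_delta": 1.0,
        "heteroduplex_weight": 0.5,
        "noise_sd": 2.0,
        "tm_jitter_sd": 0.05,
        "n_standards": 8,
        "n_unknowns": 20,
        "seed": 0,
    },
    "evaluation": {
        "grouping": None,  # scheme option name, e.g. "A"
        "protocol": "collapse",  # collapse | retrain
    },
}


def default_config() -> dict[str, Any]:
    return copy.deepcopy(_DEFAULTS)


def _merge(base: dict[str, Any], override: Mapping[str, Any], path: str = "") -> dict[str, Any]:
    out = copy.deepcopy(base)
    for key, value in override.items():
        where = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown config key {where!r}")
        if isinstance(base[key], dict):
            if not isinstance(value, Mapping):
                raise ConfigError(f"config key {where!r} must be a mapping")
            out[key] = _merge(base[key], value, where)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None) -> dict[str, Any]:
    """Load a YAML config, merged over the defaults; ``None`` -> defaults."""
    if path is None:
        return default_config()
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    cfg = _merge(_DEFAULTS, data)
    proto = cfg["evaluation"]["protocol"]
    if proto not in ("collapse", "retrain"):
        raise ConfigError(f"evaluation.protocol must be collapse|retrain, got {proto!r}")
    return cfg
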