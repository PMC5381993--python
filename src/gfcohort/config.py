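"""Configuration loading: defaults shipped with the package, user overrides.

The shipped ``defaults.yaml`` holds the exposure-metric constants, the lag
windows, the six model specifications, the synthetic-cohort generating
parameters and the pipeline defaults.  ``load_config`` deep-merges a user
YAML file (or dict) over the defaults.
"""

from __future__ import annotations

import copy
from importlib import resources
from typing import Mapping, Optional

import yaml

from .exposure import ExposureCoefficients, LagSpec
from .models import ModelSpec

__all__ = ["default_config", "load_config", "exposure_from_config", "lag_from_config", "model_specs_from_config"]


def default_config() -> dict:
    text = resources.files("gfcohort").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


# subtrees replaced wholly when present in an override: a model specification
# or a generating-coefficient dict must stay internally consistent, so partial
# key-wise merging with the defaults would corrupt it
ATOMIC_KEYS = {"model_specs", "coefficients"}


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if k in ATOMIC_KEYS:
            out[k] = copy.deepcopy(dict(v)) if isinstance(v, Mapping) else copy.deepcopy(v)
        elif isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path_or_dict: Optional[object] = None) -> dict:
    """Defaults deep-merged with a YAML file path or a plain mapping."""
    cfg = default_config()
    if path_or_dict is None:
        return cfg
    if isinstance(path_or_dict, Mapping):
        return _deep_merge(cfg, path_or_dict)
    with open(path_or_dict) as fh:
        user = yaml.safe_load(fh) or {}
    return _deep_merge(cfg, user)


def exposure_from_config(cfg: dict) -> ExposureCoefficients:
    e = cfg["exposure"]
    return ExposureCoefficients(
        conc_light=e["conc_light"],
        conc_medium=e["conc_medium"],
        conc_heavy=e["conc_heavy"],
        gamma=e["gamma"],
    )


def lag_from_config(cfg: dict) -> LagSpec:
    lag = cfg["lag"]
    return LagSpec(
        lag=lag["lag"],
        windows=tuple(tuple(w) for w in lag["windows"]),
        recent=tuple(lag["recent"]),
    )


def model_specs_from_config(cfg: dict) -> dict:
    return {
        name: ModelSpec(
            outcome=name,
            covariates=tuple(s["covariates"]),
            family=s["family"],
            risk_set=s["risk_set"],
        )
        for name, s in cfg["model_specs"].items()
    }
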