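"""Run-configuration schema, defaults and validation."""

from __future__ import annotations

import difflib
from copy import deepcopy

import yaml

from .errors import ConfigError

DEFAULTS: dict = {
    "seed": 0,
    "out_dir": "dccn_run",
    "simulate": {
        "enabled": True,
        "n_diabetic": 2000,
        "n_non_diabetic": 2000,
        "n_foods": 45,
        "effect_log_irr_per_sd": 0.4054651081081644,  # log(1.5)
        "outcome_mode": "group_label",
        "differential_rho": 0.4,
    },
    "input": {
        "cohort_csv": None,
        "food_prefix": "food_",
        "food_columns": None,
    },
    "exclusions": {
        "energy_low": 0.005,
        "energy_high": 0.995,
    },
    "intake": {
        "design": "multi_visit",
    },
    "network": {
        "n_iter": 100,
        "subsample_frac": 0.5,
        "r_threshold": 0.2,
        "alpha": 0.05,
        "with_replacement": False,
    },
    "score": {
        "policy": "strict",
        "quantile_method": "linear",
    },
    "assoc": {
        "adjust": "full",
        "smoking": "indicators",
    },
}


def _merge(defaults: dict, user: dict, path: str, errors: list[str]) -> dict:
    out = deepcopy(defaults)
    for key, value in user.items():
        if key not in defaults:
            candidates = difflib.get_close_matches(str(key), defaults, n=1,
                                                   cutoff=0.5)
            hint = f"; did you mean {candidates[0]!r}?" if candidates else ""
            errors.append(f"unknown key {path + str(key)!r}{hint}")
            continue
        if isinstance(defaults[key], dict) and defaults[key]:
            if not isinstance(value, dict):
                errors.append(f"{path + str(key)!r} must be a mapping")
                continue
            out[key] = _merge(defaults[key], value, path + key + ".", errors)
        else:
            out[key] = value
    return out


def _check_ranges(cfg: dict, errors: list[str]) -> None:
    net = cfg["network"]
    if not (0 < net["r_threshold"] < 1):
        errors.append("network.r_threshold must be in (0,1)")
    if not (0 < net["subsample_frac"] <= 1):
        errors.append("network.subsample_frac must be in (0,1]")
    if not (0 < net["alpha"] < 1):
        errors.append("network.alpha must be in (0,1)")
    if net["n_iter"] < 1:
        errors.append("network.n_iter must be >= 1")
    exc = cfg["exclusions"]
    if not (0 <= exc["energy_low"] < exc["energy_high"] <= 1):
        errors.append("exclusions percentiles must satisfy 0 <= low < high <= 1")
    if cfg["intake"]["design"] not in ("multi_visit", "baseline_plus_one"):
        errors.append("intake.design must be multi_visit or baseline_plus_one")
    if cfg["score"]["policy"] not in ("strict", "drop_missing"):
        errors.append("score.policy must be strict or drop_missing")
    if cfg["assoc"]["adjust"] not in ("full", "age_sex", "none"):
        errors.append("assoc.adjust must be full, age_sex or none")
    if cfg["assoc"]["smoking"] not in ("indicators", "current"):
        errors.append("assoc.smoking must be indicators or current")
    if not cfg["simulate"]["enabled"] and not cfg["input"]["cohort_csv"]:
        errors.append("either simulate.enabled or input.cohort_csv is required")


def validate_config(source) -> dict:
    """Normalize a YAML path / mapping into a full config, or raise.

    Unknown keys are rejected with a closest-match suggestion; all
    violations are reported together in the :class:`ConfigError` message.
    An empty file yields pure defaults.
    """
    if source is None:
        user: dict = {}
    elif isinstance(source, dict):
        user = source
    else:
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"config root must be a mapping, got {type(user)}")
    errors: list[str] = []
    cfg = _merge(DEFAULTS, user, "", errors)
    if not errors:
        _check_ranges(cfg, errors)
    if errors:
        raise ConfigError("; ".join(errors))
    return cfg
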