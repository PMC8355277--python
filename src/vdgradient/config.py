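"""YAML configuration: schema, defaults, validation."""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

from ._errors import ConfigError
from .synth import AreaSpec, BehaviorSpec, TaskParams, DEFAULT_AREAS

__all__ = ["default_config", "load_config", "validate_config",
           "config_hash", "areas_from_config", "task_from_config",
           "behavior_from_config"]

_SECTIONS = ("task", "areas", "epochs", "decoding", "timescale", "seed")


def default_config() -> dict:
    return {
        "task": {
            "n_trials": 500,
            "safe_prob_one": False,
            "choice_beta": BehaviorSpec().beta,
            "side_bias": 0.0,
        },
        "areas": [
            {"name": a.name, "order_index": a.order_index,
             "n_neurons": a.n_neurons, "snr_scale": a.snr_scale,
             "ou_tau_mean": a.ou_tau_mean}
            for a in DEFAULT_AREAS
        ],
        "epochs": {"duration_ms": 500, "bin_width_ms": 20},
        "decoding": {
            "n_reps": 200,
            "n_pseudotrials": 1000,
            "shuffle_reps": 50,
            "decimate_to": 125,
            "run_decimation": True,
            "run_multinomial": False,
        },
        "timescale": {"max_lag_ms": 720, "delta_ms": 20},
        "seed": 0,
    }


def validate_config(cfg: dict) -> dict:
    missing = [s for s in _SECTIONS if s not in cfg]
    if missing:
        raise ConfigError(f"config missing sections: {missing}")
    areas = cfg["areas"]
    if not isinstance(areas, list) or len(areas) == 0:
        raise ConfigError("config 'areas' must be a non-empty list")
    orders = [a.get("order_index") for a in areas]
    if len(set(orders)) != len(orders) or any(o is None for o in orders):
        raise ConfigError("area order_index values must be present and distinct")
    for a in areas:
        for key in ("name", "n_neurons", "snr_scale", "ou_tau_mean"):
            if key not in a:
                raise ConfigError(f"area entry missing {key!r}: {a}")
    if cfg["task"].get("n_trials", 0) < 1:
        raise ConfigError("task.n_trials must be >= 1")
    dec = cfg["decoding"]
    for key in ("n_reps", "n_pseudotrials"):
        if dec.get(key, 0) < 1:
            raise ConfigError(f"decoding.{key} must be >= 1")
    return cfg


def load_config(path=None) -> dict:
    cfg = default_config()
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        user = yaml.safe_load(path.read_text()) or {}
        for k, v in user.items():
            if k not in _SECTIONS:
                raise ConfigError(f"unknown config section {k!r}")
            if isinstance(v, dict):
                merged = copy.deepcopy(cfg[k])
                merged.update(v)
                cfg[k] = merged
            else:
                cfg[k] = v
    return validate_config(cfg)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


_OPTIONAL_AREA_KEYS = ("baseline_mean", "baseline_log_sd", "base_weight_sd",
                       "ou_sigma_frac", "noise_sd")


def areas_from_config(cfg: dict):
    out = []
    for a in cfg["areas"]:
        extra = {k: float(a[k]) for k in _OPTIONAL_AREA_KEYS if k in a}
        out.append(AreaSpec(a["name"], int(a["order_index"]),
                            int(a["n_neurons"]), float(a["snr_scale"]),
                            float(a["ou_tau_mean"]), **extra))
    return out


def task_from_config(cfg: dict) -> TaskParams:
    return TaskParams(safe_prob_one=bool(cfg["task"].get("safe_prob_one", False)))


def behavior_from_config(cfg: dict) -> BehaviorSpec:
    return BehaviorSpec(beta=float(cfg["task"].get("choice_beta",
                                                   BehaviorSpec().beta)),
                        side_bias=float(cfg["task"].get("side_bias", 0.0)))
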