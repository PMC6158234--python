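"""Run configuration files, sweep expansion and reproducibility manifests.

Configs are flat YAML key/value files; unspecified fields fall back to the
standard parameter set (N=100, log-normal F with V=1e-4, tau=100, u1=1e-4,
u2=2e-4, r0=1, r1=0.95, r2=5, T_max=3650*N).  An optional ``sweep`` block
maps parameter names to lists of values and is expanded as a Cartesian
product of conditions.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import math
from dataclasses import replace
from pathlib import Path

import yaml

from .effects import ConfigurationError, EffectDistribution
from .engine import SimConfig, ValleyParams, child_seeds

__all__ = ["load_config", "build_config", "expand_sweep", "config_hash", "make_manifest"]

_SCALAR_KEYS = {
    "N": int,
    "family": str,
    "V": float,
    "tau": None,  # int or "inf"
    "lifetime_mode": str,
    "scale_mode": str,
    "r0": float,
    "r1": float,
    "r2": float,
    "u1": float,
    "u2": float,
    "t_max": int,
    "seed": int,
    "trace_stride": int,
    "init_s1": int,
    "snapshot_generations": None,  # list of numbers
}

_DEFAULTS = {
    "N": 100,
    "family": "lognormal",
    "V": 1e-4,
    "tau": 100,
    "lifetime_mode": "deterministic",
    "scale_mode": "multiplicative",
    "r0": 1.0,
    "r1": 0.95,
    "r2": 5.0,
    "u1": 1e-4,
    "u2": 2e-4,
    "t_max": None,
    "seed": 0,
    "trace_stride": 0,
    "init_s1": 0,
    "snapshot_generations": (),
}


def _parse_tau(v):
    if isinstance(v, str):
        if v.lower() in ("inf", "infinity"):
            return math.inf
        raise ConfigurationError(f"invalid tau value {v!r}")
    if v != int(v) and not math.isinf(v):
        raise ConfigurationError(f"tau must be an integer or inf, got {v}")
    return math.inf if math.isinf(v) else int(v)


def build_config(params: dict) -> SimConfig:
    """Build a validated SimConfig from a flat parameter dict."""
    p = dict(_DEFAULTS)
    for key, value in params.items():
        if key not in _SCALAR_KEYS:
            raise ConfigurationError(f"unknown configuration key {key!r}")
        p[key] = value
    try:
        valley = ValleyParams(
            r0=float(p["r0"]), r1=float(p["r1"]), r2=float(p["r2"]),
            u1=float(p["u1"]), u2=float(p["u2"]),
        )
        return SimConfig(
            N=int(p["N"]),
            effect_dist=EffectDistribution(p["family"], float(p["V"])),
            tau=_parse_tau(p["tau"]),
            lifetime_mode=str(p["lifetime_mode"]),
            scale_mode=str(p["scale_mode"]),
            valley=valley,
            t_max=None if p["t_max"] is None else int(p["t_max"]),
            seed=int(p["seed"]),
            trace_stride=int(p["trace_stride"]),
            snapshot_generations=tuple(p["snapshot_generations"]),
            init_s1=int(p["init_s1"]),
        )
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigurationError):
            raise
        raise ConfigurationError(str(exc)) from exc


def load_config(path) -> tuple[SimConfig, dict]:
    """Read a YAML config; returns (base SimConfig, sweep axes)."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config {path} must be a mapping")
    sweep = raw.pop("sweep", {}) or {}
    if not isinstance(sweep, dict):
        raise ConfigurationError("sweep block must map parameter names to lists")
    for key, values in sweep.items():
        if key not in _SCALAR_KEYS or key == "snapshot_generations":
            raise ConfigurationError(f"cannot sweep over {key!r}")
        if not isinstance(values, (list, tuple)) or not values:
            raise ConfigurationError(f"sweep axis {key!r} must be a non-empty list")
    cfg = build_config(raw)
    # re-validate each sweep point eagerly so bad axes fail at load time
    for _label, _cfg in expand_sweep(raw, sweep):
        pass
    return cfg, sweep


def expand_sweep(base_params: dict, sweep: dict) -> list[tuple[str, SimConfig]]:
    """Cartesian expansion of sweep axes into labelled conditions."""
    if not sweep:
        return [("base", build_config(base_params))]
    keys = sorted(sweep)
    out = []
    for combo in itertools.product(*(sweep[k] for k in keys)):
        params = dict(base_params)
        params.update(dict(zip(keys, combo)))
        label = "_".join(f"{k}={v}" for k, v in zip(keys, combo))
        out.append((label, build_config(params)))
    return out


def config_params(cfg: SimConfig) -> dict:
    """Flat, JSON-serializable parameter dict of a SimConfig."""
    return {
        "N": cfg.N,
        "family": cfg.effect_dist.family,
        "V": cfg.effect_dist.V,
        "tau": "inf" if math.isinf(cfg.tau) else int(cfg.tau),
        "lifetime_mode": cfg.lifetime_mode,
        "scale_mode": cfg.scale_mode,
        "r0": cfg.valley.r0,
        "r1": cfg.valley.r1,
        "r2": cfg.valley.r2,
        "u1": cfg.valley.u1,
        "u2": cfg.valley.u2,
        "t_max": cfg.steps,
        "trace_stride": cfg.trace_stride,
        "snapshot_generations": list(cfg.snapshot_generations),
        "init_s1": cfg.init_s1,
    }


def config_hash(cfg: SimConfig) -> str:
    blob = json.dumps(config_params(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def make_manifest(cfg: SimConfig, master_seed: int, n_reps: int, outputs: dict) -> dict:
    """Reproducibility record: same config + master seed => same child seeds."""
    from . import __version__

    return {
        "tool": "valleycross",
        "version": __version__,
        "config": config_params(cfg),
        "config_hash": config_hash(cfg),
        "master_seed": int(master_seed),
        "n_reps": int(n_reps),
        "child_seeds": [int(s) for s in child_seeds(master_seed, n_reps)],
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
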