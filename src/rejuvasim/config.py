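"""Plain-text configuration handling.

Configs are YAML mappings whose keys are exactly the model-parameter field
names (g, k1, k2, Q, R, re, s, P_div, D_death, D_health) plus the
mixed-effects and run keys (sigma, n_founders, max_generation, max_cells,
t_spawn_horizon, max_divisions, max_lifetime, seed).  An infinite repair
capacity is written as the literal string ``inf``.

Two wildtype presets are shipped: ``decline`` (R = 1/pi, k2 = 0.138) and
``unlimited`` (R = inf, k2 = 0.092), both at k1 = 0.4 with the repository's
calibrated base (g = 4.0, Q = 0.35, P_div = 0.7, s = 0.64).
"""

from __future__ import annotations

import math
from dataclasses import fields as dc_fields
from importlib import resources
from pathlib import Path

import yaml

from .lineage import MixedEffectsSpec
from .model import ModelParameters, R_MIN

__all__ = [
    "wildtype_params",
    "RETENTION_WILDTYPE",
    "load_config",
    "params_from_config",
    "spec_from_config",
    "run_kwargs_from_config",
    "dump_config",
]

#: Retention factor of the retention wildtype (the published grid anchor).
RETENTION_WILDTYPE = 0.2957

_PRESETS = {
    "decline": {"R": R_MIN, "k2": 0.138},
    "unlimited": {"R": math.inf, "k2": 0.092},
}

_PARAM_KEYS = tuple(f.name for f in dc_fields(ModelParameters))

_RUN_KEYS = ("max_generation", "max_cells", "t_spawn_horizon",
             "max_divisions", "max_lifetime")


def wildtype_params(regime: str = "decline", *, re: float = RETENTION_WILDTYPE,
                    **overrides) -> ModelParameters:
    """Wildtype parameter preset for one repair-capacity regime."""
    if regime not in _PRESETS:
        raise ValueError(f"unknown regime {regime!r}; use 'decline' or 'unlimited'")
    kw = dict(_PRESETS[regime])
    kw["re"] = re
    kw.update(overrides)
    return ModelParameters(**kw)


def _coerce(key: str, value):
    if key == "R" and isinstance(value, str):
        if value.lower() in ("inf", "infinity"):
            return math.inf
        return float(value)
    return value


def load_config(path: str | Path) -> dict:
    """Read a YAML config mapping; unknown keys are preserved."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    return {k: _coerce(k, v) for k, v in raw.items()}


def params_from_config(cfg: dict) -> ModelParameters:
    kw = {k: float(cfg[k]) for k in _PARAM_KEYS if k in cfg}
    return ModelParameters(**kw)


def spec_from_config(cfg: dict) -> MixedEffectsSpec:
    return MixedEffectsSpec(
        k1_bar=float(cfg.get("k1", ModelParameters().k1)),
        k2_bar=float(cfg.get("k2", ModelParameters().k2)),
        sigma=float(cfg.get("sigma", 0.0)),
    )


def run_kwargs_from_config(cfg: dict) -> dict:
    out = {}
    for k in _RUN_KEYS:
        if k in cfg and cfg[k] is not None:
            out[k] = int(cfg[k]) if k in ("max_generation", "max_cells",
                                          "max_divisions") else float(cfg[k])
    return out


def dump_config(params: ModelParameters, extra: dict | None = None) -> dict:
    """Snapshot of a parameter set as a YAML/JSON-safe mapping."""
    out = {}
    for k in _PARAM_KEYS:
        v = getattr(params, k)
        out[k] = "inf" if (k == "R" and math.isinf(v)) else float(v)
    if extra:
        out.update(extra)
    return out


def builtin_config(name: str) -> dict:
    """Load one of the shipped configs (``wildtype_decline``,
    ``wildtype_unlimited``)."""
    ref = resources.files("rejuvasim").joinpath(f"configs/{name}.yaml")
    raw = yaml.safe_load(ref.read_text())
    return {k: _coerce(k, v) for k, v in raw.items()}
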