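"""Run configuration for the command-line workflow.

A run config is a YAML (or JSON) mapping merged over the package
defaults, which mirror the final model: Table-style population
parameters, a 10 000-child virtual population matched to the published
weight quantiles, doubling-dilution MIC grid 0.125-128 mg/L, the
100% fT>MIC and 50% fT>4xMIC targets, and daily doses of 300 and
400 mg/kg capped at 16 g.
"""

from __future__ import annotations

import copy
import hashlib
from pathlib import Path

import yaml

from .pk_model import PopulationParameters

__all__ = ["DEFAULT_CONFIG", "config_hash", "load_config", "resolve_population_parameters"]

DEFAULT_CONFIG: dict = {
    "population_parameters": PopulationParameters().to_dict(),
    "virtual_population": {
        "n": 10000,
        "weight_quantiles": [12.6, 42.7, 94.2],
        "csv": None,
    },
    "regimens": [
        {"label": label, "dose_mg_kg_day": dose}
        for label in ("IA_q8h", "IA_q6h", "EI_q8h", "EI_q6h", "CI")
        for dose in (300, 400)
    ],
    "targets": [
        {"fraction": 1.0, "mic_multiplier": 1.0},
        {"fraction": 0.5, "mic_multiplier": 4.0},
    ],
    "mic_grid": [0.125 * 2**k for k in range(11)],
    "mics_of_interest": [2.0, 4.0, 16.0],
    "mic_distribution_csv": None,
    "bolus_duration_h": 1.0 / 12.0,
    "window_start_h": 48.0,
    "grid_step_h": 1.0 / 60.0,
    "loading_mg_per_kg": 100.0,
    "study": {},   # StudyDesign overrides for generate-data / fit / vpc
    "vpc": {"n_sim": 500, "n_bins": 3},
    "seed": 12345,
}

_KNOWN_KEYS = set(DEFAULT_CONFIG)


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML/JSON run config merged over the defaults; validate keys."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(user, dict):
            raise ValueError("run config must be a mapping")
        unknown = set(user) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = _merge(cfg, user)
    # validation that does not depend on later stages
    vp = cfg["virtual_population"]
    if vp["n"] < 0:
        raise ValueError("virtual_population.n must be non-negative")
    q = vp["weight_quantiles"]
    if not (len(q) == 3 and 0 < q[0] < q[1] < q[2]):
        raise ValueError("weight_quantiles must be three increasing positive values")
    PopulationParameters.from_dict(cfg["population_parameters"])  # raises if invalid
    for t in cfg["targets"]:
        if not 0 < t["fraction"] <= 1 or t.get("mic_multiplier", 1) < 1:
            raise ValueError(f"invalid target specification: {t}")
    return cfg


def resolve_population_parameters(cfg: dict) -> PopulationParameters:
    return PopulationParameters.from_dict(cfg["population_parameters"])


def config_hash(cfg: dict) -> str:
    """Stable short hash of the resolved config (for output provenance)."""
    text = yaml.safe_dump(cfg, sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]
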