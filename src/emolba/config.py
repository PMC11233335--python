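"""YAML configuration: sampler profiles, generator truth, drift convention."""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .hierfit import DESK_CONFIG, PAPER_CONFIG, SamplerConfig
from .simulate import DEFAULT_POPULATION_SCALE, DEFAULT_TRUTH_LOC, GeneratorConfig

#: named sampler profiles: "paper" is the full-scale run, "desk" the
#: scaled-down development profile
PROFILES = {"paper": PAPER_CONFIG, "desk": DESK_CONFIG}

DEFAULTS = {
    "profile": "desk",
    "drift_convention": "truncated",
    "model": "core",
    "sampler": {},  # overrides on top of the profile
    "generator": {
        "n_participants": 64,
        "blocks": 4,
        "trials_per_block": 60,
        "population_scale": DEFAULT_POPULATION_SCALE,
        "population_loc": dict(DEFAULT_TRUTH_LOC),
    },
    "banova": {
        "fixed_scale": 0.5,
        "random_scale": 1.0,
        "t_scale": 0.7071067811865476,
        "n_mc": 100000,
    },
}


def _deep_update(base: dict, overrides: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (overrides or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge DEFAULTS <- YAML file <- explicit overrides."""
    cfg = DEFAULTS
    if path is not None:
        cfg = _deep_update(cfg, yaml.safe_load(Path(path).read_text()) or {})
    if overrides:
        cfg = _deep_update(cfg, overrides)
    return cfg


def sampler_config(cfg: dict, seed: int = 0) -> SamplerConfig:
    profile = PROFILES[cfg.get("profile", "desk")]
    kwargs = {
        "n_chains": profile.n_chains,
        "n_burn": profile.n_burn,
        "n_sample": profile.n_sample,
        "thin": profile.thin,
        "seed": seed,
        "drift_convention": cfg.get("drift_convention", "truncated"),
    }
    kwargs.update(cfg.get("sampler") or {})
    return SamplerConfig(**kwargs)


def generator_config(cfg: dict) -> GeneratorConfig:
    g = cfg.get("generator") or {}
    return GeneratorConfig(
        n_participants=g.get("n_participants", 64),
        blocks=g.get("blocks", 4),
        trials_per_block=g.get("trials_per_block", 60),
        population_loc=g.get("population_loc", dict(DEFAULT_TRUTH_LOC)),
        population_scale=g.get("population_scale", DEFAULT_POPULATION_SCALE),
        drift_convention=cfg.get("drift_convention", "truncated"),
    )
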