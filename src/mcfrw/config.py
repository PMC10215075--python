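"""Pipeline configuration: one YAML document, model defaults built in.

Every physical and numerical constant of the model can be overridden from
the file; missing keys fall back to the standard fibril model (200 nm
diameter, 1000 nm length, 32% mineralization, dt = 2e-10 s,
D0 = 2.66e-9 m^2/s, 1000 trajectories, quote planes at multiples of
134 nm).
"""

from __future__ import annotations

import copy
import math

import yaml

from .errors import ParameterError

__all__ = ["DEFAULT_CONFIG", "load_config", "merge_config"]

DEFAULT_CONFIG = {
    "geometry": {
        "envelope_radius": 100.0,
        "envelope_length": 1000.0,
        "a_W": 13.19,
        "a_T": 2.35,
        "a_L": None,            # derived from the axial-period relation
        "d_period": 67.0,
        "stagger_offset": 0.5,
        "dim_sd_fraction": 1.0 / 6.0,
        "calibrate_means": True,
        "boundary": "clip",
        "collagen_enabled": True,
        "collagen_radius": 0.615,
        "collagen_spacing": 1.6,
        "seed": 0,
    },
    "perturbation": {
        "n_moves": 6_000_000,
        "max_translation_per_move": 1.0,
        "max_rotation_per_move_deg": 1.0,
        "max_inclination_deg": 20.0,
        "max_offset": 5.0,
        "seed": 1,
    },
    "walk": {
        "delta_t": 2e-10,
        "D0": 2.66e-9,
        "n_trajectories": 1000,
        "max_steps": 50_000_000,
        "record_stride": 20,
        "master_seed": 2,
        "blocked_move": "stay",
        "max_consecutive_rejections": 10_000,
    },
    "analysis": {
        "quotes": [134.0 * k for k in range(1, 8)],
        "tortuosity_resolution": 67.0,
        "fit_window": None,      # null = lags 1..N/10
        "ci_level": 0.95,
    },
}


def merge_config(overrides: dict | None) -> dict:
    """Deep-merge user overrides onto the defaults, rejecting unknown keys."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for section, values in (overrides or {}).items():
        if section not in cfg:
            raise ParameterError(f"unknown config section {section!r}")
        if not isinstance(values, dict):
            raise ParameterError(f"section {section!r} must be a mapping")
        for key, val in values.items():
            if key not in cfg[section]:
                raise ParameterError(
                    f"unknown config key {section}.{key!r}")
            cfg[section][key] = val
    return cfg


def load_config(path=None) -> dict:
    if path is None:
        return merge_config(None)
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return merge_config(data)


def build_objects(cfg: dict):
    """Instantiate (lattice spec, dim ranges, collagen, perturbation, walk)."""
    from .geometry import (CollagenLattice, LatticeSpec, PerturbationConfig,
                           default_dim_ranges)
    from .walker import WalkConfig

    g = cfg["geometry"]
    spec = LatticeSpec(a_W=g["a_W"], a_T=g["a_T"], a_L=g["a_L"],
                       d_period=g["d_period"],
                       stagger_offset=g["stagger_offset"])
    ranges = default_dim_ranges(calibrated=g["calibrate_means"],
                                sd_fraction=g["dim_sd_fraction"])
    collagen = CollagenLattice(radius=g["collagen_radius"],
                               spacing=g["collagen_spacing"],
                               enabled=g["collagen_enabled"])
    p = cfg["perturbation"]
    pert = PerturbationConfig(
        n_moves=int(p["n_moves"]),
        max_translation_per_move=p["max_translation_per_move"],
        max_rotation_per_move=math.radians(p["max_rotation_per_move_deg"]),
        max_inclination=math.radians(p["max_inclination_deg"]),
        max_offset=p["max_offset"],
        rng_seed=int(p["seed"]))
    w = cfg["walk"]
    walk = WalkConfig(delta_t=w["delta_t"], D0=w["D0"],
                      n_trajectories=int(w["n_trajectories"]),
                      max_steps=int(w["max_steps"]),
                      record_stride=int(w["record_stride"]),
                      master_seed=int(w["master_seed"]),
                      blocked_move=w["blocked_move"],
                      max_consecutive_rejections=int(
                          w["max_consecutive_rejections"]))
    return spec, ranges, collagen, pert, walk
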