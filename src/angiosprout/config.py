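"""Simulation parameters and configuration-file IO.

All tunables of the model live here.  Rates and lengths are in microns and
hours; ``duration_days`` is in days.  A proliferation rate PR (1/hr) maps to
a mean cell-cycle length ``cycle_mean = 1/PR``; the migration rate MR (um/hr)
is ``migration.d_base``.

Config files (YAML or JSON) mirror the dataclass fields by name; unknown keys
are rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .errors import ConfigurationError
from .vegf import VegfField


@dataclass
class MigrationParams:
    """Tip-cell migration parameters.

    ``d_base`` is the base migration rate MR in um/hr.  Direction selection
    combines a Gaussian persistence kernel of width ``sigma`` (weight
    ``gamma``) with a normalized chemotactic score over ``n_candidates``
    filopodia directions probed ``probe_length`` um ahead of the tip.  A tip
    may extend at most ``extension_cap_fraction`` of its current length per
    step and never beyond ``d_max`` total length.
    """

    d_base: float = 10.0
    gamma: float = 1.0
    sigma: float = math.pi / 6.0
    n_candidates: int = 4
    probe_length: float = 20.0
    d_max: float = 120.0
    extension_cap_fraction: float = 0.5

    def validate(self) -> None:
        if not (0.0 <= self.gamma <= 1.0):
            raise ConfigurationError("migration.gamma must be in [0, 1]")
        if self.sigma <= 0:
            raise ConfigurationError("migration.sigma must be > 0")
        if self.d_base < 0:
            raise ConfigurationError("migration.d_base must be >= 0")
        if not (0.0 < self.extension_cap_fraction <= 1.0):
            raise ConfigurationError(
                "migration.extension_cap_fraction must be in (0, 1]")
        if self.n_candidates < 1:
            raise ConfigurationError("migration.n_candidates must be >= 1")
        if self.d_max <= 0 or self.probe_length <= 0:
            raise ConfigurationError("migration.d_max and probe_length must be > 0")


@dataclass
class GrowthParams:
    """Proliferation, sprouting, anastomosis and regression parameters.

    ``cycle_mean`` (= 1/PR) and ``cycle_sd`` parameterize the normal
    cell-cycle draw; ``e_min`` is the endothelial-unit length threshold;
    ``p_sprout`` the per-eligible-unit sprouting probability per hour;
    ``d_r`` the regression distance; ``fusion_radius`` the tip contact
    distance triggering anastomosis.
    """

    cycle_mean: float = 40.0
    cycle_sd: float = 4.0
    e_min: float = 20.0
    #: nominal stalk cell-agent length (um): the span a division hands over
    #: is laid down as collinear stalk agents of at most this length
    stalk_agent_length: float = 55.0
    p_sprout: float = 0.005
    d_r: float = 100.0
    fusion_radius: float = 5.0
    #: seed length of a freshly created tip agent (um); the 50%-per-step
    #: extension rule cannot elongate an exactly-zero agent, and the seed
    #: size sets how far a tip can extend within one short cell cycle
    new_tip_length: float = 0.1
    #: sprouts proposed within this distance of a domain face are rejected
    boundary_margin: float = 5.0
    #: minimum angle (rad) between a new sprout and the local vessel axis —
    #: a sprout emerges transversally into free space, not along its vessel
    min_sprout_angle: float = 0.5235987755982988  # pi/6
    #: contact points on the parent capillary closer than this to the sprout
    #: origin never trigger anastomosis (the sprout base is attached tissue)
    origin_exclusion: float = 50.0
    #: minimum cell-cycle draw (truncation floor, hours)
    cycle_floor: float = 1.0
    #: how long (hours) after birth the regression test keeps being
    #: re-applied to a still-single-agent sprout; 0 tests only at creation
    regression_window: float = 12.0

    def validate(self) -> None:
        if self.cycle_mean <= 0:
            raise ConfigurationError("growth.cycle_mean must be > 0")
        if self.cycle_sd < 0:
            raise ConfigurationError("growth.cycle_sd must be >= 0")
        if self.d_r < 0:
            raise ConfigurationError("growth.d_r must be >= 0")
        if not (0.0 <= self.p_sprout <= 1.0):
            raise ConfigurationError("growth.p_sprout must be in [0, 1]")
        if self.e_min < 0 or self.fusion_radius <= 0:
            raise ConfigurationError("growth.e_min/fusion_radius invalid")


@dataclass
class SimulationConfig:
    """Every knob of one simulation run."""

    domain: tuple = (500.0, 500.0, 500.0)
    vegf: VegfField = field(default_factory=VegfField)
    migration: MigrationParams = field(default_factory=MigrationParams)
    growth: GrowthParams = field(default_factory=GrowthParams)
    dt: float = 1.0
    duration_days: float = 20.0
    seed: int = 0
    metric_interval: float = 24.0
    #: spatial-hash bin edge (um)
    bin_size: float = 10.0
    agent_radius: float = 5.0
    #: placement of the two initial capillaries: distance of the vessel
    #: envelope from the two nearest faces, and the axis the vessels run
    #: along
    initial_offset: float = 5.0
    initial_axis: int = 0
    #: the initial capillaries are gently helical rather than mathematically
    #: straight (real mature microvessels are tortuous); radius (um) and
    #: number of turns over the vessel length; amplitude 0 gives straight
    #: edge vessels
    initial_helix_amplitude: float = 25.0
    initial_helix_turns: float = 1.5
    #: segment convention for VSL/VST: include terminus-bounded edges or
    #: restrict to bifurcation-bifurcation edges only
    segment_convention: str = "all"

    def validate(self) -> None:
        d = np.asarray(self.domain, dtype=float)
        if d.shape != (3,) or np.any(d <= 0):
            raise ConfigurationError(f"domain: invalid extents {self.domain!r}")
        if self.dt <= 0:
            raise ConfigurationError("dt must be > 0")
        if self.duration_days <= 0:
            raise ConfigurationError("duration_days must be > 0")
        if self.metric_interval <= 0:
            raise ConfigurationError("metric_interval must be > 0")
        if self.segment_convention not in ("all", "bifurcation_only"):
            raise ConfigurationError(
                "segment_convention must be 'all' or 'bifurcation_only'")
        self.migration.validate()
        self.growth.validate()

    @property
    def n_steps(self) -> int:
        return int(round(self.duration_days * 24.0 / self.dt))

    @property
    def volume_mm3(self) -> float:
        d = np.asarray(self.domain, dtype=float)
        return float(np.prod(d / 1000.0))


def baseline_config(pr: float = 0.025, mr: float = 10.0, d_r: float = 100.0,
                    seed: int = 0, duration_days: float = 20.0,
                    **overrides) -> SimulationConfig:
    """Convenience constructor from the swept control parameters.

    PR (1/hr) sets ``cycle_mean = 1/PR`` and ``cycle_sd = 0.1/PR``; MR
    (um/hr) sets the base migration rate.
    """
    cfg = SimulationConfig(seed=seed, duration_days=duration_days, **overrides)
    cfg.migration = dataclasses.replace(cfg.migration, d_base=float(mr))
    cfg.growth = dataclasses.replace(
        cfg.growth, cycle_mean=1.0 / pr, cycle_sd=0.1 / pr, d_r=float(d_r))
    cfg.validate()
    return cfg


# --------------------------------------------------------------------- #
# config file IO
# --------------------------------------------------------------------- #
def _from_mapping(cls, data: dict, prefix: str = ""):
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigurationError(
            f"unknown config key(s): {', '.join(prefix + k for k in sorted(unknown))}")
    kwargs = {}
    for name, value in data.items():
        ftype = known[name].type
        if name == "vegf":
            kwargs[name] = _from_mapping(VegfField, dict(value), "vegf.")
        elif name == "migration":
            kwargs[name] = _from_mapping(MigrationParams, dict(value), "migration.")
        elif name == "growth":
            kwargs[name] = _from_mapping(GrowthParams, dict(value), "growth.")
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
        del ftype
    return cls(**kwargs)


def config_from_dict(data: dict) -> SimulationConfig:
    cfg = _from_mapping(SimulationConfig, dict(data))
    cfg.validate()
    return cfg


def config_to_dict(cfg: SimulationConfig) -> dict:
    def clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: clean(v) for k, v in dataclasses.asdict(obj).items()
                    if v is not None}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    return clean(cfg)


def load_config(path) -> SimulationConfig:
    """Read a YAML or JSON configuration file (unknown keys rejected)."""
    text = Path(path).read_text()
    data = (json.loads(text) if str(path).endswith(".json")
            else yaml.safe_load(text))
    if not isinstance(data, dict):
        raise ConfigurationError(f"config file {path} does not hold a mapping")
    return config_from_dict(data)


def save_config(cfg: SimulationConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))
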