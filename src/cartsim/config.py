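"""Experiment configuration: schema, defaults, YAML round trip.

The default :class:`ExperimentConfig` reproduces the reference study
conditions: a 1000³ µm domain with 20 µm microenvironment voxels and
30 µm mechanics voxels, oxygen (D = 1e5 µm²/min, λ = 0.1/min, boundary
clamped at 38 mmHg) and an immunostimulatory factor (D = 1e3 µm²/min,
λ = 0.016/min), a 3963-cell spherical organoid, the three-clock time
hierarchy (Δt_cycle = 6 min ≥ Δt_mech = 0.1 min ≥ Δt_diff = 0.01 min,
total 43200 min, saves every 1400 min) and the CAR T-cell parameter
block (r_K = 0.06/min, t_a = 60 min, r_a = 0.2/min, R_LA = 18 µm,
v_mot = 2 µm/min, b = 0.5, t_per = 10 min, lifespan 10 ± 5 days).

A single master seed drives every stream of randomness: it spawns
independent child streams for initial sampling, placement/lifespans,
cycle decisions, and the fused mechanics/immune kernel, so identical
(config, seed) pairs give bitwise-identical outputs.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import yaml

from .cycle import CycleParams, VolumeParams
from .heterogeneity import OncoproteinModel
from .immune import DoseSchedule, TCellParams
from .mechanics import MechanicsParams

__all__ = ["SubstrateSpec", "ExperimentConfig", "load_config", "save_config", "config_hash"]


@dataclass(frozen=True)
class SubstrateSpec:
    """One diffusing substrate: transport constants and boundary source."""

    name: str
    diffusion: float  # µm²/min
    decay: float  # 1/min
    initial: float
    dirichlet_boundary: float | None = None  # clamp value on the domain faces


def _default_substrates() -> tuple[SubstrateSpec, ...]:
    return (
        SubstrateSpec("oxygen", 1.0e5, 0.1, 38.0, 38.0),
        SubstrateSpec("immunostimulatory", 1.0e3, 0.016, 0.0, None),
    )


@dataclass(frozen=True)
class ExperimentConfig:
    """Full parameterisation of one simulation run."""

    box: tuple[float, float, float] = (1000.0, 1000.0, 1000.0)
    grid_dx: float = 20.0
    t_total: float = 43200.0  # min (30 days)
    t_save: float = 1400.0  # min
    dt_cycle: float = 6.0  # min
    dt_mech: float = 0.1  # min
    dt_diff: float = 0.01  # min
    substrates: tuple[SubstrateSpec, ...] = field(default_factory=_default_substrates)
    mechanics: MechanicsParams = field(default_factory=MechanicsParams)
    cycle: CycleParams = field(default_factory=CycleParams)
    volume: VolumeParams = field(default_factory=VolumeParams)
    oncoprotein: OncoproteinModel = field(default_factory=OncoproteinModel)
    tcell: TCellParams = field(default_factory=TCellParams)
    dose: DoseSchedule = field(default_factory=DoseSchedule)
    r_cell: float = 8.4  # µm
    organoid_cells: int = 3963
    o2_uptake_cancer: float = 10.0  # 1/min
    o2_uptake_tcell: float = 1.0  # 1/min
    if_secretion: float = 10.0  # 1/min
    if_saturation: float = 1.0  # arbitrary units
    # fraction of each mechanics step the Δt_diff subcycle advances the
    # (quasi-steady, relaxation-type) fields; 1.0 = full hierarchy
    field_subcycle_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.dt_diff <= self.dt_mech <= self.dt_cycle):
            raise ValueError(
                f"clock hierarchy violated: need dt_diff <= dt_mech <= dt_cycle, "
                f"got {self.dt_diff} / {self.dt_mech} / {self.dt_cycle}"
            )
        for name, num, den in (
            ("dt_mech", self.dt_cycle, self.dt_mech),
            ("dt_diff", self.dt_mech, self.dt_diff),
        ):
            k = num / den
            if abs(k - round(k)) > 1e-9:
                raise ValueError(f"{name} must divide the next-coarser time step")
        if self.t_save <= 0 or self.t_total <= 0:
            raise ValueError("t_total and t_save must be positive")
        if not (0.0 < self.field_subcycle_fraction <= 1.0):
            raise ValueError("field_subcycle_fraction must lie in (0, 1]")
        if self.organoid_cells < 1:
            raise ValueError("organoid must contain at least one cell")
        if self.dose.doses and max(d for d, _ in self.dose.doses) * 1440.0 >= self.t_total:
            raise ValueError("dose scheduled outside the simulation window")

    def replace(self, **kw: Any) -> "ExperimentConfig":
        return dataclasses.replace(self, **kw)


# ----------------------------------------------------------------------
# dict / YAML round trip

_NESTED = {
    "substrates": SubstrateSpec,
    "mechanics": MechanicsParams,
    "cycle": CycleParams,
    "volume": VolumeParams,
    "oncoprotein": OncoproteinModel,
    "tcell": TCellParams,
    "dose": DoseSchedule,
}


def config_to_dict(cfg: ExperimentConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["box"] = list(cfg.box)
    d["substrates"] = [dataclasses.asdict(s) for s in cfg.substrates]
    d["dose"] = {"doses": [list(x) for x in cfg.dose.doses]}
    return d


def _build(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, val in data.items():
        if key not in fields:
            hint = difflib.get_close_matches(key, fields, n=1)
            extra = f"; did you mean {hint[0]!r}?" if hint else ""
            raise KeyError(f"unknown config key {path}{key!r}{extra}")
        kwargs[key] = val
    return cls(**kwargs)


def config_from_dict(data: dict) -> ExperimentConfig:
    """Build a config from a (possibly partial) plain dict.

    Unspecified keys keep their defaults; unknown keys are rejected with
    the nearest valid key named.
    """
    data = dict(data or {})
    for key, cls in _NESTED.items():
        if key not in data or data[key] is None:
            continue
        val = data[key]
        if key == "substrates":
            data[key] = tuple(_build(SubstrateSpec, s, f"{key}.") for s in val)
        elif key == "dose":
            doses = tuple(tuple(x) for x in (val.get("doses") or []))
            unknown = set(val) - {"doses"}
            if unknown:
                raise KeyError(f"unknown config key dose.{sorted(unknown)[0]!r}")
            data[key] = DoseSchedule(doses)
        else:
            data[key] = _build(cls, val, f"{key}.")
    if "box" in data:
        data["box"] = tuple(float(x) for x in data["box"])
    return _build(ExperimentConfig, data, "")


def load_config(path) -> ExperimentConfig:
    """Load a YAML config file; an empty file yields the full defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})


def save_config(cfg: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)


def config_hash(cfg: ExperimentConfig) -> str:
    """Stable short hash of the full parameterisation (for manifests)."""
    canon = json.dumps(config_to_dict(cfg), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
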