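"""Run configuration: schema, validation, presets, and the builder that
turns a validated config into a ready-to-run :class:`~gsmono.solver.Simulation`.

Configs are YAML (or dict) documents validated against a strict schema:
unknown keys are rejected and out-of-range values fail with field-precise
messages.  The four FitzHugh-Nagumo benchmarks are available as one-line
presets; ``scale`` coarsens grid and time step together for desk-scale
runs.  There is no seed field anywhere — the pipeline has no randomness,
and two runs of the same config are bit-identical.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import __version__
from .cells import (FHNParameters, PlateauParameters, fhn_model,
                    surrogate_ventricular_model)
from .errors import ConfigurationError
from .geometry import benchmark, circle_ic, rectangle_ic
from .grid import ConductivityTensor, build_grid
from .mesh import Circle, MotionModel, Polygon, Rectangle, triangulate
from .solver import (Constants, Simulation, SolverOptions, StimulusProtocol,
                     ventricular_constants)

__all__ = ["RunConfig", "load_config", "preset", "PRESET_NAMES",
           "build_simulation", "save_config"]

SCHEMA_VERSION = 1


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridConfig(_Strict):
    extent: tuple[tuple[float, float], tuple[float, float]]
    n1: int = Field(ge=4)
    n2: int = Field(ge=4)


class RegionConfig(_Strict):
    type: Literal["rectangle", "circle", "polygon"]
    lo: Optional[tuple[float, float]] = None
    hi: Optional[tuple[float, float]] = None
    center: Optional[tuple[float, float]] = None
    radius: Optional[float] = Field(default=None, gt=0)
    vertices: Optional[list[tuple[float, float]]] = None

    def build(self):
        if self.type == "rectangle":
            if self.lo is None or self.hi is None:
                raise ConfigurationError("mesh.region: rectangle needs lo and hi")
            return Rectangle(self.lo, self.hi)
        if self.type == "circle":
            if self.center is None or self.radius is None:
                raise ConfigurationError("mesh.region: circle needs center and radius")
            return Circle(self.center, self.radius)
        if self.vertices is None or len(self.vertices) < 3:
            raise ConfigurationError("mesh.region: polygon needs >= 3 vertices")
        return Polygon(tuple(tuple(v) for v in self.vertices))


class MeshConfig(_Strict):
    region: RegionConfig
    target_edge_length: Optional[float] = Field(default=None, gt=0)
    rule_order: int = 2


class CellModelConfig(_Strict):
    type: Literal["fhn", "plateau_surrogate"] = "fhn"
    params: dict = Field(default_factory=dict)

    def build(self):
        try:
            if self.type == "fhn":
                return fhn_model(FHNParameters(**self.params))
            return surrogate_ventricular_model(PlateauParameters(**self.params))
        except TypeError as exc:
            raise ConfigurationError(f"cell_model.params: {exc}") from exc


class ConstantsConfig(_Strict):
    # either explicit effective values...
    cm: float = Field(default=1.0, gt=0)
    am: float = Field(default=1.0, gt=0)
    sigma_l: Optional[float] = Field(default=None, gt=0)
    sigma_t: Optional[float] = Field(default=None, gt=0)
    # ...or a named conductivity set with physiological units
    conductivity: Optional[Literal["potse"]] = None
    cm_uF_per_cm2: float = Field(default=1.0, gt=0)
    am_per_um: float = Field(default=0.24, gt=0)

    def build(self) -> Constants:
        if self.conductivity is not None:
            return ventricular_constants(ConductivityTensor.potse(),
                                         cm_uF_per_cm2=self.cm_uF_per_cm2,
                                         am_per_um=self.am_per_um)
        if self.sigma_l is None or self.sigma_t is None:
            raise ConfigurationError(
                "constants: give sigma_l and sigma_t, or a named conductivity set")
        return Constants(cm=self.cm, am=self.am,
                         sigma_l=self.sigma_l, sigma_t=self.sigma_t)


class MotionConfig(_Strict):
    active: bool = False
    centroid: Optional[tuple[float, float]] = None
    rate: float = 0.4
    t_start: float = 0.0
    t_stop: float = 1.25

    def build(self) -> Optional[MotionModel]:
        if not self.active:
            return None
        if self.centroid is None:
            raise ConfigurationError("motion.centroid required when motion.active")
        return MotionModel(centroid=self.centroid, rate=self.rate,
                           t_start=self.t_start, t_stop=self.t_stop)


class StimulusConfig(_Strict):
    """Disc-region stimulus (ventricular presets build their own masks)."""
    active: bool = False
    center: Optional[tuple[float, float]] = None
    radius: Optional[float] = Field(default=None, gt=0)
    amplitude: float = 0.0
    start: float = 0.0
    duration: float = Field(default=1.0, gt=0)


class SolverConfig(_Strict):
    dt: float = Field(gt=0)
    n_steps: int = Field(ge=0)
    reaction_mode: Literal["per_stage", "frozen"] = "per_stage"
    ghost_refresh_interval: int = Field(default=1, ge=0)
    blowup_guard: float = Field(default=1e3, gt=0)
    lumped_mass: bool = False
    enforce_refinement: bool = True
    refinement_factor: float = Field(default=0.5, gt=0)


class OutputConfig(_Strict):
    out_dir: Optional[str] = None
    snapshot_interval: int = Field(default=0, ge=0)
    probes: list[tuple[float, float]] = Field(default_factory=list)
    record_patches: bool = False
    centroid_interval: int = Field(default=0, ge=0)
    centroid_threshold: float = 0.5


class RunConfig(_Strict):
    schema_version: int = SCHEMA_VERSION
    name: str = "run"
    grid: GridConfig
    mesh: MeshConfig
    cell_model: CellModelConfig = CellModelConfig()
    constants: ConstantsConfig
    motion: MotionConfig = MotionConfig()
    stimulus: StimulusConfig = StimulusConfig()
    solver: SolverConfig
    output: OutputConfig = OutputConfig()
    initial_condition: Literal["rest", "rectangle_spiral", "circle_spiral"] = "rest"

    @model_validator(mode="after")
    def _check(self):
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(f"schema_version must be {SCHEMA_VERSION}")
        (lo1, hi1), (lo2, hi2) = self.grid.extent
        if not (hi1 > lo1 and hi2 > lo2):
            raise ValueError("grid.extent: upper bounds must exceed lower bounds")
        return self


def _wrap_validation_error(exc: ValidationError) -> ConfigurationError:
    msgs = []
    for e in exc.errors():
        path = ".".join(str(p) for p in e["loc"]) or "<root>"
        msgs.append(f"{path}: {e['msg']}")
    return ConfigurationError("invalid configuration: " + "; ".join(msgs))


def load_config(source) -> RunConfig:
    """Load and validate a RunConfig from a YAML path, YAML text, or dict."""
    if isinstance(source, RunConfig):
        return source
    if isinstance(source, dict):
        data = source
    else:
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"could not parse YAML: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigurationError("configuration must be a YAML mapping")
    data = {k: v for k, v in data.items() if not str(k).startswith("_")}
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        raise _wrap_validation_error(exc) from exc


def save_config(config: RunConfig, path) -> None:
    doc = config.model_dump(mode="json")
    doc["_package_version"] = __version__
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

PRESET_NAMES = ("rect_stationary", "circle_stationary", "rect_moving",
                "circle_moving")


def preset(name: str, scale: float = 1.0, t_end: float = 1000.0,
           reaction_mode: str = "per_stage") -> RunConfig:
    """One-line FHN benchmark presets at the printed settings.

    ``scale`` coarsens the grid (cells ~ scale) and stretches dt (~1/scale)
    together; scale = 1 reproduces the printed resolution exactly.
    """
    spec = benchmark(name)
    n = max(int(round(spec.n_cells * scale)), 8)
    dt = spec.dt / scale
    region = spec.region
    if isinstance(region, Rectangle):
        reg = {"type": "rectangle", "lo": list(region.lo), "hi": list(region.hi)}
        ic = "rectangle_spiral"
    else:
        reg = {"type": "circle", "center": list(region.center),
               "radius": region.radius}
        ic = "circle_spiral"
    cfg = {
        "name": name,
        "grid": {"extent": [list(spec.extent[0]), list(spec.extent[1])],
                 "n1": n, "n2": n},
        "mesh": {"region": reg},
        "cell_model": {"type": "fhn"},
        "constants": {"sigma_l": 1e-4, "sigma_t": 1e-4},
        "solver": {"dt": dt, "n_steps": int(round(t_end / dt)),
                   "reaction_mode": reaction_mode},
        "initial_condition": ic,
        "output": {"probes": [[1.5, 1.5]], "record_patches": True,
                   "centroid_interval": 10},
    }
    if spec.moving:
        cfg["motion"] = {"active": True,
                         "centroid": [1.25, 1.25],
                         "rate": 0.4, "t_stop": spec.motion_t_stop}
    return load_config(cfg)


# ---------------------------------------------------------------------------
# Builder
# ---------------------------------------------------------------------------

def build_simulation(config: RunConfig) -> Simulation:
    """Instantiate grid, mesh, model, and solver from a validated config."""
    g = build_grid(config.grid.extent, config.grid.n1, config.grid.n2)
    motion = config.motion.build()
    dilation = 1.0
    if motion is not None and np.isfinite(motion.t_stop):
        dilation = 1.0 + motion.rate * (motion.t_stop - motion.t_start)
    target = config.mesh.target_edge_length
    limit = config.solver.refinement_factor * min(g.dx1, g.dx2) / dilation
    target = limit if target is None else min(target, limit)
    mesh = triangulate(config.mesh.region.build(), target,
                       rule_order=config.mesh.rule_order)
    model = config.cell_model.build()
    constants = config.constants.build()
    stim = None
    if config.stimulus.active:
        s = config.stimulus
        if s.center is None or s.radius is None:
            raise ConfigurationError("stimulus: center and radius required when active")
        d = np.hypot(mesh.quad_material[:, 0] - s.center[0],
                     mesh.quad_material[:, 1] - s.center[1])
        stim = StimulusProtocol(quad_mask=d <= s.radius, amplitude=s.amplitude,
                                start=s.start, duration=s.duration)
    options = SolverOptions(
        reaction_mode=config.solver.reaction_mode,
        ghost_refresh_interval=config.solver.ghost_refresh_interval,
        blowup_guard=config.solver.blowup_guard,
        lumped_mass=config.solver.lumped_mass,
        enforce_refinement=config.solver.enforce_refinement,
        refinement_factor=config.solver.refinement_factor,
    )
    sim = Simulation(g, mesh, model, constants, config.solver.dt,
                     stimulus=stim, motion=motion, options=options)
    if config.initial_condition == "rectangle_spiral":
        sim.set_initial_potential(lambda p: rectangle_ic(p)[0])
        sim.set_initial_state(lambda p: rectangle_ic(p)[1], 0)
    elif config.initial_condition == "circle_spiral":
        sim.set_initial_potential(lambda p: circle_ic(p)[0])
        sim.set_initial_state(lambda p: circle_ic(p)[1], 0)
    return sim
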