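"""Scenario configuration: one object tying geometry, ID layout, coupling
level, stimulus, solver settings and resolution together, with YAML I/O.

A scenario is the unit the experiment drivers run: "close configuration,
w_cleft = 50 nm, w_peri = 10 nm, G_gap = 1 % of nominal, standard
stimulus".  Gap-junctional coupling can be given as an absolute
conductance (mS) or as a fraction of the nominal whole-ID value
(pi R_ID^2 / 1.5 Ohm cm^2 = 2.53 uS for the default geometry).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .fem import DomainConductivities, StimulusProtocol, assemble_system
from .geometry import GeometryParams, IDLayout, compute_nominal_ggap
from .kinetics import MembraneParams
from .mesh import (RESOLUTION_PRESETS, MeshBundle, MeshResolution,
                   build_cell_pair_mesh, build_channel_density_field)
from .solver import SimulationResult, SolverParams, run_simulation

__all__ = ["ScenarioConfig", "run_scenario", "load_config", "dump_config",
           "SOLVER_PRESETS"]

#: reduced-resolution preset for sweeps and continuous-integration runs;
#: the high-fidelity preset uses the 0.0001 ms time step
SOLVER_PRESETS = {
    "coarse": SolverParams(dt=5e-4, duration=10.0, output_stride=20,
                           stop_margin=2.5, stop_on_quiescence=True),
    "fine": SolverParams(dt=1e-4, duration=10.0, output_stride=100),
}


@dataclass
class ScenarioConfig:
    """Complete description of one simulation run."""

    geometry: GeometryParams = field(default_factory=GeometryParams)
    layout: IDLayout = field(default_factory=IDLayout)
    G_gap_fraction: float | None = 0.0     # fraction of the nominal 2.53 uS
    G_gap_absolute: float | None = None    # mS, overrides the fraction
    junctional_resistivity: float = 1.5    # Ohm cm^2, defines the nominal value
    stimuli: tuple[StimulusProtocol, ...] = (StimulusProtocol(cell=1),)
    solver: SolverParams = field(default_factory=lambda: SOLVER_PRESETS["coarse"])
    conductivities: DomainConductivities = field(default_factory=DomainConductivities)
    membrane: MembraneParams = field(default_factory=MembraneParams)
    P: float = 0.5                         # fraction of Na+ channels in the IDs
    resolution: str | MeshResolution = "coarse"
    snapshot_times: tuple[float, ...] = ()

    @property
    def G_gap(self) -> float:
        """Gap-junctional conductance in mS."""
        if self.G_gap_absolute is not None:
            return self.G_gap_absolute
        nominal = compute_nominal_ggap(self.geometry, self.junctional_resistivity)
        return (self.G_gap_fraction or 0.0) * nominal

    def mesh_resolution(self) -> MeshResolution:
        if isinstance(self.resolution, str):
            return RESOLUTION_PRESETS[self.resolution]
        return self.resolution


def run_scenario(config: ScenarioConfig, mesh: MeshBundle | None = None
                 ) -> SimulationResult:
    """Mesh (or reuse a compatible mesh), assemble and integrate one scenario.

    Passing ``mesh`` allows sweeps to reuse the single mesh that all ID
    configurations and cleft widths share; only its region tags are
    re-derived for the scenario's layout.
    """
    if mesh is None:
        mesh = build_cell_pair_mesh(config.geometry, config.layout,
                                    config.mesh_resolution())
    else:
        from .mesh import _assign_id_regions
        mesh = dataclasses.replace(mesh)
        mesh.id_region, mesh.id_in_perinexus = _assign_id_regions(
            config.geometry, config.layout, mesh.disc)
        mesh.layout = config.layout
    system = assemble_system(mesh, config.layout, config.conductivities,
                             G_gap=config.G_gap, C_m=config.membrane.C_m,
                             stimuli=config.stimuli)
    density = build_channel_density_field(config.geometry, config.layout, mesh,
                                          config.P)
    return run_simulation(system, config.solver, config.membrane, density,
                          snapshot_times=config.snapshot_times)


# ---------------------------------------------------------------------------
# YAML round trip
# ---------------------------------------------------------------------------

_SECTION_TYPES = {
    "geometry": GeometryParams,
    "layout": IDLayout,
    "solver": SolverParams,
    "conductivities": DomainConductivities,
    "membrane": MembraneParams,
}


def dump_config(config: ScenarioConfig, path: str | Path) -> None:
    """Write a scenario as a human-readable YAML file."""
    doc = {}
    for name, typ in _SECTION_TYPES.items():
        doc[name] = dataclasses.asdict(getattr(config, name))
    doc["stimuli"] = [dataclasses.asdict(s) for s in config.stimuli]
    for key in ("G_gap_fraction", "G_gap_absolute", "junctional_resistivity",
                "P", "snapshot_times"):
        doc[key] = getattr(config, key)
    doc["snapshot_times"] = list(config.snapshot_times)
    doc["resolution"] = (config.resolution if isinstance(config.resolution, str)
                         else dataclasses.asdict(config.resolution))
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a scenario YAML file (unknown keys are rejected)."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    known = set(_SECTION_TYPES) | {"stimuli", "G_gap_fraction", "G_gap_absolute",
                                   "junctional_resistivity", "P", "resolution",
                                   "snapshot_times"}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    for name, typ in _SECTION_TYPES.items():
        if name in doc:
            kwargs[name] = typ(**doc[name])
    if "stimuli" in doc:
        kwargs["stimuli"] = tuple(StimulusProtocol(**s) for s in doc["stimuli"])
    for key in ("G_gap_fraction", "G_gap_absolute", "junctional_resistivity", "P"):
        if key in doc:
            kwargs[key] = doc[key]
    if "snapshot_times" in doc:
        kwargs["snapshot_times"] = tuple(doc["snapshot_times"])
    if "resolution" in doc:
        res = doc["resolution"]
        kwargs["resolution"] = res if isinstance(res, str) else MeshResolution(**res)
    return ScenarioConfig(**kwargs)
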