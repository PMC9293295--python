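"""Semi-implicit alpha/beta time integration of the coupled FEM-membrane system.

Each step advances the Hodgkin-Huxley gates with Rush-Larsen at the
known membrane potential, evaluates the ionic current density nodally,
builds the right-hand side

    (1/dt)(1 + alpha/beta) U_N Q Vm + f_N - K_x^T V_D - U_N G I_ion,

solves the constant symmetric positive-definite system

    [K_N + (1/(dt beta)) U_N Q U_N^T] V_N = rhs,

and recovers Vm <- (1/beta) U^T V - (alpha/beta) Vm.  With
alpha = beta = 0.5 this is the Crank-Nicolson scheme; alpha = 0 / beta = 1
gives backward Euler.  The left-hand-side matrix does not change during
a run, so it is factorized once (sparse LU of the SPD matrix, reused at
every step like the classical one-time Cholesky).
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import mesh as msh
from .fem import FEMSystem, assemble_weighted_membrane_mass
from .kinetics import (GatingState, MembraneParams, rush_larsen_update,
                       sodium_current, steady_state_gates)

__all__ = ["SolverParams", "SimulationState", "SimulationResult",
           "factorize_lhs", "step", "run_simulation", "SolverError"]


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class SolverParams:
    """Scheme weights (alpha + beta = 1), time step and run control.

    The high-fidelity time step is 0.0001 ms; the reduced-resolution
    preset uses 0.0005 ms.
    """

    alpha: float = 0.5
    beta: float = 0.5
    dt: float = 0.0001            # ms
    duration: float = 10.0        # ms
    output_stride: int = 1        # record every n-th step
    v_rest: float = -85.0         # mV initialization
    stop_margin: float | None = None  # ms of extra simulation after both upstrokes
    stop_on_quiescence: bool = False  # end once all Na+ activity has died out

    def __post_init__(self) -> None:
        if abs(self.alpha + self.beta - 1.0) > 1e-12:
            raise ValueError("alpha + beta must equal 1")
        if self.beta <= 0:
            raise ValueError("beta must be > 0 (semi-implicit scheme)")
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be > 0")


@dataclass
class SimulationState:
    """Potentials at free nodes, membrane potentials and gates at time t.

    ``V_m`` is the scheme's recursion variable (the end-of-step membrane
    potential of the alpha/beta update); ``V_m_eval`` is the consistent
    time-centred value U^T V of the last solved field, which is free of
    the scheme's high-frequency reconstruction mode and is the potential
    at which gates and ionic currents are evaluated and recorded.
    """

    V_N: np.ndarray
    V_m: np.ndarray
    gates: GatingState
    t: float = 0.0
    V_m_eval: np.ndarray | None = None

    def __post_init__(self):
        if self.V_m_eval is None:
            self.V_m_eval = self.V_m.copy()


def factorize_lhs(system: FEMSystem, params: SolverParams,
                  membrane: MembraneParams | None = None,
                  density: msh.ChannelDensityField | None = None):
    """Factorize K_N + (1/(dt beta)) U_N Q U_N^T (+ the linear K+ leak)
    once for the whole run.

    The linear K+ current g_K (Vm - E_K) is folded into the left-hand
    side, which evaluates it exactly at the scheme's alpha/beta-averaged
    membrane potential (time-centred for Crank-Nicolson); only the
    nonlinear Na+ current stays explicit.
    """
    c = 1.0 / (params.dt * params.beta)
    lhs = system.K_N + c * (system.U_N @ system.Q @ system.U_N.T)
    if membrane is not None and membrane.gbar_K != 0.0:
        if density is not None and np.ptp(density.node_gk) != 0.0:
            raise SolverError("the implicit K+ leak assumes a uniform g_K field")
        lhs = lhs + membrane.gbar_K * (system.U_N @ system.G @ system.U_N.T)
    lhs = lhs.tocsc()
    asym = abs(lhs - lhs.T).max()
    if asym > 1e-9 * abs(lhs).max():
        raise SolverError(f"stepping matrix is not symmetric (|A - A^T| = {asym:.3e})")
    try:
        factor = spla.splu(lhs, permc_spec="MMD_AT_PLUS_A",
                           options={"SymmetricMode": True})
    except RuntimeError as exc:  # pragma: no cover - singular systems
        raise SolverError(
            "factorization failed (singular matrix - is any boundary grounded?): "
            f"{exc}") from exc
    # cheap definiteness guard: pivots of the LU of an SPD matrix are positive
    # and bounded away from zero; a vanishing relative pivot flags a floating
    # (ungrounded) potential
    du = factor.U.diagonal()
    if np.any(du <= 0) or du.min() < 1e-12 * du.max():
        raise SolverError(
            f"stepping matrix is singular or not positive definite "
            f"(smallest pivot {du.min():.3e}; likely missing ground)")
    return factor


def initialize_state(system: FEMSystem, params: SolverParams,
                     membrane: MembraneParams) -> SimulationState:
    """Rest state: V_i = v_rest, V_e = 0, gates at their steady state."""
    mesh = system.mesh
    V = np.zeros(mesh.n_nodes)
    intra = np.unique(mesh.tets[mesh.tet_domain != msh.DOM_EXTRA])
    V[intra] = params.v_rest
    V_N = V[system.free]
    V_m = np.full(len(mesh.mem_pairs), params.v_rest)
    gates = steady_state_gates(np.full(len(mesh.mem_pairs), params.v_rest))
    return SimulationState(V_N=V_N, V_m=V_m, gates=gates, t=0.0)


def step(state: SimulationState, system: FEMSystem, factor, params: SolverParams,
         membrane: MembraneParams, density: msh.ChannelDensityField,
         _work: dict | None = None) -> SimulationState:
    """Advance the coupled system by one time step (in place)."""
    dt, alpha, beta = params.dt, params.alpha, params.beta
    if _work is None:
        _work = {}
    if "UNQ" not in _work:
        _work["UNQ"] = (system.U_N @ system.Q).tocsr()
        _work["UNG"] = (system.U_N @ system.G).tocsr()
        # Na+ density is piecewise constant per membrane triangle: weight the
        # membrane quadrature instead of smearing the density to the nodes
        G_na = assemble_weighted_membrane_mass(system.mesh, density.mem_tri_gna)
        _work["UNG_na"] = (system.U_N @ G_na).tocsr()
        _work["KxT"] = system.K_x.T.tocsr()
        _work["UDT"] = system.U_D.T.tocsr()
        _work["UNT"] = system.U_N.T.tocsr()
    UNQ, UNG, UNG_na, KxT, UDT, UNT = (
        _work[k] for k in ("UNQ", "UNG", "UNG_na", "KxT", "UDT", "UNT"))

    # kinetics are driven by the consistent membrane potential U^T V of the
    # last solve; the raw recursion variable V_m carries an oscillatory
    # reconstruction mode for conductances with C_m/g << dt (Na+ cluster)
    v_eval = state.V_m_eval
    state.gates = rush_larsen_update(state.gates, v_eval, dt)
    i_na_unit = sodium_current(v_eval, state.gates, 1.0, membrane)
    v_d = system.dirichlet_values(state.t)
    # the K+ leak sits on the LHS evaluated at U^T V; its E_K offset and the
    # Dirichlet contribution to U^T V stay on the RHS
    gk = density.node_gk * membrane.gbar_K
    rhs = (1.0 / dt) * (1.0 + alpha / beta) * (UNQ @ state.V_m) \
        + system.neumann_source(state.t) - KxT @ v_d \
        - UNG_na @ i_na_unit + UNG @ (gk * (membrane.E_K - (UDT @ v_d)))
    V_N = factor.solve(rhs)
    if not np.all(np.isfinite(V_N)):
        raise SolverError(f"solution diverged (NaN/inf) at t = {state.t:.4f} ms")
    utv = UNT @ V_N + UDT @ v_d
    state.V_m_eval = utv
    state.V_N, state.V_m = V_N, utv / beta - (alpha / beta) * state.V_m
    state.t += dt
    return state


@dataclass
class SimulationResult:
    """Recorded time series and optional field snapshots of one run."""

    time: np.ndarray                       # ms
    patch_vi: dict                         # cell -> mV trace
    ina_id: dict                           # cell -> nA trace (ID membrane)
    ina_bulk: dict                         # cell -> nA trace (lateral + outer membranes)
    min_cleft_ve: np.ndarray               # mV trace
    snapshots: dict = field(default_factory=dict)   # t -> full node potential vector
    meta: dict = field(default_factory=dict)

    def snapshot_times(self):
        return sorted(self.snapshots)


class _Recorder:
    """Records the alpha/beta-averaged field the solver produces; samples
    are timestamped at t_n + beta*dt, the instant that field represents
    (end of step for backward Euler, midpoint for Crank-Nicolson)."""

    def __init__(self, system: FEMSystem, density, membrane, snapshot_times,
                 t_offset: float = 0.0):
        self.t_offset = t_offset
        mesh = system.mesh
        self.system = system
        self.density = density
        self.membrane = membrane
        self.snapshot_times = sorted(snapshot_times or [])
        self.rows = {c: system.node_to_free[mesh.patch_nodes[c]] for c in (1, 2)}
        self.weights = {c: mesh.patch_weights[c] for c in (1, 2)}
        # lumped membrane areas per pair DOF (cm^2) and region masks
        self.lump = np.asarray(system.G.sum(axis=1)).ravel()
        self.masks = {}
        for c, id_sheet, others in ((1, msh.MEM_ID1, (msh.MEM_LAT1, msh.MEM_OUT1)),
                                    (2, msh.MEM_ID2, (msh.MEM_LAT2, msh.MEM_OUT2))):
            self.masks[(c, "ID")] = self._pair_mask(mesh, (id_sheet,), density.mem_tri_gna)
            self.masks[(c, "bulk")] = self._pair_mask(mesh, others, density.mem_tri_gna)
        if mesh.collapsed and len(mesh.cleft_nodes):
            self.cleft_free = system.node_to_free[mesh.cleft_nodes]
        else:
            self.cleft_free = None
        self.data = {k: [] for k in ("t", "v1", "v2", "ina_id1", "ina_id2",
                                     "ina_bulk1", "ina_bulk2", "minve")}
        self.snapshots = {}

    @staticmethod
    def _pair_mask(mesh, sheets, tri_gna):
        """Density-weighted lumped areas of each pair DOF on given sheets, so
        that mask @ i_na_unit is the surface-integrated Na+ current."""
        w = np.zeros(len(mesh.mem_pairs))
        p = mesh.nodes[mesh.mem_pairs[mesh.mem_tris, 0]]
        area = 0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)
        sel = np.isin(mesh.mem_sheet, sheets)
        np.add.at(w, mesh.mem_tris[sel].ravel(),
                  np.repeat(tri_gna[sel] * area[sel] / 3.0, 3))
        return w

    def record(self, state: SimulationState):
        d = self.data
        d["t"].append(state.t - self.t_offset)
        for c in (1, 2):
            rows, w = self.rows[c], self.weights[c]
            d[f"v{c}"].append(float(state.V_N[rows] @ w))
        i_na = sodium_current(state.V_m_eval, state.gates, 1.0, self.membrane)
        for c in (1, 2):
            for reg, key in (("ID", f"ina_id{c}"), ("bulk", f"ina_bulk{c}")):
                # uA -> nA; integral of the nodal density over the region
                d[key].append(float((i_na * self.masks[(c, reg)]).sum()) * 1e3)
        if self.cleft_free is not None:
            d["minve"].append(float(state.V_N[self.cleft_free].min()))
        else:
            d["minve"].append(0.0)
        if self.snapshot_times and abs(state.t - self.snapshot_times[0]) < 1e-9:
            self.snapshot_times.pop(0)
            self.snapshots[round(state.t, 9)] = self._full_potentials(state)
        elif self.snapshot_times and state.t > self.snapshot_times[0]:
            self.snapshot_times.pop(0)
            self.snapshots[round(state.t, 9)] = self._full_potentials(state)

    def _full_potentials(self, state):
        V = np.zeros(self.system.mesh.n_nodes)
        V[self.system.free] = state.V_N
        V[self.system.dirichlet] = self.system.dirichlet_values(state.t)
        return V

    def result(self, meta) -> SimulationResult:
        d = self.data
        return SimulationResult(
            time=np.asarray(d["t"]),
            patch_vi={1: np.asarray(d["v1"]), 2: np.asarray(d["v2"])},
            ina_id={1: np.asarray(d["ina_id1"]), 2: np.asarray(d["ina_id2"])},
            ina_bulk={1: np.asarray(d["ina_bulk1"]), 2: np.asarray(d["ina_bulk2"])},
            min_cleft_ve=np.asarray(d["minve"]),
            snapshots=self.snapshots, meta=meta)


def run_simulation(system: FEMSystem, params: SolverParams,
                   membrane: MembraneParams | None = None,
                   density: msh.ChannelDensityField | None = None,
                   snapshot_times=None, progress: bool = False) -> SimulationResult:
    """Integrate a configured system and record the standard readouts.

    Records patch V_i of both cells, region-integrated I_Na (ID and bulk
    membranes per cell), the minimum cleft V_e, and optional full-field
    snapshots.  If ``params.stop_margin`` is set, the run ends that many
    ms after both patch potentials crossed 0 mV (transmission resolved);
    otherwise it runs the full duration.
    """
    membrane = membrane or MembraneParams()
    if density is None:
        mesh = system.mesh
        density = msh.build_channel_density_field(mesh.geom, mesh.layout, mesh)
    factor = factorize_lhs(system, params, membrane, density)
    state = initialize_state(system, params, membrane)
    rec = _Recorder(system, density, membrane, snapshot_times,
                    t_offset=params.alpha * params.dt)
    n_steps = int(round(params.duration / params.dt))
    work: dict = {}
    crossed = {1: None, 2: None}
    t_stop = None
    wall0 = _time.perf_counter()
    for k in range(n_steps):
        step(state, system, factor, params, membrane, density, work)
        if (k + 1) % params.output_stride == 0:
            rec.record(state)
            for c in (1, 2):
                if crossed[c] is None and rec.data[f"v{c}"][-1] >= 0.0:
                    crossed[c] = state.t
            if (params.stop_margin is not None and crossed[1] is not None
                    and crossed[2] is not None):
                if t_stop is None:
                    t_stop = max(crossed.values()) + params.stop_margin
                if state.t >= t_stop and not rec.snapshot_times:
                    break
            if params.stop_on_quiescence and state.t >= 3.0 and not rec.snapshot_times:
                d = rec.data
                quiet = all(abs(d[k][-1]) < 0.05 for k in
                            ("ina_id1", "ina_id2", "ina_bulk1", "ina_bulk2"))
                stim_over = all(t0 + du + 2.5 <= state.t for t0, du in
                                ((s_.onset, s_.duration) for s_ in system.stimuli))
                if quiet and stim_over and d["minve"][-1] > -2.0:
                    break
    meta = {"dt": params.dt, "duration": params.duration,
            "steps_run": k + 1, "wall_time_s": _time.perf_counter() - wall0,
            "n_free": len(system.free), "upstroke_crossings": dict(crossed)}
    if progress:  # pragma: no cover
        print(f"run: {meta['steps_run']} steps, {meta['wall_time_s']:.1f} s")
    return rec.result(meta)
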