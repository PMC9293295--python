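"""Membrane ionic currents and gating dynamics.

The membrane model is deliberately minimal, focusing on the action
potential upstroke: a Hodgkin-Huxley-type fast Na+ current
``I_Na = gNa_mult * gbar_Na * m^3 h j * (Vm - E_Na)`` and a linear,
time-independent K+ current ``I_K = gbar_K * (Vm - E_K)`` that anchors
the resting potential at E_K.  Gates are integrated with the
Rush-Larsen exponential scheme, which is exact for rates frozen within
a time step.  Currents are densities (uA/cm^2), outward positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import lr91_rates

__all__ = [
    "MembraneParams",
    "GatingState",
    "nernst_potential",
    "gate_rates",
    "steady_state_gates",
    "rush_larsen_update",
    "ionic_current",
]

# physical constants for the Nernst relation
_R_GAS = 8.314462618      # J / (mol K)
_FARADAY = 96485.33212    # C / mol


@dataclass(frozen=True)
class MembraneParams:
    """Maximal conductances (mS/cm^2), Nernst potentials (mV), capacitance (uF/cm^2)."""

    gbar_Na: float = 23.0
    gbar_K: float = 0.3
    E_Na: float = 55.0
    E_K: float = -85.0
    C_m: float = 1.0

    def __post_init__(self) -> None:
        if self.gbar_Na < 0 or self.gbar_K < 0:
            raise ValueError("conductances must be >= 0")
        if not self.E_K < self.E_Na:
            raise ValueError("E_K must be below E_Na")


@dataclass
class GatingState:
    """Per-membrane-node activation (m) and inactivation (h, j) probabilities."""

    m: np.ndarray
    h: np.ndarray
    j: np.ndarray

    def copy(self) -> "GatingState":
        return GatingState(self.m.copy(), self.h.copy(), self.j.copy())


def nernst_potential(z: int, c_ext: float, c_int: float, T: float = 310.0) -> float:
    """Equilibrium potential RT/(zF) ln(c_ext/c_int) in mV.

    Provided for reference; the simulator itself uses the fixed values
    E_Na = +55 mV and E_K = -85 mV of :class:`MembraneParams`.
    """
    if z == 0:
        raise ValueError("valence must be nonzero")
    if c_ext <= 0 or c_int <= 0:
        raise ValueError("concentrations must be > 0")
    return _R_GAS * T / (z * _FARADAY) * np.log(c_ext / c_int) * 1e3


def gate_rates(v_m):
    """Alpha/beta rates (1/ms) of the m, h and j gates at membrane potential ``v_m``."""
    return lr91_rates.all_rates(v_m)


def steady_state_gates(v_m) -> GatingState:
    """Gate values alpha/(alpha+beta) at fixed ``v_m`` (used for initialization)."""
    am, bm, ah, bh, aj, bj = gate_rates(v_m)
    shape = np.broadcast(np.asarray(v_m, dtype=float)).shape
    def inf(a, b):
        return np.broadcast_to(np.asarray(a / (a + b), dtype=float), shape).copy()
    return GatingState(inf(am, bm), inf(ah, bh), inf(aj, bj))


def rush_larsen_update(state: GatingState, v_m, dt: float) -> GatingState:
    """Advance gates by ``dt`` ms with the Rush-Larsen exponential integrator.

    For each gate y: y <- y_inf + (y - y_inf) * exp(-dt/tau) with y_inf
    and tau evaluated from the rates at the current ``v_m``.  Exact for
    frozen rates; unconditionally keeps gates inside [0, 1].
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    am, bm, ah, bh, aj, bj = gate_rates(v_m)

    def step(y, a, b):
        s = a + b
        y_inf = a / s
        return y_inf + (y - y_inf) * np.exp(-dt * s)

    return GatingState(step(state.m, am, bm), step(state.h, ah, bh), step(state.j, aj, bj))


def ionic_current(v_m, state: GatingState, gNa_multiplier, params: MembraneParams,
                  gK_multiplier=1.0):
    """Total ionic current density I_Na + I_K in uA/cm^2, outward positive.

    ``gNa_multiplier`` is the local channel-density scaling (unitless
    factor on gbar_Na), zero on ID membrane outside the Na+ cluster.
    """
    g_na = gNa_multiplier * params.gbar_Na * state.m ** 3 * state.h * state.j
    i_na = g_na * (v_m - params.E_Na)
    i_k = gK_multiplier * params.gbar_K * (v_m - params.E_K)
    return i_na + i_k


def sodium_current(v_m, state: GatingState, gNa_multiplier, params: MembraneParams):
    """I_Na density alone (uA/cm^2), for region-resolved recordings."""
    g_na = gNa_multiplier * params.gbar_Na * state.m ** 3 * state.h * state.j
    return g_na * (v_m - params.E_Na)
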