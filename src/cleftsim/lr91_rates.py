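"""Rate constants of the fast Na+ current gates (m, h, j).

Alpha/beta expressions of the fast sodium current of the Luo & Rudy 1991
guinea-pig ventricular model (Circ Res 68:1501-1526), which itself takes
the j gate from Beeler & Reuter.  The h and j gates switch between two
published branches at Vm = -40 mV.  Later revisions of the Luo-Rudy
dynamic model (Livshitz & Rudy) kept these expressions for the fast
I_Na; no formulation change affects the quantities computed here.

All rates are in 1/ms, Vm in mV.  Functions are vectorized over Vm.
The removable singularity of alpha_m at Vm = -47.13 mV is replaced by
its analytic limit (3.2/ms).
"""

from __future__ import annotations

import numpy as np

__all__ = ["alpha_m", "beta_m", "alpha_h", "beta_h", "alpha_j", "beta_j", "all_rates"]

_V_SWITCH = -40.0  # mV, published branch point of the h and j gates


def alpha_m(v):
    v = np.asarray(v, dtype=float)
    x = v + 47.13
    # limit x->0: 0.32 * x / (1 - exp(-0.1 x)) -> 3.2
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 0.32 * x / (1.0 - np.exp(-0.1 * x))
    return np.where(np.abs(x) < 1e-7, 3.2, out)


def beta_m(v):
    v = np.asarray(v, dtype=float)
    return 0.08 * np.exp(-v / 11.0)


def alpha_h(v):
    v = np.asarray(v, dtype=float)
    return np.where(v < _V_SWITCH, 0.135 * np.exp((80.0 + v) / -6.8), 0.0)


def beta_h(v):
    v = np.asarray(v, dtype=float)
    with np.errstate(over="ignore"):
        low = 3.56 * np.exp(0.079 * np.minimum(v, _V_SWITCH)) \
            + 3.1e5 * np.exp(0.35 * np.minimum(v, _V_SWITCH))
    high = 1.0 / (0.13 * (1.0 + np.exp((v + 10.66) / -11.1)))
    return np.where(v < _V_SWITCH, low, high)


def alpha_j(v):
    v = np.asarray(v, dtype=float)
    vc = np.minimum(v, _V_SWITCH)   # the branch is discarded above the switch
    with np.errstate(over="ignore", invalid="ignore"):
        low = ((-1.2714e5 * np.exp(0.2444 * vc) - 3.474e-5 * np.exp(-0.04391 * vc))
               * (vc + 37.78) / (1.0 + np.exp(0.311 * (vc + 79.23))))
    return np.where(v < _V_SWITCH, low, 0.0)


def beta_j(v):
    v = np.asarray(v, dtype=float)
    low = 0.1212 * np.exp(-0.01052 * v) / (1.0 + np.exp(-0.1378 * (v + 40.14)))
    high = 0.3 * np.exp(-2.535e-7 * v) / (1.0 + np.exp(-0.1 * (v + 32.0)))
    return np.where(v < _V_SWITCH, low, high)


def all_rates(v):
    """(alpha_m, beta_m, alpha_h, beta_h, alpha_j, beta_j) at Vm ``v``."""
    return (alpha_m(v), beta_m(v), alpha_h(v), beta_h(v), alpha_j(v), beta_j(v))
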