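"""Post-processing of simulation results and the sweep drivers.

Readouts follow the conventions of the experiments: the upstroke delay
is the interval between the two patch potentials crossing 0 mV (linear
interpolation between samples); the post-junctional response is
classified as action potential (0 mV crossing), subthreshold
depolarization (> 2 mV above rest without crossing) or no effect; Na+
current peaks are reported at the discrete output sample of extremal
region-integrated I_Na.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mesh import MeshBundle
from .scenarios import ScenarioConfig, run_scenario
from .solver import SimulationResult

__all__ = ["ResponseClass", "upstroke_delay", "classify_response", "region_ina",
           "min_cleft_ve", "id_diameter_profile", "run_sweep",
           "SUBTHRESHOLD_DEPOLARIZATION_MV"]

#: depolarization of the post-junctional patch (mV above rest) separating
#: "subthreshold" from "no effect"
SUBTHRESHOLD_DEPOLARIZATION_MV = 2.0


@dataclass(frozen=True)
class ResponseClass:
    """Post-junctional response category with its diagnostics."""

    label: str                  # "action_potential" | "subthreshold" | "no_effect"
    peak_vi: float              # mV, peak cell-2 patch potential
    peak_depolarization: float  # mV above rest


def _crossing_time(t: np.ndarray, v: np.ndarray, level: float = 0.0) -> float | None:
    """First upward crossing of ``level``, linearly interpolated."""
    above = v >= level
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(t[0])
    return float(np.interp(level, [v[i - 1], v[i]], [t[i - 1], t[i]]))


def upstroke_delay(result: SimulationResult) -> float | None:
    """Delay (ms) between the cell-1 and cell-2 upstrokes at V_i = 0 mV.

    Returns None when cell 2 never crosses 0 mV (no transmission) -
    distinguishable from a genuine zero delay.
    """
    t1 = _crossing_time(result.time, result.patch_vi[1])
    t2 = _crossing_time(result.time, result.patch_vi[2])
    if t1 is None or t2 is None:
        return None
    return t2 - t1


def classify_response(result: SimulationResult,
                      v_rest: float = -85.0) -> ResponseClass:
    """Categorize the post-junctional cell's response."""
    v2 = result.patch_vi[2]
    peak = float(v2.max())
    dep = peak - v_rest
    if _crossing_time(result.time, v2) is not None:
        label = "action_potential"
    elif dep > SUBTHRESHOLD_DEPOLARIZATION_MV:
        label = "subthreshold"
    else:
        label = "no_effect"
    return ResponseClass(label=label, peak_vi=peak, peak_depolarization=dep)


def region_ina(result: SimulationResult, cell: int, region: str) -> np.ndarray:
    """Surface-integrated I_Na trace (nA) of a cell's ID or bulk membrane."""
    if region == "ID":
        return result.ina_id[cell]
    if region == "bulk":
        return result.ina_bulk[cell]
    raise ValueError(f"unknown region {region!r} (expected 'ID' or 'bulk')")


def min_cleft_ve(result: SimulationResult) -> np.ndarray:
    """Minimum extracellular cleft potential over space, per output time (mV)."""
    return result.min_cleft_ve


def ina_peak(result: SimulationResult, cell: int, region: str = "ID"
             ) -> tuple[float, float]:
    """(peak value nA, peak time ms) of the most negative region-integrated
    I_Na, at the discrete output sample of the extremum."""
    trace = region_ina(result, cell, region)
    k = int(np.argmin(trace))
    return float(trace[k]), float(result.time[k])


def id_diameter_profile(result: SimulationResult, mesh: MeshBundle, t: float,
                        n_points: int = 201) -> pd.DataFrame:
    """Potential layers sampled along the ID diameter through the Na+
    cluster and plaque centres (the y axis), at snapshot time ``t``.

    Returns a table with columns position (um), V_i1, V_i2, V_e (mV),
    interpolated on a uniform 1D grid.
    """
    from scipy.interpolate import LinearNDInterpolator

    times = np.asarray(result.snapshot_times())
    if len(times) == 0:
        raise ValueError("result contains no snapshots")
    key = float(times[np.argmin(np.abs(times - t))])
    if abs(key - t) > 0.05:
        raise ValueError(f"no snapshot near t = {t} ms (have {list(times)})")
    V = result.snapshots[round(key, 9)]
    R = mesh.geom.R_ID
    s = np.linspace(-R, R, n_points)
    pts = np.column_stack([np.zeros_like(s), s])
    out = {"position_um": s}
    for name, ids in (("V_i1", mesh.id_nodes_vi1), ("V_i2", mesh.id_nodes_vi2),
                      ("V_e", mesh.cleft_nodes)):
        interp = LinearNDInterpolator(mesh.disc.nodes, V[ids])
        out[name] = interp(pts)
    df = pd.DataFrame(out)
    df.attrs["time_ms"] = key
    return df


def run_sweep(base: ScenarioConfig, overrides: list[dict],
              mesh: MeshBundle | None = None, progress: bool = False,
              return_results: bool = False):
    """Run a deterministic series of scenarios derived from ``base``.

    Each entry of ``overrides`` patches layout fields (configuration,
    w_cleft, w_peri, has_perinexus) and/or the coupling level
    (G_gap_fraction / G_gap_absolute).  All scenarios share one mesh.
    Individual run failures are recorded in the table and the sweep
    continues.
    """
    from .mesh import build_cell_pair_mesh

    if mesh is None:
        mesh = build_cell_pair_mesh(base.geometry, base.layout,
                                    base.mesh_resolution())
    rows = []
    cache = {}
    for k, ov in enumerate(overrides):
        layout_fields = {k: v for k, v in ov.items()
                         if k in ("configuration", "w_cleft", "w_peri", "w_plaque",
                                  "has_perinexus", "exclude_cluster_from_gap")}
        cfg_fields = {k: v for k, v in ov.items()
                      if k in ("G_gap_fraction", "G_gap_absolute")}
        layout = dataclasses.replace(base.layout, **layout_fields)
        cfg = dataclasses.replace(base, layout=layout, **cfg_fields)
        row = {"configuration": layout.configuration, "w_cleft_nm": layout.w_cleft,
               "w_peri_nm": layout.w_peri if layout.has_perinexus else layout.w_cleft,
               "G_gap_nS": cfg.G_gap * 1e6}
        try:
            res = run_scenario(cfg, mesh=mesh)
            cache[k] = res
            cls = classify_response(res, cfg.solver.v_rest)
            d = upstroke_delay(res)
            p1, t1 = ina_peak(res, 1)
            p2, t2 = ina_peak(res, 2)
            row.update(response=cls.label, delay_ms=d,
                       peak_depolarization_mV=cls.peak_depolarization,
                       ina_id_peak_cell1_nA=p1, ina_id_peak_time_cell1_ms=t1,
                       ina_id_peak_cell2_nA=p2, ina_id_peak_time_cell2_ms=t2,
                       min_cleft_ve_mV=float(res.min_cleft_ve.min()),
                       error="")
        except Exception as exc:  # noqa: BLE001 - sweep robustness by contract
            row.update(response="error", delay_ms=np.nan,
                       peak_depolarization_mV=np.nan,
                       ina_id_peak_cell1_nA=np.nan, ina_id_peak_time_cell1_ms=np.nan,
                       ina_id_peak_cell2_nA=np.nan, ina_id_peak_time_cell2_ms=np.nan,
                       min_cleft_ve_mV=np.nan, error=str(exc))
        rows.append(row)
        if progress:  # pragma: no cover
            print(f"sweep: {row}", flush=True)
    table = pd.DataFrame(rows)
    if return_results:
        return table, cache
    return table
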