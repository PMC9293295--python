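"""Sparse finite-element operators of the collapsed-cleft formulation.

Charge conservation in the intra- and extracellular volumes gives the
P1 tetrahedral stiffness ``K_nc``; the collapsed cleft adds a 2D
surface stiffness ``K_c`` on the ID manifold weighted by the sheet
conductance w * f_sigma * sigma_cleft; gap junctions add ``K_gap``, a
mass-matrix bridge between the matched intracellular ID layers of the
two cells.  The total stiffness is K = K_nc + K_c + K_gap.  Membrane
coupling happens through the signed incidence operator ``U`` (one +1 on
the intracellular and one -1 on the extracellular node of every
membrane pair), the membrane mass matrix ``G`` and its
capacitance-weighted version ``Q = C_m G``.

Everything is assembled symmetric by construction; units follow the
internal cm/ms/mV/mS/uF/uA system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import mesh as msh
from .mesh import MeshBundle, MeshingError

__all__ = [
    "DomainConductivities",
    "StimulusProtocol",
    "FEMSystem",
    "assemble_volume_stiffness",
    "assemble_cleft_stiffness",
    "assemble_gap_matrix",
    "assemble_mass_matrices",
    "build_incidence",
    "partition_system",
]


@dataclass(frozen=True)
class DomainConductivities:
    """Isotropic conductivities in mS/cm (sigma_e = 6.666 <-> 150 Ohm cm)."""

    sigma_i: float = 3.333
    sigma_e: float = 6.666
    sigma_cleft: float = 6.666

    def __post_init__(self) -> None:
        if min(self.sigma_i, self.sigma_e, self.sigma_cleft) < 0:
            raise ValueError("conductivities must be >= 0")


@dataclass(frozen=True)
class StimulusProtocol:
    """Patch-electrode protocol: rectangular pulse on a cell's patch.

    ``amplitude`` is in nA for current clamp, mV for voltage clamp.
    """

    cell: int = 1
    mode: str = "current_clamp"
    amplitude: float = 11.5
    onset: float = 0.0
    duration: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("current_clamp", "voltage_clamp"):
            raise ValueError("mode must be current_clamp or voltage_clamp")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")
        if self.cell not in (1, 2):
            raise ValueError("cell must be 1 or 2")

    def active(self, t: float) -> bool:
        return self.onset <= t < self.onset + self.duration


def _tet_gradients(nodes: np.ndarray, tets: np.ndarray):
    """Barycentric gradients (T,4,3) and absolute volumes (T,) of P1 tets."""
    p = nodes[tets]
    e = p[:, 1:] - p[:, :1]                      # (T,3,3) edge matrix
    det = np.linalg.det(e)
    vol = np.abs(det) / 6.0
    if np.any(vol < 1e-30):
        bad = int(np.argmin(vol))
        raise MeshingError(f"degenerate (zero-volume) tetrahedron {bad}")
    inv = np.linalg.inv(e)                       # rows: gradients of lambda_1..3
    g = np.empty((len(tets), 4, 3))
    g[:, 1:] = np.transpose(inv, (0, 2, 1))
    g[:, 0] = -g[:, 1:].sum(axis=1)
    return g, vol


def _coo_from_local(conn: np.ndarray, ke: np.ndarray, n: int) -> sp.csr_matrix:
    """Scatter local element matrices ke (T,k,k) into a global CSR matrix."""
    k = conn.shape[1]
    rows = np.repeat(conn, k, axis=1).ravel()
    cols = np.tile(conn, (1, k)).ravel()
    A = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    A.sum_duplicates()
    return A


def assemble_volume_stiffness(mesh: MeshBundle, sigma_i: float, sigma_e: float
                              ) -> sp.csr_matrix:
    """K_nc: P1 stiffness of all tetrahedra, sigma chosen per domain."""
    g, vol = _tet_gradients(mesh.nodes, mesh.tets)
    sigma = np.where(mesh.tet_domain == msh.DOM_EXTRA, sigma_e, sigma_i)
    ke = np.einsum("tid,tjd->tij", g, g) * (sigma * vol)[:, None, None]
    return _coo_from_local(mesh.tets, ke, mesh.n_nodes)


def _tri2d_geometry(disc_nodes_cm: np.ndarray, tris: np.ndarray):
    p = disc_nodes_cm[tris]
    d1 = p[:, 1] - p[:, 0]
    d2 = p[:, 2] - p[:, 0]
    det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    area = 0.5 * np.abs(det)
    if np.any(area < 1e-30):
        raise MeshingError("degenerate ID triangle")
    # gradients of the three P1 basis functions
    g = np.empty((len(tris), 3, 2))
    g[:, 1, 0] = d2[:, 1] / det
    g[:, 1, 1] = -d2[:, 0] / det
    g[:, 2, 0] = -d1[:, 1] / det
    g[:, 2, 1] = d1[:, 0] / det
    g[:, 0] = -g[:, 1] - g[:, 2]
    return g, area


def assemble_cleft_stiffness(mesh: MeshBundle, sheet_conductance: np.ndarray
                             ) -> sp.csr_matrix:
    """K_c: 2D surface stiffness on the cleft V_e layer.

    ``sheet_conductance`` is the per-triangle product w * f_sigma *
    sigma_cleft (mS, i.e. mS/cm * cm), the sheet conductance governing
    tangential current flow in the collapsed cleft.
    """
    if not mesh.collapsed:
        return sp.csr_matrix((mesh.n_nodes, mesh.n_nodes))
    if len(sheet_conductance) != len(mesh.disc.tris):
        raise MeshingError("sheet conductance field does not match the ID triangulation")
    nodes_cm = mesh.disc.nodes * 1e-4
    g, area = _tri2d_geometry(nodes_cm, mesh.disc.tris)
    ke = np.einsum("tid,tjd->tij", g, g) * (sheet_conductance * area)[:, None, None]
    conn = mesh.cleft_nodes[mesh.disc.tris]
    return _coo_from_local(conn, ke, mesh.n_nodes)


_MASS_LOCAL = np.array([[2.0, 1.0, 1.0], [1.0, 2.0, 1.0], [1.0, 1.0, 2.0]]) / 12.0


def assemble_gap_matrix(mesh: MeshBundle, sigma_gap: np.ndarray) -> sp.csr_matrix:
    """K_gap: gap-junctional bridge between the matched intracellular ID layers.

    ``sigma_gap`` is the per-triangle conductance per unit area (mS/cm^2);
    the 2D mass matrix M_gap it defines is pasted as [[M, -M], [-M, M]]
    over the (V_i1, V_i2) node pairs, keeping K symmetric positive
    semidefinite.
    """
    if not mesh.collapsed:
        return sp.csr_matrix((mesh.n_nodes, mesh.n_nodes))
    if np.all(sigma_gap == 0.0):
        return sp.csr_matrix((mesh.n_nodes, mesh.n_nodes))
    nodes_cm = mesh.disc.nodes * 1e-4
    _, area = _tri2d_geometry(nodes_cm, mesh.disc.tris)
    me = _MASS_LOCAL[None, :, :] * (sigma_gap * area)[:, None, None]
    c1 = mesh.id_tris_vi1
    c2 = mesh.id_tris_vi2
    n = mesh.n_nodes
    A = (_coo_from_local(c1, me, n) + _coo_from_local(c2, me, n)
         - _coo_from_local_rect(c1, c2, me, n) - _coo_from_local_rect(c2, c1, me, n))
    return A.tocsr()


def _coo_from_local_rect(rows_conn, cols_conn, ke, n):
    k = rows_conn.shape[1]
    rows = np.repeat(rows_conn, k, axis=1).ravel()
    cols = np.tile(cols_conn, (1, k)).ravel()
    return sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()


def assemble_mass_matrices(mesh: MeshBundle, C_m: float = 1.0
                           ) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """(G, Q): consistent membrane mass matrix over all membrane sheets
    and its capacitance weighting Q = C_m G (uniform C_m)."""
    G = assemble_weighted_membrane_mass(mesh)
    return G, C_m * G


def assemble_weighted_membrane_mass(mesh: MeshBundle, weights: np.ndarray | None = None,
                                    tri_mask: np.ndarray | None = None) -> sp.csr_matrix:
    """Membrane mass matrix with an optional piecewise-constant weight per
    triangle (used for the Na+ channel-density field, which is constant
    per triangle, zero on the ID outside the cluster)."""
    p = mesh.nodes[mesh.mem_pairs[mesh.mem_tris, 0]]
    nvec = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    area = 0.5 * np.linalg.norm(nvec, axis=1)
    if np.any(area < 1e-30):
        raise MeshingError("degenerate membrane triangle")
    w = area if weights is None else area * weights
    if tri_mask is not None:
        w = np.where(tri_mask, w, 0.0)
    me = _MASS_LOCAL[None, :, :] * w[:, None, None]
    return _coo_from_local(mesh.mem_tris, me, len(mesh.mem_pairs))


def build_incidence(mesh: MeshBundle) -> sp.csr_matrix:
    """U (n_nodes x n_membrane): +1 on the intracellular, -1 on the
    extracellular node of every membrane pair, so V_m = U^T V."""
    P = len(mesh.mem_pairs)
    rows = np.concatenate([mesh.mem_pairs[:, 0], mesh.mem_pairs[:, 1]])
    cols = np.concatenate([np.arange(P), np.arange(P)])
    vals = np.concatenate([np.ones(P), -np.ones(P)])
    return sp.coo_matrix((vals, (rows, cols)), shape=(mesh.n_nodes, P)).tocsr()


@dataclass
class FEMSystem:
    """Assembled, boundary-partitioned operators of one scenario."""

    mesh: MeshBundle
    K: sp.csr_matrix               # K_nc + K_c + K_gap (full, symmetric)
    G: sp.csr_matrix
    Q: sp.csr_matrix
    U: sp.csr_matrix
    dirichlet: np.ndarray          # global node ids with prescribed potential
    free: np.ndarray               # non-Dirichlet node ids
    K_N: sp.csr_matrix
    K_x: sp.csr_matrix             # K[dirichlet, free]
    U_N: sp.csr_matrix
    U_D: sp.csr_matrix
    stimuli: tuple[StimulusProtocol, ...] = ()
    patch_source: dict = field(default_factory=dict)   # cell -> (free-index rows, weights)
    node_to_free: np.ndarray | None = None

    def dirichlet_values(self, t: float) -> np.ndarray:
        """Prescribed potentials at the Dirichlet nodes at time t (mV)."""
        vd = np.zeros(len(self.dirichlet))
        for stim in self.stimuli:
            if stim.mode == "voltage_clamp" and stim.active(t):
                rows = self.patch_source.get(("D", stim.cell))
                if rows is not None:
                    vd[rows] = stim.amplitude
        return vd

    def neumann_source(self, t: float) -> np.ndarray:
        """f_N: nodal current sources (uA) at the free nodes at time t."""
        f = np.zeros(len(self.free))
        for stim in self.stimuli:
            if stim.mode == "current_clamp" and stim.active(t):
                entry = self.patch_source.get(("N", stim.cell))
                if entry is not None:
                    rows, w = entry
                    f[rows] += stim.amplitude * 1e-3 * w   # nA -> uA
        return f


def partition_system(mesh: MeshBundle, K: sp.csr_matrix, G: sp.csr_matrix,
                     Q: sp.csr_matrix, U: sp.csr_matrix,
                     stimuli: tuple[StimulusProtocol, ...] = ()) -> FEMSystem:
    """Split the assembled operators into Dirichlet (grounded box faces,
    voltage-clamped patches) and free blocks, and wire the stimulus
    machinery (current clamps become lumped-weight nodal sources spread
    over the patch nodes)."""
    dir_nodes = [np.asarray(mesh.ground_nodes)]
    for stim in stimuli:
        if stim.mode == "voltage_clamp":
            if stim.cell not in mesh.patch_nodes:
                raise MeshingError(f"no electrode patch for cell {stim.cell}")
            dir_nodes.append(mesh.patch_nodes[stim.cell])
    dirichlet = np.unique(np.concatenate(dir_nodes))
    mask = np.ones(mesh.n_nodes, dtype=bool)
    mask[dirichlet] = False
    free = np.nonzero(mask)[0]
    node_to_free = -np.ones(mesh.n_nodes, dtype=np.int64)
    node_to_free[free] = np.arange(len(free))
    node_to_dir = -np.ones(mesh.n_nodes, dtype=np.int64)
    node_to_dir[dirichlet] = np.arange(len(dirichlet))

    K_N = K[free][:, free].tocsr()
    K_x = K[dirichlet][:, free].tocsr()
    U_N = U[free].tocsr()
    U_D = U[dirichlet].tocsr()

    patch_source: dict = {}
    for stim in stimuli:
        nodes = mesh.patch_nodes.get(stim.cell)
        if nodes is None:
            raise MeshingError(f"no electrode patch for cell {stim.cell}")
        if stim.mode == "voltage_clamp":
            patch_source[("D", stim.cell)] = node_to_dir[nodes]
        else:
            rows = node_to_free[nodes]
            if np.any(rows < 0):
                raise MeshingError("current-clamp patch overlaps Dirichlet nodes")
            patch_source[("N", stim.cell)] = (rows, mesh.patch_weights[stim.cell])

    return FEMSystem(mesh=mesh, K=K, G=G, Q=Q, U=U, dirichlet=dirichlet, free=free,
                     K_N=K_N, K_x=K_x, U_N=U_N, U_D=U_D, stimuli=tuple(stimuli),
                     patch_source=patch_source, node_to_free=node_to_free)


def export_operators(system: "FEMSystem", directory) -> list:
    """Write the assembled sparse operators (K, G, Q, U, K_N) in Matrix
    Market exchange format for external inspection/debugging."""
    from pathlib import Path
    import scipy.io as sio
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name in ("K", "G", "Q", "U", "K_N"):
        path = directory / f"{name}.mtx"
        sio.mmwrite(path, getattr(system, name).tocoo())
        written.append(path)
    return written


def assemble_system(mesh: MeshBundle, layout, cond: DomainConductivities,
                    G_gap: float, C_m: float = 1.0,
                    stimuli: tuple[StimulusProtocol, ...] = ()) -> FEMSystem:
    """One-call assembly of the full collapsed-cleft (or explicit-cleft)
    operator set for a scenario."""
    K = assemble_volume_stiffness(mesh, cond.sigma_i, cond.sigma_e)
    if mesh.collapsed and layout is not None:
        w, f_sigma = msh.build_cleft_property_fields(layout, mesh)
        K = K + assemble_cleft_stiffness(mesh, w * f_sigma * cond.sigma_cleft)
        sigma_gap = msh.gap_conductivity_field(layout, mesh, G_gap)
        K = K + assemble_gap_matrix(mesh, sigma_gap)
    G, Q = assemble_mass_matrices(mesh, C_m)
    U = build_incidence(mesh)
    K = K.tocsr()
    K = (K + K.T) * 0.5    # remove summation-order roundoff: exact symmetry
    return partition_system(mesh, K.tocsr(), G, Q, U, stimuli)
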