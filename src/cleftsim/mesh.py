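"""Deterministic mesh generation for the collapsed-cleft cell pair.

The mesh is built programmatically from two 2D sections:

* a ring-graded triangulation ``D`` of the intercalated-disc (ID) disc,
  refined around the Na+ cluster / plaque / perinexus zone and coarsening
  towards the rim, with the rim nodes at prescribed equal angles;
* an annulus section ``A`` filling the space between that circle and the
  square cross-section of the extracellular box.

Both cells are prism-extrusions of ``D`` along the x axis (graded axial
layers, finest at the ID); the extracellular bulk is the extrusion of
``A`` alongside the cells and of ``D + A`` beyond the cell ends.  Prisms
are split into tetrahedra with a face-local minimum-key rule so that all
sub-meshes conform; because the rule keys on (station, in-section index)
and circle nodes are angle-ordered in every section, the lateral
membrane triangulations of the intra- and extracellular sides match
exactly.

In the collapsed-cleft mesh the ID is a 2D manifold at x = 0 carrying
three co-located potential layers (V_i1, V_i2, cleft V_e); cleft V_e rim
nodes are shared with the extracellular volume along the junction curve
J.  The same machinery also builds an explicit-cleft mesh (cells pushed
apart by the cleft width, cleft meshed as a thin tetrahedral layer),
which serves as the independent validation model.

Everything is pure deterministic arithmetic: identical parameters give
byte-identical meshes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .geometry import GeometryParams, IDLayout, compute_scaling_factors
from .units import UM_TO_CM

__all__ = [
    "MeshResolution",
    "MeshBundle",
    "ChannelDensityField",
    "MeshingError",
    "build_cell_pair_mesh",
    "build_explicit_pair_mesh",
    "build_cleft_property_fields",
    "build_channel_density_field",
    "audit_mesh",
    "RESOLUTION_PRESETS",
]

# membrane sheet codes
MEM_LAT1, MEM_LAT2, MEM_OUT1, MEM_OUT2, MEM_ID1, MEM_ID2 = range(6)
# domain codes for tetrahedra
DOM_EXTRA, DOM_CELL1, DOM_CELL2 = 0, 1, 2
# ID region tags
REG_BULK, REG_CLUSTER, REG_PLAQUE, REG_PERINEXUS = 0, 1, 2, 3


class MeshingError(RuntimeError):
    """Raised when mesh generation or a conformity audit fails."""


@dataclass(frozen=True)
class MeshResolution:
    """Target edge lengths (um) controlling the graded mesh density."""

    h_cluster: float = 0.17      # radial spacing inside the Na+ cluster
    h_feature: float = 0.58      # spacing in the plaque/perinexus zone
    r_feature: float = 4.0       # radius of the refined feature zone
    ring_growth: float = 1.4     # radial growth factor beyond the feature zone
    h_coarse: float = 3.4        # spacing at the disc rim
    n_rim: int = 24              # rim node count (multiple of 8)
    h_axial0: float = 0.5        # first axial layer at the ID
    axial_growth: float = 3.5
    h_axial_max: float = 60.0
    cap_h0: float = 4.0          # first extracellular layer beyond the cell ends
    cap_growth: float = 4.0
    ann_layers: int = 2          # extracellular layers between cell surface and box wall

    def refined(self, levels: int = 1, factor: float = 1.3) -> "MeshResolution":
        """Return a uniformly refined copy (every target length / factor**levels)."""
        s = factor ** levels
        n_rim = 8 * max(1, int(round(self.n_rim * s / 8.0)))
        return replace(
            self,
            h_cluster=self.h_cluster / s, h_feature=self.h_feature / s,
            h_coarse=self.h_coarse / s, n_rim=n_rim,
            h_axial0=self.h_axial0 / s, h_axial_max=self.h_axial_max / s,
            cap_h0=self.cap_h0 / s,
        )


RESOLUTION_PRESETS = {
    "coarse": MeshResolution(),
    "medium": MeshResolution().refined(1),
    "fine": MeshResolution().refined(2),
}


# ---------------------------------------------------------------------------
# 2D sections
# ---------------------------------------------------------------------------

@dataclass
class Section2D:
    """A triangulated planar cross-section (coordinates in um)."""

    nodes: np.ndarray          # (n, 2)
    tris: np.ndarray           # (m, 3), counter-clockwise
    circle_idx: np.ndarray     # angle-ordered indices of the r = R_ID circle nodes


def _ring_radii(R: float, res: MeshResolution) -> list[float]:
    """Monotone ring radii from just outside the centre to exactly R."""
    r_na = min(0.6875, R / 2)  # the cluster radius of the default geometry
    radii: list[float] = []
    # fine rings up to the cluster boundary
    n1 = max(2, int(round(r_na / res.h_cluster)))
    radii += [r_na * k / n1 for k in range(1, n1 + 1)]
    if res.r_feature > r_na and res.r_feature < R:
        n2 = max(1, int(round((res.r_feature - r_na) / res.h_feature)))
        radii += [r_na + (res.r_feature - r_na) * k / n2 for k in range(1, n2 + 1)]
    # geometric growth out to the rim
    h = (radii[-1] - radii[-2]) if len(radii) > 1 else res.h_feature
    r = radii[-1]
    while True:
        h = min(h * res.ring_growth, res.h_coarse)
        r = r + h
        if r >= R - 0.55 * h:
            break
        radii.append(r)
    radii.append(R)
    return radii


def _zip_rings(inner: np.ndarray, outer: np.ndarray) -> list[tuple[int, int, int]]:
    """Triangulate the strip between two angle-ordered closed rings of node ids."""
    n1, n2 = len(inner), len(outer)
    tris = []
    i = j = 0
    # advance the pointer whose next node has the smaller angle
    while i < n1 or j < n2:
        take_inner = False
        if j >= n2:
            take_inner = True
        elif i < n1:
            a_next = 2 * math.pi * (i + 1) / n1
            b_next = 2 * math.pi * (j + 1) / n2
            take_inner = a_next <= b_next
        if take_inner:
            tris.append((inner[i % n1], inner[(i + 1) % n1], outer[j % n2]))
            i += 1
        else:
            tris.append((inner[i % n1], outer[j % n2], outer[(j + 1) % n2]))
            j += 1
    return tris


def graded_disc_section(R: float, res: MeshResolution) -> Section2D:
    """Ring-graded triangulation of the disc of radius ``R`` (um).

    Node counts per ring track the local radial spacing so triangle
    aspect ratios stay moderate; the rim carries exactly ``res.n_rim``
    equally spaced nodes starting at angle 0, ordered by angle.
    """
    if res.n_rim % 8:
        raise MeshingError("n_rim must be a multiple of 8 (box corners must be hit)")
    radii = _ring_radii(R, res)
    nodes = [(0.0, 0.0)]
    rings: list[np.ndarray] = [np.array([0])]
    prev_r = 0.0
    for k, r in enumerate(radii):
        dr = r - prev_r
        if k == len(radii) - 1:
            n = res.n_rim
        else:
            n = int(np.clip(math.ceil(2 * math.pi * r / max(dr, 1e-9)), 8, 512))
        idx = np.arange(len(nodes), len(nodes) + n)
        ang = 2 * math.pi * np.arange(n) / n
        nodes.extend(zip(r * np.cos(ang), r * np.sin(ang)))
        rings.append(idx)
        prev_r = r
    tris = []
    for a, b in zip(rings[:-1], rings[1:]):
        if len(a) == 1:
            c = a[0]
            tris += [(c, b[i], b[(i + 1) % len(b)]) for i in range(len(b))]
        else:
            tris += _zip_rings(a, b)
    nodes_arr = np.asarray(nodes, dtype=float)
    tris_arr = _orient_ccw(nodes_arr, np.asarray(tris, dtype=np.int64))
    return Section2D(nodes_arr, tris_arr, rings[-1].astype(np.int64))


def annulus_section(R: float, half: float, res: MeshResolution,
                    n_layers: int | None = None) -> Section2D:
    """Triangulated region between the circle r = R and the square |y|,|z| <= half.

    All rings carry ``res.n_rim`` nodes at the circle's angles; ring
    shapes blend from the circle to the square so the outermost ring is
    exactly the box boundary (corners included since n_rim % 8 == 0).
    Circle nodes come first and are shared positions with the disc rim.
    """
    n = res.n_rim
    if n_layers is None:
        n_layers = res.ann_layers
    ang = 2 * math.pi * np.arange(n) / n
    cs, sn = np.cos(ang), np.sin(ang)
    r_sq = half / np.maximum(np.abs(cs), np.abs(sn))
    # graded blending: finer near the circle
    s = (np.arange(1, n_layers + 1) / n_layers) ** 1.5
    nodes = [np.column_stack([R * cs, R * sn])]
    for sj in s:
        r_j = R + sj * (r_sq - R)
        nodes.append(np.column_stack([r_j * cs, r_j * sn]))
    nodes_arr = np.vstack(nodes)
    tris = []
    for j in range(n_layers):
        a = np.arange(j * n, (j + 1) * n)
        b = np.arange((j + 1) * n, (j + 2) * n)
        for k in range(n):
            k1 = (k + 1) % n
            # fixed diagonal; conformity here is internal to this section
            tris.append((a[k], a[k1], b[k]))
            tris.append((a[k1], b[k1], b[k]))
    tris_arr = _orient_ccw(nodes_arr, np.asarray(tris, dtype=np.int64))
    return Section2D(nodes_arr, tris_arr, np.arange(n, dtype=np.int64))


def _orient_ccw(nodes: np.ndarray, tris: np.ndarray) -> np.ndarray:
    p = nodes[tris]
    cross = ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
             - (p[:, 1, 1] - p[:, 0, 1]) * (p[:, 2, 0] - p[:, 0, 0]))
    flip = cross < 0
    tris = tris.copy()
    tris[flip] = tris[flip][:, [0, 2, 1]]
    if np.any(np.abs(cross) < 1e-14):
        raise MeshingError("degenerate (zero-area) triangle in 2D section")
    return tris


def _graded_line(length: float, h0: float, growth: float, h_max: float) -> np.ndarray:
    """Positions 0 .. length with first spacing h0 growing geometrically."""
    pos = [0.0]
    h = h0
    while pos[-1] + 1.45 * h < length:
        pos.append(pos[-1] + h)
        h = min(h * growth, h_max)
    pos.append(length)
    return np.asarray(pos)


# ---------------------------------------------------------------------------
# prism -> tet splitting
# ---------------------------------------------------------------------------

def _split_prisms(tris: np.ndarray, bot: np.ndarray, top: np.ndarray,
                  local: np.ndarray) -> np.ndarray:
    """Split the prisms (section triangles extruded bottom->top) into tets.

    ``bot``/``top`` map section-local node index -> global node id;
    ``local`` is the face-local sort key (the in-section index), shared by
    all extrusions of the same sections so that faces match across
    sub-meshes.  Rule: each quad face takes the diagonal through its
    smallest-key corner (bottom corners outrank top corners).
    """
    keys = local[tris]                    # (m, 3) bottom keys
    m = keys.argmin(axis=1)
    # cyclic rotation bringing the minimum-key vertex to position 0
    idx = (np.arange(3)[None, :] + m[:, None]) % 3
    t_rot = np.take_along_axis(tris, idx, axis=1)
    v0, v1, v2 = t_rot[:, 0], t_rot[:, 1], t_rot[:, 2]
    use_a = local[v1] < local[v2]         # diagonal v1-v5 on the far quad
    b0, b1, b2 = bot[v0], bot[v1], bot[v2]
    u0, u1, u2 = top[v0], top[v1], top[v2]
    tets_a = np.stack([
        np.stack([b0, b1, b2, u2], axis=1),
        np.stack([b0, b1, u2, u1], axis=1),
        np.stack([b0, u1, u2, u0], axis=1),
    ], axis=1)
    tets_b = np.stack([
        np.stack([b0, b1, b2, u1], axis=1),
        np.stack([b0, b2, u2, u1], axis=1),
        np.stack([b0, u1, u2, u0], axis=1),
    ], axis=1)
    tets = np.where(use_a[:, None, None], tets_a, tets_b)
    return tets.reshape(-1, 4)


# ---------------------------------------------------------------------------
# mesh bundle
# ---------------------------------------------------------------------------

@dataclass
class MeshBundle:
    """Tagged unstructured mesh of the cell pair (coordinates in cm)."""

    nodes: np.ndarray            # (N, 3) cm
    tets: np.ndarray             # (T, 4)
    tet_domain: np.ndarray       # (T,) 0 extracellular, 1 cell 1, 2 cell 2
    disc: Section2D              # 2D ID triangulation (um coordinates)
    id_region: np.ndarray        # per-disc-triangle tag REG_*
    id_in_perinexus: np.ndarray  # per-disc-triangle bool (inside perinexal disc)
    id_tris_vi1: np.ndarray      # (m, 3) global ids, cell-1 intracellular ID layer
    id_tris_vi2: np.ndarray
    id_tris_ve: np.ndarray       # cleft V_e layer (empty for explicit meshes)
    id_nodes_vi1: np.ndarray     # per-disc-node global ids of the three layers
    id_nodes_vi2: np.ndarray
    cleft_nodes: np.ndarray      # cleft V_e node ids in disc-node order
    junction_nodes: np.ndarray   # J: cleft rim nodes shared with the volume mesh
    mem_pairs: np.ndarray        # (P, 2) (intracellular node, extracellular node)
    mem_tris: np.ndarray         # (M, 3) indices into mem_pairs
    mem_sheet: np.ndarray        # (M,) MEM_* code
    mem_tri_disc: np.ndarray     # (M,) disc-triangle index or -1 (lateral)
    ground_nodes: np.ndarray
    patch_nodes: dict            # cell id -> node ids
    patch_weights: dict          # cell id -> normalized weights
    collapsed: bool
    geom: GeometryParams
    resolution: MeshResolution
    layout: IDLayout | None = None
    mid_cleft_node: int = -1     # explicit meshes: extracellular node at the cleft centre

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


def _disc_lumped_areas(disc: Section2D) -> np.ndarray:
    """Nodal lumped areas (um^2) of the disc triangulation."""
    p = disc.nodes[disc.tris]
    area = 0.5 * np.abs((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                        - (p[:, 1, 1] - p[:, 0, 1]) * (p[:, 2, 0] - p[:, 0, 0]))
    lumped = np.zeros(len(disc.nodes))
    np.add.at(lumped, disc.tris.ravel(), np.repeat(area / 3.0, 3))
    return lumped


def disc_triangle_areas(disc: Section2D) -> np.ndarray:
    """Triangle areas of the ID triangulation in um^2."""
    p = disc.nodes[disc.tris]
    return 0.5 * np.abs((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                        - (p[:, 1, 1] - p[:, 0, 1]) * (p[:, 2, 0] - p[:, 0, 0]))


def _axial_stations(geom: GeometryParams, res: MeshResolution) -> np.ndarray:
    """Cell-internal stations 0 (ID) .. L, including the patch station."""
    x_patch = geom.L - geom.patch_offset
    xs = _graded_line(x_patch, res.h_axial0, res.axial_growth, res.h_axial_max)
    return np.concatenate([xs, [geom.L]])


class _NodeBook:
    """Incremental global node allocation."""

    def __init__(self) -> None:
        self.chunks: list[np.ndarray] = []
        self.count = 0

    def alloc(self, yz: np.ndarray, x: float) -> np.ndarray:
        n = len(yz)
        ids = np.arange(self.count, self.count + n, dtype=np.int64)
        block = np.empty((n, 3))
        block[:, 0] = x
        block[:, 1:] = yz
        self.chunks.append(block)
        self.count += n
        return ids

    def coords(self) -> np.ndarray:
        return np.vstack(self.chunks) if self.chunks else np.empty((0, 3))


def _build_pair(geom: GeometryParams, layout: IDLayout | None, res: MeshResolution,
                collapsed: bool, w_um: float = 0.0) -> MeshBundle:
    D = graded_disc_section(geom.R_ID, res)
    A = annulus_section(geom.R_ID, geom.Ly / 2.0, res)
    nD, nA, nrim = len(D.nodes), len(A.nodes), res.n_rim
    if not np.array_equal(D.circle_idx, np.arange(nD - nrim, nD)):
        raise MeshingError("disc rim nodes must be the trailing, angle-ordered block")
    xj = 0.0 if collapsed else 0.5 * w_um
    xs_cell = _axial_stations(geom, res)

    book = _NodeBook()
    # ---- intracellular stations (ascending x) -----------------------------
    cell_x = {1: -(xj + xs_cell)[::-1], 2: xj + xs_cell}
    cell_ids = {c: [book.alloc(D.nodes, x) for x in cell_x[c]] for c in (1, 2)}

    # ---- extracellular stations -------------------------------------------
    caps = _graded_line(geom.Lx / 2.0 - xj - geom.L, res.cap_h0, res.cap_growth,
                        geom.Lx)
    xs_ext = set(np.round(xj + xs_cell, 9)) | set(np.round(xj + geom.L + caps, 9))
    xs_ext |= {-x for x in xs_ext}
    if not collapsed:
        xs_ext |= {0.0, np.round(xj, 9), np.round(-xj, 9)}
    xs_ext = np.array(sorted(xs_ext))
    tol = 1e-6

    ext_disc, ext_ann = {}, {}
    for k, x in enumerate(xs_ext):
        has_disc = (abs(x) >= xj + geom.L - tol) or (not collapsed and abs(x) <= xj + tol)
        if has_disc:
            ext_disc[k] = book.alloc(D.nodes, x)
            ext_ann[k] = book.alloc(A.nodes[nrim:], x)   # circle shared with disc rim
        else:
            ext_disc[k] = None
            ext_ann[k] = book.alloc(A.nodes, x)

    def a_ids(k: int) -> np.ndarray:
        """Station node ids in A-section layout (circle first)."""
        if ext_disc[k] is None:
            return ext_ann[k]
        return np.concatenate([ext_disc[k][nD - nrim:], ext_ann[k]])

    def f_ids(k: int) -> np.ndarray:
        """Station node ids in combined D+A layout."""
        return np.concatenate([ext_disc[k], ext_ann[k]])

    # combined full-section triangulation (D as-is, A reindexed onto it)
    remap = np.concatenate([np.arange(nD - nrim, nD), np.arange(nD, nD + nA - nrim)])
    comb_tris = np.vstack([D.tris, remap[A.tris]])
    local_A = np.arange(nA)
    local_comb = np.arange(nD + nA - nrim)
    local_D = np.arange(nD)

    # ---- cleft V_e layer (collapsed) --------------------------------------
    k0 = int(np.argmin(np.abs(xs_ext)))
    cleft_ids = np.empty(nD, dtype=np.int64)
    if collapsed:
        cleft_ids[:nD - nrim] = book.alloc(D.nodes[:nD - nrim], 0.0)
        cleft_ids[nD - nrim:] = a_ids(k0)[:nrim]
        junction = cleft_ids[nD - nrim:].copy()
    else:
        cleft_ids[:] = -1
        junction = np.empty(0, dtype=np.int64)

    # ---- tetrahedra --------------------------------------------------------
    tet_blocks, dom_blocks = [], []
    for c in (1, 2):
        ids = cell_ids[c]
        for k in range(len(ids) - 1):
            t = _split_prisms(D.tris, ids[k], ids[k + 1], local_D)
            tet_blocks.append(t)
            dom_blocks.append(np.full(len(t), c, dtype=np.int8))
    for k in range(len(xs_ext) - 1):
        mid = 0.5 * (xs_ext[k] + xs_ext[k + 1])
        full = (abs(mid) > xj + geom.L - tol) or (not collapsed and abs(mid) < xj - tol * 0)
        if not collapsed and abs(mid) < xj:
            full = True
        if full:
            t = _split_prisms(comb_tris, f_ids(k), f_ids(k + 1), local_comb)
        else:
            t = _split_prisms(A.tris, a_ids(k), a_ids(k + 1), local_A)
        tet_blocks.append(t)
        dom_blocks.append(np.full(len(t), DOM_EXTRA, dtype=np.int8))
    tets = np.vstack(tet_blocks)
    tet_domain = np.concatenate(dom_blocks)

    # ---- membrane pairs and triangles --------------------------------------
    pair_index: dict[tuple[int, int], int] = {}
    pair_list: list[tuple[int, int]] = []

    def pid(i: int, e: int) -> int:
        key = (int(i), int(e))
        p = pair_index.get(key)
        if p is None:
            p = len(pair_list)
            pair_index[key] = p
            pair_list.append(key)
        return p

    mem_tris, mem_sheet, mem_disc = [], [], []

    def add_sheet_tris(p_of_node: np.ndarray, sheet: int) -> None:
        for t, tri in enumerate(D.tris):
            mem_tris.append([p_of_node[tri[0]], p_of_node[tri[1]], p_of_node[tri[2]]])
            mem_sheet.append(sheet)
            mem_disc.append(t)

    def station_lookup(x: float) -> int:
        k = int(np.argmin(np.abs(xs_ext - x)))
        if abs(xs_ext[k] - x) > tol:
            raise MeshingError(f"no extracellular station at x = {x}")
        return k

    # ID membranes
    for c, sheet in ((1, MEM_ID1), (2, MEM_ID2)):
        intra = cell_ids[c][-1] if c == 1 else cell_ids[c][0]
        if collapsed:
            extra_layer = cleft_ids
        else:
            extra_layer = ext_disc[station_lookup(-xj if c == 1 else xj)]
        p = np.array([pid(intra[d], extra_layer[d]) for d in range(nD)])
        add_sheet_tris(p, sheet)
    # outer disc membranes
    for c, sheet in ((1, MEM_OUT1), (2, MEM_OUT2)):
        intra = cell_ids[c][0] if c == 1 else cell_ids[c][-1]
        x_out = -(xj + geom.L) if c == 1 else xj + geom.L
        extra_layer = ext_disc[station_lookup(x_out)]
        p = np.array([pid(intra[d], extra_layer[d]) for d in range(nD)])
        add_sheet_tris(p, sheet)
    # lateral membranes
    for c, sheet in ((1, MEM_LAT1), (2, MEM_LAT2)):
        xs_c = cell_x[c]
        lat_p = []
        for k, x in enumerate(xs_c):
            circ_ext = a_ids(station_lookup(x))[:nrim]
            rim_intra = cell_ids[c][k][nD - nrim:]
            lat_p.append(np.array([pid(rim_intra[r], circ_ext[r]) for r in range(nrim)]))
        for k in range(len(xs_c) - 1):
            for r in range(nrim):
                r1 = (r + 1) % nrim
                a, b = lat_p[k][r], lat_p[k][r1]
                cc, d = lat_p[k + 1][r1], lat_p[k + 1][r]
                if r < r1:
                    mem_tris += [[a, b, cc], [a, cc, d]]
                else:
                    mem_tris += [[a, b, d], [b, cc, d]]
                mem_sheet += [sheet, sheet]
                mem_disc += [-1, -1]

    mem_pairs = np.asarray(pair_list, dtype=np.int64)
    mem_tris = np.asarray(mem_tris, dtype=np.int64)
    mem_sheet = np.asarray(mem_sheet, dtype=np.int8)
    mem_disc = np.asarray(mem_disc, dtype=np.int64)

    # ---- instrumentation ---------------------------------------------------
    ground = np.concatenate([f_ids(0), f_ids(len(xs_ext) - 1)])
    lump = _disc_lumped_areas(D)
    r = np.hypot(D.nodes[:, 0], D.nodes[:, 1])
    sel = np.where(r <= geom.patch_radius + tol)[0]
    if len(sel) == 0:
        raise MeshingError("no mesh nodes inside the electrode patch")
    w = lump[sel] / lump[sel].sum()
    k_patch = int(np.argmin(np.abs(xs_cell - (geom.L - geom.patch_offset))))
    patch_nodes = {1: cell_ids[1][len(xs_cell) - 1 - k_patch][sel],
                   2: cell_ids[2][k_patch][sel]}
    patch_weights = {1: w.copy(), 2: w.copy()}

    nodes_cm = book.coords() * UM_TO_CM

    id_nodes_vi1 = cell_ids[1][-1]
    id_nodes_vi2 = cell_ids[2][0]
    id_tris_vi1 = id_nodes_vi1[D.tris]
    id_tris_vi2 = id_nodes_vi2[D.tris]
    id_tris_ve = cleft_ids[D.tris] if collapsed else np.empty((0, 3), dtype=np.int64)

    region, inperi = _assign_id_regions(geom, layout, D)

    mid_node = -1
    if not collapsed:
        mid_node = int(ext_disc[k0][0])   # disc centre node at x = 0

    return MeshBundle(
        nodes=nodes_cm, tets=tets, tet_domain=tet_domain, disc=D,
        id_region=region, id_in_perinexus=inperi,
        id_tris_vi1=id_tris_vi1, id_tris_vi2=id_tris_vi2, id_tris_ve=id_tris_ve,
        id_nodes_vi1=id_nodes_vi1, id_nodes_vi2=id_nodes_vi2,
        cleft_nodes=cleft_ids if collapsed else np.empty(0, dtype=np.int64),
        junction_nodes=junction,
        mem_pairs=mem_pairs, mem_tris=mem_tris, mem_sheet=mem_sheet,
        mem_tri_disc=mem_disc, ground_nodes=ground,
        patch_nodes=patch_nodes, patch_weights=patch_weights,
        collapsed=collapsed, geom=geom, resolution=res, layout=layout,
        mid_cleft_node=mid_node,
    )


def _assign_id_regions(geom: GeometryParams, layout: IDLayout | None,
                       disc: Section2D) -> tuple[np.ndarray, np.ndarray]:
    """Single region tag per ID triangle (centroid rule) plus an
    in-perinexus flag used by the cleft-width field."""
    cent = disc.nodes[disc.tris].mean(axis=1)
    m = len(disc.tris)
    region = np.full(m, REG_BULK, dtype=np.int8)
    inperi = np.zeros(m, dtype=bool)
    r_c = np.hypot(cent[:, 0], cent[:, 1])
    in_cluster = r_c <= geom.r_Na
    if layout is None:
        region[in_cluster] = REG_CLUSTER
        return region, inperi
    d = layout.plaque_distance(geom)
    r_p = np.hypot(cent[:, 0], cent[:, 1] - d)
    has_plaque = layout.configuration in ("close", "remote")
    in_plaque = (r_p <= geom.r_GJ) if has_plaque else np.zeros(m, dtype=bool)
    if layout.has_perinexus and has_plaque:
        inperi = r_p <= geom.r_peri
    # tag priority: plaque > cluster > perinexus > bulk
    region[inperi] = REG_PERINEXUS
    region[in_cluster] = REG_CLUSTER
    region[in_plaque] = REG_PLAQUE
    return region, inperi


def build_cell_pair_mesh(geom: GeometryParams, layout: IDLayout | None = None,
                         resolution: MeshResolution | str = "coarse",
                         seed: int | None = None) -> MeshBundle:
    """Collapsed-cleft mesh of the default two-cell geometry.

    The mesh geometry depends only on ``geom`` and ``resolution`` — the
    three ID configurations (and all cleft widths) share byte-identical
    node coordinates, so configuration comparisons are not mesh
    artefacts.  ``layout`` only sets the ID region tags.  ``seed`` is
    accepted for interface symmetry; generation is fully deterministic.
    """
    if isinstance(resolution, str):
        resolution = RESOLUTION_PRESETS[resolution]
    return _build_pair(geom, layout, resolution, collapsed=True)


def build_explicit_pair_mesh(geom: GeometryParams, w_nm: float,
                             resolution: MeshResolution | str = "coarse") -> MeshBundle:
    """Explicit-cleft mesh: the cells pushed apart by ``w_nm`` and the
    cleft represented as a thin layer of extracellular tetrahedra.

    Used as the independent validation model for the collapsed-cleft
    formulation on miniature geometries.
    """
    if isinstance(resolution, str):
        resolution = RESOLUTION_PRESETS[resolution]
    return _build_pair(geom, None, resolution, collapsed=False, w_um=w_nm * 1e-3)


# ---------------------------------------------------------------------------
# property fields
# ---------------------------------------------------------------------------

def build_cleft_property_fields(layout: IDLayout, mesh: MeshBundle
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Per-ID-triangle cleft width (cm) and conductivity factor f_sigma.

    Plaque triangles get the 2 nm plaque width and the reduced
    conductivity factor; triangles inside the perinexal disc (including
    the Na+ cluster when it sits in the perinexus) get w_peri; everything
    else gets the bulk w_cleft.  The uniform configuration is a constant
    field.
    """
    if mesh.id_region is None or len(mesh.id_region) != len(mesh.disc.tris):
        raise MeshingError("mesh carries no ID region tags")
    m = len(mesh.disc.tris)
    w = np.full(m, layout.w_cleft * 1e-7)          # nm -> cm
    f_sigma = np.ones(m)
    if layout.has_perinexus:
        w[mesh.id_in_perinexus] = layout.w_peri * 1e-7
    if layout.configuration in ("close", "remote"):
        plaque = mesh.id_region == REG_PLAQUE
        w[plaque] = layout.w_plaque * 1e-7
        f_sigma[plaque] = layout.f_sigma_plaque
    return w, f_sigma


@dataclass
class ChannelDensityField:
    """Na+ channel density scaling over the membranes of both cells.

    ``mem_tri_gna`` multiplies gbar_Na per membrane triangle;
    ``node_gna`` is its lumped-area-weighted nodal counterpart used for
    nodal current evaluation (conserving the surface-integrated total
    conductance exactly).  ``node_gk`` is the uniform K+ multiplier.
    """

    P: float
    F_gNa_ID: float
    F_gNa_lat: float
    mem_tri_gna: np.ndarray    # (M,) per membrane triangle
    node_gna: np.ndarray       # (P,) per membrane pair DOF
    node_gk: np.ndarray


def membrane_triangle_areas(mesh: MeshBundle) -> np.ndarray:
    """Areas (cm^2) of the membrane triangles (intracellular-side coords)."""
    p = mesh.nodes[mesh.mem_pairs[mesh.mem_tris, 0]]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    return 0.5 * np.linalg.norm(n, axis=1)


def build_channel_density_field(geom: GeometryParams, layout: IDLayout | None,
                                mesh: MeshBundle, P: float = 0.5) -> ChannelDensityField:
    """Distribute Na+ channels: fraction ``P`` on the ID discs (inside the
    central cluster only), the rest uniformly on the lateral membrane.

    The ID multiplier is F_gNa_ID * (disc area / realized cluster area),
    so the surface-integrated maximal conductance per cell equals
    gbar_Na * A_cell regardless of how the coarse mesh resolves the
    cluster.  K+ conductance is uniform everywhere.
    """
    F_id, F_lat = compute_scaling_factors(geom, P)
    areas = membrane_triangle_areas(mesh)
    mult = np.zeros(len(mesh.mem_tris))
    lat = (mesh.mem_sheet == MEM_LAT1) | (mesh.mem_sheet == MEM_LAT2)
    mult[lat] = F_lat
    disc_sheets = (mesh.mem_sheet == MEM_ID1) | (mesh.mem_sheet == MEM_ID2) | \
                  (mesh.mem_sheet == MEM_OUT1) | (mesh.mem_sheet == MEM_OUT2)
    cluster = disc_sheets & (mesh.id_region[np.clip(mesh.mem_tri_disc, 0, None)] == REG_CLUSTER) \
              & (mesh.mem_tri_disc >= 0)
    # realized cluster area on one disc sheet
    one_sheet = cluster & (mesh.mem_sheet == MEM_ID1)
    a_cluster = areas[one_sheet].sum()
    if a_cluster <= 0:
        raise MeshingError("mesh resolves no triangles inside the Na+ cluster")
    a_disc = math.pi * (geom.R_ID * UM_TO_CM) ** 2
    mult[cluster] = F_id * a_disc / a_cluster
    # lumped-area-weighted nodal multiplier (conserves the total conductance)
    num = np.zeros(len(mesh.mem_pairs))
    den = np.zeros(len(mesh.mem_pairs))
    np.add.at(num, mesh.mem_tris.ravel(), np.repeat(mult * areas / 3.0, 3))
    np.add.at(den, mesh.mem_tris.ravel(), np.repeat(areas / 3.0, 3))
    node_gna = num / den
    return ChannelDensityField(P=P, F_gNa_ID=F_id, F_gNa_lat=F_lat,
                               mem_tri_gna=mult, node_gna=node_gna,
                               node_gk=np.ones(len(mesh.mem_pairs)))


def gap_conductivity_field(layout: IDLayout, mesh: MeshBundle, G_gap: float) -> np.ndarray:
    """Per-ID-triangle gap-junctional conductance per unit area (mS/cm^2).

    The configured whole-ID conductance ``G_gap`` (mS) is divided by the
    realized area of the region carrying it: the plaque for the close and
    remote configurations, the ID outside the Na+ cluster footprint for
    the uniform configuration (optionally including it).  The resulting
    two-terminal conductance between the two intracellular ID layers
    equals G_gap exactly.
    """
    m = len(mesh.disc.tris)
    sigma = np.zeros(m)
    if G_gap == 0.0:
        return sigma
    areas = disc_triangle_areas(mesh.disc) * UM_TO_CM ** 2
    if layout.configuration == "uniform":
        sel = np.ones(m, dtype=bool)
        if layout.exclude_cluster_from_gap:
            sel &= mesh.id_region != REG_CLUSTER
    else:
        sel = mesh.id_region == REG_PLAQUE
    a = areas[sel].sum()
    if a <= 0:
        raise MeshingError("gap-junction region has zero realized area")
    sigma[sel] = G_gap / a
    return sigma


# ---------------------------------------------------------------------------
# audits
# ---------------------------------------------------------------------------

def _face_key(tris: np.ndarray) -> np.ndarray:
    return np.sort(tris, axis=1)


def audit_mesh(mesh: MeshBundle) -> dict:
    """Conformity audit; raises :class:`MeshingError` on any violation.

    Checks: positive tet volumes; every interior tet face shared by
    exactly two tets; every membrane triangle is a boundary face of the
    correct volume domain on both its sides; ID potential layers
    geometrically coincident; no duplicate coincident cleft V_e nodes.
    """
    p = mesh.nodes[mesh.tets]
    vol = np.einsum("ij,ij->i", p[:, 1] - p[:, 0],
                    np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 0])) / 6.0
    if np.any(np.abs(vol) < 1e-30):
        bad = int(np.argmin(np.abs(vol)))
        raise MeshingError(f"degenerate tetrahedron {bad}")

    faces = np.vstack([_face_key(mesh.tets[:, c]) for c in
                       ([0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3])])
    uniq, counts = np.unique(faces, axis=0, return_counts=True)
    if counts.max() > 2:
        raise MeshingError("a face is shared by more than two tetrahedra")
    boundary = {tuple(f) for f in uniq[counts == 1]}

    # membrane triangles must be boundary faces on both sides
    intra_tris = _face_key(mesh.mem_pairs[mesh.mem_tris, 0])
    extra_tris = _face_key(mesh.mem_pairs[mesh.mem_tris, 1])
    n_missing = 0
    for k in range(len(intra_tris)):
        if tuple(intra_tris[k]) not in boundary:
            n_missing += 1
        ve = tuple(extra_tris[k])
        sheet = mesh.mem_sheet[k]
        if mesh.collapsed and sheet in (MEM_ID1, MEM_ID2):
            continue  # cleft layer is 2D, not a tet boundary
        if ve not in boundary:
            n_missing += 1
    if n_missing:
        raise MeshingError(f"{n_missing} membrane triangles are not volume boundary faces")

    # coincidence of ID layers
    if mesh.collapsed and len(mesh.id_tris_ve):
        for layer in (mesh.id_tris_vi2, mesh.id_tris_ve):
            if np.abs(mesh.nodes[mesh.id_tris_vi1] - mesh.nodes[layer]).max() > 1e-12:
                raise MeshingError("ID potential layers are not geometrically coincident")
        # cleft V_e interior nodes must not duplicate any extracellular volume node
        interior = np.setdiff1d(mesh.cleft_nodes, mesh.junction_nodes)
        dup = 0
        ext_nodes = np.unique(mesh.tets[mesh.tet_domain == DOM_EXTRA])
        ext_key = {tuple(r) for r in np.round(mesh.nodes[ext_nodes] / 1e-9).astype(np.int64)}
        for r in np.round(mesh.nodes[interior] / 1e-9).astype(np.int64):
            if tuple(r) in ext_key:
                dup += 1
        if dup:
            raise MeshingError(f"{dup} duplicate coincident cleft V_e nodes")

    # membrane pair coincidence
    mp = mesh.nodes[mesh.mem_pairs]
    if np.abs(mp[:, 0] - mp[:, 1]).max() > 1e-12:
        raise MeshingError("membrane node pairs are not coincident")

    return {"n_nodes": mesh.n_nodes, "n_tets": len(mesh.tets),
            "n_mem_pairs": len(mesh.mem_pairs), "min_tet_volume": float(np.abs(vol).min())}
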