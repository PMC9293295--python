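"""Mesh exchange in the Gmsh ASCII v2.2 format.

Exports the tagged cell-pair mesh (tetrahedra with their domain tag,
ID-manifold triangles with region tags) so external tools can inspect
it, and reads such files back as raw arrays.  Physical tags written:

* tetrahedra: 1 extracellular, 2 cell 1, 3 cell 2
* ID triangles: 10 + region (10 bulk, 11 cluster, 12 plaque, 13 perinexus)

Node coordinates are written in cm (the internal unit).  Importing an
externally generated mesh returns nodes/elements/tags; assembling a
full simulation bundle additionally requires the co-located ID layers
and matched membrane pairs this package's generator provides, so
external meshes are an inspection/exchange path, not a simulation path.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .mesh import MeshBundle

__all__ = ["write_msh", "read_msh"]

_TRI, _TET = 2, 4  # gmsh element type codes


def write_msh(mesh: MeshBundle, path: str | Path) -> None:
    """Write the volume mesh and the tagged ID manifold as Gmsh v2.2 ASCII."""
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat"]
    lines.append("$Nodes")
    lines.append(str(mesh.n_nodes))
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i} {x:.9g} {y:.9g} {z:.9g}")
    lines.append("$EndNodes")

    n_elem = len(mesh.tets) + len(mesh.id_tris_ve)
    lines.append("$Elements")
    lines.append(str(n_elem))
    eid = 1
    for tet, dom in zip(mesh.tets + 1, mesh.tet_domain):
        phys = int(dom) + 1
        lines.append(f"{eid} {_TET} 2 {phys} {phys} " + " ".join(map(str, tet)))
        eid += 1
    for tri, reg in zip(mesh.id_tris_ve + 1, mesh.id_region):
        phys = 10 + int(reg)
        lines.append(f"{eid} {_TRI} 2 {phys} {phys} " + " ".join(map(str, tri)))
        eid += 1
    lines.append("$EndElements")
    Path(path).write_text("\n".join(lines) + "\n")


def read_msh(path: str | Path) -> dict:
    """Read a Gmsh v2.2 ASCII file.

    Returns a dict with ``nodes`` (n, 3), ``tets`` / ``tet_tags`` and
    ``tris`` / ``tri_tags`` (zero-based connectivity, physical tags).
    """
    text = Path(path).read_text().split("\n")
    it = iter(text)

    def seek(tag):
        for line in it:
            if line.strip() == tag:
                return
        raise ValueError(f"section {tag} not found")

    seek("$MeshFormat")
    version = next(it).split()[0]
    if not version.startswith("2."):
        raise ValueError(f"unsupported msh version {version}")
    seek("$Nodes")
    n = int(next(it))
    nodes = np.empty((n, 3))
    for k in range(n):
        parts = next(it).split()
        nodes[int(parts[0]) - 1] = [float(v) for v in parts[1:4]]
    seek("$Elements")
    m = int(next(it))
    tets, tet_tags, tris, tri_tags = [], [], [], []
    for _ in range(m):
        parts = next(it).split()
        etype, ntags = int(parts[1]), int(parts[2])
        tags = [int(v) for v in parts[3:3 + ntags]]
        conn = [int(v) - 1 for v in parts[3 + ntags:]]
        phys = tags[0] if tags else 0
        if etype == _TET:
            tets.append(conn)
            tet_tags.append(phys)
        elif etype == _TRI:
            tris.append(conn)
            tri_tags.append(phys)
    return {
        "nodes": nodes,
        "tets": np.asarray(tets, dtype=np.int64).reshape(-1, 4),
        "tet_tags": np.asarray(tet_tags, dtype=np.int64),
        "tris": np.asarray(tris, dtype=np.int64).reshape(-1, 3),
        "tri_tags": np.asarray(tri_tags, dtype=np.int64),
    }
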