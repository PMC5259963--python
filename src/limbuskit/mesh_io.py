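"""Text writers for meshes and FEM results: legacy VTK and Gmsh MSH v2.

Both formats are written in their plain-ASCII form so meshes and result
fields can be inspected in ParaView / Gmsh without binary dependencies.
Boundary labels travel as cell data (VTK) or physical tags on surface
triangles (MSH).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .fem import FEMResult
from .reconstruct import FACE_LABELS, TetMesh

_VTK_TET = 10
_VTK_TRI = 5


def write_vtk(mesh: TetMesh, path: str | Path,
              result: FEMResult | None = None) -> Path:
    """Write a legacy-VTK unstructured grid (tets + labeled boundary tris).

    When ``result`` is given, nodal displacement and directional-deformation
    arrays (μm) are attached as point data.
    """
    path = Path(path)
    nt, nb = len(mesh.tets), len(mesh.boundary_tris)
    lines = [
        "# vtk DataFile Version 3.0",
        "limbuskit tetrahedral mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    lines += [" ".join(f"{v:.9g}" for v in p) for p in mesh.nodes]
    lines.append(f"CELLS {nt + nb} {5 * nt + 4 * nb}")
    lines += ["4 " + " ".join(map(str, t)) for t in mesh.tets]
    lines += ["3 " + " ".join(map(str, t)) for t in mesh.boundary_tris]
    lines.append(f"CELL_TYPES {nt + nb}")
    lines += [str(_VTK_TET)] * nt + [str(_VTK_TRI)] * nb
    lines.append(f"CELL_DATA {nt + nb}")
    lines.append("SCALARS face_label int 1")
    lines.append("LOOKUP_TABLE default")
    lines += ["-1"] * nt + [str(int(l)) for l in mesh.tri_labels]
    if result is not None:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        lines.append("VECTORS displacement_um double")
        lines += [" ".join(f"{v:.9g}" for v in u) for u in result.displacements]
        lines.append("SCALARS directional_deformation_um double 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.9g}" for v in result.directional_deformation]
    path.write_text("\n".join(lines) + "\n")
    return path


def write_msh2(mesh: TetMesh, path: str | Path) -> Path:
    """Write Gmsh MSH v2.2 ASCII with boundary labels as physical tags.

    Physical tags: tets carry tag 0; boundary triangles carry their face
    label (0 free, 1 pressure, 2 fixed).  Node/element ids are 1-based as
    the format requires.
    """
    path = Path(path)
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat"]
    lines.append("$PhysicalNames")
    lines.append(str(len(FACE_LABELS)))
    for lab_id, name in sorted(FACE_LABELS.items()):
        lines.append(f'2 {lab_id} "{name}"')
    lines.append("$EndPhysicalNames")
    lines.append("$Nodes")
    lines.append(str(mesh.n_nodes))
    for i, p in enumerate(mesh.nodes, start=1):
        lines.append(f"{i} " + " ".join(f"{v:.9g}" for v in p))
    lines.append("$EndNodes")
    lines.append("$Elements")
    lines.append(str(len(mesh.tets) + len(mesh.boundary_tris)))
    eid = 1
    for tri, lab in zip(mesh.boundary_tris, mesh.tri_labels):
        lines.append(
            f"{eid} 2 2 {int(lab)} {int(lab)} "
            + " ".join(str(n + 1) for n in tri))
        eid += 1
    for tet in mesh.tets:
        lines.append(f"{eid} 4 2 0 0 " + " ".join(str(n + 1) for n in tet))
        eid += 1
    lines.append("$EndElements")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_msh2(path: str | Path) -> TetMesh:
    """Read a mesh written by :func:`write_msh2` (round-trip support)."""
    from .reconstruct import FACE_FREE

    tokens = Path(path).read_text().splitlines()
    it = iter(tokens)
    nodes, tets, tris, labels = [], [], [], []
    for line in it:
        if line == "$Nodes":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                nodes.append([float(v) for v in parts[1:4]])
            assert next(it) == "$EndNodes"
        elif line == "$Elements":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                etype, ntags = int(parts[1]), int(parts[2])
                conn = [int(v) - 1 for v in parts[3 + ntags:]]
                if etype == 2:
                    tris.append(conn)
                    labels.append(int(parts[3]))
                elif etype == 4:
                    tets.append(conn)
            assert next(it) == "$EndElements"
    return TetMesh(
        nodes=np.asarray(nodes, dtype=np.float64),
        tets=np.asarray(tets, dtype=np.int64),
        boundary_tris=(np.asarray(tris, dtype=np.int64)
                       if tris else np.empty((0, 3), dtype=np.int64)),
        tri_labels=(np.asarray(labels, dtype=np.int64)
                    if labels else np.empty((0,), dtype=np.int64)),
    )
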