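"""Minimal legacy-ASCII VTK writer for structured hexahedral meshes.

Emits an UNSTRUCTURED_GRID of hexahedra with cell data; cylindrical
meshes are written in Cartesian coordinates (the periodic seam is
duplicated, which only affects visualisation)."""
from __future__ import annotations

from pathlib import Path

import numpy as np

from .mesh import StructuredMesh


def _corner_points(mesh: StructuredMesh):
    e1, e2, e3 = mesh.edges
    P = np.stack(np.meshgrid(e1, e2, e3, indexing="ij"), axis=-1)
    if mesh.system == "cylindrical":
        r, t, z = P[..., 0], P[..., 1], P[..., 2]
        P = np.stack([r * np.cos(t), r * np.sin(t), z], axis=-1)
    return P.reshape(-1, 3), (e1.size, e2.size, e3.size)


def _hex_connectivity(shape_pts):
    m1, m2, m3 = shape_pts
    n1, n2, n3 = m1 - 1, m2 - 1, m3 - 1
    pid = np.arange(m1 * m2 * m3).reshape(m1, m2, m3)
    i, j, k = np.meshgrid(np.arange(n1), np.arange(n2), np.arange(n3),
                          indexing="ij")
    # VTK_HEXAHEDRON ordering: bottom quad then top quad (z faces)
    conn = np.stack([
        pid[i, j, k], pid[i + 1, j, k], pid[i + 1, j + 1, k], pid[i, j + 1, k],
        pid[i, j, k + 1], pid[i + 1, j, k + 1], pid[i + 1, j + 1, k + 1],
        pid[i, j + 1, k + 1],
    ], axis=-1)
    return conn.reshape(-1, 8)


def write_vtk_fields(mesh: StructuredMesh, fields: dict, path) -> Path:
    """Write cell fields (scalars or (n,3) vectors) to a legacy VTK file."""
    path = Path(path)
    pts, shape_pts = _corner_points(mesh)
    conn = _hex_connectivity(shape_pts)
    lines = ["# vtk DataFile Version 3.0", "dialysim fields", "ASCII",
             "DATASET UNSTRUCTURED_GRID",
             f"POINTS {len(pts)} double"]
    lines += [" ".join(f"{v:.9g}" for v in p) for p in pts]
    lines.append(f"CELLS {len(conn)} {len(conn) * 9}")
    lines += ["8 " + " ".join(map(str, c)) for c in conn]
    lines.append(f"CELL_TYPES {len(conn)}")
    lines += ["12"] * len(conn)
    lines.append(f"CELL_DATA {mesh.n_cells}")
    for name, arr in fields.items():
        arr = np.asarray(arr, float)
        if arr.ndim == 2 and arr.shape[1] == 3:
            mag = np.linalg.norm(arr, axis=1)
            lines.append(f"SCALARS {name}_mag double 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{v:.9g}" for v in mag]
        else:
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{v:.9g}" for v in arr.reshape(-1)]
    path.write_text("\n".join(lines) + "\n")
    return path
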