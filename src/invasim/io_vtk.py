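"""Legacy-VTK export of triangulations and nodal fields.

Writes ASCII ``UNSTRUCTURED_GRID`` files that ParaView and VisIt read
directly: points are (lon, lat, z/EXAGGERATION) so terrain reads naturally
in 3-D views, cells are the triangles, and any number of nodal scalar
fields ride along as POINT_DATA.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .meshing import TriMesh

#: vertical scale: metres of elevation shown per degree of map extent
ELEVATION_EXAGGERATION = 100_000.0


def write_vtk(
    mesh: TriMesh,
    path: str | Path,
    point_data: dict[str, np.ndarray] | None = None,
    title: str = "invasim",
) -> None:
    z = (
        mesh.node_elevation / ELEVATION_EXAGGERATION
        if mesh.node_elevation is not None
        else np.zeros(mesh.n_nodes)
    )
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    for (x, y), zz in zip(mesh.nodes, z):
        lines.append(f"{float(x)!r} {float(y)!r} {float(zz)!r}")
    lines.append(f"CELLS {mesh.n_triangles} {4 * mesh.n_triangles}")
    for a, b, c in mesh.triangles:
        lines.append(f"3 {a} {b} {c}")
    lines.append(f"CELL_TYPES {mesh.n_triangles}")
    lines.extend(["5"] * mesh.n_triangles)  # VTK_TRIANGLE
    data = dict(point_data or {})
    if mesh.node_elevation is not None:
        data.setdefault("elevation_m", mesh.node_elevation)
    if data:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, values in data.items():
            vals = np.asarray(values, dtype=float)
            safe = np.where(np.isfinite(vals), vals, -1.0)  # VTK has no inf
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(repr(float(v)) for v in safe)
    Path(path).write_text("\n".join(lines) + "\n")
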