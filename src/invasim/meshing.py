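"""Triangular meshes of geographic domains.

The computational domain is a lat/lon rectangle (the region of interest plus
a buffer margin that pushes the zero-flux boundary away from the area whose
dynamics matter).  Meshing proceeds in the data-driven order used throughout
the package:

1. a structured background grid of right triangles at the background edge
   length;
2. size-field refinement — a region of interest and named geographic
   features impose smaller local target edge lengths;
3. per-node elevation attached by interpolation on an elevation grid;
4. gradient-driven refinement where the piecewise-linear elevation
   interpolant is steeper than a threshold.

All refinement uses conforming marked-edge (longest-edge) bisection: the
longest edge of every triangle selected for refinement is marked, marking is
closed so that any triangle with a marked edge also has its longest edge
marked, and marked edges are then bisected consistently on both sides.  On
structured right-triangle grids bisection alternates between two similarity
classes, so the minimum angle of the initial grid (45 degrees for square
cells) is preserved under arbitrary refinement and no hanging nodes can
occur.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon

from .errors import DomainError, GeometryError, ParameterError, StateError
from .terrain import ElevationGrid, elevation_at


@dataclass
class TriMesh:
    """Planar triangulation in degree coordinates.

    ``nodes``: (N, 2) array of (lon, lat); ``triangles``: (M, 3) int array of
    CCW node triples; ``node_elevation``: metres per node or None before
    elevation is attached; ``roi``: the region-of-interest polygon, if any.
    """

    nodes: np.ndarray
    triangles: np.ndarray
    node_elevation: np.ndarray | None = None
    roi: Polygon | None = None

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.triangles.size and self.triangles.max() >= len(self.nodes):
            raise GeometryError("triangle references a missing node")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def signed_areas(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        d1 = p[:, 1] - p[:, 0]
        d2 = p[:, 2] - p[:, 0]
        return 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])

    def area(self) -> float:
        return float(self.signed_areas().sum())

    def edges(self) -> np.ndarray:
        """Unique undirected edges as (n_edges, 2) sorted node pairs."""
        t = self.triangles
        e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def edge_lengths(self) -> np.ndarray:
        e = self.edges()
        d = self.nodes[e[:, 0]] - self.nodes[e[:, 1]]
        return np.hypot(d[:, 0], d[:, 1])

    def boundary_flags(self) -> np.ndarray:
        """True for nodes lying on the outer boundary (edges used once)."""
        t = self.triangles
        e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e.sort(axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        flags = np.zeros(self.n_nodes, dtype=bool)
        flags[uniq[counts == 1].ravel()] = True
        return flags

    def min_angle_deg(self) -> float:
        p = self.nodes[self.triangles]
        angles = []
        for k in range(3):
            a = p[:, (k + 1) % 3] - p[:, k]
            b = p[:, (k + 2) % 3] - p[:, k]
            cosang = (a * b).sum(1) / (np.hypot(*a.T) * np.hypot(*b.T))
            angles.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
        return float(np.min(angles))


# ---------------------------------------------------------------------------
# size fields

SizeFieldFn = Callable[[np.ndarray], np.ndarray]


def make_size_field(
    background: float,
    regions: Sequence[tuple[shapely.Geometry, float]] = (),
) -> SizeFieldFn:
    """Target-edge-length field: ``background`` everywhere, overridden by the
    minimum of all region sizes whose geometry covers a point.  Polylines
    (rivers, roads) should be passed pre-buffered to their influence width.
    """
    if background <= 0 or any(s <= 0 for _, s in regions):
        raise ParameterError("size-field targets must be strictly positive")

    def field(pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        out = np.full(len(pts), background)
        for geom, size in regions:
            inside = shapely.contains_xy(geom, pts[:, 0], pts[:, 1])
            out[inside] = np.minimum(out[inside], size)
        return out

    return field


def _validate_rectangle(domain) -> tuple[float, float, float, float]:
    """Accept a bounds 4-tuple or an axis-aligned rectangular Polygon."""
    if isinstance(domain, Polygon):
        if not domain.is_valid:
            raise GeometryError(f"invalid domain polygon: {shapely.is_valid_reason(domain)}")
        lon0, lat0, lon1, lat1 = domain.bounds
        rect = shapely.box(lon0, lat0, lon1, lat1)
        if not domain.equals_exact(rect, tolerance=1e-12 * max(lon1 - lon0, lat1 - lat0)):
            raise GeometryError(
                "only axis-aligned rectangular domains are supported; "
                "use roi/feature polygons for interior structure"
            )
        bounds = (lon0, lat0, lon1, lat1)
    else:
        bounds = tuple(float(v) for v in domain)  # type: ignore[assignment]
        if len(bounds) != 4:
            raise GeometryError("domain must be a Polygon or (lon0, lat0, lon1, lat1)")
    lon0, lat0, lon1, lat1 = bounds
    if lon1 <= lon0 or lat1 <= lat0:
        raise GeometryError("domain rectangle is degenerate")
    return bounds


def structured_mesh(bounds: tuple[float, float, float, float], h: float) -> TriMesh:
    """Uniform right-triangle grid with edge length at most ``h``."""
    if h <= 0:
        raise ParameterError("edge length must be positive")
    lon0, lat0, lon1, lat1 = bounds
    nx = max(1, int(np.ceil((lon1 - lon0) / h)))
    ny = max(1, int(np.ceil((lat1 - lat0) / h)))
    xs = np.linspace(lon0, lon1, nx + 1)
    ys = np.linspace(lat0, lat1, ny + 1)
    xg, yg = np.meshgrid(xs, ys)
    nodes = np.column_stack([xg.ravel(), yg.ravel()])

    def nid(i, j):
        return i * (nx + 1) + j

    tris = []
    for i in range(ny):
        for j in range(nx):
            a, b = nid(i, j), nid(i, j + 1)
            c, d = nid(i + 1, j + 1), nid(i + 1, j)
            tris.append((a, b, c))
            tris.append((a, c, d))
    return TriMesh(nodes=nodes, triangles=np.array(tris, dtype=np.int64))


# ---------------------------------------------------------------------------
# marked-edge bisection

def _longest_edge(nodes: np.ndarray, tri: np.ndarray) -> tuple[int, int]:
    """Longest edge of a triangle as a sorted node pair; ties broken by the
    lexicographically smallest pair so both neighbours agree."""
    best = None
    best_len = -1.0
    for k in range(3):
        a, b = int(tri[k]), int(tri[(k + 1) % 3])
        pair = (a, b) if a < b else (b, a)
        d = nodes[pair[0]] - nodes[pair[1]]
        ln = float(d[0] * d[0] + d[1] * d[1])
        if ln > best_len + 1e-15 * max(best_len, 1.0) or (
            abs(ln - best_len) <= 1e-15 * max(best_len, 1.0) and pair < best
        ):
            best, best_len = pair, ln
    return best  # type: ignore[return-value]


def refine_triangles(mesh: TriMesh, flags: np.ndarray) -> TriMesh:
    """Bisect every flagged triangle (and whatever conformity requires).

    Returns a new mesh; node order of the input is preserved, new midpoint
    nodes are appended.  Elevation, if attached, is dropped (re-attach after
    refinement so midpoints get interpolated values, not averages).
    """
    flags = np.asarray(flags, dtype=bool)
    if flags.shape != (mesh.n_triangles,):
        raise ParameterError("flags must have one entry per triangle")
    if not flags.any():
        return replace(mesh, node_elevation=None)

    nodes = mesh.nodes
    tris = mesh.triangles
    marked: set[tuple[int, int]] = set()
    for t in tris[flags]:
        marked.add(_longest_edge(nodes, t))

    # closure: a triangle touching a marked edge must have its longest edge
    # marked too, so that bisection can start from the longest edge everywhere
    changed = True
    while changed:
        changed = False
        for t in tris:
            tri_edges = [
                tuple(sorted((int(t[k]), int(t[(k + 1) % 3])))) for k in range(3)
            ]
            if any(e in marked for e in tri_edges):
                le = _longest_edge(nodes, t)
                if le not in marked:
                    marked.add(le)
                    changed = True

    new_nodes = [nodes]
    midpoint: dict[tuple[int, int], int] = {}
    next_id = mesh.n_nodes
    mid_coords = []
    for a, b in sorted(marked):
        midpoint[(a, b)] = next_id
        mid_coords.append(0.5 * (nodes[a] + nodes[b]))
        next_id += 1
    if mid_coords:
        new_nodes.append(np.array(mid_coords))
    all_nodes = np.vstack(new_nodes)

    out: list[tuple[int, int, int]] = []

    def split(tri: tuple[int, int, int]) -> None:
        tri_edges = [tuple(sorted((tri[k], tri[(k + 1) % 3]))) for k in range(3)]
        active = [k for k in range(3) if tri_edges[k] in marked]
        if not active:
            out.append(tri)
            return
        # bisect the longest marked edge, keeping child orientation CCW
        lens = []
        for k in active:
            a, b = tri_edges[k]
            d = all_nodes[a] - all_nodes[b]
            lens.append((float(d @ d), -k))
        k = -max(lens)[1]
        a, b = tri[k], tri[(k + 1) % 3]
        c = tri[(k + 2) % 3]
        m = midpoint[tri_edges[k]]
        split((c, a, m))
        split((c, m, b))

    for t in tris:
        split((int(t[0]), int(t[1]), int(t[2])))

    return TriMesh(
        nodes=all_nodes,
        triangles=np.array(out, dtype=np.int64),
        node_elevation=None,
        roi=mesh.roi,
    )


def uniform_refine(mesh: TriMesh, levels: int = 1) -> TriMesh:
    """Halve every edge length ``levels`` times (two bisection sweeps each)."""
    out = mesh
    for _ in range(2 * levels):
        out = refine_triangles(out, np.ones(out.n_triangles, dtype=bool))
    return out


# ---------------------------------------------------------------------------
# public mesh-generation pipeline

def generate_mesh(
    domain,
    size_field: SizeFieldFn | float,
    roi: Polygon | None = None,
    max_sweeps: int = 40,
) -> TriMesh:
    """Mesh a rectangular domain down to a target-edge-length field.

    ``size_field`` is either a constant edge length or a callable mapping an
    (n, 2) array of (lon, lat) points to local target lengths (see
    :func:`make_size_field`).  Refinement stops when every triangle's longest
    edge is below the smallest target among its vertices and centroid.
    """
    bounds = _validate_rectangle(domain)
    if roi is not None and not roi.is_valid:
        raise GeometryError(f"invalid roi polygon: {shapely.is_valid_reason(roi)}")
    if callable(size_field):
        field = size_field
    else:
        field = make_size_field(float(size_field))
    span = max(bounds[2] - bounds[0], bounds[3] - bounds[1])
    corners = np.array(
        [[bounds[0], bounds[1]], [bounds[2], bounds[1]],
         [bounds[2], bounds[3]], [bounds[0], bounds[3]]]
    )
    h0 = min(float(np.max(field(corners))), span)
    mesh = structured_mesh(bounds, h0)
    for _ in range(max_sweeps):
        p = mesh.nodes[mesh.triangles]
        centroids = p.mean(axis=1)
        targets = field(centroids)
        for k in range(3):
            targets = np.minimum(targets, field(p[:, k]))
        longest = np.max(
            [np.hypot(*(p[:, (k + 1) % 3] - p[:, k]).T) for k in range(3)], axis=0
        )
        flags = longest > targets * (1 + 1e-9)
        if not flags.any():
            break
        mesh = refine_triangles(mesh, flags)
    return replace(mesh, roi=roi)


def attach_elevation(mesh: TriMesh, grid: ElevationGrid) -> TriMesh:
    """Interpolate the elevation grid onto mesh nodes (idempotent)."""
    z = elevation_at(grid, mesh.nodes)
    return replace(mesh, node_elevation=np.asarray(z, dtype=float))


def elevation_gradients(mesh: TriMesh) -> np.ndarray:
    """Per-triangle gradient magnitude (m/deg) of the P1 elevation field."""
    if mesh.node_elevation is None:
        raise StateError("mesh has no elevation attached")
    p = mesh.nodes[mesh.triangles]
    z = mesh.node_elevation[mesh.triangles]
    areas = mesh.signed_areas()
    # gradient of the linear interpolant on each triangle
    gx = np.zeros(mesh.n_triangles)
    gy = np.zeros(mesh.n_triangles)
    for k in range(3):
        pj = p[:, (k + 1) % 3]
        pk = p[:, (k + 2) % 3]
        gx += z[:, k] * (pj[:, 1] - pk[:, 1])
        gy += z[:, k] * (pk[:, 0] - pj[:, 0])
    gx /= 2 * areas
    gy /= 2 * areas
    return np.hypot(gx, gy)


def gradient_refine(
    mesh: TriMesh,
    grid: ElevationGrid,
    threshold: float = 2000.0,
    passes: int = 1,
) -> TriMesh:
    """Refine triangles whose elevation gradient exceeds ``threshold`` m/deg.

    Elevation is (re-)interpolated from ``grid`` after every pass so new
    midpoint nodes carry grid values rather than edge averages.
    """
    if threshold <= 0:
        raise ParameterError("gradient threshold must be positive")
    if passes < 1:
        raise ParameterError("passes must be >= 1")
    out = attach_elevation(mesh, grid)
    for _ in range(passes):
        flags = elevation_gradients(out) > threshold
        if not flags.any():
            break
        out = attach_elevation(refine_triangles(out, flags), grid)
    return out


# ---------------------------------------------------------------------------
# point location

def locate_points(mesh: TriMesh, points: np.ndarray):
    """Containing triangle and barycentric coordinates for each point.

    Returns ``(tri_idx, bary)`` with ``bary`` of shape (n, 3).  Points not in
    any triangle raise :class:`DomainError`.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    p = mesh.nodes[mesh.triangles]
    areas2 = 2.0 * mesh.signed_areas()
    tri_idx = np.full(len(pts), -1, dtype=np.int64)
    bary = np.zeros((len(pts), 3))
    for i, (x, y) in enumerate(pts):
        l0 = ((p[:, 1, 0] - x) * (p[:, 2, 1] - y) - (p[:, 2, 0] - x) * (p[:, 1, 1] - y)) / areas2
        l1 = ((p[:, 2, 0] - x) * (p[:, 0, 1] - y) - (p[:, 0, 0] - x) * (p[:, 2, 1] - y)) / areas2
        l2 = 1.0 - l0 - l1
        ok = (l0 >= -1e-10) & (l1 >= -1e-10) & (l2 >= -1e-10)
        hits = np.flatnonzero(ok)
        if len(hits) == 0:
            raise DomainError(f"point (lon={x:.6f}, lat={y:.6f}) outside the mesh")
        j = int(hits[0])
        tri_idx[i] = j
        bary[i] = (l0[j], l1[j], l2[j])
    return tri_idx, bary


# ---------------------------------------------------------------------------
# Triangle-format I/O (.node / .ele, ASCII)

def write_mesh(mesh: TriMesh, stem: str | Path) -> None:
    """Write ``<stem>.node`` and ``<stem>.ele`` (Triangle ASCII dialect)."""
    stem = Path(stem)
    flags = mesh.boundary_flags().astype(int)
    has_z = mesh.node_elevation is not None
    with open(stem.with_suffix(".node"), "w") as fh:
        fh.write(f"{mesh.n_nodes} 2 {1 if has_z else 0} 1\n")
        for i, (x, y) in enumerate(mesh.nodes):
            attr = f" {float(mesh.node_elevation[i])!r}" if has_z else ""
            fh.write(f"{i} {float(x)!r} {float(y)!r}{attr} {flags[i]}\n")
    with open(stem.with_suffix(".ele"), "w") as fh:
        fh.write(f"{mesh.n_triangles} 3 0\n")
        for i, (a, b, c) in enumerate(mesh.triangles):
            fh.write(f"{i} {a} {b} {c}\n")


def read_mesh(stem: str | Path) -> TriMesh:
    stem = Path(stem)
    with open(stem.with_suffix(".node")) as fh:
        n, _dim, n_attr, _nb = (int(v) for v in fh.readline().split())
        nodes = np.zeros((n, 2))
        elev = np.zeros(n) if n_attr >= 1 else None
        for _ in range(n):
            parts = fh.readline().split()
            i = int(parts[0])
            nodes[i] = float(parts[1]), float(parts[2])
            if elev is not None:
                elev[i] = float(parts[3])
    with open(stem.with_suffix(".ele")) as fh:
        m, _, _ = (int(v) for v in fh.readline().split())
        tris = np.zeros((m, 3), dtype=np.int64)
        for _ in range(m):
            parts = fh.readline().split()
            tris[int(parts[0])] = [int(parts[1]), int(parts[2]), int(parts[3])]
    return TriMesh(nodes=nodes, triangles=tris, node_elevation=elev)
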