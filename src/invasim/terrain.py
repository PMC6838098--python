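"""Elevation data: SRTM HGT tiles, synthetic terrain, point-wise lookup.

SRTM distributes elevation as 1-degree by 1-degree tiles of big-endian signed
16-bit integers (metres above sea level), 1201x1201 cells at 3 arc-second
resolution or 3601x3601 at 1 arc-second.  Sea level is 0 and the sentinel
-32768 marks voids (radar shadow).  Rows in the file run north to south from
the tile's north-west corner; internally grids are stored south to north so
that (row, col) increases with (lat, lon), one consistent geographic
convention for the whole package (lon = x, lat = y, degrees everywhere).

Synthetic terrain — a Gaussian ridge along a parallel, optionally broken by a
valley gap and perturbed by seeded noise — lets every downstream computation
run without downloading tiles while exercising the same elevation pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import DomainError, FormatError, ParameterError

VOID: int = -32768
_HGT_SIZES = {1201: 3.0, 3601: 1.0}  # grid side -> cell size in arc-seconds


@dataclass
class ElevationGrid:
    """Regular lat/lon grid of integer elevations (metres).

    ``values[0, 0]`` is the south-west corner; row index increases with
    latitude, column index with longitude.  ``cell_arcsec`` is the spacing
    between adjacent grid nodes in arc-seconds.
    """

    origin_lat: float
    origin_lon: float
    n_rows: int
    n_cols: int
    cell_arcsec: float
    values: np.ndarray
    void_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int16)
        if self.values.shape != (self.n_rows, self.n_cols):
            raise FormatError(
                f"values shape {self.values.shape} != ({self.n_rows}, {self.n_cols})"
            )
        if self.void_mask is None:
            self.void_mask = self.values == VOID
        self.void_mask = np.asarray(self.void_mask, dtype=bool)

    @property
    def cell_deg(self) -> float:
        return self.cell_arcsec / 3600.0

    @property
    def lat_max(self) -> float:
        return self.origin_lat + (self.n_rows - 1) * self.cell_deg

    @property
    def lon_max(self) -> float:
        return self.origin_lon + (self.n_cols - 1) * self.cell_deg

    def lats(self) -> np.ndarray:
        return self.origin_lat + np.arange(self.n_rows) * self.cell_deg

    def lons(self) -> np.ndarray:
        return self.origin_lon + np.arange(self.n_cols) * self.cell_deg


def read_hgt(path: str | Path, tile_origin: tuple[float, float]) -> ElevationGrid:
    """Read one SRTM ``.hgt`` tile.

    Parameters
    ----------
    path:
        File of exactly ``2 n^2`` bytes, n in {1201, 3601}, big-endian int16,
        row-major from the tile's north-west corner.
    tile_origin:
        ``(lat, lon)`` of the tile's south-west corner in degrees (the pair
        encoded in SRTM file names, e.g. N43W002).
    """
    path = Path(path)
    try:
        raw = path.read_bytes()
    except OSError as exc:
        raise FormatError(f"cannot read HGT file {path}: {exc}") from exc
    n2 = len(raw) // 2
    n = int(round(n2**0.5))
    if len(raw) % 2 or n * n != n2 or n not in _HGT_SIZES:
        expected = ", ".join(f"{2 * k * k} (={k}x{k})" for k in _HGT_SIZES)
        raise FormatError(
            f"{path}: size {len(raw)} bytes is not a valid HGT tile; expected {expected}"
        )
    data = np.frombuffer(raw, dtype=">i2").reshape(n, n).astype(np.int16)
    data = data[::-1]  # north-to-south on disk -> south-to-north in memory
    lat0, lon0 = tile_origin
    return ElevationGrid(
        origin_lat=float(lat0),
        origin_lon=float(lon0),
        n_rows=n,
        n_cols=n,
        cell_arcsec=_HGT_SIZES[n],
        values=data,
    )


def write_hgt(grid: ElevationGrid, path: str | Path) -> None:
    """Write a square grid back to HGT layout (big-endian, north first)."""
    if grid.n_rows != grid.n_cols or grid.n_rows not in _HGT_SIZES:
        raise FormatError(
            f"HGT output requires a square {list(_HGT_SIZES)} grid, got "
            f"{grid.n_rows}x{grid.n_cols}"
        )
    out = grid.values.copy()
    out[grid.void_mask] = VOID
    Path(path).write_bytes(out[::-1].astype(">i2").tobytes())


def write_ascii_grid(grid: ElevationGrid, path: str | Path) -> None:
    """Write an ESRI ASCII grid (plain-text fixture format)."""
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.origin_lon!r}\n")
        fh.write(f"yllcorner {grid.origin_lat!r}\n")
        fh.write(f"cellsize {grid.cell_deg!r}\n")
        fh.write(f"NODATA_value {VOID}\n")
        out = grid.values.copy()
        out[grid.void_mask] = VOID
        for row in out[::-1]:  # ESRI ASCII is north first
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_ascii_grid(path: str | Path) -> ElevationGrid:
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh, dtype=np.int16)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if vals.shape != (n_rows, n_cols):
        raise FormatError(f"{path}: grid body {vals.shape} disagrees with header")
    return ElevationGrid(
        origin_lat=header["yllcorner"],
        origin_lon=header["xllcorner"],
        n_rows=n_rows,
        n_cols=n_cols,
        cell_arcsec=header["cellsize"] * 3600.0,
        values=vals[::-1],
    )


@dataclass
class RidgeSpec:
    """Analytic terrain: Gaussian ridge along a parallel with optional gap.

    z(lon, lat) = A * exp(-(lat - ridge_lat)^2 / (2 sigma^2)) * gap(lon) + noise

    where ``gap(lon) = 1 - exp(-(lon - gap_lon)^2 / (2 (gap_width/2)^2))`` if a
    valley gap is configured, else 1.  Amplitude in metres, widths in degrees.
    """

    amplitude: float = 0.0
    ridge_lat: float = 0.0
    ridge_sigma: float = 0.1
    gap_lon: float | None = None
    gap_width: float = 0.1
    noise_std: float = 0.0


def synth_terrain(
    bounds: tuple[float, float, float, float],
    resolution_arcsec: float,
    spec: RidgeSpec,
    seed: int = 0,
) -> ElevationGrid:
    """Generate a deterministic synthetic :class:`ElevationGrid`.

    ``bounds`` is ``(lon_min, lat_min, lon_max, lat_max)`` in degrees.  The
    surface is evaluated exactly on the grid nodes and rounded to integer
    metres; noise (if any) is drawn from a generator seeded with ``seed`` so
    the output is reproducible and platform independent.
    """
    if resolution_arcsec <= 0:
        raise ParameterError("resolution must be positive")
    if spec.amplitude < 0:
        raise ParameterError("ridge amplitude must be non-negative")
    lon_min, lat_min, lon_max, lat_max = bounds
    step = resolution_arcsec / 3600.0
    n_cols = int(round((lon_max - lon_min) / step)) + 1
    n_rows = int(round((lat_max - lat_min) / step)) + 1
    lons = lon_min + np.arange(n_cols) * step
    lats = lat_min + np.arange(n_rows) * step
    lon_g, lat_g = np.meshgrid(lons, lats)
    z = ridge_elevation(lon_g, lat_g, spec)
    if spec.noise_std > 0:
        rng = np.random.default_rng(seed)
        z = z + rng.normal(0.0, spec.noise_std, size=z.shape)
    z = np.clip(np.rint(z), -32767, 32767).astype(np.int16)
    return ElevationGrid(
        origin_lat=lat_min,
        origin_lon=lon_min,
        n_rows=n_rows,
        n_cols=n_cols,
        cell_arcsec=resolution_arcsec,
        values=z,
        void_mask=np.zeros((n_rows, n_cols), dtype=bool),
    )


def ridge_elevation(lon, lat, spec: RidgeSpec):
    """The noise-free analytic ridge surface (metres, float)."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    z = spec.amplitude * np.exp(-((lat - spec.ridge_lat) ** 2) / (2 * spec.ridge_sigma**2))
    if spec.gap_lon is not None:
        half = spec.gap_width / 2.0
        z = z * (1.0 - np.exp(-((lon - spec.gap_lon) ** 2) / (2 * half**2)))
    return z


def _nearest_valid_fill(grid: ElevationGrid) -> np.ndarray:
    """Elevations with every void replaced by its nearest non-void value."""
    if not grid.void_mask.any():
        return grid.values.astype(float)
    if grid.void_mask.all():
        raise DomainError("grid has no valid cells")
    idx = ndimage.distance_transform_edt(
        grid.void_mask, return_distances=False, return_indices=True
    )
    return grid.values.astype(float)[tuple(idx)]


def elevation_at(grid: ElevationGrid, points: np.ndarray) -> np.ndarray:
    """Bilinear elevation at ``points`` (array of ``(lon, lat)`` pairs).

    Queries with any void cell among the four surrounding values fall back to
    the nearest non-void cell's value.  Points outside the grid's node
    bounding box raise :class:`DomainError`.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    lon, lat = pts[:, 0], pts[:, 1]
    step = grid.cell_deg
    fx = (lon - grid.origin_lon) / step
    fy = (lat - grid.origin_lat) / step
    eps = 1e-9
    bad = (fx < -eps) | (fy < -eps) | (fx > grid.n_cols - 1 + eps) | (fy > grid.n_rows - 1 + eps)
    if bad.any():
        k = int(np.argmax(bad))
        raise DomainError(
            f"point (lon={lon[k]:.6f}, lat={lat[k]:.6f}) outside elevation grid "
            f"[{grid.origin_lon:.6f}, {grid.lon_max:.6f}] x "
            f"[{grid.origin_lat:.6f}, {grid.lat_max:.6f}]"
        )
    fx = np.clip(fx, 0.0, grid.n_cols - 1.0)
    fy = np.clip(fy, 0.0, grid.n_rows - 1.0)
    j0 = np.minimum(fx.astype(int), grid.n_cols - 2)
    i0 = np.minimum(fy.astype(int), grid.n_rows - 2)
    tx = fx - j0
    ty = fy - i0
    v = grid.values.astype(float)
    z = (
        v[i0, j0] * (1 - tx) * (1 - ty)
        + v[i0, j0 + 1] * tx * (1 - ty)
        + v[i0 + 1, j0] * (1 - tx) * ty
        + v[i0 + 1, j0 + 1] * tx * ty
    )
    if grid.void_mask.any():
        m = grid.void_mask
        corner_void = m[i0, j0] | m[i0, j0 + 1] | m[i0 + 1, j0] | m[i0 + 1, j0 + 1]
        if corner_void.any():
            filled = _nearest_valid_fill(grid)
            i_near = np.rint(fy[corner_void]).astype(int)
            j_near = np.rint(fx[corner_void]).astype(int)
            z[corner_void] = filled[i_near, j_near]
    return z if np.ndim(points) > 1 else z
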