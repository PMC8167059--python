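"""MRC2014 volume I/O and the world-coordinate / voxel-index contract.

A :class:`DensityMap` stores the grid with axes already reordered to
crystallographic X, Y, Z (``values[ix, iy, iz]``), so every downstream
computation is independent of how the file interleaved columns, rows and
sections.  The ``origin`` is the world coordinate (Å) of the *center* of
voxel (0, 0, 0); distances to voxels are always measured to voxel centers,
which makes the "voxels within r Å of an atom" rule unambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np

from .errors import MapDataError, MapFormatError

logger = logging.getLogger(__name__)

__all__ = [
    "DensityMap",
    "read_density_map",
    "write_density_map",
    "world_to_voxel",
    "voxel_to_world",
    "voxels_within_radius",
    "nearest_voxel",
    "is_inside_grid",
]


@dataclass
class DensityMap:
    """A 3D density volume with physical geometry.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Grid values indexed [ix, iy, iz] along crystallographic X, Y, Z.
        Stored as float64 for numerically stable statistics; written back
        to file as 32-bit reals.
    voxel_size : ndarray, shape (3,)
        Per-axis spacing in Å (anisotropic voxels allowed, all > 0).
    origin : ndarray, shape (3,)
        World coordinate (Å) of the center of voxel (0, 0, 0).
    axis_order : tuple of int
        Storage-axis permutation (mapc, mapr, maps) of the source file;
        (1, 2, 3) for data created in memory.  Informational only — values
        are always held in X, Y, Z order.
    """

    values: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray
    axis_order: tuple[int, int, int] = (1, 2, 3)
    label: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise MapDataError(f"expected a 3D grid, got ndim={self.values.ndim}")
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=np.float64), (3,)
        ).copy()
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3).copy()
        if not np.all(np.isfinite(self.voxel_size)) or np.any(self.voxel_size <= 0):
            raise MapDataError(f"voxel_size must be positive and finite, got {self.voxel_size}")
        if not np.all(np.isfinite(self.origin)):
            raise MapDataError("origin must be finite")
        if not np.all(np.isfinite(self.values)):
            raise MapDataError("grid contains NaN/Inf values")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def cell_edges(self) -> np.ndarray:
        """Physical box edge lengths in Å (dims × voxel_size)."""
        return np.asarray(self.dims) * self.voxel_size

    def with_values(self, values: np.ndarray, **kw) -> "DensityMap":
        """Copy of this map's geometry holding different values."""
        return replace(self, values=np.asarray(values, dtype=np.float64), **kw)


def read_density_map(path: str | Path) -> DensityMap:
    """Read an MRC2014 volume, normalising storage-axis order to X, Y, Z.

    The origin is taken from the MRC ORIGIN record if any component is
    nonzero, else from nstart × voxel_size (the common single-particle
    conventions).  Raises :class:`MapFormatError` for unreadable files and
    :class:`MapDataError` for non-finite voxel data.
    """
    path = Path(path)
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise MapFormatError(f"cannot read MRC map {path}: {exc}") from exc

    axis_order = tuple(m.header_i32(w) for w in (17, 18, 19))  # mapc, mapr, maps
    if sorted(axis_order) != [1, 2, 3]:
        raise MapFormatError(f"{path}: invalid axis records mapc/mapr/maps={axis_order}")
    # nstart words are per *storage* axis; map them onto crystal axes.
    nstart_storage = [m.header_i32(w) for w in (5, 6, 7)]
    nstart = np.zeros(3)
    for storage_idx, crystal_axis in enumerate(axis_order):
        nstart[crystal_axis - 1] = nstart_storage[storage_idx]
    origin_record = np.array([m.header_float(w) for w in (50, 51, 52)], dtype=np.float64)

    m.setup(float("nan"))  # reorder axes to X,Y,Z; missing cell points -> NaN
    values = np.array(m.grid, copy=True, dtype=np.float64)
    if not np.all(np.isfinite(values)):
        raise MapDataError(f"{path}: map contains NaN/Inf values")

    cell = m.grid.unit_cell
    dims = np.asarray(values.shape, dtype=np.float64)
    voxel_size = np.array([cell.a, cell.b, cell.c], dtype=np.float64) / dims
    if np.any(voxel_size <= 0) or not np.all(np.isfinite(voxel_size)):
        raise MapFormatError(f"{path}: invalid cell {cell} for dims {values.shape}")
    if not np.allclose(voxel_size, voxel_size[0], rtol=1e-4):
        logger.warning("%s: non-cubic voxels %s Å", path.name, np.round(voxel_size, 4))

    if np.any(origin_record != 0.0):
        origin = origin_record
    else:
        origin = nstart * voxel_size
    return DensityMap(
        values=values,
        voxel_size=voxel_size,
        origin=origin,
        axis_order=axis_order,  # type: ignore[arg-type]
        label=path.name,
    )


def write_density_map(dmap: DensityMap, path: str | Path) -> None:
    """Write a volume as MRC2014 mode 2 (32-bit real), X,Y,Z storage order."""
    path = Path(path)
    grid = gemmi.FloatGrid(np.ascontiguousarray(dmap.values, dtype=np.float32))
    edges = dmap.cell_edges
    grid.set_unit_cell(gemmi.UnitCell(edges[0], edges[1], edges[2], 90.0, 90.0, 90.0))
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    for word, value in zip((50, 51, 52), dmap.origin):
        m.set_header_float(word, float(value))
    try:
        m.write_ccp4_map(str(path))
    except (RuntimeError, OSError) as exc:
        raise MapFormatError(f"cannot write {path}: {exc}") from exc


def world_to_voxel(dmap: DensityMap, coord) -> np.ndarray:
    """Fractional voxel index of a world coordinate: (coord − origin)/voxel_size."""
    coord = np.asarray(coord, dtype=np.float64)
    return (coord - dmap.origin) / dmap.voxel_size


def voxel_to_world(dmap: DensityMap, index) -> np.ndarray:
    """World coordinate (Å) of a (possibly fractional) voxel index."""
    index = np.asarray(index, dtype=np.float64)
    return dmap.origin + index * dmap.voxel_size


def is_inside_grid(dmap: DensityMap, coord) -> bool:
    """True if the coordinate falls inside the volume spanned by the voxels.

    The grid is taken to extend half a voxel beyond the first/last voxel
    centers on each axis.
    """
    frac = world_to_voxel(dmap, coord)
    dims = np.asarray(dmap.dims)
    return bool(np.all(frac >= -0.5) and np.all(frac <= dims - 0.5))


def nearest_voxel(dmap: DensityMap, coord) -> tuple[int, int, int] | None:
    """Integer index of the voxel whose center is nearest, or None if outside."""
    if not is_inside_grid(dmap, coord):
        return None
    frac = world_to_voxel(dmap, coord)
    idx = np.clip(np.rint(frac).astype(int), 0, np.asarray(dmap.dims) - 1)
    return tuple(int(i) for i in idx)


def voxels_within_radius(dmap: DensityMap, coord, radius: float) -> list[tuple[int, int, int]]:
    """Integer indices of all in-grid voxels whose centers lie within
    ``radius`` Å (true Euclidean distance) of a world coordinate.

    May be empty.  ``radius`` must be positive.
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    coord = np.asarray(coord, dtype=np.float64)
    frac = world_to_voxel(dmap, coord)
    dims = np.asarray(dmap.dims)
    lo = np.maximum(np.ceil(frac - radius / dmap.voxel_size).astype(int), 0)
    hi = np.minimum(np.floor(frac + radius / dmap.voxel_size).astype(int), dims - 1)
    if np.any(lo > hi):
        return []
    ix, iy, iz = np.meshgrid(
        np.arange(lo[0], hi[0] + 1),
        np.arange(lo[1], hi[1] + 1),
        np.arange(lo[2], hi[2] + 1),
        indexing="ij",
    )
    idx = np.stack([ix.ravel(), iy.ravel(), iz.ravel()], axis=1)
    centers = dmap.origin + idx * dmap.voxel_size
    d2 = np.sum((centers - coord) ** 2, axis=1)
    keep = idx[d2 <= radius * radius]
    return [tuple(int(i) for i in row) for row in keep]
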