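"""Discretized coastal seascape: land/sea mask, bathymetry, habitat and environment.

The domain is an abstract planar grid of ``ny`` rows by ``nx`` columns of
square cells with side ``cell_size_km``.  All per-cell arrays are row-major
with shape ``(ny, nx)``; cell ``(row j, col i)`` has its center at
``x = (i + 0.5) * cell_size_km``, ``y = (j + 0.5) * cell_size_km``.

Habitat is defined hydrographically: a cell is habitat when it is sea *and*
shallower than the habitat depth limit (default 30 m), emulating the shallow
coastal band that macrophyte-associated invertebrates occupy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

DEFAULT_HABITAT_DEPTH_M = 30.0


class EmptyHabitatError(ValueError):
    """Raised when a seascape contains no habitat cell at all."""


@dataclass
class SeascapeGrid:
    """A discretized seascape domain.

    Attributes
    ----------
    nx, ny:
        Cell counts along x (columns) and y (rows).
    cell_size_km:
        Side length of a (square) cell in kilometres.
    land_mask:
        Boolean ``(ny, nx)``; True on land.
    depth_m:
        Nonnegative mean depth per cell; ignored (0) on land.
    habitat_mask:
        Boolean ``(ny, nx)``; True where sea and ``depth_m`` is below the
        habitat depth limit.
    salinity_psu, temperature_C:
        Per-cell environmental fields (may be None until assigned).
    """

    nx: int
    ny: int
    cell_size_km: float
    land_mask: np.ndarray
    depth_m: np.ndarray
    habitat_mask: np.ndarray
    habitat_depth_limit_m: float = DEFAULT_HABITAT_DEPTH_M
    salinity_psu: np.ndarray | None = None
    temperature_C: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    # -- indexing helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def sea_mask(self) -> np.ndarray:
        return ~self.land_mask

    def cell_id(self, row: np.ndarray | int, col: np.ndarray | int):
        """Flat row-major cell id for (row, col)."""
        return np.asarray(row) * self.nx + np.asarray(col)

    def cell_rowcol(self, cell: np.ndarray | int):
        cell = np.asarray(cell)
        return cell // self.nx, cell % self.nx

    def cell_center_km(self, cell: np.ndarray | int) -> np.ndarray:
        """(x, y) center coordinates in km; last axis is (x, y)."""
        row, col = self.cell_rowcol(cell)
        return np.stack(
            [(np.asarray(col) + 0.5) * self.cell_size_km,
             (np.asarray(row) + 0.5) * self.cell_size_km],
            axis=-1,
        )

    def cell_of_position(self, xy_km: np.ndarray) -> np.ndarray:
        """Flat cell id containing each position; -1 if outside the domain."""
        xy = np.atleast_2d(np.asarray(xy_km, dtype=float))
        col = np.floor(xy[..., 0] / self.cell_size_km).astype(int)
        row = np.floor(xy[..., 1] / self.cell_size_km).astype(int)
        inside = (col >= 0) & (col < self.nx) & (row >= 0) & (row < self.ny)
        out = np.where(inside, row * self.nx + col, -1)
        return out if out.shape else int(out)

    @property
    def habitat_cells(self) -> np.ndarray:
        """Sorted flat ids of habitat cells."""
        return np.flatnonzero(self.habitat_mask.ravel())

    def validate(self) -> None:
        for name in ("land_mask", "depth_m", "habitat_mask"):
            arr = getattr(self, name)
            if arr.shape != self.shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {self.shape}")
        if np.any(self.habitat_mask & self.land_mask):
            raise ValueError("habitat_mask overlaps land_mask")
        sea_hab = self.habitat_mask & ~self.land_mask
        if np.any(self.depth_m[sea_hab] >= self.habitat_depth_limit_m):
            raise ValueError("habitat cell at or below the habitat depth limit")


def build_grid(
    nx: int,
    ny: int,
    cell_size_km: float = 10.0,
    depth_m: np.ndarray | float = 10.0,
    land_mask: np.ndarray | None = None,
    habitat_depth_limit_m: float = DEFAULT_HABITAT_DEPTH_M,
) -> SeascapeGrid:
    """Build a :class:`SeascapeGrid` and derive its habitat mask.

    Habitat = sea AND ``depth_m`` strictly below ``habitat_depth_limit_m``.
    Deterministic given its arguments.

    Raises
    ------
    ValueError
        If dimensions or the depth limit are non-positive.
    EmptyHabitatError
        If no cell qualifies as habitat ("empty habitat").
    """
    if nx < 2 or ny < 2:
        raise ValueError(f"grid dimensions must be >= 2, got nx={nx}, ny={ny}")
    if cell_size_km <= 0:
        raise ValueError("cell_size_km must be positive")
    if habitat_depth_limit_m <= 0:
        raise ValueError("habitat depth limit must be positive")

    shape = (ny, nx)
    if land_mask is None:
        land_mask = np.zeros(shape, dtype=bool)
    land_mask = np.asarray(land_mask, dtype=bool)
    depth = np.broadcast_to(np.asarray(depth_m, dtype=float), shape).copy()
    if np.any(depth < 0):
        raise ValueError("depth_m must be nonnegative")
    depth[land_mask] = 0.0

    habitat = (~land_mask) & (depth < habitat_depth_limit_m)
    grid = SeascapeGrid(
        nx=nx, ny=ny, cell_size_km=float(cell_size_km),
        land_mask=land_mask, depth_m=depth, habitat_mask=habitat,
        habitat_depth_limit_m=float(habitat_depth_limit_m),
    )
    grid.validate()
    if not habitat.any():
        raise EmptyHabitatError(
            "empty habitat: no sea cell shallower than "
            f"{habitat_depth_limit_m} m"
        )
    return grid


def assign_environment(
    grid: SeascapeGrid,
    field_name: str = "salinity_psu",
    axis: str = "x",
    start: float = 25.0,
    end: float = 3.0,
) -> SeascapeGrid:
    """Assign a monotone linear environmental gradient along an axis.

    ``start`` is the value at the low-coordinate edge, ``end`` at the
    high-coordinate edge; interpolation is linear between cell centers of the
    first and last row/column.  Returns a new grid (input unchanged).
    """
    if field_name not in ("salinity_psu", "temperature_C"):
        raise ValueError(f"unknown environmental field {field_name!r}")
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    if not (np.isfinite(start) and np.isfinite(end)):
        raise ValueError("gradient endpoints must be finite")

    n = grid.nx if axis == "x" else grid.ny
    line = np.linspace(start, end, n)
    values = np.tile(line, (grid.ny, 1)) if axis == "x" else np.tile(line[:, None], (1, grid.nx))
    return replace(grid, **{field_name: values})
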