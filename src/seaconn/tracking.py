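"""Lagrangian advection of passive particles and dispersal-matrix estimation.

Particles are released from every habitat cell (with uniform sub-cell
jitter), advected for the dispersive-phase duration (default 5 days) with a
fixed-step RK4 integrator over bilinearly interpolated velocities, and
settled into the habitat cell containing their end position.  Particles are
passive: no diffusion, behavior or mortality.

Land handling: an RK4 step whose endpoint falls on a land cell is cancelled
and the particle holds position for that step (stick-in-place; simple and
direction-unbiased).  A particle whose step leaves the open domain boundary
is flagged LOST and never settles.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .grid import SeascapeGrid
from .velocity import DEFAULT_RELEASE_MONTHS, VelocityField

SECONDS_PER_DAY = 86_400.0
LOST = -1


@dataclass
class ReleaseSchedule:
    """Seasonal release plan.

    ``release_months`` defaults to April–September (one release per month);
    ``particles_per_cell`` particles start from every habitat cell at each
    release.  ``pld_days`` is the duration of the dispersive phase and
    ``dt_s`` the RK4 step.  ``layer`` is metadata only (2-D surface model).
    """

    release_months: tuple[int, ...] = DEFAULT_RELEASE_MONTHS
    particles_per_cell: int = 50
    pld_days: float = 5.0
    dt_s: float = 3600.0
    layer: str = "surface"

    def __post_init__(self) -> None:
        if self.pld_days <= 0:
            raise ValueError("pld_days must be positive")
        if self.particles_per_cell < 1:
            raise ValueError("particles_per_cell must be >= 1")
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")


@dataclass
class ParticleEnsemble:
    """Outcome of a dispersal simulation.

    ``table`` columns: particle_id, src_cell, release_index, end_x_km,
    end_y_km, dest_cell (flat habitat cell id, or -1 = LOST), lost (bool).
    """

    table: pd.DataFrame
    meta: dict = dc_field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# interpolation + integration
# ---------------------------------------------------------------------------

def _bilinear(u: np.ndarray, v: np.ndarray, xy_km: np.ndarray, cell_size_km: float) -> np.ndarray:
    """Bilinear interpolation of cell-center velocities at positions (n, 2).

    Fractional indices are clamped to the cell-center hull, so evaluation a
    hair outside the domain uses edge values (the step itself decides loss).
    Returns velocities in m/s, shape (n, 2).
    """
    ny, nx = u.shape
    fx = np.clip(xy_km[:, 0] / cell_size_km - 0.5, 0.0, nx - 1.0)
    fy = np.clip(xy_km[:, 1] / cell_size_km - 0.5, 0.0, ny - 1.0)
    i0 = np.clip(np.floor(fx).astype(int), 0, nx - 2)
    j0 = np.clip(np.floor(fy).astype(int), 0, ny - 2)
    tx = fx - i0
    ty = fy - j0
    w00 = (1 - tx) * (1 - ty)
    w10 = tx * (1 - ty)
    w01 = (1 - tx) * ty
    w11 = tx * ty
    out = np.empty((xy_km.shape[0], 2))
    for k, comp in enumerate((u, v)):
        out[:, k] = (
            w00 * comp[j0, i0] + w10 * comp[j0, i0 + 1]
            + w01 * comp[j0 + 1, i0] + w11 * comp[j0 + 1, i0 + 1]
        )
    return out


def _rk4_step(u, v, xy_km, dt_s, cell_size_km):
    """One RK4 step; velocities m/s, positions km."""
    scale = dt_s / 1000.0  # m/s * s -> km
    k1 = _bilinear(u, v, xy_km, cell_size_km)
    k2 = _bilinear(u, v, xy_km + 0.5 * scale * k1, cell_size_km)
    k3 = _bilinear(u, v, xy_km + 0.5 * scale * k2, cell_size_km)
    k4 = _bilinear(u, v, xy_km + scale * k3, cell_size_km)
    return xy_km + (scale / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)


def _advect(
    grid: SeascapeGrid,
    u: np.ndarray,
    v: np.ndarray,
    start_xy: np.ndarray,
    pld_days: float,
    dt_s: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Advect positions (n, 2) for pld_days; returns (end positions, lost mask).

    Lost particles keep the last in-domain position and stop moving; steps
    that end on land are cancelled.
    """
    pos = np.array(start_xy, dtype=float, copy=True)
    n_steps = int(round(pld_days * SECONDS_PER_DAY / dt_s))
    if not np.isclose(n_steps * dt_s, pld_days * SECONDS_PER_DAY, rtol=1e-9):
        raise ValueError("dt_s must divide the dispersive-phase duration")
    lost = np.zeros(len(pos), dtype=bool)
    xmax = grid.nx * grid.cell_size_km
    ymax = grid.ny * grid.cell_size_km
    land = grid.land_mask

    for _ in range(n_steps):
        active = ~lost
        if not active.any():
            break
        new = _rk4_step(u, v, pos[active], dt_s, grid.cell_size_km)
        out = (
            (new[:, 0] < 0) | (new[:, 0] >= xmax)
            | (new[:, 1] < 0) | (new[:, 1] >= ymax)
        )
        col = np.clip(np.floor(new[:, 0] / grid.cell_size_km).astype(int), 0, grid.nx - 1)
        row = np.clip(np.floor(new[:, 1] / grid.cell_size_km).astype(int), 0, grid.ny - 1)
        on_land = land[row, col] & ~out
        accept = ~(out | on_land)
        idx = np.flatnonzero(active)
        pos[idx[accept]] = new[accept]
        lost[idx[out]] = True
    return pos, lost


def advect_particle(
    field: VelocityField,
    grid: SeascapeGrid,
    start_xy_km: tuple[float, float],
    pld_days: float = 5.0,
    dt_s: float = 3600.0,
    time_index: int = 0,
) -> np.ndarray:
    """Advect a single particle and return its end position (km).

    Raises if the start position is on land or outside the domain.
    """
    cell = grid.cell_of_position(np.asarray(start_xy_km))
    cell = int(np.asarray(cell).ravel()[0])
    if cell < 0:
        raise ValueError("start position outside the domain")
    if grid.land_mask.ravel()[cell]:
        raise ValueError("start position on a land cell")
    u, v = field.slice(time_index)
    end, _ = _advect(grid, u, v, np.asarray([start_xy_km], dtype=float), pld_days, dt_s)
    return end[0]


# ---------------------------------------------------------------------------
# ensemble release + settlement
# ---------------------------------------------------------------------------

_NEIGHBORHOOD = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]


def _settle(grid: SeascapeGrid, end_xy: np.ndarray, lost: np.ndarray) -> np.ndarray:
    """Settlement rule: habitat cell containing the end position; else the
    nearest habitat cell within a 1-cell radius; else LOST."""
    dest = np.full(len(end_xy), LOST, dtype=int)
    cells = np.asarray(grid.cell_of_position(end_xy)).ravel()
    habitat = grid.habitat_mask
    ok = ~lost & (cells >= 0)
    rows, cols = grid.cell_rowcol(np.where(cells < 0, 0, cells))

    in_habitat = ok & habitat[rows, cols]
    dest[in_habitat] = cells[in_habitat]

    for k in np.flatnonzero(ok & ~in_habitat):
        r, c = int(rows[k]), int(cols[k])
        best, best_d2 = LOST, np.inf
        for dr, dc in _NEIGHBORHOOD:
            rr, cc = r + dr, c + dc
            if 0 <= rr < grid.ny and 0 <= cc < grid.nx and habitat[rr, cc]:
                cx = (cc + 0.5) * grid.cell_size_km
                cy = (rr + 0.5) * grid.cell_size_km
                d2 = (end_xy[k, 0] - cx) ** 2 + (end_xy[k, 1] - cy) ** 2
                cand = rr * grid.nx + cc
                if d2 < best_d2 - 1e-12 or (np.isclose(d2, best_d2) and cand < best):
                    best, best_d2 = cand, d2
        dest[k] = best
    return dest


def run_dispersal(
    grid: SeascapeGrid,
    field: VelocityField,
    schedule: ReleaseSchedule | None = None,
    seed: int | None = None,
) -> ParticleEnsemble:
    """Release, advect and settle particles from every habitat cell.

    One release per month in the seasonal window; each release uses the
    velocity slice ``release_index % field.n_times``.  Reproducible by
    ``seed`` (sub-cell jitter is the only randomness).
    """
    schedule = schedule or ReleaseSchedule()
    hab = grid.habitat_cells
    if hab.size == 0:
        raise ValueError("habitat is empty")
    rng = np.random.default_rng(seed)
    cs = grid.cell_size_km
    frames = []
    pid0 = 0
    for rel_idx, _month in enumerate(schedule.release_months):
        n = hab.size * schedule.particles_per_cell
        src = np.repeat(hab, schedule.particles_per_cell)
        rows, cols = grid.cell_rowcol(src)
        jitter = rng.uniform(0.0, 1.0, size=(n, 2))
        start = np.stack([(cols + jitter[:, 0]) * cs, (rows + jitter[:, 1]) * cs], axis=1)
        u, v = field.slice(rel_idx)
        end, lost = _advect(grid, u, v, start, schedule.pld_days, schedule.dt_s)
        dest = _settle(grid, end, lost)
        frames.append(pd.DataFrame({
            "particle_id": np.arange(pid0, pid0 + n),
            "src_cell": src,
            "release_index": rel_idx,
            "end_x_km": end[:, 0],
            "end_y_km": end[:, 1],
            "dest_cell": dest,
            "lost": dest == LOST,
        }))
        pid0 += n
    table = pd.concat(frames, ignore_index=True)
    return ParticleEnsemble(table=table, meta={
        "seed": seed,
        "pld_days": schedule.pld_days,
        "dt_s": schedule.dt_s,
        "particles_per_cell": schedule.particles_per_cell,
        "release_months": tuple(schedule.release_months),
    })


def ensemble_to_connectivity(ensemble: ParticleEnsemble, grid: SeascapeGrid) -> ConnectivityMatrix:
    """Normalize settled counts into a single-generation dispersal matrix.

    Element (i, j) = particles released at habitat cell i that settled in
    habitat cell j, divided by particles released at i.  Row sums are <= 1;
    the deficit is the lost fraction.
    """
    if len(ensemble) == 0:
        raise ValueError("empty particle ensemble")
    hab = grid.habitat_cells
    n = hab.size
    lookup = np.full(grid.nx * grid.ny, -1, dtype=int)
    lookup[hab] = np.arange(n)
    src = lookup[ensemble.table["src_cell"].to_numpy()]
    dst_cells = ensemble.table["dest_cell"].to_numpy()
    counts = np.zeros((n, n))
    released = np.bincount(src, minlength=n).astype(float)
    settled = dst_cells != LOST
    np.add.at(counts, (src[settled], lookup[dst_cells[settled]]), 1.0)
    if np.any(released == 0):
        missing = hab[released == 0]
        raise ValueError(f"habitat cells with zero released particles: {missing.tolist()}")
    values = counts / released[:, None]
    return ConnectivityMatrix(
        values=values,
        node_ids=[int(c) for c in hab],
        generations=1,
        meta={"released_per_cell": released.tolist(), **ensemble.meta},
    )
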