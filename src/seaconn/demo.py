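"""Bundled demo seascape: a multi-basin coastal domain with 31 sites.

The demo world is an abstract stand-in for a brackish marginal sea: a
600 × 400 km basin with a land frame, two peninsulas dividing it into three
sub-basins connected only across the top, a shallow coastal habitat band
(depth < 30 m within ~2 cells of land), one wind-driven gyre per sub-basin
plus a connecting jet and weak eddy noise, and a monotone salinity decline
from the oceanic end (x = 0) to the inner end.

Thirty-one sampling sites line the coast in five regions (W 9, SBA 6,
SBO 2, FBO 7, GFE 7 — the region sizes of a typical multi-basin survey),
listed in colonization order from the high-salinity entrance inward; 14
sites are flagged as MPAs.  Summer/winter salinity are deliberately
collinear so that the VIF screen in the environment regression has real
work to do.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import SeascapeGrid, assign_environment, build_grid
from .velocity import CoastalCurrent, Gyre, Jet, NoiseField, VelocityField, make_velocity_field

DEMO_NX = 60
DEMO_NY = 40
DEMO_CELL_KM = 10.0

# (region, number of sites); order = coastal path = colonization order
REGION_SIZES = (("W", 9), ("SBA", 6), ("SBO", 2), ("FBO", 7), ("GFE", 7))

# nominal site positions (km) along the coast, in path order
_SITE_POSITIONS = {
    # W: western basin, down the west coast and along the south shore
    "W-1": (15, 330), "W-2": (15, 260), "W-3": (15, 190), "W-4": (15, 120),
    "W-5": (15, 50), "W-6": (60, 15), "W-7": (110, 15), "W-8": (160, 15),
    "W-9": (185, 60),
    # SBA: along the southern shore of the middle basin
    "SBA-1": (215, 60), "SBA-2": (235, 15), "SBA-3": (280, 15),
    "SBA-4": (330, 15), "SBA-5": (380, 15), "SBA-6": (395, 60),
    # SBO: up the eastern flank of the first peninsula
    "SBO-1": (215, 250), "SBO-2": (215, 320),
    # FBO: along the northern coast
    "FBO-1": (260, 385), "FBO-2": (315, 385), "FBO-3": (370, 385),
    "FBO-4": (425, 385), "FBO-5": (480, 385), "FBO-6": (535, 385),
    "FBO-7": (585, 330),
    # GFE: down the eastern coast and along the inner southern shore
    "GFE-1": (585, 260), "GFE-2": (585, 190), "GFE-3": (585, 120),
    "GFE-4": (585, 50), "GFE-5": (540, 15), "GFE-6": (480, 15),
    "GFE-7": (425, 15),
}

_MPA_EVERY_OTHER = 14  # odd path indices 1,3,...,27


def demo_land_mask(nx: int = DEMO_NX, ny: int = DEMO_NY) -> np.ndarray:
    """Land frame plus two peninsulas reaching up from the southern shore."""
    land = np.zeros((ny, nx), dtype=bool)
    land[0, :] = land[-1, :] = True
    land[:, 0] = land[:, -1] = True
    wall_top = int(ny * 0.6)
    for wall_col in (nx // 3, 2 * nx // 3):
        land[1:wall_top, wall_col] = True
    return land


def build_demo_grid(
    nx: int = DEMO_NX, ny: int = DEMO_NY, cell_size_km: float = DEMO_CELL_KM
) -> SeascapeGrid:
    """Demo bathymetry: depth grows with distance from the nearest coast,
    leaving a shallow (< 30 m) habitat band about two cells wide."""
    land = demo_land_mask(nx, ny)
    dist_cells = ndimage.distance_transform_edt(~land)
    depth = np.where(land, 0.0, 4.0 + 12.0 * dist_cells)
    grid = build_grid(nx=nx, ny=ny, cell_size_km=cell_size_km,
                      depth_m=depth, land_mask=land)
    grid = assign_environment(grid, "salinity_psu", axis="x", start=25.0, end=3.0)
    grid = assign_environment(grid, "temperature_C", axis="y", start=16.0, end=12.0)
    return grid


def build_demo_field(grid: SeascapeGrid, seed: int | None = None) -> VelocityField:
    """One gyre per sub-basin, a jet along the open northern corridor, and
    weak divergence-free eddy noise."""
    Lx = grid.nx * grid.cell_size_km
    Ly = grid.ny * grid.cell_size_km
    components = [
        CoastalCurrent(speed_m_s=0.25, width_km=30.0),
        Gyre(center_km=(Lx / 6, Ly * 0.45), amplitude_m2_s=4e3, sigma_km=60.0),
        Gyre(center_km=(Lx / 2, Ly * 0.45), amplitude_m2_s=-4e3, sigma_km=60.0),
        Gyre(center_km=(5 * Lx / 6, Ly * 0.45), amplitude_m2_s=4e3, sigma_km=60.0),
        Jet(axis="x", position_km=Ly * 0.87, width_km=30.0, speed_m_s=0.15),
        NoiseField(amplitude_m_s=0.06, length_scale_km=40.0),
    ]
    return make_velocity_field(grid, components, seed=seed, n_times=1)


def demo_site_table(grid: SeascapeGrid, patch_radius_km: float = 35.0) -> tuple[pd.DataFrame, dict]:
    """31-site metadata table and site → habitat-cell mapping.

    Each site is anchored at the habitat cell nearest its nominal position
    and represented by the patch of habitat cells within ``patch_radius_km``
    of the anchor (a one-generation dispersal matrix between distant single
    cells would be unresolvably sparse).  Environmental covariates are read
    off the grid fields at the anchor cell.  Returns ``(sites, site_cells)``
    where ``site_cells`` maps site_id to its habitat-cell patch.
    """
    hab = grid.habitat_cells
    centers = grid.cell_center_km(hab)
    rows = []
    site_cells: dict[str, list[int]] = {}
    cum_dist = 0.0
    prev_xy = None
    for k, (site, (x, y)) in enumerate(_SITE_POSITIONS.items()):
        d2 = (centers[:, 0] - x) ** 2 + (centers[:, 1] - y) ** 2
        cell = int(hab[np.argmin(d2)])
        anchor = grid.cell_center_km(cell)
        patch_d2 = ((centers[:, 0] - anchor[0]) ** 2
                    + (centers[:, 1] - anchor[1]) ** 2)
        patch = hab[patch_d2 <= patch_radius_km**2]
        cx, cy = grid.cell_center_km(cell)
        if prev_xy is not None:
            cum_dist += float(np.hypot(cx - prev_xy[0], cy - prev_xy[1]))
        prev_xy = (cx, cy)
        r, c = grid.cell_rowcol(cell)
        sal_summer = float(grid.salinity_psu[r, c])
        temp_summer = float(grid.temperature_C[r, c])
        rows.append({
            "site_id": site,
            "x_km": float(cx), "y_km": float(cy),
            "region": site.split("-")[0],
            "salinity_psu": sal_summer,
            "temp_C": temp_summer,
            "mpa": int(k % 2 == 1),
            "salinity_summer": sal_summer,
            # winter salinity: nearly collinear with summer (VIF-screen fodder)
            "salinity_winter": 0.85 * sal_summer - 0.5 + 0.15 * np.sin(2.7 * k),
            "temp_summer": temp_summer,
            # winter temperature: correlated but retainable (VIF < 3)
            "temp_winter": 1.5 + 0.18 * temp_summer + 0.25 * np.cos(1.9 * k),
            "coast_dist_km": cum_dist,
        })
        site_cells[site] = [int(c) for c in patch]
    sites = pd.DataFrame(rows).set_index("site_id")
    return sites, site_cells


def demo_env_covariates(sites: pd.DataFrame) -> pd.DataFrame:
    """Covariate table for the He ~ environment regression."""
    cols = ["salinity_summer", "salinity_winter", "temp_summer",
            "temp_winter", "mpa", "coast_dist_km"]
    return sites[cols].astype(float)


def colonization_order(sites: pd.DataFrame) -> list[int]:
    """Deme indices in colonization order (table order = coastal path)."""
    return list(range(len(sites)))
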