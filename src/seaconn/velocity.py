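"""Synthetic surface velocity fields.

Stands in for an ocean circulation model: the field is a sum of analytic
components (gyres, jets, divergence-free noise) evaluated on cell centers.
Rotational components are derived from a streamfunction by central
differences, which makes their central-difference divergence vanish
identically on interior cells; velocities are zeroed on land.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .grid import SeascapeGrid

# Default seasonal release window: April..September (month numbers).
DEFAULT_RELEASE_MONTHS = (4, 5, 6, 7, 8, 9)


@dataclass
class Gyre:
    """Gaussian-streamfunction gyre: psi = amplitude * exp(-r^2 / (2 sigma^2)).

    ``amplitude`` is the streamfunction peak in m^2/s; positive spins
    counter-clockwise.  ``sigma_km`` sets the gyre radius.
    """

    center_km: tuple[float, float]
    amplitude_m2_s: float
    sigma_km: float


@dataclass
class SolidBodyGyre:
    """Solid-body rotation: u = -omega (y - cy), v = omega (x - cx).

    Evaluated analytically (exactly linear in position), so bilinear
    interpolation reproduces it without discretization error.  ``omega_per_s``
    is the angular velocity; positive counter-clockwise.  ``radius_km``
    optionally truncates the rotation outside that radius.
    """

    center_km: tuple[float, float]
    omega_per_s: float
    radius_km: float | None = None


@dataclass
class Jet:
    """Uni-directional channel jet with a Gaussian cross-profile.

    ``axis`` is the flow direction ('x' or 'y'); the jet is centered at
    ``position_km`` on the transverse coordinate with e-folding ``width_km``
    and peak ``speed_m_s``.
    """

    axis: str
    position_km: float
    width_km: float
    speed_m_s: float


@dataclass
class CoastalCurrent:
    """Boundary-following current: streamfunction decays with distance to land.

    psi = speed * width * exp(-d / width) with d the distance to the nearest
    land cell, so flow follows iso-distance contours alongshore with peak
    speed ~``speed_m_s`` at the coast.  Positive speed circulates
    counter-clockwise around land.
    """

    speed_m_s: float
    width_km: float = 25.0


@dataclass
class NoiseField:
    """Divergence-free random eddies from a smoothed random streamfunction.

    ``amplitude_m_s`` scales the resulting rms speed; ``length_scale_km``
    sets the smoothing (eddy) scale.  Reproducible via the field seed.
    """

    amplitude_m_s: float
    length_scale_km: float = 50.0


Component = Gyre | SolidBodyGyre | Jet | CoastalCurrent | NoiseField


@dataclass
class VelocityField:
    """Surface velocities (m/s) on cell centers, one slice per time index.

    ``u``/``v`` have shape ``(n_times, ny, nx)``.  ``release_months`` is
    seasonal metadata (the drift layer is the single surface layer; there is
    no vertical dimension).
    """

    u: np.ndarray
    v: np.ndarray
    cell_size_km: float
    release_months: tuple[int, ...] = DEFAULT_RELEASE_MONTHS
    layer: str = "surface"
    meta: dict = dc_field(default_factory=dict)

    @property
    def n_times(self) -> int:
        return self.u.shape[0]

    def slice(self, t: int) -> tuple[np.ndarray, np.ndarray]:
        t = int(t) % self.n_times
        return self.u[t], self.v[t]


def _grid_centers(grid: SeascapeGrid) -> tuple[np.ndarray, np.ndarray]:
    cs = grid.cell_size_km
    x = (np.arange(grid.nx) + 0.5) * cs
    y = (np.arange(grid.ny) + 0.5) * cs
    return np.meshgrid(x, y)


def _uv_from_streamfunction(psi: np.ndarray, cell_size_m: float) -> tuple[np.ndarray, np.ndarray]:
    """u = -dpsi/dy, v = dpsi/dx by central differences (one-sided at edges)."""
    dpsi_dy = np.gradient(psi, cell_size_m, axis=0)
    dpsi_dx = np.gradient(psi, cell_size_m, axis=1)
    return -dpsi_dy, dpsi_dx


def make_velocity_field(
    grid: SeascapeGrid,
    components: list[Component],
    seed: int | None = None,
    n_times: int = 1,
    release_months: tuple[int, ...] = DEFAULT_RELEASE_MONTHS,
) -> VelocityField:
    """Superpose velocity components on the grid and zero them on land.

    Stochastic components (``NoiseField``) are drawn independently per time
    slice from a generator seeded with ``seed``; the result is fully
    reproducible.
    """
    X, Y = _grid_centers(grid)
    cs_m = grid.cell_size_km * 1000.0
    rng = np.random.default_rng(seed)

    u = np.zeros((n_times, grid.ny, grid.nx))
    v = np.zeros_like(u)
    for t in range(n_times):
        for comp in components:
            if isinstance(comp, SolidBodyGyre):
                cx, cy = comp.center_km
                dx_m = (X - cx) * 1000.0
                dy_m = (Y - cy) * 1000.0
                cu = -comp.omega_per_s * dy_m
                cv = comp.omega_per_s * dx_m
                if comp.radius_km is not None:
                    r = np.hypot(X - cx, Y - cy)
                    inside = r <= comp.radius_km
                    cu = np.where(inside, cu, 0.0)
                    cv = np.where(inside, cv, 0.0)
            elif isinstance(comp, Gyre):
                cx, cy = comp.center_km
                r2 = ((X - cx) ** 2 + (Y - cy) ** 2) * 1e6  # m^2
                sig2 = (comp.sigma_km * 1000.0) ** 2
                psi = comp.amplitude_m2_s * np.exp(-r2 / (2.0 * sig2))
                cu, cv = _uv_from_streamfunction(psi, cs_m)
            elif isinstance(comp, Jet):
                if comp.axis not in ("x", "y"):
                    raise ValueError("jet axis must be 'x' or 'y'")
                transverse = Y if comp.axis == "x" else X
                profile = comp.speed_m_s * np.exp(
                    -(((transverse - comp.position_km) / comp.width_km) ** 2)
                )
                cu, cv = (profile, np.zeros_like(profile)) if comp.axis == "x" else (
                    np.zeros_like(profile), profile)
            elif isinstance(comp, CoastalCurrent):
                from scipy import ndimage
                dist_km = ndimage.distance_transform_edt(~grid.land_mask) * grid.cell_size_km
                width_m = comp.width_km * 1000.0
                psi = comp.speed_m_s * width_m * np.exp(-dist_km / comp.width_km)
                cu, cv = _uv_from_streamfunction(psi, cs_m)
            elif isinstance(comp, NoiseField):
                psi = _noise_streamfunction(grid, comp, rng)
                cu, cv = _uv_from_streamfunction(psi, cs_m)
            else:
                raise TypeError(f"unknown velocity component {comp!r}")
            if not (np.all(np.isfinite(cu)) and np.all(np.isfinite(cv))):
                raise ValueError("velocity component produced non-finite values")
            u[t] += cu
            v[t] += cv

    u[:, grid.land_mask] = 0.0
    v[:, grid.land_mask] = 0.0
    return VelocityField(
        u=u, v=v, cell_size_km=grid.cell_size_km,
        release_months=tuple(release_months),
        meta={"seed": seed, "n_components": len(components)},
    )


def _noise_streamfunction(grid: SeascapeGrid, comp: NoiseField, rng: np.random.Generator) -> np.ndarray:
    """Random streamfunction smoothed with a Gaussian kernel via FFT."""
    white = rng.standard_normal((grid.ny, grid.nx))
    ky = np.fft.fftfreq(grid.ny, d=grid.cell_size_km)
    kx = np.fft.fftfreq(grid.nx, d=grid.cell_size_km)
    KX, KY = np.meshgrid(kx, ky)
    k2 = KX**2 + KY**2
    kernel = np.exp(-2.0 * (np.pi * comp.length_scale_km) ** 2 * k2)
    psi = np.real(np.fft.ifft2(np.fft.fft2(white) * kernel))
    rms = np.sqrt(np.mean(psi**2)) or 1.0
    # scale so the derived speed is of order amplitude_m_s
    psi *= comp.amplitude_m_s * comp.length_scale_km * 1000.0 / rms
    return psi


def divergence(u: np.ndarray, v: np.ndarray, cell_size_m: float) -> np.ndarray:
    """Central-difference divergence du/dx + dv/dy (oracle-facing helper)."""
    return np.gradient(u, cell_size_m, axis=1) + np.gradient(v, cell_size_m, axis=0)
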