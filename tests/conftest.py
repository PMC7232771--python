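"""Shared fixtures: small analytic worlds and a session-scoped tracked seascape."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from seaconn.connectivity import log_transform, multigen, site_connectivity, symmetrize
from seaconn.demo import build_demo_field, build_demo_grid, demo_site_table
from seaconn.genotypes import GenotypeDataset
from seaconn.grid import build_grid
from seaconn.tracking import ReleaseSchedule, ensemble_to_connectivity, run_dispersal


@pytest.fixture
def open_sea_grid():
    """20×16 all-sea grid, shallow everywhere (all cells habitat)."""
    return build_grid(nx=20, ny=16, cell_size_km=10.0, depth_m=10.0)


def make_dataset(geno_by_site: dict, loci: int | None = None) -> GenotypeDataset:
    """Dataset from {site: genotype rows}; minimal metadata."""
    samples, sample_site, rows = [], [], []
    for site, G in geno_by_site.items():
        G = np.asarray(G, dtype=np.int8)
        for k in range(G.shape[0]):
            samples.append(f"{site}_{k + 1:02d}")
            sample_site.append(site)
            rows.append(G[k])
    sites = pd.DataFrame(
        {"x_km": np.arange(len(geno_by_site), dtype=float)},
        index=list(geno_by_site),
    )
    return GenotypeDataset(
        genotypes=np.asarray(rows, dtype=np.int8),
        samples=samples,
        sample_site=pd.Series(sample_site, index=samples, name="site_id"),
        sites=sites,
    )


@pytest.fixture
def dataset_factory():
    return make_dataset


def island_matrix(d: int) -> np.ndarray:
    """Symmetric island model: uniform off-diagonal donors, zero diagonal."""
    C = np.full((d, d), 1.0 / (d - 1))
    np.fill_diagonal(C, 0.0)
    return C


@pytest.fixture
def island_model():
    return island_matrix


def chain_matrix(d: int, retention: float = 0.5, hop: float = 0.05) -> np.ndarray:
    """Linear stepping-stone chain: nearest-neighbour exchange only."""
    C = np.zeros((d, d))
    np.fill_diagonal(C, retention)
    for i in range(d - 1):
        C[i, i + 1] = C[i + 1, i] = hop
    return C


@pytest.fixture
def chain_model():
    return chain_matrix


class TrackedWorld:
    """Demo seascape tracked once and aggregated to 20 sites (shared)."""

    def __init__(self) -> None:
        self.grid = build_demo_grid()
        self.field = build_demo_field(self.grid, seed=5)
        self.ensemble = run_dispersal(
            self.grid, self.field, ReleaseSchedule(particles_per_cell=20), seed=6)
        self.conn = ensemble_to_connectivity(self.ensemble, self.grid)
        sites, cells = demo_site_table(self.grid)
        keep = [s for k, s in enumerate(sites.index) if k % 3 != 2][:20]
        self.sites = sites.loc[keep]
        self.site_cells = {s: cells[s] for s in keep}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.site_conn = site_connectivity(self.conn, self.site_cells)
            capped = multigen(self.conn, 64).capped
            self.site_log_conn = log_transform(
                symmetrize(site_connectivity(capped, self.site_cells), "mean"))


@pytest.fixture(scope="session")
def tracked_world():
    return TrackedWorld()
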