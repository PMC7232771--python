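"""Wright–Fisher stepping-stone genotype simulation driven by connectivity.

Each sampling site is a deme of constant effective size N.  Per generation
every deme draws a fraction ``m`` of its gamete pool from donor demes in
proportion to the *column-normalized incoming connectivity* (the dispersal
matrix is source→destination probability; normalizing each destination
column turns it into an immigrant mixture that sums to 1 even when rows lose
mass through the open boundary), and the remaining ``1 - m`` locally; the
next generation's allele frequencies are binomial draws of 2N gametes.
Loci are independent and biallelic; there is no mutation or selection.

An optional serial-founder schedule emulates a post-glacial colonization
front: a deme is inactive until its colonization generation, at which point
its frequencies are founded from a source deme through a bottleneck of
``founder_size`` diploids.  Downstream, expected heterozygosity declines
along the colonization order — the classic signature of serial founder
effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix

MISSING = -1


@dataclass
class FounderEvent:
    """Colonization of ``node`` at ``generation`` from ``source`` through a
    bottleneck of ``founder_size`` diploid founders."""

    node: int
    generation: int
    source: int
    founder_size: int = 10


@dataclass
class DemographyConfig:
    """Free demographic parameters of the simulation (not estimates).

    ``deme_size``: effective diploids per deme.  ``migration_rate``: total
    immigrant gamete fraction per generation, in [0, 1].  ``n_loci``
    independent biallelic loci; founder frequencies uniform in
    ``init_freq_range`` (default [0.1, 0.9], avoiding immediate fixation).
    ``missing_rate`` masks genotypes uniformly at random (0.2 mimics a
    RAD-seq call-rate floor of 80%).
    """

    deme_size: int = 100
    migration_rate: float = 0.1
    n_loci: int = 1000
    n_generations: int = 200
    n_sample_per_site: int = 20
    missing_rate: float = 0.0
    init_freq_range: tuple[float, float] = (0.1, 0.9)
    founder_schedule: list[FounderEvent] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.deme_size < 1:
            raise ValueError("deme_size must be a positive integer")
        if not 0.0 <= self.migration_rate <= 1.0:
            raise ValueError("migration_rate must be in [0, 1]")
        if self.n_loci < 1 or self.n_generations < 1:
            raise ValueError("n_loci and n_generations must be positive")
        lo, hi = self.init_freq_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("init_freq_range must satisfy 0 <= lo <= hi <= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class GenotypeDataset:
    """Diploid biallelic genotypes grouped into site samples.

    ``genotypes``: int8 array (n_individuals, n_loci) of alt-allele dosage
    0/1/2, with -1 as the missing sentinel.  ``samples``: individual ids in
    row order; ``sample_site``: site id per individual.  ``sites``: metadata
    table indexed by site_id (x_km, y_km, region, salinity_psu, temp_C, mpa).
    """

    genotypes: np.ndarray
    samples: list[str]
    sample_site: pd.Series
    sites: pd.DataFrame
    locus_ids: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n, L = self.genotypes.shape
        if len(self.samples) != n:
            raise ValueError("samples length does not match genotype rows")
        if not self.locus_ids:
            self.locus_ids = [f"L{k + 1}" for k in range(L)]
        if len(self.locus_ids) != L:
            raise ValueError("locus_ids length does not match genotype columns")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype dosages must be in {0, 1, 2} or -1 (missing)")
        missing_sites = set(self.sample_site) - set(self.sites.index)
        if missing_sites:
            raise ValueError(f"samples reference sites without metadata: {sorted(missing_sites)}")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def site_ids(self) -> list:
        return list(self.sites.index)

    def site_rows(self, site_id) -> np.ndarray:
        """Row indices of the individuals sampled at ``site_id``."""
        return np.flatnonzero((self.sample_site == site_id).to_numpy())


def _immigrant_weights(C: np.ndarray) -> np.ndarray:
    """Column-normalized incoming connectivity W; W[:, j] sums to 1.

    Self-recruitment (the diagonal) is excluded: local retention is already
    the ``1 - m`` share of the gamete pool, so the immigrant mixture is
    built from other demes only.  Demes with zero incoming connectivity are
    treated as isolated (their immigrant pool is themselves) with a warning.
    """
    C = C - np.diag(np.diag(C))
    colsum = C.sum(axis=0)
    W = np.zeros_like(C, dtype=float)
    ok = colsum > 0
    W[:, ok] = C[:, ok] / colsum[ok]
    if np.any(~ok):
        warnings.warn(
            f"demes with zero incoming connectivity treated as isolated: "
            f"{np.flatnonzero(~ok).tolist()}",
            stacklevel=3,
        )
        W[~ok, ~ok] = 1.0
    return W


def simulate_genotypes(
    conn: ConnectivityMatrix | np.ndarray,
    demo: DemographyConfig,
    sites: pd.DataFrame,
    site_nodes: dict | None = None,
) -> GenotypeDataset:
    """Simulate site samples under connectivity-structured drift-migration.

    Parameters
    ----------
    conn:
        Square source→destination connectivity among demes (rows need not
        sum to 1; columns are renormalized into immigrant mixtures).
    demo:
        Demographic parameters; the single RNG stream is seeded from
        ``demo.seed`` so identical configs reproduce identical datasets.
    sites:
        Site metadata table indexed by site_id, one row per deme.
    site_nodes:
        Optional site_id → deme (row of ``conn``) mapping; defaults to table
        order.
    """
    C = conn.values if isinstance(conn, ConnectivityMatrix) else np.asarray(conn, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("connectivity must be square")
    d = C.shape[0]
    site_ids = list(sites.index)
    if site_nodes is None:
        if len(site_ids) != d:
            raise ValueError(
                f"{len(site_ids)} sites but {d} connectivity nodes; pass site_nodes")
        site_nodes = {s: k for k, s in enumerate(site_ids)}
    node_of = np.asarray([site_nodes[s] for s in site_ids], dtype=int)

    rng = np.random.default_rng(demo.seed)
    W = _immigrant_weights(C)
    m = demo.migration_rate
    N = demo.deme_size
    L = demo.n_loci

    # shared ancestral frequencies per locus (one panmictic origin)
    lo, hi = demo.init_freq_range
    p0 = rng.uniform(lo, hi, size=L)
    p = np.tile(p0, (d, 1))

    schedule = {ev.generation: [] for ev in (demo.founder_schedule or [])}
    for ev in demo.founder_schedule or []:
        schedule[ev.generation].append(ev)
    active = np.ones(d, dtype=bool)
    if demo.founder_schedule:
        colonized = {ev.node for ev in demo.founder_schedule}
        active = ~np.isin(np.arange(d), list(colonized))
        if not active.any():
            raise ValueError("founder schedule leaves no initially active deme")

    for g in range(demo.n_generations):
        for ev in schedule.get(g, ()):
            if not active[ev.source]:
                raise ValueError(
                    f"founder event at generation {g}: source deme {ev.source} "
                    "not yet colonized")
            nf = 2 * ev.founder_size
            p[ev.node] = rng.binomial(nf, p[ev.source]) / nf
            active[ev.node] = True
        # immigrant pools restricted to active donors, renormalized
        Wa = W * active[:, None]
        colsum = Wa.sum(axis=0)
        has_donor = colsum > 0
        Wa[:, has_donor] /= colsum[has_donor]
        pool = Wa.T @ p
        p_next = np.where((active & has_donor)[:, None], (1 - m) * p + m * pool, p)
        p = np.where(active[:, None], rng.binomial(2 * N, p_next) / (2.0 * N), p)

    # sample diploid individuals per site under within-deme random mating
    n_ind = demo.n_sample_per_site
    geno = np.empty((len(site_ids) * n_ind, L), dtype=np.int8)
    samples, sample_site = [], []
    for k, s in enumerate(site_ids):
        geno[k * n_ind:(k + 1) * n_ind] = rng.binomial(2, p[node_of[k]], size=(n_ind, L))
        samples.extend(f"{s}_{j + 1:02d}" for j in range(n_ind))
        sample_site.extend([s] * n_ind)
    if demo.missing_rate > 0:
        mask = rng.random(geno.shape) < demo.missing_rate
        geno[mask] = MISSING

    return GenotypeDataset(
        genotypes=geno,
        samples=samples,
        sample_site=pd.Series(sample_site, index=samples, name="site_id"),
        sites=sites,
        meta={
            "seed": demo.seed,
            "deme_size": N,
            "migration_rate": m,
            "n_generations": demo.n_generations,
            "final_freqs": p,
        },
    )


def serial_founder_schedule(
    order: list[int],
    interval: int = 10,
    founder_size: int = 10,
    start_generation: int = 1,
) -> list[FounderEvent]:
    """Chain colonization along ``order``: order[0] is the ancestral deme;
    each subsequent deme is founded from its predecessor ``interval``
    generations later."""
    events = []
    for k in range(1, len(order)):
        events.append(FounderEvent(
            node=order[k],
            generation=start_generation + (k - 1) * interval,
            source=order[k - 1],
            founder_size=founder_size,
        ))
    return events
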