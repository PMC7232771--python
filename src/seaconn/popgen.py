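"""Population-genetic summary statistics.

Implements the sample-level statistics of the analysis chain: per-site
allele frequencies, unbiased expected heterozygosity and F_IS, pairwise
Weir–Cockerham (1984) F_ST (multilocus ratio-of-averages, the GENEPOP
convention), Fisher exact tests of genic differentiation combined across
loci by Fisher's method, individual identity-by-state distances, and
classical metric MDS (principal coordinates) of distance matrices.

Missing genotypes are handled pairwise-complete per locus; per-pair locus
counts are reported.  F_ST values are not clamped (small negative estimates
are a property of the estimator); clamping to zero happens only when a
matrix is used as a distance, i.e. inside :func:`metric_mds`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeDataset


@dataclass
class PairwiseStatMatrix:
    """Symmetric per-pair statistic over sites or individuals."""

    values: np.ndarray
    ids: list
    statistic: str
    n_loci: np.ndarray | None = None  # per-pair loci used
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != self.values.shape[1]:
            raise ValueError("pairwise matrix must be square")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("pairwise matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


# ---------------------------------------------------------------------------
# per-site per-locus sufficient statistics
# ---------------------------------------------------------------------------

def _site_locus_stats(dataset: GenotypeDataset, site) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n non-missing individuals, alt frequency, observed het fraction)
    per locus for one site; frequency/het are NaN where no data."""
    rows = dataset.site_rows(site)
    if rows.size == 0:
        raise KeyError(f"unknown or empty site {site!r}")
    G = dataset.genotypes[rows]
    present = G != MISSING
    n = present.sum(axis=0).astype(float)
    alt = np.where(present, G, 0).sum(axis=0)
    het = (G == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
        h = np.where(n > 0, het / n, np.nan)
    return n, p, h


def allele_freqs(dataset: GenotypeDataset, site) -> pd.DataFrame:
    """Sample alt-allele frequency and allele count per locus at one site.

    ``p_alt = alt dosage sum / (2 × non-missing individuals)``; loci with no
    genotyped individual are flagged ``all_missing`` (frequency NaN).
    """
    n, p, _ = _site_locus_stats(dataset, site)
    return pd.DataFrame({
        "locus_id": dataset.locus_ids,
        "p_alt": p,
        "n_alleles": (2 * n).astype(int),
        "all_missing": n == 0,
    })


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def diversity(dataset: GenotypeDataset, min_individuals: int = 2) -> pd.DataFrame:
    """Per-site diversity table: He, Ho, FIS, sample size.

    Per locus the unbiased expected heterozygosity is
    ``He = (2n / (2n - 1)) * (1 - p^2 - q^2)`` with ``n`` the genotyped
    individuals; the site value is the mean over loci with data
    (monomorphic loci contribute He = 0).  ``FIS = 1 - Ho/He`` is averaged
    over polymorphic loci only.  At exact Hardy–Weinberg proportions the
    unbiased-He convention leaves a small positive bias of order 1/(2n).
    """
    rows = []
    for site in dataset.site_ids:
        idx = dataset.site_rows(site)
        if idx.size < min_individuals:
            raise ValueError(f"site {site!r} has {idx.size} individuals (< {min_individuals})")
        n, p, ho = _site_locus_stats(dataset, site)
        has_data = n > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            he = (2 * n / (2 * n - 1)) * (1 - p**2 - (1 - p) ** 2)
        poly = has_data & (he > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            fis_loc = 1.0 - ho[poly] / he[poly]
        rows.append({
            "site_id": site,
            "n_individuals": int(idx.size),
            "he": float(np.mean(he[has_data])),
            "ho": float(np.mean(ho[has_data])),
            "fis": float(np.mean(fis_loc)) if poly.any() else np.nan,
            "n_loci": int(has_data.sum()),
            "n_polymorphic": int(poly.sum()),
        })
    return pd.DataFrame(rows).set_index("site_id")


# ---------------------------------------------------------------------------
# Weir–Cockerham FST
# ---------------------------------------------------------------------------

def _wc_components(n1, p1, h1, n2, p2, h2):
    """Weir–Cockerham (1984) variance components a, b, c for two samples,
    vectorized over loci.  Loci without data in both samples return 0 and
    are flagged invalid."""
    valid = (n1 > 0) & (n2 > 0)
    n1 = np.where(valid, n1, 1.0)
    n2 = np.where(valid, n2, 1.0)
    p1 = np.where(valid, p1, 0.0)
    p2 = np.where(valid, p2, 0.0)
    h1 = np.where(valid, h1, 0.0)
    h2 = np.where(valid, h2, 0.0)

    r = 2.0
    nbar = (n1 + n2) / r
    # n̄ == 1 (one individual in each sample) leaves b undefined
    valid &= nbar > 1
    nbar = np.where(nbar > 1, nbar, 2.0)
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)

    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2.0
    zero = ~valid
    for arr in (a, b, c):
        arr[zero] = 0.0
    return a, b, c, valid


def fst_pair(dataset: GenotypeDataset, site_a, site_b) -> tuple[float, int]:
    """Multilocus Weir–Cockerham θ̂ for one site pair.

    Ratio of averages: ``θ̂ = Σ_l a_l / Σ_l (a_l + b_l + c_l)`` over loci
    genotyped in both samples.  Returns (θ̂, number of loci used).  May be
    slightly negative; raises if no shared polymorphic locus yields a
    nonzero denominator.
    """
    n1, p1, h1 = _site_locus_stats(dataset, site_a)
    n2, p2, h2 = _site_locus_stats(dataset, site_b)
    a, b, c, valid = _wc_components(n1, p1, h1, n2, p2, h2)
    denom = (a + b + c).sum()
    if denom == 0:
        raise ValueError(
            f"no shared polymorphic loci between {site_a!r} and {site_b!r}")
    return float(a.sum() / denom), int(valid.sum())


def pairwise_fst(dataset: GenotypeDataset) -> PairwiseStatMatrix:
    """Pairwise multilocus Weir–Cockerham F_ST over all site pairs."""
    sites = dataset.site_ids
    if len(sites) < 2:
        raise ValueError("pairwise FST needs at least two sites")
    stats_by_site = {s: _site_locus_stats(dataset, s) for s in sites}
    n = len(sites)
    out = np.zeros((n, n))
    used = np.zeros((n, n), dtype=int)
    for i in range(n):
        n1, p1, h1 = stats_by_site[sites[i]]
        for j in range(i + 1, n):
            n2, p2, h2 = stats_by_site[sites[j]]
            a, b, c, valid = _wc_components(n1, p1, h1, n2, p2, h2)
            denom = (a + b + c).sum()
            if denom == 0:
                raise ValueError(
                    f"no shared polymorphic loci between {sites[i]!r} and {sites[j]!r}")
            out[i, j] = out[j, i] = a.sum() / denom
            used[i, j] = used[j, i] = valid.sum()
    return PairwiseStatMatrix(values=out, ids=sites, statistic="fst_wc", n_loci=used)


# ---------------------------------------------------------------------------
# genic differentiation (Fisher exact + Fisher's method)
# ---------------------------------------------------------------------------

def genic_test(dataset: GenotypeDataset, site_a, site_b) -> tuple[pd.DataFrame, float]:
    """Exact test of allele-frequency differentiation for one site pair.

    Per locus, a two-sided Fisher exact test on the 2×2 allele-count table
    (ref/alt × site); loci monomorphic across both samples (or without data
    in either) are skipped.  Per-locus p-values are combined by Fisher's
    method (−2 Σ ln p against χ² with 2L degrees of freedom).  Returns
    (per-locus table, combined p).
    """
    n1, p1, _ = _site_locus_stats(dataset, site_a)
    n2, p2, _ = _site_locus_stats(dataset, site_b)
    alt1 = np.round(2 * n1 * np.nan_to_num(p1)).astype(int)
    alt2 = np.round(2 * n2 * np.nan_to_num(p2)).astype(int)
    ref1 = (2 * n1).astype(int) - alt1
    ref2 = (2 * n2).astype(int) - alt2
    usable = (n1 > 0) & (n2 > 0) & (alt1 + alt2 > 0) & (ref1 + ref2 > 0)
    if not usable.any():
        raise ValueError(f"no informative locus between {site_a!r} and {site_b!r}")

    records = []
    for l in np.flatnonzero(usable):
        _, p = stats.fisher_exact(
            [[ref1[l], alt1[l]], [ref2[l], alt2[l]]], alternative="two-sided")
        records.append({"locus_id": dataset.locus_ids[l], "p_value": p})
    table = pd.DataFrame(records)
    logs = np.log(np.clip(table["p_value"].to_numpy(), 1e-300, 1.0))
    x2 = -2.0 * logs.sum()
    combined = float(stats.chi2.sf(x2, df=2 * len(table)))
    return table, combined


# ---------------------------------------------------------------------------
# identity-by-state
# ---------------------------------------------------------------------------

def ibs_distance(dataset: GenotypeDataset) -> PairwiseStatMatrix:
    """Individual 1−IBS distance matrix.

    Per locus IBS between dosages d1, d2 is ``1 − |d1 − d2| / 2``; the
    distance is one minus the mean IBS over loci genotyped in both
    individuals.  Raises if some pair shares no genotyped locus.
    """
    G = dataset.genotypes
    n = G.shape[0]
    if n < 2:
        raise ValueError("IBS distance needs at least two individuals")
    ind = [(G == a).astype(np.float64) for a in (0, 1, 2)]
    counts = {}
    for a in range(3):
        for b in range(a, 3):
            counts[(a, b)] = ind[a] @ ind[b].T
    shared = sum(counts[(a, b)] + (counts[(a, b)].T if a != b else 0)
                 for a in range(3) for b in range(a, 3))
    same = counts[(0, 0)] + counts[(1, 1)] + counts[(2, 2)]
    near = counts[(0, 1)] + counts[(0, 1)].T + counts[(1, 2)] + counts[(1, 2)].T
    if np.any(shared[~np.eye(n, dtype=bool)] == 0):
        raise ValueError("some individual pair shares no genotyped locus")
    ibs = (same + 0.5 * near) / shared
    dist = 1.0 - ibs
    np.fill_diagonal(dist, 0.0)
    dist = 0.5 * (dist + dist.T)  # exact symmetry against fp jitter
    return PairwiseStatMatrix(
        values=dist, ids=list(dataset.samples), statistic="one_minus_ibs",
        n_loci=shared.astype(int),
    )


# ---------------------------------------------------------------------------
# metric MDS (classical scaling / PCoA)
# ---------------------------------------------------------------------------

def metric_mds(dist: PairwiseStatMatrix | np.ndarray, k_axes: int = 2):
    """Classical metric MDS by double-centering and eigen-decomposition.

    Negative entries (e.g. negative F_ST estimates) are clamped to 0 before
    scaling.  Returns ``(coordinates, variance_explained)`` where variance
    explained is each retained positive eigenvalue's share of the positive
    spectrum; coordinates are deterministic up to axis sign.
    """
    D = dist.values if isinstance(dist, PairwiseStatMatrix) else np.asarray(dist, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diagonal(D), 0.0):
        raise ValueError("distance matrix must have zero diagonal")
    D = np.clip(D, 0.0, None)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > max(1e-12, 1e-12 * abs(eigval[0]) if n else 0)
    n_pos = int(pos.sum())
    if n_pos == 0:
        # degenerate (e.g. all-zero) distance matrix: every point at the origin
        return np.zeros((n, k_axes)), np.zeros(k_axes)
    if k_axes > n_pos:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; truncating k_axes={k_axes}",
            stacklevel=2)
        k_axes = n_pos
    lam = eigval[:k_axes]
    coords = eigvec[:, :k_axes] * np.sqrt(lam)
    total = eigval[pos].sum()
    varexp = lam / total if total > 0 else np.zeros(k_axes)
    return coords, varexp
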