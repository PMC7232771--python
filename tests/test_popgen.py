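"""Population-genetic statistics against brute-force oracles.

The Weir–Cockerham oracle below is coded scalar-by-scalar straight from the
1984 variance-component definitions, independently of the vectorized
implementation it checks.
"""

import numpy as np
import pytest
from scipy import stats as sps
from scipy.special import comb

from seaconn.genotypes import MISSING
from seaconn.popgen import (
    allele_freqs,
    diversity,
    fst_pair,
    genic_test,
    ibs_distance,
    metric_mds,
    pairwise_fst,
)


# ---------------------------------------------------------------------------
# independent Weir–Cockerham oracle (two samples, one locus)
# ---------------------------------------------------------------------------

def wc_abc_oracle(geno1, geno2):
    """Variance components (a, b, c) from the definitions, one locus."""
    samples = []
    for geno in (geno1, geno2):
        geno = [g for g in geno if g != MISSING]
        n = len(geno)
        p = sum(geno) / (2 * n)
        h = sum(1 for g in geno if g == 1) / n
        samples.append((n, p, h))
    r = 2
    (n1, p1, h1), (n2, p2, h2) = samples
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


class TestAlleleFreqs:
    def test_counting_examples(self, dataset_factory):
        ds = dataset_factory({
            "A": [[0, 1, 2, MISSING],
                  [0, 1, 1, MISSING],
                  [0, 0, 0, MISSING]],
        })
        out = allele_freqs(ds, "A")
        assert out.p_alt.tolist()[:3] == [0.0, pytest.approx(1 / 3), 0.5]
        # {2,1,0} at locus 3: p = 3/6, six alleles called
        assert out.p_alt.iloc[2] == 0.5 and out.n_alleles.iloc[2] == 6
        assert out.all_missing.tolist() == [False, False, False, True]

    def test_unknown_site(self, dataset_factory):
        ds = dataset_factory({"A": [[0], [1]]})
        with pytest.raises(KeyError):
            allele_freqs(ds, "Z")


class TestDiversity:
    def test_monomorphic_he_zero(self, dataset_factory):
        ds = dataset_factory({"A": [[0, 2], [0, 2], [0, 2]]})
        out = diversity(ds)
        assert out.loc["A", "he"] == 0.0
        assert out.loc["A", "n_polymorphic"] == 0

    def test_unbiased_he_formula(self, dataset_factory):
        # 10 individuals, p = 0.5 → He = (20/19) * 0.5 ≈ 0.5263
        geno = [[1]] * 10
        out = diversity(dataset_factory({"A": geno}))
        assert out.loc["A", "he"] == pytest.approx(20 / 19 * 0.5, abs=1e-12)

    def test_fis_all_heterozygous(self, dataset_factory):
        geno = [[1]] * 10
        out = diversity(dataset_factory({"A": geno}))
        assert out.loc["A", "fis"] == pytest.approx(1 - 1 / (20 / 19 * 0.5), abs=1e-9)
        assert out.loc["A", "fis"] == pytest.approx(-0.9, abs=1e-9)

    def test_fis_near_zero_at_hardy_weinberg(self, dataset_factory):
        # exact HWE proportions at p = 0.5: 5 ref hom, 10 het, 5 alt hom;
        # the unbiased-He convention leaves a residual of exactly 1/(2n)
        geno = [[0]] * 5 + [[1]] * 10 + [[2]] * 5
        out = diversity(dataset_factory({"A": geno}))
        n = 20
        assert abs(out.loc["A", "fis"]) <= 1 / (2 * n) + 1e-12

    def test_too_few_individuals_rejected(self, dataset_factory):
        ds = dataset_factory({"A": [[0, 1]], "B": [[1, 1], [0, 2]]})
        with pytest.raises(ValueError, match="individuals"):
            diversity(ds)


class TestPairwiseFst:
    def test_fixed_alternate_alleles_give_one(self, dataset_factory):
        ds = dataset_factory({
            "A": [[0, 0, 0]] * 8,
            "B": [[2, 2, 2]] * 8,
        })
        fst = pairwise_fst(ds)
        assert fst.values[0, 1] == pytest.approx(1.0)

    def test_identical_samples_give_near_zero(self, dataset_factory):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.1, 0.9, size=400)
        G = rng.binomial(2, p, size=(20, 400))  # HWE draws
        ds = dataset_factory({"A": G, "B": G.copy()})
        theta = pairwise_fst(ds).values[0, 1]
        # no differentiation: at most small-sample noise, slightly negative
        assert theta <= 0.01
        assert abs(theta) <= 0.05

    def test_matches_component_oracle(self, dataset_factory):
        """Multilocus ratio-of-averages equals Σa / Σ(a+b+c) from the
        independent scalar oracle, to 1e-10."""
        rng = np.random.default_rng(7)
        G1 = rng.integers(0, 3, size=(12, 30))
        G2 = rng.integers(0, 3, size=(9, 30))
        G1[rng.random(G1.shape) < 0.1] = MISSING
        G2[rng.random(G2.shape) < 0.1] = MISSING
        ds = dataset_factory({"A": G1, "B": G2})
        theta, n_used = fst_pair(ds, "A", "B")
        num = den = 0.0
        for l in range(30):
            a, b, c = wc_abc_oracle(G1[:, l], G2[:, l])
            num += a
            den += a + b + c
        assert theta == pytest.approx(num / den, abs=1e-10)
        assert n_used == 30

    def test_symmetric_and_relabel_invariant(self, dataset_factory):
        rng = np.random.default_rng(3)
        G1 = rng.integers(0, 3, size=(10, 50))
        G2 = rng.integers(0, 3, size=(10, 50))
        ds = dataset_factory({"A": G1, "B": G2})
        shuffled = dataset_factory({"A": G1[::-1], "B": G2[::-1]})
        f1 = pairwise_fst(ds)
        f2 = pairwise_fst(shuffled)
        assert f1.values[0, 1] == f1.values[1, 0]
        assert f1.values[0, 1] == pytest.approx(f2.values[0, 1], abs=1e-14)

    def test_fst_decreases_with_migration(self, island_model):
        """Island-model mean FST is monotone decreasing in m (3-point grid)."""
        import pandas as pd
        import warnings
        from seaconn.genotypes import DemographyConfig, simulate_genotypes
        means = []
        for m in (0.005, 0.02, 0.08):
            vals = []
            for seed in range(3):
                demo = DemographyConfig(deme_size=50, migration_rate=m,
                                        n_loci=400, n_generations=300,
                                        seed=7000 + seed)
                sites = pd.DataFrame({"x": np.zeros(4)},
                                     index=[f"S{i}" for i in range(4)])
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    ds = simulate_genotypes(island_model(4), demo, sites)
                f = pairwise_fst(ds)
                vals.append(f.values[~np.eye(4, dtype=bool)].mean())
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]


class TestGenicTest:
    def test_identical_tables_give_p_one(self, dataset_factory):
        # both sites: 5 ref / 5 alt alleles at each locus
        geno = [[1], [1], [1], [1], [1]]
        ds = dataset_factory({"A": geno, "B": list(geno)})
        table, combined = genic_test(ds, "A", "B")
        assert table.p_value.iloc[0] == pytest.approx(1.0)
        assert combined == pytest.approx(1.0)

    def test_complete_separation_matches_hypergeometric(self, dataset_factory):
        """[[10,0],[0,10]] allele table: two-sided p = 2 / C(20,10)."""
        ds = dataset_factory({"A": [[0]] * 5, "B": [[2]] * 5})
        table, _ = genic_test(ds, "A", "B")
        assert table.p_value.iloc[0] == pytest.approx(2 / comb(20, 10, exact=True),
                                                      rel=1e-10)

    def test_matches_scipy_per_locus(self, dataset_factory):
        rng = np.random.default_rng(11)
        G1 = rng.integers(0, 3, size=(8, 20))
        G2 = rng.integers(0, 3, size=(8, 20))
        ds = dataset_factory({"A": G1, "B": G2})
        table, combined = genic_test(ds, "A", "B")
        for _, row in table.iterrows():
            l = ds.locus_ids.index(row.locus_id)
            t = [[int((G1[:, l] != MISSING).sum() * 2 - G1[:, l].sum()),
                  int(G1[:, l].sum())],
                 [int((G2[:, l] != MISSING).sum() * 2 - G2[:, l].sum()),
                  int(G2[:, l].sum())]]
            assert row.p_value == pytest.approx(
                sps.fisher_exact(t, "two-sided")[1], rel=1e-12)
        # Fisher's method combination
        x2 = -2 * np.log(table.p_value).sum()
        assert combined == pytest.approx(sps.chi2.sf(x2, 2 * len(table)), rel=1e-12)

    def test_monomorphic_loci_skipped(self, dataset_factory):
        ds = dataset_factory({"A": [[0, 1], [0, 1]], "B": [[0, 1], [0, 1]]})
        table, _ = genic_test(ds, "A", "B")
        assert len(table) == 1  # locus 1 only; locus 0 monomorphic everywhere


class TestIbsDistance:
    def test_identical_individuals_distance_zero(self, dataset_factory):
        ds = dataset_factory({"A": [[0, 1, 2], [0, 1, 2]]})
        assert ibs_distance(ds).values[0, 1] == 0.0

    def test_opposite_homozygotes_distance_one(self, dataset_factory):
        ds = dataset_factory({"A": [[0, 0, 0], [2, 2, 2]]})
        assert ibs_distance(ds).values[0, 1] == 1.0

    def test_het_vs_hom_half(self, dataset_factory):
        ds = dataset_factory({"A": [[1], [0]]})
        assert ibs_distance(ds).values[0, 1] == 0.5

    def test_matches_bruteforce_with_missing(self, dataset_factory):
        rng = np.random.default_rng(13)
        G = rng.integers(0, 3, size=(6, 40))
        G[rng.random(G.shape) < 0.15] = MISSING
        ds = dataset_factory({"A": G})
        out = ibs_distance(ds)
        for i in range(6):
            for j in range(i + 1, 6):
                shared = [(a, b) for a, b in zip(G[i], G[j])
                          if a != MISSING and b != MISSING]
                ibs = np.mean([1 - abs(a - b) / 2 for a, b in shared])
                assert out.values[i, j] == pytest.approx(1 - ibs, abs=1e-12)
                assert out.n_loci[i, j] == len(shared)


class TestMetricMds:
    def test_collinear_points_load_on_first_axis(self):
        x = np.array([0.0, 1.0, 3.0])
        D = np.abs(x[:, None] - x[None, :])
        with pytest.warns(UserWarning, match="positive eigenvalues"):
            coords, varexp = metric_mds(D, k_axes=2)
        assert varexp[0] == pytest.approx(1.0, abs=1e-9)

    def test_zero_matrix_gives_origin(self):
        coords, varexp = metric_mds(np.zeros((4, 4)), k_axes=2)
        assert np.allclose(coords, 0.0) and np.allclose(varexp, 0.0)

    def test_matches_skbio_pcoa_up_to_sign(self):
        """Independent classical-scaling oracle (scikit-bio PCoA)."""
        skbio_pcoa = pytest.importorskip("skbio.stats.ordination").pcoa
        from skbio import DistanceMatrix
        rng = np.random.default_rng(17)
        X = rng.random((5, 3))
        D = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
        coords, varexp = metric_mds(D, k_axes=2)
        ref = skbio_pcoa(DistanceMatrix(D), number_of_dimensions=2)
        ref_coords = ref.samples.to_numpy()
        for k in range(2):
            flip = np.sign(np.dot(coords[:, k], ref_coords[:, k])) or 1.0
            assert np.allclose(coords[:, k], flip * ref_coords[:, k], atol=1e-10)
        assert np.allclose(varexp, ref.proportion_explained[:2], atol=1e-10)

    def test_negative_fst_clamped_before_scaling(self):
        D = np.array([[0.0, -0.01, 0.2],
                      [-0.01, 0.0, 0.3],
                      [0.2, 0.3, 0.0]])
        coords, _ = metric_mds(D, k_axes=1)
        ref, _ = metric_mds(np.clip(D, 0, None), k_axes=1)
        assert np.allclose(np.abs(coords), np.abs(ref))
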