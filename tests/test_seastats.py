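"""Mantel tests, IBD regressions, He ~ environment model, region summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from seaconn.popgen import PairwiseStatMatrix
from seaconn.seastats import (
    env_regression,
    ibd_regression,
    mantel,
    region_boxplot_table,
    vif_screen,
)


def rand_sym(n, rng, zero_diag=True):
    M = rng.random((n, n))
    M = 0.5 * (M + M.T)
    if zero_diag:
        np.fill_diagonal(M, 0.0)
    return M


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

class TestMantel:
    def test_identical_matrices_give_r_one_min_p(self):
        rng = np.random.default_rng(0)
        A = rand_sym(6, rng)
        res = mantel(A, A.copy(), n_perm=99, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100)

    def test_exact_enumeration_matches_oracle(self):
        """All 24 relabelings of a 4×4 problem, against a test-side
        enumeration using scipy's Pearson correlation."""
        rng = np.random.default_rng(5)
        A, B = rand_sym(4, rng), rand_sym(4, rng)
        res = mantel(A, B, method="exact")
        iu = np.triu_indices(4, 1)
        r_obs = sps.pearsonr(A[iu], B[iu]).statistic
        count = 0
        perms = list(itertools.permutations(range(4)))
        for p in perms:
            Bp = B[np.ix_(p, p)]
            if abs(sps.pearsonr(A[iu], Bp[iu]).statistic) >= abs(r_obs) - 1e-12:
                count += 1
        assert res.r == pytest.approx(r_obs, abs=1e-12)
        assert res.p == pytest.approx(count / len(perms), abs=1e-15)
        assert res.n_perm == 24

    def test_p_invariant_under_joint_relabeling(self):
        rng = np.random.default_rng(7)
        A, B = rand_sym(5, rng), rand_sym(5, rng)
        perm = rng.permutation(5)
        a = mantel(A, B, method="exact")
        b = mantel(A[np.ix_(perm, perm)], B[np.ix_(perm, perm)], method="exact")
        assert a.p == pytest.approx(b.p, abs=1e-15)
        assert a.r == pytest.approx(b.r, abs=1e-12)

    def test_agrees_with_skbio_statistic(self):
        skbio_mantel = pytest.importorskip("skbio.stats.distance").mantel
        rng = np.random.default_rng(9)
        A, B = rand_sym(7, rng), rand_sym(7, rng)
        res = mantel(A, B, n_perm=999, seed=2)
        r_ref, p_ref, _ = skbio_mantel(A, B, permutations=999, alternative="two-sided")
        assert res.r == pytest.approx(r_ref, abs=1e-12)
        assert abs(res.p - p_ref) < 0.1  # both permutation p-values, same null

    def test_degenerate_constant_matrix_flagged(self):
        rng = np.random.default_rng(1)
        A = rand_sym(4, rng)
        const = np.ones((4, 4)) - np.eye(4)
        res = mantel(A, const, n_perm=9, seed=0)
        assert res.degenerate and np.isnan(res.r) and np.isnan(res.p)

    def test_reproducible_by_seed(self):
        rng = np.random.default_rng(3)
        A, B = rand_sym(8, rng), rand_sym(8, rng)
        assert mantel(A, B, 199, seed=5).p == mantel(A, B, 199, seed=5).p


# ---------------------------------------------------------------------------
# IBD regressions
# ---------------------------------------------------------------------------

def stat_matrix(values, ids):
    return PairwiseStatMatrix(values=values, ids=ids, statistic="fst_wc")


class TestIbdRegression:
    def make_line(self, n, slope, intercept, rng):
        """Site set whose pair FST is an exact line in log connectivity."""
        logc = rand_sym(n, rng) * 4 - 6
        fst = slope * logc + intercept
        np.fill_diagonal(fst, 0.0)
        ids = [f"S{i}" for i in range(n)]
        return stat_matrix(fst, ids), logc

    def test_exact_line_recovered(self):
        rng = np.random.default_rng(0)
        fst, logc = self.make_line(6, -0.02, 0.1, rng)
        out = ibd_regression(fst, logc, flagged_sites=())
        assert out["flagged"] is None
        fit = out["rest"]
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.params["log_connectivity"] == pytest.approx(-0.02)
        assert fit.params["const"] == pytest.approx(0.1)

    def test_two_constructed_lines_recovered_per_group(self):
        """Pairs touching flagged sites lie on one line, the rest on another
        with a different intercept; both fits are exact."""
        rng = np.random.default_rng(4)
        n = 7
        ids = [f"S{i}" for i in range(n)]
        flagged = {"S0", "S1"}
        logc = rand_sym(n, rng) * 4 - 6
        fst = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                b0 = 0.3 if (ids[i] in flagged or ids[j] in flagged) else 0.1
                fst[i, j] = fst[j, i] = -0.05 * logc[i, j] + b0
        out = ibd_regression(stat_matrix(fst, ids), logc, flagged_sites=flagged)
        for name, intercept in (("flagged", 0.3), ("rest", 0.1)):
            fit = out[name]
            assert fit.r_squared == pytest.approx(1.0)
            assert fit.params["const"] == pytest.approx(intercept)
            assert fit.params["log_connectivity"] == pytest.approx(-0.05)

    def test_empty_flag_set_reduces_to_plain_regression(self):
        rng = np.random.default_rng(2)
        fst_vals = rand_sym(5, rng) * 0.05
        logc = rand_sym(5, rng) * 3 - 5
        fst = stat_matrix(fst_vals, [f"S{i}" for i in range(5)])
        out = ibd_regression(fst, logc, flagged_sites=())
        iu = np.triu_indices(5, 1)
        ref = sps.linregress(logc[iu], fst_vals[iu])
        assert out["rest"].params["log_connectivity"] == pytest.approx(ref.slope)
        assert out["rest"].r_squared == pytest.approx(ref.rvalue**2)

    def test_tiny_group_skipped_with_warning(self):
        rng = np.random.default_rng(6)
        fst, logc = self.make_line(3, -0.02, 0.1, rng)
        with pytest.warns(UserWarning, match="skipped"):
            out = ibd_regression(fst, logc, flagged_sites={"S0", "S1", "S2"})
        assert out["rest"] is None


# ---------------------------------------------------------------------------
# He ~ environment
# ---------------------------------------------------------------------------

class TestEnvRegression:
    def test_exact_linear_salinity_dependence(self):
        n = 20
        rng = np.random.default_rng(0)
        sal = np.linspace(3, 25, n)
        other = rng.standard_normal(n)
        env = pd.DataFrame({"salinity": sal, "other": other},
                           index=[f"S{i}" for i in range(n)])
        div = pd.DataFrame({"he": 0.1 + 0.01 * sal}, index=env.index)
        out = env_regression(div, env)
        assert out.r_squared == pytest.approx(1.0)
        assert out.params["salinity"] == pytest.approx(0.01)
        assert out.anova.loc["salinity", "PR(>F)"] < 1e-10

    def test_orthogonal_predictors_have_unit_vif(self):
        n = 16
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        X = pd.DataFrame({"a": x1, "b": x2})
        screened, dropped, vifs = vif_screen(X)
        assert dropped == []
        assert np.allclose(vifs, 1.0)

    def test_duplicated_predictor_dropped_by_vif(self):
        n = 15
        rng = np.random.default_rng(3)
        x = rng.standard_normal(n)
        env = pd.DataFrame({
            "sal": x, "sal_copy": x + rng.standard_normal(n) * 1e-6,
            "noise": rng.standard_normal(n)},
            index=[f"S{i}" for i in range(n)])
        div = pd.DataFrame({"he": 0.2 + 0.05 * x + rng.standard_normal(n) * 0.01},
                           index=env.index)
        out = env_regression(div, env)
        assert len(out.dropped) == 1
        assert out.dropped[0] in ("sal", "sal_copy")
        assert (out.vif < 3).all()

    def test_too_few_sites_rejected(self):
        env = pd.DataFrame({"a": [1.0, 2.0], "b": [0.5, 1.5]}, index=["X", "Y"])
        div = pd.DataFrame({"he": [0.1, 0.2]}, index=env.index)
        with pytest.raises(ValueError, match="sites"):
            env_regression(div, env)


# ---------------------------------------------------------------------------
# regional FST summaries
# ---------------------------------------------------------------------------

def survey_regions():
    """Region labels shaped like a 31-site multi-basin survey."""
    sizes = {"W": 9, "SBA": 6, "SBO": 2, "FBO": 7, "GFE": 7}
    labels = {}
    for region, k in sizes.items():
        for i in range(k):
            labels[f"{region}-{i + 1}"] = region
    return pd.Series(labels, name="region")


class TestRegionBoxplotTable:
    def test_total_pair_count_is_465(self):
        regions = survey_regions()
        ids = list(regions.index)
        rng = np.random.default_rng(1)
        fst = stat_matrix(rand_sym(31, rng) * 0.05, ids)
        table = region_boxplot_table(fst, regions)
        assert table.n_pairs.sum() == 465  # C(31, 2)

    def test_sbo_to_w_and_gfe_pairs_number_32(self):
        regions = survey_regions()
        ids = list(regions.index)
        rng = np.random.default_rng(2)
        fst = stat_matrix(rand_sym(31, rng) * 0.05, ids)
        table = region_boxplot_table(fst, regions).set_index(["kind", "group"])
        n = (table.loc[("between", "GFE|SBO"), "n_pairs"]
             + table.loc[("between", "SBO|W"), "n_pairs"])
        assert n == 32  # 2 SBO sites × (9 W + 7 GFE)

    def test_single_region_has_no_between_rows(self):
        regions = pd.Series({"A-1": "A", "A-2": "A", "A-3": "A"})
        rng = np.random.default_rng(3)
        fst = stat_matrix(rand_sym(3, rng), list(regions.index))
        table = region_boxplot_table(fst, regions)
        assert (table.kind == "within").all()

    def test_summary_statistics_match_numpy(self):
        regions = pd.Series({"A-1": "A", "A-2": "A", "B-1": "B"})
        vals = np.array([[0.0, 0.02, 0.05],
                         [0.02, 0.0, 0.07],
                         [0.05, 0.07, 0.0]])
        fst = stat_matrix(vals, list(regions.index))
        table = region_boxplot_table(fst, regions).set_index(["kind", "group"])
        assert table.loc[("within", "A"), "mean"] == pytest.approx(0.02)
        assert table.loc[("between", "A|B"), "mean"] == pytest.approx(0.06)
        assert table.loc[("between", "A|B"), "n_pairs"] == 2

    def test_unlabeled_site_rejected(self):
        fst = stat_matrix(np.zeros((2, 2)), ["A-1", "Z-9"])
        with pytest.raises(ValueError, match="region"):
            region_boxplot_table(fst, pd.Series({"A-1": "A"}))
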