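"""Concordance between genetic structure and biophysical connectivity.

Mantel permutation tests of matrix correlation, split isolation-by-distance
regressions of pairwise F_ST on log connectivity, a multiple regression of
expected heterozygosity on site environment (with VIF screening and ANOVA),
and within/between-region F_ST summaries.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .popgen import PairwiseStatMatrix

DEFAULT_N_PERM = 9_999
VIF_LIMIT = 3.0


@dataclass
class MantelResult:
    """Correlation between two symmetric matrices with permutation p-value."""

    r: float
    p: float
    n_perm: int
    seed: int | None = None
    degenerate: bool = False
    meta: dict = field(default_factory=dict)


@dataclass
class RegressionResult:
    """OLS fit summary with optional ANOVA table and VIF diagnostics."""

    params: pd.Series
    bse: pd.Series
    r_squared: float
    n: int
    anova: pd.DataFrame | None = None
    vif: pd.Series | None = None
    dropped: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def _offdiag_vector(M: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(M.shape[0], k=1)
    return M[iu]


def _as_square(M) -> np.ndarray:
    arr = M.values if isinstance(M, PairwiseStatMatrix) else np.asarray(M, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(arr, arr.T, equal_nan=True):
        raise ValueError("matrix must be symmetric")
    return arr


def mantel(
    A,
    B,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    method: str = "permutation",
) -> MantelResult:
    """Two-sided Mantel test between symmetric matrices A and B.

    ``r`` is the Pearson correlation of the upper-triangle vectors.  The
    null distribution jointly permutes rows and columns of B; the p-value
    uses the +1 correction ``p = (1 + #{|r_perm| >= |r_obs|}) / (n_perm + 1)``.
    ``method='exact'`` enumerates all n! relabelings instead (small n), with
    ``p = #{|r_perm| >= |r_obs|} / n!`` over the full group.

    A constant off-diagonal vector in either matrix makes r undefined; the
    result is then flagged ``degenerate`` with NaN statistics.
    """
    a = _as_square(A)
    b = _as_square(B)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = a.shape[0]
    va = _offdiag_vector(a)
    if va.std() == 0 or _offdiag_vector(b).std() == 0:
        return MantelResult(r=np.nan, p=np.nan, n_perm=0, seed=seed, degenerate=True)

    va = (va - va.mean()) / va.std()

    def corr_with(mat: np.ndarray) -> float:
        vb = _offdiag_vector(mat)
        sd = vb.std()
        if sd == 0:
            return 0.0
        return float(np.mean(va * (vb - vb.mean()) / sd))

    r_obs = corr_with(b)

    if method == "exact":
        perms = list(itertools.permutations(range(n)))
        count = sum(
            abs(corr_with(b[np.ix_(p, p)])) >= abs(r_obs) - 1e-12 for p in perms
        )
        return MantelResult(r=r_obs, p=count / len(perms), n_perm=len(perms),
                            seed=None, meta={"method": "exact"})
    if method != "permutation":
        raise ValueError("method must be 'permutation' or 'exact'")

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if abs(corr_with(b[np.ix_(perm, perm)])) >= abs(r_obs) - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return MantelResult(r=r_obs, p=p, n_perm=n_perm, seed=seed,
                        meta={"method": "permutation", "alternative": "two-sided"})


# ---------------------------------------------------------------------------
# isolation-by-distance regressions
# ---------------------------------------------------------------------------

def pair_table(
    fst: PairwiseStatMatrix,
    logconn: PairwiseStatMatrix | np.ndarray,
    regions: pd.Series | None = None,
) -> pd.DataFrame:
    """Long-format table of site pairs: fst, log_connectivity, site labels."""
    conn = _as_square(logconn)
    if conn.shape != fst.values.shape:
        raise ValueError("fst and connectivity matrices have different shapes")
    ids = fst.ids
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            rec = {
                "site_a": ids[i],
                "site_b": ids[j],
                "fst": fst.values[i, j],
                "log_connectivity": conn[i, j],
            }
            if regions is not None:
                rec["region_a"] = regions[ids[i]]
                rec["region_b"] = regions[ids[j]]
            rows.append(rec)
    return pd.DataFrame(rows)


def _ols(x: np.ndarray, y: np.ndarray, xname: str) -> RegressionResult:
    X = sm.add_constant(pd.DataFrame({xname: x}))
    fit = sm.OLS(y, X).fit()
    return RegressionResult(
        params=fit.params, bse=fit.bse, r_squared=float(fit.rsquared),
        n=int(fit.nobs),
    )


def ibd_regression(
    fst: PairwiseStatMatrix,
    logconn: PairwiseStatMatrix | np.ndarray,
    flagged_sites: set | list = (),
) -> dict[str, RegressionResult | None]:
    """Split isolation-by-distance regressions of F_ST on log connectivity.

    Pairs are split into those containing at least one flagged site (e.g.
    the divergent northern samples) and the rest, and an OLS line is fitted
    per group.  A group with fewer than 3 pairs is skipped with a warning.
    Returns {'flagged': ..., 'rest': ...}; with an empty flag set the 'rest'
    fit is a plain all-pairs regression.
    """
    flagged = set(flagged_sites)
    table = pair_table(fst, logconn)
    in_flagged = table["site_a"].isin(flagged) | table["site_b"].isin(flagged)
    out: dict[str, RegressionResult | None] = {}
    for name, sub in (("flagged", table[in_flagged]), ("rest", table[~in_flagged])):
        if len(sub) < 3:
            if name == "flagged" and not flagged:
                out[name] = None
            else:
                warnings.warn(f"IBD group {name!r} has {len(sub)} pairs (< 3); skipped",
                              stacklevel=2)
                out[name] = None
            continue
        out[name] = _ols(sub["log_connectivity"].to_numpy(), sub["fst"].to_numpy(),
                         "log_connectivity")
        out[name].meta["group"] = name
        out[name].meta["n_pairs"] = len(sub)
    return out


# ---------------------------------------------------------------------------
# He ~ environment regression
# ---------------------------------------------------------------------------

def vif_screen(X: pd.DataFrame, limit: float = VIF_LIMIT) -> tuple[pd.DataFrame, list, pd.Series]:
    """Iteratively drop the predictor with the highest VIF until all < limit.

    VIFs are computed on the design with an intercept.  Returns the screened
    design, the dropped column names (in drop order), and the final VIFs.
    """
    X = X.copy()
    dropped: list[str] = []
    while X.shape[1] > 1:
        design = sm.add_constant(X)
        vifs = pd.Series(
            [variance_inflation_factor(design.to_numpy(), k + 1)
             for k in range(X.shape[1])],
            index=X.columns,
        )
        worst = vifs.idxmax()
        if vifs[worst] < limit:
            break
        dropped.append(worst)
        X = X.drop(columns=[worst])
    design = sm.add_constant(X)
    vifs = pd.Series(
        [variance_inflation_factor(design.to_numpy(), k + 1) for k in range(X.shape[1])],
        index=X.columns,
    )
    return X, dropped, vifs


def env_regression(
    diversity_table: pd.DataFrame,
    env: pd.DataFrame,
    response: str = "he",
    predictors: list[str] | None = None,
    vif_limit: float = VIF_LIMIT,
) -> RegressionResult:
    """Multiple regression of per-site diversity on environmental factors.

    Joins the diversity table to site covariates, screens collinear
    predictors by VIF (iteratively dropping the worst offender at or above
    ``vif_limit`` — collinear seasonal salinity drops out here rather than
    by fiat), fits OLS, and tests each retained factor with a sequential
    (type I) ANOVA, the convention of R's ``anova(lm(...))``.
    """
    data = diversity_table.join(env, how="inner")
    if predictors is None:
        predictors = [c for c in env.columns if pd.api.types.is_numeric_dtype(env[c])]
    missing = [c for c in predictors if c not in data.columns]
    if missing:
        raise ValueError(f"predictors not in covariate table: {missing}")
    y = data[response].astype(float)
    X = data[predictors].astype(float)
    if len(data) < len(predictors) + 2:
        raise ValueError(
            f"{len(data)} sites cannot support {len(predictors)} predictors")

    # constant columns carry no information and break VIF; drop them first
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    X = X.drop(columns=constant)
    X_screened, dropped, vifs = vif_screen(X, limit=vif_limit)

    design = sm.add_constant(X_screened)
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("design matrix is rank-deficient after VIF screening")
    fit = sm.OLS(y, design).fit()

    formula = f"{response} ~ " + " + ".join(X_screened.columns)
    from statsmodels.formula.api import ols as f_ols
    anova = anova_lm(f_ols(formula, data=data).fit())

    return RegressionResult(
        params=fit.params,
        bse=fit.bse,
        r_squared=float(fit.rsquared),
        n=int(fit.nobs),
        anova=anova,
        vif=vifs,
        dropped=constant + dropped,
        meta={"response": response, "vif_limit": vif_limit},
    )


# ---------------------------------------------------------------------------
# regional FST summaries
# ---------------------------------------------------------------------------

def region_boxplot_table(fst: PairwiseStatMatrix, regions: pd.Series) -> pd.DataFrame:
    """Within-region and between-region pairwise F_ST summaries.

    One row per region (within; requires ≥2 sites) and per unordered region
    pair (between): pair count, mean, SD, quartiles — the numbers behind a
    regional boxplot figure.
    """
    unlabeled = [s for s in fst.ids if s not in regions.index]
    if unlabeled:
        raise ValueError(f"sites without region label: {unlabeled}")
    table = pair_table(fst, np.zeros_like(fst.values), regions=regions)

    def summarize(sub: pd.DataFrame, kind: str, label: str) -> dict:
        v = sub["fst"].to_numpy()
        return {
            "kind": kind, "group": label, "n_pairs": len(v),
            "mean": v.mean(), "sd": v.std(ddof=1) if len(v) > 1 else np.nan,
            "q25": np.percentile(v, 25), "median": np.median(v),
            "q75": np.percentile(v, 75),
        }

    rows = []
    region_names = sorted(regions.loc[fst.ids].unique())
    for reg in region_names:
        sub = table[(table["region_a"] == reg) & (table["region_b"] == reg)]
        if len(sub) >= 1:
            rows.append(summarize(sub, "within", reg))
    for ra, rb in itertools.combinations(region_names, 2):
        sub = table[
            ((table["region_a"] == ra) & (table["region_b"] == rb))
            | ((table["region_a"] == rb) & (table["region_b"] == ra))
        ]
        if len(sub):
            rows.append(summarize(sub, "between", f"{ra}|{rb}"))
    return pd.DataFrame(rows)
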