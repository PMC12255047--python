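"""Association models for admixed cohorts.

Two regressions, both ordinary least squares with classical
(homoskedastic) standard errors:

* ATT / standard GWAS:  Y ~ M_k + covariates + intercept, a 1-df Wald test
  of the total-dosage coefficient;
* Tractor:  Y ~ Σ_l M_kl + Σ_{l>=1} L_kl + covariates + intercept, where the
  dosage is partitioned by local ancestry and n_L - 1 local-ancestry count
  columns are included (one dropped for collinearity, since Σ_l L_kl = 2).
  Per-ancestry 1-df Wald tests come from the marginal SEs; the combined
  n_L-df Wald test uses the estimated covariance block of the dosage
  coefficients.

Global-ancestry adjustment drops one proportion column (the reference
ancestry, index 0) and keeps the intercept, mirroring the local-ancestry
column drop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "AttResult",
    "TractorResult",
    "ancestry_covariates",
    "fit_att",
    "fit_tractor",
    "wald_combined",
    "scan_att",
    "scan_tractor",
]


def ancestry_covariates(P) -> np.ndarray:
    """Global-ancestry covariate columns: proportions with ancestry 0 dropped.

    Zero-variance columns (cohorts with fixed proportions) are removed —
    they are absorbed by the intercept.
    """
    p = np.atleast_2d(np.asarray(getattr(P, "proportions", P), dtype=float))
    cols = p[:, 1:]
    tol = 1e-9 * np.maximum(1.0, np.abs(cols).max(axis=0, initial=0.0))
    return cols[:, cols.std(axis=0) > tol]


def _ols(X: np.ndarray, y: np.ndarray):
    """OLS with classical covariance. Returns (beta, cov, dof) or None if singular."""
    n, k = X.shape
    if n <= k:
        return None
    xtx = X.T @ X
    # rank check via eigenvalues of the (small) normal matrix
    w = np.linalg.eigvalsh(xtx)
    if w[0] <= max(n, k) * np.finfo(float).eps * w[-1] or w[-1] <= 0:
        return None
    xty = X.T @ y
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ xty
    rss = float(y @ y - beta @ xty)
    dof = n - k
    sigma2 = max(rss, 0.0) / dof
    return beta, sigma2 * xtx_inv, dof


@dataclass
class AttResult:
    beta: float
    se: float
    chi2: float
    p: float
    n: int
    degenerate: bool = False

    @classmethod
    def failed(cls, n: int) -> "AttResult":
        return cls(np.nan, np.nan, np.nan, np.nan, n, degenerate=True)


@dataclass
class TractorResult:
    beta: np.ndarray  # per-ancestry dosage coefficients (NaN where absent)
    se: np.ndarray
    gamma: np.ndarray  # n_L - 1 local-ancestry coefficients
    cov: np.ndarray  # covariance block of the dosage coefficients
    chi2: float = field(init=False)
    df: int = field(init=False)
    p: float = field(init=False)
    n: int = 0
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.chi2, self.df, self.p = wald_combined(self)

    @property
    def per_ancestry_chi2(self) -> np.ndarray:
        return (self.beta / self.se) ** 2

    @property
    def per_ancestry_p(self) -> np.ndarray:
        return stats.chi2.sf(self.per_ancestry_chi2, 1)


def wald_combined(result: "TractorResult"):
    """Combined Wald test beta' V^-1 beta over the non-NaN ancestries."""
    ok = ~np.isnan(result.beta)
    df = int(ok.sum())
    if df == 0:
        return np.nan, 0, np.nan
    V = result.cov[np.ix_(ok, ok)]
    try:
        stat = float(result.beta[ok] @ np.linalg.solve(V, result.beta[ok]))
    except np.linalg.LinAlgError:
        return np.nan, df, np.nan
    return stat, df, float(stats.chi2.sf(stat, df))


def _with_intercept(n: int, covariates) -> np.ndarray:
    cols = [np.ones((n, 1))]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        if cov.size:
            cols.append(cov)
    return np.hstack(cols)


def fit_att(Y, M_k, covariates=None) -> AttResult:
    """Standard-GWAS OLS of the trait on the total dosage."""
    y = np.asarray(Y, dtype=float)
    m = np.asarray(M_k, dtype=float)
    n = y.shape[0]
    X = np.hstack([m[:, None], _with_intercept(n, covariates)])
    fit = _ols(X, y)
    if fit is None:
        return AttResult.failed(n)
    beta, cov, _ = fit
    b, se = float(beta[0]), float(np.sqrt(cov[0, 0]))
    if se == 0.0:
        chi2 = 0.0 if b == 0.0 else np.inf
    else:
        chi2 = (b / se) ** 2
    return AttResult(b, se, chi2, float(stats.chi2.sf(chi2, 1)), n)


def fit_tractor(Y, M_partitioned, L, covariates=None) -> TractorResult:
    """Tractor OLS: ancestry-partitioned dosages plus n_L-1 LA columns.

    `M_partitioned` and `L` are (n, n_L). Ancestries absent from the cohort
    at this locus (all L_il = 0) are flagged NaN and the combined test falls
    back to the present ancestries with reduced df.
    """
    y = np.asarray(Y, dtype=float)
    M = np.atleast_2d(np.asarray(M_partitioned, dtype=float))
    L = np.atleast_2d(np.asarray(L, dtype=float))
    if M.shape != L.shape:
        raise ValueError("partitioned dosages and LA counts have mismatched shapes")
    if np.any(M > L + 1e-9):
        raise ValueError("partitioned dosage exceeds local-ancestry count")
    n, n_L = M.shape
    present = np.flatnonzero(L.sum(axis=0) > 0)
    la_cols = [l for l in range(1, n_L) if l in set(present.tolist())]
    # drop one LA column for collinearity; if the reference ancestry itself is
    # absent, the present LA columns are still collinear with the intercept,
    # so drop the first present one instead.
    if 0 not in present and la_cols:
        la_cols = la_cols[1:]
    X = np.hstack(
        [M[:, present], L[:, la_cols] if la_cols else np.empty((n, 0)), _with_intercept(n, covariates)]
    )
    fit = _ols(X, y)
    beta = np.full(n_L, np.nan)
    se = np.full(n_L, np.nan)
    cov_block = np.full((n_L, n_L), np.nan)
    gamma = np.full(n_L - 1, np.nan)
    if fit is None:
        res = TractorResult.__new__(TractorResult)
        res.beta, res.se, res.gamma, res.cov = beta, se, gamma, cov_block
        res.chi2, res.df, res.p = np.nan, 0, np.nan
        res.n, res.degenerate = n, True
        return res
    b, cov, _ = fit
    k = present.shape[0]
    beta[present] = b[:k]
    se[present] = np.sqrt(np.diag(cov)[:k])
    cov_block[np.ix_(present, present)] = cov[:k, :k]
    for i, l in enumerate(la_cols):
        gamma[l - 1] = b[k + i]
    return TractorResult(beta=beta, se=se, gamma=gamma, cov=cov_block, n=n)


class _MarkerScanBase:
    pass


def scan_att(Y_list, M: np.ndarray, covariates=None):
    """Batched ATT scan: one trait (or several) against every marker column.

    `M` is (n, n_markers); `Y_list` is (n,) or a list of traits. Exploits the
    fact that the covariate block is shared: per marker only the cross
    products involving that marker change. Returns arrays (n_traits,
    n_markers) of beta, se, chi2.
    """
    M = np.asarray(M, dtype=float)
    n, n_markers = M.shape
    W = _with_intercept(n, covariates)  # shared columns
    Ys = np.atleast_2d(np.asarray(Y_list, dtype=float))
    if Ys.shape[1] != n:
        raise ValueError("trait length mismatch")
    WtW = W.T @ W
    WtW_inv = np.linalg.inv(WtW)
    WtM = W.T @ M  # (kw, n_markers)
    # residualize the marker on the shared block (FWL)
    M_resid = M - W @ (WtW_inv @ WtM)
    mm = np.einsum("ij,ij->j", M_resid, M_resid)  # residual SS of each marker
    kw = W.shape[1]
    dof = n - kw - 1
    WtY = W.T @ Ys.T  # (kw, n_traits)
    Y_resid = Ys.T - W @ (WtW_inv @ WtY)  # (n, n_traits)
    my = M_resid.T @ Y_resid  # (n_markers, n_traits)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (my / mm[:, None]).T  # (n_traits, n_markers)
        yy = np.einsum("ij,ij->j", Y_resid, Y_resid)  # (n_traits,)
        rss = yy[:, None] - beta**2 * mm[None, :]
        sigma2 = np.maximum(rss, 0.0) / dof
        se = np.sqrt(sigma2 / mm[None, :])
        chi2 = (beta / se) ** 2
    bad = mm <= n * np.finfo(float).eps * np.maximum(np.einsum("ij,ij->j", M, M), 1.0)
    beta[:, bad] = np.nan
    se[:, bad] = np.nan
    chi2[:, bad] = np.nan
    return beta, se, chi2


def scan_tractor(Y_list, M_part: np.ndarray, L: np.ndarray, covariates=None):
    """Batched Tractor scan over markers for one or more traits.

    `M_part` and `L` are (n, n_markers, n_L). Returns dict of arrays with
    leading dims (n_traits, n_markers): beta/se (.., n_L), gamma
    (.., n_L-1), chi2, df. Markers where an ancestry is absent or the design
    is singular get NaN for the affected quantities.
    """
    M_part = np.asarray(M_part, dtype=float)
    L = np.asarray(L, dtype=float)
    n, n_markers, n_L = M_part.shape
    W = _with_intercept(n, covariates)
    Ys = np.atleast_2d(np.asarray(Y_list, dtype=float))
    n_traits = Ys.shape[0]
    out_beta = np.full((n_traits, n_markers, n_L), np.nan)
    out_se = np.full((n_traits, n_markers, n_L), np.nan)
    out_gamma = np.full((n_traits, n_markers, n_L - 1), np.nan)
    out_chi2 = np.full((n_traits, n_markers), np.nan)
    out_df = np.zeros((n_traits, n_markers), dtype=int)
    kw = W.shape[1]
    YT = Ys.T  # (n, n_traits)
    yy = np.einsum("ij,ij->j", YT, YT)
    WtY = W.T @ YT
    WtW = W.T @ W
    for k in range(n_markers):
        G = np.hstack([M_part[:, k, :], L[:, k, 1:]])  # (n, 2*n_L - 1)
        keep = G.std(axis=0) > 0
        G = G[:, keep]
        kg = G.shape[1]
        X_tt = np.block([[G.T @ G, G.T @ W], [W.T @ G, WtW]])
        w = np.linalg.eigvalsh(X_tt)
        if w[0] <= max(n, kg + kw) * np.finfo(float).eps * max(w[-1], 1.0):
            continue
        Xty = np.vstack([G.T @ YT, WtY])  # (kg+kw, n_traits)
        xtx_inv = np.linalg.inv(X_tt)
        B = xtx_inv @ Xty  # coefficients for all traits at once
        rss = yy - np.einsum("kt,kt->t", B, Xty)
        dof = n - kg - kw
        sigma2 = np.maximum(rss, 0.0) / dof
        # map kept columns back to ancestries / LA slots
        dos_idx = np.flatnonzero(keep[:n_L])
        la_idx = np.flatnonzero(keep[n_L:])
        nd = dos_idx.shape[0]
        cov_unit = xtx_inv[:nd, :nd]
        se_unit = np.sqrt(np.diag(cov_unit))
        out_beta[:, k, dos_idx] = B[:nd, :].T
        out_se[:, k, dos_idx] = np.sqrt(sigma2)[:, None] * se_unit[None, :]
        for i, l in enumerate(la_idx):
            out_gamma[:, k, l] = B[nd + i, :]
        try:
            Vinv_b = np.linalg.solve(cov_unit, B[:nd, :])
        except np.linalg.LinAlgError:
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            out_chi2[:, k] = np.einsum("kt,kt->t", B[:nd, :], Vinv_b) / sigma2
        out_df[:, k] = nd
    return {
        "beta": out_beta,
        "se": out_se,
        "gamma": out_gamma,
        "chi2": out_chi2,
        "df": out_df,
    }
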