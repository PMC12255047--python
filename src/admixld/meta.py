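"""Fixed-effects meta-analysis of ancestry-specific Tractor estimates.

Because the Tractor coefficient covariance is asymptotically diagonal, the
ancestry-specific estimates behave like independent studies and can be
pooled by inverse-variance weighting. The pooled 1-df statistic T_FE and
Cochran's heterogeneity Q decompose the diagonal combined statistic
exactly:  T_FE + Q = Σ_l (β̂_l / SE_l)².  Under equal true effects T_FE
asymptotically equals Tractor's combined Wald statistic while testing a
1-parameter hypothesis, which is where the power gain comes from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["MetaResult", "fe_combine", "independence_diagnostic"]

log = logging.getLogger(__name__)


@dataclass
class MetaResult:
    beta_fe: float
    se_fe: float
    chi2_fe: float
    p_fe: float
    q: float
    df_q: int
    p_q: float
    n_studies: int


def fe_combine(betas, ses, extra_combiner=None) -> MetaResult:
    """Inverse-variance fixed-effects pooling of independent estimates.

    NaN entries (absent ancestries) are dropped, never imputed. A single
    surviving estimate passes through with Q = 0. `extra_combiner`, if
    given, is called with (betas, ses) and its result attached as
    `.extra` — an extension hook for other p-combining rules.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    ok = ~(np.isnan(b) | np.isnan(s))
    if np.any(s[ok] <= 0):
        raise ValueError("standard errors must be positive")
    b, s = b[ok], s[ok]
    if b.size == 0:
        raise ValueError("no valid estimates to combine")
    if b.size == 1:
        log.info("single estimate: fixed-effects pooling is a passthrough")
    w = 1.0 / s**2
    beta_fe = float(np.sum(w * b) / np.sum(w))
    se_fe = float(1.0 / np.sqrt(np.sum(w)))
    chi2_fe = beta_fe**2 * float(np.sum(w))
    q = float(np.sum(w * (b - beta_fe) ** 2))
    df_q = max(b.size - 1, 0)
    res = MetaResult(
        beta_fe=beta_fe,
        se_fe=se_fe,
        chi2_fe=chi2_fe,
        p_fe=float(stats.chi2.sf(chi2_fe, 1)),
        q=q,
        df_q=df_q,
        p_q=float(stats.chi2.sf(q, df_q)) if df_q > 0 else np.nan,
        n_studies=int(b.size),
    )
    if extra_combiner is not None:
        res.extra = extra_combiner(b, s)  # type: ignore[attr-defined]
    return res


def fe_combine_arrays(betas: np.ndarray, ses: np.ndarray):
    """Vectorised fixed-effects pooling over the last axis.

    Returns (beta_fe, se_fe, chi2_fe, q) arrays with that axis reduced.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    w = 1.0 / s**2
    wsum = np.nansum(np.where(np.isnan(b), np.nan, w), axis=-1)
    beta_fe = np.nansum(w * b, axis=-1) / wsum
    se_fe = 1.0 / np.sqrt(wsum)
    chi2_fe = beta_fe**2 * wsum
    q = np.nansum(w * (b - beta_fe[..., None]) ** 2, axis=-1)
    return beta_fe, se_fe, chi2_fe, q


def independence_diagnostic(beta1, beta2):
    """Cross-ancestry correlation of replicated estimates with a 95% CI.

    Supports the independence prediction when the normal-approximation CI
    for the Pearson correlation covers 0. Returns (r, lo, hi) or
    (nan, nan, nan) for degenerate input.
    """
    b1 = np.asarray(beta1, dtype=float)
    b2 = np.asarray(beta2, dtype=float)
    if b1.shape != b2.shape or b1.ndim != 1:
        raise ValueError("expect two equal-length 1-d arrays of replicate estimates")
    n = b1.size
    if n < 100:
        raise ValueError("need at least 100 replicates for the diagnostic")
    if np.std(b1) == 0 or np.std(b2) == 0:
        return np.nan, np.nan, np.nan
    r = float(np.corrcoef(b1, b2)[0, 1])
    # Fisher z interval
    z = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
    half = 1.959963984540054 / np.sqrt(n - 3)
    return r, float(np.tanh(z - half)), float(np.tanh(z + half))
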