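"""Closed-form predictions of the PSD / ePSD algebra.

Under the PSD model, the asymptotic variance of the standard-GWAS (ATT)
marker coefficient and of Tractor's ancestry-specific coefficients depends
only on the first and second moments of the global-ancestry distribution and
on the ancestry-specific marker frequencies g_lk:

* Var of the centred total dosage (two ancestries):
      E[M~_k^2] = 2 Σ_l g_l(1-g_l) E[P_l] + 2 (g_1-g_2)^2 E[P_1 P_2]
* the Tractor coefficient covariance matrix is *diagonal* with entries
      2 g_l(1-g_l) E[P_l],
  so the ancestry-specific estimates from the same regression are
  asymptotically independent;
* standard errors are sqrt(resid_var / (n * variance)) with the shared
  proportional constant resid_var = E[Var(Y|P)];
* Wald statistics are therefore ordered
      per-ancestry <= Tractor combined <= ATT,
  with the ATT excess driven by the allele-frequency heterogeneity term
  (g_1-g_2)^2 E[P_1 P_2] (admixture LD).

Under the ePSD extension (within-continental LD confined to local-ancestry
segments) the marginal coefficients are LD-weighted sums of causal effects:
Tractor's beta_lk = Σ_j D_ljk/(g_lk(1-g_lk)) α_j — exactly what a
single-continental GWAS in population l would estimate — and the
local-ancestry coefficient γ_lk absorbs only the imperfectly tagged remnant
of *linked* causal variants, vanishing under perfect tagging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PSDMoments",
    "LDParams",
    "var_att_marker",
    "var_tractor_matrix",
    "predicted_se",
    "expected_statistics",
    "beta_tractor_epsd",
    "gamma_tractor_epsd",
    "beta_att_epsd",
    "la_covariance_pulse",
    "epsd_ld_weight",
    "epsd_ld_corr",
    "effective_n_factor",
]


@dataclass
class PSDMoments:
    """First and second moments of the global-ancestry vector."""

    mean: np.ndarray  # E[P_l], length n_L
    second: np.ndarray  # E[P_l P_l'], (n_L, n_L)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.second = np.asarray(self.second, dtype=float)
        if abs(self.mean.sum() - 1.0) > 1e-8:
            raise ValueError("E[P] must sum to 1")
        if np.any(self.second < -1e-12):
            raise ValueError("second moments must be non-negative")
        if np.any(np.abs(self.second.sum(axis=1) - self.mean) > 1e-8):
            raise ValueError("second moments inconsistent: sum_l' E[P_l P_l'] must equal E[P_l]")

    @property
    def n_ancestries(self) -> int:
        return self.mean.shape[0]

    @classmethod
    def fixed(cls, p) -> "PSDMoments":
        """Moments of a point mass at proportion vector p."""
        p = np.asarray(p, dtype=float)
        return cls(mean=p, second=np.outer(p, p))

    @classmethod
    def dirichlet(cls, conc) -> "PSDMoments":
        a = np.asarray(conc, dtype=float)
        a0 = a.sum()
        mean = a / a0
        second = np.outer(a, a) / (a0 * (a0 + 1.0))
        second[np.diag_indices_from(second)] = a * (a + 1.0) / (a0 * (a0 + 1.0))
        return cls(mean=mean, second=second)


@dataclass
class LDParams:
    """Two-locus frequencies between a marker k and a set of causal loci.

    Arrays are (n_ancestries, n_causal) except `g` which is per ancestry.
    D_ljk = h_ljk - f_lj * g_lk is the within-continental LD covariance.
    """

    f: np.ndarray  # causal-allele frequency f_lj
    g: np.ndarray  # marker frequency g_lk, length n_L
    h: np.ndarray  # joint frequency h_ljk
    D: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.f = np.atleast_2d(np.asarray(self.f, dtype=float))
        self.h = np.atleast_2d(np.asarray(self.h, dtype=float))
        self.g = np.asarray(self.g, dtype=float)
        lo = np.maximum(0.0, self.f + self.g[:, None] - 1.0)
        hi = np.minimum(self.f, self.g[:, None])
        if np.any(self.h < lo - 1e-12) or np.any(self.h > hi + 1e-12):
            raise ValueError("joint frequency h violates the Frechet bounds for (f, g)")
        self.D = self.h - self.f * self.g[:, None]

    def linked_sets(self, tol: float = 0.0) -> list[np.ndarray]:
        """[k]_l = indices of causal loci with nonzero LD to the marker in l."""
        return [np.flatnonzero(np.abs(self.D[l]) > tol) for l in range(self.D.shape[0])]


def _check_moments(moments: PSDMoments, g: np.ndarray) -> np.ndarray:
    g = np.asarray(g, dtype=float)
    if g.shape[0] != moments.n_ancestries:
        raise ValueError("marker frequencies and moments disagree on ancestry count")
    return g


def var_att_marker(moments: PSDMoments, g) -> float:
    """E[Var(M_k | P)] of the total dosage: general-n_L conditional variance.

    Expectation of
        2 Σ_l g_l(1-g_l) P_l + 2 Σ_l g_l^2 P_l(1-P_l) - 2 Σ_{l≠l'} g_l g_l' P_l P_l'
    over P. For two ancestries this reduces to
        2 Σ_l g_l(1-g_l) E[P_l] + 2 (g_1-g_2)^2 E[P_1 P_2].
    """
    g = _check_moments(moments, g)
    m, s = moments.mean, moments.second
    diag = np.diag(s)
    term1 = 2.0 * np.sum(g * (1.0 - g) * m)
    term2 = 2.0 * np.sum(g**2 * (m - diag))
    off = s - np.diag(diag)
    term3 = 2.0 * float(g @ off @ g)
    out = term1 + term2 - term3
    if out < -1e-12:
        raise ValueError("negative predicted variance; invalid moments")
    return float(max(out, 0.0))


def var_tractor_matrix(moments: PSDMoments, g) -> np.ndarray:
    """Diagonal covariance matrix of centred partitioned dosages.

    diag(2 g_l (1-g_l) E[P_l]); the off-diagonals are exactly zero, which is
    what makes ancestry-specific Tractor estimates independent.
    """
    g = _check_moments(moments, g)
    return np.diag(2.0 * g * (1.0 - g) * moments.mean)


def predicted_se(method: str, moments: PSDMoments, g, resid_var: float, n: int):
    """Predicted OLS standard error: sqrt(resid_var / (n * variance)).

    method 'att' -> scalar SE of the total-dosage coefficient;
    method 'tractor' -> vector of per-ancestry SEs.
    The shared proportional constant resid_var is E[Var(Y|P)].
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if resid_var < 0:
        raise ValueError("residual variance must be non-negative")
    if method == "att":
        v = var_att_marker(moments, g)
        if v <= 0:
            raise ValueError("marker has zero predicted variance (monomorphic)")
        return float(np.sqrt(resid_var / (n * v)))
    if method == "tractor":
        v = np.diag(var_tractor_matrix(moments, g))
        if np.any(v <= 0):
            raise ValueError("an ancestry has zero predicted dosage variance")
        return np.sqrt(resid_var / (n * v))
    raise ValueError(f"unknown method {method!r}")


def expected_statistics(beta: float, moments: PSDMoments, g, resid_var: float):
    """Large-n Wald statistics per individual under equal effects beta.

    Returns (per_ancestry: array, combined: float, att: float), each the
    limit of T/n. They satisfy per-ancestry <= combined <= att, with
    equality of combined and att when the frequencies are homogeneous.
    """
    g = _check_moments(moments, g)
    c = 1.0 / resid_var if resid_var > 0 else np.inf
    per = beta**2 * 2.0 * g * (1.0 - g) * moments.mean * c
    combined = float(per.sum())
    att = beta**2 * var_att_marker(moments, g) * c
    return per, combined, float(att)


def beta_tractor_epsd(ld: LDParams, alpha) -> np.ndarray:
    """Tractor's ancestry-specific marginal effect under ePSD.

    beta_lk = Σ_{j in [k]_l} D_ljk / (g_lk (1 - g_lk)) * α_j — the marginal
    effect a single-continental GWAS in population l would estimate.
    """
    alpha = np.asarray(alpha, dtype=float)
    g = ld.g
    if np.any((g <= 0) | (g >= 1)):
        raise ValueError("marker frequency at 0 or 1: weight undefined")
    return (ld.D / (g * (1.0 - g))[:, None]) @ alpha


def gamma_tractor_epsd(ld: LDParams, alpha) -> np.ndarray:
    """Local-ancestry coefficients γ_lk (l >= 1, relative to ancestry 0).

    γ absorbs the remnant of linked causal effects that the marker does not
    fully tag; under perfect tagging (f = h in every ancestry) it is exactly
    zero. Returns an array of length n_L - 1 for ancestries 1..n_L-1.
    """
    alpha = np.asarray(alpha, dtype=float)
    g = ld.g
    if np.any(g >= 1):
        raise ValueError("marker frequency of 1: weight undefined")
    remnant = (ld.f - ld.h) / (1.0 - g)[:, None]  # (n_L, n_causal)
    # the sum runs over the linked set [k]_l of each non-reference ancestry
    linked = (np.abs(ld.D[1:]) > 0).astype(float)
    return (linked * (remnant[1:] - remnant[0][None, :])) @ alpha


def la_covariance_pulse(P, l: int, lp: int, d: float, g: float) -> float:
    """Haplotype local-ancestry covariance under a single-pulse model.

    Markov ancestry along the chromosome: breakpoints Poisson(rate g per
    Morgan), new segment ancestry redrawn i.i.d. from P. Then
        Cov(1{A(0)=l}, 1{A(d)=l'} | P) = (P_l δ_{ll'} − P_l P_l') e^{−g d}.
    This is a modelling choice of this package (the covariance has no
    closed form in terms of source-population LD parameters alone); it is
    validated against the mosaic simulator by Monte Carlo.
    """
    if d < 0 or g < 0:
        raise ValueError("distance and generations must be non-negative")
    P = np.asarray(P, dtype=float)
    base = P[l] * (1.0 - P[l]) if l == lp else -P[l] * P[lp]
    return float(base * np.exp(-g * d))


def beta_att_epsd(ld: LDParams, alpha, moments: PSDMoments, la_cov=None) -> float:
    """ATT's marginal effect under ePSD: within-continental plus admixture LD.

    `la_cov(l, l', j)` returns E over P of the haplotype local-ancestry
    covariance between the marker and causal locus j for the ancestry pair
    (l, l'); defaults to zero (distant loci). The shared denominator is the
    general-n_L E[Var(M_k | P)].
    """
    alpha = np.asarray(alpha, dtype=float)
    g = ld.g
    denom = var_att_marker(moments, g)
    if denom <= 0:
        raise ValueError("marker has zero variance")
    n_L, n_j = ld.D.shape
    # within-continental LD term: E[ Σ_l 2 D_ljk P_l ] / denom
    within = 2.0 * (moments.mean @ ld.D)  # per causal locus
    # admixture-LD term: Σ_{l,l'} 2 g_l f_l'j E[Cov(L^h_kl, L^h_jl' | P)]
    admix = np.zeros(n_j)
    if la_cov is not None:
        for j in range(n_j):
            acc = 0.0
            for l in range(n_L):
                for lp in range(n_L):
                    acc += g[l] * ld.f[lp, j] * la_cov(l, lp, j)
            admix[j] = 2.0 * acc
    return float(((within + admix) / denom) @ alpha)


def epsd_ld_weight(D: float, g_freq: float) -> float:
    """ePSD-predicted regression weight D / (g (1 - g))."""
    if not 0.0 < g_freq < 1.0:
        raise ValueError("marker frequency must be strictly inside (0, 1)")
    return float(D / (g_freq * (1.0 - g_freq)))


def epsd_ld_corr(D: float, g_freq: float, f_freq: float) -> float:
    """ePSD-predicted LD correlation D / sqrt(g(1-g) f(1-f))."""
    if not (0.0 < g_freq < 1.0 and 0.0 < f_freq < 1.0):
        raise ValueError("frequencies must be strictly inside (0, 1)")
    r = D / np.sqrt(g_freq * (1.0 - g_freq) * f_freq * (1.0 - f_freq))
    return float(r)


def effective_n_factor(mean_P_l: float) -> tuple[float, float, float]:
    """SE inflation, Z deflation and effective-sample-size multiplier.

    Relative to a single-continental GWAS of ancestry l with the same n:
    the Tractor-l SE is inflated by 1/sqrt(E[P_l]), the Z-score deflated by
    sqrt(E[P_l]), and the effective sample size is the admixed sample size
    times sqrt(E[P_l]).
    """
    if not 0.0 < mean_P_l <= 1.0:
        raise ValueError("E[P_l] must lie in (0, 1]")
    root = float(np.sqrt(mean_P_l))
    return 1.0 / root, root, root
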