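"""Local-ancestry-adjusted LD in admixed cohorts vs panel LD.

For a locus pair (j, k) the LA-adjusted LD coefficients are the
coefficients of the ancestry-partitioned dosages M_k1, M_k2 in the
individual-level regression

    C_j ~ M_k1 + M_k2 + L_k2 (+ intercept),

and the panel coefficient is the slope of C_j ~ M_k (+ intercept) in a
single-continental diploid sample. Under the ePSD model both should equal
the predicted weight D_ljk / (g_lk (1 - g_lk)) per ancestry. Distance-
binned Pearson concordance between the adjusted and panel coefficients is
the summary that exposes where the ePSD assumption holds (proximal pairs)
and where it fails (distal pairs in Wright–Fisher cohorts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import AdmixedPopulation, HaplotypePanel
from .theory import epsd_ld_weight

__all__ = [
    "PairLD",
    "ConcordanceBin",
    "la_adjusted_ld",
    "panel_ld",
    "panel_pair_weight",
    "pair_catalog",
    "scan_pairs",
    "concordance_by_distance",
    "ld_vs_segments",
    "DEFAULT_BIN_EDGES_CM",
]

DEFAULT_BIN_EDGES_CM = (0.0, 0.05, 0.1, 0.25, 0.5, 1.0, 2.0, 3.0)


@dataclass
class PairLD:
    j: int
    k: int
    dist_bp: int
    dist_cm: float
    adjusted: np.ndarray  # per-ancestry LA-adjusted coefficient (admixed)
    adjusted_se: np.ndarray
    panel: np.ndarray  # per-ancestry single-continental coefficient
    panel_se: np.ndarray
    predicted: np.ndarray  # ePSD weight from panel haplotype tallies
    n_admixed: int
    n_panel: np.ndarray


@dataclass
class ConcordanceBin:
    lo_cm: float
    hi_cm: float
    corr: np.ndarray  # per ancestry
    n_pairs: int
    sparse: bool  # fewer than 10 pairs


def _ols_cols(X: np.ndarray, y: np.ndarray, n_keep: int):
    """First `n_keep` coefficients and SEs of an OLS fit, NaN if singular."""
    n, k = X.shape
    xtx = X.T @ X
    w = np.linalg.eigvalsh(xtx)
    if w[0] <= max(n, k) * np.finfo(float).eps * max(w[-1], 1.0):
        return np.full(n_keep, np.nan), np.full(n_keep, np.nan)
    inv = np.linalg.inv(xtx)
    beta = inv @ (X.T @ y)
    rss = float(y @ y - beta @ (X.T @ y))
    sigma2 = max(rss, 0.0) / (n - k)
    se = np.sqrt(sigma2 * np.diag(inv))
    return beta[:n_keep], se[:n_keep]


def la_adjusted_ld(target_dosage, M_part_k, L_k):
    """LA-adjusted LD coefficients of a pair in an admixed cohort.

    `M_part_k` and `L_k` are (n, n_L); the regression includes all
    ancestry dosage columns, the non-reference LA columns, and an
    intercept. Returns (coef, se) per ancestry, NaN where the design is
    rank-deficient (e.g. ancestry fixed at the locus).
    """
    y = np.asarray(target_dosage, dtype=float)
    M = np.atleast_2d(np.asarray(M_part_k, dtype=float))
    L = np.atleast_2d(np.asarray(L_k, dtype=float))
    n, n_L = M.shape
    X = np.hstack([M, L[:, 1:], np.ones((n, 1))])
    coef, se = _ols_cols(X, y, n_L)
    if np.isnan(coef).all() and n_L >= 1:
        # retry per ancestry with the other dosage columns dropped if only
        # one ancestry is variable
        keep = M.std(axis=0) > 0
        if keep.any() and not keep.all():
            Xr = np.hstack([M[:, keep], L[:, 1:][:, L[:, 1:].std(axis=0) > 0], np.ones((n, 1))])
            c_r, s_r = _ols_cols(Xr, y, int(keep.sum()))
            coef = np.full(n_L, np.nan)
            se = np.full(n_L, np.nan)
            coef[keep] = c_r
            se[keep] = s_r
    return coef, se


def panel_ld(target_dosage, marker_dosage):
    """Single-continental LD coefficient: slope of C_j ~ M_k + intercept."""
    y = np.asarray(target_dosage, dtype=float)
    m = np.asarray(marker_dosage, dtype=float)
    if np.std(m) == 0:
        return np.nan, np.nan
    X = np.column_stack([m, np.ones_like(m)])
    coef, se = _ols_cols(X, y, 1)
    return float(coef[0]), float(se[0])


def panel_pair_weight(panel: HaplotypePanel, j: int, k: int) -> float:
    """ePSD predicted weight D/(g(1-g)) from the panel's haplotype tallies."""
    hj = panel.haplotypes[:, j].astype(float)
    hk = panel.haplotypes[:, k].astype(float)
    g = hk.mean()
    if g in (0.0, 1.0):
        return np.nan
    D = (hj * hk).mean() - hj.mean() * g
    return epsd_ld_weight(D, g)


def pair_catalog(
    gmap,
    max_distance_cm: float,
    max_pairs: int | None = None,
    seed: int | np.random.Generator = 0,
    min_distance_cm: float = 0.0,
) -> np.ndarray:
    """Unordered locus pairs within the genetic-distance window.

    Returns an (n_pairs, 2) array of (j, k) with j < k, uniformly
    subsampled to `max_pairs` (deterministic given the seed).
    """
    if max_distance_cm <= 0:
        raise ValueError("max_distance_cm must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cm = gmap.cm
    pairs = []
    for j in range(cm.shape[0]):
        hi = np.searchsorted(cm, cm[j] + max_distance_cm, side="right")
        lo = np.searchsorted(cm, cm[j] + min_distance_cm, side="left")
        lo = max(lo, j + 1)
        for k in range(lo, hi):
            pairs.append((j, k))
    out = np.asarray(pairs, dtype=int).reshape(-1, 2)
    if max_pairs is not None and out.shape[0] > max_pairs:
        idx = rng.choice(out.shape[0], size=max_pairs, replace=False)
        out = out[np.sort(idx)]
    return out


def scan_pairs(
    pop: AdmixedPopulation,
    panels,
    pairs: np.ndarray,
    panel_offsets=None,
    n_panel_individuals: int | None = None,
) -> list[PairLD]:
    """Estimate adjusted, panel, and predicted LD for every catalogued pair.

    Panel coefficients per ancestry come from diploid samples formed from
    each panel's haplotypes (`panel_offsets` selects disjoint haplotypes if
    the panel also founded the admixed cohort).
    """
    from .forward import panel_diploids

    geno = pop.genotypes()
    M_part = geno.partitioned.astype(float)  # (n, n_loci, n_L)
    L = pop.local_ancestry().counts().astype(float)
    C = geno.dosage().astype(float)  # (n, n_loci)
    n_L = len(panels)
    offs = panel_offsets or [0] * n_L
    pan_geno = [
        panel_diploids(panels[l], n_panel_individuals, offset=offs[l]).dosage().astype(float)
        for l in range(n_L)
    ]
    out = []
    for j, k in pairs:
        adj, adj_se = la_adjusted_ld(C[:, j], M_part[:, k, :], L[:, k, :])
        pan = np.empty(n_L)
        pan_se = np.empty(n_L)
        pred = np.empty(n_L)
        for l in range(n_L):
            pan[l], pan_se[l] = panel_ld(pan_geno[l][:, j], pan_geno[l][:, k])
            pred[l] = panel_pair_weight(panels[l], j, k)
        out.append(
            PairLD(
                j=int(j), k=int(k),
                dist_bp=int(pop.gmap.bp[k] - pop.gmap.bp[j]),
                dist_cm=float(pop.gmap.cm[k] - pop.gmap.cm[j]),
                adjusted=adj, adjusted_se=adj_se,
                panel=pan, panel_se=pan_se, predicted=pred,
                n_admixed=pop.n_individuals,
                n_panel=np.array([g.shape[0] for g in pan_geno]),
            )
        )
    return out


def concordance_by_distance(pairs: list[PairLD], bin_edges_cm=DEFAULT_BIN_EDGES_CM):
    """Per-bin Pearson correlation of adjusted vs panel coefficients.

    Bins are half-open [lo, hi); bins with < 10 pairs are flagged sparse;
    empty bins give NaN correlations.
    """
    edges = np.asarray(bin_edges_cm, dtype=float)
    dist = np.array([p.dist_cm for p in pairs])
    adj = np.array([p.adjusted for p in pairs])  # (n_pairs, n_L)
    pan = np.array([p.panel for p in pairs])
    n_L = adj.shape[1] if adj.size else 0
    bins = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (dist >= lo) & (dist < hi)
        corr = np.full(n_L, np.nan)
        for l in range(n_L):
            ok = mask & ~np.isnan(adj[:, l]) & ~np.isnan(pan[:, l])
            if ok.sum() >= 2 and np.std(adj[ok, l]) > 0 and np.std(pan[ok, l]) > 0:
                corr[l] = float(np.corrcoef(adj[ok, l], pan[ok, l])[0, 1])
        bins.append(
            ConcordanceBin(lo_cm=float(lo), hi_cm=float(hi), corr=corr,
                           n_pairs=int(mask.sum()), sparse=bool(mask.sum() < 10))
        )
    return bins


def ld_vs_segments(pairs: list[PairLD], segment_lengths_cm, r_threshold: float = 0.1):
    """Overlay of LD-correlation extent against segment lengths.

    Converts each pair's predicted panel weight into the ePSD correlation
    scale |r| (using the panel frequencies via the weight-to-correlation
    factor already folded into `predicted` when frequencies are equal this
    is the weight itself; here we use the panel regression coefficient
    converted by the realized frequency ratio). Returns a dict with the
    per-pair (distance, |r|) table, a segment-length histogram on a shared
    cM axis, and the overlap index: the fraction of pairs with |r| >
    `r_threshold` at distances beyond the median segment length.
    """
    seg = np.asarray(segment_lengths_cm, dtype=float)
    dist = np.array([p.dist_cm for p in pairs])
    # mean absolute adjusted coefficient across ancestries as the LD measure
    with np.errstate(invalid="ignore"):
        r_abs = np.array([
            np.nanmean(np.abs(p.adjusted)) if not np.isnan(p.adjusted).all() else np.nan
            for p in pairs
        ])
    keep = ~np.isnan(r_abs)
    dist, r_abs = dist[keep], r_abs[keep]
    med = float(np.median(seg)) if seg.size else np.nan
    edges = np.linspace(0.0, max(seg.max() if seg.size else 1.0, dist.max() if dist.size else 1.0), 21)
    hist, _ = np.histogram(seg, bins=edges)
    beyond = dist > med
    overlap = float(np.mean(r_abs[beyond] > r_threshold)) if beyond.any() else 0.0
    return {
        "dist_cm": dist,
        "abs_ld": r_abs,
        "segment_hist_edges": edges,
        "segment_hist_counts": hist,
        "median_segment_cm": med,
        "overlap_index": overlap,
    }
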