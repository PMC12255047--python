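"""End-to-end experiments: power theory, effect-size concordance, LD scan.

Each experiment is deterministic given its seed, returns a report dict of
summary scalars plus pandas tables, and can write its tables and a run
manifest under an output directory. Problem sizes are desk-scale defaults
chosen to reproduce the qualitative regimes of the underlying theory in
minutes; see docs/methods.md for the rationale.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, forward, ldscan, meta, psd, theory, traits
from .rng import substream

__all__ = [
    "PowerConfig",
    "ConcordanceConfig",
    "LDConfig",
    "run_power_experiment",
    "run_concordance_experiment",
    "run_ld_experiment",
    "write_report",
]

log = logging.getLogger(__name__)


def _resid_var_given_ancestry(Y, P) -> float:
    """E[Var(Y|P)] estimate: residual mean square of Y ~ ancestry covariates."""
    X = np.column_stack([np.ones(len(Y)), assoc.ancestry_covariates(P)])
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return float(resid @ resid / (len(Y) - X.shape[1]))


# --------------------------------------------------------------------------
# Power experiment (PSD closed-form predictions)
# --------------------------------------------------------------------------


@dataclass
class PowerConfig:
    """Study conditions for the PSD power-theory checks.

    Ancestry proportions centre on the 80/20 African/European admixture of
    the motivating design; marker frequencies per ancestry are uniform over
    a common range so SEs genuinely vary across markers.
    """

    n_se: int = 10_000  # cohort size for the SE-accuracy check
    n_markers_se: int = 200
    dirichlet: tuple = (8.0, 2.0)
    freq_range: tuple = (0.1, 0.9)
    n_order: int = 4_000  # cohort size per frequency-gap grid point
    markers_per_gap: int = 125
    freq_gaps: tuple = (0.0, 0.2, 0.4, 0.6)
    alpha_order: float = 0.15
    n_reps_independence: int = 1_000
    n_independence: int = 2_000
    g_independence: tuple = (0.2, 0.8)
    n_reps_unbiased: int = 500
    n_unbiased: int = 2_000
    alpha_unbiased: float = 0.3
    g_unbiased: tuple = (0.3, 0.7)
    n_null_fe: int = 100_000
    n_tagging: int = 50_000
    g_tagging: tuple = (0.3, 0.7)
    mean_p_grid: tuple = (0.2, 0.5, 0.8)
    n_effn: int = 6_000
    n_markers_effn: int = 50


def _se_accuracy(cfg: PowerConfig, seed: int) -> dict:
    """Predicted (closed-form) vs empirical OLS standard errors."""
    rng = substream(seed, "se_accuracy")
    n, m = cfg.n_se, cfg.n_markers_se
    g = rng.uniform(*cfg.freq_range, size=(2, m))
    cohort = psd.simulate_cohort(n, m, ("dirichlet", cfg.dirichlet), g,
                                 int(rng.integers(2**31)))
    Y = rng.normal(size=n)
    cov = assoc.ancestry_covariates(cohort.P)
    att_beta, att_se, _ = assoc.scan_att(Y, cohort.geno.dosage().astype(float), cov)
    tr = assoc.scan_tractor(Y, cohort.geno.partitioned.astype(float),
                            cohort.la.counts().astype(float), cov)
    moments = cohort.P.moments()
    resid_var = _resid_var_given_ancestry(Y, cohort.P)
    pred_att = np.array([theory.predicted_se("att", moments, g[:, k], resid_var, n)
                         for k in range(m)])
    pred_tr = np.array([theory.predicted_se("tractor", moments, g[:, k], resid_var, n)
                        for k in range(m)])
    emp = np.concatenate([att_se[0], tr["se"][0].ravel()])
    pred = np.concatenate([pred_att, pred_tr.ravel()])
    ok = ~np.isnan(emp)
    rel_err = np.abs(pred[ok] - emp[ok]) / emp[ok]
    table = pd.DataFrame({
        "marker": np.arange(m).tolist() * 3,
        "kind": ["att"] * m + ["tractor_anc0"] * m + ["tractor_anc1"] * m,
        "predicted": np.concatenate([pred_att, pred_tr[:, 0], pred_tr[:, 1]]),
        "empirical": np.concatenate([att_se[0], tr["se"][0, :, 0], tr["se"][0, :, 1]]),
    })
    return {
        "correlation": float(np.corrcoef(pred[ok], emp[ok])[0, 1]),
        "median_rel_err": float(np.median(rel_err)),
        "table": table,
    }


def _chi2_ordering(cfg: PowerConfig, seed: int) -> dict:
    """Mean Wald statistics: per-ancestry <= FE/combined <= ATT across a
    frequency-gap grid; the ATT excess grows with (g1-g2)^2."""
    rng = substream(seed, "ordering")
    rows = []
    for gap in cfg.freq_gaps:
        g = np.array([0.5 + gap / 2.0, 0.5 - gap / 2.0])
        P = psd.draw_global_ancestry(cfg.n_order, ("dirichlet", (2.0, 2.0)), rng)
        cov = assoc.ancestry_covariates(P)
        for _ in range(cfg.markers_per_gap):
            la = psd.draw_local_ancestry(P, 1, rng)
            geno = psd.partition_dosage(psd.draw_genotypes(la, psd.FreqTable(g[:, None]), rng), la)
            M = geno.dosage()[:, 0].astype(float)
            Y = cfg.alpha_order * M + rng.normal(size=cfg.n_order)
            att = assoc.fit_att(Y, M, cov)
            tr = assoc.fit_tractor(Y, geno.partitioned[:, 0, :], la.counts()[:, 0, :], cov)
            fe = meta.fe_combine(tr.beta, tr.se)
            rows.append({
                "freq_gap": gap,
                "att": att.chi2,
                "combined": tr.chi2,
                "fe": fe.chi2_fe,
                "anc0": tr.per_ancestry_chi2[0],
                "anc1": tr.per_ancestry_chi2[1],
            })
    df = pd.DataFrame(rows)
    means = df.groupby("freq_gap").mean()
    means["att_excess"] = means["att"] - means["combined"]
    overall = df.drop(columns="freq_gap").mean()
    return {
        "mean_att": float(overall["att"]),
        "mean_combined": float(overall["combined"]),
        "mean_fe": float(overall["fe"]),
        "mean_anc_max": float(max(overall["anc0"], overall["anc1"])),
        "excess_by_gap": means["att_excess"].to_dict(),
        "table": df,
    }


def _independence(cfg: PowerConfig, seed: int) -> dict:
    """Replicated Tractor fits at one marker: cross-ancestry estimate correlation."""
    rng = substream(seed, "independence")
    g = np.asarray(cfg.g_independence)
    b1, b2 = [], []
    for _ in range(cfg.n_reps_independence):
        P = psd.draw_global_ancestry(cfg.n_independence, ("dirichlet", (8.0, 2.0)), rng)
        la = psd.draw_local_ancestry(P, 1, rng)
        geno = psd.partition_dosage(psd.draw_genotypes(la, psd.FreqTable(g[:, None]), rng), la)
        Y = rng.normal(size=cfg.n_independence)
        tr = assoc.fit_tractor(Y, geno.partitioned[:, 0, :], la.counts()[:, 0, :],
                               assoc.ancestry_covariates(P))
        b1.append(tr.beta[0])
        b2.append(tr.beta[1])
    r, lo, hi = meta.independence_diagnostic(np.asarray(b1), np.asarray(b2))
    return {"corr": r, "ci_lo": lo, "ci_hi": hi,
            "bound": 3.0 / np.sqrt(cfg.n_reps_independence),
            "beta1": np.asarray(b1), "beta2": np.asarray(b2)}


def _unbiasedness(cfg: PowerConfig, seed: int) -> dict:
    """ATT and Tractor estimates at a directly tested causal variant."""
    rng = substream(seed, "unbiasedness")
    g = np.asarray(cfg.g_unbiased)
    est = {"att": [], "anc0": [], "anc1": []}
    for _ in range(cfg.n_reps_unbiased):
        P = psd.draw_global_ancestry(cfg.n_unbiased, ("dirichlet", (8.0, 2.0)), rng)
        la = psd.draw_local_ancestry(P, 1, rng)
        geno = psd.partition_dosage(psd.draw_genotypes(la, psd.FreqTable(g[:, None]), rng), la)
        M = geno.dosage()[:, 0].astype(float)
        Y = cfg.alpha_unbiased * M + rng.normal(size=cfg.n_unbiased)
        cov = assoc.ancestry_covariates(P)
        est["att"].append(assoc.fit_att(Y, M, cov).beta)
        tr = assoc.fit_tractor(Y, geno.partitioned[:, 0, :], la.counts()[:, 0, :], cov)
        est["anc0"].append(tr.beta[0])
        est["anc1"].append(tr.beta[1])
    out = {}
    for key, vals in est.items():
        v = np.asarray(vals)
        out[key] = {"mean": float(v.mean()),
                    "se_of_mean": float(v.std(ddof=1) / np.sqrt(v.size)),
                    "z_from_alpha": float((v.mean() - cfg.alpha_unbiased)
                                          / (v.std(ddof=1) / np.sqrt(v.size)))}
    out["alpha"] = cfg.alpha_unbiased
    return out


def _fe_null(cfg: PowerConfig, seed: int) -> dict:
    """FE chi-square calibration under the null.

    Null replicate estimate pairs are drawn from the asymptotic sampling
    law of the Tractor coefficients (independent normals with the
    theory-predicted SEs); the pooled statistic should be chi-square(1).
    """
    rng = substream(seed, "fe_null")
    moments = theory.PSDMoments.dirichlet((8.0, 2.0))
    se = theory.predicted_se("tractor", moments, np.array([0.3, 0.7]), 1.0, 5_000)
    betas = rng.normal(0.0, se[None, :], size=(cfg.n_null_fe, 2))
    ses = np.broadcast_to(se, (cfg.n_null_fe, 2))
    _, _, chi2_fe, q = meta.fe_combine_arrays(betas, ses)
    return {
        "mean_chi2_fe": float(chi2_fe.mean()),
        "mc_se": float(chi2_fe.std(ddof=1) / np.sqrt(cfg.n_null_fe)),
        "mean_q": float(q.mean()),
    }


def _perfect_tagging(cfg: PowerConfig, seed: int) -> dict:
    """LA coefficient at a directly tested causal variant is zero."""
    rng = substream(seed, "tagging")
    g = np.asarray(cfg.g_tagging)
    # closed form: marker tags itself perfectly, f = h
    ld = theory.LDParams(f=g[:, None], g=g, h=g[:, None])
    gamma_closed = theory.gamma_tractor_epsd(ld, np.array([1.0]))
    P = psd.draw_global_ancestry(cfg.n_tagging, ("dirichlet", (8.0, 2.0)), rng)
    la = psd.draw_local_ancestry(P, 1, rng)
    geno = psd.partition_dosage(psd.draw_genotypes(la, psd.FreqTable(g[:, None]), rng), la)
    # the marker tags the causal variant perfectly (it *is* the causal
    # variant); environmental noise keeps the regression non-degenerate
    Y = 0.5 * geno.dosage()[:, 0].astype(float) + rng.normal(size=cfg.n_tagging)
    tr = assoc.fit_tractor(Y, geno.partitioned[:, 0, :], la.counts()[:, 0, :],
                           assoc.ancestry_covariates(P))
    # gamma SE: refit via statsmodels-free path — use the design's covariance
    # through a direct OLS on the same columns
    X = np.column_stack([
        geno.partitioned[:, 0, 0], geno.partitioned[:, 0, 1],
        la.counts()[:, 0, 1], assoc.ancestry_covariates(P)[:, 0], np.ones(cfg.n_tagging),
    ]).astype(float)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)
    rss = float(Y @ Y - beta @ (X.T @ Y))
    gamma_se = float(np.sqrt(max(rss, 0.0) / (cfg.n_tagging - X.shape[1]) * xtx_inv[2, 2]))
    return {
        "gamma_closed_form": float(np.max(np.abs(gamma_closed))),
        "gamma_hat": float(tr.gamma[0]),
        "gamma_se": gamma_se,
        "abs_z": float(abs(tr.gamma[0]) / gamma_se) if gamma_se > 0 else np.inf,
    }


def _effective_n(cfg: PowerConfig, seed: int) -> dict:
    """Tractor-l SE inflation vs a single-continental GWAS of equal n."""
    rng = substream(seed, "effective_n")
    out = {}
    for p in cfg.mean_p_grid:
        g_shared = rng.uniform(0.2, 0.8, size=cfg.n_markers_effn)
        g = np.vstack([g_shared, g_shared])  # no frequency heterogeneity
        admixed = psd.simulate_cohort(cfg.n_effn, cfg.n_markers_effn, (p, 1.0 - p), g,
                                      int(rng.integers(2**31)))
        Y = rng.normal(size=cfg.n_effn)
        tr = assoc.scan_tractor(Y, admixed.geno.partitioned.astype(float),
                                admixed.la.counts().astype(float),
                                assoc.ancestry_covariates(admixed.P))
        single = psd.simulate_cohort(cfg.n_effn, cfg.n_markers_effn, (1.0, 0.0), g,
                                     int(rng.integers(2**31)))
        Ys = rng.normal(size=cfg.n_effn)
        _, se_single, _ = assoc.scan_att(Ys, single.geno.dosage().astype(float), None)
        ratio = tr["se"][0, :, 0] / se_single[0]
        out[p] = {
            "mean_ratio": float(np.nanmean(ratio)),
            "predicted": theory.effective_n_factor(p)[0],
        }
    return out


def run_power_experiment(seed: int = 0, config: PowerConfig | None = None,
                         out_dir=None) -> dict:
    """PSD power-theory experiment: SE accuracy, statistic ordering,
    estimate independence, unbiasedness, FE calibration, perfect tagging,
    and the effective-sample-size factor."""
    cfg = config or PowerConfig()
    t0 = time.time()
    report = {
        "experiment": "power",
        "seed": seed,
        "se_accuracy": _se_accuracy(cfg, seed),
        "ordering": _chi2_ordering(cfg, seed),
        "independence": _independence(cfg, seed),
        "unbiasedness": _unbiasedness(cfg, seed),
        "fe_null": _fe_null(cfg, seed),
        "perfect_tagging": _perfect_tagging(cfg, seed),
        "effective_n": _effective_n(cfg, seed),
    }
    report["elapsed_s"] = time.time() - t0
    log.info("power experiment done in %.1fs", report["elapsed_s"])
    if out_dir is not None:
        write_report(report, out_dir, asdict(cfg))
    return report


# --------------------------------------------------------------------------
# Concordance experiment (Tractor vs single-continental marginal effects)
# --------------------------------------------------------------------------


@dataclass
class ConcordanceConfig:
    """Forward-WF admixed cohort vs single-continental panel GWAS.

    Admixture 12 generations ago at 80% ancestry-0 / 20% ancestry-1; trait
    heritability fixed at 1 (no environmental noise) so discordance is
    attributable to LD differences alone. Replicate trait draws per
    polygenicity give enough causal markers at the sparse end of the grid.
    """

    n_loci: int = 2000
    region_bp: int = 50_000_000
    recomb_rate: float = 1.0e-8
    p_anc_range: tuple = (0.1, 0.9)
    fst: tuple = (0.15, 0.15)
    lam: float = 0.002  # Morgans: short within-continental LD (~0.2 cM)
    pi: tuple = (0.8, 0.2)
    generations: int = 12
    n_admixed: int = 2000
    n_single: int = 1000  # diploids per single-continental cohort
    n_founders_wf: int = 400  # small founder pool -> long-range admixed LD
    n_founder_hap: int = 2000  # haplotypes available to the founding pulse
    polygenicity_grid: tuple = traits.POLYGENICITY_GRID
    reps_per_polygenicity: tuple = (20, 8, 5, 3)
    effect_sd: float = 1.0
    h2: float = 1.0
    maf: float = 0.01


def _build_linked_world(n_loci, region_bp, recomb_rate, p_anc_range, fst, lam,
                        n_hap_total, seed):
    """Shared scaffolding: map, BN frequencies, one panel per ancestry."""
    gmap = forward.GeneticMap.uniform(n_loci, region_bp, recomb_rate)
    rng = substream(seed, "panel_freqs")
    p_anc = rng.uniform(*p_anc_range, size=gmap.n_loci)
    freqs = forward.ancestral_freqs(p_anc, fst, seed=rng,
                                    clip=1.0 / (2.0 * n_hap_total))
    panels = [
        forward.simulate_panel(freqs.freqs[l], gmap, lam, n_hap_total,
                               substream(seed, f"panel_{l}"), label=f"anc{l}",
                               fst=fst[l])
        for l in range(len(fst))
    ]
    return gmap, freqs, panels


def _split_panel(panel, n_front):
    """Slice one simulated panel into disjoint front/back sub-panels."""
    front = forward.HaplotypePanel(panel.label, panel.haplotypes[:n_front],
                                   panel.gmap, panel.target_freqs, panel.lam, panel.fst)
    back = forward.HaplotypePanel(panel.label, panel.haplotypes[n_front:],
                                  panel.gmap, panel.target_freqs, panel.lam, panel.fst)
    return front, back


def run_concordance_experiment(seed: int = 0, config: ConcordanceConfig | None = None,
                               out_dir=None) -> dict:
    """Tractor (admixed) vs single-continental marginal effects by polygenicity."""
    cfg = config or ConcordanceConfig()
    t0 = time.time()
    n_hap_total = 2 * cfg.n_single + cfg.n_founder_hap
    gmap, _, panels = _build_linked_world(
        cfg.n_loci, cfg.region_bp, cfg.recomb_rate, cfg.p_anc_range, cfg.fst,
        cfg.lam, n_hap_total, seed)
    ref_panels, founder_panels = zip(*[_split_panel(p, 2 * cfg.n_single) for p in panels])
    founders = forward.found_admixed(founder_panels, cfg.n_founders_wf, cfg.pi,
                                     substream(seed, "founding"))
    admixed = forward.evolve_wright_fisher(founders, cfg.generations,
                                           substream(seed, "wf"),
                                           final_size=cfg.n_admixed)
    geno = admixed.genotypes()
    la_counts = admixed.local_ancestry().counts().astype(float)
    M_part = geno.partitioned.astype(float)
    P_real = forward.realized_global_ancestry(admixed)
    cov = assoc.ancestry_covariates(P_real)
    singles = [forward.panel_diploids(rp) for rp in ref_panels]
    pooled = geno.pooled_freq()
    usable = (np.minimum(pooled, 1 - pooled) >= cfg.maf)
    for s in singles:
        pf = s.pooled_freq()
        usable &= (np.minimum(pf, 1 - pf) >= cfg.maf)

    trait_rng = substream(seed, "traits")
    jobs = []  # (polygenicity, arch)
    for pg, reps in zip(cfg.polygenicity_grid, cfg.reps_per_polygenicity):
        for _ in range(reps):
            # at the sparsest polygenicity an architecture draw can come up
            # empty (prob ~ e^{-2} per draw); redraw until a causal set exists
            for _attempt in range(50):
                try:
                    arch = traits.draw_architecture(cfg.n_loci, pg, cfg.effect_sd,
                                                    trait_rng, h2=cfg.h2)
                    break
                except ValueError:
                    log.info("empty architecture at polygenicity %g; redrawing", pg)
            else:
                raise RuntimeError(f"could not draw a causal set at polygenicity {pg}")
            jobs.append((pg, arch))
    Y_adm = np.stack([
        traits.simulate_trait(geno.dosage().astype(float), arch, seed=trait_rng).Y
        for _, arch in jobs
    ])
    Y_single = [
        np.stack([traits.simulate_trait(s.dosage().astype(float), arch, seed=trait_rng).Y
                  for _, arch in jobs])
        for s in singles
    ]
    tr = assoc.scan_tractor(Y_adm, M_part, la_counts, cov)
    single_beta = [assoc.scan_att(Y_single[l], singles[l].dosage().astype(float), None)[0]
                   for l in range(len(singles))]

    rows = []
    for t, (pg, arch) in enumerate(jobs):
        causal_mask = np.zeros(cfg.n_loci, dtype=bool)
        causal_mask[arch.causal_idx] = True
        for l in range(len(singles)):
            adm = tr["beta"][t, :, l]
            sc = single_beta[l][t]
            ok = usable & ~np.isnan(adm) & ~np.isnan(sc)
            for scope, mask in (("all", ok), ("causal", ok & causal_mask)):
                rows.append({
                    "polygenicity": pg, "replicate": t, "ancestry": l, "scope": scope,
                    "n_markers": int(mask.sum()),
                    "adm": adm[mask], "single": sc[mask],
                })
    # pool replicates within (polygenicity, ancestry, scope)
    summary = []
    for pg in cfg.polygenicity_grid:
        for l in range(len(singles)):
            for scope in ("all", "causal"):
                sel = [r for r in rows
                       if r["polygenicity"] == pg and r["ancestry"] == l and r["scope"] == scope]
                a = np.concatenate([r["adm"] for r in sel])
                s = np.concatenate([r["single"] for r in sel])
                corr = float(np.corrcoef(a, s)[0, 1]) if a.size >= 3 and a.std() > 0 else np.nan
                summary.append({"polygenicity": pg, "ancestry": l, "scope": scope,
                                "n_points": int(a.size), "correlation": corr})
    df = pd.DataFrame(summary)

    def _get(pg, scope):
        sel = df[(df.polygenicity == pg) & (df.scope == scope)]
        return float(sel.correlation.mean())

    grid = cfg.polygenicity_grid
    report = {
        "experiment": "concordance",
        "seed": seed,
        "summary": df,
        "all_marker_corr_low_poly": _get(grid[0], "all"),
        "all_marker_corr_high_poly": _get(grid[-1], "all"),
        "causal_corr_low_poly": _get(grid[0], "causal"),
        "causal_corr_high_poly": _get(grid[-1], "causal"),
        "all_marker_corr_by_poly": {pg: _get(pg, "all") for pg in grid},
        "causal_corr_by_poly": {pg: _get(pg, "causal") for pg in grid},
        "elapsed_s": time.time() - t0,
    }
    log.info("concordance experiment done in %.1fs", report["elapsed_s"])
    if out_dir is not None:
        write_report(report, out_dir, asdict(cfg))
    return report


# --------------------------------------------------------------------------
# LD experiment (ePSD positive control and Wright-Fisher failure mode)
# --------------------------------------------------------------------------


@dataclass
class LDConfig:
    """Mosaic-copy and forward-WF scenarios on shared maps and frequencies.

    Two LD regimes: `lam_short` (within-continental LD far shorter than the
    ~8 cM ancestry segments — where the ePSD approximation should hold) and
    `lam_long` (LD length comparable to 1/g — where it breaks). The
    positive-control agreement checks run on the short-LD mosaic arm; the
    distance-binned concordance contrast runs on the long-LD mosaic and WF
    arms. The WF arm is founded from a deliberately small pool and expanded
    in the final generation, which strengthens founder LD beyond ancestry
    segments.
    """

    n_loci: int = 1200
    region_bp: int = 50_000_000
    recomb_rate: float = 1.0e-8
    p_anc_range: tuple = (0.15, 0.85)
    fst: tuple = (0.15, 0.15)
    lam_short: float = 0.002  # Morgans
    lam_long: float = 0.05  # Morgans, comparable to 1/g
    pi: tuple = (0.8, 0.2)
    generations: int = 12
    n_admixed: int = 2000
    n_founders_wf: int = 400
    n_single: int = 1000
    n_founder_hap: int = 2000
    max_distance_cm: float = 3.0
    max_pairs: int = 4000
    overlay_distance_cm: float = 12.0  # catalog for the segment-length overlay
    overlay_pairs: int = 2000
    bin_edges_cm: tuple = ldscan.DEFAULT_BIN_EDGES_CM
    panel_r_threshold: float = 0.2


def run_ld_experiment(seed: int = 0, config: LDConfig | None = None,
                      out_dir=None) -> dict:
    """LA-adjusted vs panel LD for ePSD-true (mosaic) and WF cohorts."""
    cfg = config or LDConfig()
    t0 = time.time()
    n_hap_total = 2 * cfg.n_single + cfg.n_founder_hap
    pairs_idx = None
    overlay_idx = None
    arms = {}
    gmap = None
    for regime, lam in (("short", cfg.lam_short), ("long", cfg.lam_long)):
        gmap, _, panels = _build_linked_world(
            cfg.n_loci, cfg.region_bp, cfg.recomb_rate, cfg.p_anc_range, cfg.fst,
            lam, n_hap_total, seed)
        ref_panels, founder_panels = zip(*[_split_panel(p, 2 * cfg.n_single)
                                          for p in panels])
        if pairs_idx is None:
            pairs_idx = ldscan.pair_catalog(gmap, cfg.max_distance_cm, cfg.max_pairs,
                                            substream(seed, "pairs"))
            overlay_idx = ldscan.pair_catalog(gmap, cfg.overlay_distance_cm,
                                              cfg.overlay_pairs,
                                              substream(seed, "overlay_pairs"))
        mosaic = forward.mosaic_copy(founder_panels, cfg.n_admixed, cfg.pi,
                                     cfg.generations, substream(seed, f"mosaic_{regime}"))
        pops = {f"mosaic_{regime}": mosaic}
        if regime == "long":
            founders = forward.found_admixed(founder_panels, cfg.n_founders_wf,
                                             cfg.pi, substream(seed, "founding"))
            pops["forward_wf"] = forward.evolve_wright_fisher(
                founders, cfg.generations, substream(seed, "wf"),
                final_size=cfg.n_admixed)
        for name, pop in pops.items():
            pairs = ldscan.scan_pairs(pop, ref_panels, pairs_idx)
            arms[name] = {
                "pairs": pairs,
                "bins": ldscan.concordance_by_distance(pairs, cfg.bin_edges_cm),
                "overlay_pairs": ldscan.scan_pairs(pop, ref_panels, overlay_idx),
                "ref_panels": ref_panels,
                "pop": pop,
            }

    # positive-control agreement on short-LD mosaic pairs with real panel LD
    pos = []
    ctl = arms["mosaic_short"]
    for p in ctl["pairs"]:
        for l in range(2):
            r_panel = _coef_to_corr(p, l, ctl["ref_panels"])
            if np.isnan(r_panel) or abs(r_panel) <= cfg.panel_r_threshold:
                continue
            if np.isnan(p.adjusted[l]) or np.isnan(p.panel[l]):
                continue
            se = float(np.hypot(p.adjusted_se[l], p.panel_se[l]))
            if se <= 0:
                continue
            pos.append({
                "dist_cm": p.dist_cm, "ancestry": l,
                "adj_minus_panel_z": (p.adjusted[l] - p.panel[l]) / se,
                "adj_minus_pred_z": (p.adjusted[l] - p.predicted[l]) / se,
            })
    pos_df = pd.DataFrame(pos)

    seg = forward.segment_lengths(ctl["pop"])
    seg_oracle = forward.interior_segment_mean_oracle(cfg.generations,
                                                      gmap.total_morgans)

    bins_df = _bins_frame(arms, cfg)
    report = {
        "experiment": "ld",
        "seed": seed,
        "bins": bins_df,
        "positive_control": pos_df,
        "n_positive_pairs": int(len(pos_df)),
        "frac_within_3se_panel": float(np.mean(np.abs(pos_df.adj_minus_panel_z) < 3.0)),
        "frac_within_3se_pred": float(np.mean(np.abs(pos_df.adj_minus_pred_z) < 3.0)),
        "segment_mean_cm": float(seg.mean()),
        "segment_mean_mc_se": float(seg.std(ddof=1) / np.sqrt(seg.size)),
        "segment_mean_oracle_cm": seg_oracle,
        "segment_naive_mean_cm": 100.0 / cfg.generations,
        "n_interior_segments": int(seg.size),
        "overlap": {
            name: ldscan.ld_vs_segments(arms[name]["overlay_pairs"],
                                        forward.segment_lengths(arms[name]["pop"]))
            for name in arms
        },
        "elapsed_s": time.time() - t0,
    }
    report["overlap_index_short"] = report["overlap"]["mosaic_short"]["overlap_index"]
    report["overlap_index_wf"] = report["overlap"]["forward_wf"]["overlap_index"]
    log.info("ld experiment done in %.1fs", report["elapsed_s"])
    if out_dir is not None:
        write_report(report, out_dir, asdict(cfg))
    return report


def _coef_to_corr(pair, l, ref_panels) -> float:
    """Convert the panel regression coefficient to the correlation scale."""
    pan = ref_panels[l]
    g = pan.haplotypes[:, pair.k].mean()
    f = pan.haplotypes[:, pair.j].mean()
    if g in (0.0, 1.0) or f in (0.0, 1.0) or np.isnan(pair.panel[l]):
        return np.nan
    return float(pair.panel[l] * np.sqrt(g * (1 - g) / (f * (1 - f))))


def _bins_frame(arms, cfg) -> pd.DataFrame:
    rows = []
    for name, arm in arms.items():
        for b in arm["bins"]:
            rows.append({
                "arm": name, "lo_cm": b.lo_cm, "hi_cm": b.hi_cm,
                "n_pairs": b.n_pairs, "sparse": b.sparse,
                "corr_anc0": b.corr[0], "corr_anc1": b.corr[1],
            })
    return pd.DataFrame(rows)


def write_report(report: dict, out_dir, config_echo: dict | None = None) -> None:
    """Persist the report's tables as TSV plus a manifest."""
    from .io import write_manifest

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs = []
    for key, val in list(report.items()):
        if isinstance(val, pd.DataFrame):
            path = out / f"{report['experiment']}_{key}.tsv"
            val.to_csv(path, sep="\t", index=False, float_format="%.10g")
            outputs.append(path.name)
        elif isinstance(val, dict) and "table" in val and isinstance(val["table"], pd.DataFrame):
            path = out / f"{report['experiment']}_{key}.tsv"
            val["table"].to_csv(path, sep="\t", index=False, float_format="%.10g")
            outputs.append(path.name)
    write_manifest(out / f"{report['experiment']}_manifest.json",
                   config_echo or {}, {"seed": report.get("seed")},
                   outputs=outputs)
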