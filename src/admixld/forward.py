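"""Admixed-cohort simulation with linked loci and exact local ancestry.

Source haplotype panels with within-continental LD are built from a
latent-Gaussian model: along the locus grid, each haplotype carries a
stationary AR(1) Gaussian sequence with inter-locus correlation
exp(-d / lambda) at genetic distance d Morgans, thresholded at the
(1 - f)-quantile so the allele frequency is f and the pairwise allele
correlation decays monotonically with distance (computable exactly from the
bivariate-normal orthant probability). Allele-frequency divergence between
panels follows the Balding–Nichols model parameterised by Fst.

Admixed cohorts are then created two ways:

* `found_admixed` + `evolve_wright_fisher` — a single admixture pulse
  followed by forward Wright–Fisher mating with Poisson recombination
  (rate 1 per Morgan); alleles and ancestry labels are inherited jointly,
  so local ancestry is exact. Realistic: long-range LD beyond ancestry
  segments can arise, and the ePSD assumption may fail.
* `mosaic_copy` — ancestry breakpoints from a Poisson process of rate g per
  Morgan, i.i.d. segment ancestries, each segment copied from an
  independently re-chosen panel haplotype. This realises the ePSD model by
  construction (conditional on local ancestry, different segments are
  independent) and serves as the positive control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .psd import FreqTable, GenotypeSet, GlobalAncestry, LocalAncestry

__all__ = [
    "GeneticMap",
    "HaplotypePanel",
    "AdmixedPopulation",
    "SimConfig",
    "ancestral_freqs",
    "simulate_panel",
    "found_admixed",
    "evolve_wright_fisher",
    "mosaic_copy",
    "segment_lengths",
    "interior_segment_mean_oracle",
    "realized_global_ancestry",
    "panel_diploids",
    "latent_to_allele_corr",
]


@dataclass
class GeneticMap:
    """Locus grid: physical positions (bp, 0-based) and genetic positions (M)."""

    bp: np.ndarray
    morgans: np.ndarray

    def __post_init__(self) -> None:
        self.bp = np.asarray(self.bp, dtype=np.int64)
        self.morgans = np.asarray(self.morgans, dtype=float)
        if self.bp.shape != self.morgans.shape or self.bp.ndim != 1:
            raise ValueError("bp and Morgan position vectors must be 1-d and equal length")
        if np.any(np.diff(self.bp) <= 0) or np.any(np.diff(self.morgans) <= 0):
            raise ValueError("map positions must be strictly increasing")
        if self.morgans[0] != 0.0:
            raise ValueError("genetic position must be 0 at the first locus")
        if np.any(self.morgans < 0):
            raise ValueError("genetic positions must be non-negative")

    @classmethod
    def uniform(cls, n_loci: int, region_bp: int, rate_per_bp: float) -> "GeneticMap":
        """Evenly spaced loci over [0, region_bp) at a constant recombination rate."""
        bp = np.linspace(0, region_bp, n_loci, endpoint=False).astype(np.int64)
        bp = np.unique(bp)
        return cls(bp=bp, morgans=(bp - bp[0]) * rate_per_bp)

    @property
    def n_loci(self) -> int:
        return self.bp.shape[0]

    @property
    def cm(self) -> np.ndarray:
        return self.morgans * 100.0

    @property
    def total_morgans(self) -> float:
        return float(self.morgans[-1])

    def locus_weights_morgans(self) -> np.ndarray:
        """Morgan span attributed to each locus (midpoint partition of the map)."""
        m = self.morgans
        mids = (m[:-1] + m[1:]) / 2.0
        edges = np.concatenate([[m[0]], mids, [m[-1]]])
        w = np.diff(edges)
        if self.n_loci == 1:
            return np.ones(1)
        return w


def ancestral_freqs(
    p_anc,
    fst,
    n_loci: int | None = None,
    seed: int | np.random.Generator = 0,
    clip: float | None = None,
) -> FreqTable:
    """Balding–Nichols ancestry-specific frequencies around p_anc.

    Per population l with drift F_l, the frequency at each locus is drawn
    Beta(p (1-F)/F, (1-p)(1-F)/F), so E = p and cross-population
    E[(f_1 - f_2)^2] = (F_1 + F_2) p (1 - p). `clip` bounds the output away
    from {0, 1} (use 1/(2 * panel size)).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fst = np.atleast_1d(np.asarray(fst, dtype=float))
    if np.any((fst <= 0.0) | (fst >= 1.0)):
        raise ValueError("Fst must lie strictly inside (0, 1)")
    p = np.atleast_1d(np.asarray(p_anc, dtype=float))
    if n_loci is not None and p.size == 1:
        p = np.full(n_loci, p[0])
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("ancestral frequencies must lie strictly inside (0, 1)")
    out = np.empty((fst.size, p.size))
    for l, F in enumerate(fst):
        scale = (1.0 - F) / F
        out[l] = rng.beta(p * scale, (1.0 - p) * scale)
    if clip is not None:
        out = np.clip(out, clip, 1.0 - clip)
    return FreqTable(out)


@dataclass
class HaplotypePanel:
    """A source-population haplotype sample on a shared locus grid."""

    label: str
    haplotypes: np.ndarray  # (n_hap, n_loci) int8
    gmap: GeneticMap
    target_freqs: np.ndarray  # the f used to threshold
    lam: float  # LD decay length in Morgans
    fst: float | None = None

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[1]

    def realized_freqs(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


def latent_to_allele_corr(rho: float, f1: float = 0.5, f2: float = 0.5) -> float:
    """Allele correlation implied by latent Gaussian correlation `rho`.

    Orthant probability of the bivariate normal: with thresholds at the
    (1 - f)-quantiles, P11 = P(X > a, Y > b), and the allele correlation is
    (P11 - f1 f2) / sqrt(f1(1-f1) f2(1-f2)).
    """
    a = stats.norm.ppf(1.0 - f1)
    b = stats.norm.ppf(1.0 - f2)
    p11 = stats.multivariate_normal(cov=[[1.0, rho], [rho, 1.0]]).cdf([-a, -b])
    return float((p11 - f1 * f2) / np.sqrt(f1 * (1 - f1) * f2 * (1 - f2)))


def simulate_panel(
    freqs,
    gmap: GeneticMap,
    lam: float,
    n_hap: int,
    seed: int | np.random.Generator,
    label: str = "panel",
    fst: float | None = None,
) -> HaplotypePanel:
    """Latent-AR(1) haplotype panel with LD decay length `lam` Morgans."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if lam <= 0:
        raise ValueError("LD decay length lambda must be positive")
    f = np.asarray(freqs, dtype=float)
    if f.shape[0] != gmap.n_loci:
        raise ValueError("frequency vector and map disagree on locus count")
    n_loci = gmap.n_loci
    d = np.diff(gmap.morgans)
    rho = np.exp(-d / lam)
    x = np.empty((n_hap, n_loci))
    x[:, 0] = rng.normal(size=n_hap)
    innov = rng.normal(size=(n_hap, n_loci - 1))
    for k in range(1, n_loci):
        r = rho[k - 1]
        x[:, k] = r * x[:, k - 1] + np.sqrt(1.0 - r * r) * innov[:, k - 1]
    thresh = stats.norm.ppf(1.0 - f)
    hap = (x > thresh[None, :]).astype(np.int8)
    return HaplotypePanel(label=label, haplotypes=hap, gmap=gmap, target_freqs=f,
                          lam=lam, fst=fst)


@dataclass
class AdmixedPopulation:
    """Admixed cohort with exact per-haplotype local-ancestry tracks.

    Haplotypes 2i and 2i+1 belong to individual i. `breakpoints`, when
    present (mosaic flavour), stores each haplotype's recombination-
    delimited segment boundaries in Morgans; for Wright–Fisher cohorts the
    ancestry track is the per-locus label array.
    """

    haplotypes: np.ndarray  # (2n, n_loci) int8 alleles
    labels: np.ndarray  # (2n, n_loci) int8 ancestry labels
    gmap: GeneticMap
    pi: np.ndarray
    generations: int
    flavor: str  # {"forward_wf", "mosaic_copy", "founder"}
    n_ancestries: int
    breakpoints: list | None = None  # per haplotype, Morgans, interior only

    def __post_init__(self) -> None:
        if self.haplotypes.shape != self.labels.shape:
            raise ValueError("allele and label matrices must share a shape")
        if self.haplotypes.shape[0] % 2:
            raise ValueError("odd haplotype count: expected diploid individuals")

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[1]

    def local_ancestry(self) -> LocalAncestry:
        lab = self.labels.reshape(self.n_individuals, 2, self.n_loci)
        return LocalAncestry(lab.copy(), n_ancestries=self.n_ancestries)

    def genotypes(self) -> GenotypeSet:
        from .psd import partition_dosage

        hap = self.haplotypes.reshape(self.n_individuals, 2, self.n_loci)
        return partition_dosage(GenotypeSet(hap.copy()), self.local_ancestry())


@dataclass
class SimConfig:
    """Desk-scale scenario defaults for the linked-locus experiments."""

    n_loci: int = 2000
    region_bp: int = 50_000_000
    recomb_rate: float = 1.0e-8  # per bp per generation -> 50 cM region
    n_hap_panel: int = 2000
    n_admixed: int = 2000
    fst: tuple = (0.15, 0.15)
    lam: float = 0.05  # Morgans; ~1/g, the "LD comparable to segments" regime
    pi: tuple = (0.8, 0.2)
    generations: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.pi) - 1.0) > 1e-9:
            raise ValueError("admixture proportions must sum to 1")
        for name in ("n_loci", "region_bp", "n_hap_panel", "n_admixed"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def build_map(self) -> GeneticMap:
        return GeneticMap.uniform(self.n_loci, self.region_bp, self.recomb_rate)


def _check_panels(panels) -> tuple[int, GeneticMap]:
    if not panels or any(p.n_hap == 0 for p in panels):
        raise ValueError("need non-empty haplotype panels")
    n_loci = panels[0].n_loci
    if any(p.n_loci != n_loci for p in panels):
        raise ValueError("panels must share one locus grid")
    return n_loci, panels[0].gmap


def found_admixed(
    panels,
    n_individuals: int,
    pi,
    seed: int | np.random.Generator,
) -> AdmixedPopulation:
    """Single-pulse founding: each founder haplotype is a whole panel haplotype."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_loci, gmap = _check_panels(panels)
    pi = np.asarray(pi, dtype=float)
    n_hap = 2 * n_individuals
    anc = rng.choice(pi.size, size=n_hap, p=pi)
    hap = np.empty((n_hap, n_loci), dtype=np.int8)
    lab = np.empty((n_hap, n_loci), dtype=np.int8)
    for l, panel in enumerate(panels):
        idx = np.flatnonzero(anc == l)
        src = rng.integers(panel.n_hap, size=idx.size)
        hap[idx] = panel.haplotypes[src]
        lab[idx] = l
    return AdmixedPopulation(
        haplotypes=hap, labels=lab, gmap=gmap, pi=pi, generations=0,
        flavor="founder", n_ancestries=len(panels),
        breakpoints=[np.empty(0) for _ in range(n_hap)],
    )


def _gametes(hap, lab, parents, gmap: GeneticMap, rng) -> tuple[np.ndarray, np.ndarray]:
    """One recombined gamete per parent in `parents` (indices of individuals)."""
    morgans = gmap.morgans
    total = gmap.total_morgans
    n_out = parents.shape[0]
    n_loci = morgans.shape[0]
    out_h = np.empty((n_out, n_loci), dtype=np.int8)
    out_l = np.empty((n_out, n_loci), dtype=np.int8)
    n_break = rng.poisson(total, size=n_out)
    starts = rng.integers(2, size=n_out)
    for i in range(n_out):
        a, b = 2 * parents[i], 2 * parents[i] + 1
        if n_break[i] == 0:
            src = a if starts[i] == 0 else b
            out_h[i] = hap[src]
            out_l[i] = lab[src]
            continue
        pos = np.sort(rng.random(n_break[i]) * total)
        seg = np.searchsorted(pos, morgans, side="right")
        use_b = (seg + starts[i]) % 2 == 1
        out_h[i] = np.where(use_b, hap[b], hap[a])
        out_l[i] = np.where(use_b, lab[b], lab[a])
    return out_h, out_l


def evolve_wright_fisher(
    pop: AdmixedPopulation,
    generations: int,
    seed: int | np.random.Generator,
    final_size: int | None = None,
) -> AdmixedPopulation:
    """Forward Wright–Fisher mating with Poisson recombination.

    Each round replaces the population with N offspring; every offspring
    draws two distinct parents uniformly (no selfing, shared parents
    allowed) and receives one recombined gamete from each. Alleles and
    ancestry labels are inherited jointly, so local ancestry stays exact.
    `final_size`, if given, sets the offspring count of the last round
    (e.g. to expand a small founder pool into the analysis cohort).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if generations < 0:
        raise ValueError("generations must be non-negative")
    if pop.n_individuals < 2:
        raise ValueError("need at least 2 individuals for Wright-Fisher mating")
    hap, lab = pop.haplotypes, pop.labels
    n = pop.n_individuals
    for gen in range(generations):
        n_off = n if (final_size is None or gen < generations - 1) else final_size
        p1 = rng.integers(n, size=n_off)
        p2 = rng.integers(n - 1, size=n_off)
        p2 = p2 + (p2 >= p1)
        g1h, g1l = _gametes(hap, lab, p1, pop.gmap, rng)
        g2h, g2l = _gametes(hap, lab, p2, pop.gmap, rng)
        hap = np.empty((2 * n_off, pop.n_loci), dtype=np.int8)
        lab = np.empty((2 * n_off, pop.n_loci), dtype=np.int8)
        hap[0::2], hap[1::2] = g1h, g2h
        lab[0::2], lab[1::2] = g1l, g2l
        n = n_off
    return AdmixedPopulation(
        haplotypes=hap, labels=lab, gmap=pop.gmap, pi=pop.pi,
        generations=pop.generations + generations,
        flavor="forward_wf" if generations > 0 else pop.flavor,
        n_ancestries=pop.n_ancestries, breakpoints=None,
    )


def mosaic_copy(
    panels,
    n_individuals: int,
    pi,
    g: float,
    seed: int | np.random.Generator,
) -> AdmixedPopulation:
    """ePSD-true mosaic cohort: independent panel copies per segment.

    Breakpoints follow a Poisson process of rate `g` per Morgan; segment
    ancestries are i.i.d. from `pi`; each segment is copied from a freshly,
    uniformly chosen panel haplotype of its ancestry. Conditional on the
    ancestry track, alleles on different segments are independent, and
    within a segment LD equals panel LD.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_loci, gmap = _check_panels(panels)
    pi = np.asarray(pi, dtype=float)
    if g < 0:
        raise ValueError("generations-since-admixture rate must be non-negative")
    if g == 0:
        pop = found_admixed(panels, n_individuals, pi, rng)
        pop.flavor = "mosaic_copy"
        return pop
    total = gmap.total_morgans
    morgans = gmap.morgans
    n_hap = 2 * n_individuals
    hap = np.empty((n_hap, n_loci), dtype=np.int8)
    lab = np.empty((n_hap, n_loci), dtype=np.int8)
    bps: list = []
    for i in range(n_hap):
        nb = rng.poisson(g * total)
        pos = np.sort(rng.random(nb) * total)
        bps.append(pos)
        edges = np.concatenate([[0.0], pos, [np.inf]])
        anc = rng.choice(pi.size, size=nb + 1, p=pi)
        lo = 0
        for s in range(nb + 1):
            hi = n_loci if s == nb else int(np.searchsorted(morgans, edges[s + 1], side="right"))
            if hi <= lo:
                continue
            l = anc[s]
            src = rng.integers(panels[l].n_hap)
            hap[i, lo:hi] = panels[l].haplotypes[src, lo:hi]
            lab[i, lo:hi] = l
            lo = hi
    return AdmixedPopulation(
        haplotypes=hap, labels=lab, gmap=gmap, pi=pi, generations=int(round(g)),
        flavor="mosaic_copy", n_ancestries=len(panels), breakpoints=bps,
    )


def segment_lengths(pop: AdmixedPopulation, include_censored: bool = False):
    """Local-ancestry segment lengths in cM.

    For mosaic cohorts the explicit recombination-delimited breakpoint
    tracks are used (segments between consecutive breakpoints); otherwise
    segments are maximal runs of constant ancestry label, with boundaries
    at the genetic midpoint between the flanking loci. Segments touching
    the region ends are censored and excluded unless `include_censored`.
    Returns (interior_lengths_cm, censored_lengths_cm) when
    `include_censored`, else interior lengths only.
    """
    interior: list = []
    censored: list = []
    total_cm = pop.gmap.total_morgans * 100.0
    if pop.breakpoints is not None:
        for pos in pop.breakpoints:
            cm = np.asarray(pos) * 100.0
            if cm.size == 0:
                censored.append(total_cm)
                continue
            interior.extend(np.diff(cm).tolist())
            censored.extend([cm[0], total_cm - cm[-1]])
    else:
        cm_pos = pop.gmap.cm
        for row in pop.labels:
            change = np.flatnonzero(row[1:] != row[:-1])
            if change.size == 0:
                censored.append(total_cm)
                continue
            mids = (cm_pos[change] + cm_pos[change + 1]) / 2.0
            edges = np.concatenate([[cm_pos[0]], mids, [cm_pos[-1]]])
            lens = np.diff(edges)
            if lens.size > 2:
                interior.extend(lens[1:-1].tolist())
            censored.extend([lens[0], lens[-1]])
    interior_arr = np.asarray(interior)
    if include_censored:
        return interior_arr, np.asarray(censored)
    return interior_arr


def interior_segment_mean_oracle(g: float, total_morgans: float) -> float:
    """Exact mean interior-segment length (cM) for a Poisson(g) track.

    On a window of T Morgans the interior (complete) spacings have density
    proportional to g e^{-g x} (T - x), so the mean is below 1/g; it
    converges to 100/g cM as gT grows. Derived by integrating the
    consecutive-pair intensity of the Poisson process over the window.
    """
    if g <= 0 or total_morgans <= 0:
        raise ValueError("need positive rate and window")
    u = g * total_morgans
    # mean in units of 1/g: (u * int_0^u t e^-t dt - int_0^u t^2 e^-t dt) /
    #                        (u * int_0^u e^-t dt - int_0^u t e^-t dt)
    e = np.exp(-u)
    i0 = 1.0 - e
    i1 = 1.0 - (1.0 + u) * e
    i2 = 2.0 - (u * u + 2.0 * u + 2.0) * e
    mean_units = (u * i1 - i2) / (u * i0 - i1)
    return float(mean_units / g * 100.0)


def realized_global_ancestry(pop: AdmixedPopulation) -> GlobalAncestry:
    """Morgan-weighted local-ancestry fraction per individual."""
    w = pop.gmap.locus_weights_morgans()
    w = w / w.sum()
    lab = pop.labels.reshape(pop.n_individuals, 2, pop.n_loci)
    out = np.zeros((pop.n_individuals, pop.n_ancestries))
    for l in range(pop.n_ancestries):
        out[:, l] = ((lab == l) * w[None, None, :]).sum(axis=(1, 2)) / 2.0
    out = np.clip(out, 0.0, 1.0)
    out /= out.sum(axis=1, keepdims=True)
    return GlobalAncestry(out, source="realized")


def panel_diploids(panel: HaplotypePanel, n_individuals: int | None = None,
                   offset: int = 0) -> GenotypeSet:
    """Pair panel haplotypes (2i, 2i+1) into a single-continental cohort."""
    avail = (panel.n_hap - offset) // 2
    n = avail if n_individuals is None else n_individuals
    if n > avail:
        raise ValueError("panel too small for the requested diploid cohort")
    hap = panel.haplotypes[offset : offset + 2 * n].reshape(n, 2, panel.n_loci)
    return GenotypeSet(hap.copy())
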