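"""Single-locus PSD (Pritchard–Stephens–Donnelly) cohort simulation.

The PSD model generates genotypes of an admixed individual in three steps:

1. global ancestry: a proportion vector P_i on the simplex (optionally
   Dirichlet-distributed) giving the probability that a random locus
   descends from each ancestral source population;
2. local ancestry: at each locus, each of the two haplotypes draws its
   source population independently from P_i, so the diploid count vector
   L_ik ~ Multinomial(2, P_i);
3. alleles: a haplotype whose local ancestry is l carries the reference
   allele with probability f_lk, the frequency of the allele in source
   population l, independently across haplotypes (source-population HWE)
   and across loci.

Loci are mutually independent — this is the regime in which the model's
closed-form power predictions (module :mod:`admixld.theory`) are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GlobalAncestry",
    "LocalAncestry",
    "FreqTable",
    "GenotypeSet",
    "draw_global_ancestry",
    "draw_local_ancestry",
    "draw_genotypes",
    "partition_dosage",
    "simulate_cohort",
]

_ROW_SUM_TOL = 1e-12


@dataclass
class GlobalAncestry:
    """Per-individual ancestral proportions P_il (rows sum to 1)."""

    proportions: np.ndarray  # (n_individuals, n_ancestries)
    source: str = "fixed"  # {"fixed", "dirichlet", "realized"}

    def __post_init__(self) -> None:
        self.proportions = np.atleast_2d(np.asarray(self.proportions, dtype=float))
        p = self.proportions
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("ancestry proportions must lie in [0, 1]")
        rows = p.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-8):
            bad = int(np.argmax(np.abs(rows - 1.0)))
            raise ValueError(f"row {bad} of ancestry proportions sums to {rows[bad]}, not 1")

    @property
    def n_individuals(self) -> int:
        return self.proportions.shape[0]

    @property
    def n_ancestries(self) -> int:
        return self.proportions.shape[1]

    def moments(self) -> "PSDMomentsLike":
        """Sample first/second moments, for feeding the theory module."""
        from .theory import PSDMoments

        p = self.proportions
        return PSDMoments(
            mean=p.mean(axis=0),
            second=(p[:, :, None] * p[:, None, :]).mean(axis=0),
        )


# typing helper without importing theory at module scope
PSDMomentsLike = "admixld.theory.PSDMoments"


@dataclass
class LocalAncestry:
    """Per-haplotype ancestry labels; diploid counts L_ikl sum to 2."""

    haplotype_labels: np.ndarray  # (n_individuals, 2, n_loci) int8
    n_ancestries: int

    def __post_init__(self) -> None:
        lab = np.asarray(self.haplotype_labels)
        if lab.ndim != 3 or lab.shape[1] != 2:
            raise ValueError("haplotype_labels must have shape (n, 2, n_loci)")
        if lab.size and (lab.min() < 0 or lab.max() >= self.n_ancestries):
            raise ValueError("haplotype label outside the valid ancestry index range")
        self.haplotype_labels = lab

    @property
    def n_individuals(self) -> int:
        return self.haplotype_labels.shape[0]

    @property
    def n_loci(self) -> int:
        return self.haplotype_labels.shape[2]

    def counts(self) -> np.ndarray:
        """Diploid counts L_ikl, shape (n_individuals, n_loci, n_ancestries)."""
        lab = self.haplotype_labels
        out = np.zeros((lab.shape[0], lab.shape[2], self.n_ancestries), dtype=np.int8)
        for l in range(self.n_ancestries):
            out[:, :, l] = (lab[:, 0, :] == l).astype(np.int8) + (lab[:, 1, :] == l)
        return out


@dataclass
class FreqTable:
    """Ancestry-specific reference-allele frequencies, (n_ancestries, n_loci)."""

    freqs: np.ndarray

    def __post_init__(self) -> None:
        f = np.atleast_2d(np.asarray(self.freqs, dtype=float))
        if np.any(f < 0) or np.any(f > 1):
            raise ValueError("allele frequencies must lie in [0, 1]")
        self.freqs = f

    @property
    def n_ancestries(self) -> int:
        return self.freqs.shape[0]

    @property
    def n_loci(self) -> int:
        return self.freqs.shape[1]

    def monomorphic(self) -> np.ndarray:
        """Loci monomorphic in every ancestry: unusable for association."""
        f = self.freqs
        return np.all((f == 0.0) | (f == 1.0), axis=0)


@dataclass
class GenotypeSet:
    """Phased alleles plus diploid and ancestry-partitioned dosages."""

    haplotypes: np.ndarray  # (n_individuals, 2, n_loci) int8 in {0,1}
    partitioned: np.ndarray | None = None  # (n, n_loci, n_ancestries)

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[2]

    def dosage(self) -> np.ndarray:
        """Diploid reference allele count M_ik, shape (n, n_loci)."""
        return self.haplotypes.sum(axis=1).astype(np.int8)

    def pooled_freq(self) -> np.ndarray:
        return self.dosage().mean(axis=0) / 2.0


def draw_global_ancestry(
    n: int,
    spec: Sequence[float] | tuple[str, Sequence[float]],
    seed: int | np.random.Generator,
) -> GlobalAncestry:
    """Draw a cohort's global-ancestry matrix.

    `spec` is either a fixed proportion vector (every individual identical)
    or `("dirichlet", concentration)` for Dirichlet-distributed proportions.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n <= 0:
        raise ValueError("cohort size must be positive")
    if isinstance(spec, tuple) and len(spec) == 2 and spec[0] == "dirichlet":
        conc = np.asarray(spec[1], dtype=float)
        if np.any(conc <= 0):
            bad = int(np.argmax(conc <= 0))
            raise ValueError(f"Dirichlet concentration entry {bad} is {conc[bad]}; must be > 0")
        return GlobalAncestry(rng.dirichlet(conc, size=n), source="dirichlet")
    vec = np.asarray(spec, dtype=float)
    if np.any(vec < 0):
        bad = int(np.argmax(vec < 0))
        raise ValueError(f"fixed proportion entry {bad} is {vec[bad]}; must be >= 0")
    if abs(vec.sum() - 1.0) > 1e-8:
        raise ValueError(f"fixed proportion vector sums to {vec.sum()}, not 1")
    return GlobalAncestry(np.tile(vec, (n, 1)), source="fixed")


def draw_local_ancestry(
    P: GlobalAncestry, n_loci: int, seed: int | np.random.Generator
) -> LocalAncestry:
    """Draw per-haplotype local ancestry: i.i.d. categorical(P_i) per locus.

    The diploid count vector is then Multinomial(2, P_i) at every locus,
    independent across loci.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_loci <= 0:
        raise ValueError("n_loci must be positive")
    p = P.proportions  # (n, nL)
    cum = np.cumsum(p, axis=1)[:, None, :]  # (n, 1, nL)
    u = rng.random((P.n_individuals, 2, n_loci))
    labels = (u[:, :, :, None] >= cum[:, :, None, :-1]).sum(axis=3).astype(np.int8)
    return LocalAncestry(labels, n_ancestries=P.n_ancestries)


def draw_genotypes(
    la: LocalAncestry, freqs: FreqTable, seed: int | np.random.Generator
) -> GenotypeSet:
    """Bernoulli alleles conditional on each haplotype's local ancestry."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if freqs.n_ancestries < la.n_ancestries:
        raise ValueError(
            f"frequency table covers {freqs.n_ancestries} ancestries but local "
            f"ancestry uses {la.n_ancestries}"
        )
    if freqs.n_loci != la.n_loci:
        raise ValueError("frequency table and local ancestry disagree on locus count")
    lab = la.haplotype_labels  # (n, 2, n_loci)
    f_here = freqs.freqs[lab, np.arange(la.n_loci)[None, None, :]]
    alleles = (rng.random(lab.shape) < f_here).astype(np.int8)
    return GenotypeSet(alleles)


def partition_dosage(geno: GenotypeSet, la: LocalAncestry) -> GenotypeSet:
    """Fill M_ikl: the reference-allele count carried on ancestry-l copies.

    Satisfies sum_l M_ikl = M_ik and M_ikl <= L_ikl.
    """
    if geno.haplotypes.shape != la.haplotype_labels.shape:
        raise ValueError("genotypes and local ancestry have mismatched shapes")
    lab, hap = la.haplotype_labels, geno.haplotypes
    part = np.zeros((geno.n_individuals, geno.n_loci, la.n_ancestries), dtype=np.int8)
    for l in range(la.n_ancestries):
        part[:, :, l] = ((lab[:, 0, :] == l) * hap[:, 0, :]) + ((lab[:, 1, :] == l) * hap[:, 1, :])
    return GenotypeSet(hap, partitioned=part)


@dataclass
class PSDCohort:
    """A fully simulated PSD cohort with usable-marker bookkeeping."""

    P: GlobalAncestry
    la: LocalAncestry
    freqs: FreqTable
    geno: GenotypeSet
    maf_threshold: float = 0.01
    usable: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        pooled = self.geno.pooled_freq()
        maf = np.minimum(pooled, 1.0 - pooled)
        self.usable = (maf >= self.maf_threshold) & ~self.freqs.monomorphic()


def simulate_cohort(
    n: int,
    n_loci: int,
    ancestry_spec,
    freqs: FreqTable | np.ndarray,
    seed: int,
    maf_threshold: float = 0.01,
) -> PSDCohort:
    """Convenience pipeline: ancestry -> local ancestry -> alleles -> partition.

    Uses one named substream per stage derived from `seed`.
    """
    from . import rng as _rng

    if not isinstance(freqs, FreqTable):
        freqs = FreqTable(freqs)
    P = draw_global_ancestry(n, ancestry_spec, _rng.substream(seed, "global_ancestry"))
    la = draw_local_ancestry(P, n_loci, _rng.substream(seed, "local_ancestry"))
    geno = draw_genotypes(la, freqs, _rng.substream(seed, "alleles"))
    geno = partition_dosage(geno, la)
    return PSDCohort(P=P, la=la, freqs=freqs, geno=geno, maf_threshold=maf_threshold)
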