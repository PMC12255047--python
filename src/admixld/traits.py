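"""Additive quantitative-trait simulation.

Y_i = Σ_j C_ij α_j + α_0 + ε_i : each locus is causal independently with
probability `polygenicity`; effects are i.i.d. zero-mean normal on the raw
allele-dosage scale and identical across ancestry tracts. At heritability 1
no environmental noise is injected; otherwise the noise variance is set so
the genetic values explain an h² share of the trait variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = ["TraitArchitecture", "TraitVector", "draw_architecture", "simulate_trait",
           "POLYGENICITY_GRID"]

log = logging.getLogger(__name__)

# polygenicity values exercised by the concordance experiment
POLYGENICITY_GRID = (1e-3, 5e-3, 1e-2, 5e-2)


@dataclass
class TraitArchitecture:
    causal_idx: np.ndarray  # sorted unique locus indices
    alpha: np.ndarray  # effect per causal locus, trait units per allele
    alpha0: float = 0.0
    polygenicity: float = 1.0
    h2: float = 1.0

    def __post_init__(self) -> None:
        self.causal_idx = np.asarray(self.causal_idx, dtype=int)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.causal_idx.shape != self.alpha.shape:
            raise ValueError("causal indices and effects have different lengths")
        if np.unique(self.causal_idx).shape != self.causal_idx.shape:
            raise ValueError("causal indices must be unique")
        if not 0.0 < self.polygenicity <= 1.0:
            raise ValueError("polygenicity must lie in (0, 1]")
        if not 0.0 < self.h2 <= 1.0:
            raise ValueError("heritability must lie in (0, 1]")

    def alpha_full(self, n_loci: int) -> np.ndarray:
        """Effect vector over the whole locus grid (zeros at non-causal loci)."""
        out = np.zeros(n_loci)
        out[self.causal_idx] = self.alpha
        return out


@dataclass
class TraitVector:
    Y: np.ndarray
    genetic: np.ndarray
    noise: np.ndarray
    alpha0: float = 0.0

    def __post_init__(self) -> None:
        assert np.allclose(self.Y, self.genetic + self.alpha0 + self.noise)


def draw_architecture(
    n_loci: int,
    polygenicity: float,
    effect_sd: float,
    seed: int | np.random.Generator,
    h2: float = 1.0,
) -> TraitArchitecture:
    """Select causal loci at the given rate and draw normal effects."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not 0.0 < polygenicity <= 1.0:
        raise ValueError("polygenicity must lie in (0, 1]")
    causal = np.flatnonzero(rng.random(n_loci) < polygenicity)
    if causal.size == 0:
        log.warning("no causal loci drawn at polygenicity %g; resampling once", polygenicity)
        causal = np.flatnonzero(rng.random(n_loci) < polygenicity)
        if causal.size == 0:
            raise ValueError(
                f"no causal loci drawn at polygenicity {polygenicity} over {n_loci} loci"
            )
    alpha = rng.normal(0.0, effect_sd, size=causal.size)
    return TraitArchitecture(causal, alpha, polygenicity=polygenicity, h2=h2)


def simulate_trait(
    causal_dosages: np.ndarray,
    arch: TraitArchitecture,
    h2: float | None = None,
    seed: int | np.random.Generator = 0,
) -> TraitVector:
    """Build the trait from the dosages at the architecture's causal loci.

    `causal_dosages` is (n, n_causal) in the architecture's locus order, or
    the full (n, n_loci) matrix from which the causal columns are taken.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h2 = arch.h2 if h2 is None else h2
    C = np.asarray(causal_dosages, dtype=float)
    if C.shape[1] != arch.causal_idx.shape[0]:
        C = C[:, arch.causal_idx]
    genetic = C @ arch.alpha
    if h2 >= 1.0:
        noise = np.zeros_like(genetic)
    else:
        var_g = float(np.var(genetic))
        if var_g == 0.0:
            raise ValueError(
                f"architecture with {arch.causal_idx.size} causal loci has zero "
                "genetic variance; cannot target h2 < 1"
            )
        noise = rng.normal(0.0, np.sqrt(var_g * (1.0 - h2) / h2), size=genetic.shape)
    return TraitVector(Y=genetic + arch.alpha0 + noise, genetic=genetic, noise=noise,
                       alpha0=arch.alpha0)
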