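# Methods

## Models

### Single-locus PSD cohorts (`psd`)

Global ancestry `P_i` is either a fixed simplex vector or Dirichlet; only
its first two moments enter any prediction, so the experiments default to
Dirichlet(8, 2) — mean 80/20, matching the admixture proportions used
throughout — and expose the concentration as a knob. Haplotype local
ancestry is categorical(`P_i`) i.i.d. per locus (diploid counts
Multinomial(2, `P_i`)); alleles are Bernoulli(`f_lk`) given ancestry,
independent across haplotypes (source-population HWE) and loci. Loci are
mutually independent — the regime where the closed-form power algebra in
`theory` is exact. Markers with pooled MAF < 0.01 (configurable) are
flagged unusable to avoid degenerate designs.

### Linked-locus simulators (`forward`)

**Panels.** Source haplotypes come from a latent-Gaussian model: a
stationary AR(1) sequence along the locus grid with correlation
`exp(−d/λ)` at genetic distance `d`, thresholded at the `(1−f)`-quantile.
This gives exact marginal frequencies, monotone LD decay with a tunable
length `λ` (Morgans), and a closed-form allele correlation via the
bivariate-normal orthant probability — used as the independent oracle in
tests. Allele-frequency divergence between populations follows
Balding–Nichols with Fst 0.15 per population (the Fst between the
motivating source populations is not pinned by any published value we rely
on; 0.15 is a conventional African–European scale and is a config knob).
Frequencies are clipped away from {0,1} by 1/(2·panel size).

**Wright–Fisher arm.** A single admixture pulse (each founder haplotype
copied whole from a panel chosen by π = (0.8, 0.2)) followed by `g = 12`
generations of forward WF mating: every offspring draws two distinct
parents uniformly (no selfing, shared parents allowed, no sex structure);
each gamete recombines with breakpoints from a Poisson process of rate 1
per Morgan and a fair start-haplotype coin. Alleles and ancestry labels are
inherited jointly, so local ancestry is exact and mutation-free allele
traceability holds. `final_size` lets a small founder pool be expanded in
the last round; the LD experiments found from 400 individuals to
strengthen founder LD beyond segment boundaries — the mechanism that makes
the ePSD approximation fail (the motivating demography has its own
bottleneck; the pool size is a desk-scale proxy, not a calibrated census
size).

**Mosaic arm.** Ancestry breakpoints Poisson(rate `g` per Morgan), segment
ancestries i.i.d. π, each segment copied from a freshly chosen panel
haplotype. Conditional on local ancestry, distinct segments are
independent and within-segment LD equals panel LD — the ePSD model holds
by construction, giving the positive control.

Coordinates are 0-based with half-open intervals; genetic distance is
Morgans internally, cM at interfaces.

### Traits (`traits`)

`Y = Σ_j C_j α_j + α_0 + ε`, causal loci Bernoulli(polygenicity), effects
i.i.d. N(0, sd²) on the raw dosage scale (the ePSD algebra is written on
raw dosages) and identical across ancestries. At h² = 1 the noise is
exactly zero; below 1 the noise variance targets the requested genetic
share. α_0 defaults to 0. The experiment grid {1e-3, 5e-3, 1e-2, 5e-2}
with h² = 1 is the study condition.

### Regressions (`assoc`) and meta-analysis (`meta`)

OLS with classical homoskedastic SEs (the form the asymptotic variance
formulas predict). Global-ancestry adjustment drops the reference-ancestry
proportion column (mirroring the LA-column drop); zero-variance covariate
columns are absorbed by the intercept. The combined Tractor test is a Wald
quadratic form on the estimated covariance block of the dosage
coefficients (asymptotically equivalent to the likelihood-ratio form), with
df reduced when an ancestry is absent. Scans over many markers use
precomputed normal equations (the covariate block is shared and, across
traits, the per-marker Gram matrix is reused); `fit_att`/`fit_tractor` are
cross-checked against `statsmodels.OLS` in the test suite. FE meta-analysis
is inverse-variance pooling with Cochran's Q; the identity
`T_FE + Q = Σ(β̂_l/SE_l)²` is exact and property-tested. A Han–Eskin-style
random-effects combiner is deliberately out of scope; `fe_combine` accepts
an arbitrary extra combiner hook.

### LD scan (`ldscan`)

The LA-adjusted regression `C_j ~ M_k1 + M_k2 + L_k2` includes an
intercept, so each dosage coefficient is a covariance-over-variance and
matches `D/(g(1−g))` under HWE; the panel coefficient is the slope of
`C_j ~ M_k` in diploids formed from panel haplotypes disjoint from the
founders. Regressions are genotype-level (the model is written on
individual-level dosages). Distance bins default to
{0, 0.05, 0.1, 0.25, 0.5, 1, 2, 3} cM, half-open; bins with < 10 pairs are
flagged. Pair catalogues subsample uniformly and deterministically.

## Closed forms worth restating

* General-`n_L` conditional dosage variance:
  `Var(M_k|P) = 2Σ g(1−g)P_l + 2Σ g²P_l(1−P_l) − 2Σ_{l≠l'} g g' P_l P_l'`;
  the familiar two-ancestry form with the `(g₁−g₂)²E[P₁P₂]` term is a
  checked specialisation.
* The admixture-LD covariance `Cov(L^h_kl, L^h_jl' | P)` has no closed form
  in source-population LD parameters; this package models it with a
  single-pulse Markov track — breakpoints Poisson(`g`/Morgan), ancestry
  redrawn i.i.d. from `P` — giving `(P_l δ_ll' − P_l P_l') e^{−g d}`. It is
  validated only against the package's own mosaic process.
* Windowed segment-length law: on a region of `T` Morgans, interior
  (uncensored) Poisson(`g`) segments have density ∝ `e^{−gx}(T−x)`, so
  their mean is below `1/g` (0.804/g at `gT` = 6) and converges to `1/g`
  as the window grows. The simulators are checked against this exact
  windowed mean, not the naive `100/g` cM, which is only the wide-window
  limit; censored end segments are excluded from summaries by default.
* Effective sample size: Tractor-`l` SE = single-continental SE ×
  `1/√E[P_l]`, i.e. Z-scores deflate by `√E[P_l]` and the effective sample
  size is the admixed `n` times `√E[P_l]`.

## Problem sizes and numerical choices

Experiments are sized to finish in seconds–minutes on one CPU while
keeping every Monte-Carlo comparison inside its stated error budget:

* power experiment — SE check at n = 10,000 × 200 markers; ordering over
  500 equal-effect markers (125 per frequency gap in {0, .2, .4, .6},
  n = 4,000, α = 0.15); independence over 1,000 replicate fits (n = 2,000);
  unbiasedness over 500 replicates (α = 0.3); FE null over 1e5 replicate
  pairs drawn from the theory-predicted sampling law of the coefficients;
  perfect-tagging fit at n = 50,000; effective-n at n = 6,000 × 50 markers
  for E[P] in {0.2, 0.5, 0.8}.
* concordance experiment — 2,000 loci over 50 cM (5e7 bp at 1e-8 /bp/gen),
  λ = 0.002 M, panels feeding 2×1,000 single-continental diploids and a
  2,000-individual WF cohort founded from 400; trait replicates
  (20, 8, 5, 3) across the polygenicity grid so the sparse end still
  yields tens of causal markers.
* LD experiment — 1,200 loci over 50 cM; short-LD (λ = 0.002 M) mosaic
  positive control, long-LD (λ = 0.05 M ≈ 1/g) mosaic control and WF arm;
  4,000 catalogued pairs to 3 cM plus a 2,000-pair catalogue to 12 cM for
  the segment-length overlay.

Singularity is detected on the (small) normal-equation eigenvalues;
degenerate fits are flagged, never silently dropped. Absent ancestries
yield NaN estimates and reduced-df combined tests. All randomness flows
through named substreams (`rng.substream`) derived from one run seed, so
stages are independently reproducible and experiment outputs are
bit-identical under a fixed seed.

## What the generators do and do not emulate

The synthetic panels reproduce tunable allele-frequency divergence and
monotone LD decay, and the admixed simulators reproduce exact
local-ancestry mosaics, admixture LD, founder drift, and post-admixture
recombination. They do not emulate mutation, selection, continuous
post-pulse migration, assortative mating, variable recombination maps, or
realistic site-frequency spectra; the AR(1) latent LD is stationary,
unlike block-structured human LD. Passing tests therefore demonstrate the
internal consistency of the theory and the qualitative LD phenomena —
not calibrated estimates for any particular human cohort; real-data
summary-statistic analyses are out of scope.

## Design choices that were genuinely open

* The concordance experiment's polygenicity contrast is asserted at causal
  markers. In this additive, h² = 1 setting the *all-marker* correlation
  between admixed and single-continental marginal effects is essentially
  invariant to polygenicity: per-marker signal, LD-discordance and
  estimation-noise variances all scale linearly with the number of causal
  loci, so their ratios — and hence the pooled Pearson correlation — do
  not move. The causal-marker correlation does fall (its self-term is
  fixed while contamination grows), which is the contrast the experiments
  test; all-marker values are still reported.
* Forward WF replaces a backward coalescent: classic coalescent machinery
  cannot produce the long-range LD that extends beyond ancestry segments,
  while 12 generations of forward simulation are exact for the
  post-admixture period and cheap at these sizes.
* `segment_lengths` measures recombination-delimited mosaic segments when
  the explicit breakpoint track exists (mosaic cohorts) and falls back to
  maximal constant-ancestry label runs with midpoint boundaries otherwise
  (WF cohorts, file-loaded tracks). With i.i.d. segment ancestries the two
  differ: merging same-ancestry neighbours inflates run lengths by
  1/(2π₁π₂) on average, so the Exponential(1/g) law applies to the
  breakpoint-delimited segments only.
* Residual variance for SE prediction is estimated as the mean squared
  residual of the trait on ancestry covariates alone, matching the
  conditioning of the asymptotic variance formula.

## Known limitations

Two-ancestry experiments only (the data model supports more); quantitative
traits only; no relatedness/mixed-model correction; the latent-AR(1) LD
model is a stylised stand-in for demographic LD; the FE null calibration
draws replicate estimate pairs from the theory-predicted coefficient
sampling law rather than refitting 1e5 regressions.
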