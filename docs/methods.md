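# Methods

## The biological problem

Metastatic cancer cells form thin membranous conduits — tunnelling-nanotube
(TNT)-like nanoscale bridges — with endothelial cells, through which they
transfer cytoplasmic cargo including miRNA. The reported bridges measure
290 ± 20 nm across and 30.69 ± 2.43 μm long (mean ± s.e.m., n > 300), about
70% of them contain both actin and tubulin, and their cargo-transfer activity
is quantified by flow cytometry (≈30% of co-cultured endothelial cells become
dye-positive, versus <5% in a contact-free Boyden dual culture) and by
relative qPCR (5× miR-132 increase in recipient cells, 26× decrease under an
antagomir). This package implements the mechanical model that rationalizes
those geometries and the quantification pipelines that produce those numbers,
exercised end-to-end on synthetic data with known ground truth.

## Composite-bundle buckling model (`mechanics`)

A projection is a bundle of `n_a` actin filaments and `n_t` microtubules
under an axial load `F`. The model is the standard filopodial one:

* **Rigidity.** Each filament contributes `B_i = k_B·T·L_p,i`; the bundle is
  uncoupled, so rigidities add: `B = k_B·T·(n_a·L_p,a + n_t·L_p,t)`. A
  `coupling_exponent` argument (`κ`) generalizes to `Σ n_i^κ L_p,i`; fully
  cross-linked bundles (`κ = 2`) are a config away, but uncoupled is the
  default because inter-filament cross-linker density in these structures is
  unknown.
* **Buckling.** Euler: `F_b = I·B/L²`, `L_max = sqrt(I·B/F)`. The boundary
  prefactor `I` defaults to π²/4 (clamped base, free tip — the geometry of a
  projection anchored in the cortex) and is configurable over
  [π²/4, 4π²].
* **Packing.** The minimal sheath diameter comes from hexagonal close
  packing of filament cross-sections: `D_min = 2·sqrt(Σ n_i r_i² / φ)`,
  φ = π/(2√3) ≈ 0.9069. The same formula is applied down to N = 1 for
  continuity, accepting a slight >2r artifact there.
* **Constants.** `k_B·T = 4.28 pN·nm` (310 K), `r_a = 3.5 nm`,
  `r_t = 14 nm` (4× actin), `L_p,a = 17.7 μm`, `L_p,t = 5.2 mm`,
  `F = 10 pN`. These are literature-standard values; all are YAML-
  configurable with units in the key names.

Inverting the packing formula gives the largest bundle of a given tubulin
number fraction `f` that fits a measured width (counts floored; composition
ties round toward fewer microtubules, the conservative choice for
feasibility). Chaining capacity → rigidity → buckling length yields the
feasibility curve `L_max(D_min)`; a measured (length, width) pair is
*infeasible* at a composition when its length exceeds `L_max` of the largest
packable bundle. The observed mean geometry is infeasible for an actin-only
bundle at 10 pN (`L_max ≈ 5.4 μm` at 290 nm), which is the quantitative
content of the claim that the longer bridges must contain microtubules.

**Optimal tubulin fraction.** "Maximize flexural strength while minimizing
thickness" is operationalized as maximizing `P(f) = L_max(f)/D_min(f)²` at
fixed total filament count over the tubulin *number* fraction. In reduced
units `P(f) ∝ sqrt(1 + f(ρ−1)) / (1 + f(q−1))` with `ρ = L_p,t/L_p,a` and
`q = (r_t/r_a)²`; stationarity gives the closed form

    f* = 1/(q−1) − 2/(ρ−1),

whose stiff-microtubule limit is `1/(q−1) = 1/15 ≈ 6.7%`, and which equals
6.6% at `ρ = 3000, q = 16` — the parameterization used for the headline
optimum. The closed form is cross-checked against bounded 1-D numerical
maximization and a 10⁻⁵ grid search in the tests. An interior optimum exists
only for `ρ > 2q−1`; otherwise `f* = 0` is returned with an
`interior=False` flag. This metric was chosen because it is the only simple
strength-per-thickness ratio whose optimum is consistent with both the 4×
radius ratio and a ~6.6% optimum; with the default persistence lengths
(ρ ≈ 294) the same formula gives 5.98%.

## Synthetic data (`synthetic`)

The generators define the study conditions; all take explicit seeds and
attach ground-truth columns.

* **Morphometry.** Axis populations are lognormal matched by moments to the
  printed mean ± s.e.m. with s.d. = s.e.m.·√n_reported (n_reported = 300).
  Lognormal because the implied coefficient of variation exceeds 1
  (346 nm s.d. on a 290 nm mean), which no normal on positive lengths can
  carry. Short and long axes are drawn independently — real bridges likely
  correlate the two, so classification results on synthetic data bound the
  rule's behaviour only under independence.
* **Kinetics.** Mean length is a logistic rise (rate 0.8 h⁻¹, half-rise 5 h
  before the peak) multiplied by a mild exponential decline (0.03 h⁻¹)
  after `t_peak` (default 17.5 h). A pure logistic never attains a peak, so
  the reported "peak reached between 15 and 20 h" would be undetectable
  without the decline term; the chosen rates place the ≥95%-of-range window
  of the noiseless curve at ≈[15.8, 19.6] h. Gaussian measurement noise
  (default s.d. 3 μm, 30 measurements per timepoint) is added per
  measurement.
* **Cytometry.** Events are lognormal intensity mixtures over channels
  {diI, pecam, cfse}: negative median 100, positive median 10,000
  (σ_log 0.55), i.e. 100× median separation over a ~4-decade range; a
  warning flag is attached when configured medians are within e^(4σ) of
  each other. Endothelial events (default 50%) are double-positive in
  DiI-Ac-LDL and PECAM-1; cancer events are CFSE-loaded. Among endothelial
  events, CFSE-high status is a three-way categorical — truly transferred
  (condition preset: 30% co-culture, 4% dual culture/inhibitor), spurious
  background (3% in every condition; the study states only that background
  was subtracted, not its size), or negative — so the background-subtracted
  pipeline is unbiased for the transfer truth by construction. Channels are
  generated spectrally independent (no compensation modelling). An
  `unstained=True` table (all channels negative) provides the sample that
  percentile gates are placed on.
* **Composition.** Bernoulli draws with p_dual = 0.70.
* **qPCR.** Target Ct = base − log2(fold) + noise per replicate; reference
  gene constant up to the same noise. Defaults: base Ct 28 (target) / 20
  (reference), noise s.d. 0.1 cycles, 3 replicates.

## Measurement pipelines

* **Morphometry** (`morphometry`): exact mean / n−1 s.d. / s.e.m.
  summaries; nanobridge vs lamellipodium rule (short axis < 1 μm AND aspect
  ratio ≥ 10, both thresholds configurable — each sits between the two
  printed population means); per-cell connection statistics with zeros
  included; peak-window detection; one-way ANOVA with pairwise
  equal-variance t-tests and Bonferroni adjustment `min(1, m·p)` (Welch off
  by default, matching the classic procedure).
* **Peak windows.** Growth and transfer curves saturate, so peaks are
  reported as the interval of timepoints whose (moving-average-smoothed)
  value reaches 95% of the smoothed *range* above the minimum. Using the
  range rather than the raw maximum makes the rule invariant to adding a
  constant to all means; for curves that start near zero the two rules
  coincide. All-equal series return the full range with a `flat` flag.
* **Transfer** (`transfer`): events are gated on asinh-transformed
  intensities (cofactor 150); thresholds are fixed or placed at the 99.5th
  percentile of an unstained control per channel. Endothelial gate =
  DiI AND PECAM above threshold. The cargo-positive percentage of the gated
  set is corrected by subtracting the percentage measured identically on a
  gated cargo-free control, clipped at zero. Co-culture minus dual-culture
  isolates the conduit-attributable component. Confidence intervals are
  nonparametric bootstrap over events (1,000 resamples, seeded; binary
  positivity arrays use the exact binomial shortcut).
* **Expression** (`expression`): the comparative-Ct method,
  `fold = 2^(−ΔΔCt)`, amplification efficiency fixed at 2; replicates
  aggregated by arithmetic Ct mean; CI from pooled replicate variances on
  ΔΔCt (normal approximation). A 26-fold *decrease* is reported as the
  reciprocal of the recovered fold. Marker summaries report medians (robust
  to lognormal tails) with means alongside and delegate testing to the
  shared ANOVA routine.

## Numerical and design notes

* Error propagation bounds what noisy-recovery tests can demand: with Ct
  noise s.d. 0.1 on both genes of both conditions and 3 replicates,
  s.d.(ΔΔCt) = 0.1·√(4/3) ≈ 0.115 cycles, i.e. a ~8.3% multiplicative
  spread on the fold; the probability of a single recovered fold landing
  within 15% of truth is ≈ 0.94, and the test suite asserts that empirical
  rate, not a higher one.
* Bundle capacity search is a bisection on total filament count (the packed
  area is monotone in N), so feasibility curves over hundreds of grid
  points are effectively instant.
* Problem sizes used throughout (10,000 projections, 50,000 events, 3 qPCR
  replicates, ≤200-replicate simulation loops) keep the full suite and the
  acceptance script in the seconds-to-a-minute range.

## Known limitations

* The mechanics is statics-only Euler buckling: no polymerization dynamics,
  no membrane tension beyond the single load parameter, no post-buckling
  behaviour.
* The synthetic cytometry omits doublets, spillover/compensation and
  scatter channels; passing recovery tests demonstrates correctness of the
  gating arithmetic, not robustness to those artifacts.
* The dual-culture condition *is* the baseline by design; no mechanistic
  exosome-flux model is attempted.
* qPCR efficiency is fixed at 2; no amplification-curve fitting.
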