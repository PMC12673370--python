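# Methods

This note documents the models, defaults and design choices behind
`mitoflux`, and what the synthetic-data generators do and do not emulate.

## Respirometry model

A chamber run is modelled as a piecewise-constant metabolic O₂ flux per SUIT
state. Within a state, the clean concentration obeys
`dc/dt = −J_V/1000` µM s⁻¹ with `J_V = J_mass·m/V` (m = wet sample mass in
mg, V = chamber volume in mL; defaults 2 mg in 2 mL). The generator's true
state fluxes are the *mitochondrial* (Rox-corrected) values; the Rox flux
(default 4 pmol s⁻¹ mg⁻¹) is added to every post-sample state, so the
analysis-side Rox subtraction removes a real baseline. Default state fluxes
(N_L 12, N_P 60, NS_P 90, NS_E 110, S_E 60 pmol s⁻¹ mg⁻¹) are representative
of rodent brain homogenate. Cytochrome c raises the mitochondrial part of
N_P by 5% by default (an intact-membrane preparation); the uncoupler
titration follows a rise-peak-decline profile (0.93, 1.00, 0.97 × NS_E) so
optimum selection is non-trivial.

Two O₂ regimes are operating *bands*: air saturation 150–200 µM and tissue
normoxia 30–40 µM. When the concentration reaches the band floor the chamber
is "opened": the concentration steps instantaneously back to the ceiling and
a reoxygenation event is recorded (the real kinetics of chamber opening are
not modelled). Scheduled reoxygenation events are also honoured. Every
injection inserts a 10 s mixing transient — an exponential spike plus a
`transient` label — so that window-selection logic is genuinely exercised.

Sampling interval: 2 s (the usual recording interval of high-resolution
respirometers). O₂ noise: white Gaussian, SD 0.5 µM per sample; fluorescence
noise SD 0.002 V. No instrument noise magnitudes are published for these
assays; these are plausible instrument-scale values and are configurable.

### Flux estimation

Per state, the plateau span runs from its defining injection to the next
one. Within the span, clean fragments exclude the 10 s transients, end 30 s
before the next *injection* (pipetting-artifact guard), and end 4 s before a
*reoxygenation* (opening the chamber produces no pre-event artifact, so the
long guard would only discard valid steady-state data). Window policy: the
latest 120 s window within a fragment when one fits; otherwise the longest
fragment ≥ 30 s.

Two estimators are provided:

* `compute_volume_flux` — ordinary least-squares slope on a single window
  (the classical marked-section estimate; SE from the regression);
* `compute_state_flux` — the default in `analyze_trace`: a common-slope fit
  across *all* clean fragments of the plateau with per-fragment intercepts
  (within-fragment demeaning). A reoxygenation shifts the O₂ level but not
  the flux, so pooling restores the information that fragmentation would
  otherwise discard; on an uninterrupted plateau it reduces exactly to the
  single-window fit. This matters at tissue normoxia, where the 10 µM band
  forces reoxygenations every 1–3 minutes.

An optional linear instrumental O₂ background correction (sensor
consumption/back-diffusion) was considered and left out: the generator does
not simulate it and the studies emulated report fluxes already
background-corrected by the instrument software.

Rox correction subtracts the ROX entry from every state under every
normalization, zeroes ROX exactly, preserves (and flags) negative corrected
values rather than clamping them, and is idempotent. FCRs and the E–P / P–L
control efficiencies are computed from the corrected mass-specific fluxes;
both are invariant under any uniform rescaling, so the choice of
normalization does not affect them.

## AmR (H₂O₂) channel

Fluorescence is modelled as `F(t) = a + b·t + s(t)·C(t)`: a linear chemical
background (the functional form is an assumption; nothing more specific is
published), cumulative H₂O₂ `C(t)` (metabolic release integrated per state
plus 0.1 µM calibration titrations as instantaneous steps), and a
sensitivity `s(t)` decaying exponentially at a configured fraction per hour
(default 10%/h; the decay law is an assumption — only the existence of drift
is documented for the assay).

Calibration is two-layered:

1. **Pre-sample**: a joint least-squares fit of
   `F = a + b·t + s₀·(1 + g·t)·C_titr(t)` over the reagent-only segment.
   The `g` regressor absorbs first-order sensitivity drift during the
   calibration so it cannot leak into the chemical drift `b` (without it,
   the drift estimate is biased by `≈ s·ln(1−d)/3600 · C̄`, which
   extrapolates into a flux bias over the run). `s₀` anchors the sensitivity
   track at t = 0.
2. **In-run**: each 0.1 µM titration yields a knot `s(t_i)` = step height /
   0.1 µM, the step height measured against a local pre-titration linear fit
   extrapolated across the masked transient (cancelling both background
   drift and the metabolic ramp). Between knots `s` is interpolated
   linearly; outside them the nearest knot value is used.

Because nearest-knot extrapolation cannot track decay, the default H₂O₂
protocol schedule brackets the run: titrations at the configured interval
(20 min) *plus one near the run end*, so every analysis window lies inside
the knot-interpolated span. With 10%/h decay and bracketed 20-min titrations
the noiseless round-trip error is < 1% in every state.

The J_H2O2/J_O2 ratio is always formed against a paired AmR-free O₂
measurement (the dye and fluorescence light perturb respiration), never the
with-AmR O₂ channel. States with non-positive corrected O₂ flux (ROX) report
a missing ratio. The default H₂O₂ preset keeps the ratio below the ~2%
physiological envelope in every state, with the LEAK state highest — the
pattern expected from tissue.

## CS assay

`v = r_A/(l·ε_B·v_B) · (V_cuvette/V_sample)/ρ`, with defaults l = 1 cm,
ε_B = 13.6 mM⁻¹ cm⁻¹, v_B = 1, V_cuvette = 1 mL, V_sample = 50 µL,
ρ = 2 mg mL⁻¹. Both volumes are converted to mL before forming their ratio.
The generator inverts the same equation, so the noiseless round-trip is
exact. Blank correction subtracts the blank's fitted slope when a blank
series is supplied (whether the emulated studies blank-corrected is not
documented; the option defaults to doing so when a blank is given). A
declining absorbance trend sets a "reaction not proceeding" flag instead of
raising, since zero-activity series are legitimate.

## qPCR

Plain `2^(−ΔΔCt)` (no amplification-efficiency correction). The control
baseline is the arithmetic mean of control ΔCt — median was considered and
rejected for consistency with the mean-based convention of the downstream
summaries. Samples lacking a reference-gene Ct are dropped with a warning;
group folds are summarized as mean ± SD. The generator draws the
reference-gene Ct ~ N(20, 0.7) independent of group (the housekeeping
assumption) and writes `Ct_target = Ct_ref + ΔCt_gene − log₂(fold)`, so any
per-sample plate offset cancels exactly through ΔCt.

## Morphometry

Pipeline: linear percentile stretch (default 0.35% saturated per tail) →
median despeckle (disk radius 1) → global threshold within the delineated
cell → 8-connected components → calibrated areas (px² × pixel-size²) →
manual-exclusion list → area ≤ 3 exclusion (inclusive, the false-positive
guard) → per-cell metrics. The threshold is Otsu by default (selectable:
li/yen/isodata/mean) and is floored at median + 5 robust SDs (1.4826·MAD) of
the in-cell intensities: Otsu is undefined on unimodal noise, and the floor
makes signal-free images yield zero particles while leaving rod detection
untouched down to SNR ≈ 5 (at 5σ amplitude the blurred rod interior sits far
above the floor). Both threshold and stretch are data-relative, so
segmentation is invariant to uniform intensity scaling. Manual false-positive
correction is represented as a reproducible exclusion list, not interactive
editing.

The generator renders rods as oriented rectangles (width 5 px, length
12–22 px), Gaussian-blurred (σ = 1 px) with Poisson + Gaussian camera noise,
inside an elliptical cell mask. The fusion degree f maps n rods onto
`max(1, round(n·(1−f)))` chains placed end-to-end with small bends; chaining
re-uses the same rod dimensions, so ground-truth particle area is conserved
to rasterization accuracy (≲ 0.3%) while the particle count drops — the
fusion signature (count and mean size change, total area fraction does not).
Measured area fractions inflate by ~1–1.5% under fusion because blurred rod
*ends* lose a few threshold-crossing pixels and fusion hides ends; this is a
property of thresholded imaging, not of the generator's geometry.

What the image model does **not** emulate: out-of-focus light, uneven
illumination, neighbouring cells, genuinely curved/branched mitochondria, or
3-D structure. Passing tests therefore demonstrate correctness of the
measurement chain, not robustness to every real-microscopy artifact.

## Statistics

ROUT is implemented for the constant-location case relevant to group scalar
data (the regression generality of the original method is out of scope):
location = median, robust scale RSDR = 68.27th percentile of |residuals| ×
n/(n−1), residuals converted to two-sided t-tail probabilities (df = n−1)
and screened by Benjamini–Hochberg at Q (default 1%, the conventional
default; configurable). With n < 4 nothing is flagged. On clean normal
samples (n = 20) the realized false-flag rate is well under the 3% working
bound.

Mann–Whitney U uses exact enumeration of all C(n₁+n₂, n₁) assignments
(mid-ranks, so ties are handled) for combined n ≤ 20 — the library
asymptotic path would be wrong-sized there and the exact path of common
libraries rejects ties — and the tie-corrected normal approximation above.
The two-sided exact p is `2·min(P(U ≤ u), P(U ≥ u))` capped at 1 (so a group
compared with itself gives p = 1). Pairwise comparisons after one-way ANOVA
use the pooled-error t statistic on df = N−k, with Šidák adjustment
`1 − (1−p)^m`; all tests are two-sided at α = 0.05. Outlier screening runs
per group before testing.

## The in-silico study (analysis/)

The cohort (6 animals × 2 groups, both regimes) imposes multiplicative group
effects chosen to mirror the qualitative biology being emulated: reduced
respiration after preconditioning at (effectively hyperoxic) air saturation,
increased respiration at tissue normoxia, a moderate rise in H₂O₂ release
(kept within the < 2% J_H2O2/J_O2 physiological envelope), fusion-shifted
morphology immediately after hypoxia, and fusion-gene induction with
transient Drp1 suppression. Animal scatter is lognormal (CV 15%); H₂O₂
release tracks each animal's mitochondrial scale with 10% extra scatter.
These are illustrative settings for exercising the pipeline end-to-end, not
estimates of any real effect sizes; at n = 6 the p-values the drivers print
are expected to hover around significance.

## Numerical choices and degenerate inputs

* Problem sizes throughout (20 traces per regime for recovery checks, 100
  images for detection, 10,000 replicates for test-size checks) are chosen
  to give stable statistics at desk scale.
* Tie-breaks: uncoupler optimum prefers the lower concentration; an optimum
  on the last titration step raises an under-titration flag.
* Windows with fewer than 10 samples, missing defining events, empty cell
  masks, empty control groups, non-positive calibration sensitivities and
  non-positive normalization denominators all raise informative errors
  naming the offending state/quantity.
* Constant inputs short-circuit: identical ROUT values flag nothing, a
  constant image passes preprocessing unchanged and segments to zero
  particles.
* Amperometric settings (500 mV, gain 1000) are config metadata only; no
  published mapping from volts to amperometric settings exists, so
  calibrations are strictly per-run and never pooled across runs.

## Known limitations

* Fluxes are imposed, not mechanistic: no oxygen kinetics (p50), membrane
  potential, RET, or AmR oxygen-dependence.
* The exact plateau-marking rule and flux estimator of the original
  instrument software are proprietary/undocumented; the window policy here
  is an explicit, configurable reimplementation of the marked-sections idea.
* No quantitative cytochrome-c acceptance cutoff is published; the 15%
  default threshold is a convention and, at the default noise level, the
  integrity test on a single run has a standard error of a few percent —
  occasional false flags at n = 1 are expected.
* The ROUT constant-model implementation reproduces the screening behaviour
  (robust fit + FDR criterion) rather than any specific software's exact
  flag-for-flag output.
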