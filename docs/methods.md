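# Methods

This note documents the models, conventions and numerical choices
behind the package, and what the synthetic-data validation does and
does not demonstrate.

## Signals and conventions

A `TimeSeries` is a uniformly sampled 1-D signal with sampling interval
`dt`. Spectral operations use the one-sided power convention scaled so
that the spectrum sums exactly to the (population) temporal variance of
the mean-removed signal; band power is therefore identical to the
variance of the ideally band-filtered signal, and band variances are
exactly additive over disjoint bands.

All band-pass filtering is a zero-phase ideal (boxcar) mask in the
frequency domain, keeping bins with `low <= f <= high`. This choice is
deterministic, phase-free and makes the Parseval bookkeeping exact,
which the pulsation analysis relies on; the trade-off is spectral
leakage at the series edges, which the trim step (below) absorbs.

## Cleaning pipeline

Order of operations: truncate to the initial frames (`keep_first`) →
scrub → second-order polynomial detrend → band-pass 0.01–0.1 Hz → trim
ends. Whether scrubbing should precede or follow filtering is not
dictated by the protocols this package reproduces; scrubbing-first is
this package's documented choice and is applied consistently.

Frame-wise displacement uses the backward-difference convention:
FD(i) = Σ|Δtranslation| + r·Σ|Δrotation|, with the rotation arc radius
`r` configurable (50 mm default for human heads, 5 mm for mouse).
Frames with FD **strictly** greater than the 0.35 mm threshold are
dropped, never interpolated; a frame at exactly 0.35 mm survives.
Dropping frames shortens the series rather than leaving gaps; the
censor mask is returned so a caller may instead insert NaNs, which the
cross-correlation handles by pair-wise deletion inside each lag's
overlap window.

Human-protocol defaults: TR 2.68 s, first 150 scans analysed, 5 scans
trimmed per end. Mouse-protocol values (TR 0.3 s, 250 scans trimmed
per end) are reachable through the same parameters.

## BOLD–CSF coupling

`r(ℓ)` is the Pearson correlation of `bold(t + ℓ)` against `csf(t)`
over their overlap, each lag normalised by the overlapping segments'
own means and SDs so `|r(ℓ)| <= 1` holds at every lag. A negative
optimal lag means BOLD precedes CSF. Coupling strength is `r` at a
species preset (human −1 scan, mouse 0); whether mouse coupling should
instead be read at each animal's optimal lag is ambiguous, so the
reference lag is an explicit parameter rather than a constant. Optimal
lag ties break to the smallest absolute lag, then to the negative one
(the physiologically expected direction). Oscillation amplitude is the
sample SD (ddof = 1) of the preprocessed series.

## Synthetic data

The generator defines the study conditions; its defaults are not
tuning knobs.

* **Coupled BOLD/CSF** — the BOLD signal is white Gaussian noise
  masked to 0.01–0.1 Hz in the frequency domain (exact band control)
  and scaled to unit SD; the CSF signal is
  `−coupling_amp · bold(t + lag) + noise`, with the lag applied by
  integer shift on an over-generated series whose wrapped segment is
  discarded, so the true lag is exact. Defaults: 20 subjects, TR
  2.68 s, 150 frames, lag −1, noise SD 0.3 — a noise level at which
  per-subject lag recovery is reliable but not trivial.
* **Gd curves** — zero baseline (3 frames), linear ramp (sigmoid
  behind a flag) from frame 6 to the peak at frame 12, then exactly
  `A·e^(−t/Decay) + C` with A = 0.38, C = 0.02 (peak +40 %),
  Decay = 30 min on a 3.33 min/frame, 40-frame grid; "SNR 20" means
  additive Gaussian noise with SD = peak/20.
* **Pulsatile signal** — unit-mean sum of sinusoids: cardiac 4.58 Hz
  (amplitude 0.05), its first harmonic at 0.4× that amplitude
  generated in continuous time and sampled at 70 ms so it aliases
  naturally to ≈ 5.13 Hz, respiration 1.5 Hz, vasomotion 0.05 Hz,
  plus optional white noise; 2500 frames.
* **pCASL** — constant control signal and T1 map; the label signal is
  obtained by inverting the quantification formula at the true CBF, so
  quantification is an exact round trip.

Determinism: every generator draws from `default_rng([stream, seed,
unit])` with fixed per-generator stream offsets — independent,
reproducible substreams from one integer seed.

What passing these simulations shows: the estimators are unbiased and
correctly implemented under the stated signal model. What they do not
show: robustness to scanner physics (T2* decay, partial volume),
registration error, non-stationary physiology or structured (non-white)
noise — none of which the generator models.

The emulated infusion protocol is arithmetically self-consistent in
duration (8.0 µl at 0.5 µl/min = 16 min) but the generator deliberately
models signal shape only, not dose.

## Tracer kinetics

Curves are stored as fractional signal change (0.2 = +20 %); all
kinetic times are scale-invariant, and the AUC map alone is divided by
the whole-brain AUC (mean masked-voxel AUC) — normalising the curves
themselves before kinetics would change nothing but the AUC unit.
Arrival is the first post-injection frame **strictly** above 20 % of
the post-injection maximum, reported at frame resolution (3.33 min) —
no sub-frame interpolation, because the definition is a threshold
crossing on sampled frames. The influx rate is a least-squares slope
over the arrival-to-peak window (a two-point mode exists behind a
flag). The decay fit parameterises time from the peak frame
(`A·e^(−(t−t_peak)/Decay) + C`), removing the A/Decay degeneracy of an
absolute time origin; initialisation is C₀ = last value, A₀ = peak −
last, Decay₀ = time to fall halfway from peak to last (fallback: half
the post-peak span); Decay is bounded positive; parameter tolerance
1e-10 with deterministic restarts, and persistent non-convergence
raises a flagged error instead of silent NaNs. Voxel-wise failures
(no enhancement, failed fits) are flagged in a QC map and excluded,
never interpolated.

## Pulsation

"2 Hz width" is read as the total band width (cardiac ± 1 Hz); a
half-width mode exists behind a flag. The aliased first harmonic is
not widened into the band: it contributes only when its folded
frequency naturally falls inside (which it does for the default TR and
heart rates), and is reported either way. Power is the plain variance
of the band-filtered mean-normalised signal, not of its envelope.

## CBF

The inversion-recovery T1 model is the magnitude form
`|s0·(1 − b·e^(−TI/T1))|` with the inversion factor `b` free (perfect
inversion gives b = 2) for robustness to imperfect inversion. With λ
in ml/g and times in ms the quantification formula yields ml/g/ms; the
output unit ml/100 g/min (the field convention — the formula itself is
unit-agnostic) uses the conversion factor 100 × 60000 = 6e6, which is
asserted by a dimensional-analysis test. Labeling efficiencies outside
[0, 1] (a mis-set labeling phase) are clipped with a warning; when
arrayed labeling-power data provide several phase settings, the
maximum α is the one to use.

## Statistics

The normality gate is Shapiro–Wilk at p < 0.05 per group (the gate's
cut-off is this package's documented choice); both groups normal →
pooled-variance two-sample t (Welch behind a flag), otherwise Wilcoxon
rank-sum. One-tailed directions must be supplied by the caller —
pre-stated hypotheses are not inferred from data. Partial correlation
is residual-on-residual Pearson with n − k − 2 degrees of freedom; a
predictor collinear with the covariates is an error, while an outcome
fully explained by the covariates returns a partial correlation of 0
(nothing left to explain). Holm–Bonferroni is the step-down
`max_{j≤i}((m−j+1)·p(j))` capped at 1. Joint linear models report R²
and each predictor's unique ΔR² against the model without it.

Voxel-wise inference: pooled t per voxel, two-sided threshold at the
voxel p, 26-connected components, and a cluster-extent threshold taken
from the permutation distribution of the maximum suprathreshold
cluster size under group-label exchange (clusters must **exceed** the
(1 − p_cluster) quantile of that null). This permutation null replaces
Gaussian-random-field Monte-Carlo cluster simulation: it is
self-contained, assumption-light, and its false-positive calibration
is itself tested (500 null simulations in the acceptance suite, with
2000-draw type-I calibration of the gated group test).

## Problem sizes used in validation

Cohort simulations use 20 subjects × 150 frames; lag-recovery
properties use 200 replicates; kinetic recovery uses 100 noisy curves;
cluster-null calibration uses 500 simulations of 8×8×8 grids with
6 + 6 subjects and 99 permutations each — sizes at which the Monte-
Carlo standard errors are small relative to the tolerances being
asserted.

## Known limitations

* No image registration, motion *correction*, denoising or
  segmentation — upstream tools own those steps; only FD computation
  from given motion parameters is provided.
* Scrubbed-then-filtered series treat the retained frames as contiguous
  (the standard consequence of dropping frames before filtering).
* Frequency-domain filtering assumes effectively stationary signals
  within the analysed window.
* The cluster-extent permutation null assumes group exchangeability
  and a common grid; it does not model spatial autocorrelation beyond
  what the data themselves carry.
* Kinetic times are frame-resolution quantities; sub-frame precision
  would require a model-based interpolation that the arrival
  definition deliberately avoids.
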