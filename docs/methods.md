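# Methods

This note documents the models implemented in `phasesom`, the defaults that
matter, and the reasoning behind the choices that were genuinely open.

## Filtering

All filters are linear-phase FIR band-pass/band-stop designs obtained by
least squares (`scipy.signal.firls`) and applied forward and backward
(`filtfilt`, reflected-edge padding), so the net phase response is exactly
zero and the effective magnitude response is the square of the single-pass
response. Instantaneous-phase estimation breaks under phase distortion,
which rules out IIR filters entirely.

- **Filter length**: next odd integer ≥ 7 cycles of the band's low edge
  (`7·fs/f_lo`). Shorter designs (3 cycles) leave 5–8% passband ripple,
  which violates the amplitude-preservation contract we impose (in-band
  gain within 1% single-pass, 2% after the two passes); 7 cycles with a
  10:1 passband weighting brings in-band deviation below 0.9% for all five
  bands at both 500 and 250 Hz.
- **Transition width**: 25% of the band's low edge per side. This keeps the
  Delta filter realizable at 500 Hz (0.375 Hz transitions, 2335 taps).
- **Notch**: a zero-phase FIR band-stop at 49–51 Hz, ~2 s of taps; residual
  50 Hz amplitude after the two passes is below 2% in practice (contract:
  5%). The 80 Hz low-pass is skipped automatically when the sampling rate
  cannot support it.
- **Edge margins**: every filtering pass adds `n_taps` samples per end to
  the recording's `edge_margin`; all phase statistics exclude those
  samples. This is deliberately conservative — transients decay faster —
  but costs little at minute-long recordings.

## Phase synchrony

The analytic signal is computed per channel with the FFT-based Hilbert
transform; phases are four-quadrant angles, optionally unwrapped.
Zero-magnitude samples have no phase and propagate as NaN with a warning.

Circular correlation uses circular means computed with `arctan2` (a
single-argument arctangent is quadrant-ambiguous) and the balanced
quotient with the square root of the product of summed squared sines in
the denominator. Matrices store |r| so entries lie in [0, 1]; the signed
matrix is kept alongside because the sign (phase deviations co-varying in
anti-phase) is information.

**Full-recording vs epoch-averaged estimates.** By default
`connectivity_matrix` uses the whole (margin-trimmed) recording. The
wrapped phase of a narrowband signal is close to uniform on the circle, so
its circular mean — the anchor of the correlation — is itself a noisy
estimate, and single-shot r values of genuinely coupled pairs scatter
widely between subjects. `epoch_average_connectivity` cuts the recording
into windows (default 5 s) and averages the per-epoch matrices, which
stabilizes the estimate markedly; the reference studies in
`phasesom.studies` use this mode, and it is what makes planted effects
recoverable at realistic cohort sizes. Nothing else in the pipeline
depends on the choice.

## Synthetic cohorts

Each coupling entry (band, channel pair, weight w ∈ [0, 1]) owns a shared
narrowband source: unit-variance white noise filtered into the band (with a
sharpened 10% transition so ≥ 93% of source power lies strictly in-band).
Both channels of the pair receive w·s(t); every channel additionally
receives independent Gaussian noise (default s.d. **0.8**). The default was
calibrated once so that w = 0.8 produces a Beta-band circular correlation
around 0.5–0.8 (measured ≈ 0.59 at 500 Hz, ≈ 0.67 at 250 Hz), with w = 0.3
clearly lower (≈ 0.3) — a strong but not trivial planted effect.
Per-subject randomness is seeded from (master seed, subject index), so
cohorts are bit-reproducible while subjects stay independent. An optional
100% amplitude modulation of the sources (4.8 or 16 Hz) is available for
realism; it does not change the phase-synchrony ground truth and defaults
off.

What the generator does **not** emulate: volume conduction (a single source
leaking into neighbouring electrodes), 1/f background spectra, ocular and
muscle artefacts, non-stationarity, or within-group heterogeneity of
coupling. Passing tests on these cohorts therefore demonstrate that the
pipeline recovers planted phase coupling under additive noise — not that it
is robust to the confounds of real scalp EEG.

## SOM anomaly detection

Prototypes are initialized linearly on the first two principal components
(rows span ±2 s.d. along PC1, columns along PC2; degenerate grids collapse
gracefully) and trained with online updates
ω_i ← ω_i + α(t)·h_i(t)·(x − ω_i), Gaussian neighbourhood h, exponential
decay of both α (0.5 → 0.01) and the neighbourhood width σ
(max(rows, cols)/2 → 0.5) over `500 × n_samples` presentations drawn with
replacement under the stored seed. The training loop is a numba kernel:
permutation testing retrains the map tens of thousands of times.

- **Grid size**: the library default is 8×8. The *studies* use 3×3: with
  ~16 control training subjects per CV fold, a map with more units than
  samples memorizes them (training QE → 0), and the Bayes threshold —
  fitted on training QE — then misclassifies held-out controls wholesale.
  Keeping the prototype count below the training-set size keeps the map a
  genuine quantizer. If you have hundreds of training samples, grow the
  grid (a common heuristic is ≈ 5√N units).
- **QE and band relevance**: QE is the Euclidean distance to the BMU (ties
  broken to the lowest unit index); per-unit mean QE over receptive fields
  gives activation maps (empty units are NaN, not zero). Band separability
  is the symmetrized KL divergence, 0.5·(D(P‖Q)+D(Q‖P)), of the two
  groups' QE histograms on shared equal-width bins (Freedman–Diaconis
  count on the pooled sample, additive smoothing 1e-9).
- **Bayes threshold**: one-dimensional Gaussian class-conditionals on QE
  with empirical priors; the threshold is the posterior-equality point
  between the class means (found by bracketed root-finding, with the
  quadratic-root fallback when extreme priors push the crossing outside).
  A sample exactly at the threshold counts as control. ROC scores use the
  posterior log-odds of the anomaly class — monotone in the posterior but
  immune to its floating-point saturation at 1.0.

## Evaluation

Cross-validation is stratified at the subject level; when recordings are
epoched, all epochs of a subject share its fold, so no subject leaks
between train and test. Within a fold the SOM sees only control training
samples; QE of *all* training samples fits the threshold; test samples are
scored and classified. Metrics are reported as mean ± s.d. across folds
(the s.d. is across folds only, not repetitions).

Per-edge group differences use two-sided Mann–Whitney tests — exact
enumeration when both groups have ≤ 8 subjects, the tie- and
continuity-corrected normal approximation otherwise — with
Benjamini–Hochberg adjustment across all C(C−1)/2 edges at α = 0.05 and a
stricter display flag at adjusted p < 0.01. AUC uses the rank (U-statistic)
formulation, handling ties exactly.

The permutation test shuffles subject labels, re-runs the full CV per
permutation, and reports both the plain empirical p,
(#null > observed)/B, and the smoothed (b+1)/(B+1) variant; the plain
count can be exactly zero, which the smoothed form avoids. Calibration
checks use the smoothed p.

## Problem sizes used in validation

The reference planted-deficit study uses 20 controls / 10 cases, 16
channels, 60 s at 250 Hz, Beta coupling 0.8 → 0.3 on 8 disjoint edges —
small enough for multi-seed runs in minutes, large enough for the edge
tests to have real power. Null calibrations use 10+10 subjects at 20 s
(edge tests, 16 channels) and 10+6 subjects, 4 channels (permutation
calibration, B = 99 across 100 repetitions). These sizes are scaled-down
study designs, chosen to make repeated end-to-end validation routine.

## Known limitations

- Synchrony here is undirected and within-band; cross-frequency coupling,
  coherence and causality measures are out of scope.
- The circular correlation is undefined for channels with zero circular
  variance (constant phase); such pairs are flagged NaN rather than
  imputed.
- The Bayes threshold assumes roughly Gaussian QE within each class; with
  strongly multimodal QE the posterior-crossing point between the means
  may be a poor operating point even when ranking (AUC) is excellent.
- The threshold is fitted on training-set QE, which underestimates
  held-out QE when the map is large relative to the training set;
  accuracy is therefore more grid-sensitive than AUC.
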