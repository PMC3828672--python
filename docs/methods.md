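# Methods

This note documents the models, numerical choices and limitations of
`muhit`: a pipeline that decodes a discrete motor act ("hit" vs "no-hit")
from multi-unit intracortical recordings, and the synthetic world used to
validate it.

## 1. The decoding pipeline

### 1.1 Wavelet denoising

A 5-level orthogonal discrete wavelet transform is applied per channel over
the whole recording; all detail coefficients are soft-thresholded with a
single global threshold `Th = γ σ √(2 ln N)` and the signal reconstructed.
Approximation coefficients are untouched (standard practice for denoising:
the lowest band carries slow structure, not the broadband noise being
suppressed).

* **Noise scale σ** is the least-squares slope of the empirical order
  statistics against standard-normal quantiles, restricted to the central
  25th–75th percentile band.  The central band makes the estimate robust to
  spike-driven tails; on pure Gaussian noise it is asymptotically unbiased,
  and the suite verifies recovery within 5% (10% with 10σ spikes at 20 Hz
  superimposed).  A constant window returns σ = 0.
* **N** is the full per-channel vector length.  With minutes of data at
  24.414 kHz, `√(2 ln N) ≈ 5.5`, so large-γ grid cells are aggressive and
  shrink small spikes along with the noise.  That is intentional: the
  threshold correction factor γ is swept over 10 values in [0.4, 2] exactly
  so the grid spans gentle to destructive shrinkage, and the best cell is
  selected by downstream classification error, not by signal fidelity.
* **γ = 0 is accepted** as an explicit identity limit (Th = 0, perfect
  reconstruction); it doubles as a diagnostic that Case B degenerates to
  Case A exactly.
* **Mother wavelets**: haar, db2/4/6, sym2/4/6, coif2/4/5 — short
  orthogonal filters whose shapes resemble extracellular action
  potentials.

**Transform implementation.**  No wavelet library is assumed: the DWT is a
periodized (circular) orthogonal filter bank implemented in-package.  With
an orthonormal bank, circular boundary handling is exactly orthogonal for
every even length (the even-lag circular autocorrelation of the filters
aliases only at multiples of the signal length), so reconstruction is exact
to round-off with no coefficient redundancy; odd lengths at any level are
extended by repeating the final sample and cropped on inversion, which
preserves exactness.  Circular edge effects are confined to one filter
length (≤ 30 samples ≈ 1.2 ms) at the recording boundary — negligible on
multi-minute channels.  Filter coefficients were derived from first
principles (`scripts/make_filters.py`): spectral factorization of the
maximally-flat half-band polynomial for the Daubechies family
(minimum-phase root selection), enumeration of conjugate-consistent
spectral factors for the least-asymmetric Symlets, and a Newton solve of
the orthonormality/vanishing-moment equations for the Coiflets.  The test
suite re-verifies unit norm, `Σh = √2`, double-shift orthogonality and the
exact vanishing-moment counts, so correctness does not rest on the
generator.  Convolutions are evaluated in the time domain (the filters are
≤ 30 taps); an FFT formulation was rejected because recording lengths
routinely contain large prime factors.

### 1.2 SNR metric

`SNR_estim = 20 log₁₀(A_s / A_n)` on a 400 ms window, with `A_s = max|x|`
(peak amplitude, signal plus noise) and `A_n = 4 σ_D`,
`σ_D = median|x| / 0.6745`.  An all-zero window has undefined SNR and is
flagged (NaN) rather than raised, since windows are evaluated in bulk.

### 1.3 Spike detection

Threshold excursions with `Thr_D = 4 σ_D` recomputed per consecutive,
non-overlapping 400 ms window (adaptive mode) or one fixed level (manual
mode).  Choices the data format forces but the method description leaves
open:

* **Polarity**: absolute-value crossings by default (multi-unit recordings
  mix polarities; `negative`/`positive` are available).
* **Timestamp**: the extremum within 1 ms after the first crossing — more
  stable for interval counting than the crossing sample itself.
* **Refractory**: 1 ms; crossings are processed in order and the earlier
  spike wins.
* The trailing partial window computes its threshold from its own samples.
* Interval counts use half-open bins `[t0, t1)`, so contiguous bins
  partition without double counting.

### 1.4 Features and trial selection

A successful trial is three consecutive paddle hits; trials flagged as
failures (non-preferred limb, premature hit) or containing an inter-hit gap
< 200 ms are discarded, and only the first hit of each surviving trial is
used.  Default interval placement ("gap40"): hit bins at [−400, −280),
[−280, −160), [−160, −40) ms relative to the hit — ending 40 ms before
contact because forelimb muscle activity begins ≈ 300 ms before a reach and
cortical activity leads it; no-hit bins are the same pattern 500 ms
earlier, [−900, −540).  A window "up to −400 ms before the hit" admits two
natural anchorings; `WindowSpec.flush()` implements the alternative
([−360, 0) / [−860, −500)) behind one switch rather than deciding silently.
Only channels whose microstimulation category is pure "paw" enter the
feature matrix (channel-major, then interval); each trial contributes one
hit and one no-hit row, so the design is exactly balanced.

### 1.5 Classification and evaluation

QDA with maximum-likelihood class Gaussians.  Covariances receive a ridge
`Σ ← Σ + ε·(tr Σ / d)·I`, ε = 10⁻⁶ (ε·I if a class is fully degenerate), so
small sessions with constant count columns still yield positive-definite
models.  Exact posterior ties break toward the larger prior, then the
earlier label.  Evaluation is stratified, seeded five-fold cross-validation
(80/20): per-fold error = 100·(FN+FP)/fold size, session error = fold mean,
accuracy = 100 − error; sensitivity and specificity are computed on pooled
fold counts.  Whether the original analysis stratified its folds is
unknown; stratification preserves the balanced design in every fold and is
the deterministic choice.  ANOVA across cases is the classical one-way F
test on session-level errors (session-level, not fold-level, matching an
"average error across sessions" comparison); fully constant input is
rejected as degenerate rather than returning NaN.

## 2. The synthetic world

The generator emulates the statistical structure the pipeline assumes — it
is a stated world, not a fit to data.

| parameter | default | rationale |
|---|---|---|
| sampling rate | 24 414 Hz | acquisition rate of the emulated system |
| baseline MU rate | 20 Hz/channel | typical multi-unit rate on a cortical microwire |
| units per channel | 2–5, amplitudes 0.5–1.0 × nominal | unsorted multi-unit character |
| hit modulation | ×3 in [−300, 0) ms before each hit | onset matches the ~300 ms forelimb EMG lead; the magnitude is a free parameter of the world — the emulated recordings report only that decoding succeeds |
| spike amplitude | 80 µV nominal (8σ); 50 µV (5σ) in the `low_snr` preset | comfortable vs marginal detection regimes |
| noise | white, σ = 10 µV (pink and burst variants available) | thermal/electrical floor; biological excess |
| no-hit background | ×1.5 noise amplitude in ~70% of inter-trial epochs | higher-amplitude activity is *typically* (not always) observed between hitting sequences; making it stochastic keeps it a nuisance rather than a leak-free label (a constant gain let a fixed threshold decode from false alarms alone, inverting the finding under study) |
| protocol | 3 hits/trial, self-paced 0.4–1.2 s gaps, 9 s retraction, 10% failure trials, 5% short hit pairs | the behavioral task's stated structure, plus enough pathology to exercise the exclusion rules |
| refractory | 1 ms on the merged channel train | matches the detector's assumption |

Spike waveform: 0.4 ms negative lobe, 0.6 ms positive overshoot scaled so
the waveform is exactly zero-mean — its spectrum then concentrates around
1–2 kHz inside the 0.8–8 kHz acquisition band with no DC component.  An
explicit causal band-pass at the 0.8 kHz edge was tried and rejected: the
filter's rebound exceeded the negative lobe, destroying the
negative-leading shape; zero-mean construction achieves the band-limiting
intent without the distortion.  Spike times are quantized to the sample
grid so ground truth and rendering agree exactly.  Manual thresholds for
Case C are the true 4σ level biased +20%, emulating a once-per-session
visual estimate.

**What the generator does not emulate** — and hence what a green test does
not establish: electrode drift and unit loss across sessions, spectrally
realistic chewing artifacts (bursts are amplitude-only), correlated
inter-unit firing, non-Poisson spike statistics, and any kinematic content
beyond the binary act.  Null configurations (modulation 1, equal
backgrounds) carry no class information by construction, and the suite
checks the whole pipeline sits at chance there — that is a calibration
check, not evidence about real recordings.

## 3. Scale of the shipped experiments

Desk-scale runs use 8–12 trials per session and 1–4 channels (the emulated
experiments averaged ~59 accepted trials over 16-channel arrays, 25
sessions).  The acceptance checks therefore test *directional* claims —
denoising + adaptive detection beats raw adaptive detection and manual
thresholding on noisy sessions, chance-level behavior under the null —
never the absolute accuracies of the original recordings, which are not
reproducible without the animal data.

## 4. Known limitations

* The universal threshold uses one global Th for all five detail levels;
  level-dependent thresholds are common elsewhere but are not part of the
  emulated analysis.
* QDA covariance estimation is noisy below ~10 trials per class per 3
  features; the ridge keeps it defined, not well-conditioned.
* The Q-Q σ estimate is mildly inflated when a large fraction of the
  recording carries the elevated no-hit background (it sees a variance
  mixture); this only scales the γ grid, which is swept anyway.
* `grid_search_caseB` reports the grid *minimum* with a shared CV seed —
  an optimistic model-selection estimate, as in the emulated analysis; it
  is interpreted comparatively, not as an unbiased accuracy.
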