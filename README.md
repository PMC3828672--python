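# muhit — movement-intent detection from multi-unit motor-cortex recordings

`muhit` implements a hit / no-hit decoding pipeline for intracortical
multi-unit (MU) recordings from freely moving animals, together with a
synthetic-session generator that makes every stage testable against known
ground truth.  The scientific question it addresses: can a discrete motor
act (a rat pressing a paddle) be detected from unsorted M1 multi-unit
activity, and how much do wavelet denoising and adaptive (rather than
manually set) detection thresholds help when the recordings are noisy and
the animal is free to move?

The pipeline compares three analysis cases on each session:

* **Case A** — adaptive spike detection on the raw signal,
* **Case B** — wavelet soft-threshold denoising, then adaptive detection,
* **Case C** — fixed, manually set detection threshold (routine practice).

## The method

**Denoising.** Each channel is decomposed with a 5-level orthogonal DWT
(10 candidate mother wavelets: haar, db2/4/6, sym2/4/6, coif2/4/5) and every
detail coefficient is soft-thresholded, `c ↦ sign(c)·max(|c|−Th, 0)`, with
the universal threshold

    Th = γ · σ · √(2 ln N),

where `σ` is the noise standard deviation read off a quantile–quantile plot
of the samples against standard-normal quantiles (central 25–75% band, so
spike-driven tails don't bias it), `N` is the channel length in samples and
`γ ∈ [0.4, 2]` is a correction factor swept over 10 values.

**Detection.** Spikes are threshold excursions with a 1 ms refractory
period.  The adaptive threshold is recomputed on consecutive 400 ms
windows as

    Thr_D = 4·σ_D,   σ_D = median(|x|) / 0.6745,

a robust noise scale that high firing rates cannot inflate (an RMS-based
level would rise with the spikes themselves).

**Features and classification.** For each accepted trial (three consecutive
paddle hits; trials with hit pairs closer than 200 ms, or flagged failures,
are discarded; only the first hit is used) the paw-responsive channels
contribute spike counts in three 120 ms intervals ending 40 ms before the
hit ("hit" class) and three equal intervals 500 ms earlier ("no-hit"
class).  A quadratic discriminant (class-conditional Gaussians, ridge-
regularized covariances) is scored by stratified five-fold cross-validation;
reported metrics are the fold-averaged error, accuracy = 100 − error, and
pooled sensitivity TP/(TP+FN) and specificity TN/(TN+FP).  Session errors
across cases are compared with a one-way ANOVA.

**Synthetic sessions.**  Because the original animal recordings are not
public, the package ships a generator: inhomogeneous-Poisson multi-unit
trains (2–5 units per channel) whose rate triples in the 300 ms before each
hit on movement channels, ~1 ms biphasic negative-leading waveforms,
additive white/pink/burst noise whose amplitude is raised in ~70% of the
inter-trial epochs (emulating the typically higher no-hit background), and
the full paddle protocol with 9 s retractions and failure trials.  One seed
fixes a session bit-for-bit.

## Worked example

`python examples/05_compare_cases.py` (three seeded low-SNR sessions,
reduced 4×4 denoising grid) prints:

```
 session  err A %  err B %  err C % best wavelet  gamma
       1     68.3     10.0     31.7         haar   1.20
       2     40.0     13.3     36.7         haar   0.40
       3     26.7      6.7     46.7         sym4   0.80

Case A: error 45.0 +/- 21.3 %  (accuracy 55.0 %)
Case B: error 10.0 +/- 3.3 %  (accuracy 90.0 %)
Case C: error 38.3 +/- 7.6 %  (accuracy 61.7 %)
ANOVA  A vs B: F = 7.92, p = 0.0481;  B vs C: F = 34.68, p = 0.0042
```

Read: with spike amplitudes only 5× the noise floor, raw adaptive detection
(A) misses small units and decodes poorly; denoising first (B) collapses the
noise floor so the re-adapted threshold recovers them, and the best
wavelet/γ cell differs per session — both the accuracy gain from denoising
and the session-dependence of the best combination mirror what is seen on
real recordings.  The fixed manual threshold (C) suffers wherever the
inter-trial background shifts under it.

The other examples walk the individual stages: `01` session synthesis and
disk round-trip, `02` denoising and the SNR_estim metric, `03` adaptive vs
manual detection scored by F1 against ground truth, `04` feature extraction
and cross-validated QDA.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates seeded synthetic sessions and recomputes the full three-case
comparison (Case B over the complete 10-wavelet × 10-γ grid), printing the
per-session errors, the across-session summary and the ANOVAs, and writing
the results object to `--out`.
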