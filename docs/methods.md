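# Methods

## The problem

Continuous speech contains no isolated "events", yet evoked-potential
analysis needs time-locking points. The package treats every phone instance
in a forced alignment as an event: segments of continuous-speech EEG are
aligned to phoneme onsets and averaged per phoneme category, yielding
phoneme-related potentials (PRPs). Pairing each PRP with the identically
epoched auditory spectrogram of the stimulus lets the representational
geometry of the two spaces be compared lag by lag, which is how the package
quantifies *when* acoustic-phonetic and speaker information appear in the
EEG.

## Core quantities

With `r(e, t)` the preprocessed EEG of electrode `e` and `s(f, t)` the
auditory spectrogram, and category `k` occurring at onsets `T_k1 … T_kN`:

    PRP(k, e, τ) = (1/N_k) Σ_n r(e, T_kn + τ)
    S̄(k, f, τ)  = (1/N_k) Σ_n s(f, T_kn + τ)

for lags τ in −100…600 ms. Everything downstream is built from these two
tensors:

* **Distance series** — at each lag, the K×K Euclidean distance matrix
  between category vectors (electrodes or frequency channels).
  Similarity is `m − D` with `m` the mean of the matrix entries (including
  the zero diagonal; a lower-triangle-only mode exists).
* **Cross-covariance map** — covariance between the strict lower triangles
  of the two series at every lag pair; only the lower triangle enters to
  avoid double-counting the symmetric matrix. Significance comes from a
  paired token bootstrap (n = 20 resamples, both spaces resampled with the
  same draw). Because a percentile p-value from 20 resamples is floored at
  1/21 ≈ 0.048 and can never clear q = 1e-4, the null is a bootstrap-t: the
  two-sided t(n−1) tail of mean/std of the resampled covariances against
  zero, BH-FDR corrected. The null definition is recorded in the result's
  metadata, and its type-I behaviour is verified empirically (see
  `null_calibration`).
* **Manner F series** — one-way ANOVA (plosive / fricative / nasal / vowel)
  at each lag, BH-FDR at q = 0.05. The default analysis unit is the
  per-category-per-subject PRP trace at one electrode (grand-average
  framing); a token-level mode uses single epochs and is what the
  latency-recovery study exercises. Zero within-group variance with nonzero
  between-group variance yields +inf with an exact-separation flag.
* **Speaker quantities** — per-speaker PRPs give a 2K×2K distance matrix
  whose diagonal quadrants are within-speaker and off-diagonal quadrants
  between-speaker distances. The scalar speaker index is
  mean(within) − mean(between) with i = j cells excluded everywhere (the
  within diagonal is structurally zero and the between diagonal is the
  same-phoneme cross-speaker distance; excluding both makes the index
  exactly zero for identical speakers). The per-phoneme speaker-encoding
  index is

      SE(i) = mean_{j≠i} [ (d_BS1(i,j) + d_BS2(i,j))
                         − (d_WS1(i,j) + d_WS2(i,j)) ] / 2

  over feature×lag vectors in the 0–400 ms window: zero when the two
  speakers' representations coincide, growing with their separation, and
  free to go negative. The lag×lag speaker map correlates, across category
  pairs, the between-minus-within contrast patterns of the two spaces; the
  same-phoneme diagonal is excluded from the pattern because its magnitude
  is dominated by per-category estimation noise whose size tracks category
  counts in both spaces and would correlate the maps everywhere.
* **Clustering / embedding** — UPGMA (average linkage) on Euclidean
  distances between electrode×lag vectors in 0–400 ms, implemented directly
  (O(K³), K ≤ 60) so the tie rule is explicit: among equal-distance pairs
  the lowest (row, column) index pair merges first. Non-metric MDS
  (Kruskal stress-1) uses scikit-learn's SMACOF with 8 seeded restarts;
  output is centered, the first item forced non-negative in dimension 1,
  and lags with no significant electrode emit all-zero coordinates. The
  two-point case is embedded exactly at ±d/2. Silhouette is the standard
  per-item (b − a)/max(a, b), singletons scoring 0.

## Preprocessing

Zero-phase FIR bandpass 2–15 Hz: a symmetric Hamming windowed-sinc kernel
(length ≈ 3.3·fs / transition, default transition 0.5 Hz) applied once with
its group delay removed and reflection padding at the edges — exactly
zero-phase by symmetry. Channels are z-scored (constant channels dropped
with a warning). Epochs are rejected when any sample of any electrode
exceeds ±10 z-units — the per-electrode reading of the threshold, the
stricter of the two possibilities. Tokens within 500 ms of their
utterance's first onset are excluded to suppress the dominant
utterance-onset response. Token intervals are half-open `[onset, offset)`
and an onset maps to the nearest sample at or after it.

## Auditory spectrogram

Three stages over 128 channels log-spaced 80 Hz–8 kHz (test configurations
use fewer channels):

1. **Cochlear filterbank** — zero-phase FFT filtering with asymmetric
   magnitude responses: Gaussian skirts in log-frequency with the high side
   steeper (σ_high = σ_low / asymmetry, default asymmetry 2, σ_high
   0.35 octaves).
2. **Hair cell** — cube-root compression then a low-pass at 2 kHz. The
   low-pass is a non-negative Hann kernel (length fs/cutoff) rather than a
   Butterworth: a non-negative impulse response is what preserves pointwise
   ordering (larger input ⇒ larger-or-equal output), which the stage
   guarantees as an invariant.
3. **Lateral inhibition** — first difference along the channel axis with a
   replicated edge (channel 0 maps to zero), then half-wave rectification.
   The replicate edge makes a spectrally flat input map to exactly zero —
   the defining property of a spectral derivative — at the cost that an
   impulse confined to channel 0 is invisible.

The envelope of each channel is the rectified signal smoothed by a Hann
kernel at half the frame rate and sampled at `frame_rate` (default 1 kHz, so
acoustic and EEG lags share a grid after resampling). Envelope extraction by
rectify-then-smooth rather than the analytic signal is a configuration
choice of this implementation.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *design* of a two-speaker continuous-speech
EEG study, not speech itself: 30 ARPAbet categories partitioned into the
four manners; utterances alternating between a male-like (f0 110 Hz) and a
female-like (f0 220 Hz, formants ×1.2) speaker; token durations log-normal
per manner (means 60/90/90/120 ms for plosive/fricative/nasal/vowel,
log-sd 0.25); category draws uniform (per-category phone frequencies are
not reported for the original materials, so no frequency prior is
imposed). Audio renders vowels and nasals as harmonic complexes and
obstruents as shaped noise with plosive bursts; formant scaling applies to
sonorant resonances only. An "ideal spectrogram" path paints category
spectral profiles directly onto a log-frequency grid — the controlled
acoustic representation used when a test must own the acoustic distance
structure exactly.

EEG is a linear forward model: per-token kernels of four Gaussian
components at 50/120/230/400 ms (σ 18/20/24/32 ms — wide enough that each
component is effectively band-limited inside the 2–15 Hz analysis band),
manner-dependent signed amplitudes, smooth electrode topographies, plus 1/f
noise at a configurable SNR and sparse 200 ms boxcar artifacts. Three
amplitude-table properties are deliberate:

* deflection signs vary by manner (second component positive for plosives,
  negative for vowels; fourth component signs cancel in the average) — and,
  numerically just as important, near-zero across-manner means for the later
  components. Because vowels are longer than plosives, the *next* token's
  mean response is time-locked at a manner-dependent delay; if a component
  had a large mean amplitude its neighbor image would plant spurious
  manner structure at displaced lags. Zero-mean components remove that
  image at the source.
* later-component amplitudes are additionally modulated by each category's
  standardized log center frequency (coupling 0.5), so the acoustic
  ordering of categories re-appears in the neural kernels at 120/230/400 ms
  — the planted "recurrent structure".
* obstruents and sonorants form tight amplitude pairs, so the top split of
  an UPGMA tree over the kernels is the obstruent/sonorant tier, with the
  first component's ordering decorrelated from the second's to keep the
  between-group F landscape from developing a spurious inter-component
  ridge.

The speaker effect is a single scalar: speaker 2's vowel amplitude on the
230 ms component is multiplied by (1 + separation), default 0.4; separation
0 makes the speakers' kernels identical (an exact identity the tests rely
on). Artifact transients are scaled so they measure 15 z-units *after*
downstream z-scoring, solving amp = z·sd/√(1 − z²·f) for coverage fraction
f; at high rates this has no solution (the artifacts would dominate the
variance) and the generator warns and caps the amplitude.

What the generator does **not** emulate: intelligible speech, realistic
head-volume conduction (topographies are smooth weight vectors, not lead
fields), non-stationary noise, eye or muscle artifact morphology, coarticulation,
or phonotactics (tokens are iid). Passing tests therefore demonstrate that
the *analysis* recovers what the forward model plants under realistic
noise, overlap and artifact conditions — not that real EEG would show these
effects at these magnitudes.

## Reference study conditions

The verification experiments (shared between the test suite and
`scripts/acceptance.py`) run at desk scale: 8 electrodes, EEG generated at
500 Hz, sessions of 1–5 minutes, and where cohorts are needed, 6 subjects
per run; the original study's scale (62 electrodes, 2 kHz, 60 minutes, 22
subjects) remains the default configuration of the pipeline types. Two
experiments equalize duration means across manners — with manner-dependent
durations, neighboring-token timing itself carries manner and speaker
information (a real phenomenon, visible as early-lag structure in the
covariance maps), and the controlled condition isolates the kernel-planted
effect being recovered. The latency-recovery study keeps the naturalistic
duration distributions. The vowel-speaker study uses +10 dB SNR (the
speaker contrast is one scalar on one component of one manner — far
subtler than the manner contrasts probed at 0 dB).

## Numerical choices

* F-peak matching: a planted latency counts as recovered when the F argmax
  within ±25 ms (neighborhoods disjoint for the 50/120/230/400 grid) lies
  within ±10 ms and is FDR-significant.
* The covariance/bootstrap analyses decimate the lag axis (steps of 4–5
  samples ≈ 8–10 ms) — far finer than the ~50 ms component spacing.
* Ridge regularization for the manner classifier is selected on an inner
  90/10 split over a log grid 1e−3…1e3; features are standardized with the
  training statistics.
* BH-FDR delegates to `statsmodels.stats.multitest.multipletests`; a
  brute-force step-up oracle exists only in the tests.
* Degenerate inputs: constant channels are dropped (z-score), constant
  confusion matrices and SE vectors raise, single-category sets raise,
  empty alignments warn and return empty sets.

## Known limitations

* Overlapping epochs are averaged raw; there is no deconvolution of
  adjacent-phone responses, so neighbor images are part of the estimated
  PRP (they are part of the method being implemented, not an artifact of
  this implementation).
* The bootstrap-t null is an approximation; with n = 20 resamples its tail
  calibration is verified empirically at the q used, not guaranteed
  analytically.
* EDF files can be read (through mne, when installed) but not written; the
  package's native EEG format is delimited text with a JSON header.
* The cochlear filter shapes are a parametric stand-in for measured
  cochlear tuning; only qualitative properties (log spacing, asymmetry,
  tone-to-channel mapping) are asserted.
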