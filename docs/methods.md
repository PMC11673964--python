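# Methods

This note documents the models and procedures behind ecgkit, the parameters
that matter, the numerical choices, and the limits of what the synthetic
benchmarks can show about real recordings.

## Synthetic ECG model

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) placed relative to
the R peak at time 0. Wave durations are drawn once per record from
physiological ranges: P 60–80 ms, QRS 80–120 ms, PR 120–200 ms, ST
100–120 ms, T 120–160 ms (explicit overrides may leave these ranges, e.g.
to emulate abnormally wide complexes). Default amplitudes approximate a
lead-II trace: P 0.15, Q −0.10, R 1.0, S −0.15, T 0.30 mV. Geometry: QRS
onset/offset at ∓w/2 from R, Q and S at ∓w/3 with σ = w/12, R with
σ = w/10 (narrow enough that the Q/S troughs remain visible deflections),
P and T with σ = width/6 so the annotated onsets/offsets sit at 3σ, where
the Gaussian has decayed to ~1% of its peak. The generator records the exact
sample index of every fiducial, which is what makes detector scoring exact.

Beat timing comes from the configured heart rate (scalar or per-beat
sequence), optionally modulated sinusoidally (`hrv_modulation =
(frequency_hz, depth_s)`) to emulate respiratory sinus arrhythmia. The
first R peak sits at RR/2 so a `duration`-second record at h bpm contains
exactly `duration·h/60` beats when that is an integer.

Rhythm classes are rate-defined with standard clinical thresholds:
bradycardia < 60 bpm, tachycardia > 100 bpm, boundary rates normal. The
class-conditional dataset generator (`generate_labeled_dataset`) instead
draws per-record heart rate, QRS amplitude, QRS duration and PR interval
from per-class normal distributions whose means/SDs are the statistics of
the reference recordings (`RHYTHM_PROFILES`); note those statistics report
a "bradycardia" group with mean HR 84.09 bpm, i.e. the group label there
encodes the source cohort, not the rate-threshold definition. Labels of
generated records always follow the generating class.

### Noise model

Three physical sources plus white noise. Baseline wander: a sub-1 Hz
sinusoid, or (when no frequency is given) a random walk low-passed at 1 Hz.
Powerline: a 50/60 Hz sinusoid with seeded random phase; `amplitude` is the
peak value. Motion artifact: 1–10 Hz band-passed Gaussian noise shaped by a
smooth burst envelope (~40% duty cycle); for the stochastic kinds
`amplitude` is the realized RMS, which makes `noise_for_snr` exact. Every
realization is fully determined by its seed, so clean signals are
recoverable by subtraction and SNR is measurable, not estimated.

What the generator does **not** emulate: multi-lead geometry, beat-to-beat
morphology variability within a record, ectopy, atrial-fibrillation
f-waves, electrode pop artifacts, or realistic 1/f sensor noise. Passing
tests therefore demonstrate algorithmic correctness and noise robustness in
the modelled bands — not clinical-grade performance on arrhythmia
databases.

## Filtering

All stages are Butterworth designs applied forward–backward
(`sosfiltfilt`), i.e. zero phase, so fiducial timing is never shifted.
Defaults: 4th-order 100 Hz low-pass, 4th-order 0.5–100 Hz band-pass,
2nd-order high-pass at 0.1 Hz for baseline removal, and an optional IIR
notch (Q = 35) at 50/60 Hz. The band-pass cannot remove in-band mains
coupling, hence the explicit notch stage. The baseline high-pass rejects
only components below its cutoff: drift at 0.3 Hz requires a cutoff above
0.3 Hz (still < 1 Hz); the 0.1 Hz default is the conservative choice that
preserves ST-segment morphology. Cutoffs are validated against Nyquist and
both band-pass corner frequencies are exposed as parameters.

## Wavelet-packet engine

The Daubechies scaling filter of order N (2N taps, N vanishing moments) is
constructed by spectral factorization: root the binomial half-band
polynomial `P(y) = Σ_{k<N} C(N−1+k, k) y^k`, map each root to the z-plane
via `z² − (2−4y)z + 1 = 0`, keep the minimum-phase root, and multiply by
`(1+z)^N`; normalize to `Σg = √2`. Orders 1–10 are supported; coefficients
agree with PyWavelets' `rec_lo` to ~1e-14 (the package convolves with `g`
where PyWavelets correlates, so its `dec_lo` is the reversed filter — the
exact coefficient mapping is pinned in a test).

Analysis/synthesis use periodic (circular) boundary handling, which makes
the one-step map an orthogonal matrix: perfect reconstruction and Parseval
hold exactly, as does the zeroing identity below. Odd-length nodes are
wrap-padded by one sample before splitting and trimmed on reconstruction;
reconstruction stays exact, while level energies are then conserved for the
padded signal rather than the original (exact on power-of-two lengths).
Downsampling keeps even-indexed outputs; node indexing is natural
filter-bank order (position 0 = pure low-pass path at every level), not
Gray-code frequency order.

### Overlap zeroing

The redundancy targeted by the compression step is interpreted through a
pluggable policy:

* `levels_full` (default): zero every node at the listed levels (default
  {3, 4}) except the pure-approximation path, then re-derive descendants of
  modified nodes so the tree stays self-consistent. After zeroing {3, 4}
  only the A⁴ node (band 0 … fs/32) survives at the leaves.
* `magnitude`: per-node quantile threshold on |coefficient| (default
  median, removing ~half).
* `duplicate_run`: suppress repeated near-equal consecutive coefficients,
  keeping the first of each run.

Because the transform is orthonormal, the leaf energy removed equals the
squared reconstruction error exactly (`N·RMSE² = zeroed leaf energy`,
verified to ~1e-15 relative), and enlarging the zero set can never reduce
the error. "Lossless" therefore holds exactly when the zeroed coefficients
carry zero energy; on band-limited signals it holds approximately — a clean
synthetic ECG sampled at 1 kHz keeps ≥ 0.99 correlation with its
reconstruction after default zeroing because the retained 0–31 Hz band
covers virtually all template energy. At lower sampling rates (e.g. 360 Hz,
retained band 0–11.25 Hz) part of the narrow R spike is discarded; the
pipeline still classifies accurately because rhythm features survive the
smoothing, but the reconstruction is visibly low-passed.

## Feature extraction

R-peak detection follows the classic envelope pipeline: 5–15 Hz band-pass →
derivative → squaring → 150 ms moving-window integration → adaptive
signal/noise threshold (running estimates, threshold = noise + 0.25·(signal
− noise)) with a 200 ms refractory period; each accepted envelope peak is
refined to the dominant local extremum of the raw trace within ±100 ms. The
detector is deterministic and rejects records shorter than 2 s.

Delineation anchors on each R peak: Q and S as local minima within ±120 ms;
QRS onset/offset where the trace settles within 2% of the R amplitude
around the local baseline (median of the record); P peak as the last local
maximum in the 200→40 ms pre-QRS window (the *last* one, because at short
RR the previous T wave leans into the window — at rates well above 120 bpm
P/T overlap still biases the PR estimate); T peak as the largest maximum
100–400 ms after the QRS. Failed searches are flagged missing, never
fabricated, and flagged beats are excluded from the affected statistics.

HRV feature groups follow standard task-force conventions: time domain
(mean/median RR, RMSSD, average/maximum deviation, >50 ms successive-pair
count, 32-bin histogram over 0.3–2.0 s); frequency domain (linear
interpolation of the RR series onto a 4 Hz grid, Welch PSD, band powers
ULF < 0.003, VLF 0.003–0.04, LF 0.04–0.15, HF 0.15–0.4 Hz, LF/HF ratio);
distribution statistics (mean, median, SD with n−1 denominator, excess
kurtosis, range, skewness; NaN for the degenerate constant series). The
eight per-record beat statistics used for classification are the mean and
SD of heart rate, QRS amplitude (R peak minus the QRS-onset sample — a
simpler, deterministic baseline than the isoelectric PR segment), QRS
duration, and PR interval. `hr_mean` is defined as 60/mean(RR); `hr_sd` is
the SD of per-beat instantaneous rates.

## RFDDT classifier

Bootstrap sample of size n per tree; at each node the best Gini split among
⌈√p⌉ randomly selected features, thresholds at midpoints between sorted
distinct values; trees grown to purity by default ("deep":
`max_depth=None`, `min_samples_leaf=1`, both exposed). Majority vote with
ties to the lexicographically smallest label. Default 100 trees. All
randomness flows from one `SeedSequence`, so a seed reproduces the forest
bit-for-bit, and each tree's bootstrap sample can be regenerated from its
stored seed (used by the 1−e⁻¹ ≈ 0.632 unique-fraction check).

Multi-class scores are one-vs-rest per class and macro-averaged, since a
single sensitivity/specificity number is otherwise undefined for three
classes. Undefined ratios (zero denominators) are NaN, never a crash. The
benchmark harness runs stratified k-fold CV and accepts any estimator with
a fit/predict contract; sklearn's SVM, KNN, AdaBoost, gradient boosting,
logistic regression and bagging are the stock baselines.

## Pipeline and reproducibility

`run_pipeline` executes simulate/read → band-pass (optional notch) →
WPT decompose → zero → reconstruct → features → stratified-CV RFDDT, wraps
stage errors with the stage name, and logs timings. The global seed fans
out via `SeedSequence.spawn` (child 0: synthesis, child 1: CV/classifier),
so one integer reproduces the entire run. The default problem size (30
records per class, 20 s at 360 Hz, 100 trees, 5 folds) keeps a full run in
a few seconds while leaving per-class feature distributions comfortably
estimable.

## Known limitations

* The periodic boundary is chosen for exactness; symmetric extension (less
  edge ringing for visual work) is not yet wired through the tree API.
* WFDB support is a minimal native reader (formats 16 and 212, beat-level
  `.atr` annotations) plus a format-16 writer for fixtures; multi-segment
  records, other signal formats and non-beat annotation semantics are out
  of scope.
* Delineation assumes a single dominant positive R deflection; inverted or
  biphasic QRS morphologies would need a polarity-aware search.
* Classification experiments here quantify the pipeline's behavior on the
  synthetic cohort; they say nothing about accuracy on clinical arrhythmia
  databases, which depend on labeling and splitting protocols outside this
  package.
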