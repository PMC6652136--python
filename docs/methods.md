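# Methods

This note records the scientific and numerical choices behind the
package: what the simulator emulates, how each pipeline stage is defined,
where the design was genuinely open and what was decided, and what the
desk-scale results do and do not show.

## Synthetic cohort generator (`signal_sim`)

**Protocol.** Each subject performs nine 5-min tasks: relaxation at
positions 1, 3, 5, 7, 9 and the four stressors (easy/hard mental
arithmetic, easy/hard Stroop) once each, in a seeded random permutation.
Tasks switch instantaneously — no physiological ramp is modelled, because
the first 50-s clip of every task is discarded downstream anyway.

**Heart rhythm.** RR intervals are generated beat by beat as

RR = 60/HR(state) + A_LF · sin(2π·0.1·t) + A_HF · sin(φ_resp(t)) + ε,

where φ_resp is the integral of the instantaneous breathing rate (so the
high-frequency modulation is genuine respiratory sinus arrhythmia, locked
to the rendered RESP channel), ε ~ N(0, σ_RR), and intervals are clipped
at 0.25 s. State defaults (relax → stress): HR 65 → 80 bpm, A_LF
0.03 → 0.04 s, A_HF 0.04 → 0.015 s, breathing 14 → 19 breaths/min,
σ_RR = 10 ms. These are textbook-scale sympathetic-activation effects —
higher rate, suppressed vagal (HF) modulation, faster breathing — large
enough for a desk-scale classifier study; they are parameters, not claims
about any particular dataset. Per-subject jitter (±2 bpm, ±0.8
breaths/min, shared across states) provides inter-subject variability.

**ECG morphology.** Each beat is a sum of five Gaussian bumps (P, Q, R,
S, T) with fixed offsets/widths/amplitudes chosen so the R wave dominates
(argmax within one sample of the nominal R time) and P/QRS/T are visually
distinct — the property the activation-visualization stage needs.
Optional additive disturbances: 60 Hz powerline (off by default) and
sub-0.5 Hz baseline wander (0.05 mV). The generator emulates none of the
morphology variability, ectopy, electrode artifacts or device
idiosyncrasies of real recordings; passing tests therefore demonstrate
pipeline correctness and the learnability of the encoded contrast, not
field performance on human data.

**Respiration** is a unit-amplitude quasi-sinusoid of the instantaneous
breathing rate plus Gaussian noise (σ = 0.05). Inspiration peaks and
expiration troughs are recorded exactly from the noise-free phase.

**Self-report (VAS).** One 0–10 score per task: relax ~ N(2, 1), easy
stressors ~ N(5, 1.5), hard Stroop ~ N(6, 1.5), hard math ~ N(7, 1.5),
clipped to [0, 10] — reproducing the qualitative ordering (relaxation
lowest, hard math highest) without asserting numeric values.

**Randomness.** One master seed; subject *i* uses
`default_rng([seed, i])`, so any subject can be regenerated in isolation
and cohorts are bit-reproducible across platforms.

## Preprocessing (`preprocess`)

The ECG passes a 2000th-order 58–62 Hz FIR notch and then a 3000th-order
1.5–150 Hz FIR bandpass; respiration is deliberately unfiltered. The
design method (unspecified in most descriptions of such filters) is
windowed-sinc with a Hamming window — deterministic and standard.
Filtering is causal with the linear-phase group delay `(order)/2` samples
removed afterwards, so the stated order is applied exactly once;
forward–backward (zero-phase) filtering would effectively double it.

Segmentation uses strictly non-overlapping half-open windows
`[k·50, (k+1)·50)` seconds within each task; a 300-s task yields six
clips, the first is dropped (task-initialisation transient), leaving five.
The artifact screen is a pluggable per-segment predicate; the default
rejects zero-variance clips and clips with more than 1% of samples pinned
at either amplitude rail.

## Handcrafted features (`hrv_features`)

R-peaks: Pan–Tompkins-style detection (5–15 Hz bandpass, derivative,
squaring, 150-ms moving-window integration, adaptive threshold, 0.25 s
refractory period), refined to the local ECG maximum and amplitude-gated
at 25% of the largest refined peak so filter ringing cannot masquerade as
beats. On default synthetic clips the detector recovers ground-truth R
times with median error well under 20 ms.

NN intervals outside (0.25 s, 2.0 s) are rejected. The tachogram is
cubically interpolated onto a uniform 4 Hz grid, linearly detrended, and
Welch-estimated (Hann window, `nperseg = min(N, 256)`, 50% overlap); a
Lomb–Scargle path is available for irregular series. Band powers are
trapezoidal integrals of the PSD over VLF 0–0.04, LF 0.04–0.15, HF
0.15–0.40 Hz. Two deliberate literalisms:

* **TF band** is implemented as printed in the source feature table,
  0.14–0.40 Hz, with a `tf_band` override (0.04–0.40 Hz is the likely
  intent, but intent is not guessed).
* **MDA** follows the table definition — root mean square of successive
  differences — rather than the body text's "mean difference between
  adjacent elements"; the table definition wins.

Ratio features of a spectrally degenerate (near-constant) series are
emitted as 0 with a `degenerate` flag; the power floor is 10⁻¹⁵ s²,
orders of magnitude below any physiological modulation.

RESP features use Welch directly on the raw 25 Hz clip with the same
window convention; bands are the four 1-Hz strips up to 4 Hz.

## Baselines (`baselines`)

MinMax scaling to [0, 1] is fitted on training rows only (test rows may
leave the interval; constant columns map to 0). Outer five-fold CV uses a
seeded random shuffle into near-equal folds at segment level (a
subject-level grouping is available as an extension). Within each outer
training fold, each of SVM (RBF), random forest, k-NN, logistic regression
and decision tree is tuned by an inner 3-fold grid search over small
standard grids (documented in `DEFAULT_GRIDS`; the original study's grids
are unpublished, and these are not claimed to be them). AUC uses
predicted probabilities where available, otherwise the logistic-squashed
decision margin.

## The network (`engine`, `model`)

Architecture details not fixed by the published description, and how they
were resolved:

* **Dropout / batch-norm placement**: batch-norm after each convolution
  (pre-activation), dropout 0.5 after each LSTM and after the dense
  layer.
* **Pooling stride**: non-overlapping (stride = pool length), consistent
  with the stated dimensionality reduction (50 000 → 62 steps).
* **Weight decay** (10⁻⁴) is an L2 penalty on convolution, LSTM and dense
  kernels only — not biases or batch-norm parameters.
* **First LSTM returns sequences** (a second LSTM consumes it).
* **Validation split** (0.3) is stratified by label with the run seed.
* **Initialisation**: Glorot-uniform kernels, orthogonal LSTM recurrence,
  forget-gate bias 1.

Numerical implementation choices:

* The first convolution of each branch (600-sample kernel over 50 000
  samples at 1 kHz) is evaluated as an FFT cross-correlation; because it
  is followed by ReLU and a long non-overlapping max-pool, the training
  gradient reaching it is non-zero only at the pooled argmax positions,
  and the backward pass gathers exactly those input windows
  (`ConvPoolBlock`). Monotonicity of ReLU and of the per-filter affine
  batch-norm map makes the fused forward exact (windowed max for positive
  BN scale, windowed min for negative).
* Batch statistics of all normalization layers are treated as constants
  in the backward pass (no gradient through batch mean/variance). In
  evaluation mode, where running statistics are used, gradients are
  exact; the test suite's finite-difference checks run in that mode.
* Arithmetic is float32; losses are accumulated in float64. Predicted
  probabilities are clipped to [10⁻⁷, 1−10⁻⁷] inside the cross-entropy.
* Running statistics use momentum 0.99 and ε = 10⁻³.

Divergence (non-finite loss) aborts training with diagnostics. Identical
seeds give bit-identical training histories.

## Desk-scale study profile (`workflows`)

The full comparison study (`desk_benchmark`) runs on 16 simulated
subjects with the default effect sizes — 720 segments, of which 320 are
stressed. Problem sizes were chosen so the whole study, including
training, fits comfortably on one CPU core:

* ECG is simulated at **320 Hz** rather than 1 kHz. 320 Hz is near the
  floor admitted by the 1.5–150 Hz bandpass (the upper edge must stay
  below Nyquist) and preserves every architectural relation — kernel and
  pool spans in seconds, 62 pooled steps, the 20-s second-conv coverage.
  Protocol/segmentation bookkeeping is still verified at the native
  1 kHz.
* The main cross-validation trains **10 epochs per fold** (best
  validation-loss epoch selected, as in the full 250-epoch profile, which
  remains available through `TrainConfig`); the label-permutation null
  uses 3 epochs, since chance-level AUC is insensitive to training
  length.
* Activation co-location is measured on 20 segments (~1 300 beats,
  ~480 breath events).

Two co-location quantities are reported, deliberately in different
directions. For ECG, the fraction of ground-truth QRS complexes with a
top-decile activation of the best (highest-energy) filter within
±100 ms. For RESP, a first-layer filter spanning one breath period
phase-locks to a single phase of the cycle — individual trained filters
respond around peaks *or* around troughs, mirroring the two displayed
patterns of the original visualization analysis — so covering the pooled
peak+trough event set with one filter is structurally impossible (each
leading filter covers ~94% of one event type and ~0% of the other). The
RESP quantity is therefore the concentration of the activations
themselves: the fraction of the best filter's top-decile samples within
±0.5 s of the nearest breath peak or trough. Top-decile samples are
required to be strictly positive (dead ReLU outputs are not activations).

## Known limitations

* Cross-validation is segment-level, as in the original evaluation
  scheme: clips from one subject appear in both training and test folds,
  which inflates absolute performance relative to subject-independent
  evaluation. The `groups` option of `make_cv_split` provides the
  stricter split.
* The synthetic contrast is strong and clean; all models (deep and
  classical) can saturate on it. Results establish correctness and
  relative behaviour, not expected accuracy on human recordings.
* The WFDB importer covers single-file format-16 records with named ECG
  and RESP channels — enough for driver-stress-style data — and is
  read-only.
* The Lomb–Scargle HRV path uses a crude density normalisation and is
  intended for band-ranking, not absolute power comparison with the Welch
  path.
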