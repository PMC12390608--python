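# Methods

`erpauth` implements an EEG biometric identification pipeline — the
"registration phase" of a brainwave authentication system — together with a
synthetic ERP data generator so that every stage can be exercised and
validated without access to any recorded dataset. This note documents the
models, the numerical conventions, and the design decisions that were
genuinely open.

## Signal model and preprocessing

Recordings are multi-channel EEG in microvolts with a nominal rate of
256 Hz on the 14-electrode Emotiv EPOC+ montage (AF3, F7, F3, FC5, T7, P7,
O1, O2, P8, T8, FC6, F4, F8, AF4).

**Band-pass filter.** Preprocessing applies a zero-phase Hamming-windowed
FIR band-pass of 0.1–30 Hz. Each band edge is designed as a windowed-sinc
section with its own length from the `3.3 / transition-width` rule
(seconds, rounded up to odd taps) and its −6 dB point at the middle of its
transition band: lower transition 0.1 Hz (−6 dB at 0.05 Hz), upper
transition 7.5 Hz (−6 dB at 33.75 Hz). At 256 Hz the narrow lower edge
dictates 8449 taps. The construction is delegated to
`mne.filter.create_filter`, which implements exactly this per-edge scheme.
The kernel is applied in a single pass after reflect-padding by half the
kernel, then cropped to cancel the linear-phase group delay, so a symmetric
input maps to a symmetric output (zero net phase). Forward–backward
filtering was deliberately not used: the single-pass delay-compensated
convention is the one whose ripple/attenuation figures match a single
application of the Hamming design.

**Measuring ripple and attenuation.** A windowed-sinc design is
conventionally characterized by one number, its peak approximation error
δ, quoted in two forms: stopband attenuation `−20·log10(δ)` and passband
ripple `20·log10(1+δ)`. `measure_filter_response` measures δ from the
realized response as the highest stopband *sidelobe peak* (the stopband
begins a full transition width beyond the pass band; the monotone tail of
the main lobe just after the nominal stopband edge is rolloff, not a
sidelobe). For the study design this yields ≈53.0 dB attenuation and
≈0.0194 dB ripple. The raw maximum deviation from unity gain across the
whole 0.1–30 Hz pass band is also reported
(`max_passband_deviation_db`, ≈0.037 dB); it is larger because it includes
the onset of band-edge rolloff and the superposition of the two edges'
ripple patterns, and is the honest bound to use when an absolute gain
guarantee is needed.

**Average reference** subtracts the instantaneous mean across all channels
from every channel. Note the structural consequence: any spatially uniform
signal component is annihilated, and the across-all-channels mean of the
referenced data is identically zero.

## Epoching

Epochs span −100 ms to +900 ms around each stimulus onset with *both*
endpoint samples kept: the sample window is
`[onset + round(tmin·f), onset + round(tmax·f)]` inclusive, which at 256 Hz
gives 257 timepoints — the inclusive convention is the only one that
produces this count from a one-second window. Events whose window crosses a
recording boundary are dropped and counted. Baseline correction
(subtracting the pre-stimulus mean per epoch and channel) is implemented
but **off** by default; the pipeline it mirrors applies none.

## Features

A *sample* is built from a group of consecutive epochs of one subject
(non-overlapping groups, leftovers dropped; grouping in recording order
avoids train/test leakage through shared epochs).

- **Temporal (257 values).** The ERP is the arithmetic mean over the
  group's epochs per channel and timepoint, then reduced to one value per
  timepoint by averaging channels. Because the average reference forces the
  all-channel mean to zero exactly, the default reduction averages a
  configurable posterior subset (P7, O1, O2, P8 — the sites where P300/N400
  components are maximal) rather than the full montage; full-montage and
  per-channel (257 × 14) modes remain available.
- **Spectral (30 values).** Welch PSDs (Hann window, 256-sample segments,
  50 % overlap; an epoch shorter than one segment contributes one
  full-epoch segment) are averaged over the group's epochs, then summarized
  as the mean PSD in five canonical bands — delta 0.5–4, theta 4–8, alpha
  8–13, beta 13–30, gamma 30–45 Hz — on six configured channels (default
  F3, F4, P7, P8, O1, O2). The PSD grid extends to 45 Hz so the gamma band
  has support; after the 30 Hz low-pass its power is necessarily near zero,
  which is faithful to the stated pipeline. Band bins are half-open
  `lo ≤ f < hi`, last band closed.
- **Fusion.** Concatenation gives a 287-vector; temporal indices 0–256,
  spectral 257–286. This layout is asserted in tests.

## Classifiers

All models receive per-feature z-scored inputs; the standardizer is fit on
the training split only.

**1-D CNN** (implemented in numpy, self-contained): three conv blocks of
64/128/256 filters, each conv → batch-norm → ReLU → dropout (rates
0.2/0.2/0.4), max pooling after blocks 2 and 3; flatten; dense 256 and 128
(ReLU, dropout 0.3); softmax over subjects. Kernel size, pool size and
padding are not dictated by the architecture description; the defaults are
kernel 5, pool 2, "same" padding, chosen by validation performance on
development seeds. Training: Adam (lr 0.001), batch 16, at most 1000
epochs, early stopping on the validation loss of an internal stratified
80/20 split of the training portion, patience 15, best weights restored.
Hidden weights use He-scaled normal initialization; the softmax output
layer uses a gain-1 (Xavier-style) normal so initial logits stay small —
with He scaling there the initial loss is far above ln(n_classes) and
early stopping can fire before learning starts. Loss is categorical
cross-entropy. Per-epoch train and validation loss/accuracy are recorded
for learning curves. With 36 classes and 287 inputs the default
architecture has 4,897,316 trainable parameters (the count for any
configuration is computable in closed form and verified in tests); no
kernel/pool combination of the literal block description reproduces a
six-figure count in the quarter-million range with a flatten-plus-dense
head, so the count is recorded, not targeted.

**Classical baselines** (scikit-learn): SVM (RBF, C=1, gamma="scale"),
random forest (100 trees, Gini, unlimited depth), gradient boosting
(100 estimators, lr 0.1), k-NN (k=5, Euclidean), decision tree (Gini,
unlimited depth), Gaussian naive Bayes, logistic regression (L2, tol 1e-4,
lbfgs). The classical path is bit-reproducible under a fixed seed; the CNN
is reproducible under a fixed seed on a fixed numpy backend.

## Verification metrics

Identification is closed-set, but the evaluation also reports biometric
verification error rates. Every (test sample, claimed identity) pair is
treated as an authentication attempt: the softmax score of the claimed
class joins the genuine pool when the claim is true, otherwise the impostor
pool (n samples × k classes gives n genuine and n·(k−1) impostor claims).
FAR(t) is the fraction of impostor scores ≥ t (ties accept), FRR(t) the
fraction of genuine scores < t; both are monotone in t by construction. The
EER is located by sweeping all observed scores as thresholds and linearly
interpolating between the two thresholds where FAR − FRR changes sign; the
implementation is tested against an exhaustive-enumeration oracle on
randomized small score sets. Precision/recall/F1 are macro-averaged
(classes are balanced by design).

## Synthetic data generator

The generator emulates a multi-subject, single-session oddball (P300) or
semantic (N400) experiment:

- **ERP component.** Per subject: a Gaussian bump (sd 50 ms) with amplitude
  ~N(15, 4²) µV (floored at a quarter of the mean), peak latency uniform in
  250–500 ms (P300, positive) or 300–500 ms (N400, negative), zero before
  stimulus onset, and a spatial weight vector that jitters (uniform
  0.6–1.4 per channel) around a fixed posterior-dominant topography. Trials
  jitter the latency (sd 20 ms) and amplitude (CV 0.1).
- **Background.** Per channel: 1/f-power noise of 10 µV RMS plus 2 µV white
  noise. The 1/f profile rolls off below 0.5 Hz: infra-slow drift is
  electrode artifact rather than neural background, and a diverging low end
  would give every recording a persistent session fingerprint that
  identifies the *recording* rather than the subject (verified empirically:
  without the roll-off, classifiers beat chance even with all subject
  traits disabled).
- **Subject spectral signature.** Three sinusoidal rhythms with fixed
  topographies and subject-specific amplitudes: occipital alpha at 10 Hz
  (1–12 µV — individual alpha power genuinely spans near-absent to
  dominant), fronto-central mu/beta at 16 Hz (0.5–4.5 µV) and
  frontal-midline theta at 6 Hz (0.5–5 µV); a subject-specific 1/f exponent
  (1 ± 0.25); and an anatomy/electrode gain field — a global amplitude gain
  (0.7–1.4) times per-channel gains (±25 %) — multiplying the whole signal.
  These are the stable individual traits EEG biometrics exploits.
- **Separability dial.** A single scalar multiplies *every*
  subject-distinguishing deviation from the population mean — the ERP
  template, rhythm amplitudes *and* their per-channel weight jitter, the
  spectral exponent, and the gain field. At separability 0 all subjects are
  statistically identical (verified: classifiers sit at chance); 1 is the
  default study condition; larger values make identification easier.
  Accuracy is monotone in this dial.
- **Timing.** Stimuli are spaced uniformly 1.5–2.5 s apart (epochs never
  overlap), with a 2 s lead-in; recordings are padded to at least 36 s so
  they always exceed the 33 s filter kernel.

Everything is drawn from one `numpy` Generator seeded from the config, so
identical (config, seed) pairs reproduce recordings bit for bit, and a
subject's traits can be replayed independently of the full dataset.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: volume-conduction correlations between
channels (noise is channel-independent), non-stationary rhythm amplitude
modulation, eye-blink/EMG artifacts, cross-session variability (electrode
placement shifts), and realistic ERP component mixtures (one component, not
a P1/N1/P3 complex). Recovery results on synthetic data bound what the
pipeline can do when its assumptions hold; they do not predict real-data
accuracy.

## Recovery experiment and problem sizes

`recovery_experiment` runs the full chain — generate, filter, re-reference,
epoch, group-average features, stratified 80/20 split, train, evaluate — at
the default condition of 10 subjects × 40 trials. Feature samples use
groups of 4 epochs (10 samples per subject, 100 total), keeping at least
ten samples per subject from 40 trials; the group of 10 is used in the
full-scale profile. These sizes keep a complete recovery run in seconds for
classical models and a few minutes for the CNN, while leaving the test
split (20 samples) large enough for the error rates reported. The
chance-level check uses an exact binomial test at α = 0.01 against
p = 1/n_subjects.

## Numerical conventions and degenerate inputs

- Filter response grids must resolve the narrowest transition band
  (≥ 8 points across it) or measurement is refused.
- Epoch endpoints land on the sample nearest tmin/tmax; `times` reports the
  realized sample times.
- Welch grids are cropped to [0.5, 45] Hz before band summaries; an empty
  band (no bins) is an error, not a zero.
- Score ties at a verification threshold count as accepts (≥ convention).
- A feature standard deviation of exactly zero standardizes to zero (the
  constant feature is passed through, not divided by zero).
- EDF export quantizes to 16 bits over each channel's physical range;
  round-trips are exact only to that step.

## Known limitations

- The CNN trains on CPU in numpy; it is sized for hundreds of samples, not
  for large-scale experiments.
- At the default recovery condition the CNN sees only 80 training samples
  (64 after the internal validation split) against millions of parameters;
  despite dropout and early stopping its test error rates vary noticeably
  with the generator seed, whereas the random-forest baseline is stable.
  This mirrors the general small-sample disadvantage of deep models and is
  why the forest is the default pipeline classifier.
- FAR/FRR/EER are computed from pooled identity claims of a closed-set
  classifier; open-set verification with enrollment/probe protocols is out
  of scope.
- The EDF reader supports 16-bit continuous EDF via `mne`; EDF+ annotations
  are ignored.
- Per-task analyses of the real study dataset are supported as a workflow
  (read EDF/CSV, supply an event table) but ship without that data.
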