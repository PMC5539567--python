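# Methods

## Problem setting

The package implements a hybrid movement-prediction system for
rehabilitation-style brain–computer interfaces.  Three physiological
signatures of an upcoming or ongoing self-paced arm movement are detected in
parallel from multichannel recordings sampled at 5 kHz:

* **EMG onsets** — muscle activity, detected without any trained model by a
  running-variance filter and an adaptive threshold;
* **MRCPs** (movement-related cortical potentials) — a slow cortical
  negativity that develops over the last ~1–2 s before movement onset,
  detected from heavily decimated EEG with a supervised spatial filter and a
  linear classifier;
* **P300 responses** — stimulus-locked potentials following rare task-relevant
  (Target) stimuli in an oddball stream; a detected P300 acts as a *switch*
  indicating that a movement is expected within the next seconds, not as a
  movement detector itself.

Each branch emits one binary decision per 40 ms, indexed by segment end
time.  Decisions are fused into eight system outputs (single modalities,
AND/OR combinations, optionally gated by the P300 switch) and scored with a
segment-based evaluation scheme built around each movement onset.

## Synthetic sessions

No public recordings exist for this paradigm, so the package generates its
own sessions with the paradigm's timing statistics: stimuli with an
inter-stimulus interval of 1 s ± 100 ms (uniform), a configurable Target
fraction (default 0.2, a typical oddball rarity, chosen once), an
imposed wait of ≥ 2 s between a Target and the movement it licenses (plus
0–0.5 s of uniform jitter, making the wait unpredictable), a 1 s movement,
and a run that ends after 40 correct movements.

Templates are stylized morphologies, not fits to any subject:

* MRCP: quadratic ramp to −8 µV over 1.5 s, ending at the onset marker, with
  a 0.5 s linear return to baseline afterwards; loaded on the "central" half
  of the EEG channels with weights 1 → 0.6.
* P300: +10 µV Gaussian bump (σ = 120 ms) peaking 350 ms after each Target;
  loaded on the "parietal" half of the channels.
* EMG burst: amplitude-modulated white noise (σ = 40 µV) lasting 1 s on the
  four right-arm channels.  The burst begins 150 ms **before** the
  movement-onset marker: the marker corresponds to a mechanically registered
  event (hand leaving a button board), which muscle activity precedes by an
  electromechanical delay.  This lead is what makes EMG-based *prediction*
  of the marker possible at all, and matches the positive EMG prediction
  times the method is known to produce.

EEG background noise is Gaussian with a 1/f amplitude spectrum (β = 1); EMG
baseline noise is white.  Default noise σ = 5 µV.  Everything is a pure
function of (configuration, seed).

What the generator does **not** emulate: volume conduction/head-model
mixing (topographies are fixed loading vectors), ocular and line-noise
artifacts, nonstationary rhythms (ERD/ERS), subject-to-subject morphology
variation, and missed or erroneous movements.  Passing tests on these
sessions therefore demonstrate correctness of the processing chain and its
contracts, not clinical-grade performance on real EEG.

## EMG branch

Running variance over a causal window of W_VF ms (the standard unbiased
form v = (Σx² − (Σx)²/W)/(W−1); the window lengths come from the grid
{10, 20, 50, 100, 200} ms).  The unbiased sample variance is the form used:
it is non-negative by construction and matches a streaming one-pass
computation of the same moments.  The adaptive
threshold T(t) = μ(t) + p·σ(t) uses trailing mean and *sample* standard
deviation of the variance-filtered series over W_AT ∈
{100, …, 5000} ms, with sensitivity p ∈ {3, …, 12}.  A segment is positive
when the variance sample at its end exceeds the threshold on ≥ n_COT
channels.  Predictions are forced to 0 until both windows are filled.
The parameter triple and channel setup are chosen by exhaustive grid search
maximizing the segment-based balanced accuracy on the training runs; ties
break toward smaller W_VF, then W_AT, then p, then fewer channels, for
reproducibility.

Implementation note: the rolling statistics are computed with pandas'
numerically stable rolling moments; the running variance is additionally
made shift-invariant by removing the global mean first, so it matches a
per-window two-pass computation to ~1e−12 relative error.

## EEG preprocessing

A first-order DC-blocking IIR (y[t] = x[t] − x[t−1] + a·y[t−1], a = 0.999
at 5 kHz — deliberately minimal: cheap, streaming, and flat across the
MRCP band) removes drift, then two FIR decimation stages take 5 kHz → 125 Hz → 25 Hz.
Both stages are windowed-sinc (Hamming) designs normalized to exact unit DC
gain: stage 1 has 351 taps with a 10 Hz flat-band edge, stage 2 has 63 taps
with a 2.5 Hz flat-band edge (−6 dB near 5.8 Hz), attenuating everything
above ~4 Hz by design intent and reaching ≥ 40 dB well before each stage's
output Nyquist.  The tap counts were chosen so the Hamming transition band
(~3.3·fs/N) fits between the flat band and the output Nyquist; a 255-tap
stage-1 filter with a 50 Hz edge cannot satisfy that constraint, which is
why the slightly longer filter and lower edge are the defaults.

Filters are causal and carry per-channel state, so streaming in arbitrary
block sizes equals single-shot processing (to ~1e−16; scipy's filter kernel
is not bit-reproducible across block splits).  Group delay (~35 ms stage 1,
~248 ms stage 2) is deliberately **not** compensated: the system is online,
all streams are indexed by segment end time, and the delay is uniform
across the EEG branches, so it shifts both training and test features
identically.

## Segmentation and labels

* EMG: contiguous 40 ms windows (200 × c samples at 5 kHz).
* MRCP: sliding 200 ms windows of the 25 Hz stream (5 samples, hop 1
  sample = 40 ms; adjacent windows overlap by 160 ms).
* P300: 25-sample (1000 ms) windows starting at the first 25 Hz sample
  at/after each Standard/Target marker (causal alignment; markers too close
  to the stream end are skipped).

Training labels around each onset (segment end times, endpoints inclusive
on the 40 ms grid): [−120, +120] ms → movement; inside the movement and up
to 200 ms after its end → excluded; everything else → rest.  The ±120 ms
window is interpreted with respect to segment *ends*, consistent with every
other statement of the scheme.

## Spatial filtering (xDAWN) and features

The supervised filter maximizes w'Sₑw / w'Sₓw, where Sₑ is the covariance
of the target-class average response and Sₓ the covariance of all training
epochs; solved as a symmetric-definite generalized eigenproblem with a
relative ridge (1e−9·tr(Sₓ)/c) on Sₓ, batch-fitted once on the training
runs (the train-2/test-1 protocol makes incremental updating unnecessary).
Component signs are fixed by making the largest-magnitude loading positive.
Four components are retained for both branches; for the MRCP branch this is
what makes the 20-dimensional feature vector (5 samples × 4 components) —
a single retained component could only yield 5 features.

P300 features: each filtered 25 × 4 window is cut into 400 ms subsegments
shifted by 120 ms (6 per component); the least-squares slope of each
subsegment (time axis in seconds, slopes in µV/s) gives a 24-dimensional
vector, concatenated channel-major.  Channel-major vs time-major ordering
is irrelevant to a linear classifier and is fixed here by convention.
MRCP features: channel-major flattening of the 5 × 4 window (20 values).
Both are standardized element-wise with the training mean and sample
standard deviation; a constant feature (σ = 0 up to rounding of the mean)
standardizes to 0 with a warning.

## Classification (PA-1)

Passive-Aggressive type I with hinge loss: τ = min(C, ℓ/‖x‖²),
w ← w + τyx; bias via a constant augmented feature.  Training makes 3
passes over the seeded-shuffled stream — enough for the online solution to
stabilize without adding convergence machinery.  C is
selected from {10⁰, …, 10⁻⁶} by stratified 3-fold inner cross-validation
maximizing balanced accuracy (ties → smallest C).  Class imbalance
(~1:20–1:110 movement:rest) is compensated by a decision-threshold
correction: the offset maximizing training balanced accuracy over all
midpoints of consecutive sorted unique scores (plus 0; ties → smallest
|offset|).  Prediction is 1 iff score − offset > 0 (strict).

## Fusion and evaluation

A P300 detected for a stimulus at time t̂ opens a gate over
[t̂ + 1 s, t̂ + 5 s] (endpoints inclusive on the grid; overlapping gates are
unioned).  The gate is anchored at the stimulus time: with the paradigm's
≥ 2 s stimulus-to-movement wait this covers the entire pre-movement
evaluation window.  The eight outputs are pointwise Boolean combinations
(see the fusion module docstring).

Evaluation assigns dynamic truth labels per onset: −80/−40 ms segments are
obligatory movement segments; in [−1 s, −120 ms] a backward-extending run
of movement *predictions* anchored at −120 ms, tolerating at most one
interruption, is labeled movement (the scan stops at the second gap).  The
tolerated gap itself keeps the rest label — the scheme labels segments that
belong to a sequence of movement-class predictions, which a rest prediction
is not; this is the one genuinely open reading in the scheme and is fixed
here deliberately (the alternative would count the gap as a false
negative).  Segments from onset to movement end + 200 ms are excluded from
the counts.  Onsets are snapped to the nearest grid point (generator jitter
≤ 20 ms).

Balanced accuracy, FNR, FPR and precision follow the usual confusion-matrix
definitions; an empty class raises rather than returning a silent default.
The prediction time of a movement is the earliest predicted segment end in
its movement-labeled run, in time before onset; movements without any such
prediction count toward FNR but are excluded from the time statistics (no
imputation is defined for them).  Quartiles are nearest-rank; Qt75 is the
time exceeded by 75 % of movements, so Qt75 ≤ Qt50 ≤ Qt25.

## Fixed-point emulation

Q(m, n) values live on a 2⁻ⁿ grid with saturation at ±(2^m − 2⁻ⁿ)
(wrap-around available), rounding nearest (half-up) or truncate.
Quantization is applied at *stage granularity*: raw inputs, all static
coefficients (FIR taps, spatial-filter weights, classifier weights,
offsets) and the output of every processing stage pass through the grid;
individual multiply-accumulate steps inside a stage run in doubles.
Cycle-accurate accumulator emulation is out of scope — the question the
mode answers is whether finite-precision storage of signals and models
changes the *decisions*, and the defaults (Q(8, 24) for signals and
coefficients, Q(16, 32) for wide intermediates such as running variances,
thresholds and scores) leave headroom for every quantity the chain
produces on µV-scale data.  Training always runs in floating point;
only inference is quantized, mirroring a software-trained /
hardware-deployed split.  A saturation monitor warns when > 1 % of
quantized samples clip.

On the benchmark session the quantized and float pipelines agree on 100 %
of decisions; agreement degrades monotonically as n shrinks (checked at
n ∈ {8, 16, 24}).

## Problem sizes and determinism

The package's own study conditions are three synthetic runs of 40 movements
each (~300–380 s per run at 5 kHz), 8 EEG + 4 EMG channels, default
template amplitudes and noise; the acceptance script and the acceptance
tests train on two runs and evaluate the third at exactly these sizes.
Unit and integration tests use shorter runs (6–10 movements) and reduced
EMG grids where the full search adds nothing.  Every source of randomness
flows from explicit integer seeds (per-run seeds are spawned from a root
SeedSequence); rerunning any entry point with the same inputs reproduces
identical reports.

## Known limitations

* Topographies are fixed vectors; no forward-model mixing, so spatial
  filtering faces an easier problem than on real EEG.
* The EMG branch's adaptive threshold is self-masking at very low baseline
  noise (the burst inflates its own threshold window); the grid search
  resolves this by preferring long threshold windows, but single fixed
  parameter choices can miss obligatory segments in the zero-noise limit.
* The P300 branch sees MRCP leakage when a stimulus falls near a movement;
  with the default disjoint topographies this is separable, with realistic
  mixing it would not be fully.
* BrainVision support covers the subset the package writes
  (IEEE_FLOAT_32, multiplexed, µV); other binary formats are rejected with
  a descriptive error rather than mis-read.
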