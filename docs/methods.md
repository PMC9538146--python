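# Methods

`lagfuse` implements a pipeline for decoding lower-limb movement
intention from simultaneously recorded EEG (9 channels) and surface EMG
(4 channels) at 1,024 Hz.  Its central idea is that cortical activity
leads muscular activity by a *response-time difference* ΔT, and that
multimodal fusion improves when the two signal streams are re-aligned
by that lag before being fed to a classifier.  This note documents the
models, the estimation procedures, the synthetic data used to validate
them, and the numerical choices made where the design was open.

## The response-time difference ΔT

Taking the cortical surface potential as the time reference, the delay
between the scalp EEG and the skin-recorded sEMG of the same motor act
decomposes as

    ΔT = −t1 + t2 + t3 + t4

where t1 (cortex→scalp volume conduction) and t4 (muscle→skin volume
conduction) are microsecond-scale and treated as zero, t2 = D_n / v is
the motor-nerve conduction time, and t3 is the neuromuscular-junction
conversion delay.  With a scalp-to-tibialis-anterior path of
D_n = 1.4–1.5 m, a conduction velocity v = 60 m/s and
t3 = 0.5–1.0 ms, the bound is t2 ≈ 23–25 ms and ΔT ≈ 24–26 ms
(`coupling.physio_delta_t`).  These parameter defaults are adult-human
values; all are exposed in `PhysioParams` with units of m, m/s and ms.

## Data-driven lag estimation: symbolic transfer entropy

The empirical estimate quantizes both signals with a uniform amplitude
partition of [min, max] into Ps + 1 bins of width
δ = (max − min)/(Ps + 1), Ps = 30 by default.  Symbol labels are
categorical; any bijective relabeling leaves every entropy unchanged
(tested).  The directed coupling at time step u is the plug-in transfer
entropy

    TE_{x→y}(u) = Σ p(y_{i+u}, y_i, x_i)
                  · log2 [ p(y_{i+u}, y_i, x_i) p(y_i)
                         / (p(y_{i+u}, y_i) p(y_i, x_i)) ]

with all probabilities estimated as relative frequencies over the same
triplet sample, which makes the estimate a conditional mutual
information I(y_{i+u}; x_i | y_i) and hence non-negative up to
rounding.  Embedding order is one in both past terms; the logarithm is
base 2 (bits).  Profiles are computed per trial for u = 1..u_max
(default 50) and averaged element-wise across trials — no triplet ever
straddles a trial boundary.  The lag estimate is the argmax of the
averaged profile, converted to ms via the sampling rate (at 1,024 Hz
one sample ≈ 0.98 ms).

With a 31-letter alphabet and 4-s trials the triplet space
(31³ ≈ 3·10⁴ states) is undersampled and the plug-in estimator carries
a positive bias.  The bias is nearly flat in u, so the *location* of
the profile peak — the only quantity used downstream — is robust; the
shuffle-null test in the suite confirms that independent signals stay
within the bias floor at every u.

## Preprocessing

* Butterworth band-pass, order 4, applied forward–backward
  (zero phase): 0.5–64 Hz for EEG, 20–200 Hz for sEMG, each followed by
  a second-order 50 Hz notch (quality factor 30).  Zero-phase filtering
  is essential here: ΔT is meaningful at the millisecond scale and a
  causal filter would add a modality-dependent group delay.  Channel
  means are subtracted before filtering (baseline calibration).
* Movement onset is detected on an sEMG channel as the first index
  where a 50 ms moving RMS exceeds the baseline mean + 3 SD (baseline =
  first second of rest) for at least 25 ms.
* Epochs span −2..+2 s around onset (4,096 samples at 1,024 Hz,
  onset at index 2,048); onsets without full margins are skipped.
* Sliding windows of length L start at multiples of the hop
  (default 0.5 L).  L is interpreted in samples at the native rate; at
  1,024 Hz the samples-vs-milliseconds ambiguity is below 2.5%.

Min-max normalization maps a sequence to [−1, 1] exactly
(2(x − min)/(max − min) − 1); constant input is a degenerate-input
error.  For dataset construction, normalization is applied **per
modality, per epoch**: the 9-channel EEG block and the 4-channel sEMG
block of each epoch are each scaled as wholes.  Normalizing each
channel (or each window) separately would rescale silent channels to
full range and erase the relative-amplitude pattern that carries the
class information; the per-modality scope preserves it while still
bounding all values in [−1, 1].  The standalone alignment helpers also
offer the stricter per-window scope via a flag.

## Lag-compensated fusion

With lag = round(ΔT · fs / 1000) samples (round half up; 35 ms →
36 samples at 1,024 Hz):

* offline, EEG time t is the benchmark: EEG rows from [t, t+L), sEMG
  rows from [t+lag, t+lag+L);
* online, the freshest sEMG sample is the benchmark because future
  sEMG is not yet buffered: sEMG takes the last L samples, EEG the L
  samples ending lag before the buffer end.

The two conventions express the same shift and agree exactly on
identical absolute spans (tested).  Windows whose compensated span
would leave the epoch are dropped, not padded — padding would inject
class-correlated artifacts; drops are counted and logged.
`build_dataset` emits either the aligned signal matrices
("data fusion", shape (9+4) × L) or cascaded feature vectors
("feature fusion") with the epoch's label.

## Features

EEG channels are decimated to 128 Hz (factor 8; the 0.5–64 Hz
band-pass is the anti-alias filter) and decomposed with a full
wavelet-packet tree, Daubechies-4, 5 layers, periodization boundary
mode (orthogonal: leaf energies sum to signal energy, relative error
< 1e−8).  Frequency-ordered leaves tile 0–64 Hz in 2 Hz strips and are
pooled by leaf center frequency into delta (0–4), theta (4–8), alpha
(8–12) and beta (12–32 Hz); the nominal 13–30 Hz beta band cannot be
hit on a dyadic grid, so the 12–32 Hz cover is used.  Each band
contributes its coefficient variance and its relative energy: 8 values
per channel.  On windows too short for 5 layers the layer count adapts
downward (flagged option), degrading band resolution gracefully; at
L = 50 (≈ 6 decimated samples) the named bands are no longer
resolvable, which is an inherent limit of feature fusion at short
windows.

Each sEMG channel contributes variance (1/(N−1) convention),
slope-sign-change count (threshold ε = 0.01, assuming inputs
normalized to [−1, 1]), strict zero-crossing count, RMS, mean power
frequency (Welch periodogram, power-weighted mean over 0–200 Hz), and
the first 4 Fourier cepstrum coefficients (DCT-II of the natural-log
magnitude spectrum, 1e−12 floor inside the log): 9 values per channel.
The fusion vector cascades EEG blocks then sEMG blocks in channel
order: 9·8 + 4·9 = 108 values.

## The CNN-LSTM decoder

The decoder is four convolution → ELU → average-pooling blocks along
time, a fold into a (time, feature) sequence, two LSTM + dropout
blocks, and a dense softmax head.  The LSTM follows the standard gate
equations (logistic gates i, f, o; tanh candidate;
c_t = f⊗c_{t−1} + i⊗c̃; h_t = o⊗tanh c_t); `model.lstm_step` is a
standalone reference implementation against which the training
backend's cell is verified to 1e−5.

The network and its training loop (Adam, cross-entropy) are
implemented in NumPy (`lagfuse.nn`) with reverse-mode gradients
verified against finite differences in the suite.  Training is
deterministic given the seed.  Only the block structure is fixed;
kernel widths (5), channel counts (16, 32, 32, 64), pooling width (2),
hidden sizes (64, 64), dropout (0.5), learning rate (3e−3), batch size
(64) and the 16-epoch budget are free hyperparameters sized for
single-CPU training at desk scale, exposed in `ModelSpec`.  Feature
vectors are decoded by the same architecture as 1 × 108 sequences;
inputs are standardized on training statistics (per feature, or per
channel for signal windows).

Evaluation uses stratified k-fold cross-validation (k = 5).  When
window-to-epoch group labels are available the split is group-aware:
all windows of one epoch stay in one fold, so overlapping windows of a
trial can never leak between training and test.  A fold missing a
class raises a stratification error rather than silently reporting an
optimistic score.

## The synthetic-data generator

No recordings ship with the package; the generator emulates the
coupling structure the method targets, with known ground truth:

* a latent cortical driver: band-limited (0.5–64 Hz) Gaussian noise;
* EEG channels: the driver plus independent band-limited noise;
* sEMG channels: independent 20–200 Hz Gaussian carriers whose
  amplitude envelope is the rectified, delayed driver
  max(1 + g·driver(t − lag), 0), modulation depth g = 1;
* 50 Hz line interference on all channels; coupling SNR stated in dB
  on the envelope-modulation component versus additive noise power
  (default 5 dB, the condition under which lag recovery is validated).

Movement trials add class structure: each of the 8 classes owns a
distinct binary activation mask per modality (masks pairwise distinct
within each modality) and a class-specific envelope frequency
(2 + 0.75·c Hz).  The sEMG activation starts at the trial midpoint —
exactly `lag` samples after the EEG drive changes — and the activation
envelope keeps a tonic floor of 0.35 with the rhythmic class-frequency
modulation on top, as sustained movement does.  EEG channels
additionally carry a class-masked preparatory component ramping up
over the 1.5 s before the drive onset, mirroring the readiness
activity that precedes muscular onset in real recordings; without it,
pre-onset windows would be unclassifiable noise, which real data are
not.

What the generator does **not** emulate: volume-conduction mixing
between channels, motor-unit action potentials, non-stationary
impedance drift, eye/cardiac artifacts, inter-subject variability, and
session-to-session covariate shift.  Passing tests therefore
demonstrate that the estimators and the decoder recover the structure
they are designed for — not that the published accuracy levels
transfer to any particular recording.

## Numerical choices and degenerate inputs

* Constant sequences cannot be symbolized or min-max scaled
  (degenerate-input errors); silent channel rows inside an alignment
  window are set to 0 rather than raising.
* 0·log 0 terms in the TE sum are dropped by construction (only
  observed states enter).
* ΔT is stored in ms and converted with round-half-up; the simulator's
  35-sample delay equals 34.18 ms, and the working compensation value
  of 35 ms equals 36 samples at 1,024 Hz.
* The TE averaged profile requires identical u grids and sampling
  rates; mismatches raise.
* Filter tests measure steady-state gain: the 0.5 Hz high-pass edge
  rings for seconds, so tone fixtures are long and edges trimmed.

## Problem sizes used in the validation suite

The suite validates lag recovery on 20 four-second trials, end-to-end
decoding on the 8-class dataset with 10 trials per class at L = 200
(3,120 windows, 5-fold grouped CV, 16 training epochs; the
permuted-label null reuses the pipeline at a 4-epoch budget, which is
ample for a model that has nothing to learn), and the
compensation-direction comparison on 10 replicates of 5 trials per
class at L = 50 with a reduced network and 8-epoch budget.  These
sizes are the package's desk-scale defaults; they were chosen so the
whole suite runs on one CPU in well under half an hour while keeping
every comparison far from its decision boundary.

## Known limitations

* The plug-in TE estimator is biased at Ps = 30 on 4-s trials; only
  the profile's argmax is interpreted, never its absolute value.
* Feature fusion at L = 50 is structurally information-poor (see the
  wavelet-band resolution limit above); the package reproduces the
  qualitative ordering (data fusion ≥ feature fusion at short windows)
  but no quantitative claim is made.
* The compensation benefit on synthetic data is small (a few percent,
  matching the scale of the effect the method targets) and is asserted
  only directionally across replicates.
* The decoder's hyperparameters are sized for desk-scale validation,
  not tuned for maximum accuracy on any real dataset.
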