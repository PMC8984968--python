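# Methods

`eegcursor` decodes noninvasive EEG into decoupled horizontal/vertical
cursor velocities with a spectral–temporal LSTM (stLSTM) trained under a
velocity-constrained loss, and evaluates the resulting 2D trajectories.
This note documents the model, the synthetic data it is tested on, the
numerical choices, and the limits of what the tests show.

## Signal model and features

A trial is `X ∈ R^{n×m}`: `n` samples of `m` EEG channels at rate `f_o`
(default 100 Hz after preprocessing), with one motor-imagery class per
trial — left hand (L), right hand (R), both hands (U), relax (D) — mapped
to left/right/up/down cursor motion.

**Preprocessing** picks the 10-channel sensorimotor montage
(C1 C2 C3 C4 C5 C6 FC3 FC4 CP3 CP4), optionally notches mains
interference, down-samples to 100 Hz (polyphase, anti-aliased) and
band-passes 0.1–30 Hz with a zero-phase 4th-order Butterworth filter.
Zero-phase filtering matters because the temporal features are
latency-sensitive; the filter's reflect-padding is extended to the 0.1 Hz
corner's settling scale so its transient does not contaminate trial edges.
The band-pass runs after decimation (at the target rate); the polyphase
stage supplies its own anti-alias filtering.

**Spectral features** (`X_S`). Each 400 ms window (40 samples), advanced
by 10 ms (1 sample), of each channel is fit with a 16th-order
autoregressive model by the Burg recursion. The PSD

    P(f) = σ² / |1 + Σ_{k=1}^{p} a_k e^{−i·2πfk/f_s}|²

is evaluated on the mu-band grid 8.0–13.0 Hz in Δf = 0.5 Hz steps
(11 points; the grid is a declared convention) and summed, `Σ P(f)·Δf`,
into one mu-band power per channel per window. A trial yields
`X_S ∈ R^{(n−39)×m}`. Notes:

* The PSD is the literal all-pole expression above, with no sampling-rate
  factor; band powers are used z-scored downstream, so only relative
  scale matters. In normalized-frequency units (f_s = 1) the doubled
  one-sided integral of `P` recovers the process variance, which is the
  Parseval check the tests use.
* Coefficients are stored in the `1 + Σ a_k z^{−k}` convention (the Burg
  recursion's native output; equal to minus the "x(t) = Σ φ x(t−k)"
  convention) and validated against the PSD-peak and
  `statsmodels.regression.linear_model.burg` oracles.
* A 16th-order fit on 40 samples is noisy; that is the operating point of
  the decoding pipeline, and the order/window are configurable.
* No taper is applied before Burg (parametric estimators need none).
* Flat (zero-variance) windows inside a trial give 0 power with a warning
  instead of aborting; `burg_ar` on such a window directly is an error.

**Temporal features** (`X_T`). Each channel is convolved with the first
derivative of a Gaussian, scale `l = 30` samples (300 ms):

    X_T[t, j] = (1/l) Σ_{i=0}^{l−1} k(l−i) · X[t−i, j]

The kernel is centred mid-window with σ = l/6 (so ±3σ spans the window)
and unit peak absolute value; all three are configurable choices — the
shape is what matters: an antisymmetric, zero-sum transient detector that
responds to the positive error-locked deflection (~300 ms post-error,
P300-like) and rejects constant or slowly varying activity. No padding:
rows start at the first full window, giving `X_T ∈ R^{(n−l+1)×m}`.

**Fusion and segmentation.** `X_T` has 10 more leading rows than `X_S` at
the defaults; they are dropped (right-alignment), the matrices are
concatenated column-wise (spectral first) into `X ∈ R^{(n−39)×2m}`, and
`X` is cut into consecutive non-overlapping `T = 30`-row segments
(trailing remainder discarded), i.e. `N = ⌊(n−39)/30⌋` samples per trial.
Each sample's velocity label is the mean ground-truth velocity over the
raw samples its rows cover, then zeroed on the non-class axis: up/down
trials have horizontal label 0, left/right trials vertical label 0.

Splits are made at **trial** granularity (segments of one trial never
straddle TRAIN and TEST), class-balanced, default ratio 0.7; TESTUD and
TESTLR are the up/down and left/right views of TEST. Features are
z-scored per feature column with statistics frozen on TRAIN (band powers
and wavelet outputs differ by orders of magnitude); the parameters are
stored with the model.

## Decoder and loss

Two parallel branches — one per screen axis — each consist of one LSTM
layer (100 hidden units) reading the `T×E` sample and a linear head on the
final hidden state; outputs are concatenated as (horizontal, vertical).
The "two parallel single-layer branches" reading makes "predict the
velocity in the corresponding direction separately" literal; a stacked
two-layer variant is available via `ModelConfig.n_layers=2`.

The training loss is `L = L_MSE + λ·L_VC` with

    L_MSE = mean_i ‖y_i − ŷ_i‖²
    L_VC  = mean_i  { ‖ŷ_⊥‖² − ‖ŷ_∥‖²   (left/right samples)
                    { ‖ŷ_∥‖² − ‖ŷ_⊥‖²   (up/down samples)

(∥ horizontal, ⊥ vertical): speed along the imagined axis is rewarded,
speed along the orthogonal (non-imaginary) axis penalized. Each sample
contributes with its own class; batches mix classes. λ is selected from
the candidate grid {1e−4, 0.001…0.009 (step 0.001), 0.01…0.1 (step 0.01)}
by training one freshly initialized model per candidate and keeping the
lowest held-out MSE (ties to the smallest λ).

**Optimization.** Full-batch adam ("batch gradient descent": one update
per epoch over the whole training set), implemented in numpy with exact
backpropagation through time (verified against central finite differences
to 1e−4 in the tests). Defaults, all configurable: 200 epochs, learning
rate 0.01. Two stabilizers address the regime of very few (one per
epoch) updates:

* *Polyak tail averaging* (`tail_average = 0.25`): constant-rate
  full-batch adam ends in a loss oscillation; the returned weights are
  the average of the final 25% of epochs, which lands at the
  oscillation's centre instead of an arbitrary phase. A cosine
  learning-rate decay is available (`lr_schedule="cosine"`) but
  undertrains at this epoch budget.
* *VC warm-up* (`lambda_warmup`, default 0 = off): optionally hold the
  VC weight at 0 for an initial fraction of training. Off by default on
  empirical grounds: the VC term earns its keep while the fit is forming
  (it shapes what the branches learn); applied only late in training,
  its imagined-axis amplification leaks into the orthogonal axis and
  the suppression benefit largely disappears.

Training is float32 (2× throughput; the gradient checks run in float64)
and bit-reproducible given the seeds.

`L_VC` is unbounded below, so a pathologically large λ drives the total
loss to −∞ while the MSE *grows* (the imagined-axis outputs diverge).
Training aborts with a labelled error after 20 consecutive epochs of
negative, strictly decreasing total loss with strictly increasing MSE.
A healthy well-fit model may also show a slightly negative total (small
residual MSE plus λ·VC < 0) — there the MSE keeps falling, and no abort
occurs. During λ selection a diverged candidate simply scores infinite
held-out MSE.

## Evaluation

Velocities are integrated by forward Euler (`dt` = one segment = 300 ms of
signal; pixel units inherit velocity units) into cursor trajectories.

* **RMSE** per axis. On TESTUD the horizontal axis is the non-imaginary
  one (ideal velocity 0); on TESTLR the vertical axis.
* **ACC**: the percentage of decoded samples whose dominant signed
  component matches the intended direction (right = +horizontal,
  up = +vertical); exact |h| = |v| ties count as incorrect. Directions are
  decoded per sample (one per segment), the decoder's native output rate.
* **MAR** = RMSE/(ε + ACC), ε = 1e−8, on the non-imaginary axis, with ACC
  entered on the **percent** scale — the scale that reproduces the one
  internally consistent published worked cell (5.62/61.40 → 0.09); the
  scale is recorded in every report.
* **Gate test**: a 400-pixel-wide gate perpendicular to the start→target
  line at its midpoint; a trial succeeds iff its trajectory's *first*
  crossing of the midpoint plane lies within the gate (crossing found by
  the sign change of the signed distance along the start→target axis,
  linearly interpolated); never reaching the plane is a failure. The
  trial's target is its ideal (label-integrated) endpoint.

## Synthetic data

The simulator generates the statistical structure the decoder relies on —
not biophysically realistic EEG:

* **Mu rhythm**: a 10 Hz sinusoid per channel with random phase and a
  slowly varying log-normal Ornstein–Uhlenbeck amplitude envelope
  (τ = 0.5 s, log-SD 0.25) — the simplest rhythm whose band power the AR
  extractor can track. Base amplitude 4 (microvolt-like units).
* **ERD/ERS**: left-hand imagery multiplies the mu amplitude of
  right-hemisphere channels (even digits: C2 C4 C6 FC4 CP4) by
  `1 − d·intensity` with ERD depth d = 0.5; right-hand imagery attenuates
  the left hemisphere; both-hands attenuates both; relax *boosts* both by
  `1 + d·intensity` (ERS). `d·intensity` is clipped at 1. ERD scaling
  with imagery intensity mirrors the finding that corticospinal
  excitability grows with imagery intensity; the relax class's spectral
  signature is an assumption (ERS) chosen so all four classes are
  separable in band power.
* **Error events**: a Poisson process (0.1 events/s) of observed
  trajectory errors; each adds a positive Gaussian pulse (peak 5 units,
  σ = 0.1 s) centred 300 ms after onset on FC3/FC4 and half that on
  C1/C2 — the error-locked deflection the temporal features detect.
* **Noise**: unit-SD 1/f pink noise plus white noise, mixed equally at
  total SD 1.5 per channel.
* **Ground truth velocity**: constant within a trial at
  `speed_gain·intensity` = 25 pixels/step along the class axis (screen
  convention L = −x, R = +x, U = +y, D = −y), zero on the other axis —
  the single-imagery-per-trial paradigm. 25 px/step makes a 10 s trial
  traverse ~800 px, so the 400 px gate is a meaningful criterion.
  Velocity units are arbitrary; "pixels per feature step" is a naming
  convention.

What passing tests on this data do **not** show: robustness to artifacts
(EMG, blinks), volume conduction, non-stationary rhythms, inter-subject
variability, or realistic error-potential morphology. They do show that
every pipeline stage implements its stated computation and that the VC
loss systematically suppresses non-imaginary velocity when the features
carry the class signal.

## Problem sizes used in the automated checks

The suppression experiment trains λ = 0 vs λ = 0.01 at five matched seeds
on 24 trials (6 per class, 10 s, 100 Hz; 768 segments, 7:3 trial-level
split) for 200 epochs per model — sizes chosen so the full experiment
runs in minutes on one CPU while leaving the architecture (100 hidden
units, T = 30, E = 20) and the simulator's default conditions untouched.
The per-seed success criterion is the mean of the two non-imaginary-axis
RMSEs (horizontal on TESTUD, vertical on TESTLR).

## Known limitations

* The numpy LSTM is single-threaded BLAS; it is sized for desk-scale
  experiments, not GPU-scale training.
* EDF files are read (via `mne`) but not written (no EDF writer among the
  runtime dependencies); CSV and the HDF5 container cover interchange.
* Full-batch training holds the whole activation history in memory
  (~6·T·B·H floats per branch); mini-batching is not implemented.
* The runaway-λ guard is a heuristic; λ values far outside the candidate
  grid may fail in other ways (e.g. non-finite losses, which also abort).
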