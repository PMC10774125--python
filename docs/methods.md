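# Methods

This note documents the models, numerical choices and limitations behind
`fusbmi`, in the order data flows through the pipeline.

## Synthetic fUS sessions

The generator produces sessions with the statistical structure the decoder
assumes, not an acoustic simulation (no beamforming, angle compounding or
speckle). A phantom consists of:

- **Anatomy**: a strictly positive background with smoothed curvilinear
  vessel-like structures, drawn deterministically from the phantom seed.
  Default grid 128×160 voxels = 12.8×16 mm at 0.1 mm spacing; tests and the
  acceptance script use 24×32 to 64×80 grids to keep whole-session
  simulations fast — a size choice only, signal and noise parameters are
  unchanged.
- **Tuned patches**: voxel sets with a shared preferred direction. The
  response to a cue at angle φ is the von Mises tuning
  `exp(κ·(cos(φ − φ_pref) − 1))` (1 at the preferred direction), scaled by
  the patch amplitude (default 0.10 = 10% peak fractional CBV increase,
  κ = 2). The default layout has an "LIP-like" patch preferring 0° and an
  "MIP-like" patch preferring 90°, so the pair jointly disambiguates all
  eight directions; single-patch layouts are used for searchlight ground
  truth.
- **Hemodynamics**: the cue+memory boxcar is convolved with a gamma-variate
  response function (shape 4, scale 0.5 s → 1.5 s time-to-peak, ~2.4 s
  FWHM, no undershoot), normalized to unit area so a sustained stimulus
  converges to the nominal amplitude. fUS hemodynamics are seconds-scale;
  the exact kernel is configurable because no canonical fUS HRF exists.
- **Noise**: multiplicative i.i.d. Gaussian voxel noise (default sd 0.02 —
  power-Doppler intensities are positive and their variance scales with
  signal), a global per-frame random-walk gain (sd 0.002) for slow drift,
  and a 0.3 Hz sinusoidal gain (amplitude 0.01) as an aliased-heartbeat
  pulsatility surrogate. These are placeholders with plausible magnitudes,
  exposed in `PhantomSpec`; real fUS noise spectra are not modeled.
- **Task timing**: fixation 5±1 s, cue 0.4 s, memory 5±1 s, hold 1.5±0.5 s,
  intertrial interval 8±2 s (uniform jitter), 2 Hz framing, 20° target
  eccentricity. Cue order is balanced block randomization (each direction
  appears ⌊n/k⌋ or ⌈n/k⌉ times).

What passing tests on this generator do **not** show: robustness to real
vascular noise statistics, behavioral nonstationarity, out-of-plane motion,
or within-session motion (none of which the pipeline corrects for).

Inter-session shifts are simulated by rigidly transforming anatomy and
patch masks together (bounds ±10°, ±20 px) and optionally scaling intensity;
the ground-truth transform is returned for oracle tests. The SVD clutter
filter is a self-contained demonstration at the Doppler-ensemble level: the
⌊0.3·N⌋ largest singular components of the (voxels × N) Casorati matrix are
zeroed and power is the slow-time mean squared residual.

## Preprocessing

Frames stream through a rolling 60-frame (30 s) FIFO buffer. Each frame is
voxel-wise z-scored against the buffer's mean and *sample* (ddof = 1)
standard deviation — zero-variance voxels map to 0 to avoid NaN
propagation — and then convolved with a unit-sum pillbox kernel of radius
2 px with zero-padded borders. Order (z-score, then filter) follows the
protocol's stated sequence. The default kernel weights boundary pixels by
their fractional disk coverage ("antialiased", the conventional pillbox); a
binary-lattice dialect (13 pixels at radius 2) is available and is the
convention used for searchlight ROI membership.

A trial's features are the last three frames with timestamp ≤ memory end,
each z-scored against the buffer state at its own arrival (streaming-causal
default; a `zscore_at="final"` flag re-scores all three against the
buffer at the last frame), flattened oldest-first. Predictions require a
warm buffer (≥ 2 frames); in practice the 8 s intertrial interval
guarantees this for every trial. The batch/window extraction path shares
the per-window kernel with the streaming class and is bit-identical to it —
the backbone of replay determinism.

## Decoders

**Two-class (cPCA+LDA).** Per class, principal axes are retained up to 95%
of that class's variance (smallest leading eigenvalue set whose cumulative
sum reaches the target); the per-class bases are pooled and QR-
orthonormalized (rank-deficient columns dropped at 1e-10); features are
projected onto the pooled subspace and a single LDA separates the classes.
The class-wise-PCA literature admits several variants; this subspace-union
realization is isolated behind the model interface so alternatives can be
swapped.

**Eight-direction multicoder.** Direction labels decompose into vertical
(up/mid/down) and horizontal (right/mid/left) components; two 3-class
pooled-PCA (95%) + LDA models are fit on the same feature vectors and their
independent argmaxes combine into a direction. (mid, mid) yields CENTER,
which is never a cue; CENTER predictions are scored as always-wrong with
180° angular error (a conservative choice; the scoring of such predictions
is otherwise unspecified).

**LDA.** Discriminants use the pooled within-class covariance shrunk toward
`trace(S)/p · I` with coefficient 0.1 (configurable, 0 disables):
early in online training the trial count is far below the feature dimension
even after reduction, and unregularized covariance estimates are singular.
The implementation is in-package (it matches scikit-learn's
`lsqr`+shrinkage solver, asserted in tests) because the searchlight's
~45,000 per-ROI fits make per-call overhead matter. Score ties break by
fixed class order (R before L; UP before MID before DOWN; RIGHT before MID
before LEFT) for determinism. PCA eigenproblems are solved on the n×n Gram
matrix since n ≪ D throughout.

Models serialize to HDF5 (bases, LDA weights, class labels, config) and
reload to identical predictions.

## Closed-loop protocol

The session starts in the training phase: the subject's overt movement
determines success, the decoder (once all classes have ≥ 2 samples) makes
invisible shadow predictions, and each successful trial's features join the
training set with a refit between trials. After 100 training successes
(configurable) the task switches — exactly once — to BMI mode, where
success = correct prediction AND maintained fixation. Training-set
policies: `realtime` appends only successful trials (the online rule);
`replay` appends every valid trial (the post hoc rule, which prevents class
starvation when predictions are poor). Pretraining imports all valid trials
of a rigidly-aligned previous session before trial 1 and fits immediately;
retraining then continues per policy, or is disabled with `freeze_model`
for the pretrain-only variant.

The cue of the in-progress trial is never visible to the decoder path until
the trial ends: the model receives a bare feature array, and an ordered
predict/reveal event log makes the contract testable (mirroring a
label-withholding server design without sockets).

Performance traces evaluate predictions from trial 20 onward by default
(`min_eval_trial`, set to 1 in pretraining comparisons where early trials
are the object of study). Retraining is synchronous between trials;
wall-clock latency is out of scope. Reward-size bookkeeping is metadata
only.

## Alignment

`RigidTransform2D` is a rotation about the image center plus a translation,
applied with bilinear interpolation and zero fill; rotation-about-center is
a convention (any pivot choice is absorbed by the translation). Scaling is
deliberately excluded — brain size does not change between sessions.
Registration minimizes the mean squared intensity difference over the
in-bounds region with a regular-step gradient descent (central-difference
gradients, step halving on direction reversal or cost increase, stop at
step < 0.005) over a 3-level pyramid (factors 4/2/1, Gaussian-smoothed
decimation). Both images are mean-normalized so inter-session gain changes
do not bias the optimum. Divergence (final MSE above initial) returns the
initial transform with a warning flag. Under the study conditions
(|θ| ≤ 5°, |t| ≤ 10 px, 2% noise) recovery is ≈ 0.01 px / 0.01° median
error; out-of-plane shifts are not modeled.

## Chance statistics

Accuracy envelopes come from the exact binomial law at chance 1/n_targets:
lower bound (largest k with CDF(k−1) ≤ α)/n, upper bound (smallest k with
CDF(k) ≥ 1−α)/n, α = 0.05 one-sided; "significant" means strictly beyond
the bound. The discrete upper bound is a sawtooth in n (it is *not*
pointwise non-increasing as a fraction; it does decrease whenever n
doubles, which is the property the tests assert). The angular-error
envelope is a permutation null: uniform random predictions against uniform
cues (by symmetry, conditioning on any cue sequence gives the same error
law), cumulative means over 10⁵ replicates, 5th/95th quantiles. The
enumerated null error distribution is P(0°) = P(180°) = 1/8,
P(45°) = P(90°) = P(135°) = 1/4, mean 90°. The "last nonsignificant trial"
is the largest evaluated index whose statistic is not beyond its envelope,
reported separately for accuracy and angular error.

## Searchlight

Centers are all voxels whose binary-lattice disk (radius 2 px = 200 µm, 13
voxels) fits in-grid. Each ROI's features (13 voxels × 3 frames) run
through the task-appropriate decoder under stratified 10-fold CV with a
fold assignment shared across centers, so maps are deterministic and
independent of scan order; the mean fold performance goes to the center
voxel. Significance is an artifact choice (the source protocol reports
q-value thresholds without stating the test): one-sided exact binomial
tail for accuracy maps, permutation tail for angular-error maps, and
Benjamini–Hochberg FDR over scored voxels. The overlay mask is the top
⌈10%⌉ of scored voxels, ties broken by p-value then scan order.

## Acceptance-check design choices

- Whole-session simulations use 180 trials at 24×32 voxels (closed-loop
  detection), 60-trial pairs (pretraining), and 40 trials at 64×80
  (searchlight); perturbations in the pretraining pairs are ±2°/±3 px,
  scaled to the reduced field of view.
- The zero-amplitude control is a group-level calibration check: each null
  session ends above a 95% one-sided envelope with probability ≤ 5%, so
  demanding all 20 seeds stay inside would fail ~half the time under
  perfect calibration. The check allows at most 3 of 20 exceedances
  (P(≥4) ≈ 1.6% under exact calibration); signal sessions must all end
  above.
- Pretraining comparisons count a pair as consistent when the pretrained
  run reaches significance *no later* than the unpretrained one (ties
  count), using registration-recovered transforms rather than ground truth.

## Known limitations

- The generator's tuning is homogeneous within a patch and noise is
  spatially white; real mesoscopic maps have gradients and structured
  noise.
- The cPCA variant is one member of a family; accuracy-critical results do
  not depend on the choice, but absolute numbers could shift under another
  realization.
- Registration assumes in-plane rigid motion only.
- The permutation-null machinery is specific to the eight-direction
  geometry (45° spacing).
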