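# fusbmi

A tested, reusable implementation of a closed-loop functional-ultrasound
brain–machine interface (fUS-BMI) pipeline. Functional ultrasound streams
2 Hz power-Doppler images of cerebral blood volume at 100 µm in-plane
resolution from posterior parietal cortex while a subject performs
memory-guided eye or hand movements; a linear decoder reads the delay-period
activity and, after an initial training block, drives the task itself. The
package provides every stage of that loop — streaming preprocessing, the
decoders, the online training protocol, cross-session alignment,
chance-envelope statistics and searchlight information maps — exercised end
to end on a synthetic fUS session generator, so no animal data are required.

It is written for researchers building or evaluating imaging-based BMIs who
want the full protocol as an importable, deterministic library.

## The pipeline

- **Preprocessing** (`fusbmi.preprocess`): each incoming frame enters a
  rolling 60-frame (30 s) buffer, is voxel-wise z-scored against the buffer
  and smoothed with a 2-pixel-radius pillbox filter. A trial's feature
  vector is the last three preprocessed frames of the memory period.
- **Decoders** (`fusbmi.decoders`): two-class decoding uses class-wise PCA
  (per-class principal subspaces at 95% retained variance, pooled and
  orthonormalized) followed by regularized LDA. Eight-direction decoding
  uses a *multicoder*: vertical (up/mid/down) and horizontal
  (right/mid/left) components are predicted independently by pooled
  PCA+LDA models and combined — so neighboring directions share structure,
  and a (mid, mid) outcome yields a CENTER prediction that is never correct.
- **Closed loop** (`fusbmi.closed_loop`): successful overt-movement trials
  grow the training set and the decoder refits between trials; after 100
  training successes the task switches to BMI control, where success
  requires a correct prediction plus maintained fixation. Post hoc replay
  streams a recorded session through the identical code path.
- **Alignment & pretraining** (`fusbmi.alignment`): a previous session's
  anatomy is rigidly registered to the current one (mean-squared-error
  metric, regular-step gradient descent, multi-resolution), the transform is
  applied to all previous frames, and every valid previous trial seeds the
  new decoder — decoding from trial 1, no recalibration block.
- **Statistics** (`fusbmi.metrics`): cumulative percent correct
  (#correct/#predictions) against an exact binomial chance envelope at
  α = 0.05, and cumulative mean angular error (mean |angular error|, in
  {0, 45, …, 180}°) against a permutation null (10⁵ replicates, 5th/95th
  quantiles), with the last-nonsignificant-trial marker.
- **Searchlight** (`fusbmi.searchlight`): a 200 µm (2 voxel) circular ROI
  slides over the image; 10-fold cross-validated decoding on the 13 ROI
  voxels scores each center, with binomial/permutation p-values, BH-FDR
  q-values and a top-decile overlay mask.
- **Synthetic sessions** (`fusbmi.synthetic`): vascular phantoms with
  direction-tuned patches (von Mises tuning × gamma-variate hemodynamic
  response), multiplicative noise, drift and pulsatility, the jittered task
  timeline, inter-session rigid perturbations with ground-truth transforms,
  and an SVD clutter-filter demonstration.

## A worked example

```python
from fusbmi import (ClosedLoopConfig, TaskConfig, generate_session,
                    make_phantom, run_closed_loop)

phantom = make_phantom(seed=0, grid=(24, 32), patch_area_vox=40)
session = generate_session(phantom, TaskConfig(n_targets=2), n_trials=150, seed=1)
result = run_closed_loop(session, ClosedLoopConfig())
trace = result.trace
print(result.switch_trial(), trace.final_accuracy, trace.trials_to_significance())
```

Running `python examples/02_closed_loop_decoding.py` (the same computation)
prints:

```
switched to closed-loop BMI control at trial 101
evaluated trials (shadow from trial 20 + BMI): 131
final cumulative accuracy: 100.0% (upper chance bound 57.3%)
last nonsignificant trial: 23 -> significant from trial 24
BMI-mode success rate: 50/50 (success = correct prediction + fixation held)
```

The decoder trains on the first 100 successful trials (its shadow
predictions become significant at trial 24, i.e. the cumulative accuracy
first exceeds and then stays above the binomial envelope), then controls
the task for the remaining 50 trials. The other scripts in `examples/`
walk through session simulation and I/O, eight-direction multicoder
decoding with its confusion matrix, alignment + pretraining across a
simulated inter-session brain shift, searchlight mapping, and the
Doppler-level clutter filter.

A thin CLI wraps the same functions for shell use:
`fusbmi simulate | align | run-bmi | replay | report | searchlight`
(see `fusbmi --help`).

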