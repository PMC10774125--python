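"""The closed-loop experiment protocol.

A session begins in the training phase: the subject performs overt movements,
every successful trial's memory-period features are appended to the training
set, and the decoder is refit between trials (shadow predictions are logged
but invisible).  After 100 successful training trials the protocol switches
to BMI mode: the decoder's prediction drives the task, and a trial succeeds
only when the prediction matches the cue and fixation is maintained through
reward.

Training-set policies: ``realtime`` appends only successful trials (the
online rule); ``replay`` appends every valid trial regardless of prediction
correctness (the post hoc simulation rule, which avoids class starvation
when predictions are poor); pretraining seeds the set with all valid trials
of a rigidly-aligned previous session before the first current-session trial.

The cued direction of the in-progress trial is never visible to the decoder
path until after the trial ends: the model only ever receives a bare feature
array, and an ordered event log records every predict/reveal so the contract
is testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from . import metrics
from .alignment import RigidTransform2D, apply_transform
from .decoders import DecoderModel, TrainingSet, _fit_for_kind
from .preprocess import FeatureVector, PreprocessConfig, extract_trial_features
from .session_model import (
    HORIZONTAL_ORDER,
    VERTICAL_ORDER,
    Direction,
    SessionRecording,
    TrialRecord,
    decompose_direction,
)

__all__ = [
    "TrainingSetPolicy",
    "ClosedLoopConfig",
    "ProtocolState",
    "TrialResult",
    "ClosedLoopResult",
    "trial_success",
    "step_session",
    "run_closed_loop",
    "pretrain_from_previous",
    "replay_session",
]


class TrainingSetPolicy(Enum):
    REALTIME = "realtime"  # append only successful trials
    REPLAY = "replay"  # append all valid trials
    PRETRAIN_IMPORT = "pretrain_import"  # provenance tag for imported trials


@dataclass
class ClosedLoopConfig:
    switch_threshold: int = 100  # successful training trials before BMI mode
    min_eval_trial: int = 20  # first trial counted in performance traces
    policy: TrainingSetPolicy = TrainingSetPolicy.REALTIME
    retrain: bool = True
    retained_variance: float = 0.95
    shrinkage: float = 0.1
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    alpha: float = 0.05
    permutation_replicates: int = 20_000  # trace envelope for 8-target runs
    trace_seed: int = 0


@dataclass
class ProtocolState:
    phase: str  # "training" | "bmi"
    decoder_kind: str
    config: ClosedLoopConfig
    n_success_training: int = 0
    training_set: TrainingSet = field(default_factory=TrainingSet)
    model: DecoderModel | None = None
    events: list = field(default_factory=list)  # ordered (event, trial_index)

    def validate(self) -> None:
        if self.phase == "bmi" and self.n_success_training < self.config.switch_threshold:
            raise ValueError("BMI phase before reaching the training-success threshold")


@dataclass
class TrialResult:
    index: int
    cue: Direction
    prediction: Direction | None
    success: bool
    phase: str
    valid: bool


@dataclass
class ClosedLoopResult:
    trials: list[TrialResult]
    trace: metrics.PerformanceTrace | None
    model: DecoderModel | None
    state: ProtocolState
    session: SessionRecording

    @property
    def predictions(self) -> list[Direction | None]:
        return [t.prediction for t in self.trials]

    def switch_trial(self) -> int | None:
        """Index of the first trial run in BMI mode, if the switch happened."""
        for t in self.trials:
            if t.phase == "bmi":
                return t.index
        return None


def trial_success(trial: TrialRecord, phase: str, prediction: Direction | None) -> bool:
    """Phase-dependent success rule.

    Training: success iff the overt movement succeeded (the shadow prediction
    is irrelevant).  BMI: success iff the prediction matches the cue AND
    fixation was maintained (the trial's behavioral flag).
    """
    if not trial.valid:
        return False
    if phase == "training":
        return bool(trial.success)
    if phase == "bmi":
        if prediction is None or prediction is Direction.CENTER:
            return False
        return prediction == trial.cued_direction and bool(trial.success)
    raise ValueError(f"unknown phase {phase!r}")


def _can_fit(ts: TrainingSet, kind: str) -> bool:
    if len(ts) < 4:
        return False
    counts = ts.class_counts()
    if kind == "cpca_lda_2class":
        return len(counts) == 2 and all(v >= 2 for v in counts.values())
    vcounts: dict = {}
    hcounts: dict = {}
    for lab, n in counts.items():
        comp = decompose_direction(lab)
        vcounts[comp.vertical] = vcounts.get(comp.vertical, 0) + n
        hcounts[comp.horizontal] = hcounts.get(comp.horizontal, 0) + n
    return all(vcounts.get(v, 0) >= 2 for v in VERTICAL_ORDER) and all(
        hcounts.get(h, 0) >= 2 for h in HORIZONTAL_ORDER
    )


def _refit(state: ProtocolState) -> None:
    if _can_fit(state.training_set, state.decoder_kind):
        cfg = state.config
        state.model = _fit_for_kind(
            state.training_set, state.decoder_kind, cfg.retained_variance, cfg.shrinkage
        )


def step_session(
    state: ProtocolState,
    features: FeatureVector | None,
    trial: TrialRecord,
    freeze_model: bool = False,
) -> tuple[Direction | None, bool]:
    """Run one trial through the protocol: predict (from features only),
    score success, grow the training set per policy, refit, and advance the
    phase counter.  Returns (prediction, success)."""
    cfg = state.config
    phase = state.phase

    prediction: Direction | None = None
    if state.model is not None and features is not None:
        state.events.append(("predict", trial.index))
        prediction = state.model.predict(features.values)  # bare array: no label

    state.events.append(("reveal_cue", trial.index))
    valid = trial.valid and features is not None
    success = trial_success(trial, phase, prediction) if valid else False

    admit = False
    if valid and not freeze_model:
        if cfg.policy is TrainingSetPolicy.REALTIME:
            admit = success
        elif cfg.policy is TrainingSetPolicy.REPLAY:
            admit = True
    if admit:
        state.training_set.add(
            FeatureVector(
                values=features.values,
                label=trial.cued_direction,
                trial_index=trial.index,
                frame_shape=features.frame_shape,
                provenance="current",
            )
        )
        state.events.append(("append", trial.index))
        if cfg.retrain and not freeze_model:
            _refit(state)

    if phase == "training" and success:
        state.n_success_training += 1
        if state.n_success_training >= cfg.switch_threshold:
            state.phase = "bmi"  # subsequent trials run closed-loop
    return prediction, success


def pretrain_from_previous(
    prev: SessionRecording,
    transform: RigidTransform2D,
    state: ProtocolState,
) -> ProtocolState:
    """Seed the training set with every valid trial of a previous session,
    rigidly aligned into the current plane, and fit the initial model."""
    if prev.frames.shape[1:] != tuple(prev.anatomy.shape):
        raise ValueError("previous session frames/anatomy dimension mismatch")
    warped_frames = apply_transform(prev.frames.astype(float), transform, cval=0.0)
    warped = replace(
        prev,
        frames=np.asarray(warped_frames, dtype=np.float32),
        anatomy=np.asarray(apply_transform(prev.anatomy.astype(float), transform), np.float32),
    )
    feats = extract_trial_features(warped, state.config.preprocess, provenance="previous")
    for tr in warped.trials:
        if tr.valid and tr.index in feats:
            state.training_set.add(feats[tr.index])
    _refit(state)
    return state


def run_closed_loop(
    session: SessionRecording,
    config: ClosedLoopConfig | None = None,
    pretrain: tuple[SessionRecording, RigidTransform2D] | None = None,
    freeze_model: bool = False,
) -> ClosedLoopResult:
    """Execute the full protocol over a session source (live synthetic or
    recorded).  Deterministic given (session, config)."""
    config = config or ClosedLoopConfig()
    n_targets = int(session.meta.get("n_targets", 2))
    kind = "cpca_lda_2class" if n_targets == 2 else "multicoder_8dir"

    state = ProtocolState(phase="training", decoder_kind=kind, config=config)
    if pretrain is not None:
        prev, transform = pretrain
        pretrain_from_previous(prev, transform, state)

    features = extract_trial_features(session, config.preprocess)

    results: list[TrialResult] = []
    for tr in session.trials:
        phase = state.phase
        fv = features.get(tr.index)
        prediction, success = step_session(state, fv, tr, freeze_model=freeze_model)
        results.append(
            TrialResult(
                index=tr.index,
                cue=tr.cued_direction,
                prediction=prediction,
                success=success,
                phase=phase,
                valid=tr.valid and fv is not None,
            )
        )

    evaluated = [
        r
        for r in results
        if r.prediction is not None and r.valid and r.index >= config.min_eval_trial
    ]
    trace = None
    if evaluated:
        trace = metrics.cumulative_trace(
            predictions=[r.prediction for r in evaluated],
            cues=[r.cue for r in evaluated],
            n_targets=n_targets,
            trial_numbers=[r.index for r in evaluated],
            alpha=config.alpha,
            seed=config.trace_seed,
            permutation_replicates=config.permutation_replicates,
        )
    return ClosedLoopResult(trials=results, trace=trace, model=state.model,
                            state=state, session=session)


def replay_session(
    recorded: SessionRecording,
    config: ClosedLoopConfig | None = None,
    pretrain: tuple[SessionRecording, RigidTransform2D] | None = None,
    freeze_model: bool = False,
) -> ClosedLoopResult:
    """Stream a recorded session through the identical protocol code path.

    With the default replay policy every valid trial joins the training set;
    ``pretrain=None`` gives the no-pretraining simulation and
    ``freeze_model=True`` the pretrain-only (no current-session retraining)
    variant.
    """
    config = config or ClosedLoopConfig(policy=TrainingSetPolicy.REPLAY)
    return run_closed_loop(recorded, config, pretrain=pretrain, freeze_model=freeze_model)
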