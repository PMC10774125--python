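"""Protocol state machine: phase switch, policies, pretraining, replay."""

import dataclasses

import numpy as np
import pytest

from fusbmi import (
    ClosedLoopConfig,
    Direction,
    RigidTransform2D,
    TaskConfig,
    TrainingSetPolicy,
    generate_session,
    make_phantom,
    perturb_for_next_session,
    replay_session,
    run_closed_loop,
    trial_success,
)
from fusbmi.closed_loop import ProtocolState, step_session
from fusbmi.decoders import fit_cpca_lda
from fusbmi.preprocess import extract_trial_features
from fusbmi.session_model import PhaseTimes, TrialRecord


def _config(**kw):
    defaults = dict(switch_threshold=8, min_eval_trial=5, permutation_replicates=2000)
    defaults.update(kw)
    return ClosedLoopConfig(**defaults)


def _trial(index=1, cue=Direction.R, success=True, valid=True):
    return TrialRecord(
        index=index, task="bmi", cued_direction=cue,
        phase_times=PhaseTimes(10, 15, 15.4, 20, 20, 21.5),
        valid=valid, success=success,
    )


class TestTrialSuccess:
    def test_bmi_correct_prediction_with_fixation(self):
        assert trial_success(_trial(success=True), "bmi", Direction.R)

    def test_bmi_fixation_break_fails_despite_correct_prediction(self):
        assert not trial_success(_trial(success=False), "bmi", Direction.R)

    def test_bmi_center_prediction_never_succeeds(self):
        assert not trial_success(_trial(success=True), "bmi", Direction.CENTER)

    def test_training_success_independent_of_shadow_prediction(self):
        assert trial_success(_trial(success=True), "training", Direction.L)
        assert not trial_success(_trial(success=False), "training", Direction.R)


class TestProtocol:
    def test_switch_exactly_after_threshold_successes(self, session_2t):
        res = run_closed_loop(session_2t, _config(switch_threshold=8))
        assert res.switch_trial() == 9
        assert all(t.phase == "training" for t in res.trials[:8])
        assert all(t.phase == "bmi" for t in res.trials[8:])
        assert res.state.n_success_training >= 8

    def test_phase_flips_once_and_set_grows_monotonically(self, session_2t):
        res = run_closed_loop(session_2t, _config())
        phases = [t.phase for t in res.trials]
        assert phases == sorted(phases, key=lambda p: p != "training")

    def test_realtime_policy_skips_failed_bmi_trials(self, session_2t):
        res = run_closed_loop(session_2t, _config())
        appended = {i for ev, i in res.state.events if ev == "append"}
        for t in res.trials:
            assert (t.index in appended) == t.success

    def test_replay_policy_appends_all_valid_trials(self, session_2t):
        cfg = _config(policy=TrainingSetPolicy.REPLAY)
        res = run_closed_loop(session_2t, cfg)
        assert len(res.state.training_set) == sum(t.valid for t in res.trials)

    def test_deterministic_given_same_inputs(self, session_2t):
        a = run_closed_loop(session_2t, _config())
        b = run_closed_loop(session_2t, _config())
        assert a.predictions == b.predictions
        assert [t.success for t in a.trials] == [t.success for t in b.trials]

    def test_no_model_means_no_prediction(self, session_2t):
        res = run_closed_loop(session_2t, _config())
        # the very first trials cannot have predictions (no fitted model yet)
        assert res.trials[0].prediction is None

    def test_label_withholding_contract(self, session_2t):
        """The decoder never sees the cue before the prediction: for every
        trial the predict event precedes the cue-reveal event."""
        res = run_closed_loop(session_2t, _config())
        events = res.state.events
        for idx in (t.index for t in res.trials if t.prediction is not None):
            order = [ev for ev, i in events if i == idx and ev in ("predict", "reveal_cue")]
            assert order[0] == "predict" and "reveal_cue" in order

    def test_prediction_inputs_are_bare_arrays(self, session_2t, monkeypatch):
        """Spy on the decoder: everything shown to it is a plain feature
        array carrying no label/direction information."""
        from fusbmi.decoders import DecoderModel

        seen = []
        orig = DecoderModel.predict

        def spy(self, values):
            seen.append(values)
            return orig(self, values)

        monkeypatch.setattr(DecoderModel, "predict", spy)
        run_closed_loop(session_2t, _config())
        assert seen
        assert all(isinstance(v, np.ndarray) for v in seen)


class TestPretraining:
    def test_identity_pretrain_matches_direct_fit(self, session_2t):
        """Pretraining on the same session through the identity transform
        equals fitting directly on that session's valid trials."""
        cfg = _config()
        state = ProtocolState(phase="training", decoder_kind="cpca_lda_2class", config=cfg)
        from fusbmi.closed_loop import pretrain_from_previous

        pretrain_from_previous(session_2t, RigidTransform2D(), state)

        feats = extract_trial_features(session_2t, cfg.preprocess)
        from fusbmi.decoders import TrainingSet

        direct = fit_cpca_lda(TrainingSet([feats[t.index] for t in session_2t.trials
                                           if t.valid and t.index in feats]))
        assert state.model is not None
        probe = np.stack([feats[i].values for i in list(feats)[:10]])
        assert [state.model.predict(x) for x in probe] == [direct.predict(x) for x in probe]
        assert all(v.provenance == "previous" for v in state.training_set.vectors)

    def test_pretrained_session_predicts_from_first_trial(self, phantom):
        task = TaskConfig(n_targets=2)
        prev = generate_session(phantom, task, n_trials=40, seed=31)
        pert, true_t = perturb_for_next_session(phantom, 1.0, (2.0, -1.0))
        curr = generate_session(pert, task, n_trials=20, seed=32)
        res = run_closed_loop(curr, _config(), pretrain=(prev, true_t))
        assert res.trials[0].prediction is not None

    def test_pretraining_reaches_significance_no_later(self, phantom):
        """On a matched pair, trials-to-significance with pretraining is at
        most that without (the qualitative pretraining claim)."""
        task = TaskConfig(n_targets=2)
        prev = generate_session(phantom, task, n_trials=60, seed=41)
        pert, true_t = perturb_for_next_session(phantom, 1.5, (2.0, 1.0))
        curr = generate_session(pert, task, n_trials=60, seed=42)
        cfg = _config(min_eval_trial=1)
        without = run_closed_loop(curr, cfg)
        with_pre = run_closed_loop(curr, cfg, pretrain=(prev, true_t))
        t_without = without.trace.trials_to_significance() or 10**9
        t_with = with_pre.trace.trials_to_significance() or 10**9
        assert t_with <= t_without


class TestReplay:
    def test_replay_reproduces_recorded_run_bitwise(self, session_2t):
        cfg = _config()
        first = run_closed_loop(session_2t, cfg)
        again = replay_session(session_2t, cfg)
        assert first.predictions == again.predictions
        assert [t.success for t in first.trials] == [t.success for t in again.trials]

    def test_frozen_model_never_retrains(self, phantom):
        task = TaskConfig(n_targets=2)
        prev = generate_session(phantom, task, n_trials=40, seed=51)
        curr = generate_session(phantom, task, n_trials=20, seed=52)
        cfg = _config(policy=TrainingSetPolicy.REPLAY)
        res = replay_session(curr, cfg, pretrain=(prev, RigidTransform2D()),
                             freeze_model=True)
        assert len(res.state.training_set) == 40  # imported trials only
        assert all(v.provenance == "previous" for v in res.state.training_set.vectors)

    def test_shuffled_label_replay_inside_chance(self, phantom):
        """Scoring predictions against shuffled cues lands inside the
        binomial envelope (permutation control)."""
        from fusbmi import binomial_envelope

        task = TaskConfig(n_targets=2)
        sess = generate_session(phantom, task, n_trials=60, seed=61)
        res = replay_session(sess, _config(policy=TrainingSetPolicy.REPLAY))
        evaluated = [t for t in res.trials if t.prediction is not None]
        rng = np.random.default_rng(0)
        accs = []
        for _ in range(10):  # mean over shuffles concentrates at chance
            cues = [t.cue for t in evaluated]
            rng.shuffle(cues)
            accs.append(np.mean([t.prediction == c for t, c in zip(evaluated, cues)]))
        low, high = binomial_envelope(len(evaluated), 0.5)
        assert low <= np.mean(accs) <= high
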