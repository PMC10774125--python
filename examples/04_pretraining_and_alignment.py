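"""Stabilize the decoder across sessions with rigid alignment + pretraining.

The brain shifts slightly relative to the transducer between sessions.  A
previous session's anatomy is registered to the current one (MSE metric,
regular-step gradient descent), the recovered rigid transform is applied to
every previous frame, and all valid previous trials seed the new decoder —
so decoding starts at trial 1 instead of after a fresh training block.
"""

from fusbmi import (
    ClosedLoopConfig,
    TaskConfig,
    generate_session,
    make_phantom,
    perturb_for_next_session,
    register_rigid,
    run_closed_loop,
)

phantom = make_phantom(seed=5, grid=(24, 32), patch_area_vox=40)
task = TaskConfig(n_targets=2)
previous = generate_session(phantom, task, n_trials=60, seed=6)

# the next day: same brain, shifted 2 px right / 1.5 px down, rotated 1.5 deg
shifted, true_transform = perturb_for_next_session(phantom, 1.5, (1.5, 2.0))
current = generate_session(shifted, task, n_trials=60, seed=7)

reg = register_rigid(previous.anatomy, current.anatomy)
t = reg.transform
print(f"true transform:      theta={true_transform.theta_deg:+.2f} deg, "
      f"t=({true_transform.tx_px:+.2f}, {true_transform.ty_px:+.2f}) px")
print(f"recovered transform: theta={t.theta_deg:+.2f} deg, "
      f"t=({t.tx_px:+.2f}, {t.ty_px:+.2f}) px  (final MSE {reg.final_mse:.2e})")

cfg = ClosedLoopConfig(min_eval_trial=1)
without = run_closed_loop(current, cfg)
with_pre = run_closed_loop(current, cfg, pretrain=(previous, t))

print(f"\nwithout pretraining: first prediction at trial "
      f"{next(t_.index for t_ in without.trials if t_.prediction)}, "
      f"significant from trial {without.trace.trials_to_significance()}")
print(f"with pretraining:    first prediction at trial "
      f"{next(t_.index for t_ in with_pre.trials if t_.prediction)}, "
      f"significant from trial {with_pre.trace.trials_to_significance()}")
print(f"imported previous trials: "
      f"{with_pre.state.training_set.provenance_counts().get('previous', 0)}")
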