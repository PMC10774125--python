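"""Synthetic session generator: determinism, balance, tuning, clutter filter,
inter-session perturbation."""

import numpy as np
import pytest

import fusbmi as fb
from fusbmi import (
    Direction,
    TaskConfig,
    generate_session,
    make_phantom,
    perturb_for_next_session,
    svd_clutter_filter,
    tuning,
)


class TestPhantom:
    def test_same_seed_bit_identical(self):
        a = make_phantom(seed=3, grid=(24, 32))
        b = make_phantom(seed=3, grid=(24, 32))
        assert np.array_equal(a.anatomy, b.anatomy)
        for pa, pb in zip(a.patches, b.patches):
            assert np.array_equal(pa.mask, pb.mask)

    def test_default_phantom_positive_with_two_patches(self):
        ph = make_phantom(seed=0, grid=(32, 40))
        assert np.all(ph.anatomy > 0)
        assert len(ph.patches) == 2
        assert ph.patches[0].preferred_deg != ph.patches[1].preferred_deg

    def test_patch_area_request_honored(self):
        ph = make_phantom(seed=0, grid=(64, 80), patch_area_vox=200)
        assert all(p.mask.sum() == 200 for p in ph.patches)


class TestTuningCurve:
    def test_closed_form(self):
        assert tuning(90.0, 90.0, 2.0) == pytest.approx(1.0)
        assert tuning(270.0, 90.0, 2.0) == pytest.approx(np.exp(-4.0))
        assert tuning(270.0, 90.0, 0.5) == pytest.approx(np.exp(-1.0))

    def test_monotone_in_cosine_distance(self):
        vals = tuning(np.array([0, 45, 90, 135, 180]), 0.0, 2.0)
        assert np.all(np.diff(vals) < 0)


class TestGenerateSession:
    def test_deterministic_given_seed(self, phantom):
        task = TaskConfig(n_targets=2)
        a = generate_session(phantom, task, n_trials=6, seed=9)
        b = generate_session(phantom, task, n_trials=6, seed=9)
        assert np.array_equal(a.frames, b.frames)
        assert [t.cued_direction for t in a.trials] == [t.cued_direction for t in b.trials]

    @pytest.mark.parametrize("n_targets,n_trials", [(8, 16), (2, 10)])
    def test_cue_balance(self, phantom, n_targets, n_trials):
        task = TaskConfig(n_targets=n_targets)
        sess = generate_session(phantom, task, n_trials=n_trials, seed=4)
        cues = [t.cued_direction for t in sess.trials]
        counts = {d: cues.count(d) for d in set(cues)}
        assert len(counts) == n_targets
        assert all(c == n_trials // n_targets for c in counts.values())

    def test_frame_budget_error(self, phantom):
        with pytest.raises(ValueError, match="budget"):
            generate_session(phantom, TaskConfig(), n_trials=50, seed=0, max_frames=100)

    def test_noiseless_response_matches_convolved_boxcar(self):
        """With one sharply tuned patch and no noise, the preferred-cue
        response equals amplitude * (boxcar conv HRF), and the anti-preferred
        response vanishes (numerical convolution as the oracle)."""
        ph = make_phantom(
            seed=5, grid=(24, 32), noise_sd=0.0, drift_sd=0.0, pulsatility_amp=0.0,
            patch_specs=[{"center_frac": (0.5, 0.5), "preferred_deg": 0.0,
                          "area_vox": 40, "kappa": 50.0}],
        )
        task = TaskConfig(n_targets=2, fixation_jitter_s=0, memory_jitter_s=0,
                          hold_jitter_s=0, iti_jitter_s=0)
        sess = generate_session(ph, task, n_trials=4, seed=6)
        patch = ph.patches[0]
        dt = 0.5

        # independent oracle: rectangular stimulus convolved with the kernel
        times = sess.timestamps
        kernel = patch.hrf.kernel(dt)
        expected = np.zeros_like(times)
        for tr in sess.trials:
            w = patch.amplitude * tuning(tr.cued_direction.angle_deg, 0.0, 50.0)
            box = ((times >= tr.phase_times.cue_on) & (times < tr.phase_times.memory_end))
            for k, hk in enumerate(kernel):
                shifted = np.zeros_like(expected)
                shifted[k:] = box[: len(times) - k] * w
                expected += hk * shifted

        ratio = sess.frames / ph.anatomy[None].astype(np.float32) - 1.0
        observed = ratio[:, patch.mask].mean(axis=1)
        assert np.allclose(observed, expected, atol=1e-5)

        # preferred memory-period mean exceeds anti-preferred by ~amplitude
        pref = [t for t in sess.trials if t.cued_direction is Direction.R][0]
        anti = [t for t in sess.trials if t.cued_direction is Direction.L][0]

        def memory_mean(tr):
            m = (times >= tr.phase_times.cue_on + 3.0) & (times <= tr.phase_times.memory_end)
            return observed[m].mean()

        assert memory_mean(pref) > memory_mean(anti) + 0.9 * patch.amplitude

    def test_valid_session_invariants(self, session_8t):
        session_8t.validate()
        assert np.all(np.diff(session_8t.timestamps) > 0)


class TestPerturbation:
    def test_identity_transform_unchanged(self, phantom):
        pert, t = perturb_for_next_session(phantom, 0.0, (0.0, 0.0), gain=1.0)
        assert t.is_identity
        assert np.allclose(pert.anatomy, phantom.anatomy)
        assert np.array_equal(pert.patches[0].mask, phantom.patches[0].mask)

    def test_shift_recovered_by_phase_correlation(self):
        """Independent oracle: skimage phase correlation finds the (3, -4)
        pixel shift applied to the anatomy."""
        from skimage.registration import phase_cross_correlation

        ph = make_phantom(seed=8, grid=(64, 80))
        pert, t = perturb_for_next_session(ph, 0.0, (3.0, -4.0))
        shift, _, _ = phase_cross_correlation(pert.anatomy, ph.anatomy)
        assert shift[0] == pytest.approx(3.0, abs=0.5)
        assert shift[1] == pytest.approx(-4.0, abs=0.5)

    def test_rotation_roundtrip_within_interpolation_tolerance(self):
        ph = make_phantom(seed=8, grid=(64, 80))
        pert, _ = perturb_for_next_session(ph, 2.0, (0.0, 0.0))
        back, _ = perturb_for_next_session(pert, -2.0, (0.0, 0.0))
        interior = np.s_[8:-8, 8:-8]
        scale = ph.anatomy.max() - ph.anatomy.min()
        mae = np.abs(back.anatomy[interior] - ph.anatomy[interior]).mean()
        assert mae < 0.02 * scale

    def test_patch_off_grid_rejected(self):
        ph = make_phantom(
            seed=8, grid=(32, 40),
            patch_specs=[{"center_frac": (0.5, 0.95), "preferred_deg": 0.0, "area_vox": 60}],
        )
        with pytest.raises(ValueError, match="off the grid"):
            perturb_for_next_session(ph, 0.0, (0.0, 10.0))

    def test_sanity_bounds(self, phantom):
        with pytest.raises(ValueError):
            perturb_for_next_session(phantom, 11.0, (0, 0))
        with pytest.raises(ValueError):
            perturb_for_next_session(phantom, 0.0, (0, 25))


class TestClutterFilter:
    def test_static_clutter_removed(self, rng):
        frame = rng.uniform(1, 2, size=(10, 12))
        ensemble = np.repeat(frame[None], 10, axis=0)  # rank 1
        power = svd_clutter_filter(ensemble, discard_fraction=0.3)
        assert np.all(power < 1e-12)

    def test_discard_count_matches_floor_rule(self, rng):
        """N=200 compounded frames at fraction 0.3 discard exactly 60
        components: residual power equals the trailing-spectrum energy."""
        ensemble = rng.standard_normal((200, 16, 16))  # 256 voxels: full rank
        power = svd_clutter_filter(ensemble, discard_fraction=0.3)
        s = np.linalg.svd(ensemble.reshape(200, -1).T, compute_uv=False)
        # total residual power = energy of the spectrum past component 60
        assert power.sum() == pytest.approx(np.sum(s[60:] ** 2) / 200.0, rel=1e-8)
        # one component more or fewer would change the energy measurably
        assert power.sum() < np.sum(s[59:] ** 2) / 200.0
        assert power.sum() > np.sum(s[61:] ** 2) / 200.0

    def test_blood_voxel_survives_clutter(self, rng):
        """Rank-1 tissue clutter plus one fluctuating blood voxel: after
        removing the single clutter component, power peaks at that voxel."""
        clutter = np.outer(np.ones(40), rng.uniform(10, 20, 12 * 10)).reshape(40, 12, 10)
        noise = 0.01 * rng.standard_normal(clutter.shape)
        blood = np.zeros_like(clutter)
        blood[:, 6, 4] = rng.standard_normal(40)
        power = svd_clutter_filter(clutter + noise + blood, discard_fraction=0.03)
        assert np.unravel_index(np.argmax(power), power.shape) == (6, 4)

    def test_bad_inputs(self, rng):
        with pytest.raises(ValueError, match="discard_fraction"):
            svd_clutter_filter(rng.standard_normal((10, 4, 4)), discard_fraction=1.0)
        with pytest.raises(ValueError, match="at least 4"):
            svd_clutter_filter(rng.standard_normal((3, 4, 4)))
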