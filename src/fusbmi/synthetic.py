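"""Synthetic fUS session generator.

Builds phantom sessions with the statistical structure the decoder assumes:
a positive vascular background image, patches of direction-tuned voxels whose
memory-period cerebral-blood-volume response follows a von Mises tuning curve
convolved with a seconds-scale gamma-variate response function, multiplicative
voxel noise, slow global gain drift and a pulsatility surrogate, all on the
memory-guided task timeline (5 +- 1 s fixation, 400 ms cue, 5 +- 1 s memory,
1.5 +- 0.5 s hold, 8 +- 2 s intertrial interval at 2 Hz framing).

Also provides inter-session rigid perturbations (for alignment/pretraining
experiments, returning the ground-truth transform) and a self-contained SVD
clutter-filter demonstration at the Doppler-ensemble level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.stats import gamma as gamma_dist

from .alignment import RigidTransform2D, apply_transform
from .session_model import (
    PERIPHERAL_DIRECTIONS,
    Direction,
    PhaseTimes,
    SessionRecording,
    TrialRecord,
)

__all__ = [
    "GammaHRF",
    "TunedPatch",
    "PhantomSpec",
    "TaskConfig",
    "tuning",
    "make_phantom",
    "generate_session",
    "perturb_for_next_session",
    "svd_clutter_filter",
]


@dataclass(frozen=True)
class GammaHRF:
    """Gamma-variate hemodynamic response function.

    Defaults give a ~1.5 s time-to-peak and ~2 s FWHM with no undershoot,
    the seconds-scale neurovascular coupling regime fUS operates in.  The
    kernel is normalized to unit area so a sustained stimulus converges to
    the nominal response amplitude.
    """

    delay_s: float = 0.0
    shape: float = 4.0
    scale_s: float = 0.5

    @property
    def peak_s(self) -> float:
        return self.delay_s + (self.shape - 1.0) * self.scale_s

    def kernel(self, dt: float, duration_s: float = 15.0) -> np.ndarray:
        t = np.arange(0.0, duration_s, dt)
        h = gamma_dist.pdf(t - self.delay_s, a=self.shape, scale=self.scale_s)
        total = h.sum() * dt
        if total <= 0:
            raise ValueError("degenerate HRF kernel")
        return h * dt / total  # discrete kernel summing to 1


@dataclass
class TunedPatch:
    """A contiguous set of voxels sharing one direction tuning."""

    mask: np.ndarray  # (H, W) bool
    preferred_deg: float
    kappa: float = 2.0
    amplitude: float = 0.10  # peak fractional CBV increase at preferred dir
    hrf: GammaHRF = field(default_factory=GammaHRF)
    name: str = "patch"

    def validate(self, grid: tuple[int, int]) -> None:
        if self.mask.shape != grid:
            raise ValueError(f"patch '{self.name}' mask shape {self.mask.shape} != grid {grid}")
        if self.amplitude < 0:
            raise ValueError("patch amplitude must be >= 0")
        if not self.mask.any():
            raise ValueError(f"patch '{self.name}' is empty")


@dataclass
class PhantomSpec:
    """Everything needed to synthesize frames: anatomy, tuned patches, noise."""

    grid: tuple[int, int] = (128, 160)  # 12.8 x 16 mm at 0.1 mm voxels
    anatomy: np.ndarray | None = None  # (H, W) > 0
    patches: list[TunedPatch] = field(default_factory=list)
    noise_sd: float = 0.02  # multiplicative voxel noise, fraction of baseline
    drift_sd: float = 0.002  # per-frame random-walk gain sd
    pulsatility_amp: float = 0.01  # global gain oscillation amplitude
    pulsatility_freq_hz: float = 0.3  # aliased heartbeat surrogate
    seed: int | None = None

    def validate(self) -> None:
        if self.anatomy is None:
            raise ValueError("phantom has no anatomy image")
        if self.anatomy.shape != tuple(self.grid):
            raise ValueError("anatomy shape does not match grid")
        if not np.all(self.anatomy > 0):
            raise ValueError("anatomy must be strictly positive")
        for p in self.patches:
            p.validate(tuple(self.grid))


@dataclass
class TaskConfig:
    """Memory-guided task geometry and timing (uniform jitter)."""

    n_targets: int = 2  # 2 (L/R) or 8
    task: str = "saccade"
    eccentricity_deg: float = 20.0
    fixation_s: float = 5.0
    fixation_jitter_s: float = 1.0
    cue_s: float = 0.4
    memory_s: float = 5.0
    memory_jitter_s: float = 1.0
    hold_s: float = 1.5
    hold_jitter_s: float = 0.5
    iti_s: float = 8.0
    iti_jitter_s: float = 2.0
    frame_rate_hz: float = 2.0
    p_behavior_success: float = 1.0

    def validate(self) -> None:
        if self.n_targets not in (2, 8):
            raise ValueError("n_targets must be 2 or 8")
        for name in ("fixation_s", "cue_s", "memory_s", "hold_s", "iti_s", "frame_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.p_behavior_success <= 1.0:
            raise ValueError("p_behavior_success must be in [0, 1]")

    @property
    def targets(self) -> tuple[Direction, ...]:
        if self.n_targets == 2:
            return (Direction.R, Direction.L)
        return PERIPHERAL_DIRECTIONS


def tuning(phi_deg, preferred_deg: float, kappa: float):
    """Von Mises tuning normalized to 1 at the preferred direction:
    exp(kappa * cos(phi - pref)) / exp(kappa)."""
    delta = np.deg2rad(np.asarray(phi_deg, dtype=float) - preferred_deg)
    return np.exp(kappa * (np.cos(delta) - 1.0))


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------


def _disk_mask(grid: tuple[int, int], center: tuple[float, float], area_vox: int) -> np.ndarray:
    """Disk of exactly ``area_vox`` voxels: grow by distance rank from center."""
    H, W = grid
    if area_vox < 1:
        raise ValueError("patch area must be >= 1 voxel")
    rr, cc = np.mgrid[0:H, 0:W]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    flat = np.argsort(d2, axis=None, kind="stable")[:area_vox]
    mask = np.zeros(H * W, dtype=bool)
    mask[flat] = True
    mask = mask.reshape(H, W)
    if area_vox > mask.sum():
        raise ValueError("patch does not fit in grid")
    return mask


def _vessel_anatomy(grid: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Smoothed curvilinear vessel-like structures over a low background."""
    H, W = grid
    img = np.zeros((H, W), dtype=float)
    n_vessels = max(6, (H * W) // 1800)
    for _ in range(n_vessels):
        r = rng.uniform(0, H - 1)
        c = rng.uniform(0, W - 1)
        ang = rng.uniform(0, 2 * math.pi)
        curv = rng.normal(0.0, 0.15)
        intensity = rng.uniform(0.8, 2.5)
        n_steps = int(rng.uniform(0.4, 1.2) * max(H, W))
        for _ in range(n_steps):
            ri, ci = int(round(r)), int(round(c))
            if 0 <= ri < H and 0 <= ci < W:
                img[ri, ci] += intensity
            ang += curv + rng.normal(0.0, 0.05)
            r += math.sin(ang)
            c += math.cos(ang)
    img = ndimage.gaussian_filter(img, sigma=1.2)
    background = 0.5 + 0.15 * ndimage.gaussian_filter(rng.standard_normal((H, W)), sigma=4.0)
    anatomy = np.clip(background, 0.1, None) + img
    return anatomy


def make_phantom(
    seed: int = 0,
    *,
    grid: tuple[int, int] = (128, 160),
    patch_area_vox: int = 200,
    patch_specs: list[dict] | None = None,
    noise_sd: float = 0.02,
    drift_sd: float = 0.002,
    pulsatility_amp: float = 0.01,
    amplitude: float = 0.10,
    kappa: float = 2.0,
    hrf: GammaHRF | None = None,
) -> PhantomSpec:
    """Build a deterministic phantom: vascular anatomy plus tuned patches.

    Default layout places an "LIP-like" patch (preferred 0 deg, i.e. R) and
    an "MIP-like" patch (preferred 90 deg, i.e. U) so that the pair jointly
    disambiguates all eight directions; ``patch_specs`` overrides the layout
    with dicts of ``center_frac``, ``preferred_deg`` and optional ``kappa``,
    ``amplitude``, ``area_vox``, ``name``.
    """
    rng = np.random.default_rng(seed)
    grid = tuple(int(g) for g in grid)
    anatomy = _vessel_anatomy(grid, rng)
    hrf = hrf or GammaHRF()

    if patch_specs is None:
        patch_specs = [
            {"center_frac": (0.30, 0.35), "preferred_deg": 0.0, "name": "LIP-like"},
            {"center_frac": (0.45, 0.65), "preferred_deg": 90.0, "name": "MIP-like"},
        ]

    patches = []
    for ps in patch_specs:
        area = int(ps.get("area_vox", patch_area_vox))
        cf = ps["center_frac"]
        center = (cf[0] * (grid[0] - 1), cf[1] * (grid[1] - 1))
        mask = _disk_mask(grid, center, area)
        patches.append(
            TunedPatch(
                mask=mask,
                preferred_deg=float(ps["preferred_deg"]),
                kappa=float(ps.get("kappa", kappa)),
                amplitude=float(ps.get("amplitude", amplitude)),
                hrf=ps.get("hrf", hrf),
                name=str(ps.get("name", f"patch{len(patches)}")),
            )
        )

    spec = PhantomSpec(
        grid=grid,
        anatomy=anatomy,
        patches=patches,
        noise_sd=noise_sd,
        drift_sd=drift_sd,
        pulsatility_amp=pulsatility_amp,
        seed=seed,
    )
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# session synthesis
# ---------------------------------------------------------------------------


def _balanced_cues(targets, n_trials: int, rng: np.random.Generator) -> list[Direction]:
    """Balanced pseudo-random cue order: shuffled blocks, each direction cued
    floor(n/k) or ceil(n/k) times (Latin-square-style block randomization)."""
    k = len(targets)
    cues: list[Direction] = []
    while len(cues) < n_trials:
        block = list(targets)
        rng.shuffle(block)
        cues.extend(block)
    return cues[:n_trials]


def generate_session(
    phantom: PhantomSpec,
    task: TaskConfig,
    n_trials: int,
    seed: int = 0,
    max_frames: int | None = None,
) -> SessionRecording:
    """Synthesize a full session.

    Frame f at time t is
    ``anatomy * (1 + sum_p tuning(cue; pref_p, kappa_p) * amp_p * (boxcar_{cue+memory} conv hrf)(t))
    * (1 + noise) * gain(t)``
    with gain(t) the drift random walk times the pulsatility oscillation.
    Trial records carry the ground-truth cue, jittered phase times and a
    behavioral success draw at ``task.p_behavior_success``.
    """
    phantom.validate()
    task.validate()
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    dt = 1.0 / task.frame_rate_hz

    cues = _balanced_cues(task.targets, n_trials, rng)

    # --- schedule ----------------------------------------------------------
    def jit(base, j):
        return base + rng.uniform(-j, j) if j > 0 else base

    t = jit(task.iti_s, task.iti_jitter_s)  # lead-in interval before trial 1
    trials: list[TrialRecord] = []
    for i, cue in enumerate(cues, start=1):
        t_fix = t
        t_cue_on = t_fix + jit(task.fixation_s, task.fixation_jitter_s)
        t_cue_off = t_cue_on + task.cue_s
        t_mem_end = t_cue_off + jit(task.memory_s, task.memory_jitter_s)
        t_move = t_mem_end
        t_reward = t_move + jit(task.hold_s, task.hold_jitter_s)
        t = t_reward + jit(task.iti_s, task.iti_jitter_s)
        success = bool(rng.uniform() < task.p_behavior_success)
        trials.append(
            TrialRecord(
                index=i,
                task=task.task,
                cued_direction=cue,
                phase_times=PhaseTimes(t_fix, t_cue_on, t_cue_off, t_mem_end, t_move, t_reward),
                valid=True,
                success=success,
                prediction=None,
            )
        )

    t_end = trials[-1].phase_times.reward + 6.0  # tail for HRF decay
    n_frames = int(math.ceil(t_end / dt)) + 1
    if max_frames is not None and n_frames > max_frames:
        raise ValueError(
            f"schedule needs {n_frames} frames but the frame budget is {max_frames}"
        )
    times = np.arange(n_frames) * dt

    # --- noise, drift, pulsatility (multiplicative, so order-free) ---------
    H, W = phantom.grid
    # build frames in float32 with in-place ops; the stack dominates memory
    if phantom.noise_sd > 0:
        frames = rng.standard_normal((n_frames, H, W), dtype=np.float32)
        frames *= phantom.noise_sd
        frames += 1.0
    else:
        frames = np.ones((n_frames, H, W), dtype=np.float32)
    gain = np.ones(n_frames)
    if phantom.drift_sd > 0:
        gain = gain + np.cumsum(rng.normal(0.0, phantom.drift_sd, size=n_frames))
    if phantom.pulsatility_amp > 0:
        gain = gain * (
            1.0 + phantom.pulsatility_amp * np.sin(2 * np.pi * phantom.pulsatility_freq_hz * times)
        )
    frames *= gain[:, None, None].astype(np.float32)
    frames *= phantom.anatomy[None, :, :].astype(np.float32)

    # --- hemodynamic signal: tuned boxcar (cue+memory) conv HRF ------------
    for patch in phantom.patches:
        stim = np.zeros(n_frames, dtype=float)
        for tr in trials:
            w = patch.amplitude * float(
                tuning(tr.cued_direction.angle_deg, patch.preferred_deg, patch.kappa)
            )
            on = tr.phase_times.cue_on
            off = tr.phase_times.memory_end
            stim[(times >= on) & (times < off)] += w
        resp = np.convolve(stim, patch.hrf.kernel(dt))[:n_frames]
        frames[:, patch.mask] *= (1.0 + resp[:, None]).astype(np.float32)

    anatomy = phantom.anatomy * (1.0 + rng.normal(0.0, phantom.noise_sd, size=(H, W)))

    session = SessionRecording(
        frames=frames,
        timestamps=times.astype(float),
        trials=trials,
        anatomy=np.asarray(anatomy, dtype=np.float32),
        meta={
            "n_targets": task.n_targets,
            "task": task.task,
            "eccentricity_deg": task.eccentricity_deg,
            "seed": seed,
            "phantom_seed": phantom.seed,
            "frame_period_s": dt,
            "provenance": "fusbmi.synthetic.generate_session",
        },
    )
    session.validate()
    return session


# ---------------------------------------------------------------------------
# inter-session perturbation
# ---------------------------------------------------------------------------


def perturb_for_next_session(
    phantom: PhantomSpec,
    rotate_deg: float = 0.0,
    shift_px: tuple[float, float] = (0.0, 0.0),
    gain: float = 1.0,
    seed: int | None = None,
) -> tuple[PhantomSpec, RigidTransform2D]:
    """Rigidly shift/rotate the phantom, as the brain does relative to the
    transducer between sessions; returns (new phantom, true transform).

    The returned transform maps the ORIGINAL phantom onto the perturbed one,
    i.e. it is the transform a registration of (moving=original anatomy,
    fixed=new anatomy) should recover.
    """
    if abs(rotate_deg) > 10:
        raise ValueError("|rotate_deg| must be <= 10 (sanity bound)")
    if max(abs(shift_px[0]), abs(shift_px[1])) > 20:
        raise ValueError("|shift| must be <= 20 px (sanity bound)")
    phantom.validate()

    transform = RigidTransform2D(theta_deg=rotate_deg, tx_px=shift_px[1], ty_px=shift_px[0])
    fill = float(np.percentile(phantom.anatomy, 5))
    new_anatomy = apply_transform(phantom.anatomy, transform, cval=fill) * gain

    H, W = phantom.grid
    th = math.radians(rotate_deg)
    cos_, sin_ = math.cos(th), math.sin(th)
    c0, c1 = (H - 1) / 2.0, (W - 1) / 2.0
    new_patches = []
    for p in phantom.patches:
        rr, cc = np.nonzero(p.mask)
        r_new = cos_ * (rr - c0) + sin_ * (cc - c1) + c0 + shift_px[0]
        c_new = -sin_ * (rr - c0) + cos_ * (cc - c1) + c1 + shift_px[1]
        if (r_new.min() < -0.5 or r_new.max() > H - 0.5
                or c_new.min() < -0.5 or c_new.max() > W - 0.5):
            raise ValueError(f"transform pushes patch '{p.name}' off the grid")
        warped = apply_transform(p.mask.astype(float), transform, cval=0.0)
        new_patches.append(replace(p, mask=warped > 0.5))

    new_spec = replace(phantom, anatomy=new_anatomy, patches=new_patches)
    new_spec.validate()
    return new_spec, transform


# ---------------------------------------------------------------------------
# Doppler-level clutter filter demo
# ---------------------------------------------------------------------------


def svd_clutter_filter(ensemble: np.ndarray, discard_fraction: float = 0.3) -> np.ndarray:
    """SVD clutter filter over a slow-time ensemble of N compounded frames.

    The (voxels x N) Casorati matrix is decomposed by SVD; the
    ``floor(discard_fraction * N)`` largest singular components (tissue
    clutter) are zeroed; the power-Doppler image is the slow-time mean of the
    squared residual magnitude per voxel.
    """
    if not 0.0 <= discard_fraction < 1.0:
        raise ValueError("discard_fraction must be in [0, 1)")
    ensemble = np.asarray(ensemble)
    if ensemble.ndim != 3:
        raise ValueError("ensemble must be (N, H, W)")
    N, H, W = ensemble.shape
    if N < 4:
        raise ValueError("ensemble must hold at least 4 frames")

    casorati = ensemble.reshape(N, H * W).T  # voxels x N
    u, s, vt = np.linalg.svd(casorati, full_matrices=False)
    n_discard = int(math.floor(discard_fraction * N))
    s_filtered = s.copy()
    s_filtered[:n_discard] = 0.0
    residual = (u * s_filtered) @ vt
    power = np.mean(np.abs(residual) ** 2, axis=1).reshape(H, W)
    return power
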