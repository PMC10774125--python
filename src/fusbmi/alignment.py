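"""Cross-session rigid alignment of imaging planes.

A previous session's anatomical (mean power-Doppler) image is aligned to the
current session's anatomy with a rotation-plus-translation transform --- no
scaling, since brain size does not change between sessions --- by minimizing
the mean squared intensity difference with a regular-step gradient descent
over a 3-level multi-resolution pyramid.  The recovered transform is then
applied to every frame of the previous session before its trials are imported
as pretraining data.  Out-of-plane shifts are not modeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "RigidTransform2D",
    "RegistrationConfig",
    "RegistrationResult",
    "register_rigid",
    "manual_adjust",
    "apply_transform",
]


@dataclass(frozen=True)
class RigidTransform2D:
    """Rotation (degrees, about the image center, counterclockwise in x-y
    with x = column and y = row) followed by translation in pixels."""

    theta_deg: float = 0.0
    tx_px: float = 0.0  # column shift
    ty_px: float = 0.0  # row shift

    @property
    def is_identity(self) -> bool:
        return self.theta_deg == 0.0 and self.tx_px == 0.0 and self.ty_px == 0.0

    def then(self, second: "RigidTransform2D") -> "RigidTransform2D":
        """Composition: apply self first, then ``second`` (both about the
        image center): p'' = R2 R1 (p - c) + c + R2 t1 + t2."""
        th2 = math.radians(second.theta_deg)
        cos2, sin2 = math.cos(th2), math.sin(th2)
        # rotate (tx, ty) = (col, row); row/col frame shares the x-y rotation
        tx = cos2 * self.tx_px - sin2 * self.ty_px + second.tx_px
        ty = sin2 * self.tx_px + cos2 * self.ty_px + second.ty_px
        return RigidTransform2D(self.theta_deg + second.theta_deg, tx, ty)

    def inverse(self) -> "RigidTransform2D":
        th = math.radians(-self.theta_deg)
        cos_, sin_ = math.cos(th), math.sin(th)
        tx = -(cos_ * self.tx_px - sin_ * self.ty_px)
        ty = -(sin_ * self.tx_px + cos_ * self.ty_px)
        return RigidTransform2D(-self.theta_deg, tx, ty)

    def as_dict(self) -> dict:
        return {"theta_deg": self.theta_deg, "tx_px": self.tx_px, "ty_px": self.ty_px}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform2D":
        return cls(float(d["theta_deg"]), float(d["tx_px"]), float(d["ty_px"]))


def _inverse_map(t: RigidTransform2D, shape: tuple[int, int]):
    """(matrix, offset) for scipy affine_transform in (row, col) coordinates:
    input_coord = M @ output_coord + offset, i.e. the inverse of ``t``."""
    H, W = shape
    th = math.radians(t.theta_deg)
    cos_, sin_ = math.cos(th), math.sin(th)
    # forward in (row, col): [r'; c'] = [[cos, sin], [-sin, cos]] @ [r; c]
    # about center, plus (ty, tx); inverse rotation is theta -> -theta
    minv = np.array([[cos_, -sin_], [sin_, cos_]])
    center = np.array([(H - 1) / 2.0, (W - 1) / 2.0])
    shift = np.array([t.ty_px, t.tx_px])
    offset = center - minv @ (center + shift)
    return minv, offset


def apply_transform(
    frames: np.ndarray, t: RigidTransform2D, cval: float = 0.0, order: int = 1
) -> np.ndarray:
    """Resample (H, W) or (T, H, W) data under the forward transform ``t``
    with bilinear interpolation; out-of-bounds voxels get ``cval``."""
    frames = np.asarray(frames)
    single = frames.ndim == 2
    stack = frames[None] if single else frames
    if t.is_identity:
        out = stack.copy()
    else:
        matrix, offset = _inverse_map(t, stack.shape[1:])
        out = np.empty_like(stack, dtype=float)
        for i in range(stack.shape[0]):
            out[i] = ndimage.affine_transform(
                stack[i].astype(float), matrix, offset=offset, order=order, cval=cval,
                mode="constant", prefilter=False,
            )
        out = out.astype(stack.dtype) if np.issubdtype(stack.dtype, np.floating) else out
    return out[0] if single else out


def manual_adjust(
    t: RigidTransform2D, d_theta: float = 0.0, dx: float = 0.0, dy: float = 0.0
) -> RigidTransform2D:
    """Programmatic stand-in for the manual shift/rotate step: compose an
    extra rotation/translation on top of ``t``."""
    return t.then(RigidTransform2D(d_theta, dx, dy))


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------


@dataclass
class RegistrationConfig:
    pyramid_factors: tuple[int, ...] = (4, 2, 1)
    max_iterations: tuple[int, ...] = (80, 60, 50)
    initial_step: float = 2.0  # in scaled parameter units (deg / px)
    min_step: float = 0.005
    relaxation: float = 0.5
    grad_delta: tuple[float, float, float] = (0.2, 0.2, 0.2)  # theta, tx, ty


@dataclass
class RegistrationResult:
    transform: RigidTransform2D
    final_mse: float
    initial_mse: float
    converged: bool
    diverged: bool = False
    n_evaluations: int = 0


def _downsample(img: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return img
    smoothed = ndimage.gaussian_filter(img, sigma=factor / 2.0)
    return smoothed[::factor, ::factor]


def _masked_mse(moving, fixed, ones, t: RigidTransform2D) -> float:
    warped = apply_transform(moving, t, cval=0.0)
    valid = apply_transform(ones, t, cval=0.0) > 0.999
    if valid.sum() < 0.25 * valid.size:
        return float("inf")
    diff = warped[valid] - fixed[valid]
    return float(np.mean(diff * diff))


def register_rigid(
    moving: np.ndarray,
    fixed: np.ndarray,
    init: RigidTransform2D | None = None,
    config: RegistrationConfig | None = None,
) -> RegistrationResult:
    """Find the rigid transform minimizing the MSE of moving-after-transform
    against fixed, via regular-step gradient descent from ``init`` over a
    multi-resolution pyramid.

    The MSE is evaluated on the in-bounds region only and both images are
    normalized by their means, so a global gain difference between sessions
    does not bias the optimum.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise ValueError("moving and fixed images must share dimensions")
    if not (np.all(np.isfinite(moving)) and np.all(np.isfinite(fixed))):
        raise ValueError("non-finite pixels in input images")
    cfg = config or RegistrationConfig()
    init = init or RigidTransform2D()

    moving = moving / np.mean(moving)
    fixed = fixed / np.mean(fixed)

    params = np.array([init.theta_deg, init.tx_px, init.ty_px], dtype=float)
    n_eval = 0
    initial_mse = None
    best_cost = float("inf")
    diverged = False

    for factor, max_iter in zip(cfg.pyramid_factors, cfg.max_iterations):
        mov_l = _downsample(moving, factor)
        fix_l = _downsample(fixed, factor)
        ones = np.ones_like(mov_l)
        scale = np.array([1.0, 1.0 / factor, 1.0 / factor])  # px shrink at coarse levels

        def cost(p) -> float:
            nonlocal n_eval
            n_eval += 1
            return _masked_mse(mov_l, fix_l, ones, RigidTransform2D(p[0], p[1], p[2]))

        p_l = params * scale
        current = cost(p_l)
        if initial_mse is None:
            initial_mse = current
        step = cfg.initial_step / factor if factor > 1 else cfg.initial_step
        step = max(step, 4 * cfg.min_step)
        prev_dir = None
        delta = np.asarray(cfg.grad_delta, dtype=float)

        for _ in range(max_iter):
            grad = np.zeros(3)
            for j in range(3):
                dp = np.zeros(3)
                dp[j] = delta[j]
                grad[j] = (cost(p_l + dp) - cost(p_l - dp)) / (2 * delta[j])
            gnorm = np.linalg.norm(grad)
            if not np.isfinite(gnorm) or gnorm == 0:
                break
            direction = -grad / gnorm
            if prev_dir is not None and float(direction @ prev_dir) < 0:
                step *= cfg.relaxation
            candidate = p_l + step * direction
            cand_cost = cost(candidate)
            if cand_cost < current:
                p_l = candidate
                current = cand_cost
                prev_dir = direction
            else:
                step *= cfg.relaxation
            if step < cfg.min_step:
                break

        params = p_l / scale
        best_cost = current

    final_t = RigidTransform2D(float(params[0]), float(params[1]), float(params[2]))
    final_mse = _masked_mse(moving, fixed, np.ones_like(moving), final_t)
    if initial_mse is not None and final_mse > initial_mse:
        # descent failed; report best-so-far (the init) with a warning flag
        diverged = True
        final_t = init
        final_mse = initial_mse
    return RegistrationResult(
        transform=final_t,
        final_mse=float(final_mse),
        initial_mse=float(initial_mse),
        converged=not diverged,
        diverged=diverged,
        n_evaluations=n_eval,
    )
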