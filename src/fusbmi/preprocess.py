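"""Streaming preprocessing applied before classification.

Each incoming 2 Hz power-Doppler frame enters a rolling 60-frame (30 s)
buffer; the frame is voxel-wise z-scored against that buffer (sample standard
deviation, zero-variance voxels mapped to 0) and then smoothed with a pillbox
spatial filter of 2-pixel radius.  A trial's feature vector is the last three
preprocessed frames of the memory period (1.5 s of data), flattened
frame-major, oldest first.

The streaming path and the batch path share the same per-window kernel, so
replaying a recorded session frame-by-frame yields bit-identical features to
batch extraction --- the backbone of replay determinism.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import ndimage

from .session_model import SessionRecording, TrialRecord

__all__ = [
    "PreprocessConfig",
    "RollingBuffer",
    "FeatureVector",
    "rolling_zscore",
    "pillbox_kernel",
    "pillbox_filter",
    "SessionPreprocessor",
    "preprocess_session",
    "extract_features",
    "extract_trial_features",
]


@dataclass(frozen=True)
class PreprocessConfig:
    buffer_frames: int = 60  # 30 s at 2 Hz
    zscore_ddof: int = 1
    pillbox_radius_px: int = 2
    pillbox_dialect: str = "antialiased"  # or "binary"
    boundary: str = "zero"  # zero padding at image edges
    n_feature_frames: int = 3  # last 1.5 s of the memory period
    zscore_at: str = "arrival"  # z-score decode frames at their own arrival


@dataclass
class FeatureVector:
    """Flattened (k x H x W) preprocessed intensities with provenance."""

    values: np.ndarray  # 1-D, length k*H*W
    label: object  # Direction or ComponentLabel, set by the caller
    trial_index: int
    frame_shape: tuple[int, int]
    provenance: str = "current"  # "current" | "previous"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")


class RollingBuffer:
    """FIFO buffer of the most recent <= capacity raw frames."""

    def __init__(self, capacity: int = 60, frame_shape: tuple[int, int] | None = None):
        if capacity < 2:
            raise ValueError("buffer capacity must be >= 2")
        self.capacity = int(capacity)
        self.frame_shape = tuple(frame_shape) if frame_shape else None
        self._frames: deque[np.ndarray] = deque(maxlen=self.capacity)

    def push(self, frame: np.ndarray) -> "RollingBuffer":
        frame = np.asarray(frame)
        if self.frame_shape is None:
            self.frame_shape = frame.shape
        elif frame.shape != self.frame_shape:
            raise ValueError(f"frame shape {frame.shape} != buffer shape {self.frame_shape}")
        self._frames.append(frame)
        return self

    def __len__(self) -> int:
        return len(self._frames)

    @property
    def last(self) -> np.ndarray:
        return self._frames[-1]

    def as_array(self) -> np.ndarray:
        return np.stack(self._frames)


def _zscore_window(window: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Z-score every frame of a (k, H, W) window against the window's own
    voxel-wise mean and sample sd; zero-variance voxels map to 0."""
    mean = np.mean(window, axis=0)
    sd = np.std(window, axis=0, ddof=ddof)
    z = np.zeros_like(window, dtype=float)
    ok = sd > 0
    z[:, ok] = (window[:, ok] - mean[ok]) / sd[ok]
    return z


def rolling_zscore(buf: RollingBuffer, ddof: int = 1) -> np.ndarray:
    """Z-score the buffered stack voxel-wise against the buffer statistics."""
    if len(buf) < 2:
        raise ValueError("rolling z-score needs at least 2 buffered frames")
    return _zscore_window(buf.as_array(), ddof=ddof)


@lru_cache(maxsize=8)
def pillbox_kernel(radius_px: int = 2, dialect: str = "antialiased") -> np.ndarray:
    """Disk kernel of the given radius normalized to sum 1.

    ``antialiased`` weights boundary pixels by their fractional coverage of
    the disk (the conventional pillbox); ``binary`` includes exactly the
    lattice points with dx^2 + dy^2 <= r^2 (13 pixels at radius 2).
    """
    if radius_px < 1:
        raise ValueError("pillbox radius must be >= 1")
    r = int(radius_px)
    size = 2 * r + 1
    if dialect == "binary":
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        kernel = ((yy**2 + xx**2) <= r**2).astype(float)
    elif dialect == "antialiased":
        ss = 32  # subpixel sampling per axis for coverage fractions
        sub = (np.arange(ss) + 0.5) / ss - 0.5
        kernel = np.empty((size, size))
        for i in range(size):
            for j in range(size):
                dy = (i - r) + sub[:, None]
                dx = (j - r) + sub[None, :]
                kernel[i, j] = np.mean(dy**2 + dx**2 <= r**2)
    else:
        raise ValueError(f"unknown pillbox dialect: {dialect!r}")
    kernel = kernel / kernel.sum()
    kernel.flags.writeable = False
    return kernel


def pillbox_filter(
    frame: np.ndarray, radius_px: int = 2, dialect: str = "antialiased"
) -> np.ndarray:
    """2-D convolution with the unit-sum disk kernel; zero-padded borders."""
    kernel = pillbox_kernel(radius_px, dialect)
    return ndimage.convolve(np.asarray(frame, dtype=float), kernel, mode="constant", cval=0.0)


class SessionPreprocessor:
    """Streaming z-score + pillbox pipeline over one session."""

    def __init__(self, config: PreprocessConfig | None = None):
        self.config = config or PreprocessConfig()
        self.buffer = RollingBuffer(self.config.buffer_frames)

    def process_frame(self, frame: np.ndarray) -> np.ndarray | None:
        """Push a frame; return its preprocessed version, or None while the
        buffer is cold (< 2 frames: the sample sd is undefined)."""
        self.buffer.push(frame)
        if len(self.buffer) < 2:
            return None
        z = _zscore_window(self.buffer.as_array(), ddof=self.config.zscore_ddof)[-1]
        return pillbox_filter(z, self.config.pillbox_radius_px, self.config.pillbox_dialect)


def preprocess_session(
    session: SessionRecording, config: PreprocessConfig | None = None
) -> np.ndarray:
    """Preprocess every frame by streaming it through the rolling pipeline.

    Returns a (T, H, W) stack; frame 0 (cold buffer) is NaN-filled.
    """
    config = config or PreprocessConfig()
    pre = SessionPreprocessor(config)
    out = np.full(session.frames.shape, np.nan)
    for i in range(session.n_frames):
        res = pre.process_frame(session.frames[i])
        if res is not None:
            out[i] = res
    return out


def _preprocess_at(
    frames: np.ndarray, index: int, config: PreprocessConfig
) -> np.ndarray | None:
    """Preprocessed frame ``index`` exactly as the streaming path computes it:
    z-scored against the buffer state at its own arrival, then filtered."""
    if index < 1:
        return None
    lo = max(0, index - config.buffer_frames + 1)
    window = np.stack(list(frames[lo : index + 1]))
    z = _zscore_window(window, ddof=config.zscore_ddof)[-1]
    return pillbox_filter(z, config.pillbox_radius_px, config.pillbox_dialect)


def extract_features(
    session: SessionRecording,
    trial: TrialRecord,
    config: PreprocessConfig | None = None,
    provenance: str = "current",
    return_frames: bool = False,
):
    """Feature vector for one trial: the k most recent frames with timestamp
    <= memory end, each preprocessed at its own arrival, flattened oldest
    first.  Returns None (trial not decodable) if the buffer was cold or
    fewer than k frames precede the memory end.
    """
    config = config or PreprocessConfig()
    k = config.n_feature_frames
    idx = np.flatnonzero(session.timestamps <= trial.phase_times.memory_end)
    if idx.size < k:
        return None
    sel = idx[-k:]
    if config.zscore_at == "final":
        # all k frames z-scored against the buffer state at the last frame
        last = int(sel[-1])
        if last < 1:
            return None
        lo = max(0, last - config.buffer_frames + 1)
        window = np.stack(list(session.frames[lo : last + 1]))
        z = _zscore_window(window, ddof=config.zscore_ddof)
        pos = sel - lo
        if np.any(pos < 0):
            return None
        processed = [
            pillbox_filter(z[p], config.pillbox_radius_px, config.pillbox_dialect) for p in pos
        ]
    else:
        processed = []
        for i in sel:
            res = _preprocess_at(session.frames, int(i), config)
            if res is None:
                return None
            processed.append(res)
    stack = np.stack(processed)  # (k, H, W), oldest first
    fv = FeatureVector(
        values=stack.reshape(-1),
        label=trial.cued_direction,
        trial_index=trial.index,
        frame_shape=session.shape,
        provenance=provenance,
    )
    return (fv, stack) if return_frames else fv


def extract_trial_features(
    session: SessionRecording,
    config: PreprocessConfig | None = None,
    provenance: str = "current",
    return_frames: bool = False,
) -> dict[int, object]:
    """Features for every trial of a session, keyed by trial index.

    Trials whose feature frames are unavailable (cold buffer) are omitted;
    the caller marks them invalid.
    """
    config = config or PreprocessConfig()
    out: dict[int, object] = {}
    for tr in session.trials:
        res = extract_features(session, tr, config, provenance, return_frames)
        if res is not None:
            out[tr.index] = res
    return out
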