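"""Core data types for fUS-BMI sessions.

A session is an ordered stack of 2 Hz power-Doppler frames together with a
per-trial event log from a memory-guided movement task (saccade, reach or
BMI-controlled).  Movement targets live on a ring of eight directions at 45
degree spacing; the eight-direction "multicoder" additionally factorizes each
direction into a vertical component (up / mid / down) and a horizontal
component (right / mid / left), with (mid, mid) standing for a center
prediction that is never a cue.

On disk a session is a directory holding a NIfTI-1 frame stack, a NIfTI-1
anatomical (mean power-Doppler) image, a CSV trial table and a JSON sidecar
with timestamps and task metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import NamedTuple, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Direction",
    "Vertical",
    "Horizontal",
    "ComponentLabel",
    "PERIPHERAL_DIRECTIONS",
    "VERTICAL_ORDER",
    "HORIZONTAL_ORDER",
    "decompose_direction",
    "combine_components",
    "PhaseTimes",
    "TrialRecord",
    "PowerDopplerFrame",
    "SessionRecording",
    "SessionFormatError",
    "read_session",
    "write_session",
]


class Direction(Enum):
    """Movement target direction.

    Peripheral directions carry an angle with R = 0 deg and counterclockwise
    positive (screen-up = 90 deg); only the 45 deg spacing between neighbors
    is physically meaningful.  CENTER is representable because the multicoder
    can emit it, but it is never a valid cue.
    """

    R = 0.0
    UR = 45.0
    U = 90.0
    UL = 135.0
    L = 180.0
    DL = 225.0
    D = 270.0
    DR = 315.0
    CENTER = "center"

    @property
    def is_peripheral(self) -> bool:
        return self is not Direction.CENTER

    @property
    def angle_deg(self) -> float:
        if self is Direction.CENTER:
            raise ValueError("CENTER has no direction angle")
        return float(self.value)

    def __repr__(self) -> str:  # compact in logs / dataframes
        return self.name


#: Canonical ordering of the eight cueable directions (also the decoder
#: tie-break order: R before L).
PERIPHERAL_DIRECTIONS: tuple[Direction, ...] = (
    Direction.R,
    Direction.UR,
    Direction.U,
    Direction.UL,
    Direction.L,
    Direction.DL,
    Direction.D,
    Direction.DR,
)


class Vertical(Enum):
    UP = "up"
    MID = "mid"
    DOWN = "down"

    def __repr__(self) -> str:
        return self.name


class Horizontal(Enum):
    RIGHT = "right"
    MID = "mid"
    LEFT = "left"

    def __repr__(self) -> str:
        return self.name


VERTICAL_ORDER: tuple[Vertical, ...] = (Vertical.UP, Vertical.MID, Vertical.DOWN)
HORIZONTAL_ORDER: tuple[Horizontal, ...] = (
    Horizontal.RIGHT,
    Horizontal.MID,
    Horizontal.LEFT,
)


class ComponentLabel(NamedTuple):
    """(vertical, horizontal) factorization of a direction on the 3x3 grid."""

    vertical: Vertical
    horizontal: Horizontal


_DECOMPOSE: dict[Direction, ComponentLabel] = {
    Direction.R: ComponentLabel(Vertical.MID, Horizontal.RIGHT),
    Direction.UR: ComponentLabel(Vertical.UP, Horizontal.RIGHT),
    Direction.U: ComponentLabel(Vertical.UP, Horizontal.MID),
    Direction.UL: ComponentLabel(Vertical.UP, Horizontal.LEFT),
    Direction.L: ComponentLabel(Vertical.MID, Horizontal.LEFT),
    Direction.DL: ComponentLabel(Vertical.DOWN, Horizontal.LEFT),
    Direction.D: ComponentLabel(Vertical.DOWN, Horizontal.MID),
    Direction.DR: ComponentLabel(Vertical.DOWN, Horizontal.RIGHT),
}
_COMBINE: dict[ComponentLabel, Direction] = {v: k for k, v in _DECOMPOSE.items()}
_COMBINE[ComponentLabel(Vertical.MID, Horizontal.MID)] = Direction.CENTER


def decompose_direction(d: Direction) -> ComponentLabel:
    """Split a peripheral direction into its (vertical, horizontal) components.

    Raises ``ValueError`` for CENTER, which is never a cue.
    """
    if d is Direction.CENTER:
        raise ValueError("CENTER is not a cueable direction and has no components")
    return _DECOMPOSE[d]


def combine_components(c: ComponentLabel) -> Direction:
    """Combine component predictions into a direction; (MID, MID) -> CENTER."""
    return _COMBINE[ComponentLabel(Vertical(c[0]), Horizontal(c[1]))]


# ---------------------------------------------------------------------------
# trials and sessions
# ---------------------------------------------------------------------------

_PHASE_ORDER = ("fixation", "cue_on", "cue_off", "memory_end", "movement", "reward")


@dataclass(frozen=True)
class PhaseTimes:
    """Onsets (seconds) of the task phases of one trial, in task order."""

    fixation: float
    cue_on: float
    cue_off: float
    memory_end: float
    movement: float
    reward: float

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, k) for k in _PHASE_ORDER)

    def validate(self) -> None:
        ts = self.as_tuple()
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise ValueError(f"phase times out of order: {ts}")


@dataclass
class TrialRecord:
    """One trial: cue, phase onsets, behavioral outcome and decoder output."""

    index: int  # 1-based, matching trial-number axes
    task: str  # "saccade" | "reach" | "bmi"
    cued_direction: Direction
    phase_times: PhaseTimes
    valid: bool = True
    success: bool = False
    prediction: Direction | None = None

    def validate(self) -> None:
        if self.index < 1:
            raise ValueError("trial numbering is 1-based")
        if self.cued_direction is Direction.CENTER:
            raise ValueError("CENTER cannot be cued")
        if self.success and not self.valid:
            raise ValueError("a successful trial must be valid")
        self.phase_times.validate()


@dataclass(frozen=True)
class PowerDopplerFrame:
    """A single power-Doppler image with its acquisition time."""

    pixels: np.ndarray  # (H, W), non-negative power-Doppler intensity
    timestamp: float  # seconds
    voxel_size_mm: tuple[float, float] = (0.1, 0.1)


@dataclass
class SessionRecording:
    """An ordered 2 Hz frame stack plus trial log: the unit of storage/replay."""

    frames: np.ndarray  # (T, H, W) float32
    timestamps: np.ndarray  # (T,) seconds, strictly increasing
    trials: list[TrialRecord]
    anatomy: np.ndarray  # (H, W) mean power-Doppler image for alignment
    meta: dict = field(default_factory=dict)
    voxel_size_mm: tuple[float, float] = (0.1, 0.1)

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        return (int(self.frames.shape[1]), int(self.frames.shape[2]))

    @property
    def frame_period_s(self) -> float:
        if self.n_frames < 2:
            return float(self.meta.get("frame_period_s", 0.5))
        return float(np.median(np.diff(self.timestamps)))

    def frame(self, i: int) -> PowerDopplerFrame:
        return PowerDopplerFrame(self.frames[i], float(self.timestamps[i]), self.voxel_size_mm)

    def validate(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) stack")
        if self.frames.shape[0] != self.timestamps.shape[0]:
            raise SessionFormatError(
                f"{self.frames.shape[0]} frames but {self.timestamps.shape[0]} timestamps"
            )
        if self.anatomy.shape != self.frames.shape[1:]:
            raise ValueError("anatomy image dims differ from frame dims")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        t0, t1 = float(self.timestamps[0]), float(self.timestamps[-1])
        for tr in self.trials:
            tr.validate()
            ts = tr.phase_times.as_tuple()
            if ts[0] < t0 or ts[-1] > t1:
                raise ValueError(
                    f"trial {tr.index} phase times {ts[0]:.2f}..{ts[-1]:.2f} outside "
                    f"frame range {t0:.2f}..{t1:.2f}"
                )


class SessionFormatError(ValueError):
    """Malformed on-disk session (frame/timestamp mismatch, bad CSV row...)."""


# ---------------------------------------------------------------------------
# on-disk format
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "trial",
    "task",
    "cued_direction",
    "t_fixation",
    "t_cue_on",
    "t_cue_off",
    "t_memory_end",
    "t_movement",
    "t_reward",
    "valid",
    "success",
    "prediction",
]


def _nifti_image(data_2d_or_3d: np.ndarray, voxel_size_mm, frame_period_s: float):
    """Pack (H,W[,T]) data as an H x W x 1 x T NIfTI-1 image."""
    arr = np.asarray(data_2d_or_3d, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[:, :, None, None]
    else:  # (T, H, W) -> (H, W, 1, T)
        arr = arr.transpose(1, 2, 0)[:, :, None, :]
    affine = np.diag([voxel_size_mm[0], voxel_size_mm[1], 1.0, 1.0])
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms((voxel_size_mm[0], voxel_size_mm[1], 1.0, frame_period_s))
    img.header.set_xyzt_units("mm", "sec")
    return img


def write_session(session: SessionRecording, path: str | Path) -> Path:
    """Write a session directory (frames.nii.gz, anatomy.nii.gz, events.csv,
    session.json).  Lossless for float32 pixels, timestamps and trial fields."""
    session.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    period = session.frame_period_s
    nib.save(_nifti_image(session.frames, session.voxel_size_mm, period), path / "frames.nii.gz")
    nib.save(_nifti_image(session.anatomy, session.voxel_size_mm, period), path / "anatomy.nii.gz")

    rows = []
    for tr in session.trials:
        pt = tr.phase_times
        rows.append(
            {
                "trial": tr.index,
                "task": tr.task,
                "cued_direction": tr.cued_direction.name,
                "t_fixation": pt.fixation,
                "t_cue_on": pt.cue_on,
                "t_cue_off": pt.cue_off,
                "t_memory_end": pt.memory_end,
                "t_movement": pt.movement,
                "t_reward": pt.reward,
                "valid": int(tr.valid),
                "success": int(tr.success),
                "prediction": "" if tr.prediction is None else tr.prediction.name,
            }
        )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path / "events.csv", index=False)

    sidecar = {
        "timestamps": [float(t) for t in session.timestamps],
        "voxel_size_mm": list(session.voxel_size_mm),
        "meta": _jsonable(session.meta),
    }
    (path / "session.json").write_text(json.dumps(sidecar, indent=1))
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Enum):
        return obj.name
    return obj


def _parse_trial_row(i: int, row: pd.Series) -> TrialRecord:
    try:
        cue = Direction[str(row["cued_direction"])]
        pred_raw = row["prediction"]
        pred = None
        if isinstance(pred_raw, str) and pred_raw:
            pred = Direction[pred_raw]
        elif not (pred_raw is None or (isinstance(pred_raw, float) and np.isnan(pred_raw))):
            pred = Direction[str(pred_raw)]
        tr = TrialRecord(
            index=int(row["trial"]),
            task=str(row["task"]),
            cued_direction=cue,
            phase_times=PhaseTimes(
                float(row["t_fixation"]),
                float(row["t_cue_on"]),
                float(row["t_cue_off"]),
                float(row["t_memory_end"]),
                float(row["t_movement"]),
                float(row["t_reward"]),
            ),
            valid=bool(int(row["valid"])),
            success=bool(int(row["success"])),
            prediction=pred,
        )
        tr.validate()
        return tr
    except (KeyError, ValueError, TypeError) as exc:
        raise SessionFormatError(f"events.csv row {i}: {exc}") from exc


def read_session(path: str | Path) -> SessionRecording:
    """Read a session directory written by :func:`write_session`."""
    path = Path(path)
    frames_img = nib.load(path / "frames.nii.gz")
    anat_img = nib.load(path / "anatomy.nii.gz")
    sidecar = json.loads((path / "session.json").read_text())

    arr = np.asarray(frames_img.dataobj, dtype=np.float32)  # (H, W, 1, T)
    if arr.ndim == 3:
        arr = arr[:, :, :, None]
    frames = arr[:, :, 0, :].transpose(2, 0, 1)
    anatomy = np.asarray(anat_img.dataobj, dtype=np.float32)[:, :, 0, 0]

    timestamps = np.asarray(sidecar["timestamps"], dtype=float)
    if frames.shape[0] != timestamps.shape[0]:
        raise SessionFormatError(
            f"frame stack has {frames.shape[0]} frames but sidecar lists "
            f"{timestamps.shape[0]} timestamps"
        )

    events = pd.read_csv(path / "events.csv", float_precision="round_trip")
    missing = [c for c in _CSV_COLUMNS if c not in events.columns]
    if missing:
        raise SessionFormatError(f"events.csv missing columns: {missing}")
    trials = [_parse_trial_row(i, row) for i, row in events.iterrows()]

    session = SessionRecording(
        frames=frames,
        timestamps=timestamps,
        trials=trials,
        anatomy=anatomy,
        meta=sidecar.get("meta", {}),
        voxel_size_mm=tuple(sidecar.get("voxel_size_mm", (0.1, 0.1))),
    )
    session.validate()
    return session
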