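"""Searchlight mapping of decodable information.

A circular region of interest (200 um radius = 2 voxels at 0.1 mm spacing)
slides across every voxel whose ROI fits entirely in the grid.  For each
center the trial features are restricted to the ROI voxels (all three memory
frames), the task-appropriate decoder (cPCA+LDA for two classes, PCA+LDA
multicoder for eight directions) is run under stratified 10-fold
cross-validation, and the mean fold performance (accuracy, or mean angular
error for eight targets) is assigned to the center voxel.

Significance is an artifact choice the source protocol leaves unstated: a
one-sided exact binomial tail per voxel for accuracy maps (permutation tail
for angular error), with Benjamini-Hochberg FDR q-values over scored voxels.
The overlay mask keeps the top decile of scored voxels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from . import metrics
from .decoders import cross_validate
from .session_model import Direction

__all__ = [
    "disk_offsets",
    "SearchlightMap",
    "searchlight_map",
    "voxel_significance",
    "top_decile_mask",
]


def disk_offsets(radius_px: int) -> np.ndarray:
    """Lattice offsets (dr, dc) with dr^2 + dc^2 <= r^2 (13 voxels at r=2)."""
    r = int(radius_px)
    offs = [
        (dr, dc)
        for dr in range(-r, r + 1)
        for dc in range(-r, r + 1)
        if dr * dr + dc * dc <= r * r
    ]
    return np.array(offs, dtype=int)


@dataclass
class SearchlightMap:
    score: np.ndarray  # (H, W); NaN where the ROI does not fit
    metric: str  # "accuracy" | "mean_angular_error"
    n_targets: int
    n_trials: int
    roi_radius_px: int
    folds: int
    seed: int
    p: np.ndarray | None = None
    q: np.ndarray | None = None

    @property
    def scored_mask(self) -> np.ndarray:
        return ~np.isnan(self.score)

    @property
    def n_scored(self) -> int:
        return int(self.scored_mask.sum())


def searchlight_map(
    trial_frames: np.ndarray,
    labels: list,
    n_targets: int,
    radius_px: int = 2,
    folds: int = 10,
    seed: int = 0,
    retained_variance: float = 0.95,
    shrinkage: float = 0.1,
) -> SearchlightMap:
    """Sliding-ROI cross-validated decoding map.

    ``trial_frames``: (n_trials, k, H, W) preprocessed memory-period frames;
    ``labels``: cued Direction per trial.  Fold assignment is stratified by
    class and shared across all centers, so maps are deterministic and
    independent of ROI visit order.
    """
    trial_frames = np.asarray(trial_frames, dtype=float)
    if trial_frames.ndim != 4:
        raise ValueError("trial_frames must be (n_trials, k, H, W)")
    n_trials, k, H, W = trial_frames.shape
    if len(labels) != n_trials:
        raise ValueError("labels must align with trial_frames")
    offs = disk_offsets(radius_px)
    r = int(radius_px)
    if H < 2 * r + 1 or W < 2 * r + 1:
        raise ValueError("ROI radius too large: no ROI fits inside the grid")

    kind = "cpca_lda_2class" if n_targets == 2 else "multicoder_8dir"
    names = np.array([lab.name for lab in labels])
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(n_trials), names))

    flat = trial_frames.reshape(n_trials, k, H * W)
    score = np.full((H, W), np.nan)
    for cr in range(r, H - r):
        row_idx = (cr + offs[:, 0]) * W
        for cc in range(r, W - r):
            cols = row_idx + cc + offs[:, 1]
            X = flat[:, :, cols].reshape(n_trials, -1)
            preds, _ = cross_validate(
                X, labels, kind, folds=folds, seed=seed,
                retained_variance=retained_variance, shrinkage=shrinkage, splits=splits,
            )
            if n_targets == 2:
                score[cr, cc] = float(
                    np.mean([p == lab for p, lab in zip(preds, labels)])
                )
            else:
                score[cr, cc] = float(
                    np.mean([metrics.angular_error(lab, p) for p, lab in zip(preds, labels)])
                )
    return SearchlightMap(
        score=score,
        metric="accuracy" if n_targets == 2 else "mean_angular_error",
        n_targets=n_targets,
        n_trials=n_trials,
        roi_radius_px=r,
        folds=folds,
        seed=seed,
    )


def voxel_significance(
    smap: SearchlightMap,
    permutation_replicates: int = 10_000,
    seed: int = 0,
) -> SearchlightMap:
    """Attach per-voxel one-sided p-values and Benjamini-Hochberg q-values.

    Accuracy maps use the exact binomial tail at chance 1/n_targets; angular
    error maps use the permutation null of the cumulative mean error.
    """
    mask = smap.scored_mask
    scores = smap.score[mask]
    n = smap.n_trials
    if smap.metric == "accuracy":
        k = np.round(scores * n).astype(int)
        ps = stats.binom.sf(k - 1, n, 1.0 / smap.n_targets)
    else:
        # same null as metrics.permutation_envelope, evaluated at length n
        rng = np.random.default_rng(seed)
        null = rng.choice(
            metrics.ANGULAR_ERROR_VALUES,
            size=(permutation_replicates, n),
            p=metrics.ANGULAR_ERROR_PROBS,
        ).mean(axis=1)
        ps = np.array([(1 + np.sum(null <= s)) / (len(null) + 1) for s in scores])
    qs = stats.false_discovery_control(ps, method="bh")
    p_map = np.full(smap.score.shape, np.nan)
    q_map = np.full(smap.score.shape, np.nan)
    p_map[mask] = ps
    q_map[mask] = qs
    smap.p = p_map
    smap.q = q_map
    return smap


def top_decile_mask(smap: SearchlightMap, fraction: float = 0.10) -> np.ndarray:
    """Boolean mask of the ceil(fraction * n_scored) best-scoring voxels
    (highest accuracy / lowest angular error); ties break by p-value then
    fixed scan order, so the mask is rank-based and scale-invariant."""
    mask = smap.scored_mask
    n_keep = int(math.ceil(fraction * smap.n_scored))
    rows, cols = np.nonzero(mask)
    scores = smap.score[mask]
    goodness = scores if smap.metric == "accuracy" else -scores
    pvals = smap.p[mask] if smap.p is not None else np.zeros_like(scores)
    scan = np.arange(scores.size)
    # sort best first: highest goodness, then smallest p, then scan order
    order = np.lexsort((scan, pvals, -goodness))
    keep = order[:n_keep]
    out = np.zeros(smap.score.shape, dtype=bool)
    out[rows[keep], cols[keep]] = True
    return out
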