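"""Movement-intention classifiers.

Two-class decoding (e.g. left vs right) uses class-wise PCA (cPCA): a
principal subspace is fit per class at 95% retained within-class variance,
the per-class bases are pooled and orthonormalized, features are projected
onto the pooled subspace and a regularized LDA separates the classes.

Eight-direction decoding uses the "multicoder": the vertical (up/mid/down)
and horizontal (right/mid/left) movement components are predicted by two
independent pooled-PCA + 3-class LDA models trained on the same feature
vectors, and the component predictions combine into one of the eight
peripheral directions --- or CENTER when both components come out mid, which
is never a cue and therefore never correct.

LDA uses shrinkage regularization (default 0.1 toward the diagonal) because
early in online training the number of trials is far below the feature
dimension even after reduction.  Score ties break by fixed class order
(R before L; UP before MID before DOWN) for determinism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from .preprocess import FeatureVector
from .session_model import (
    HORIZONTAL_ORDER,
    PERIPHERAL_DIRECTIONS,
    VERTICAL_ORDER,
    ComponentLabel,
    Direction,
    Horizontal,
    Vertical,
    combine_components,
    decompose_direction,
)

__all__ = [
    "TrainingSet",
    "ComponentModel",
    "DecoderModel",
    "fit_cpca_lda",
    "fit_pca_lda_3class",
    "fit_multicoder",
    "cross_validate",
    "save_model",
    "load_model",
]


class TrainingSet:
    """Labeled feature vectors with class-balance bookkeeping."""

    def __init__(self, vectors: list[FeatureVector] | None = None):
        self.vectors: list[FeatureVector] = []
        for v in vectors or []:
            self.add(v)

    def add(self, fv: FeatureVector) -> None:
        if self.vectors and fv.values.shape[0] != self.dim:
            raise ValueError(
                f"feature dimension {fv.values.shape[0]} != training set dim {self.dim}"
            )
        self.vectors.append(fv)

    def __len__(self) -> int:
        return len(self.vectors)

    @property
    def dim(self) -> int:
        if not self.vectors:
            raise ValueError("empty training set has no dimension")
        return int(self.vectors[0].values.shape[0])

    @property
    def X(self) -> np.ndarray:
        return np.stack([v.values for v in self.vectors])

    @property
    def labels(self) -> list:
        return [v.label for v in self.vectors]

    def class_counts(self) -> dict:
        counts: dict = {}
        for v in self.vectors:
            counts[v.label] = counts.get(v.label, 0) + 1
        return counts

    def provenance_counts(self) -> dict:
        counts: dict = {}
        for v in self.vectors:
            counts[v.provenance] = counts.get(v.provenance, 0) + 1
        return counts


# ---------------------------------------------------------------------------
# subspace helpers
# ---------------------------------------------------------------------------


def retained_components(X: np.ndarray, retained_variance: float = 0.95):
    """Principal axes of ``X`` (rows = samples) keeping the smallest leading
    set of eigenvalues whose cumulative sum reaches the retained-variance
    target.  Returns (components (D, k), mean (D,), retained fraction)."""
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    Xc = X - mean
    n, D = Xc.shape
    if n <= D:
        # n << D throughout online training: eigendecompose the n x n Gram
        # matrix instead of the n x D SVD (same spectrum, much cheaper)
        gram = Xc @ Xc.T
        evals, evecs = np.linalg.eigh(gram)
        evals = evals[::-1]
        evecs = evecs[:, ::-1]
        evals = np.clip(evals, 0.0, None)
    else:
        _, s, vt = np.linalg.svd(Xc, full_matrices=False)
        evals = s**2
    total = evals.sum()
    if total <= 0:  # all samples identical: keep one trivial axis
        basis = np.zeros((D, 1))
        basis[0, 0] = 1.0
        return basis, mean, 1.0
    cum = np.cumsum(evals) / total
    k = int(np.searchsorted(cum, retained_variance - 1e-12) + 1)
    k = min(k, int(np.sum(evals > total * 1e-12)))
    k = max(k, 1)
    if n <= D:
        comps = Xc.T @ (evecs[:, :k] / np.sqrt(evals[:k]))
    else:
        comps = vt[:k].T
    return comps, mean, float(cum[k - 1])


def _orthonormal_union(bases: list[np.ndarray]) -> np.ndarray:
    """QR-orthonormalize the pooled per-class bases, dropping rank-deficient
    columns."""
    stacked = np.hstack(bases)
    q, r = np.linalg.qr(stacked)
    keep = np.abs(np.diag(r)) > 1e-10
    return q[:, keep]


def _fit_lda(Z: np.ndarray, y: np.ndarray, n_classes: int, shrinkage: float):
    """LDA discriminant weights on the reduced features.

    Gaussian classes with a shared covariance: the pooled within-class
    covariance (prior-weighted, shrunk toward ``trace(S)/p * I`` by the
    shrinkage coefficient) gives linear scores
    ``z @ cov^-1 mu_k - 0.5 mu_k' cov^-1 mu_k + log prior_k``.
    Returns (coef (n_classes, p), intercept (n_classes,)).
    """
    n, p = Z.shape
    counts = np.bincount(y, minlength=n_classes).astype(float)
    priors = counts / n
    means = np.stack([Z[y == k].mean(axis=0) for k in range(n_classes)])
    cov = np.zeros((p, p))
    for k in range(n_classes):
        Xk = Z[y == k] - means[k]
        S = (Xk.T @ Xk) / counts[k]
        if shrinkage and shrinkage > 0:
            mu = np.trace(S) / p
            S = (1.0 - shrinkage) * S
            S[np.diag_indices(p)] += shrinkage * mu
        cov += priors[k] * S
    try:
        coef = np.linalg.solve(cov, means.T).T
    except np.linalg.LinAlgError:
        coef = np.linalg.lstsq(cov, means.T, rcond=None)[0].T
    intercept = -0.5 * np.einsum("kp,kp->k", means, coef) + np.log(priors)
    return coef, intercept


@dataclass
class ComponentModel:
    """One reduction + LDA stage: either the 2-class cPCA+LDA decoder or a
    3-class axis model of the multicoder."""

    classes: list  # canonical order; LDA scores index into this
    basis: np.ndarray  # (D, r) orthonormal projection
    mean: np.ndarray | None  # center before projecting (pooled PCA) or None (cPCA)
    lda_coef: np.ndarray  # (n_classes, r)
    lda_intercept: np.ndarray  # (n_classes,)
    retained_fraction: dict = field(default_factory=dict)
    reduction: str = "cpca"  # "cpca" | "pca"

    @property
    def dim(self) -> int:
        return int(self.basis.shape[0])

    def project(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.mean is not None:
            x = x - self.mean
        return x @ self.basis

    def scores(self, x: np.ndarray) -> np.ndarray:
        z = self.project(x)
        return z @ self.lda_coef.T + self.lda_intercept

    def predict(self, x: np.ndarray):
        s = self.scores(x)
        return self.classes[int(np.argmax(s))]  # first max wins = fixed order


def _canonical_sort(labels, order) -> list:
    pos = {lab: i for i, lab in enumerate(order)}
    return sorted(set(labels), key=lambda lab: pos[lab])


def _check_counts(y, classes, min_per_class: int) -> None:
    for c in classes:
        n = sum(1 for lab in y if lab == c)
        if n < min_per_class:
            raise ValueError(f"class {c!r} has {n} samples; needs >= {min_per_class}")


def fit_cpca_lda(
    ts: TrainingSet, retained_variance: float = 0.95, shrinkage: float = 0.1
) -> "DecoderModel":
    """Two-class cPCA + LDA.

    Per class, the principal axes retaining 95% of that class's variance are
    computed; features are projected onto the orthonormalized union of the
    class bases; a single LDA is fit on the projections.
    """
    labels = ts.labels
    classes = _canonical_sort(labels, PERIPHERAL_DIRECTIONS)
    if len(classes) != 2:
        raise ValueError(f"cPCA+LDA decoder needs exactly 2 classes, got {classes}")
    _check_counts(labels, classes, 2)
    X = ts.X
    y = np.array([classes.index(lab) for lab in labels])

    bases, retained = [], {}
    for ci, c in enumerate(classes):
        basis_c, _, frac = retained_components(X[y == ci], retained_variance)
        bases.append(basis_c)
        retained[c.name] = frac
    Q = _orthonormal_union(bases)
    Z = X @ Q
    coef, intercept = _fit_lda(Z, y, 2, shrinkage)
    component = ComponentModel(
        classes=classes, basis=Q, mean=None, lda_coef=coef, lda_intercept=intercept,
        retained_fraction=retained, reduction="cpca",
    )
    return DecoderModel(
        kind="cpca_lda_2class",
        primary=component,
        n_train=len(ts),
        config={"retained_variance": retained_variance, "shrinkage": shrinkage},
    )


def fit_pca_lda_3class(
    ts: TrainingSet,
    axis: str,
    retained_variance: float = 0.95,
    shrinkage: float = 0.1,
) -> ComponentModel:
    """Pooled PCA to 95% variance + 3-class LDA for one multicoder axis.

    ``ts`` labels must be ComponentLabel; ``axis`` selects vertical or
    horizontal.
    """
    if axis not in ("vertical", "horizontal"):
        raise ValueError("axis must be 'vertical' or 'horizontal'")
    order = VERTICAL_ORDER if axis == "vertical" else HORIZONTAL_ORDER
    axis_labels = [getattr(lab, axis) for lab in ts.labels]
    classes = _canonical_sort(axis_labels, order)
    if len(classes) != 3:
        missing = [c for c in order if c not in classes]
        raise ValueError(f"axis {axis!r} is missing labels {missing}")
    _check_counts(axis_labels, classes, 2)

    X = ts.X
    y = np.array([classes.index(lab) for lab in axis_labels])
    basis, mean, frac = retained_components(X, retained_variance)
    Z = (X - mean) @ basis
    coef, intercept = _fit_lda(Z, y, 3, shrinkage)
    return ComponentModel(
        classes=classes, basis=basis, mean=mean, lda_coef=coef, lda_intercept=intercept,
        retained_fraction={"pooled": frac}, reduction="pca",
    )


def fit_multicoder(
    ts: TrainingSet, retained_variance: float = 0.95, shrinkage: float = 0.1
) -> "DecoderModel":
    """Eight-direction multicoder: vertical and horizontal 3-class models fit
    on the same feature vectors via the direction decomposition."""
    for lab in ts.labels:
        if not isinstance(lab, Direction):
            raise ValueError("multicoder training labels must be Directions")
    comp_ts = TrainingSet()
    for v in ts.vectors:
        fv = FeatureVector(
            values=v.values, label=decompose_direction(v.label),
            trial_index=v.trial_index, frame_shape=v.frame_shape, provenance=v.provenance,
        )
        comp_ts.add(fv)
    vertical = fit_pca_lda_3class(comp_ts, "vertical", retained_variance, shrinkage)
    horizontal = fit_pca_lda_3class(comp_ts, "horizontal", retained_variance, shrinkage)
    return DecoderModel(
        kind="multicoder_8dir",
        primary=vertical,
        secondary=horizontal,
        n_train=len(ts),
        config={"retained_variance": retained_variance, "shrinkage": shrinkage},
    )


@dataclass
class DecoderModel:
    """A fitted decoder: a single 2-class model or a multicoder pair."""

    kind: str  # "cpca_lda_2class" | "multicoder_8dir"
    primary: ComponentModel  # the 2-class model, or the vertical axis model
    secondary: ComponentModel | None = None  # horizontal axis model
    n_train: int = 0
    config: dict = field(default_factory=dict)

    @property
    def dim(self) -> int:
        return self.primary.dim

    def predict(self, values: np.ndarray) -> Direction:
        return self.predict_with_scores(values)[0]

    def predict_with_scores(self, values: np.ndarray):
        """Predicted direction plus per-class LDA scores.

        For the multicoder the vertical and horizontal argmaxes are taken
        independently and combined; (MID, MID) yields CENTER.
        """
        values = np.asarray(values, dtype=float).ravel()
        if values.shape[0] != self.dim:
            raise ValueError(f"feature dimension {values.shape[0]} != model dim {self.dim}")
        if self.kind == "cpca_lda_2class":
            s = self.primary.scores(values)
            pred = self.primary.classes[int(np.argmax(s))]
            scores = {c: float(v) for c, v in zip(self.primary.classes, s)}
            return pred, scores
        sv = self.primary.scores(values)
        sh = self.secondary.scores(values)
        v = self.primary.classes[int(np.argmax(sv))]
        h = self.secondary.classes[int(np.argmax(sh))]
        pred = combine_components(ComponentLabel(v, h))
        scores = {
            **{c: float(x) for c, x in zip(self.primary.classes, sv)},
            **{c: float(x) for c, x in zip(self.secondary.classes, sh)},
        }
        return pred, scores


def _fit_for_kind(ts: TrainingSet, kind: str, retained_variance=0.95, shrinkage=0.1):
    if kind == "cpca_lda_2class":
        return fit_cpca_lda(ts, retained_variance, shrinkage)
    if kind == "multicoder_8dir":
        return fit_multicoder(ts, retained_variance, shrinkage)
    raise ValueError(f"unknown decoder kind {kind!r}")


def cross_validate(
    X: np.ndarray,
    labels: list,
    kind: str,
    folds: int = 10,
    seed: int = 0,
    retained_variance: float = 0.95,
    shrinkage: float = 0.1,
    splits: list[tuple[np.ndarray, np.ndarray]] | None = None,
):
    """Stratified k-fold cross-validated predictions.

    Returns (predictions aligned with ``labels``, fold assignment).  Runs the
    same reduction + LDA cores as the model-fitting path on bare arrays, so
    the searchlight's per-ROI loop stays fast and a searchlight ROI covering
    the whole image reproduces whole-image CV decoding.
    """
    from sklearn.model_selection import StratifiedKFold

    X = np.asarray(X, dtype=float)
    labels = list(labels)
    n = len(labels)
    if splits is None:
        names = np.array([getattr(lab, "name", str(lab)) for lab in labels])
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(skf.split(np.zeros(n), names))

    preds: list = [None] * n
    fold_of = np.full(n, -1, dtype=int)

    if kind == "cpca_lda_2class":
        classes = _canonical_sort(labels, PERIPHERAL_DIRECTIONS)
        if len(classes) != 2:
            raise ValueError(f"cPCA+LDA decoder needs exactly 2 classes, got {classes}")
        y = np.array([classes.index(lab) for lab in labels])
        for f, (tr, te) in enumerate(splits):
            Xtr, ytr = X[tr], y[tr]
            if np.bincount(ytr, minlength=2).min() < 2:
                raise ValueError("a training fold has a class with < 2 samples")
            bases = [retained_components(Xtr[ytr == k], retained_variance)[0] for k in (0, 1)]
            Q = _orthonormal_union(bases)
            coef, icp = _fit_lda(Xtr @ Q, ytr, 2, shrinkage)
            scores = (X[te] @ Q) @ coef.T + icp
            for i, s in zip(te, scores):
                preds[i] = classes[int(np.argmax(s))]
                fold_of[i] = f
    elif kind == "multicoder_8dir":
        comps = [decompose_direction(lab) for lab in labels]
        yv = np.array([VERTICAL_ORDER.index(c.vertical) for c in comps])
        yh = np.array([HORIZONTAL_ORDER.index(c.horizontal) for c in comps])
        for f, (tr, te) in enumerate(splits):
            Xtr = X[tr]
            if min(np.bincount(yv[tr], minlength=3).min(),
                   np.bincount(yh[tr], minlength=3).min()) < 2:
                raise ValueError("a training fold misses a component class")
            basis, mean, _ = retained_components(Xtr, retained_variance)
            Ztr = (Xtr - mean) @ basis
            cv_, iv_ = _fit_lda(Ztr, yv[tr], 3, shrinkage)
            ch_, ih_ = _fit_lda(Ztr, yh[tr], 3, shrinkage)
            Zte = (X[te] - mean) @ basis
            sv = Zte @ cv_.T + iv_
            sh = Zte @ ch_.T + ih_
            for i, vrow, hrow in zip(te, sv, sh):
                v = VERTICAL_ORDER[int(np.argmax(vrow))]
                h = HORIZONTAL_ORDER[int(np.argmax(hrow))]
                preds[i] = combine_components(ComponentLabel(v, h))
                fold_of[i] = f
    else:
        raise ValueError(f"unknown decoder kind {kind!r}")
    return preds, fold_of


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _write_component(grp: h5py.Group, comp: ComponentModel) -> None:
    grp.attrs["classes"] = json.dumps([c.name for c in comp.classes])
    grp.attrs["class_type"] = type(comp.classes[0]).__name__
    grp.attrs["reduction"] = comp.reduction
    grp.attrs["retained_fraction"] = json.dumps(comp.retained_fraction)
    grp.create_dataset("basis", data=comp.basis)
    if comp.mean is not None:
        grp.create_dataset("mean", data=comp.mean)
    grp.create_dataset("lda_coef", data=comp.lda_coef)
    grp.create_dataset("lda_intercept", data=comp.lda_intercept)


_CLASS_TYPES = {"Direction": Direction, "Vertical": Vertical, "Horizontal": Horizontal}


def _read_component(grp: h5py.Group) -> ComponentModel:
    cls = _CLASS_TYPES[grp.attrs["class_type"]]
    classes = [cls[name] for name in json.loads(grp.attrs["classes"])]
    return ComponentModel(
        classes=classes,
        basis=np.asarray(grp["basis"]),
        mean=np.asarray(grp["mean"]) if "mean" in grp else None,
        lda_coef=np.asarray(grp["lda_coef"]),
        lda_intercept=np.asarray(grp["lda_intercept"]),
        retained_fraction=json.loads(grp.attrs["retained_fraction"]),
        reduction=str(grp.attrs["reduction"]),
    )


def save_model(model: DecoderModel, path) -> None:
    """Persist a fitted decoder to HDF5 (bases, LDA weights, labels, config)."""
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = model.kind
        f.attrs["n_train"] = model.n_train
        f.attrs["config"] = json.dumps(model.config)
        _write_component(f.create_group("primary"), model.primary)
        if model.secondary is not None:
            _write_component(f.create_group("secondary"), model.secondary)


def load_model(path) -> DecoderModel:
    with h5py.File(path, "r") as f:
        return DecoderModel(
            kind=str(f.attrs["kind"]),
            primary=_read_component(f["primary"]),
            secondary=_read_component(f["secondary"]) if "secondary" in f else None,
            n_train=int(f.attrs["n_train"]),
            config=json.loads(f.attrs["config"]),
        )
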