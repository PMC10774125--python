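"""cPCA+LDA, pooled PCA+LDA and the eight-direction multicoder."""

import numpy as np
import pytest

from fusbmi import Direction, PERIPHERAL_DIRECTIONS, binomial_envelope
from fusbmi.decoders import (
    ComponentModel,
    TrainingSet,
    _fit_lda,
    cross_validate,
    fit_cpca_lda,
    fit_multicoder,
    fit_pca_lda_3class,
    load_model,
    retained_components,
    save_model,
)
from fusbmi.preprocess import FeatureVector
from fusbmi.session_model import ComponentLabel, decompose_direction


def _ts(X, labels):
    return TrainingSet(
        [
            FeatureVector(values=x, label=lab, trial_index=i, frame_shape=(0, 0))
            for i, (x, lab) in enumerate(zip(X, labels), start=1)
        ]
    )


def _two_clouds(rng, n=100, d=300, sep=8.0):
    mu = rng.standard_normal(d)
    mu *= sep / np.linalg.norm(mu)
    X = np.vstack([rng.standard_normal((n, d)) - mu / 2, rng.standard_normal((n, d)) + mu / 2])
    labels = [Direction.L] * n + [Direction.R] * n
    return X, labels


class TestRetainedComponents:
    def test_spike_spectrum_keeps_one_component(self, rng):
        """Eigenvalue bookkeeping: spectrum (100, 1, 1, 1, 1) retains a
        single axis at the 95% target (100/104 > 0.95)."""
        n, d = 12, 40
        A = rng.standard_normal((n, 5))
        A -= A.mean(axis=0)
        Q, _ = np.linalg.qr(A)  # orthonormal, mean-zero columns
        V, _ = np.linalg.qr(rng.standard_normal((d, 5)))
        X = Q @ np.diag(np.sqrt([100.0, 1, 1, 1, 1])) @ V.T
        basis, mean, frac = retained_components(X, 0.95)
        assert basis.shape[1] == 1
        assert frac >= 100.0 / 104.0 - 1e-9

    def test_rank_bound(self, rng):
        X = rng.standard_normal((7, 50))
        basis, _, _ = retained_components(X, 0.95)
        assert basis.shape[1] <= 6  # <= n - 1 after centering

    def test_retained_fraction_meets_target(self, rng):
        X = rng.standard_normal((30, 80))
        _, _, frac = retained_components(X, 0.95)
        assert frac >= 0.95


class TestCpcaLda:
    def test_separated_clouds_decoded_above_95(self, rng):
        X, labels = _two_clouds(rng)
        preds, _ = cross_validate(X, labels, "cpca_lda_2class", folds=10, seed=0)
        acc = np.mean([p is lab for p, lab in zip(preds, labels)])
        assert acc >= 0.95

    def test_no_signal_stays_at_chance(self, rng):
        X, labels = _two_clouds(rng, sep=0.0)
        preds, _ = cross_validate(X, labels, "cpca_lda_2class", folds=10, seed=0)
        acc = np.mean([p is lab for p, lab in zip(preds, labels)])
        low, high = binomial_envelope(len(labels), 0.5)
        assert low <= acc <= high

    def test_class_with_one_sample_rejected(self, rng):
        X = rng.standard_normal((3, 10))
        ts = _ts(X, [Direction.L, Direction.L, Direction.R])
        with pytest.raises(ValueError, match="needs >= 2"):
            fit_cpca_lda(ts)

    def test_dimension_mismatch_rejected(self, rng):
        X, labels = _two_clouds(rng, n=5, d=20)
        model = fit_cpca_lda(_ts(X, labels))
        with pytest.raises(ValueError, match="dimension"):
            model.predict(np.zeros(19))

    def test_retained_variance_invariant(self, rng):
        X, labels = _two_clouds(rng, n=30, d=100)
        model = fit_cpca_lda(_ts(X, labels))
        assert all(v >= 0.95 for v in model.primary.retained_fraction.values())


class TestPcaLda3Class:
    @staticmethod
    def _component_sets(rng, n=60, d=60, sep=8.0):
        verts = [ComponentLabel(v, h) for v in
                 (decompose_direction(Direction.U).vertical,
                  decompose_direction(Direction.R).vertical,
                  decompose_direction(Direction.D).vertical)
                 for h in [decompose_direction(Direction.R).horizontal]]
        # three collinear separated clusters along one axis
        axis = rng.standard_normal(d)
        axis /= np.linalg.norm(axis)
        X, labels = [], []
        for k, lab in enumerate(verts):
            X.append(rng.standard_normal((n // 3, d)) + (k - 1) * sep * axis)
            labels += [lab] * (n // 3)
        return np.vstack(X), labels

    def test_collinear_clusters_separated(self, rng):
        X, labels = self._component_sets(rng)
        model = fit_pca_lda_3class(_ts(X, labels), "vertical")
        preds = [model.predict(x) for x in X]
        acc = np.mean([p == lab.vertical for p, lab in zip(preds, labels)])
        assert acc >= 0.95

    def test_shuffled_labels_near_chance(self, rng):
        X, labels = self._component_sets(rng)
        shuffled = list(labels)
        rng.shuffle(shuffled)
        model = fit_pca_lda_3class(_ts(X[::2], shuffled[::2]), "vertical")
        preds = [model.predict(x) for x in X[1::2]]
        acc = np.mean([p == lab.vertical for p, lab in zip(preds, shuffled[1::2])])
        assert acc <= binomial_envelope(len(preds), 1.0 / 3.0)[1]

    def test_missing_axis_label_rejected(self, rng):
        X = rng.standard_normal((8, 10))
        labels = [decompose_direction(Direction.U)] * 4 + [decompose_direction(Direction.D)] * 4
        with pytest.raises(ValueError, match="missing"):
            fit_pca_lda_3class(_ts(X, labels), "vertical")

    def test_pca_dimension_bounded_by_rank(self, rng):
        X, labels = self._component_sets(rng, n=9, d=50)
        model = fit_pca_lda_3class(_ts(X, labels), "vertical")
        assert model.basis.shape[1] <= len(labels) - 1


class TestMulticoder:
    @staticmethod
    def _directional_data(rng, per_dir=6, d=80, scale=8.0):
        """Each direction's mean encodes (cos, sin) in two random axes."""
        b1, b2 = np.linalg.qr(rng.standard_normal((d, 2)))[0].T
        X, labels = [], []
        for direction in PERIPHERAL_DIRECTIONS:
            ang = np.deg2rad(direction.angle_deg)
            mu = scale * (np.cos(ang) * b1 + np.sin(ang) * b2)
            X.append(rng.standard_normal((per_dir, d)) + mu)
            labels += [direction] * per_dir
        return np.vstack(X), labels

    def test_axis_class_counts_for_balanced_set(self, rng):
        X, labels = self._directional_data(rng, per_dir=2)
        ts = _ts(X, labels)
        model = fit_multicoder(ts)
        # 3 directions map to UP, 2 to MID, 3 to DOWN (and mirrored for L/R)
        verts = [decompose_direction(lab).vertical for lab in labels]
        counts = {v: verts.count(v) for v in set(verts)}
        assert sorted(counts.values()) == [4, 6, 6]
        assert model.secondary is not None

    def test_combined_equals_independent_component_argmaxes(self, rng):
        from fusbmi.session_model import combine_components

        X, labels = self._directional_data(rng)
        model = fit_multicoder(_ts(X, labels))
        for x in X[::5]:
            v = model.primary.predict(x)
            h = model.secondary.predict(x)
            assert model.predict(x) is combine_components(ComponentLabel(v, h))

    def test_strong_tuning_decodes_above_chance(self, rng):
        X, labels = self._directional_data(rng)
        preds, _ = cross_validate(X, labels, "multicoder_8dir", folds=6, seed=0)
        acc = np.mean([p is lab for p, lab in zip(preds, labels)])
        assert acc > binomial_envelope(len(labels), 1 / 8)[1]

    def test_center_prediction_possible(self, rng):
        """A feature vector at the task center (equidistant from all tuned
        means) comes out (MID, MID), i.e. CENTER, despite CENTER never being
        a cue."""
        X, labels = self._directional_data(rng, per_dir=8)
        model = fit_multicoder(_ts(X, labels))
        assert model.predict(np.zeros(X.shape[1])) is Direction.CENTER

    def test_serialization_round_trip(self, rng, tmp_path):
        X, labels = self._directional_data(rng)
        model = fit_multicoder(_ts(X, labels))
        save_model(model, tmp_path / "m.h5")
        back = load_model(tmp_path / "m.h5")
        probe = rng.standard_normal((20, X.shape[1]))
        assert [model.predict(x) for x in probe] == [back.predict(x) for x in probe]
        assert back.kind == "multicoder_8dir" and back.n_train == len(labels)


class TestLdaAgainstSklearn:
    """Dual-route check: the in-package shrinkage LDA must match sklearn's
    lsqr+shrinkage solver (the established implementation) on scores."""

    @pytest.mark.parametrize("n_classes,shrinkage", [(2, 0.1), (3, 0.1), (3, 0.4)])
    def test_scores_match(self, rng, n_classes, shrinkage):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        Z = rng.standard_normal((45, 12))
        y = rng.integers(0, n_classes, 45)
        coef, icp = _fit_lda(Z, y, n_classes, shrinkage)
        sk = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage).fit(Z, y)
        mine = np.argmax(Z @ coef.T + icp, axis=1)
        assert np.array_equal(mine, sk.predict(Z))
        if n_classes > 2:
            assert np.allclose(Z @ coef.T + icp, Z @ sk.coef_.T + sk.intercept_)


class TestLabelPermutationChance:
    def test_shuffled_labels_inside_chance_envelope(self, rng):
        """Mean CV accuracy over label shuffles falls within the binomial
        chance envelope."""
        X, labels = _two_clouds(rng, n=30, d=60, sep=6.0)
        accs = []
        for _ in range(8):
            shuffled = list(labels)
            rng.shuffle(shuffled)
            preds, _ = cross_validate(X, shuffled, "cpca_lda_2class", folds=5, seed=0)
            accs.append(np.mean([p is lab for p, lab in zip(preds, shuffled)]))
        low, high = binomial_envelope(len(labels) * 8, 0.5)
        assert low <= np.mean(accs) <= high
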