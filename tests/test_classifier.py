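"""Pixel MLP: learning behavior, determinism, serialization, probability maps."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone
from sklearn.metrics import roc_auc_score
from sklearn.neural_network import MLPClassifier

from mmpol.classifier import (
    PixelMLP,
    TrainConfig,
    _sigmoid,
    load_model,
    probability_map,
    save_model,
    train,
)
from mmpol.features import build_feature_table
from mmpol.phantom import CohortConfig, generate_cohort


def two_clusters(n=2000, d=10, sep=6.0, seed=0):
    """Linearly separable toy problem: two Gaussian clusters sep sds apart."""
    rng = np.random.default_rng(seed)
    half = n // 2
    X = np.vstack(
        [rng.normal(0.0, 1.0, (half, d)), rng.normal(sep / np.sqrt(d), 1.0, (half, d))]
    )
    y = np.repeat([0.0, 1.0], half)
    order = rng.permutation(n)
    return X[order], y[order]


class TestLearning:
    def test_separable_clusters_reach_high_auc(self):
        X, y = two_clusters(seed=1)
        X_test, y_test = two_clusters(seed=2)
        model = PixelMLP(random_state=0).fit(X, y)
        auc = roc_auc_score(y_test, model.predict_proba(X_test)[:, 1])
        assert auc > 0.99

    def test_pure_noise_stays_near_chance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(2000, 10))
        y = np.repeat([0.0, 1.0], 1000)
        X_test = rng.normal(size=(2000, 10))
        y_test = np.repeat([0.0, 1.0], 1000)
        model = PixelMLP(random_state=0).fit(X, y)
        auc = roc_auc_score(y_test, model.predict_proba(X_test)[:, 1])
        assert abs(auc - 0.5) < 0.07

    def test_loss_decreases_over_training(self):
        X, y = two_clusters(seed=4)
        model = PixelMLP(random_state=0).fit(X, y)
        assert model.loss_curve_[-1] <= model.loss_curve_[0]
        assert len(model.loss_curve_) == model.epochs

    def test_agrees_with_independent_mlp_implementation(self):
        """Cross-check: sklearn's MLP with the same architecture also solves it."""
        X, y = two_clusters(seed=5)
        X_test, y_test = two_clusters(seed=6)
        ours = PixelMLP(random_state=0).fit(X, y)
        theirs = MLPClassifier(
            hidden_layer_sizes=(64,),
            activation="relu",
            solver="adam",
            learning_rate_init=1e-3,
            max_iter=200,
            random_state=0,
        ).fit(X, y)
        auc_ours = roc_auc_score(y_test, ours.predict_proba(X_test)[:, 1])
        auc_theirs = roc_auc_score(y_test, theirs.predict_proba(X_test)[:, 1])
        assert auc_ours > 0.99 and auc_theirs > 0.99


class TestDeterminismAndValidation:
    def test_same_seed_identical_parameters(self):
        X, y = two_clusters(n=600, seed=7)
        a = PixelMLP(random_state=42).fit(X, y)
        b = PixelMLP(random_state=42).fit(X, y)
        for wa, wb in zip(a.coefs_, b.coefs_):
            assert np.array_equal(wa, wb)
        c = PixelMLP(random_state=43).fit(X, y)
        assert not np.array_equal(a.coefs_[0], c.coefs_[0])

    def test_single_class_rejected(self):
        X = np.zeros((10, 3))
        with pytest.raises(ValueError):
            PixelMLP().fit(X, np.zeros(10))

    def test_nan_features_rejected(self):
        X, y = two_clusters(n=100, seed=0)
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            PixelMLP().fit(X, y)

    def test_dimension_mismatch_rejected(self):
        X, y = two_clusters(n=200, d=5, seed=0)
        model = PixelMLP(random_state=0).fit(X, y)
        with pytest.raises(ValueError):
            model.predict_proba(np.zeros((3, 7)))

    def test_sklearn_protocol(self):
        model = PixelMLP(hidden_units=8, epochs=2)
        params = model.get_params()
        assert params["hidden_units"] == 8
        cloned = clone(model)
        assert cloned.get_params() == params


class TestPredictProba:
    def test_probabilities_bounded_and_consistent(self):
        X, y = two_clusters(n=400, seed=8)
        model = PixelMLP(random_state=0).fit(X, y)
        proba = model.predict_proba(X)
        assert (proba >= 0).all() and (proba <= 1).all()
        assert np.allclose(proba.sum(axis=1), 1.0)
        dup = model.predict_proba(np.vstack([X[0], X[0]]))
        assert dup[0, 1] == dup[1, 1]

    def test_zero_weight_model_outputs_sigmoid_bias(self):
        model = PixelMLP()
        model.coefs_ = [np.zeros((4, 3)), np.zeros((3, 1))]
        model.intercepts_ = [np.zeros(3), np.array([0.7])]
        model.classes_ = np.array([0, 1])
        model.n_features_in_ = 4
        model.loss_curve_ = []
        proba = model.predict_proba(np.random.default_rng(0).normal(size=(5, 4)))
        assert np.allclose(proba[:, 1], _sigmoid(np.array([0.7])))

    def test_batch_order_invariance(self):
        X, y = two_clusters(n=300, seed=9)
        model = PixelMLP(random_state=0).fit(X, y)
        p = model.predict_proba(X)[:, 1]
        perm = np.random.default_rng(0).permutation(len(X))
        assert np.allclose(model.predict_proba(X[perm])[:, 1], p[perm])


def test_train_wrapper_and_serialization(tmp_path):
    X, y = two_clusters(n=400, d=5, seed=10)
    table = pd.DataFrame(X, columns=[f"f{i}" for i in range(5)])
    table.insert(0, "label", y.astype(int))
    table.insert(0, "patient_id", "P0")
    model = train(table, TrainConfig(epochs=3, seed=1))
    save_model(model, tmp_path / "model.json")
    loaded = load_model(tmp_path / "model.json")
    assert np.array_equal(loaded.predict_proba(X), model.predict_proba(X))


class TestProbabilityMap:
    def test_constant_tissue_gives_near_constant_map(self):
        config = CohortConfig(
            n_patients=2, n_samples=2, frac_mixed=0.0, frac_normal=0.5, frac_abnormal=0.5,
            image_shape=(16, 16), seed=6,
        )
        from mmpol.phantom import normal_tissue_spec, abnormal_tissue_spec

        frozen_normal = normal_tissue_spec(
            retardance_sd=0.0, fast_axis_spread=0.0, depol_sd=0.0,
            diattenuation_sd=0.0, m00_sd=0.0,
        )
        frozen_abnormal = abnormal_tissue_spec(
            retardance_sd=0.0, fast_axis_spread=0.0, depol_sd=0.0,
            diattenuation_sd=0.0, m00_sd=0.0,
        )
        cohort = generate_cohort(config, frozen_normal, frozen_abnormal)
        images = [s.mm_image for s in cohort.samples]
        layouts = [s.layout for s in cohort.samples]
        table = build_feature_table(images, layouts, "pol")
        model = train(table, TrainConfig(seed=0))
        pmap = probability_map(model, images[0], "pol")
        assert pmap.shape == images[0].matrices.shape[:2]
        assert np.nanstd(pmap) < 0.05

    def test_invalid_pixels_are_nodata(self, tiny_cohort):
        _, images, layouts = tiny_cohort
        table = build_feature_table(images, layouts, "nopol")
        model = train(table, TrainConfig(epochs=1, seed=0))
        image = images[0]
        image.valid_mask[0, 0] = False
        pmap = probability_map(model, image, "nopol")
        assert np.isnan(pmap[0, 0])
        assert np.isfinite(pmap[1:, 1:]).all()

    def test_mode_model_mismatch_rejected(self, tiny_cohort):
        _, images, layouts = tiny_cohort
        table = build_feature_table(images, layouts, "nopol")
        model = train(table, TrainConfig(epochs=1, seed=0))
        with pytest.raises(ValueError):
            probability_map(model, images[0], "pol")


def test_score_rises_with_abnormality_contrast():
    """The abnormal class is the positive class: stronger abnormal signal in
    a pixel raises its expected score across contrast levels."""
    from mmpol.phantom import abnormal_tissue_spec

    config = CohortConfig(
        n_patients=2, n_samples=2, frac_mixed=1.0, frac_normal=0.0, frac_abnormal=0.0,
        image_shape=(24, 24), intensity_matched=True, seed=12,
    )
    cohort = generate_cohort(config)
    table = build_feature_table(
        [s.mm_image for s in cohort.samples], [s.layout for s in cohort.samples], "pol"
    )
    model = train(table, TrainConfig(seed=3))
    feat = [c for c in table.columns if c.startswith("f")]
    mean_scores = []
    for retardance in (0.6, 0.9, 1.2):
        probe = generate_cohort(
            CohortConfig(
                n_patients=1, n_samples=1, frac_mixed=0.0, frac_normal=0.0,
                frac_abnormal=1.0, image_shape=(16, 16), intensity_matched=True, seed=50,
                patient_effect_sd=0.0,
            ),
            abnormal_spec=abnormal_tissue_spec(retardance_mean=retardance),
        )
        ptable = build_feature_table(
            [probe.samples[0].mm_image], [probe.samples[0].layout], "pol"
        )
        mean_scores.append(model.predict_proba(ptable[feat].to_numpy())[:, 1].mean())
    assert mean_scores[0] < mean_scores[1] < mean_scores[2]
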