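"""Neural-network construction, losses, training, hybrids and searches."""

import copy

import numpy as np
import pytest

from grnkit import (
    ClassifierSpec,
    ModelConfig,
    build_feature_matrix,
    build_model,
    extract_features,
    fit_hybrid,
    generate_dataset,
    grid_search,
    kernel_grid_experiment,
    load_model,
    preprocess_features,
    reshape_pair_input,
    roc_auc,
    sample_negative_pairs,
    save_model,
    split_holdout,
    train_model,
)
from grnkit.models import LOSSES, EncoderFeatures, cnn_feature_dim
from grnkit.synthetic import SyntheticSpec


# hand-computed closed forms for p=(0.9, 0.2, 0.6), y=(1, 0, 1)
_P = np.array([0.9, 0.2, 0.6])
_Y = np.array([1.0, 0.0, 1.0])
_EXPECTED_LOSS = {
    "bce": 0.279777,  # -(ln .9 + ln .8 + ln .6)/3
    "hinge": 0.566667,  # (0.1 + 1.2 + 0.4)/3 with +/-1 labels
    "mse": 0.07,
    "msle": 0.028555,
    "mae": 0.233333,
    "poisson": 0.772062,  # (p - y ln p) averaged
    "huber": 0.035,  # quadratic zone, delta=1
    "logcosh": 0.034271,
}


class TestLosses:
    @pytest.mark.parametrize("name", sorted(LOSSES))
    def test_textbook_closed_form_on_toy_vector(self, name):
        value_fn, _ = LOSSES[name]
        assert float(value_fn(_P, _Y).mean()) == pytest.approx(_EXPECTED_LOSS[name], abs=1e-5)

    @pytest.mark.parametrize("name", sorted(LOSSES))
    def test_gradient_matches_numeric_derivative(self, name):
        value_fn, grad_fn = LOSSES[name]
        p = np.array([0.31, 0.62, 0.87])  # away from kinks of mae/hinge/huber
        y = np.array([0.0, 1.0, 1.0])
        h = 1e-6
        numeric = (value_fn(p + h, y) - value_fn(p - h, y)) / (2 * h)
        np.testing.assert_allclose(grad_fn(p, y), numeric, atol=1e-5)

    def test_unknown_loss_lists_valid_names(self):
        with pytest.raises(ValueError, match="bce"):
            ModelConfig(loss_name="xent")


class TestReshape:
    def test_definition(self):
        np.testing.assert_array_equal(
            reshape_pair_input(np.array([1, 2, 3, 4, 5, 6])), [[1, 2, 3], [4, 5, 6]]
        )

    def test_inverse_is_identity(self):
        row = np.random.default_rng(0).normal(size=2 * 1253)
        grid = reshape_pair_input(row)
        assert grid.shape == (2, 1253)
        np.testing.assert_array_equal(grid.ravel(), row)

    def test_odd_length_rejected(self):
        with pytest.raises(ValueError, match="even"):
            reshape_pair_input(np.arange(5))


class TestArchitecture:
    def test_fcn_parameter_count_closed_form(self):
        model = build_model(ModelConfig(model_family="fcn"), 2506)
        expected = (2506 * 256 + 256) + (256 * 128 + 128) + (128 * 1 + 1)
        assert model.n_parameters() == expected

    @pytest.mark.parametrize("s,k2", [(100, 8), (200, 16), (1253, 8)])
    def test_cnn_feature_dim_matches_shape_trace(self, s, k2):
        # conv(same) keeps 2 x S; pool (1,2) halves S; twice; flatten
        model = build_model(ModelConfig(conv_kernels=(8, k2)), 2 * s)
        hand = 2 * ((s // 2) // 2) * k2
        assert model.feature_dim == hand == cnn_feature_dim(2 * s, k2)
        X = np.zeros((2, 2 * s))
        assert model.encode(X).shape == (2, hand)

    def test_odd_cnn_input_rejected(self):
        with pytest.raises(ValueError, match="even"):
            build_model(ModelConfig(), 15)


class TestTraining:
    def _toy(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        y = np.repeat([0.0, 1.0], n // 2)
        X = rng.normal(size=(n, 2)) + y[:, None] * 3.0
        return X, y

    def test_separable_toy_reaches_high_accuracy(self):
        X, y = self._toy()
        cfg = ModelConfig(model_family="fcn", epochs=100, learning_rate=1e-3, seed=0)
        model = train_model(build_model(cfg, 2), X, y)
        assert ((model.predict_proba(X) >= 0.5) == y).mean() >= 0.95
        assert len(model.history) == 100
        assert model.history[-1]["loss"] <= model.history[0]["loss"]

    def test_zero_epochs_leaves_weights_untouched(self):
        X, y = self._toy()
        cfg = ModelConfig(model_family="fcn", epochs=0, seed=0)
        model = build_model(cfg, 2)
        before = copy.deepcopy([p.copy() for l in model.layers for p in l.param_arrays()])
        train_model(model, X, y)
        after = [p for l in model.layers for p in l.param_arrays()]
        assert model.history == []
        for b, a in zip(before, after):
            np.testing.assert_array_equal(b, a)

    def test_single_class_labels_rejected(self):
        X, _ = self._toy()
        with pytest.raises(ValueError, match="single class"):
            train_model(build_model(ModelConfig(model_family="fcn"), 2), X, np.zeros(200))

    def test_row_label_mismatch_rejected(self):
        X, y = self._toy()
        with pytest.raises(ValueError, match="rows"):
            train_model(build_model(ModelConfig(model_family="fcn"), 2), X, y[:-1])

    def test_permuted_labels_give_chance_holdout_accuracy(self):
        X, y = self._toy(n=400, seed=1)
        rng = np.random.default_rng(2)
        y_perm = rng.permutation(y)
        cfg = ModelConfig(model_family="fcn", epochs=60, learning_rate=1e-3, seed=0)
        model = train_model(build_model(cfg, 2), X[:300], y_perm[:300])
        acc = ((model.predict_proba(X[300:]) >= 0.5) == y_perm[300:]).mean()
        assert 0.4 <= acc <= 0.6

    def test_fixed_seed_training_is_reproducible(self):
        X, y = self._toy()
        cfg = ModelConfig(model_family="fcn", epochs=5, learning_rate=1e-3, seed=3)
        a = train_model(build_model(cfg, 2), X, y).predict_proba(X)
        b = train_model(build_model(cfg, 2), X, y).predict_proba(X)
        np.testing.assert_array_equal(a, b)


class TestEncoderFeatures:
    def _encoder(self, s=20, trained=False):
        cfg = ModelConfig(conv_kernels=(4, 4), epochs=5, learning_rate=1e-3, seed=0)
        model = build_model(cfg, 2 * s)
        if trained:
            rng = np.random.default_rng(0)
            y = np.repeat([0.0, 1.0], 30)
            X = rng.normal(size=(60, 2 * s)) + y[:, None]
            train_model(model, X, y)
        return model

    def test_inference_is_deterministic(self):
        model = self._encoder(trained=True)
        X = np.random.default_rng(1).normal(size=(8, 40))
        a = extract_features(model, X)
        b = extract_features(model, X)
        np.testing.assert_array_equal(a.values, b.values)

    def test_row_count_and_width(self):
        model = self._encoder()
        feats = extract_features(model, np.zeros((7, 40)))
        assert feats.values.shape == (7, model.feature_dim)

    def test_zero_input_zero_bias_gives_zero_features(self):
        model = self._encoder()
        feats = extract_features(model, np.zeros((3, 40)))
        np.testing.assert_array_equal(feats.values, 0.0)

    def test_fcn_rejected(self):
        fcn = build_model(ModelConfig(model_family="fcn"), 40)
        with pytest.raises(ValueError, match="CNN"):
            extract_features(fcn, np.zeros((2, 40)))


class TestHybrid:
    def test_one_nearest_neighbor_memorizes_training_set(self):
        rng = np.random.default_rng(0)
        feats = EncoderFeatures(rng.normal(size=(50, 6)), "test")
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        model = fit_hybrid(feats, y, ClassifierSpec("knn", {"n_neighbors": 1}))
        assert (model.predict(feats) == y).all()

    def test_constant_features_give_chance_auc(self):
        rng = np.random.default_rng(3)
        y = rng.permutation(np.repeat([0, 1], 100))
        const = np.full((200, 5), 3.14)
        model = fit_hybrid(EncoderFeatures(const[:150], "c"), y[:150], ClassifierSpec("random_forest"))
        scores = model.predict_proba(const[150:])
        jitter = rng.normal(0, 1e-9, 50)  # break exact ties for the sweep
        assert 0.35 <= roc_auc(scores + jitter, y[150:]).auc <= 0.65

    def test_strong_signal_features_give_high_auc(self):
        rng = np.random.default_rng(4)
        y = np.repeat([0, 1], 150)
        feats = rng.normal(size=(300, 10)) + y[:, None] * 1.5
        model = fit_hybrid(EncoderFeatures(feats[::2], "s"), y[::2], ClassifierSpec("random_forest"))
        assert roc_auc(model.predict_proba(feats[1::2]), y[1::2]).auc >= 0.9

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            ClassifierSpec("neural_forest")

    def test_probabilities_within_unit_interval(self):
        rng = np.random.default_rng(5)
        y = np.repeat([0, 1], 40)
        feats = EncoderFeatures(rng.normal(size=(80, 4)) + y[:, None], "p")
        for family in ("logistic_regression", "svm", "adaboost"):
            model = fit_hybrid(feats, y, ClassifierSpec(family))
            p = model.predict_proba(feats)
            assert np.all((p >= 0) & (p <= 1))


class TestGridSearch:
    def _toy(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 100)
        X = rng.normal(size=(200, 2)) + y[:, None] * 3.0
        return X, y

    def test_single_point_grid_returns_it(self):
        X, y = self._toy()
        best, table = grid_search(
            ClassifierSpec("random_forest"), {"n_estimators": [20]}, X, y, folds=10, seed=0
        )
        assert best == {"n_estimators": 20}
        assert [c for c in table.columns if c.startswith("fold_")] == [
            f"fold_{i}" for i in range(10)
        ]

    def test_better_grid_point_wins_on_xor_data(self):
        # a depth-1 stump cannot represent XOR; a deeper tree can
        rng = np.random.default_rng(1)
        X = rng.normal(size=(300, 2))
        y = ((X[:, 0] * X[:, 1]) > 0).astype(int)
        best, table = grid_search(
            ClassifierSpec("decision_tree"), {"max_depth": [1, 6]}, X, y, folds=5, seed=0
        )
        assert best == {"max_depth": 6}
        accs = table.set_index("max_depth")["mean_accuracy"]
        assert accs[6] > accs[1]

    def test_excessive_folds_rejected(self):
        X, y = self._toy()
        with pytest.raises(ValueError, match="folds"):
            grid_search(ClassifierSpec("knn"), {"n_neighbors": [1]}, X, y, folds=150)

    def test_empty_grid_rejected(self):
        X, y = self._toy()
        with pytest.raises(ValueError, match="nonempty"):
            grid_search(ClassifierSpec("knn"), {}, X, y)

    def test_shipped_grids_cover_all_families_and_instantiate(self):
        from grnkit.models import _FAMILIES, load_default_grids, make_classifier

        grids = load_default_grids()
        assert set(grids) == set(_FAMILIES)
        for family, grid in grids.items():
            point = {k: v[0] for k, v in grid.items()}
            make_classifier(ClassifierSpec(family, hyperparameters=point))


@pytest.fixture(scope="module")
def strong_signal_split():
    spec = SyntheticSpec(
        n_genes=200, n_tfs=20, n_samples=64, n_positive_pairs=100,
        signal=3.0, noise_sd=0.3, seed=3,
    )
    ds = generate_dataset(spec)
    negs = sample_negative_pairs(ds.tf_ids, ds.compendium.gene_ids, ds.positives, 100, seed=4)
    train_p, test_p = split_holdout(ds.positives + negs, 0.25, 5)
    Ftr = build_feature_matrix(train_p, ds.compendium)
    Fte = build_feature_matrix(test_p, ds.compendium)
    Xtr, stats = preprocess_features(Ftr.values)
    Xte, _ = preprocess_features(Fte.values, stats=stats)
    return (Xtr, Ftr.labels), (Xte, Fte.labels)


class TestKernelGrid:
    def test_grid_shape_range_and_strong_signal_bound(self, strong_signal_split):
        train, holdout = strong_signal_split
        base = ModelConfig(epochs=60, learning_rate=2e-3, batch_size=32, seed=2)
        table = kernel_grid_experiment([4, 8], train, holdout, base_config=base)
        assert len(table) == 4
        assert set(zip(table.k1, table.k2)) == {(4, 4), (4, 8), (8, 4), (8, 8)}
        assert ((table.accuracy >= 0.0) & (table.accuracy <= 1.0)).all()
        assert (table.accuracy >= 0.8).all()

    def test_repeated_run_is_identical(self, strong_signal_split):
        train, holdout = strong_signal_split
        base = ModelConfig(epochs=5, learning_rate=2e-3, batch_size=32, seed=2)
        a = kernel_grid_experiment([4], train, holdout, base_config=base)
        b = kernel_grid_experiment([4], train, holdout, base_config=base)
        assert a.equals(b)


def test_save_load_roundtrip(tmp_path):
    cfg = ModelConfig(conv_kernels=(4, 4), epochs=3, learning_rate=1e-3, seed=0)
    model = build_model(cfg, 24)
    rng = np.random.default_rng(0)
    y = np.repeat([0.0, 1.0], 20)
    X = rng.normal(size=(40, 24)) + y[:, None]
    train_model(model, X, y)
    save_model(model, tmp_path / "m")
    back = load_model(tmp_path / "m")
    np.testing.assert_array_equal(back.predict_proba(X), model.predict_proba(X))
    assert back.config == model.config
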