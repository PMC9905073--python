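"""Classifier architecture, convolution oracle, loss, and training."""

import numpy as np
import pytest

import hydrosite as hs
from hydrosite.cnn import ModelConfig, _sigmoid

TINY = dict(n_conv_units=2, conv_layers_per_unit=1, channels=4, fcb_nodes=8,
            input_edge=9, dropout_rate=0.0)


def _six_loop_conv(x, f):
    """Independent brute-force oracle: six explicit nested loops."""
    F = f.shape[0]
    m = x.shape[0] - F + 1
    out = np.zeros((m, m, m))
    for i in range(m):
        for j in range(m):
            for k in range(m):
                acc = 0.0
                for p in range(F):
                    for q in range(F):
                        for r in range(F):
                            acc += x[i + p, j + q, k + r] * f[p, q, r]
                out[i, j, k] = acc
    return out


class TestConvReference:
    def test_delta_filter_is_identity_on_interior(self, rng):
        x = rng.random((6, 6, 6))
        f = np.zeros((3, 3, 3))
        f[1, 1, 1] = 1.0
        np.testing.assert_allclose(hs.conv3d_reference(x, f), x[1:-1, 1:-1, 1:-1])

    def test_all_ones_gives_27(self):
        out = hs.conv3d_reference(np.ones((5, 5, 5)), np.ones((3, 3, 3)))
        np.testing.assert_allclose(out, 27.0)

    def test_matches_six_loop_oracle(self, rng):
        x = rng.random((6, 6, 6))
        f = rng.random((3, 3, 3))
        np.testing.assert_allclose(hs.conv3d_reference(x, f), _six_loop_conv(x, f),
                                   rtol=1e-12)

    def test_filter_larger_than_input_rejected(self):
        with pytest.raises(ValueError):
            hs.conv3d_reference(np.ones((2, 2, 2)), np.ones((3, 3, 3)))


class TestLayerConvAgainstReference:
    def test_same_padded_layer_matches_valid_reference_interior(self, rng):
        """The network's vectorized conv equals the triple-summation oracle.

        'same' zero-padding means interior outputs (offset 1 for F=3)
        equal the 'valid' reference applied to the unpadded input, summed
        over input channels.
        """
        model = hs.HydrationCNN(n_conv_units=1, conv_layers_per_unit=1,
                                channels=3, fcb_nodes=4, input_edge=8,
                                random_state=0).initialize()
        conv = model.layers_[0]
        x = rng.random((2, 8, 8, 8, 4)).astype(np.float32)
        out = conv.forward(x, train=False) - conv.b
        for b in range(2):
            for o in range(3):
                expected = sum(
                    hs.conv3d_reference(x[b, :, :, :, c], conv.W[:, :, :, c, o])
                    for c in range(4)
                )
                np.testing.assert_allclose(out[b, 1:-1, 1:-1, 1:-1, o], expected,
                                           rtol=1e-5, atol=1e-5)


class TestBceLoss:
    def test_half_probability_is_ln2(self):
        assert hs.bce_loss([hs.LabeledOutput(0.5, 0)]) == pytest.approx(np.log(2))
        assert hs.bce_loss([hs.LabeledOutput(0.5, 1)]) == pytest.approx(np.log(2))

    def test_perfect_prediction_near_zero(self):
        assert hs.bce_loss([hs.LabeledOutput(1.0, 1), hs.LabeledOutput(0.0, 0)]) \
            == pytest.approx(0.0, abs=1e-5)

    def test_hand_summed_batch_of_four(self):
        batch = [(0.9, 1), (0.2, 0), (0.6, 1), (0.7, 0)]
        expected = -(np.log(0.9) + np.log(0.8) + np.log(0.6) + np.log(0.3)) / 4
        assert hs.bce_loss(batch) == pytest.approx(expected, rel=1e-12)

    def test_array_form_matches_pair_form(self, rng):
        y = rng.random(16)
        d = rng.integers(0, 2, 16)
        assert hs.bce_loss(y, d) == pytest.approx(hs.bce_loss(list(zip(y, d))))

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            hs.bce_loss([])


class TestModelConfig:
    def test_hand_counted_parameters(self):
        # conv 3^3*4*2+2 = 218; pool 9->4; dense 2*4^3*4+4 = 516; head 4+1 = 5
        cfg = ModelConfig(n_conv_units=1, conv_layers_per_unit=1, channels=2,
                          filter_size=3, fcb_nodes=4, input_edge=9)
        assert cfg.n_parameters() == 218 + 516 + 5 == 739

    def test_built_model_matches_config_count(self):
        model = hs.HydrationCNN(n_conv_units=1, conv_layers_per_unit=1, channels=2,
                                fcb_nodes=4, input_edge=9, random_state=0).initialize()
        assert model.n_parameters_ == 739

    def test_selected_architecture_builds_and_outputs_probability(self):
        # two convolution units, 3x3x3 filters, 32 channels, 32-node FCB
        model = hs.HydrationCNN(input_edge=41, box=hs.FINE_BOX,
                                random_state=0).initialize()
        grid = np.zeros((1, 4, 41, 41, 41), dtype=np.float32)
        grid[0, 0, 20, 20, 20] = 1
        p = model.predict_water_probability(grid)
        assert 0.0 < p[0] < 1.0

    def test_pooling_exhaustion_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            ModelConfig(n_conv_units=4, input_edge=9)

    def test_edge_schedule_fine_and_coarse(self):
        assert ModelConfig(input_edge=41).edge_schedule() == [20, 10]
        assert ModelConfig(input_edge=21).edge_schedule() == [10, 5]


class TestTraining:
    def test_zero_epochs_leaves_parameters_unchanged(self, rng):
        model = hs.HydrationCNN(random_state=3, **TINY).initialize()
        before = [p.copy() for p in model._params()]
        X = (rng.random((8, 4, 9, 9, 9)) < 0.05).astype(np.float32)
        y = rng.integers(0, 2, 8)
        split = _as_split(X, y)
        hs.train(model, split, epochs=0)
        for a, b in zip(before, model._params()):
            np.testing.assert_array_equal(a, b)

    def test_overfits_sixteen_patterns(self, rng):
        X = (rng.random((16, 4, 9, 9, 9)) < 0.03).astype(np.float32)
        y = np.arange(16) % 2
        model = hs.HydrationCNN(epochs=200, batch_size=16, learning_rate=3e-3,
                                random_state=0, **TINY)
        model.fit(X, y)
        assert model.history_["train_loss"][-1] < 0.05

    def test_loss_decreases_on_separable_toy_set(self):
        # label = whether the centre voxel of channel O is occupied
        rng = np.random.default_rng(0)
        X = (rng.random((64, 4, 9, 9, 9)) < 0.02).astype(np.float32)
        y = rng.integers(0, 2, 64)
        X[:, 2, 4, 4, 4] = y
        model = hs.HydrationCNN(epochs=10, batch_size=64, learning_rate=1e-3,
                                random_state=1, **TINY)
        model.fit(X, y)
        losses = model.history_["train_loss"]
        violations = sum(b > a for a, b in zip(losses, losses[1:]))
        assert violations <= 1

    def test_untrained_accuracy_near_half_on_balanced_set(self):
        rng = np.random.default_rng(2)
        X = (rng.random((400, 4, 9, 9, 9)) < 0.02).astype(np.float32)
        y = np.arange(400) % 2
        accs = []
        for seed in (0, 1, 2):
            model = hs.HydrationCNN(random_state=seed, **TINY).initialize()
            accs.append(np.mean(model.predict(X) == y))
        assert all(abs(a - 0.5) <= 0.1 for a in accs)

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_divergence_error_names_epoch(self, rng):
        X = rng.random((8, 4, 9, 9, 9)).astype(np.float32) * 100
        y = np.arange(8) % 2
        model = hs.HydrationCNN(epochs=50, batch_size=8, learning_rate=1e18,
                                random_state=0, **TINY)
        try:
            model.fit(X, y)
        except hs.cnn.TrainingDivergedError as err:
            assert "epoch" in str(err)


class TestInference:
    def test_repeated_prediction_identical(self, rng):
        model = hs.HydrationCNN(random_state=0,
                                **{**TINY, "dropout_rate": 0.4}).initialize()
        x = (rng.random((1, 4, 9, 9, 9)) < 0.05).astype(np.float32)
        a = model.predict_water_probability(x)
        b = model.predict_water_probability(x)
        np.testing.assert_array_equal(a, b)

    def test_all_zero_grid_valid(self):
        model = hs.HydrationCNN(random_state=0, **TINY).initialize()
        p = model.predict_water_probability(np.zeros((1, 4, 9, 9, 9), np.float32))
        assert 0.0 <= p[0] <= 1.0

    def test_batch_equals_per_pattern(self, rng):
        model = hs.HydrationCNN(random_state=0, **TINY).initialize()
        X = (rng.random((7, 4, 9, 9, 9)) < 0.05).astype(np.float32)
        batch = model.predict_water_probability(X)
        single = [hs.predict_pattern(model, X[i]) for i in range(7)]
        np.testing.assert_allclose(batch, single, rtol=1e-6)

    def test_sparse_and_dense_paths_agree(self, rng):
        model = hs.HydrationCNN(random_state=0, **TINY).initialize()
        Xs = (rng.random((5, 4, 9, 9, 9)) < 0.01).astype(np.float32)
        sparse = model.predict_water_probability(Xs)
        dense = model.predict_water_probability(Xs + np.float32(1e-12))
        np.testing.assert_allclose(sparse, dense, rtol=1e-4, atol=1e-6)

    def test_predict_proba_columns(self, rng):
        model = hs.HydrationCNN(random_state=0, **TINY).initialize()
        X = (rng.random((3, 4, 9, 9, 9)) < 0.05).astype(np.float32)
        proba = model.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        np.testing.assert_array_equal(model.classes_, [0, 1])

    def test_shape_mismatch_rejected(self):
        model = hs.HydrationCNN(random_state=0, **TINY).initialize()
        with pytest.raises(ValueError, match="shape"):
            model.predict_water_probability(np.zeros((1, 4, 7, 7, 7), np.float32))


class TestPersistence:
    def test_checkpoint_round_trip(self, rng, tmp_path):
        X = (rng.random((12, 4, 9, 9, 9)) < 0.05).astype(np.float32)
        y = np.arange(12) % 2
        model = hs.HydrationCNN(epochs=2, batch_size=4, random_state=0,
                                box=hs.BoxSpec(9, 0.5), resolution_tag="coarse",
                                **TINY)
        model.fit(X, y)
        path = tmp_path / "model.npz"
        model.save(path)
        back = hs.HydrationCNN.load(path)
        np.testing.assert_array_equal(back.predict_water_probability(X),
                                      model.predict_water_probability(X))
        assert back.box == hs.BoxSpec(9, 0.5)
        assert back.resolution_tag == "coarse"
        assert back.history_["epoch"] == model.history_["epoch"]

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone
        model = hs.HydrationCNN(channels=8, random_state=5)
        twin = clone(model)
        assert twin.get_params() == model.get_params()


def _as_split(X, y):
    box = hs.BoxSpec(9, 0.5)
    pats = [hs.Pattern(grid=X[i], center=np.zeros(3),
                       label="water_present" if y[i] else "water_absent")
            for i in range(len(y))]
    ds = hs.PatternDataset(patterns=pats, n_present=int(np.sum(y == 1)),
                           n_absent=int(np.sum(y == 0)))
    return hs.SplitDataset(train=ds,
                           validation=hs.PatternDataset([], 0, 0), fraction=1.0)


def test_sigmoid_saturates_safely():
    z = np.array([-1000.0, 0.0, 1000.0])
    s = _sigmoid(z)
    assert s[0] == 0.0 and s[1] == 0.5 and s[2] == 1.0
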