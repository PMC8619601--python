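"""Network construction, activations, training loop and prediction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wavemri as w
from wavemri import (
    ConfigurationError,
    DataError,
    NetworkConfig,
    TrainingDivergenceError,
    batch_norm_forward,
    build_network,
    classify,
    predict,
    relu,
    train,
)

TINY = dict(
    input_shape=(8, 8, 3),
    block_channels=(4, 8),
    fc_hidden=(16,),
    epochs=2,
    batch_size=8,
    rotation_degrees=0.0,
)


class TestBuildNetwork:
    def test_default_conv_channels_in_order(self):
        spec = build_network(NetworkConfig()).spec
        convs = [r for r in spec.rows if r.kind == "conv"]
        assert [r.shape_out[-1] for r in convs] == [8, 16, 32, 64]

    def test_final_layer_is_single_sigmoid_unit(self):
        spec = build_network(NetworkConfig()).spec
        assert spec.rows[-1].kind == "sigmoid"
        assert spec.rows[-1].shape_out == (1,)

    def test_default_spatial_trace(self):
        """64 -> 32 -> 16 -> 8 -> 4 across the four stride-2 pools."""
        spec = build_network(NetworkConfig()).spec
        pools = [r for r in spec.rows if r.kind == "maxpool"]
        assert [r.shape_in[0] for r in pools] == [64, 32, 16, 8]
        assert [r.shape_out[0] for r in pools] == [32, 16, 8, 4]

    def test_parameter_count_matches_hand_arithmetic(self):
        # conv: k*k*cin*cout + cout; bn: 2c; dense: nin*nout + nout
        conv = (3 * 3 * 3 * 8 + 8) + (3 * 3 * 8 * 16 + 16) + (3 * 3 * 16 * 32 + 32) + (
            3 * 3 * 32 * 64 + 64
        )
        bn = 2 * (8 + 16 + 32 + 64)
        fc = (4 * 4 * 64 * 512 + 512) + (512 * 1024 + 1024) + (1024 * 1 + 1)
        assert build_network(NetworkConfig()).spec.n_params == conv + bn + fc

    def test_layer_count_conventions(self):
        spec = build_network(NetworkConfig()).spec
        assert spec.n_layers_table == 25  # grouped published-table convention
        assert spec.n_weight_layers == 7  # 4 conv + 3 dense

    def test_pool_subset_variant_keeps_8x8_map(self):
        """Pooling only in blocks 1-3 leaves an 8x8 map before the FC stack."""
        spec = build_network(NetworkConfig(pool_blocks=(0, 1, 2))).spec
        flatten = next(r for r in spec.rows if r.kind == "flatten")
        assert flatten.shape_in == (8, 8, 64)

    def test_spatial_collapse_rejected(self):
        with pytest.raises(ConfigurationError):
            build_network(NetworkConfig(input_shape=(8, 8, 3)))  # 4 pools on 8px

    def test_dwt_input_is_64x_smaller_than_raw(self):
        assert (512 * 512 * 3) // (64 * 64 * 3) == 64

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(channels=st.lists(st.integers(1, 8), min_size=1, max_size=3))
    def test_shape_chaining_holds_for_random_configs(self, channels):
        # NetworkSpec.__post_init__ raises on any shape break
        net = build_network(
            NetworkConfig(input_shape=(16, 16, 3), block_channels=tuple(channels),
                          fc_hidden=(8,))
        )
        assert net.spec.rows[0].shape_in == (16, 16, 3)
        assert net.spec.rows[-1].shape_out == (1,)


class TestActivations:
    def test_relu_examples(self):
        assert relu(-3) == 0
        assert relu(5) == 5

    def test_relu_idempotent(self, rng):
        x = rng.standard_normal(100)
        np.testing.assert_array_equal(relu(relu(x)), relu(x))

    def test_batch_norm_hand_example(self):
        """Batch {1, 3}: mean 2, variance 1; gamma=2, beta=1 -> {-1, 3}."""
        out = batch_norm_forward(np.array([1.0, 3.0]), gamma=2.0, beta=1.0, eps=1e-12)
        np.testing.assert_allclose(out, [-1.0, 3.0], atol=1e-5)

    def test_batch_norm_identity_on_standardized_batch(self, rng):
        x = rng.standard_normal(1000)
        x = (x - x.mean()) / x.std()
        out = batch_norm_forward(x, gamma=1.0, beta=0.0, eps=1e-12)
        np.testing.assert_allclose(out, x, atol=1e-5)

    def test_batch_norm_constant_batch_collapses_to_beta(self):
        out = batch_norm_forward(np.full(8, 5.0), gamma=3.0, beta=-2.0)
        np.testing.assert_allclose(out, -2.0, atol=1e-9)


class TestPredict:
    def test_zeroed_head_gives_exactly_half(self, rng):
        net = build_network(NetworkConfig(**TINY))
        net.output_layer.W[...] = 0.0
        net.output_layer.b[...] = 0.0
        probs = predict(net, rng.random((4, 8, 8, 3)).astype(np.float32))
        np.testing.assert_array_equal(probs, 0.5)

    def test_probabilities_strictly_inside_unit_interval(self, rng):
        net = build_network(NetworkConfig(**TINY, seed=3))
        probs = predict(net, rng.random((6, 8, 8, 3)).astype(np.float32))
        assert np.all(probs > 0.0) and np.all(probs < 1.0)

    def test_classify_threshold_contract(self):
        np.testing.assert_array_equal(classify(np.array([0.49, 0.51])), [0, 1])
        np.testing.assert_array_equal(classify(np.array([0.5])), [1])

    def test_shape_mismatch_rejected(self, rng):
        net = build_network(NetworkConfig(**TINY))
        with pytest.raises(ValueError):
            predict(net, rng.random((2, 9, 8, 3)))


class TestTrain:
    def _toy_data(self, rng, n=16):
        x = rng.random((n, 8, 8, 3)).astype(np.float32)
        y = np.array([0, 1] * (n // 2))
        x[y == 1, :4] += 0.5  # separable-ish
        return np.clip(x, 0, 1), y

    def test_zero_epochs_leaves_report_empty(self, rng):
        net = build_network(NetworkConfig(**{**TINY, "epochs": 0}))
        x, y = self._toy_data(rng)
        rep = train(net, x, y)
        assert rep.epochs_completed == 0 and rep.epoch_loss == []

    def test_single_class_rejected(self, rng):
        net = build_network(NetworkConfig(**TINY))
        x, _ = self._toy_data(rng)
        with pytest.raises(DataError):
            train(net, x, np.ones(len(x)))

    def test_seeded_determinism(self, rng):
        x, y = self._toy_data(rng)
        reports = []
        for _ in range(2):
            net = build_network(NetworkConfig(**TINY, seed=5))
            reports.append(train(net, x, y))
        assert reports[0].epoch_loss == reports[1].epoch_loss

    def test_poisoned_weights_raise_divergence_error(self, rng):
        net = build_network(NetworkConfig(**TINY))
        net.output_layer.b[...] = np.nan
        x, y = self._toy_data(rng)
        with np.errstate(invalid="ignore"), pytest.raises(TrainingDivergenceError):
            train(net, x, y)

    def test_validation_checkpoints_recorded(self, rng):
        cfg = NetworkConfig(**{**TINY, "epochs": 4, "validation_frequency": 3})
        net = build_network(cfg)
        x, y = self._toy_data(rng)
        rep = train(net, x, y, validation=(x, y))
        assert rep.val_iterations and rep.val_iterations[0] == 3
        assert all(v >= 0 for v in rep.val_loss)
        assert all(0 <= e <= 1 for e in rep.val_error)


@pytest.fixture(scope="module")
def overfit_run():
    """40 maximally separable phantoms, 35 epochs, regularization off."""
    params = w.PhantomParams(seed=3, noise_density=0.0, lesion_contrast=255.0)
    imgs, labels, _ = w.make_dataset(40, params)
    x = w.prepare_inputs(imgs, use_dwt=True, levels=3)
    net = build_network(
        NetworkConfig(seed=1, epochs=35, dropout_rate=0.0, rotation_degrees=0.0)
    )
    report = train(net, x, labels)
    return net, x, labels, report


class TestOverfitTinySet:
    def test_reaches_perfect_training_accuracy(self, overfit_run):
        net, x, labels, _ = overfit_run
        probs = predict(net, x)
        assert np.mean(classify(probs) == labels) == 1.0

    def test_loss_window_medians_nonincreasing(self, overfit_run):
        _, _, _, report = overfit_run
        losses = np.asarray(report.epoch_loss)
        medians = [np.median(losses[i : i + 5]) for i in range(0, len(losses) - 4, 5)]
        assert all(b <= a + 1e-9 for a, b in zip(medians, medians[1:]))
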