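"""Network forward/backward correctness, pinned by finite-difference oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from adamom import network as net
from conftest import assert_grads_close, finite_difference_grads


class TestActivations:
    def test_relu_examples(self):
        np.testing.assert_array_equal(net.relu(np.array([-1.0, 0.0, 2.0])), [0.0, 0.0, 2.0])
        np.testing.assert_array_equal(net.relu(-np.ones(5)), np.zeros(5))

    @given(hnp.arrays(float, (7,), elements=st.floats(-50, 50)))
    @settings(max_examples=50, derandomize=True)
    def test_relu_idempotent(self, x):
        np.testing.assert_array_equal(net.relu(net.relu(x)), net.relu(x))

    def test_softmax_uniform(self):
        np.testing.assert_allclose(net.softmax(np.zeros(4)), np.full(4, 0.25), atol=1e-12)

    def test_softmax_reference_values(self):
        # exp(1..3) normalized, high-precision reference
        np.testing.assert_allclose(
            net.softmax(np.array([1.0, 2.0, 3.0])),
            [0.09003057317038046, 0.24472847105479767, 0.6652409557748219],
            rtol=1e-12,
        )

    @given(
        hnp.arrays(float, (5,), elements=st.floats(-30, 30)),
        st.floats(-100, 100),
    )
    @settings(max_examples=50, derandomize=True)
    def test_softmax_shift_invariance_and_normalization(self, z, c):
        p = net.softmax(z)
        np.testing.assert_allclose(p, net.softmax(z + c), atol=1e-12)
        assert abs(p.sum() - 1.0) < 1e-12
        assert (p > 0).all()

    def test_softmax_empty_raises(self):
        with pytest.raises(ValueError):
            net.softmax(np.array([]))


class TestCrossEntropy:
    def test_degenerate_perfect_prediction_zero(self):
        assert net.cross_entropy(np.array([[1.0, 0.0]]), np.array([[1.0, 0.0]])) == pytest.approx(0.0)

    def test_log_half(self):
        loss = net.cross_entropy(np.array([[0.5, 0.5]]), np.array([[1.0, 0.0]]))
        assert loss == pytest.approx(np.log(2), rel=1e-9)

    def test_uniform_over_four_classes(self):
        loss = net.cross_entropy(np.full((1, 4), 0.25), np.array([[0, 1, 0, 0]], dtype=float))
        assert loss == pytest.approx(np.log(4), rel=1e-9)

    def test_class_weights_scale_terms(self):
        p = np.array([[0.5, 0.5], [0.5, 0.5]])
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        base = net.cross_entropy(p, y)
        weighted = net.cross_entropy(p, y, class_weights=np.array([2.0, 2.0]))
        assert weighted == pytest.approx(2 * base)

    def test_multilabel_sums_over_labels(self):
        p = np.array([[0.5, 0.5]])
        y = np.array([[1.0, 0.0]])
        loss = net.cross_entropy(p, y, kind="multilabel")
        assert loss == pytest.approx(2 * np.log(2), rel=1e-9)

    def test_non_binary_target_raises(self):
        with pytest.raises(ValueError):
            net.cross_entropy(np.array([[0.5, 0.5]]), np.array([[0.3, 0.7]]))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            net.cross_entropy(np.ones((1, 3)) / 3, np.array([[1.0, 0.0]]))


class TestForward:
    def test_dense_zero_weights_outputs_activation_of_bias(self):
        layers = (net.LayerSpec("dense", units=2), net.LayerSpec("softmax"))
        spec = net.NetworkSpec((3,), layers, "multiclass", 2)
        params = [{"w": np.zeros((3, 2)), "b": np.array([1.0, 3.0])}, {}]
        out, _ = net.forward(spec, params, np.ones((4, 3)), mode="eval")
        np.testing.assert_allclose(out, np.tile(net.softmax(np.array([1.0, 3.0])), (4, 1)))

    def test_one_by_one_conv_doubles_pixels(self):
        layers = (net.LayerSpec("conv2d", filters=1, kernel_size=1), net.LayerSpec("sigmoid"))
        spec = net.NetworkSpec((2, 2, 1), layers, "binary", 1)
        params = [{"w": np.full((1, 1, 1, 1), 2.0), "b": np.zeros(1)}, {}]
        x = np.arange(4, dtype=float).reshape(1, 2, 2, 1)
        out, cache = net.forward(spec, params, x, mode="eval")
        conv_out = cache[1][2]  # sigmoid cache holds the probabilities
        np.testing.assert_allclose(conv_out, net.sigmoid(2 * x))

    def test_hand_computed_two_layer_dense(self):
        # 3-2-2 net, fixed weights, manual matrix arithmetic
        layers = (
            net.LayerSpec("dense", units=2),
            net.LayerSpec("relu"),
            net.LayerSpec("dense", units=2),
            net.LayerSpec("softmax"),
        )
        spec = net.NetworkSpec((3,), layers, "multiclass", 2)
        w1 = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, -1.0]])
        b1 = np.array([0.0, 0.5])
        w2 = np.array([[1.0, -1.0], [2.0, 0.0]])
        b2 = np.array([0.0, 1.0])
        params = [{"w": w1, "b": b1}, {}, {"w": w2, "b": b2}, {}]
        x = np.array([[1.0, 2.0, -1.0]])
        # h = relu([1*1+2*0-1*1, 1*0+2*1+1] ) = relu([0, 3.5]) = [0, 3.5]
        # z = [0*1+3.5*2, -0+0+1] = [7, 1]
        expected = net.softmax(np.array([7.0, 1.0]))
        out, _ = net.forward(spec, params, x, mode="eval")
        np.testing.assert_allclose(out[0], expected, rtol=1e-12)

    def test_bad_batch_shape_raises(self, tiny_conv_spec):
        params = net.init_parameters(tiny_conv_spec, seed=0)
        with pytest.raises(net.SpecError):
            net.forward(tiny_conv_spec, params, np.zeros((2, 5, 5, 1)))

    def test_dropout_seed_determinism(self):
        layers = (
            net.LayerSpec("flatten"),
            net.LayerSpec("dropout", drop_rate=0.5),
            net.LayerSpec("dense", units=2),
            net.LayerSpec("softmax"),
        )
        spec = net.NetworkSpec((4, 4, 1), layers, "multiclass", 2)
        params = net.init_parameters(spec, seed=1)
        x = np.random.default_rng(0).random((3, 4, 4, 1))
        out1, _ = net.forward(spec, params, x, mode="train", rng_seed=7)
        out2, _ = net.forward(spec, params, x, mode="train", rng_seed=7)
        out3, _ = net.forward(spec, params, x, mode="train", rng_seed=8)
        np.testing.assert_array_equal(out1, out2)
        assert not np.array_equal(out1, out3)

    def test_train_eval_agree_when_bn_stats_match_and_no_dropout(self, rng):
        layers = (
            net.LayerSpec("conv2d", filters=2, kernel_size=3, padding="same"),
            net.LayerSpec("batchnorm"),
            net.LayerSpec("relu"),
            net.LayerSpec("flatten"),
            net.LayerSpec("dense", units=2),
            net.LayerSpec("softmax"),
        )
        spec = net.NetworkSpec((4, 4, 1), layers, "multiclass", 2)
        params = net.init_parameters(spec, seed=0)
        x = rng.random((5, 4, 4, 1))
        out_train, cache = net.forward(spec, params, x, mode="train")
        # copy the exact batch statistics into the running slots
        conv_out, _ = net._conv2d_forward(x, params[0]["w"], params[0]["b"], 1, "same")
        params[1]["running_mean"] = conv_out.mean(axis=(0, 1, 2))
        params[1]["running_var"] = conv_out.var(axis=(0, 1, 2))
        out_eval, _ = net.forward(spec, params, x, mode="eval")
        np.testing.assert_array_equal(out_train, out_eval)


class TestBackward:
    def test_dense_net_matches_finite_differences(self, tiny_dense_spec, rng):
        params = net.init_parameters(tiny_dense_spec, seed=3)
        x = rng.normal(size=(4, 3))
        y = np.eye(2)[rng.integers(0, 2, size=4)]
        out, cache = net.forward(tiny_dense_spec, params, x, mode="train")
        grads = net.backward(tiny_dense_spec, params, cache, y)
        fd = finite_difference_grads(tiny_dense_spec, params, x, y)
        assert_grads_close(grads, fd)

    def test_conv_net_matches_finite_differences(self, tiny_conv_spec, rng):
        params = net.init_parameters(tiny_conv_spec, seed=4)
        x = rng.normal(size=(3, 4, 4, 1))
        y = np.eye(3)[rng.integers(0, 3, size=3)]
        out, cache = net.forward(tiny_conv_spec, params, x, mode="train")
        grads = net.backward(tiny_conv_spec, params, cache, y)
        fd = finite_difference_grads(tiny_conv_spec, params, x, y)
        assert_grads_close(grads, fd)

    def test_all_layer_kinds_match_finite_differences(self, rng):
        # conv + BN + dropout (frozen mask) + maxpool + dense + BN chain
        layers = (
            net.LayerSpec("conv2d", filters=2, kernel_size=3, padding="same"),
            net.LayerSpec("batchnorm"),
            net.LayerSpec("relu"),
            net.LayerSpec("dropout", drop_rate=0.25),
            net.LayerSpec("maxpool", pool_size=2),
            net.LayerSpec("flatten"),
            net.LayerSpec("dense", units=4),
            net.LayerSpec("batchnorm"),
            net.LayerSpec("relu"),
            net.LayerSpec("dense", units=2),
            net.LayerSpec("softmax"),
        )
        spec = net.NetworkSpec((6, 6, 1), layers, "multiclass", 2)
        params = net.init_parameters(spec, seed=5)
        x = rng.normal(size=(4, 6, 6, 1))
        y = np.eye(2)[rng.integers(0, 2, size=4)]
        out, cache = net.forward(spec, params, x, mode="train", rng_seed=11)
        grads = net.backward(spec, params, cache, y)
        fd = finite_difference_grads(spec, params, x, y, rng_seed=11)
        assert_grads_close(grads, fd, rtol=2e-4, atol=1e-6)

    def test_sigmoid_multilabel_head_matches_finite_differences(self, rng):
        layers = (
            net.LayerSpec("flatten"),
            net.LayerSpec("dense", units=3),
            net.LayerSpec("sigmoid"),
        )
        spec = net.NetworkSpec((2, 2, 1), layers, "multilabel", 3)
        params = net.init_parameters(spec, seed=6)
        x = rng.normal(size=(5, 2, 2, 1))
        y = rng.integers(0, 2, size=(5, 3)).astype(float)
        out, cache = net.forward(spec, params, x, mode="train")
        grads = net.backward(spec, params, cache, y)
        fd = finite_difference_grads(spec, params, x, y)
        assert_grads_close(grads, fd)

    def test_weighted_loss_gradient_matches_finite_differences(self, tiny_dense_spec, rng):
        params = net.init_parameters(tiny_dense_spec, seed=7)
        x = rng.normal(size=(4, 3))
        y = np.eye(2)[np.array([0, 1, 1, 1])]
        w = np.array([2.0, 0.5])
        out, cache = net.forward(tiny_dense_spec, params, x, mode="train")
        grads = net.backward(tiny_dense_spec, params, cache, y, class_weights=w)
        fd = finite_difference_grads(tiny_dense_spec, params, x, y, class_weights=w)
        assert_grads_close(grads, fd)

    def test_perfect_prediction_gives_zero_output_gradient(self):
        layers = (net.LayerSpec("dense", units=2), net.LayerSpec("softmax"))
        spec = net.NetworkSpec((2,), layers, "multiclass", 2)
        params = [{"w": np.array([[40.0, -40.0], [-40.0, 40.0]]), "b": np.zeros(2)}, {}]
        x = np.array([[1.0, 0.0]])
        y = np.array([[1.0, 0.0]])
        out, cache = net.forward(spec, params, x, mode="train")
        grads = net.backward(spec, params, cache, y)
        np.testing.assert_allclose(grads[0]["w"], 0.0, atol=1e-12)


class TestArchitecture:
    def test_reference_cnn_shape_chain_64x64(self):
        spec = net.build_reference_cnn((64, 64, 3), 4, "multiclass")
        shapes = net.infer_shapes(spec)
        by_kind = list(zip([l.kind for l in spec.layers], shapes))
        assert by_kind[0][1] == (64, 64, 32)
        assert by_kind[4][1] == (62, 62, 64)
        assert by_kind[7][1] == (15, 15, 64)
        assert by_kind[8][1] == (15, 15, 128)
        flatten_shapes = [s for k, s in by_kind if k == "flatten"]
        assert flatten_shapes == [(28800,)]
        assert shapes[-1] == (4,)
        assert spec.layers[-1].kind == "softmax"

    def test_reference_cnn_parameter_counts(self):
        spec = net.build_reference_cnn((64, 64, 3), 4, "multiclass")
        counts, total = net.count_parameters(spec)
        conv_counts = [c for l, c in zip(spec.layers, counts) if l.kind == "conv2d"]
        dense_counts = [c for l, c in zip(spec.layers, counts) if l.kind == "dense"]
        bn_counts = [c for l, c in zip(spec.layers, counts) if l.kind == "batchnorm"]
        assert conv_counts == [896, 18496, 73856]
        assert dense_counts == [14746112, 2052]
        assert bn_counts == [128, 256, 512, 2048]

    def test_input_too_small_raises(self):
        with pytest.raises(net.SpecError):
            net.build_reference_cnn((8, 8, 1), 2, "multiclass")

    def test_shape_propagation_total(self):
        # a dense layer on an unflattened image must fail loudly
        layers = (net.LayerSpec("dense", units=4), net.LayerSpec("softmax"))
        with pytest.raises(net.SpecError):
            net.NetworkSpec((4, 4, 1), layers, "multiclass", 4)

    def test_spec_yaml_roundtrip(self, tmp_path):
        spec = net.build_reference_cnn((32, 32, 1), 3, "multiclass")
        path = tmp_path / "spec.yaml"
        net.save_spec(spec, path)
        loaded = net.load_spec(path)
        assert loaded == spec

    def test_parameter_checkpoint_roundtrip(self, tiny_conv_spec, tmp_path):
        params = net.init_parameters(tiny_conv_spec, seed=9)
        path = tmp_path / "params.npz"
        net.save_parameters(params, path)
        loaded = net.load_parameters(path)
        assert len(loaded) == len(params)
        for a, b in zip(params, loaded):
            assert sorted(a) == sorted(b)
            for k in a:
                np.testing.assert_array_equal(a[k], b[k])
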