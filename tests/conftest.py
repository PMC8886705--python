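import numpy as np
import pytest

from adamom import network as net


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dense_spec():
    """3-2-2 dense multiclass net: the hand-checkable workhorse."""
    layers = (
        net.LayerSpec("flatten"),
        net.LayerSpec("dense", units=2),
        net.LayerSpec("relu"),
        net.LayerSpec("dense", units=2),
        net.LayerSpec("softmax"),
    )
    return net.NetworkSpec(input_shape=(3,), layers=layers, task="multiclass", n_outputs=2)


@pytest.fixture
def tiny_conv_spec():
    """4x4 input, one 3x3 conv, dense softmax head."""
    layers = (
        net.LayerSpec("conv2d", filters=2, kernel_size=3, padding="valid"),
        net.LayerSpec("relu"),
        net.LayerSpec("flatten"),
        net.LayerSpec("dense", units=3),
        net.LayerSpec("softmax"),
    )
    return net.NetworkSpec(input_shape=(4, 4, 1), layers=layers, task="multiclass", n_outputs=3)


def finite_difference_grads(spec, params, batch, target, rng_seed=0, class_weights=None, step=1e-5):
    """Central-difference gradient oracle for the batch cross-entropy loss.

    Re-runs the forward pass (same dropout seed, train mode) for every
    perturbed parameter entry; independent of the analytic backward path.
    """
    kind = "multiclass" if spec.task == "multiclass" else spec.task

    def loss_of():
        out, _ = net.forward(spec, params, batch, mode="train", rng_seed=rng_seed)
        return net.cross_entropy(out, target, class_weights, kind)

    fd = [dict() for _ in params]
    for li, par in enumerate(params):
        for name, arr in par.items():
            if name.startswith("running_"):
                continue
            g = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                ix = it.multi_index
                orig = arr[ix]
                arr[ix] = orig + step
                up = loss_of()
                arr[ix] = orig - step
                dn = loss_of()
                arr[ix] = orig
                g[ix] = (up - dn) / (2 * step)
            fd[li][name] = g
    return fd


def assert_grads_close(analytic, fd, rtol=1e-4, atol=1e-7):
    for li, (a, f) in enumerate(zip(analytic, fd)):
        for name, g_fd in f.items():
            g_an = a.get(name)
            assert g_an is not None, f"layer {li} missing gradient {name!r}"
            np.testing.assert_allclose(
                g_an, g_fd, rtol=rtol, atol=atol, err_msg=f"layer {li} {name}"
            )
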