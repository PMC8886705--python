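"""From-scratch layered neural network with manual gradients.

Supports the layer kinds needed for small image-classification CNNs:
2-D convolution (cross-correlation orientation, stride, same/valid
padding), dense, batch normalization, inverted dropout, max pooling,
flatten, ReLU, and softmax/sigmoid output heads for the three task types
(binary, multiclass, multilabel).  Forward passes return a per-layer
cache from which :func:`backward` computes exact analytic gradients of
the batch cross-entropy loss; correctness is pinned by finite-difference
oracles in the test suite.

Everything is plain NumPy and functional: ``forward`` never mutates the
parameter set (batch-norm running-statistic updates are returned in the
cache and applied explicitly by the caller via :func:`apply_bn_updates`),
so any training step can be replayed deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "SpecError",
    "LayerSpec",
    "NetworkSpec",
    "relu",
    "softmax",
    "sigmoid",
    "cross_entropy",
    "infer_shapes",
    "init_parameters",
    "forward",
    "backward",
    "apply_bn_updates",
    "build_reference_cnn",
    "build_linear_model",
    "count_parameters",
    "spec_to_dict",
    "spec_from_dict",
    "save_spec",
    "load_spec",
    "save_parameters",
    "load_parameters",
]

_PROB_FLOOR = 1e-12  # clip floor for log arguments in the loss
_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9  # running-statistic EMA weight

_LAYER_KINDS = (
    "conv2d",
    "dense",
    "batchnorm",
    "dropout",
    "maxpool",
    "flatten",
    "relu",
    "softmax",
    "sigmoid",
)
_TASKS = ("binary", "multiclass", "multilabel")


class SpecError(ValueError):
    """Architecture description is internally inconsistent with its input."""


@dataclass(frozen=True)
class LayerSpec:
    """One layer of a network; only the fields relevant to ``kind`` are used."""

    kind: str
    filters: int | None = None
    kernel_size: int = 3
    stride: int = 1
    padding: str = "valid"  # {"same", "valid"}
    units: int | None = None
    pool_size: int = 2
    pool_stride: int | None = None
    drop_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _LAYER_KINDS:
            raise SpecError(f"unknown layer kind {self.kind!r}")
        if self.kind == "conv2d":
            if self.filters is None or self.filters < 1:
                raise SpecError("conv2d requires filters >= 1")
            if self.kernel_size < 1 or self.stride < 1:
                raise SpecError("conv2d kernel_size and stride must be >= 1")
            if self.padding not in ("same", "valid"):
                raise SpecError(f"conv2d padding must be same/valid, got {self.padding!r}")
        if self.kind == "dense" and (self.units is None or self.units < 1):
            raise SpecError("dense requires units >= 1")
        if self.kind == "maxpool" and self.pool_size < 1:
            raise SpecError("maxpool pool_size must be >= 1")
        if self.kind == "dropout" and not (0.0 <= self.drop_rate < 1.0):
            raise SpecError("drop_rate must lie in [0, 1)")


@dataclass(frozen=True)
class NetworkSpec:
    """Ordered architecture plus the task it is trained for.

    ``input_shape`` is (height, width, channels) for image inputs or a
    1-tuple (features,) for flat inputs.  ``n_outputs`` is the number of
    classes (multiclass), labels (multilabel), or 1 (binary).
    """

    input_shape: tuple
    layers: tuple
    task: str
    n_outputs: int

    def __post_init__(self) -> None:
        if self.task not in _TASKS:
            raise SpecError(f"task must be one of {_TASKS}, got {self.task!r}")
        if self.n_outputs < 1:
            raise SpecError("n_outputs must be >= 1")
        object.__setattr__(self, "input_shape", tuple(int(s) for s in self.input_shape))
        object.__setattr__(self, "layers", tuple(self.layers))
        infer_shapes(self)  # fail fast on impossible chains


# ---------------------------------------------------------------------------
# elementwise primitives


def relu(x: np.ndarray) -> np.ndarray:
    """Rectified linear unit, max(0, x) elementwise."""
    return np.maximum(0.0, np.asarray(x, dtype=float))


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Shift-invariant softmax along ``axis``; rows sum to one."""
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ValueError("softmax of an empty vector is undefined")
    shifted = z - np.max(z, axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / np.sum(e, axis=axis, keepdims=True)


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def cross_entropy(
    predicted: np.ndarray,
    target: np.ndarray,
    class_weights: np.ndarray | None = None,
    kind: str = "multiclass",
) -> float:
    """Batch cross-entropy loss.

    multiclass: mean over the batch of -sum_i y_i log x_i (rows of
    ``predicted`` are probability vectors, rows of ``target`` one-hot),
    each sample's term optionally multiplied by the weight of its class.
    multilabel / binary: elementwise binary cross-entropy on sigmoid
    outputs, summed over labels and averaged over the batch, with
    optional per-label (multilabel) or per-class (binary) weights.
    Probabilities are clipped at 1e-12 before the log.
    """
    p = np.atleast_2d(np.asarray(predicted, dtype=float))
    y = np.atleast_2d(np.asarray(target, dtype=float))
    if p.shape != y.shape:
        raise ValueError(f"prediction shape {p.shape} != target shape {y.shape}")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("target entries must be 0 or 1")
    n = p.shape[0]
    if kind == "multiclass":
        logp = np.log(np.clip(p, _PROB_FLOOR, None))
        per_sample = -np.sum(y * logp, axis=1)
        if class_weights is not None:
            w = np.asarray(class_weights, dtype=float)
            per_sample = per_sample * (y @ w)
        return float(per_sample.mean())
    if kind in ("binary", "multilabel"):
        pc = np.clip(p, _PROB_FLOOR, 1.0 - _PROB_FLOOR)
        bce = -(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc))
        if class_weights is not None:
            w = np.asarray(class_weights, dtype=float)
            if kind == "binary":
                bce = bce * np.where(y == 1.0, w[1], w[0])
            else:
                bce = bce * w[np.newaxis, :]
        return float(bce.sum(axis=1).mean())
    raise ValueError(f"unknown loss kind {kind!r}")


# ---------------------------------------------------------------------------
# shape propagation


def _conv_out(size: int, k: int, s: int, padding: str) -> tuple[int, int]:
    """Return (output size, total padding) for one spatial dimension."""
    if padding == "same":
        out = -(-size // s)  # ceil
        pad = max((out - 1) * s + k - size, 0)
        return out, pad
    out = (size - k) // s + 1
    return out, 0


def infer_shapes(spec: NetworkSpec) -> list[tuple]:
    """Per-layer output shapes (excluding the batch axis); raises SpecError."""
    shape = tuple(spec.input_shape)
    shapes = []
    for i, layer in enumerate(spec.layers):
        k = layer.kind
        if k == "conv2d":
            if len(shape) != 3:
                raise SpecError(f"layer {i}: conv2d needs a 3-D input, got {shape}")
            h, w, _ = shape
            oh, _ = _conv_out(h, layer.kernel_size, layer.stride, layer.padding)
            ow, _ = _conv_out(w, layer.kernel_size, layer.stride, layer.padding)
            if oh < 1 or ow < 1:
                raise SpecError(f"layer {i}: conv2d output collapses to {oh}x{ow}")
            shape = (oh, ow, layer.filters)
        elif k == "maxpool":
            if len(shape) != 3:
                raise SpecError(f"layer {i}: maxpool needs a 3-D input, got {shape}")
            h, w, c = shape
            p = layer.pool_size
            s = layer.pool_stride or p
            oh = (h - p) // s + 1
            ow = (w - p) // s + 1
            if oh < 1 or ow < 1:
                raise SpecError(f"layer {i}: pool output collapses to {oh}x{ow}")
            shape = (oh, ow, c)
        elif k == "dense":
            if len(shape) != 1:
                raise SpecError(f"layer {i}: dense needs a flat input, got {shape}")
            shape = (layer.units,)
        elif k == "flatten":
            shape = (int(np.prod(shape)),)
        elif k in ("batchnorm", "dropout", "relu", "softmax", "sigmoid"):
            pass  # shape preserved
        else:  # pragma: no cover - guarded in LayerSpec
            raise SpecError(f"layer {i}: unknown kind {k!r}")
        shapes.append(shape)
    return shapes


# ---------------------------------------------------------------------------
# parameters


def init_parameters(spec: NetworkSpec, seed: int = 0) -> list[dict]:
    """He-style fan-in uniform init for conv/dense; BN scale 1, offset 0."""
    rng = np.random.default_rng(seed)
    params: list[dict] = []
    shape = tuple(spec.input_shape)
    for layer, out_shape in zip(spec.layers, infer_shapes(spec)):
        k = layer.kind
        if k == "conv2d":
            c_in = shape[2]
            fan_in = layer.kernel_size * layer.kernel_size * c_in
            limit = np.sqrt(6.0 / fan_in)
            w = rng.uniform(-limit, limit, (layer.kernel_size, layer.kernel_size, c_in, layer.filters))
            params.append({"w": w, "b": np.zeros(layer.filters)})
        elif k == "dense":
            fan_in = shape[0]
            limit = np.sqrt(6.0 / fan_in)
            w = rng.uniform(-limit, limit, (fan_in, layer.units))
            params.append({"w": w, "b": np.zeros(layer.units)})
        elif k == "batchnorm":
            c = shape[-1]
            params.append(
                {
                    "gamma": np.ones(c),
                    "beta": np.zeros(c),
                    "running_mean": np.zeros(c),
                    "running_var": np.ones(c),
                }
            )
        else:
            params.append({})
        shape = out_shape
    return params


def count_parameters(spec: NetworkSpec) -> tuple[list[int], int]:
    """Per-layer and total parameter counts.

    Conv: filters*(kh*kw*c_in + 1); dense: units*(inputs + 1);
    batch norm: 4 per channel (scale, offset, running mean/variance);
    pool/dropout/flatten/activations: 0.
    """
    counts = []
    shape = tuple(spec.input_shape)
    for layer, out_shape in zip(spec.layers, infer_shapes(spec)):
        k = layer.kind
        if k == "conv2d":
            counts.append(layer.filters * (layer.kernel_size * layer.kernel_size * shape[2] + 1))
        elif k == "dense":
            counts.append(layer.units * (shape[0] + 1))
        elif k == "batchnorm":
            counts.append(4 * shape[-1])
        else:
            counts.append(0)
        shape = out_shape
    return counts, int(sum(counts))


# ---------------------------------------------------------------------------
# layer forward/backward kernels


def _conv2d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int, padding: str):
    n, h, wd, _ = x.shape
    kh, kw, _, f = w.shape
    oh, ph = _conv_out(h, kh, stride, padding)
    ow, pw = _conv_out(wd, kw, stride, padding)
    pt, pl = ph // 2, pw // 2
    xp = np.pad(x, ((0, 0), (pt, ph - pt), (pl, pw - pl), (0, 0)))
    out = np.zeros((n, oh, ow, f))
    for u in range(kh):
        for v in range(kw):
            xs = xp[:, u : u + stride * oh : stride, v : v + stride * ow : stride, :]
            out += xs @ w[u, v]
    out += b
    return out, (xp, (pt, pl), (h, wd))


def _conv2d_backward(dout, w, stride, cache):
    xp, (pt, pl), (h, wd) = cache
    kh, kw, _, _ = w.shape
    n, oh, ow, _ = dout.shape
    dxp = np.zeros_like(xp)
    dw = np.zeros_like(w)
    for u in range(kh):
        for v in range(kw):
            xs = xp[:, u : u + stride * oh : stride, v : v + stride * ow : stride, :]
            dw[u, v] = np.tensordot(xs, dout, axes=([0, 1, 2], [0, 1, 2]))
            dxp[:, u : u + stride * oh : stride, v : v + stride * ow : stride, :] += dout @ w[u, v].T
    db = dout.sum(axis=(0, 1, 2))
    dx = dxp[:, pt : pt + h, pl : pl + wd, :]
    return dx, dw, db


def _maxpool_forward(x: np.ndarray, p: int, s: int):
    n, h, w, c = x.shape
    oh = (h - p) // s + 1
    ow = (w - p) // s + 1
    if s == p:
        xc = x[:, : oh * p, : ow * p, :]
        win = xc.reshape(n, oh, p, ow, p, c).transpose(0, 1, 3, 2, 4, 5).reshape(n, oh, ow, p * p, c)
    else:
        win = np.empty((n, oh, ow, p * p, c))
        for i in range(oh):
            for j in range(ow):
                win[:, i, j] = x[:, i * s : i * s + p, j * s : j * s + p, :].reshape(n, p * p, c)
    arg = win.argmax(axis=3)
    out = np.take_along_axis(win, arg[:, :, :, None, :], axis=3)[:, :, :, 0, :]
    return out, (arg, x.shape, p, s)


def _maxpool_backward(dout, cache):
    arg, xshape, p, s = cache
    n, h, w, c = xshape
    oh, ow = dout.shape[1], dout.shape[2]
    dwin = np.zeros((n, oh, ow, p * p, c))
    np.put_along_axis(dwin, arg[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
    dx = np.zeros(xshape)
    if s == p:
        block = dwin.reshape(n, oh, ow, p, p, c).transpose(0, 1, 3, 2, 4, 5).reshape(n, oh * p, ow * p, c)
        dx[:, : oh * p, : ow * p, :] = block
    else:
        for i in range(oh):
            for j in range(ow):
                dx[:, i * s : i * s + p, j * s : j * s + p, :] += dwin[:, i, j].reshape(n, p, p, c)
    return dx


def _bn_axes(x: np.ndarray) -> tuple:
    return tuple(range(x.ndim - 1))  # all but the channel/feature axis


def _batchnorm_forward(x, par, mode):
    axes = _bn_axes(x)
    if mode == "train":
        mean = x.mean(axis=axes)
        var = x.var(axis=axes)
        new_running = {
            "running_mean": _BN_MOMENTUM * par["running_mean"] + (1 - _BN_MOMENTUM) * mean,
            "running_var": _BN_MOMENTUM * par["running_var"] + (1 - _BN_MOMENTUM) * var,
        }
    else:
        mean, var = par["running_mean"], par["running_var"]
        new_running = None
    inv_std = 1.0 / np.sqrt(var + _BN_EPS)
    xhat = (x - mean) * inv_std
    out = par["gamma"] * xhat + par["beta"]
    return out, (xhat, inv_std, par["gamma"], new_running)


def _batchnorm_backward(dout, cache):
    xhat, inv_std, gamma, _ = cache
    axes = _bn_axes(dout)
    m = np.prod([dout.shape[a] for a in axes])
    dgamma = (dout * xhat).sum(axis=axes)
    dbeta = dout.sum(axis=axes)
    dx = (gamma * inv_std / m) * (m * dout - dbeta - xhat * dgamma)
    return dx, dgamma, dbeta


# ---------------------------------------------------------------------------
# network forward / backward


def forward(
    spec: NetworkSpec,
    params: list[dict],
    batch: np.ndarray,
    mode: str = "train",
    rng_seed: int = 0,
) -> tuple[np.ndarray, list]:
    """Run the network; returns (output probabilities, per-layer cache).

    Dropout is active only in train mode with masks drawn from
    ``rng_seed`` (same seed, same masks).  Batch norm uses batch
    statistics in train mode and running statistics in eval mode; the
    updated running statistics are placed in the cache and applied by the
    caller through :func:`apply_bn_updates`.
    """
    if mode not in ("train", "eval"):
        raise ValueError(f"mode must be train/eval, got {mode!r}")
    x = np.asarray(batch, dtype=float)
    expected = tuple(spec.input_shape)
    if x.shape[1:] != expected:
        raise SpecError(f"batch shape {x.shape[1:]} does not match input_shape {expected}")
    if len(params) != len(spec.layers):
        raise SpecError("parameter set does not match layer count")
    rng = np.random.default_rng(rng_seed)
    cache: list = []
    for layer, par in zip(spec.layers, params):
        k = layer.kind
        if k == "conv2d":
            x, c = _conv2d_forward(x, par["w"], par["b"], layer.stride, layer.padding)
            cache.append(("conv2d", layer, c))
        elif k == "dense":
            inp = x
            x = x @ par["w"] + par["b"]
            cache.append(("dense", layer, inp))
        elif k == "batchnorm":
            x, c = _batchnorm_forward(x, par, mode)
            cache.append(("batchnorm", layer, c))
        elif k == "dropout":
            if mode == "train" and layer.drop_rate > 0.0:
                mask = (rng.random(x.shape) >= layer.drop_rate) / (1.0 - layer.drop_rate)
                x = x * mask
                cache.append(("dropout", layer, mask))
            else:
                cache.append(("dropout", layer, None))
        elif k == "maxpool":
            x, c = _maxpool_forward(x, layer.pool_size, layer.pool_stride or layer.pool_size)
            cache.append(("maxpool", layer, c))
        elif k == "flatten":
            shape = x.shape
            x = x.reshape(shape[0], -1)
            cache.append(("flatten", layer, shape))
        elif k == "relu":
            mask = x > 0.0
            x = x * mask
            cache.append(("relu", layer, mask))
        elif k == "softmax":
            x = softmax(x, axis=-1)
            cache.append(("softmax", layer, x))
        elif k == "sigmoid":
            x = sigmoid(x)
            cache.append(("sigmoid", layer, x))
    return x, cache


def backward(
    spec: NetworkSpec,
    params: list[dict],
    cache: list,
    target: np.ndarray,
    class_weights: np.ndarray | None = None,
) -> list[dict]:
    """Gradients of the batch cross-entropy loss w.r.t. every parameter.

    The final softmax/sigmoid layer is fused with the loss: the gradient
    at its pre-activation is (predicted - target)/N, optionally scaled by
    class weights, which is exact for softmax + categorical cross-entropy
    and for sigmoid + binary cross-entropy.
    """
    if len(cache) != len(spec.layers):
        raise SpecError("cache does not match layer count")
    head_kind, _, probs = cache[-1]
    if head_kind not in ("softmax", "sigmoid"):
        raise SpecError("network must end in a softmax or sigmoid head")
    y = np.atleast_2d(np.asarray(target, dtype=float))
    if y.shape != probs.shape:
        raise SpecError(f"target shape {y.shape} != output shape {probs.shape}")
    n = probs.shape[0]
    dz = (probs - y) / n
    if class_weights is not None:
        w = np.asarray(class_weights, dtype=float)
        if spec.task == "multiclass":
            dz = dz * (y @ w)[:, None]
        elif spec.task == "binary":
            dz = dz * np.where(y == 1.0, w[1], w[0])
        else:
            dz = dz * w[np.newaxis, :]

    grads: list[dict] = [dict() for _ in spec.layers]
    dx = dz
    for i in range(len(spec.layers) - 2, -1, -1):
        kind, layer, c = cache[i]
        par = params[i]
        if kind == "conv2d":
            dx, dw, db = _conv2d_backward(dx, par["w"], layer.stride, c)
            grads[i] = {"w": dw, "b": db}
        elif kind == "dense":
            grads[i] = {"w": c.T @ dx, "b": dx.sum(axis=0)}
            dx = dx @ par["w"].T
        elif kind == "batchnorm":
            dx, dgamma, dbeta = _batchnorm_backward(dx, c)
            grads[i] = {"gamma": dgamma, "beta": dbeta}
        elif kind == "dropout":
            if c is not None:
                dx = dx * c
        elif kind == "maxpool":
            dx = _maxpool_backward(dx, c)
        elif kind == "flatten":
            dx = dx.reshape(c)
        elif kind == "relu":
            dx = dx * c
        else:  # pragma: no cover
            raise SpecError(f"unexpected cached kind {kind!r}")
    return grads


def apply_bn_updates(params: list[dict], cache: list) -> None:
    """Write the running-statistic updates from a train-mode forward pass."""
    for par, (kind, _, c) in zip(params, cache):
        if kind == "batchnorm" and c[3] is not None:
            par["running_mean"] = c[3]["running_mean"]
            par["running_var"] = c[3]["running_var"]


# ---------------------------------------------------------------------------
# reference architectures


def build_reference_cnn(input_shape: tuple, n_outputs: int, task: str = "multiclass") -> NetworkSpec:
    """The compact three-conv reference CNN.

    conv(32, 3x3, same) -> BN -> ReLU -> dropout 0.3
    -> conv(64, 3x3, valid) -> BN -> ReLU -> maxpool(4x4, stride 4)
    -> conv(128, 3x3, same) -> BN -> ReLU -> flatten
    -> dense(512) -> BN -> ReLU -> dropout 0.5 -> dense(n_outputs) head.

    For a 64x64x3 input the stage shapes are 64x64x32, 62x62x64,
    15x15x64, 15x15x128, flatten 28 800, 512.  The spatial input must be
    at least 16x16 for the pooling chain to survive.
    """
    if len(input_shape) != 3:
        raise SpecError("reference CNN expects an (h, w, c) input shape")
    if min(input_shape[0], input_shape[1]) < 16:
        raise SpecError("reference CNN needs spatial input of at least 16x16")
    head = "softmax" if task == "multiclass" else "sigmoid"
    layers = (
        LayerSpec("conv2d", filters=32, kernel_size=3, padding="same"),
        LayerSpec("batchnorm"),
        LayerSpec("relu"),
        LayerSpec("dropout", drop_rate=0.3),
        LayerSpec("conv2d", filters=64, kernel_size=3, padding="valid"),
        LayerSpec("batchnorm"),
        LayerSpec("relu"),
        LayerSpec("maxpool", pool_size=4),
        LayerSpec("conv2d", filters=128, kernel_size=3, padding="same"),
        LayerSpec("batchnorm"),
        LayerSpec("relu"),
        LayerSpec("flatten"),
        LayerSpec("dense", units=512),
        LayerSpec("batchnorm"),
        LayerSpec("relu"),
        LayerSpec("dropout", drop_rate=0.5),
        LayerSpec("dense", units=n_outputs),
        LayerSpec(head),
    )
    return NetworkSpec(input_shape=tuple(input_shape), layers=layers, task=task, n_outputs=n_outputs)


def build_linear_model(input_shape: tuple, n_outputs: int, task: str = "multiclass") -> NetworkSpec:
    """Flatten -> dense head: a logistic-regression-sized model."""
    head = "softmax" if task == "multiclass" else "sigmoid"
    layers = (
        LayerSpec("flatten"),
        LayerSpec("dense", units=n_outputs),
        LayerSpec(head),
    )
    return NetworkSpec(input_shape=tuple(input_shape), layers=layers, task=task, n_outputs=n_outputs)


# ---------------------------------------------------------------------------
# serialization


def spec_to_dict(spec: NetworkSpec) -> dict:
    layers = []
    for layer in spec.layers:
        d = {"kind": layer.kind}
        defaults = LayerSpec(layer.kind, filters=layer.filters, units=layer.units)
        for f in ("filters", "kernel_size", "stride", "padding", "units", "pool_size", "pool_stride", "drop_rate"):
            v = getattr(layer, f)
            if v != getattr(defaults, f):
                d[f] = v
            elif f in ("filters", "units") and v is not None:
                d[f] = v
        layers.append(d)
    return {
        "input_shape": list(spec.input_shape),
        "task": spec.task,
        "n_outputs": spec.n_outputs,
        "layers": layers,
    }


def spec_from_dict(d: dict) -> NetworkSpec:
    layers = tuple(LayerSpec(**layer) for layer in d["layers"])
    return NetworkSpec(
        input_shape=tuple(d["input_shape"]),
        layers=layers,
        task=d["task"],
        n_outputs=int(d["n_outputs"]),
    )


def save_spec(spec: NetworkSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)


def load_spec(path) -> NetworkSpec:
    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh))


def save_parameters(params: list[dict], path) -> None:
    """Parameter checkpoint as an ``.npz`` archive keyed layer<i>.<name>."""
    arrays = {f"layer{i}.{k}": v for i, par in enumerate(params) for k, v in par.items()}
    arrays["n_layers"] = np.asarray(len(params))
    np.savez(path, **arrays)


def load_parameters(path) -> list[dict]:
    with np.load(path) as data:
        n = int(data["n_layers"])
        params: list[dict] = [dict() for _ in range(n)]
        for key in data.files:
            if key == "n_layers":
                continue
            layer_part, name = key.split(".", 1)
            params[int(layer_part[5:])][name] = data[key]
        return params
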