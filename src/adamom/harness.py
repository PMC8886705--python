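"""Training loop, optimizer comparison, and convergence diagnostics.

The harness wires the synthetic tasks, the from-scratch network and the
optimizers into seeded, fully replayable experiments: a fixed
:class:`RunConfig` always produces the same :class:`TrainingHistory`.
For the adaptive optimizer the momentum coefficient alpha(n) is updated
once per epoch from the epoch's mean training loss and held fixed across
the following epoch's minibatches; the very first alpha comes from a
pre-training evaluation pass whose loss E(0) is self-paired.

Convergence diagnostics mirror, empirically, the properties claimed for
the adaptive schedule: monotone non-increase of the epoch loss,
approach of E(n) to a limit, and a vanishing gradient norm.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import network as net
from . import optim
from .synthetic import (
    SyntheticDataset,
    TaskSpec,
    compute_class_weights,
    make_dataset,
    train_test_split,
)

__all__ = [
    "DivergenceError",
    "TargetNotReached",
    "RunConfig",
    "TrainResult",
    "ConvergenceReport",
    "train",
    "compare_optimizers",
    "convergence_report",
    "convergence_speedup",
    "quadratic_descent",
    "multiclass_benchmark",
]

_OPTIMIZERS = ("adaptive", "sgd", "momentum_fixed", "adam", "rmsprop")


class DivergenceError(RuntimeError):
    """Training loss became NaN/Inf; message names the epoch."""


class TargetNotReached(RuntimeError):
    """A history never reached the requested target loss."""


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one training run.

    ``model`` is "reference" (the compact 3-conv CNN), "linear"
    (flatten + dense head), or an explicit :class:`~adamom.network.NetworkSpec`.
    ``fixed_momentum`` may be a scalar or a per-epoch sequence; the
    latter makes ``momentum_fixed`` replay an arbitrary alpha schedule.
    """

    task_spec: TaskSpec
    optimizer: str = "adaptive"
    model: object = "reference"
    epochs: int = 5
    batch_size: int = 32
    seed: int = 0
    test_fraction: float = 0.2
    learning_rate: float | None = None
    beta: float = 0.9
    weight_decay: float = 0.0005
    fixed_momentum: object = 0.9
    use_class_weights: bool = False
    error_kind: str = "loss"  # or "error_rate"
    eval_batch: int = 256

    def __post_init__(self) -> None:
        if self.optimizer not in _OPTIMIZERS:
            raise ValueError(f"optimizer must be one of {_OPTIMIZERS}, got {self.optimizer!r}")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.error_kind not in ("loss", "error_rate"):
            raise ValueError("error_kind must be 'loss' or 'error_rate'")


@dataclass
class TrainResult:
    """History table, final parameters, and the underlying specs."""

    history: pd.DataFrame
    params: list
    spec: net.NetworkSpec
    error_history: list
    config: RunConfig


@dataclass(frozen=True)
class ConvergenceReport:
    """Empirical analogues of the weak-convergence claims."""

    monotone_fraction: float
    limit_spread: float
    limit_reached: bool
    final_grad_norm: float | None


# ---------------------------------------------------------------------------
# parameter flattening between the network and the optimizer


def _flatten_params(params: list[dict]):
    tensors, keys, decay = [], [], []
    for i, par in enumerate(params):
        for name in sorted(par):
            if name.startswith("running_"):
                continue  # BN running stats are not optimized
            tensors.append(par[name])
            keys.append((i, name))
            decay.append(name == "w")
    return tensors, keys, decay


def _write_back(params: list[dict], tensors: list, keys: list) -> None:
    for (i, name), t in zip(keys, tensors):
        params[i][name] = t


def _batch_seed(master: int, epoch: int, batch: int) -> int:
    return (master * 1_000_003 + epoch * 10_007 + batch) % (2**31 - 1)


def _encode_targets(labels: np.ndarray, spec: net.NetworkSpec) -> np.ndarray:
    if spec.task == "multiclass":
        return np.eye(spec.n_outputs)[labels.astype(int)]
    if spec.task == "binary":
        return labels.reshape(-1, 1).astype(float)
    return labels.astype(float)


def _predict_labels(probs: np.ndarray, task: str) -> np.ndarray:
    if task == "multiclass":
        return probs.argmax(axis=1)
    return (probs >= 0.5).astype(int)


def _accuracy_of(probs: np.ndarray, labels: np.ndarray, task: str) -> float:
    pred = _predict_labels(probs, task)
    if task == "multiclass":
        return float(np.mean(pred == labels))
    if task == "binary":
        return float(np.mean(pred[:, 0] == labels))
    return float(np.mean(pred == labels))  # micro label-wise accuracy


def _eval_pass(spec, params, images, targets, labels, task, class_weights, batch):
    """Eval-mode loss and accuracy over a dataset, in batches."""
    losses, n_seen, probs_all = [], 0, []
    for start in range(0, len(images), batch):
        xb = images[start : start + batch]
        out, _ = net.forward(spec, params, xb, mode="eval")
        kind = "multiclass" if task == "multiclass" else task
        losses.append(net.cross_entropy(out, targets[start : start + batch], class_weights, kind) * len(xb))
        probs_all.append(out)
        n_seen += len(xb)
    probs = np.concatenate(probs_all)
    return float(np.sum(losses) / n_seen), _accuracy_of(probs, labels, task)


def _resolve_model(config: RunConfig, input_shape, n_outputs) -> net.NetworkSpec:
    if isinstance(config.model, net.NetworkSpec):
        return config.model
    if config.model == "reference":
        return net.build_reference_cnn(input_shape, n_outputs, config.task_spec.task)
    if config.model == "linear":
        return net.build_linear_model(input_shape, n_outputs, config.task_spec.task)
    raise ValueError(f"unknown model {config.model!r}")


def _default_lr(optimizer: str) -> float:
    return 0.001 if optimizer in ("adam", "rmsprop") else 0.01


def train(config: RunConfig, dataset: SyntheticDataset | None = None) -> TrainResult:
    """Run one seeded training experiment.

    Raises :class:`DivergenceError` (naming the epoch) if the loss goes
    non-finite — surfacing, not masking, optimizer instability.
    """
    if dataset is None:
        dataset = make_dataset(config.task_spec)
    train_ds, test_ds = train_test_split(dataset, config.test_fraction, seed=config.seed)
    task = dataset.task
    n_outputs = 1 if task == "binary" else dataset.n_classes

    x_train = train_ds.images[..., None]  # add channel axis
    x_test = test_ds.images[..., None]
    spec = _resolve_model(config, x_train.shape[1:], n_outputs)
    y_train = _encode_targets(train_ds.labels, spec)
    y_test = _encode_targets(test_ds.labels, spec)

    class_weights = None
    if config.use_class_weights:
        class_weights = compute_class_weights(train_ds.labels, dataset.n_classes)
        if task == "binary" and class_weights.shape[0] != 2:
            raise ValueError("binary task needs two class weights")

    params = net.init_parameters(spec, seed=config.seed)
    tensors, keys, decay = _flatten_params(params)
    state = optim.init_state(tensors, decay)
    eta = config.learning_rate if config.learning_rate is not None else _default_lr(config.optimizer)
    lam = config.weight_decay
    adaptive_cfg = optim.AdaptiveMomentumConfig(beta=config.beta, eta=eta, weight_decay=lam)
    baseline_cfg = None
    if config.optimizer in ("adam", "rmsprop"):
        baseline_cfg = optim.BaselineOptimizerConfig(kind=config.optimizer, learning_rate=eta)

    loss_kind = "multiclass" if task == "multiclass" else task
    error_history: list[float] = []

    if config.optimizer == "adaptive":
        e0, acc0 = _eval_pass(
            spec, params, x_train, y_train, train_ds.labels, task, class_weights, config.eval_batch
        )
        if config.error_kind == "error_rate":
            e0 = 1.0 - acc0
        state = optim.epoch_alpha_update(state, e0, adaptive_cfg)
        error_history.append(e0)

    n = len(x_train)
    rows = []
    for epoch in range(1, config.epochs + 1):
        t0 = time.perf_counter()
        alpha_used = _epoch_alpha(config, state, epoch)
        perm = np.random.default_rng(_batch_seed(config.seed, epoch, 0)).permutation(n)
        batch_losses, batch_sizes, correct, n_scored = [], [], 0, 0
        grad_norm = np.nan
        for b, start in enumerate(range(0, n, config.batch_size)):
            idx = perm[start : start + config.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            out, cache = net.forward(
                spec, params, xb, mode="train", rng_seed=_batch_seed(config.seed, epoch, b + 1)
            )
            loss = net.cross_entropy(out, yb, class_weights, loss_kind)
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"{config.optimizer}: non-finite loss at epoch {epoch}, batch {b}"
                )
            grads = net.backward(spec, params, cache, yb, class_weights)
            net.apply_bn_updates(params, cache)
            flat_grads = [grads[i].get(name, np.zeros_like(params[i][name])) for i, name in keys]
            state = _apply_step(config, state, flat_grads, alpha_used, eta, lam, baseline_cfg)
            _write_back(params, state.parameters, keys)
            batch_losses.append(loss * len(xb))
            batch_sizes.append(len(xb))
            pred = _predict_labels(out, task)
            if task == "multiclass":
                correct += int(np.sum(pred == train_ds.labels[idx]))
                n_scored += len(idx)
            elif task == "binary":
                correct += int(np.sum(pred[:, 0] == train_ds.labels[idx]))
                n_scored += len(idx)
            else:  # micro label-wise accuracy
                correct += int(np.sum(pred == train_ds.labels[idx]))
                n_scored += pred.size
            grad_norm = float(np.sqrt(sum(float(np.sum(g * g)) for g in flat_grads)))
        epoch_loss = float(np.sum(batch_losses) / n)
        train_acc = correct / n_scored
        epoch_error = (1.0 - train_acc) if config.error_kind == "error_rate" else epoch_loss
        if config.optimizer == "adaptive":
            state = optim.epoch_alpha_update(state, epoch_error, adaptive_cfg)
        error_history.append(epoch_error)
        _, test_acc = _eval_pass(
            spec, params, x_test, y_test, test_ds.labels, task, class_weights, config.eval_batch
        )
        rows.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss,
                "train_accuracy": train_acc,
                "test_accuracy": test_acc,
                "alpha": alpha_used,
                "grad_norm": grad_norm,
                "wall_time": time.perf_counter() - t0,
            }
        )
    history = pd.DataFrame(rows)
    return TrainResult(history=history, params=params, spec=spec, error_history=error_history, config=config)


def _epoch_alpha(config: RunConfig, state: optim.OptimizerState, epoch: int) -> float:
    if config.optimizer == "adaptive":
        return state.alpha_current
    if config.optimizer == "momentum_fixed":
        fm = config.fixed_momentum
        if np.isscalar(fm):
            return float(fm)
        return float(fm[epoch - 1])
    return 0.0


def _apply_step(config, state, grads, alpha, eta, lam, baseline_cfg):
    opt = config.optimizer
    if opt in ("adaptive", "momentum_fixed"):
        return optim.momentum_step(state, grads, alpha, eta, lam)
    if opt == "sgd":
        return optim.sgd_step(state, grads, eta, lam)
    if opt == "adam":
        return optim.adam_step(state, grads, baseline_cfg, lam)
    return optim.rmsprop_step(state, grads, baseline_cfg, lam)


def compare_optimizers(config: RunConfig, optimizers: list[str]) -> pd.DataFrame:
    """Per-epoch test accuracy, one column per optimizer.

    Every optimizer sees the same data, split and initial weights (the
    shared seed); a failing run aborts with the optimizer named.
    """
    if len(optimizers) < 2:
        raise ValueError("need at least two optimizers to compare")
    dataset = make_dataset(config.task_spec)
    series = []
    for opt in optimizers:
        try:
            run_cfg = replace(config, optimizer=opt, learning_rate=None)
            result = train(run_cfg, dataset=dataset)
        except Exception as exc:  # noqa: BLE001 - re-raise with context
            raise RuntimeError(f"optimizer {opt!r} failed: {exc}") from exc
        series.append(result.history["test_accuracy"].to_numpy())
    table = pd.DataFrame(np.column_stack(series), columns=list(optimizers))
    table.insert(0, "epoch", np.arange(1, config.epochs + 1))
    return table


def convergence_report(
    losses,
    tolerance: float = 1e-8,
    grad_norms=None,
    last_k: int = 5,
) -> ConvergenceReport:
    """Empirical convergence diagnostics for a loss history.

    Reports the fraction of steps with E(n+1) <= E(n) + tolerance, the
    spread (max - min) of the last ``last_k`` losses as a limit check,
    and the final gradient norm when available.
    """
    e = np.asarray(losses, dtype=float)
    if e.size == 0:
        raise ValueError("history must be non-empty")
    if e.size == 1:
        frac = 1.0
    else:
        frac = float(np.mean(np.diff(e) <= tolerance))
    tail = e[-min(last_k, e.size):]
    spread = float(tail.max() - tail.min())
    gn = None if grad_norms is None else float(np.asarray(grad_norms, dtype=float)[-1])
    return ConvergenceReport(
        monotone_fraction=frac,
        limit_spread=spread,
        limit_reached=spread <= tolerance,
        final_grad_norm=gn,
    )


def _epochs_to_target(losses, target: float) -> int:
    e = np.asarray(losses, dtype=float)
    hits = np.flatnonzero(e <= target)
    if hits.size == 0:
        raise TargetNotReached(f"target loss {target} never reached (min {e.min():.3g})")
    return int(hits[0]) + 1


def convergence_speedup(history_a, history_b, target_loss: float) -> float:
    """epochs_b / epochs_a, where each is the first 1-based epoch whose
    loss is at or below ``target_loss``.  Ratio > 1 means a is faster."""
    ea = _epochs_to_target(history_a, target_loss)
    eb = _epochs_to_target(history_b, target_loss)
    return eb / ea


# ---------------------------------------------------------------------------
# benchmarks


def quadratic_descent(
    hessian: np.ndarray,
    w0: np.ndarray,
    optimizer: str = "adaptive",
    eta: float = 0.01,
    steps: int = 500,
    beta: float = 0.9,
    fixed_momentum: float = 0.9,
) -> dict:
    """Full-batch descent on the convex quadratic E(w) = 0.5 w' H w.

    Each step is treated as an epoch: the adaptive alpha is refreshed
    from the current loss before every update (self-paired on the first
    step).  Returns losses (per step, pre-update), gradient norms,
    alphas, and the final iterate.
    """
    h = np.asarray(hessian, dtype=float)
    w = np.asarray(w0, dtype=float).copy()
    state = optim.init_state([w], [False])
    cfg = optim.AdaptiveMomentumConfig(beta=beta, eta=eta, weight_decay=0.0)
    losses, norms, alphas = [], [], []
    for _ in range(steps):
        g = h @ state.parameters[0]
        loss = 0.5 * float(state.parameters[0] @ h @ state.parameters[0])
        losses.append(loss)
        norms.append(float(np.linalg.norm(g)))
        if optimizer == "adaptive":
            state = optim.epoch_alpha_update(state, loss, cfg)
            alpha = state.alpha_current
            state = optim.momentum_step(state, [g], alpha, eta)
        elif optimizer == "momentum_fixed":
            alpha = fixed_momentum
            state = optim.momentum_step(state, [g], alpha, eta)
        elif optimizer == "sgd":
            alpha = 0.0
            state = optim.sgd_step(state, [g], eta)
        else:
            raise ValueError(f"unsupported optimizer {optimizer!r} for the quadratic benchmark")
        alphas.append(alpha)
    w_final = state.parameters[0]
    return {
        "losses": np.asarray(losses),
        "grad_norms": np.asarray(norms),
        "alphas": np.asarray(alphas),
        "final_w": w_final,
        "final_loss": 0.5 * float(w_final @ h @ w_final),
        "final_grad_norm": float(np.linalg.norm(h @ w_final)),
    }


def multiclass_benchmark(
    seeds=(0, 1, 2, 3, 4),
    optimizers=("adaptive", "sgd"),
    epochs: int = 5,
    batch_size: int = 32,
) -> pd.DataFrame:
    """Scaled-down optimizer comparison on the synthetic multiclass task.

    Study conditions (fixed): 4 imbalanced classes (0.4/0.3/0.2/0.1),
    16x16 images, 400 samples, pixel noise 0.1, test fraction 0.25,
    class weights on, the reference CNN, lr 0.01 for SGD/adaptive,
    beta 0.9, weight decay 0.0005.  Returns one row per (seed,
    optimizer) with the final test accuracy.
    """
    rows = []
    for seed in seeds:
        task = TaskSpec(
            task="multiclass",
            n_classes=4,
            image_size=16,
            n_samples=400,
            class_proportions=(0.4, 0.3, 0.2, 0.1),
            noise_sd=0.1,
            seed=seed,
        )
        dataset = make_dataset(task)
        for opt in optimizers:
            cfg = RunConfig(
                task_spec=task,
                optimizer=opt,
                model="reference",
                epochs=epochs,
                batch_size=batch_size,
                seed=seed,
                test_fraction=0.25,
                use_class_weights=True,
            )
            result = train(cfg, dataset=dataset)
            rows.append(
                {
                    "seed": seed,
                    "optimizer": opt,
                    "final_test_accuracy": float(result.history["test_accuracy"].iloc[-1]),
                    "final_train_loss": float(result.history["train_loss"].iloc[-1]),
                }
            )
    return pd.DataFrame(rows)
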