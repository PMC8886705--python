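"""Error-adaptive momentum optimization and baseline optimizers.

The central object is the adaptive momentum coefficient

    alpha(n) = beta / (1 + exp(-1 / sqrt(E(n) * E(n-1))))

where ``beta`` is the forgetting factor (0 < beta < 1) and ``E(n)`` is the
scalar training error of epoch ``n``.  The coefficient is a logistic
function of the reciprocal geometric mean of the last two epoch errors:
it rises toward ``beta`` as training error shrinks (strong momentum near a
minimum, accelerating convergence) and falls toward ``beta/2`` as the error
grows (damped momentum when the loss surface is still being explored).
``alpha(n)`` is therefore always confined to ``(beta/2, beta]`` and needs no
per-problem tuning beyond the single forgetting factor.

All update rules share one functional contract: they take an
:class:`OptimizerState` plus a congruent list of gradients and return a new
state; nothing is mutated in place, so a training step is replayable
bit-for-bit from the same inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CongruenceError",
    "AdaptiveMomentumConfig",
    "BaselineOptimizerConfig",
    "OptimizerState",
    "init_state",
    "adaptive_momentum_coefficient",
    "epoch_alpha_update",
    "momentum_step",
    "sgd_step",
    "adam_step",
    "rmsprop_step",
    "save_state",
    "load_state",
]


class CongruenceError(ValueError):
    """Gradients (or velocities) do not match parameter shapes."""


_BASELINE_KINDS = ("sgd", "momentum_fixed", "adam", "rmsprop")
# learning rates the comparison protocol fixes per optimizer family
_DEFAULT_LR = {"sgd": 0.01, "momentum_fixed": 0.01, "adam": 0.001, "rmsprop": 0.001}


@dataclass(frozen=True)
class AdaptiveMomentumConfig:
    """Hyperparameters of the error-adaptive momentum rule.

    Parameters
    ----------
    beta:
        Forgetting factor, the supremum of alpha(n).  Must lie strictly in
        (0, 1); the schedule only makes sense when beta is "large enough"
        (0.9 by default) so that early momentum is substantial.
    eta:
        Learning rate for the momentum update (0.01 by default).
    weight_decay:
        L2 penalty coefficient lambda; contributes ``2*lambda*w`` to each
        weight gradient.  Biases and batch-norm scale/offset are exempt.
    error_floor:
        Positive guard below which the error product ``E(n)*E(n-1)`` is
        treated as zero and alpha takes its analytic limit ``beta``.
    """

    beta: float = 0.9
    eta: float = 0.01
    weight_decay: float = 0.0005
    error_floor: float = 1e-30

    def __post_init__(self) -> None:
        if not (0.0 < self.beta < 1.0):
            raise ValueError(f"beta must lie in (0, 1), got {self.beta}")
        if self.eta <= 0.0:
            raise ValueError(f"eta must be positive, got {self.eta}")
        if self.weight_decay < 0.0:
            raise ValueError(f"weight_decay must be >= 0, got {self.weight_decay}")
        if self.error_floor <= 0.0:
            raise ValueError(f"error_floor must be positive, got {self.error_floor}")


@dataclass(frozen=True)
class BaselineOptimizerConfig:
    """Configuration of the reference optimizers used for comparison.

    Defaults follow the benchmarking protocol: Adam/RMSprop at learning
    rate 0.001 with beta1=0.9, beta2=0.999, epsilon=1e-7; plain and
    fixed-momentum SGD at learning rate 0.01.
    """

    kind: str
    learning_rate: float | None = None
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-7
    fixed_momentum: float = 0.9

    def __post_init__(self) -> None:
        if self.kind not in _BASELINE_KINDS:
            raise ValueError(f"kind must be one of {_BASELINE_KINDS}, got {self.kind!r}")
        if self.learning_rate is None:
            object.__setattr__(self, "learning_rate", _DEFAULT_LR[self.kind])
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0.0 <= self.fixed_momentum < 1.0):
            raise ValueError("fixed_momentum must lie in [0, 1)")


@dataclass
class OptimizerState:
    """Per-parameter tensors plus the epoch error history driving alpha(n).

    ``parameters`` and ``velocity`` are congruent ordered lists of arrays
    (one per trainable parameter group).  ``decay_mask`` marks the groups
    subject to weight decay (weights yes; biases and batch-norm
    scale/offset no).  ``slots`` holds optimizer-specific accumulators
    (Adam/RMSprop moments and step counter).
    """

    parameters: list[np.ndarray]
    velocity: list[np.ndarray]
    alpha_current: float = 0.0
    error_history: list[float] = field(default_factory=list)
    epoch_index: int = 0
    decay_mask: list[bool] = field(default_factory=list)
    slots: dict = field(default_factory=dict)


def init_state(parameters: list[np.ndarray], decay_mask: list[bool] | None = None) -> OptimizerState:
    """Create a fresh state with zero velocity around ``parameters``."""
    params = [np.asarray(p, dtype=float) for p in parameters]
    if decay_mask is None:
        decay_mask = [True] * len(params)
    if len(decay_mask) != len(params):
        raise CongruenceError("decay_mask length does not match parameter count")
    return OptimizerState(
        parameters=params,
        velocity=[np.zeros_like(p) for p in params],
        decay_mask=list(decay_mask),
    )


def _check_congruent(params: list[np.ndarray], others: list[np.ndarray], what: str) -> None:
    if len(params) != len(others):
        raise CongruenceError(f"{what}: expected {len(params)} groups, got {len(others)}")
    for i, (p, g) in enumerate(zip(params, others)):
        if np.shape(p) != np.shape(g):
            raise CongruenceError(
                f"{what}: group {i} shape {np.shape(g)} != parameter shape {np.shape(p)}"
            )


def adaptive_momentum_coefficient(
    e_curr: float,
    e_prev: float,
    beta: float,
    error_floor: float = 1e-30,
) -> float:
    """Evaluate the adaptive momentum coefficient alpha(n).

    ``alpha = beta / (1 + exp(-1/sqrt(e_curr * e_prev)))``.  When the error
    product falls at or below ``error_floor`` the analytic zero-error limit
    ``beta`` is returned (the exponent diverges to -inf, the logistic term
    to 1).  For any positive errors the result lies in ``(beta/2, beta]``.

    Raises
    ------
    ValueError
        If ``beta`` is outside (0, 1) or either error is negative or
        non-finite.
    """
    if not (0.0 < beta < 1.0):
        raise ValueError(f"beta must lie in (0, 1), got {beta}")
    for name, e in (("e_curr", e_curr), ("e_prev", e_prev)):
        if not math.isfinite(e):
            raise ValueError(f"{name} must be finite, got {e}")
        if e < 0.0:
            raise ValueError(f"{name} must be non-negative, got {e}")
    product = e_curr * e_prev
    if product <= error_floor:
        return beta
    return beta / (1.0 + math.exp(-1.0 / math.sqrt(product)))


def epoch_alpha_update(
    state: OptimizerState,
    epoch_error: float,
    config: AdaptiveMomentumConfig,
) -> OptimizerState:
    """Record an epoch error E(n) and refresh alpha for the next epoch.

    Appends ``epoch_error`` to the history and sets
    ``alpha_current = alpha(E(n), E(n-1))``.  Before two epochs exist the
    current error is self-paired, E(n-1) := E(n), which bootstraps the
    schedule from the initial loss.  The returned alpha is then held fixed
    for every minibatch step of the following epoch.
    """
    if not math.isfinite(epoch_error) or epoch_error < 0.0:
        raise ValueError(f"epoch_error must be finite and >= 0, got {epoch_error}")
    history = list(state.error_history) + [float(epoch_error)]
    e_prev = history[-2] if len(history) >= 2 else float(epoch_error)
    alpha = adaptive_momentum_coefficient(
        float(epoch_error), e_prev, config.beta, config.error_floor
    )
    return replace(
        state,
        error_history=history,
        alpha_current=alpha,
        epoch_index=state.epoch_index + 1,
    )


def _decayed(grad: np.ndarray, param: np.ndarray, lam: float, decays: bool) -> np.ndarray:
    if lam > 0.0 and decays:
        return grad + 2.0 * lam * param
    return grad


def momentum_step(
    state: OptimizerState,
    gradients: list[np.ndarray],
    alpha: float,
    eta: float,
    weight_decay: float = 0.0,
) -> OptimizerState:
    """One momentum update: v' = alpha*v - eta*(g + 2*lambda*w); w' = w + v'.

    With ``alpha = 0`` this reduces exactly to :func:`sgd_step`.  Weight
    decay applies only to groups flagged in ``state.decay_mask``.
    """
    if not (0.0 <= alpha < 1.0):
        raise ValueError(f"alpha must lie in [0, 1), got {alpha}")
    _check_congruent(state.parameters, gradients, "momentum_step gradients")
    new_v = []
    new_p = []
    for p, v, g, decays in zip(state.parameters, state.velocity, gradients, state.decay_mask):
        g = _decayed(np.asarray(g, dtype=float), p, weight_decay, decays)
        v_next = alpha * v - eta * g
        new_v.append(v_next)
        new_p.append(p + v_next)
    return replace(state, parameters=new_p, velocity=new_v)


def sgd_step(
    state: OptimizerState,
    gradients: list[np.ndarray],
    eta: float,
    weight_decay: float = 0.0,
) -> OptimizerState:
    """Plain gradient step w' = w - eta*(g + 2*lambda*w); velocity untouched."""
    _check_congruent(state.parameters, gradients, "sgd_step gradients")
    new_p = []
    for p, g, decays in zip(state.parameters, gradients, state.decay_mask):
        g = _decayed(np.asarray(g, dtype=float), p, weight_decay, decays)
        new_p.append(p - eta * g)
    return replace(state, parameters=new_p)


def adam_step(
    state: OptimizerState,
    gradients: list[np.ndarray],
    config: BaselineOptimizerConfig,
    weight_decay: float = 0.0,
) -> OptimizerState:
    """Standard Adam with bias correction at the configured defaults."""
    if config.kind != "adam":
        raise ValueError(f"adam_step requires kind='adam', got {config.kind!r}")
    _check_congruent(state.parameters, gradients, "adam_step gradients")
    slots = state.slots
    t = int(slots.get("step", 0)) + 1
    m_prev = slots.get("m") or [np.zeros_like(p) for p in state.parameters]
    v_prev = slots.get("v") or [np.zeros_like(p) for p in state.parameters]
    b1, b2, eps, lr = config.beta1, config.beta2, config.epsilon, config.learning_rate
    new_p, m_new, v_new = [], [], []
    for p, g, m, v, decays in zip(state.parameters, gradients, m_prev, v_prev, state.decay_mask):
        g = _decayed(np.asarray(g, dtype=float), p, weight_decay, decays)
        m = b1 * m + (1.0 - b1) * g
        v = b2 * v + (1.0 - b2) * g * g
        m_hat = m / (1.0 - b1**t)
        v_hat = v / (1.0 - b2**t)
        new_p.append(p - lr * m_hat / (np.sqrt(v_hat) + eps))
        m_new.append(m)
        v_new.append(v)
    return replace(state, parameters=new_p, slots={**slots, "m": m_new, "v": v_new, "step": t})


def rmsprop_step(
    state: OptimizerState,
    gradients: list[np.ndarray],
    config: BaselineOptimizerConfig,
    weight_decay: float = 0.0,
) -> OptimizerState:
    """Standard RMSprop: EMA of squared gradients with decay ``beta2``."""
    if config.kind != "rmsprop":
        raise ValueError(f"rmsprop_step requires kind='rmsprop', got {config.kind!r}")
    _check_congruent(state.parameters, gradients, "rmsprop_step gradients")
    slots = state.slots
    acc_prev = slots.get("sq") or [np.zeros_like(p) for p in state.parameters]
    rho, eps, lr = config.beta2, config.epsilon, config.learning_rate
    new_p, acc_new = [], []
    for p, g, a, decays in zip(state.parameters, gradients, acc_prev, state.decay_mask):
        g = _decayed(np.asarray(g, dtype=float), p, weight_decay, decays)
        a = rho * a + (1.0 - rho) * g * g
        new_p.append(p - lr * g / (np.sqrt(a) + eps))
        acc_new.append(a)
    return replace(state, parameters=new_p, slots={**slots, "sq": acc_new})


def save_state(state: OptimizerState, path) -> None:
    """Serialize an optimizer state to an ``.npz`` archive with shape metadata."""
    arrays = {}
    for i, (p, v) in enumerate(zip(state.parameters, state.velocity)):
        arrays[f"param_{i}"] = p
        arrays[f"velocity_{i}"] = v
    arrays["decay_mask"] = np.asarray(state.decay_mask, dtype=bool)
    arrays["error_history"] = np.asarray(state.error_history, dtype=float)
    arrays["meta"] = np.asarray([state.alpha_current, float(state.epoch_index)])
    np.savez(path, **arrays)


def load_state(path) -> OptimizerState:
    """Inverse of :func:`save_state` (optimizer slots are not persisted)."""
    with np.load(path) as data:
        n = sum(1 for k in data.files if k.startswith("param_"))
        params = [data[f"param_{i}"] for i in range(n)]
        velocity = [data[f"velocity_{i}"] for i in range(n)]
        meta = data["meta"]
        return OptimizerState(
            parameters=params,
            velocity=velocity,
            alpha_current=float(meta[0]),
            error_history=[float(x) for x in data["error_history"]],
            epoch_index=int(meta[1]),
            decay_mask=[bool(b) for b in data["decay_mask"]],
        )
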