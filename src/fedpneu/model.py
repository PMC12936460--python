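"""The 3-layer MLP base classifier and its local SGD-with-momentum trainer.

The base model is a multilayer perceptron with two hidden dense layers of
200 units (ReLU) and a 2-unit softmax output, trained with mean categorical
cross-entropy.  A client's local update runs E epochs of mini-batch SGD
with classical momentum and 1/(1 + decay*t) learning-rate decay over a
seeded per-epoch shuffle of its shard, and returns the parameter snapshot
of the epoch with the lowest shard loss (the client-side argmin rule).

Backpropagation is implemented analytically (affine / ReLU / softmax
stack); gradient correctness is pinned by finite-difference tests.
"""

from __future__ import annotations

import json
import weakref
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

_PROB_CLIP = 1e-12  # floor on predicted probabilities inside the log


class ModelParams:
    """Ordered parameter tensors [W1, b1, W2, b2, W3, b3] of the MLP.

    Live instances are counted through a weak-reference registry so the
    orchestrator's memory-hygiene contract (bounded number of simultaneous
    model copies) is testable.
    """

    _live: "weakref.WeakSet[ModelParams]" = weakref.WeakSet()
    _peak: int = 0

    def __init__(self, tensors) -> None:
        self.tensors = [np.asarray(t, dtype=np.float64) for t in tensors]
        for t in self.tensors:
            if not np.isfinite(t).all():
                raise ValueError("model parameters must be finite")
        ModelParams._live.add(self)
        ModelParams._peak = max(ModelParams._peak, len(ModelParams._live))

    @classmethod
    def live_count(cls) -> int:
        return len(cls._live)

    @classmethod
    def peak_live(cls) -> int:
        return cls._peak

    @classmethod
    def reset_peak(cls) -> None:
        cls._peak = len(cls._live)

    @property
    def shapes(self) -> list[tuple[int, ...]]:
        return [t.shape for t in self.tensors]

    def copy(self) -> "ModelParams":
        return ModelParams([t.copy() for t in self.tensors])

    def allclose(self, other: "ModelParams", atol: float = 0.0, rtol: float = 0.0) -> bool:
        return len(self.tensors) == len(other.tensors) and all(
            np.allclose(a, b, atol=atol, rtol=rtol)
            for a, b in zip(self.tensors, other.tensors)
        )

    def equals(self, other: "ModelParams") -> bool:
        """Bitwise equality of every tensor."""
        return len(self.tensors) == len(other.tensors) and all(
            a.shape == b.shape and np.array_equal(a, b)
            for a, b in zip(self.tensors, other.tensors)
        )


@dataclass
class OptimizerState:
    """Momentum velocities plus the step counter driving learning-rate decay."""

    velocity: list[np.ndarray]
    step_count: int = 0

    @classmethod
    def zeros_like(cls, params: ModelParams) -> "OptimizerState":
        return cls(velocity=[np.zeros_like(t) for t in params.tensors], step_count=0)


@dataclass
class FedConfig:
    """All federated-run hyperparameters.

    Defaults are the study configuration: batch size 32, learning rate
    1e-4, SGD with momentum 0.9 and decay 1e-6, 10 local epochs, 100
    rounds, shuffle seed 42, 90:10 split, 28x28 single-channel input.
    ``decay_mode`` selects the decay semantics: ``"lr"`` (learning-rate
    decay lr/(1 + decay*t), the default) or ``"l2"`` (weight decay).
    """

    batch_size: int = 32
    learning_rate: float = 1e-4
    momentum: float = 0.9
    decay: float = 1e-6
    decay_mode: str = "lr"
    epochs: int = 10
    rounds: int = 100
    n_clients: int = 2
    seed: int = 42
    split_ratio: float = 0.9
    image_size: tuple[int, int] = (28, 28)
    channels: int = 1
    hidden_units: int = 200

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.learning_rate < 0:
            raise ValueError(f"learning_rate must be >= 0, got {self.learning_rate}")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError(f"momentum must lie in [0, 1), got {self.momentum}")
        if self.decay < 0:
            raise ValueError(f"decay must be >= 0, got {self.decay}")
        if self.decay_mode not in ("lr", "l2"):
            raise ValueError(f"decay_mode must be 'lr' or 'l2', got {self.decay_mode!r}")
        if self.epochs < 1 or self.rounds < 1:
            raise ValueError("epochs and rounds must be >= 1")
        if self.n_clients < 1:
            raise ValueError(f"n_clients must be >= 1, got {self.n_clients}")
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError(f"split_ratio must lie in (0, 1), got {self.split_ratio}")

    @property
    def input_dim(self) -> int:
        h, w = self.image_size
        return h * w * self.channels

    def with_overrides(self, **kwargs) -> "FedConfig":
        return replace(self, **kwargs)


def init_mlp(
    input_dim: int, hidden: int = 200, n_classes: int = 2, seed: int = 42
) -> ModelParams:
    """Seeded initial parameters: scaled-uniform hidden weights, zero output layer.

    Hidden weights are Glorot-uniform; all biases and the output-layer
    weights start at zero, so the untrained network outputs exactly uniform
    class probabilities (and hence cross-entropy ln C) on any input.
    """
    if min(input_dim, hidden, n_classes) < 1:
        raise ValueError(
            f"all dimensions must be positive, got ({input_dim}, {hidden}, {n_classes})"
        )
    rng = np.random.default_rng(seed)

    def glorot(fan_in: int, fan_out: int) -> np.ndarray:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out))

    return ModelParams(
        [
            glorot(input_dim, hidden),
            np.zeros(hidden),
            glorot(hidden, hidden),
            np.zeros(hidden),
            np.zeros((hidden, n_classes)),
            np.zeros(n_classes),
        ]
    )


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward_cached(tensors, batch: np.ndarray):
    w1, b1, w2, b2, w3, b3 = tensors
    if batch.ndim != 2 or batch.shape[1] != w1.shape[0]:
        raise ValueError(
            f"batch width {batch.shape[-1] if batch.ndim else '?'} does not match "
            f"input_dim {w1.shape[0]}"
        )
    h1 = np.maximum(batch @ w1 + b1, 0.0)
    h2 = np.maximum(h1 @ w2 + b2, 0.0)
    logits = h2 @ w3 + b3
    if not np.isfinite(logits).all():
        raise FloatingPointError("non-finite activations in forward pass")
    return _softmax(logits), h1, h2


def forward(params: ModelParams, batch: np.ndarray) -> np.ndarray:
    """Class-probability matrix for a flattened batch (rows sum to 1)."""
    probs, _, _ = _forward_cached(params.tensors, np.asarray(batch, dtype=np.float64))
    return probs


def _check_one_hot(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=np.float64)
    if (
        labels.ndim != 2
        or not np.isin(labels, (0.0, 1.0)).all()
        or not (labels.sum(axis=1) == 1.0).all()
    ):
        raise ValueError("labels must be one-hot rows (one 1 per row, rest 0)")
    return labels


def local_loss(params: ModelParams, batch: np.ndarray, labels_onehot: np.ndarray) -> float:
    """Mean categorical cross-entropy -(1/n) sum_i sum_c y_ic log p_ic."""
    batch = np.asarray(batch, dtype=np.float64)
    if len(batch) == 0:
        raise ValueError("batch must be non-empty")
    labels = _check_one_hot(labels_onehot)
    probs = forward(params, batch)
    return float(-np.mean(np.sum(labels * np.log(np.maximum(probs, _PROB_CLIP)), axis=1)))


def gradients(
    params: ModelParams, batch: np.ndarray, labels_onehot: np.ndarray
) -> list[np.ndarray]:
    """Exact analytic gradients of :func:`local_loss`, shaped like the params."""
    batch = np.asarray(batch, dtype=np.float64)
    if len(batch) == 0:
        raise ValueError("batch must be non-empty")
    labels = _check_one_hot(labels_onehot)
    w1, b1, w2, b2, w3, b3 = params.tensors
    probs, h1, h2 = _forward_cached(params.tensors, batch)
    n = len(batch)

    # softmax + cross-entropy collapses to (p - y)/n at the logits
    dlogits = (probs - labels) / n
    dw3 = h2.T @ dlogits
    db3 = dlogits.sum(axis=0)
    dh2 = (dlogits @ w3.T) * (h2 > 0)
    dw2 = h1.T @ dh2
    db2 = dh2.sum(axis=0)
    dh1 = (dh2 @ w2.T) * (h1 > 0)
    dw1 = batch.T @ dh1
    db1 = dh1.sum(axis=0)
    return [dw1, db1, dw2, db2, dw3, db3]


def sgd_step(
    params: ModelParams,
    grads,
    state: OptimizerState,
    cfg: FedConfig,
) -> tuple[ModelParams, OptimizerState]:
    """One SGD-with-momentum update; pure in its inputs.

    With ``decay_mode="lr"`` the effective rate is lr_t = lr/(1 + decay*t)
    at step count t; velocities follow the classical rule v <- beta*v -
    lr_t*g and parameters move by w <- w + v.  ``decay_mode="l2"`` instead
    adds decay*w to the gradient at a constant rate.
    """
    new_tensors, new_velocity = _sgd_step_raw(
        params.tensors, list(grads), state.velocity, state.step_count, cfg
    )
    return (
        ModelParams(new_tensors),
        OptimizerState(velocity=new_velocity, step_count=state.step_count + 1),
    )


def _sgd_step_raw(tensors, grads, velocity, step_count, cfg):
    """Update on raw tensor lists (keeps transient copies out of the live-model count)."""
    if [t.shape for t in tensors] != [np.shape(g) for g in grads]:
        raise ValueError("gradient shapes do not match parameter shapes")
    if cfg.decay_mode == "lr":
        lr_t = cfg.learning_rate / (1.0 + cfg.decay * step_count)
        effective_grads = grads
    else:
        lr_t = cfg.learning_rate
        effective_grads = [g + cfg.decay * w for g, w in zip(grads, tensors)]
    new_velocity = [
        cfg.momentum * v - lr_t * g for v, g in zip(velocity, effective_grads)
    ]
    new_tensors = [w + v for w, v in zip(tensors, new_velocity)]
    return new_tensors, new_velocity


def local_update(
    global_params: ModelParams,
    shard,
    cfg: FedConfig,
    seed: int | None = None,
) -> tuple[ModelParams, float]:
    """Algorithm run at one client: E epochs of mini-batch SGD from the global model.

    The shard is reshuffled each epoch under a seeded RNG; the final
    partial batch is included.  After every epoch the loss over the full
    shard is recorded, and the snapshot of the epoch with the lowest loss
    (earliest on ties) is returned together with that loss.  The global
    parameters are never mutated.

    ``shard`` is a :class:`~fedpneu.federation.ClientShard` or any object
    with a ``data`` LabelledDataset attribute; a bare dataset also works.
    """
    data = getattr(shard, "data", shard)
    n = len(data)
    if n == 0:
        raise ValueError("client shard must be non-empty")
    x = np.ascontiguousarray(
        np.asarray(data.images, dtype=np.float64).reshape(n, -1)
    )  # row-major flattening
    y = np.asarray(data.labels_onehot, dtype=np.float64)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    # raw tensor lists keep transient copies out of the live-model registry
    tensors = [t.copy() for t in global_params.tensors]
    velocity = [np.zeros_like(t) for t in tensors]
    step_count = 0
    best_tensors: list[np.ndarray] | None = None
    best_loss = np.inf

    probe = ModelParams.__new__(ModelParams)  # uncounted view for loss/grad calls
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            probe.tensors = tensors
            grads = gradients(probe, x[idx], y[idx])
            tensors, velocity = _sgd_step_raw(tensors, grads, velocity, step_count, cfg)
            step_count += 1
        probe.tensors = tensors
        epoch_loss = local_loss(probe, x, y)
        if epoch_loss < best_loss:
            best_loss = epoch_loss
            best_tensors = [t.copy() for t in tensors]
    assert best_tensors is not None
    return ModelParams(best_tensors), float(best_loss)


def save_checkpoint(params: ModelParams, path: str | Path, meta: dict | None = None) -> None:
    """Archive the named parameter tensors plus a JSON header; bit-exact round-trip."""
    path = Path(path)
    header = {
        "format": "fedpneu-checkpoint-v1",
        "shapes": [list(s) for s in params.shapes],
        **(meta or {}),
    }
    arrays = {f"tensor_{i}": t for i, t in enumerate(params.tensors)}
    np.savez(path, __header__=np.array(json.dumps(header)), **arrays)


def load_checkpoint(path: str | Path) -> tuple[ModelParams, dict]:
    """Inverse of :func:`save_checkpoint`."""
    with np.load(Path(path), allow_pickle=False) as archive:
        header = json.loads(str(archive["__header__"]))
        n_tensors = sum(1 for k in archive.files if k.startswith("tensor_"))
        tensors = [archive[f"tensor_{i}"] for i in range(n_tensors)]
    return ModelParams(tensors), header
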