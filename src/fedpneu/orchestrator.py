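"""The federated round loop: broadcast, local update, FedAVG, evaluate, select.

Each of the R communication rounds sends the current global parameters to
every client, runs the clients' local updates sequentially in fixed client
order (the cross-silo "in parallel" is simulated; the contract is
order-independence of the aggregate, not concurrency), aggregates the
scaled results into the new global model, and evaluates it on the central
held-out test set.  After round R the round with the minimal global loss
(earliest on ties) provides the optimal model w*.

Per-round client RNG streams are derived deterministically from
(seed, round, client index) so runs are reproducible and clients are
decorrelated.  Transient per-round model copies are released eagerly; the
number of simultaneously live model copies never exceeds n_clients + 2.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import LabelledDataset
from .federation import create_shards, fedavg, scale_model, weight_scaling_factor
from .model import FedConfig, ModelParams, forward, init_mlp, local_loss, local_update

logger = logging.getLogger(__name__)


@dataclass
class RoundRecord:
    """Global metrics after one communication round."""

    round_index: int
    global_accuracy: float
    global_loss: float
    wall_time_s: float


@dataclass
class FederatedResult:
    """Round history plus the argmin-loss optimal model."""

    history: list[RoundRecord]
    w_star: ModelParams
    best_round: int

    @property
    def best_record(self) -> RoundRecord:
        return self.history[self.best_round - 1]


def evaluate_global(
    params: ModelParams, test: LabelledDataset
) -> tuple[float, float]:
    """Accuracy and mean cross-entropy of the global model on the test set.

    Predictions are argmax over class probabilities; on exact probability
    ties the lowest class index (first name in the vocabulary) wins.
    """
    n = len(test)
    if n == 0:
        raise ValueError("test set must be non-empty")
    x = np.asarray(test.images, dtype=np.float64).reshape(n, -1)
    y = np.asarray(test.labels_onehot, dtype=np.float64)
    probs = forward(params, x)
    accuracy = float(np.mean(np.argmax(probs, axis=1) == np.argmax(y, axis=1)))
    loss = local_loss(params, x, y)
    return accuracy, loss


def client_round_seed(seed: int, round_index: int, client_index: int) -> int:
    """Deterministic per-(round, client) RNG seed below 2**31."""
    return int(
        np.random.SeedSequence([seed, round_index, client_index]).generate_state(1)[0]
        % (2**31)
    )


def run_round(
    global_params: ModelParams,
    shards,
    factors,
    cfg: FedConfig,
    round_index: int,
    client_seeds=None,
) -> ModelParams:
    """One communication round: local updates, scaling, FedAVG aggregation."""
    if client_seeds is None:
        client_seeds = [
            client_round_seed(cfg.seed, round_index, k) for k in range(len(shards))
        ]
    scaled: list[ModelParams] = []
    for shard, factor, client_seed in zip(shards, factors, client_seeds):
        local_params, _ = local_update(global_params, shard, cfg, seed=client_seed)
        scaled.append(scale_model(local_params, factor.factor))
        del local_params  # release the unscaled copy promptly
    return fedavg(scaled)


def run_federated_training(
    train: LabelledDataset,
    test: LabelledDataset,
    cfg: FedConfig,
    round_callback=None,
    early_stop_accuracy: float | None = None,
) -> FederatedResult:
    """Run the full R-round federated loop and select the optimal round.

    ``round_callback(record)`` is invoked after each round (metrics
    logging, progress bars).  ``early_stop_accuracy`` terminates the loop
    once the global accuracy reaches the given level — a convenience for
    convergence studies; the argmin selection then runs over the rounds
    actually executed.
    """
    shards = create_shards(train, cfg.n_clients, cfg.seed)
    factors = [weight_scaling_factor(shards, s.client_id) for s in shards]
    input_dim = int(np.prod(train.images.shape[1:]))
    global_params = init_mlp(
        input_dim, hidden=cfg.hidden_units, n_classes=test.labels_onehot.shape[1],
        seed=cfg.seed,
    )

    history: list[RoundRecord] = []
    # the running best is kept as raw tensors so it does not count as a live model copy
    best_tensors: list[np.ndarray] | None = None
    best_loss = np.inf
    best_round = 0
    for r in range(1, cfg.rounds + 1):
        t0 = time.perf_counter()
        try:
            global_params = run_round(global_params, shards, factors, cfg, r)
            accuracy, loss = evaluate_global(global_params, test)
        except Exception as exc:
            raise RuntimeError(f"federated training failed in round {r}") from exc
        record = RoundRecord(
            round_index=r,
            global_accuracy=accuracy,
            global_loss=loss,
            wall_time_s=time.perf_counter() - t0,
        )
        history.append(record)
        if loss < best_loss:
            best_loss = loss
            best_round = r
            best_tensors = [t.copy() for t in global_params.tensors]
        logger.debug(
            "round %d: accuracy=%.4f loss=%.6f (%.2fs)",
            r, accuracy, loss, record.wall_time_s,
        )
        if round_callback is not None:
            round_callback(record)
        if early_stop_accuracy is not None and accuracy >= early_stop_accuracy:
            break
    assert best_tensors is not None
    return FederatedResult(
        history=history, w_star=ModelParams(best_tensors), best_round=best_round
    )


def train_centralized(
    train: LabelledDataset, test: LabelledDataset, cfg: FedConfig
) -> FederatedResult:
    """Single-site oracle: R repetitions of the local update on the whole set.

    Uses the same seeded shuffle, initialization and per-round RNG streams
    as a one-client federated run, but no scaling or aggregation — the
    reference against which single-client federation must be bitwise equal.
    """
    shard = create_shards(train, 1, cfg.seed)[0]
    input_dim = int(np.prod(train.images.shape[1:]))
    params = init_mlp(
        input_dim, hidden=cfg.hidden_units, n_classes=test.labels_onehot.shape[1],
        seed=cfg.seed,
    )
    history: list[RoundRecord] = []
    best_tensors: list[np.ndarray] | None = None
    best_loss = np.inf
    best_round = 0
    for r in range(1, cfg.rounds + 1):
        t0 = time.perf_counter()
        params, _ = local_update(params, shard, cfg, seed=client_round_seed(cfg.seed, r, 0))
        accuracy, loss = evaluate_global(params, test)
        history.append(
            RoundRecord(r, accuracy, loss, time.perf_counter() - t0)
        )
        if loss < best_loss:
            best_loss, best_round = loss, r
            best_tensors = [t.copy() for t in params.tensors]
    assert best_tensors is not None
    return FederatedResult(
        history=history, w_star=ModelParams(best_tensors), best_round=best_round
    )


def select_optimal(history) -> int:
    """Round index minimizing the global loss; earliest round on ties."""
    records = list(history)
    if not records:
        raise ValueError("history must be non-empty")
    best = min(records, key=lambda rec: (rec.global_loss, rec.round_index))
    return best.round_index


def _full_precision(x) -> str:
    """Shortest decimal string that round-trips the float exactly."""
    return repr(float(x))


def write_metrics(history, path: str | Path) -> tuple[Path, Path]:
    """Serialize the round history to CSV, plus a per-10-round summary.

    The main file has columns ``round,global_accuracy,global_loss,
    wall_time_s``; the companion ``*_summary.csv`` keeps rounds 10, 20, ...
    (and the final round if it is not a multiple of 10).  Values round-trip
    at full precision.  Returns both paths.
    """
    records = list(history)
    if not records:
        raise ValueError("cannot write metrics for an empty history")
    path = Path(path)
    frame = pd.DataFrame(
        {
            "round": [r.round_index for r in records],
            "global_accuracy": [r.global_accuracy for r in records],
            "global_loss": [r.global_loss for r in records],
            "wall_time_s": [r.wall_time_s for r in records],
        }
    )
    frame.to_csv(path, index=False, float_format=_full_precision)
    last = records[-1].round_index
    keep = frame["round"].map(lambda r: r % 10 == 0 or r == last)
    summary_path = path.with_name(path.stem + "_summary" + path.suffix)
    frame[keep].to_csv(summary_path, index=False, float_format=_full_precision)
    return path, summary_path


def read_metrics(path: str | Path) -> list[RoundRecord]:
    """Inverse of :func:`write_metrics` for the main metrics file."""
    frame = pd.read_csv(path, float_precision="round_trip")
    return [
        RoundRecord(
            round_index=int(row["round"]),
            global_accuracy=float(row["global_accuracy"]),
            global_loss=float(row["global_loss"]),
            wall_time_s=float(row["wall_time_s"]),
        )
        for _, row in frame.iterrows()
    ]
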