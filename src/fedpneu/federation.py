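"""Client sharding, data-proportional scaling factors, and FedAVG aggregation.

The cross-silo setting is simulated: the pooled training set is shuffled
once under a seed and partitioned into near-equal contiguous shards, one
per participating client ("clients_1", "clients_2", ...).  Each client's
scaling factor is its share of the total training data; aggregation sums
the pre-scaled parameter tensors, which — because the factors sum to 1 —
is the data-weighted average of the client models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import LabelledDataset
from .model import ModelParams


@dataclass
class ClientShard:
    """One client's private partition of the training data."""

    client_id: str
    data: LabelledDataset

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class ScalingFactor:
    """A client's fraction of the pooled training data, in (0, 1]."""

    client_id: str
    factor: float


def create_shards(
    train: LabelledDataset, n_clients: int, seed: int = 42
) -> list[ClientShard]:
    """Partition the training set into ``n_clients`` IID shards.

    The partition is a contiguous slicing of the seeded shuffle; shard
    sizes differ by at most one, with the first ``N mod n_clients`` shards
    receiving the extra sample.
    """
    n = len(train)
    if n_clients < 1:
        raise ValueError(f"n_clients must be >= 1, got {n_clients}")
    if n_clients > n:
        raise ValueError(f"cannot create {n_clients} shards from {n} samples")
    order = np.random.default_rng(seed).permutation(n)
    base, extra = divmod(n, n_clients)
    shards: list[ClientShard] = []
    start = 0
    for k in range(n_clients):
        size = base + (1 if k < extra else 0)
        shards.append(
            ClientShard(
                client_id=f"clients_{k + 1}",
                data=train.subset(order[start : start + size]),
            )
        )
        start += size
    return shards


def weight_scaling_factor(shards, client_id: str) -> ScalingFactor:
    """factor = |shard(client_id)| / sum of all shard sizes."""
    sizes = {s.client_id: len(s) for s in shards}
    if client_id not in sizes:
        raise KeyError(f"unknown client_id {client_id!r}; have {sorted(sizes)}")
    return ScalingFactor(
        client_id=client_id, factor=sizes[client_id] / sum(sizes.values())
    )


def scale_model(params: ModelParams, factor: float) -> ModelParams:
    """Multiply every parameter tensor elementwise by ``factor``."""
    if not np.isfinite(factor):
        raise ValueError(f"scaling factor must be finite, got {factor}")
    if not 0.0 < factor <= 1.0:
        raise ValueError(f"scaling factor must lie in (0, 1], got {factor}")
    return ModelParams([t * factor for t in params.tensors])


def fedavg(scaled_params_list) -> ModelParams:
    """Tensor-wise sum of pre-scaled client parameters.

    With data-proportional factors summing to 1 this is the data-weighted
    average of the client models.  Summation runs in list order (fixed
    client-id order upstream) for bit-reproducibility.
    """
    scaled = list(scaled_params_list)
    if not scaled:
        raise ValueError("fedavg requires at least one client model")
    ref_shapes = scaled[0].shapes
    for k, params in enumerate(scaled[1:], start=1):
        for j, (a, b) in enumerate(zip(ref_shapes, params.shapes)):
            if a != b:
                raise ValueError(
                    f"shape mismatch in tensor {j} of client entry {k}: {b} != {a}"
                )
        if len(params.tensors) != len(ref_shapes):
            raise ValueError(f"client entry {k} has a different tensor count")
    total = [t.copy() for t in scaled[0].tensors]
    for params in scaled[1:]:
        for j, t in enumerate(params.tensors):
            total[j] += t
    return ModelParams(total)
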