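"""MLP forward/loss/backprop, the momentum-SGD update rule, the client-side
epoch-argmin local update, and checkpoint round-trips."""

import math

import numpy as np
import pytest

from fedpneu import (
    FedConfig,
    ModelParams,
    OptimizerState,
    create_shards,
    forward,
    gradients,
    init_mlp,
    load_checkpoint,
    local_loss,
    local_update,
    save_checkpoint,
    sgd_step,
)
from fedpneu.model import _sgd_step_raw


def identity_stack():
    """2-in/2-hidden/2-out net whose logits equal its (non-negative) inputs."""
    eye = np.eye(2)
    zero = np.zeros(2)
    return ModelParams([eye, zero, eye, zero, eye, zero])


def logits_for_probs(probs):
    """Non-negative inputs whose softmax through the identity stack is `probs`."""
    logs = np.log(np.asarray(probs, dtype=np.float64))
    return logs - logs.min(axis=1, keepdims=True)


class TestInitAndForward:
    def test_architecture_shapes(self):
        params = init_mlp(784, hidden=200, n_classes=2, seed=0)
        assert params.shapes == [
            (784, 200), (200,), (200, 200), (200,), (200, 2), (2,),
        ]

    def test_seeded_init_is_deterministic(self):
        assert init_mlp(10, 5, 2, seed=3).equals(init_mlp(10, 5, 2, seed=3))
        assert not init_mlp(10, 5, 2, seed=3).equals(init_mlp(10, 5, 2, seed=4))

    def test_nonpositive_dimension_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            init_mlp(0, 5, 2, seed=1)

    def test_zero_output_layer_yields_uniform_probabilities(self):
        params = init_mlp(12, hidden=7, n_classes=2, seed=5)
        probs = forward(params, np.random.default_rng(0).uniform(size=(9, 12)))
        assert np.allclose(probs, 0.5, atol=1e-12)

    def test_rows_always_sum_to_one(self):
        rng = np.random.default_rng(1)
        params = ModelParams([rng.normal(size=s) for s in
                              [(6, 4), (4,), (4, 4), (4,), (4, 2), (2,)]])
        probs = forward(params, rng.uniform(size=(20, 6)))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(probs >= 0)

    def test_hand_computed_forward_pass(self):
        # x=(1,2); W1=[[1,0],[1,1]], b1=(0.5,-3) -> pre-act (3.5,-1), ReLU (3.5,0)
        # W2=[[1,1],[0,1]], b2=0 -> (3.5,3.5), ReLU same
        # W3=[[1,0],[0,2]], b3=(0,-3.5) -> logits (3.5, 3.5); softmax (0.5, 0.5)
        params = ModelParams([
            np.array([[1.0, 0.0], [1.0, 1.0]]), np.array([0.5, -3.0]),
            np.array([[1.0, 1.0], [0.0, 1.0]]), np.zeros(2),
            np.array([[1.0, 0.0], [0.0, 2.0]]), np.array([0.0, -3.5]),
        ])
        probs = forward(params, np.array([[1.0, 2.0]]))
        assert probs[0] == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_batch_width_mismatch_rejected(self):
        with pytest.raises(ValueError, match="input_dim"):
            forward(init_mlp(4, 3, 2, seed=0), np.zeros((2, 5)))


class TestLocalLoss:
    def test_uniform_predictions_give_ln2(self):
        params = init_mlp(6, 4, 2, seed=0)
        x = np.random.default_rng(2).uniform(size=(10, 6))
        y = np.tile([[1.0, 0.0]], (10, 1))
        assert local_loss(params, x, y) == pytest.approx(math.log(2), abs=1e-12)

    def test_saturated_correct_predictions_give_near_zero_loss(self):
        params = identity_stack()
        x = np.array([[60.0, 0.0], [0.0, 60.0]])  # logit gap 60 -> p ~ 1
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert local_loss(params, x, y) <= 1e-10

    def test_stated_probability_batch_matches_hand_mean(self):
        probs = [[0.9, 0.1], [0.2, 0.8], [0.6, 0.4]]
        y = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        loss = local_loss(identity_stack(), logits_for_probs(probs), y)
        expected = -(math.log(0.9) + math.log(0.8) + math.log(0.6)) / 3
        assert loss == pytest.approx(expected, abs=1e-12)

    def test_non_one_hot_labels_rejected(self):
        params = init_mlp(2, 2, 2, seed=0)
        with pytest.raises(ValueError, match="one-hot"):
            local_loss(params, np.zeros((1, 2)), np.array([[0.5, 0.5]]))


class TestGradients:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_central_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        params = ModelParams([rng.normal(scale=0.5, size=s) for s in
                              [(2, 3), (3,), (3, 3), (3,), (3, 2), (2,)]])
        x = rng.uniform(size=(4, 2))
        y = np.eye(2)[rng.integers(0, 2, size=4)]
        grads = gradients(params, x, y)
        step = 1e-5
        for j, tensor in enumerate(params.tensors):
            for idx in np.ndindex(tensor.shape):
                hi, lo = params.copy(), params.copy()
                hi.tensors[j][idx] += step
                lo.tensors[j][idx] -= step
                fd = (local_loss(hi, x, y) - local_loss(lo, x, y)) / (2 * step)
                assert grads[j][idx] == pytest.approx(
                    fd, rel=1e-4, abs=1e-7
                ), f"tensor {j} entry {idx}"

    def test_gradient_vanishes_at_a_saturated_minimum(self):
        params = identity_stack()
        x = np.array([[60.0, 0.0]])
        y = np.array([[1.0, 0.0]])
        grads = gradients(params, x, y)
        assert max(np.abs(g).max() for g in grads) <= 1e-6

    def test_duplicating_the_batch_leaves_the_mean_gradient_unchanged(self):
        rng = np.random.default_rng(9)
        params = init_mlp(3, 4, 2, seed=1)
        x = rng.uniform(size=(5, 3))
        y = np.eye(2)[rng.integers(0, 2, size=5)]
        single = gradients(params, x, y)
        doubled = gradients(params, np.vstack([x, x]), np.vstack([y, y]))
        assert all(np.allclose(a, b, atol=1e-14) for a, b in zip(single, doubled))


class TestSgdStep:
    def test_two_momentum_steps_reproduce_hand_recursion(self):
        cfg = FedConfig(learning_rate=0.1, momentum=0.9, decay=0.0)
        params = ModelParams([np.array([1.0])])
        state = OptimizerState.zeros_like(params)
        grads = [np.array([1.0])]
        params, state = sgd_step(params, grads, state, cfg)  # v1=-0.1, w=0.9
        params, state = sgd_step(params, grads, state, cfg)  # v2=-0.19, w=0.71
        assert params.tensors[0][0] == pytest.approx(0.71, abs=1e-15)
        assert state.step_count == 2

    def test_zero_momentum_reduces_to_vanilla_sgd_bitwise(self):
        rng = np.random.default_rng(4)
        cfg = FedConfig(learning_rate=0.05, momentum=0.0, decay=0.0)
        params = ModelParams([rng.normal(size=(3, 2)), rng.normal(size=2)])
        grads = [rng.normal(size=(3, 2)), rng.normal(size=2)]
        stepped, _ = sgd_step(params, grads, OptimizerState.zeros_like(params), cfg)
        for w, g, out in zip(params.tensors, grads, stepped.tensors):
            assert np.array_equal(out, w - cfg.learning_rate * g)

    def test_zero_gradient_drifts_by_decayed_velocity_only(self):
        cfg = FedConfig(learning_rate=0.1, momentum=0.9, decay=0.0)
        params = ModelParams([np.array([2.0])])
        state = OptimizerState(velocity=[np.array([0.5])], step_count=3)
        stepped, new_state = sgd_step(params, [np.array([0.0])], state, cfg)
        assert new_state.velocity[0][0] == pytest.approx(0.45)
        assert stepped.tensors[0][0] == pytest.approx(2.45)

    def test_learning_rate_decay_schedule(self):
        cfg = FedConfig(learning_rate=0.1, momentum=0.0, decay=0.5)
        params = ModelParams([np.array([0.0])])
        state = OptimizerState(velocity=[np.array([0.0])], step_count=2)
        stepped, _ = sgd_step(params, [np.array([1.0])], state, cfg)
        # lr_t = 0.1 / (1 + 0.5 * 2) = 0.05
        assert stepped.tensors[0][0] == pytest.approx(-0.05)

    def test_l2_mode_applies_weight_decay_at_constant_rate(self):
        cfg = FedConfig(learning_rate=0.1, momentum=0.0, decay=0.01,
                        decay_mode="l2")
        params = ModelParams([np.array([2.0])])
        state = OptimizerState.zeros_like(params)
        stepped, _ = sgd_step(params, [np.array([0.0])], state, cfg)
        assert stepped.tensors[0][0] == pytest.approx(2.0 - 0.1 * 0.01 * 2.0)

    def test_shape_mismatch_rejected(self):
        params = ModelParams([np.zeros((2, 2))])
        with pytest.raises(ValueError, match="shape"):
            sgd_step(params, [np.zeros(3)], OptimizerState.zeros_like(params),
                     FedConfig())


class TestLocalUpdate:
    def _shard(self, pair, n_clients=1, seed=0):
        return create_shards(pair.train, n_clients, seed=seed)[0]

    def test_single_epoch_full_batch_equals_one_sgd_step(self, small_pair):
        shard = self._shard(small_pair)
        cfg = FedConfig(batch_size=len(shard), epochs=1, learning_rate=0.01,
                        momentum=0.9)
        global_params = init_mlp(np.prod(shard.data.images.shape[1:]), 16, 2, seed=0)
        best, best_loss = local_update(global_params, shard, cfg, seed=123)

        x = shard.data.images.reshape(len(shard), -1)
        y = shard.data.labels_onehot
        # the epoch visits the seeded shuffle; replay it for bitwise agreement
        order = np.random.default_rng(123).permutation(len(shard))
        expected, _ = sgd_step(
            global_params, gradients(global_params, x[order], y[order]),
            OptimizerState.zeros_like(global_params), cfg,
        )
        assert best.equals(expected)
        assert best_loss == local_loss(expected, x, y)

    def test_frozen_learning_rate_returns_global_params_bitwise(self, small_pair):
        shard = self._shard(small_pair)
        cfg = FedConfig(learning_rate=0.0, epochs=3)
        global_params = init_mlp(np.prod(shard.data.images.shape[1:]), 8, 2, seed=1)
        best, best_loss = local_update(global_params, shard, cfg, seed=5)
        assert best.equals(global_params)
        x = shard.data.images.reshape(len(shard), -1)
        assert best_loss == local_loss(global_params, x, shard.data.labels_onehot)

    def test_returns_argmin_epoch_snapshot(self, small_pair):
        """Dual-route: replay the epoch loop with the public primitives and
        check the returned snapshot is the epoch-end argmin."""
        shard = self._shard(small_pair)
        cfg = FedConfig(batch_size=32, epochs=4, learning_rate=0.05, momentum=0.9)
        global_params = init_mlp(np.prod(shard.data.images.shape[1:]), 8, 2, seed=2)
        best, best_loss = local_update(global_params, shard, cfg, seed=77)

        x = shard.data.images.reshape(len(shard), -1)
        y = shard.data.labels_onehot
        rng = np.random.default_rng(77)
        params = global_params.copy()
        state = OptimizerState.zeros_like(params)
        epoch_losses, snapshots = [], []
        for _ in range(cfg.epochs):
            order = rng.permutation(len(shard))
            for start in range(0, len(shard), cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                params, state = sgd_step(
                    params, gradients(params, x[idx], y[idx]), state, cfg
                )
            epoch_losses.append(local_loss(params, x, y))
            snapshots.append(params.copy())
        k = int(np.argmin(epoch_losses))  # earliest argmin
        assert best_loss == epoch_losses[k]
        assert best.equals(snapshots[k])

    def test_training_reduces_loss_on_separable_data(self, small_pair):
        shard = self._shard(small_pair)
        cfg = FedConfig(learning_rate=0.01, epochs=10, batch_size=32)
        global_params = init_mlp(np.prod(shard.data.images.shape[1:]), 32, 2, seed=0)
        x = shard.data.images.reshape(len(shard), -1)
        initial = local_loss(global_params, x, shard.data.labels_onehot)
        _, best_loss = local_update(global_params, shard, cfg, seed=9)
        assert best_loss < initial

    def test_global_params_are_never_mutated(self, small_pair):
        shard = self._shard(small_pair)
        global_params = init_mlp(np.prod(shard.data.images.shape[1:]), 8, 2, seed=3)
        frozen = global_params.copy()
        local_update(global_params, shard,
                     FedConfig(learning_rate=0.02, epochs=2), seed=1)
        assert global_params.equals(frozen)

    def test_identical_inputs_give_bitwise_identical_outputs(self, small_pair):
        shard = self._shard(small_pair)
        cfg = FedConfig(learning_rate=0.01, epochs=2)
        global_params = init_mlp(np.prod(shard.data.images.shape[1:]), 8, 2, seed=4)
        a, loss_a = local_update(global_params, shard, cfg, seed=11)
        b, loss_b = local_update(global_params, shard, cfg, seed=11)
        assert a.equals(b) and loss_a == loss_b
        c, _ = local_update(global_params, shard, cfg, seed=12)
        assert not a.equals(c)

    def test_empty_shard_rejected(self):
        from fedpneu.data import LabelledDataset
        from fedpneu.federation import ClientShard

        empty = ClientShard("clients_1", LabelledDataset(
            np.empty((0, 2, 2, 1)), np.empty((0, 2)), ("normal", "pneumonia")))
        with pytest.raises(ValueError, match="non-empty"):
            local_update(init_mlp(4, 2, 2, seed=0), empty, FedConfig())


class TestCheckpoint:
    def test_bit_exact_round_trip_with_header(self, tmp_path):
        params = init_mlp(12, 6, 2, seed=8)
        path = tmp_path / "model.npz"
        save_checkpoint(params, path, meta={"best_round": 27})
        loaded, header = load_checkpoint(path)
        assert loaded.equals(params)
        assert header["best_round"] == 27
        assert header["shapes"] == [list(s) for s in params.shapes]


def test_raw_step_helper_matches_public_sgd_step():
    rng = np.random.default_rng(0)
    cfg = FedConfig(learning_rate=0.1, momentum=0.9, decay=1e-3)
    tensors = [rng.normal(size=(2, 2))]
    grads = [rng.normal(size=(2, 2))]
    vel = [rng.normal(size=(2, 2))]
    raw_t, raw_v = _sgd_step_raw(tensors, grads, vel, 5, cfg)
    public, new_state = sgd_step(
        ModelParams(tensors), grads, OptimizerState(velocity=vel, step_count=5), cfg
    )
    assert np.array_equal(raw_t[0], public.tensors[0])
    assert np.array_equal(raw_v[0], new_state.velocity[0])
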