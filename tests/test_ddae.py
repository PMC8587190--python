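"""Denoising autoencoder, single-layer fine-tuning and the transfer store."""

import numpy as np
import pytest

import eanr
from eanr.ddae import (
    TransferEntry, apply_transfer, build_store, ddae_enhance, ddae_init,
    ddae_train, derive_nd_layer, layer_sweep, substituted_layer_index,
)
from eanr.errors import InvalidArgumentError, StaleStoreError
from eanr.features import NormStats
from eanr.mlp import MlpModel, TrainCfg, count_parameters


def _identity_ddae(width=6, n_layers=5):
    """ReLU network that is the identity on non-negative inputs."""
    ws = [np.eye(width) for _ in range(n_layers)]
    bs = [np.zeros(width) for _ in range(n_layers)]
    m = MlpModel(ws, bs, "relu", "linear")
    m.norm_stats = NormStats.identity(width)
    return m


def _trained_tiny(seed=0, epochs=40):
    rng = np.random.default_rng(seed)
    clean = rng.standard_normal((400, 8))
    noisy = clean + 0.3 * rng.standard_normal((400, 8))
    model = ddae_init((8, 6, 6, 6, 6, 8), seed=seed)
    trained, hist = ddae_train(model, noisy, clean,
                               TrainCfg(lr=1e-3, epochs=epochs, seed=seed))
    return trained, noisy, clean, hist


class TestInit:
    def test_example_parameter_count(self):
        assert count_parameters(ddae_init((8, 4, 4, 4, 4, 8), 0)) == 136

    def test_relu_hidden_linear_output(self):
        m = _identity_ddae()
        x = np.array([[1.0, -1.0, 2.0, 0.0, 0.5, -3.0]])
        # identity weights, so hidden relu clips the negatives once
        out = m.forward(x)
        assert np.allclose(out, np.maximum(x, 0.0))

    def test_deterministic(self):
        a, b = ddae_init(seed=5), ddae_init(seed=5)
        for wa, wb in zip(a.weights, b.weights):
            assert np.array_equal(wa, wb)

    def test_width_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ddae_init((8, 4, 4, 4, 4, 7), 0)

    def test_substituted_index_default(self):
        assert substituted_layer_index(5) == 2  # L - r with r = 3
        assert substituted_layer_index(5, r=1) == 4
        with pytest.raises(InvalidArgumentError):
            substituted_layer_index(5, r=5)


class TestEnhance:
    def test_identity_network_passes_input_through(self):
        m = _identity_ddae()
        x = np.abs(np.random.default_rng(0).standard_normal((20, 6)))
        assert np.allclose(ddae_enhance(m, x), x, atol=1e-6)

    def test_output_shape_matches_input(self):
        trained, noisy, _, _ = _trained_tiny()
        assert ddae_enhance(trained, noisy).shape == noisy.shape

    def test_overfits_a_single_repeated_pair(self):
        rng = np.random.default_rng(2)
        clean = rng.standard_normal((1, 8))
        noisy = clean + rng.standard_normal((1, 8))
        model = ddae_init((8, 16, 16, 16, 16, 8), seed=2)
        model.norm_stats = NormStats.identity(8)
        trained, hist = ddae_train(model, np.repeat(noisy, 32, 0),
                                   np.repeat(clean, 32, 0),
                                   TrainCfg(lr=1e-3, epochs=300, seed=2))
        assert hist[-1] < 0.01 * hist[0]
        assert np.allclose(ddae_enhance(trained, noisy), clean, atol=0.15)

    def test_width_mismatch_rejected(self):
        trained, _, _, _ = _trained_tiny()
        with pytest.raises(InvalidArgumentError):
            ddae_enhance(trained, np.ones((3, 5)))


class TestTraining:
    def test_autoencoding_clean_data_drives_loss_down(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((500, 8))
        model = ddae_init((8, 16, 16, 16, 16, 8), seed=1)
        _, hist = ddae_train(model, x, x,
                             TrainCfg(lr=1e-3, epochs=1500, seed=1))
        assert hist[-1] < hist[0]
        assert hist[-1] / x.shape[1] < 1e-3  # per-unit normalized MSE

    def test_all_frozen_mask_rejected(self):
        model = ddae_init((8, 6, 6, 6, 6, 8), 0)
        with pytest.raises(InvalidArgumentError):
            ddae_train(model, np.ones((4, 8)), np.ones((4, 8)),
                       TrainCfg(epochs=1, trainable_mask=(False,) * 5))

    def test_single_trainable_layer_changes_exactly_one_pair(self):
        rng = np.random.default_rng(4)
        noisy = rng.standard_normal((200, 8))
        clean = rng.standard_normal((200, 8))
        model = ddae_init((8, 6, 6, 6, 6, 8), seed=4)
        mask = tuple(i == 1 for i in range(5))  # weight layer 2 = L - r, r=3
        trained, _ = ddae_train(model, noisy, clean,
                                TrainCfg(epochs=3, trainable_mask=mask))
        changed = [not (np.array_equal(trained.weights[i], model.weights[i])
                        and np.array_equal(trained.biases[i], model.biases[i]))
                   for i in range(5)]
        assert changed == [False, True, False, False, False]

    def test_misaligned_pairs_rejected(self):
        model = ddae_init((8, 6, 6, 6, 6, 8), 0)
        with pytest.raises(InvalidArgumentError):
            ddae_train(model, np.ones((4, 8)), np.ones((5, 8)), TrainCfg(epochs=1))


class TestTransfer:
    def test_entry_shape_matches_base_layer(self):
        trained, noisy, clean, _ = _trained_tiny()
        entry = derive_nd_layer(trained, noisy, clean, class_id=0,
                                cfg=TrainCfg(lr=1e-4, epochs=2))
        assert entry.weight.shape == trained.weights[1].shape
        assert entry.bias.shape == trained.biases[1].shape

    def test_zero_epoch_fine_tune_is_identity(self):
        trained, noisy, clean, _ = _trained_tiny()
        entry = derive_nd_layer(trained, noisy, clean, class_id=0,
                                cfg=TrainCfg(epochs=0))
        assert np.array_equal(entry.weight, trained.weights[1])
        assert np.array_equal(entry.bias, trained.biases[1])

    def test_base_model_never_mutated(self):
        trained, noisy, clean, _ = _trained_tiny()
        before = trained.checksum()
        derive_nd_layer(trained, noisy, clean, class_id=0,
                        cfg=TrainCfg(lr=1e-3, epochs=3))
        store = build_store(trained, [TransferEntry(
            0, trained.weights[1] + 1.0, trained.biases[1] + 1.0, 1)])
        apply_transfer(trained, store, 0)
        assert trained.checksum() == before

    def test_bad_index_rejected(self):
        trained, noisy, clean, _ = _trained_tiny()
        with pytest.raises(InvalidArgumentError):
            derive_nd_layer(trained, noisy, clean, 0, substituted_index=6,
                            cfg=TrainCfg(epochs=1))

    def test_untrained_base_rejected(self):
        model = ddae_init((8, 6, 6, 6, 6, 8), 0)
        with pytest.raises(InvalidArgumentError):
            derive_nd_layer(model, np.ones((4, 8)), np.ones((4, 8)), 0)

    def test_apply_swaps_only_the_stored_layer(self):
        trained, noisy, clean, _ = _trained_tiny()
        e0 = derive_nd_layer(trained, noisy, clean, 0, cfg=TrainCfg(lr=1e-3, epochs=3, seed=1))
        e1 = derive_nd_layer(trained, noisy, clean, 1, cfg=TrainCfg(lr=1e-3, epochs=6, seed=2))
        store = build_store(trained, [e0, e1])
        nd0 = apply_transfer(trained, store, 0)
        nd1 = apply_transfer(trained, store, 1)
        for i in range(5):
            if i == 1:
                continue
            assert np.array_equal(nd0.weights[i], trained.weights[i])
            assert np.array_equal(nd1.weights[i], trained.weights[i])
        assert not np.array_equal(nd0.weights[1], nd1.weights[1])

    def test_zero_epoch_store_reproduces_base_outputs(self):
        trained, noisy, clean, _ = _trained_tiny()
        entry = derive_nd_layer(trained, noisy, clean, 0, cfg=TrainCfg(epochs=0))
        nd = apply_transfer(trained, build_store(trained, [entry]), 0)
        x = np.random.default_rng(7).standard_normal((10, 8))
        assert np.array_equal(ddae_enhance(nd, x), ddae_enhance(trained, x))

    def test_stale_store_rejected(self):
        trained, noisy, clean, _ = _trained_tiny()
        store = build_store(trained, [derive_nd_layer(
            trained, noisy, clean, 0, cfg=TrainCfg(epochs=0))])
        other, _, _, _ = _trained_tiny(seed=9)
        with pytest.raises(StaleStoreError):
            apply_transfer(other, store, 0)

    def test_unknown_class_rejected(self):
        trained, noisy, clean, _ = _trained_tiny()
        store = build_store(trained, [derive_nd_layer(
            trained, noisy, clean, 0, cfg=TrainCfg(epochs=0))])
        with pytest.raises(KeyError):
            apply_transfer(trained, store, 5)


class TestLayerSweep:
    def test_grid_and_zero_epoch_identity(self):
        trained, noisy, clean, _ = _trained_tiny()
        data = {0: (noisy[:100], clean[:100]), 1: (noisy[100:], clean[100:])}

        def eval_fn(cid, model):
            lo, hi = (0, 100) if cid == 0 else (100, 200)
            pred = ddae_enhance(model, noisy[lo:hi])
            return {"mse": float(np.mean((pred - clean[lo:hi]) ** 2))}

        table = layer_sweep(trained, data, eval_fn, r_values=(0, 1, 2, 3, 4),
                            cfg=TrainCfg(epochs=0))
        assert sorted(table["r"].unique()) == [0, 1, 2, 3, 4]
        assert sorted(table["substituted_index"].unique()) == [1, 2, 3, 4, 5]
        assert len(table) == 10
        # 0-epoch fine-tune: every row equals the base model's score
        base = {cid: eval_fn(cid, trained)["mse"] for cid in (0, 1)}
        for _, row in table.iterrows():
            assert row["mse"] == base[row["class_id"]]
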