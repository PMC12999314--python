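import numpy as np
import pytest

import ppifern.sdae as sdae
from ppifern.sdae import (
    CorruptionSpec,
    LayerParams,
    SDAEConfig,
    corrupt,
    decode_layer,
    encode,
    encode_layer,
    fine_tune,
    pretrain,
    reconstruction_loss,
    train_dae,
)
from ppifern.synthetic import generate_blobs


class TestCorrupt:
    def test_masking_rate_zero_is_identity(self):
        x = np.arange(10.0) + 1
        out = corrupt(x, CorruptionSpec("masking", 0.0), np.random.default_rng(0))
        np.testing.assert_array_equal(out, x)

    def test_masking_rate_one_zeroes_everything(self):
        x = np.arange(10.0) + 1
        out = corrupt(x, CorruptionSpec("masking", 1.0), np.random.default_rng(0))
        assert (out == 0).all()

    def test_gaussian_sigma_zero_is_identity(self):
        x = np.arange(10.0)
        out = corrupt(
            x, CorruptionSpec("additive_gaussian", 0.0), np.random.default_rng(0)
        )
        np.testing.assert_array_equal(out, x)

    def test_masking_zeroes_exact_count_per_sample(self):
        rng = np.random.default_rng(1)
        X = np.ones((50, 20))
        out = corrupt(X, CorruptionSpec("masking", 0.3), rng)
        # floor(0.3 * 20) = 6 zeroed coordinates in every row
        assert ((out == 0).sum(axis=1) == 6).all()
        assert set(np.unique(out)) <= {0.0, 1.0}

    def test_masked_subsets_vary_across_rows(self):
        rng = np.random.default_rng(2)
        out = corrupt(np.ones((200, 20)), CorruptionSpec("masking", 0.5), rng)
        patterns = {tuple(row) for row in (out == 0)}
        assert len(patterns) > 50


class TestLayers:
    def test_zero_weights_give_half(self):
        layer = LayerParams(
            we=np.zeros((3, 5)), be=np.zeros(3), wd=np.zeros((5, 3)), bd=np.zeros(5)
        )
        np.testing.assert_array_equal(encode_layer(np.ones(5), layer), 0.5 * np.ones(3))
        np.testing.assert_array_equal(decode_layer(np.ones(3), layer), 0.5 * np.ones(5))

    def test_hand_arithmetic_two_by_two(self):
        layer = LayerParams(
            we=np.array([[1.0, 2.0], [-1.0, 0.5]]),
            be=np.array([0.5, -0.5]),
            wd=np.eye(2),
            bd=np.zeros(2),
        )
        x = np.array([1.0, -1.0])
        # we @ x + be = [1 - 2 + 0.5, -1 - 0.5 - 0.5] = [-0.5, -2.0]
        expected = 1.0 / (1.0 + np.exp(-np.array([-0.5, -2.0])))
        np.testing.assert_allclose(encode_layer(x, layer), expected, rtol=1e-15)

    def test_reconstruction_loss_examples(self):
        assert reconstruction_loss(np.ones(4), np.ones(4)) == 0.0
        assert reconstruction_loss(np.zeros(2), np.ones(2)) == 1.0
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=8), rng.normal(size=8)
        assert reconstruction_loss(x, y) >= 0.0


class TestTrainDae:
    def test_loss_improves_on_reconstructable_data(self):
        rng = np.random.default_rng(0)
        data = np.tile(rng.uniform(0.2, 0.8, size=(1, 8)), (200, 1))
        config = SDAEConfig(
            layer_dims=(8,), corruption=CorruptionSpec("masking", 0.0),
            epochs_pretrain=20, learning_rate=0.5,
        )
        _, losses = train_dae(data, 8, 8, config, np.random.default_rng(1))
        assert losses[-1] < losses[0]

    def test_bitwise_determinism(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(size=(50, 10))
        config = SDAEConfig(layer_dims=(4,), epochs_pretrain=5)
        l1, _ = train_dae(data, 10, 4, config, np.random.default_rng(7))
        l2, _ = train_dae(data, 10, 4, config, np.random.default_rng(7))
        for a, b in [(l1.we, l2.we), (l1.be, l2.be), (l1.wd, l2.wd), (l1.bd, l2.bd)]:
            np.testing.assert_array_equal(a, b)

    def test_one_unit_bottleneck_captures_rank_one_manifold(self):
        # x = z * v with scalar z: a single hidden unit suffices, so the
        # final loss must fall well below the data variance.
        rng = np.random.default_rng(3)
        v = rng.uniform(0.5, 1.0, size=6)
        z = rng.uniform(0.1, 0.9, size=(300, 1))
        data = z * v
        config = SDAEConfig(
            layer_dims=(1,), corruption=CorruptionSpec("masking", 0.0),
            epochs_pretrain=500, learning_rate=2.0,
        )
        _, losses = train_dae(data, 6, 1, config, np.random.default_rng(4))
        assert losses[-1] < 0.1 * data.var()


class TestStack:
    def test_single_layer_stack_equals_train_dae(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(size=(40, 12))
        config = SDAEConfig(layer_dims=(8,), epochs_pretrain=3)
        model = pretrain(data, config, np.random.default_rng(5))
        layer, _ = train_dae(data, 12, 8, config, np.random.default_rng(5))
        np.testing.assert_array_equal(model.layers[0].we, layer.we)
        np.testing.assert_array_equal(model.layers[0].wd, layer.wd)

    def test_layer_wiring_dimensions(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(size=(30, 20))
        config = SDAEConfig(layer_dims=(16, 8), epochs_pretrain=1)
        model = pretrain(data, config)
        assert model.layers[0].we.shape == (16, 20)
        assert model.layers[1].we.shape == (8, 16)
        assert model.output_dim == 8

    def test_pretrain_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(size=(30, 10))
        config = SDAEConfig(layer_dims=(6, 4), epochs_pretrain=2, seed=13)
        m1, m2 = pretrain(data, config), pretrain(data, config)
        np.testing.assert_array_equal(m1.layers[1].we, m2.layers[1].we)


class TestFineTune:
    def test_zero_epochs_leaves_encoder_unchanged(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(size=(30, 10))
        y = np.r_[np.zeros(15, dtype=int), np.ones(15, dtype=int)]
        config = SDAEConfig(layer_dims=(4,), epochs_pretrain=1, epochs_finetune=0)
        model = pretrain(data, config)
        tuned = fine_tune(model, data, y, config)
        np.testing.assert_array_equal(tuned.layers[0].we, model.layers[0].we)
        assert tuned.head_w is not None

    def test_single_class_labels_rejected(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(size=(10, 6))
        config = SDAEConfig(layer_dims=(3,), epochs_pretrain=1)
        model = pretrain(data, config)
        with pytest.raises(ValueError, match="both binary classes"):
            fine_tune(model, data, np.zeros(10, dtype=int), config)

    def test_separable_blobs_reach_high_head_accuracy(self):
        X, y = generate_blobs(300, 12, 8.0, rng=0)
        config = SDAEConfig(
            layer_dims=(8,), epochs_pretrain=5, epochs_finetune=60,
            learning_rate=0.5, seed=2,
        )
        model = fine_tune(pretrain(X, config), X, y, config)
        acc = (sdae.head_predict_proba(model, X).argmax(axis=1) == y).mean()
        assert acc >= 0.95

    def test_decoders_retained_untouched(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(size=(30, 10))
        y = (rng.random(30) < 0.5).astype(int)
        y[:2] = [0, 1]
        config = SDAEConfig(layer_dims=(4,), epochs_pretrain=2, epochs_finetune=5)
        model = pretrain(data, config)
        tuned = fine_tune(model, data, y, config)
        np.testing.assert_array_equal(tuned.layers[0].wd, model.layers[0].wd)
        np.testing.assert_array_equal(tuned.layers[0].bd, model.layers[0].bd)


class TestEncode:
    def test_zero_weight_layer_encodes_to_half(self):
        model = sdae.SDAEModel(
            layers=[LayerParams(np.zeros((4, 6)), np.zeros(4),
                                np.zeros((6, 4)), np.zeros(6))],
            config=SDAEConfig(layer_dims=(4,)),
            input_dim=6,
        )
        np.testing.assert_array_equal(encode(model, np.ones(6)), 0.5 * np.ones(4))

    def test_encode_equals_chained_layers_and_is_bounded(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(size=(20, 10))
        config = SDAEConfig(layer_dims=(6, 3), epochs_pretrain=2)
        model = pretrain(data, config)
        out = encode(model, data)
        manual = encode_layer(encode_layer(data, model.layers[0]), model.layers[1])
        np.testing.assert_array_equal(out, manual)
        assert ((out > 0) & (out < 1)).all()
        # deterministic: no corruption at inference
        np.testing.assert_array_equal(out, encode(model, data))
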