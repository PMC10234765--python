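"""Architecture contracts: positional encoding, attention, convolution, blocks."""

import numpy as np
import pytest

from pepfun._autodiff import Tensor
from pepfun.io import encode_batch
from pepfun.network import BACKBONES, Network, NetworkConfig, positional_encoding

from conftest import small_net_config


class TestPositionalEncoding:
    def test_closed_form_full_size(self):
        P = positional_encoding(50, 192)
        i = np.arange(50)[:, None]
        j2 = np.arange(0, 192, 2)[None, :]
        angle = i / 10000.0 ** (j2 / 192.0)
        assert np.abs(P[:, 0::2] - np.sin(angle)).max() < 1e-12
        assert np.abs(P[:, 1::2] - np.cos(angle)).max() < 1e-12

    def test_row_zero_alternates(self):
        P = positional_encoding(10, 8)
        assert np.allclose(P[0, 0::2], 0.0)
        assert np.allclose(P[0, 1::2], 1.0)

    def test_first_position_first_dimension_is_sin_one(self):
        assert positional_encoding(4, 6)[1, 0] == pytest.approx(0.841471, abs=1e-6)

    def test_specific_entry_d4(self):
        # i = 2, dimension pair j = 1 at d = 4: sin(2 / 10000^(2/4))
        assert positional_encoding(4, 4)[2, 2] == pytest.approx(
            np.sin(2 / 10000 ** 0.5), abs=1e-12)

    def test_bounded_and_odd_d_rejected(self):
        assert (np.abs(positional_encoding(30, 16)) <= 1.0).all()
        with pytest.raises(ValueError):
            positional_encoding(10, 7)


@pytest.fixture()
def batch():
    return encode_batch(["ACDEFGHIK", "WWYYACDEF", "AAAAAAAAAA"])


class TestEmbedding:
    def test_full_size_shape_contract(self, batch):
        net = Network(NetworkConfig(label_dim=21), seed=0)
        assert net.embed(batch).shape == (3, 50, 192)

    def test_positional_toggle_is_additive(self, batch):
        cfg_on = small_net_config(use_pos=True)
        cfg_off = small_net_config(use_pos=False)
        on, off = Network(cfg_on, seed=3), Network(cfg_off, seed=3)
        diff = on.embed(batch).data - off.embed(batch).data
        expected = positional_encoding(50, cfg_on.embed_dim).astype(np.float32)
        assert np.allclose(diff, np.broadcast_to(expected, diff.shape), atol=1e-6)

    def test_identical_sequences_embed_identically(self):
        net = Network(small_net_config(), seed=0)
        b = encode_batch(["ACDEF", "ACDEF"])
        e = net.embed(b).data
        assert np.array_equal(e[0], e[1])

    def test_out_of_range_code_rejected(self):
        net = Network(small_net_config(), seed=0)
        with pytest.raises(ValueError):
            net.embed(np.full((1, 50), 21))


class TestMHSA:
    def test_uniform_attention_fixed_point(self):
        # identity projections + all-equal token vectors -> output = the vector
        cfg = small_net_config(embed_dim=8, n_heads=1, use_pos=False)
        net = Network(cfg, seed=0)
        for nm in ("wq", "wk", "wv", "wo"):
            net.params[f"attn0_{nm}"].data = np.eye(8, dtype=np.float32)
        net.params["attn0_bo"].data[:] = 0
        v = np.arange(8, dtype=np.float32)
        x = Tensor(np.tile(v, (2, 6, 1)))
        out = net.mhsa_block(x, np.ones((2, 6)))
        assert np.allclose(out.data, np.tile(v, (2, 6, 1)), atol=1e-5)

    def test_attention_rows_sum_to_one_over_real_keys(self, batch):
        net = Network(small_net_config(), seed=1)
        x = net.embed(batch)
        mask = (batch != 0).astype(float)
        _, w = net.mhsa_block(x, mask, return_weights=True)
        assert np.allclose(w.data.sum(axis=-1), 1.0, atol=1e-6)

    def test_pad_keys_get_zero_weight(self, batch):
        net = Network(small_net_config(), seed=1)
        x = net.embed(batch)
        mask = (batch != 0).astype(float)
        _, w = net.mhsa_block(x, mask, return_weights=True)
        pad_cols = mask[:, None, None, :] == 0
        assert np.abs(w.data[np.broadcast_to(pad_cols, w.shape)]).max() == 0.0

    def test_pad_value_invariance_at_real_positions(self, batch):
        net = Network(small_net_config(), seed=2)
        x = net.embed(batch).data.copy()
        mask = (batch != 0).astype(float)
        out1 = net.mhsa_block(Tensor(x), mask).data
        x2 = x.copy()
        x2[mask == 0] = 999.0  # scramble pad rows
        out2 = net.mhsa_block(Tensor(x2), mask).data
        real = mask.astype(bool)
        assert np.allclose(out1[real], out2[real], atol=1e-5)

    def test_all_pad_sequence_rejected(self):
        net = Network(small_net_config(), seed=0)
        with pytest.raises(ValueError, match="all-pad"):
            net.forward(np.zeros((1, 50), dtype=int))


class TestTextCNN:
    def test_default_output_width(self, batch):
        net = Network(NetworkConfig(label_dim=21), seed=0)
        feat = net.textcnn_block(net.embed(batch))
        assert feat.shape == (3, 4 * 128)  # kernels {2,3,4,5} x 128 filters

    def test_constant_input_averaging_filter(self):
        # an averaging filter over a constant feature map pools to the
        # activated constant response
        cfg = small_net_config(embed_dim=4, kernel_sizes=(2,), filters_per_kernel=1,
                               use_pos=False)
        net = Network(cfg, seed=0)
        net.params["conv2_w"].data = np.full((8, 1), 1 / 8, dtype=np.float32)
        net.params["conv2_b"].data[:] = 0
        x = Tensor(np.full((1, 6, 4), 3.0, dtype=np.float32))
        out = net.textcnn_block(x)
        assert out.data[0, 0] == pytest.approx(3.0, abs=1e-6)  # relu(3) = 3

    def test_max_pool_is_position_permutation_invariant(self):
        cfg = small_net_config()
        net = Network(cfg, seed=4)
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 20, cfg.embed_dim)).astype(np.float32)
        # permuting positions changes convolution windows, so compare through
        # pooling of the *post-convolution* map: pool(max) over a permuted
        # feature map equals pool over the original
        k = 2
        conv = (np.concatenate([x[:, j:j + 19, :] for j in range(k)], axis=-1)
                @ net.params["conv2_w"].data + net.params["conv2_b"].data)
        conv = np.maximum(conv, 0)
        pooled1 = conv.max(axis=1)
        pooled2 = conv[:, rng.permutation(19), :].max(axis=1)
        assert np.allclose(pooled1, pooled2)

    def test_kernel_larger_than_sequence_rejected(self):
        cfg = small_net_config()
        net = Network(cfg, seed=0)
        with pytest.raises(ValueError, match="kernel"):
            net.textcnn_block(Tensor(np.zeros((1, 3, cfg.embed_dim), dtype=np.float32)))


class TestFFN:
    def test_zero_weights_pass_residual_through_ln(self):
        # all-zero inner weights: LN(Y) of a zero-mean unit-variance row is Y
        cfg = small_net_config()
        net = Network(cfg, seed=0)
        kf = cfg.pooled_width
        for nm in ("ffn_w1", "ffn_b1", "ffn_w2", "ffn_b2"):
            net.params[nm].data[:] = 0
        row = np.zeros((1, kf), dtype=np.float32)
        row[0, 0], row[0, 1] = 1.0, -1.0
        row = row * np.sqrt(kf / 2)  # unit variance across the row
        out = net.ffn_block(Tensor(row))
        assert np.allclose(out.data, row, atol=1e-3)

    def test_rows_are_layer_normalized(self, rng):
        cfg = small_net_config()
        net = Network(cfg, seed=5)
        y = Tensor(rng.standard_normal((4, cfg.pooled_width)).astype(np.float32))
        out = net.ffn_block(y).data
        assert np.allclose(out.mean(axis=1), 0.0, atol=1e-4)
        assert np.allclose(out.var(axis=1), 1.0, atol=1e-2)

    def test_shape_preserved(self, rng):
        cfg = small_net_config()
        net = Network(cfg, seed=5)
        y = rng.standard_normal((7, cfg.pooled_width)).astype(np.float32)
        assert net.ffn_block(Tensor(y)).shape == y.shape


class TestHeadAndForward:
    def test_zero_head_gives_half_probabilities(self, batch):
        net = Network(small_net_config(), seed=0)
        net.params["head_w"].data[:] = 0
        net.params["head_b"].data[:] = 0
        P = net.forward(batch).data
        assert np.allclose(P, 0.5)

    def test_monotone_in_logit(self):
        net = Network(small_net_config(), seed=0)
        f = Tensor(np.zeros((1, net.config.pooled_width), dtype=np.float32))
        base = net.classification_head(f).data.copy()
        net.params["head_b"].data[2] += 1.0
        bumped = net.classification_head(f).data
        assert bumped[0, 2] > base[0, 2]
        assert np.allclose(np.delete(bumped, 2), np.delete(base, 2))

    def test_default_label_width(self, batch):
        net = Network(NetworkConfig(label_dim=21), seed=0)
        assert net.forward(batch).shape == (3, 21)

    def test_probabilities_in_unit_interval(self, batch):
        net = Network(small_net_config(), seed=6)
        P = net.forward(batch).data
        assert ((P > 0) & (P < 1)).all()

    def test_inference_is_deterministic(self, batch):
        net = Network(small_net_config(), seed=6)
        a = net.forward(batch).data
        b = net.forward(batch).data
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("backbone", BACKBONES)
    def test_backbones_run_and_discriminate(self, backbone, batch):
        cfg = small_net_config(backbone=backbone)
        net = Network(cfg, seed=7)
        P = net.forward(batch).data
        assert P.shape == (3, 6)
        # distinct inputs map to distinct outputs (blocks are connected)
        assert not np.allclose(P[0], P[2])

    def test_ablation_flags_change_parameter_sets(self):
        full = Network(small_net_config(), seed=0).params
        no_ffn = Network(small_net_config(use_ffn=False), seed=0).params
        no_tc = Network(small_net_config(use_textcnn=False), seed=0).params
        assert any(k.startswith("ffn") for k in full)
        assert not any(k.startswith("ffn") for k in no_ffn)
        assert any(k.startswith("conv") for k in full)
        assert not any(k.startswith("conv") for k in no_tc)

    def test_no_pos_ablation_drops_positional_term(self, batch):
        on = Network(small_net_config(), seed=9)
        off = Network(small_net_config(use_pos=False), seed=9)
        assert not np.allclose(on.embed(batch).data, off.embed(batch).data)

    def test_mean_pool_backbone_invariant_to_pad_embedding(self, batch):
        # without convolution the whole forward pass masks pads, so logits
        # cannot depend on the pad row of the embedding table
        cfg = small_net_config(backbone="mhsa_cb")
        net = Network(cfg, seed=8)
        P1 = net.forward(batch).data.copy()
        net.params["emb"].data[0, :] = 123.0
        P2 = net.forward(batch).data
        assert np.allclose(P1, P2, atol=1e-5)


class TestConfigAndCheckpoint:
    @pytest.mark.parametrize("bad", [
        dict(label_dim=6, embed_dim=30, n_heads=4),          # not divisible
        dict(label_dim=6, kernel_sizes=(1, 2)),              # kernel < 2
        dict(label_dim=6, dropout=1.0),
        dict(label_dim=6, backbone="transformer"),
        dict(label_dim=1),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            NetworkConfig(**bad)

    def test_checkpoint_round_trip(self, tmp_path, batch):
        net = Network(small_net_config(), seed=11)
        before = net.forward(batch).data
        path = tmp_path / "model.npz"
        net.save(path, label_names=["C0", "C1", "C2", "C3", "C4", "C5"],
                 extra={"note": "test"})
        loaded, meta = Network.load(path)
        assert meta["label_names"][0] == "C0" and meta["extra"]["note"] == "test"
        assert np.array_equal(loaded.forward(batch).data, before)
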