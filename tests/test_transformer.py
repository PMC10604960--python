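import numpy as np
import pytest

from mdalink.config import TransformerConfig
from mdalink.encoders.transformer import (
    EncoderLayer,
    InputEncoder,
    StructuralAttention,
    TransformerChannel,
)
from mdalink.nn import Tensor


def small_cfg(**kw) -> TransformerConfig:
    defaults = dict(heads=2, layers=2, model_dim=8, ffn_hidden=16, dropout=0.0)
    defaults.update(kw)
    return TransformerConfig(**defaults)


rng0 = np.random.default_rng(0)


def vanilla_transformer_oracle(x: np.ndarray, channel: TransformerChannel) -> np.ndarray:
    """Independent plain-numpy post-LN transformer encoder with the channel's
    own weights; no SPD bias, no degree embedding."""

    def layer_norm(v, gamma, beta, eps=1e-5):
        mu = v.mean(axis=-1, keepdims=True)
        var = v.var(axis=-1, keepdims=True)
        return (v - mu) / np.sqrt(var + eps) * gamma + beta

    h = x
    for layer in channel.enc_layers:
        att = layer.attn
        heads = []
        hd = att.cfg.model_dim // att.cfg.heads
        for k in range(att.cfg.heads):
            q = h @ att.w_q[k].data
            key = h @ att.w_k[k].data
            v = h @ att.w_v[k].data
            logits = q @ key.T / np.sqrt(hd)
            e = np.exp(logits - logits.max(axis=-1, keepdims=True))
            a = e / e.sum(axis=-1, keepdims=True)
            heads.append(a @ v)
        mh = np.concatenate(heads, axis=-1) @ att.w_o.weight.data + att.w_o.bias.data
        h1 = layer_norm(h + mh, layer.ln1.gamma.data, layer.ln1.beta.data)
        ffn = np.maximum(h1 @ layer.ffn1.weight.data + layer.ffn1.bias.data, 0)
        ffn = ffn @ layer.ffn2.weight.data + layer.ffn2.bias.data
        h = layer_norm(h1 + ffn, layer.ln2.gamma.data, layer.ln2.beta.data)
    return h


def make_inputs(m=5, n=4, seed=0):
    gen = np.random.default_rng(seed)
    mf = gen.random((m, m))
    mf = (mf + mf.T) / 2
    df = gen.random((n, n))
    df = (df + df.T) / 2
    degrees = gen.integers(0, 6, size=m + n)
    spd = gen.integers(0, 9, size=(m + n, m + n))
    spd = np.minimum(spd, spd.T)
    np.fill_diagonal(spd, 0)
    return mf, df, degrees, spd


class TestInputEncoder:
    def test_zero_degree_table_reduces_to_projections(self):
        cfg = small_cfg()
        enc = InputEncoder(5, 4, cfg, np.random.default_rng(0))
        enc.deg_embed.table.data[:] = 0.0
        mf, df, degrees, _ = make_inputs()
        out = enc(Tensor(mf), Tensor(df), degrees)
        expected = np.concatenate(
            [
                mf @ enc.proj_m.weight.data + enc.proj_m.bias.data,
                df @ enc.proj_d.weight.data + enc.proj_d.bias.data,
            ]
        )
        np.testing.assert_allclose(out.data, expected, atol=1e-12)

    def test_degree_term_discriminates(self):
        cfg = small_cfg()
        enc = InputEncoder(2, 2, cfg, np.random.default_rng(0))
        mf = np.ones((2, 2))
        df = np.ones((2, 2))
        out = enc(Tensor(mf), Tensor(df), np.array([0, 5, 1, 1]))
        assert not np.allclose(out.data[0], out.data[1])
        np.testing.assert_allclose(out.data[2], out.data[3], atol=1e-12)

    def test_shape(self):
        cfg = small_cfg()
        enc = InputEncoder(5, 4, cfg, np.random.default_rng(0))
        mf, df, degrees, _ = make_inputs()
        assert enc(Tensor(mf), Tensor(df), degrees).shape == (9, cfg.model_dim)


class TestStructuralAttention:
    def test_zero_bias_is_scaled_dot_product(self):
        cfg = small_cfg(heads=1)
        att = StructuralAttention(cfg, np.random.default_rng(0))
        att.spd_bias[0].data[:] = 0.0
        x = rng0.normal(size=(6, cfg.model_dim))
        spd = np.ones((6, 6), dtype=int)
        a, v = att.head_attention(Tensor(x), spd, 0)
        q = x @ att.w_q[0].data
        k = x @ att.w_k[0].data
        logits = q @ k.T / np.sqrt(cfg.model_dim)
        e = np.exp(logits - logits.max(axis=-1, keepdims=True))
        np.testing.assert_allclose(a.data, e / e.sum(axis=-1, keepdims=True), atol=1e-12)

    def test_rows_sum_to_one(self):
        cfg = small_cfg()
        att = StructuralAttention(cfg, np.random.default_rng(0))
        x = rng0.normal(size=(7, cfg.model_dim))
        spd = np.random.default_rng(1).integers(0, 9, size=(7, 7))
        out = att(Tensor(x), spd)
        for k in range(cfg.heads):
            a, _ = att.head_attention(Tensor(x), spd, k)
            np.testing.assert_allclose(a.data.sum(axis=-1), 1.0, atol=1e-6)
        assert out.shape == (7, cfg.model_dim)

    def test_large_negative_bias_confines_to_neighbors(self):
        """Bias -inf surrogate beyond distance 1 must reproduce masked attention."""
        cfg = small_cfg(heads=1)
        att = StructuralAttention(cfg, np.random.default_rng(0))
        att.spd_bias[0].data[:] = 0.0
        att.spd_bias[0].data[2:] = -1e9
        gen = np.random.default_rng(5)
        adj = (gen.random((6, 6)) < 0.4).astype(int)
        adj = ((adj + adj.T) > 0).astype(int)
        np.fill_diagonal(adj, 0)
        from mdalink.graphs import shortest_path_matrix

        spd = shortest_path_matrix(adj, clip=8)
        x = gen.normal(size=(6, cfg.model_dim))
        a, _ = att.head_attention(Tensor(x), spd, 0)
        # independent masked-attention oracle
        q = x @ att.w_q[0].data
        k = x @ att.w_k[0].data
        logits = q @ k.T / np.sqrt(cfg.model_dim)
        mask = spd <= 1
        logits = np.where(mask, logits, -np.inf)
        e = np.exp(logits - logits.max(axis=-1, keepdims=True))
        oracle = e / e.sum(axis=-1, keepdims=True)
        np.testing.assert_allclose(a.data, oracle, atol=1e-9)

    def test_per_head_bias_tables(self):
        cfg = small_cfg(per_head_bias=True)
        att = StructuralAttention(cfg, np.random.default_rng(0))
        assert len(att.spd_bias) == cfg.heads


class TestMultiHeadAndEncoder:
    def test_single_head_equals_attention_plus_projection(self):
        cfg = small_cfg(heads=1)
        att = StructuralAttention(cfg, np.random.default_rng(0))
        x = rng0.normal(size=(5, cfg.model_dim))
        spd = np.zeros((5, 5), dtype=int)
        a, v = att.head_attention(Tensor(x), spd, 0)
        manual = (a.data @ v.data) @ att.w_o.weight.data + att.w_o.bias.data
        np.testing.assert_allclose(att(Tensor(x), spd).data, manual, atol=1e-12)

    def test_output_shape_invariant_to_heads(self):
        for heads in (1, 2, 4):
            cfg = small_cfg(heads=heads)
            att = StructuralAttention(cfg, np.random.default_rng(0))
            out = att(Tensor(rng0.normal(size=(5, cfg.model_dim))), np.zeros((5, 5), dtype=int))
            assert out.shape == (5, cfg.model_dim)

    def test_zero_layers_is_input_identity(self):
        cfg = small_cfg(layers=0)
        ch = TransformerChannel(5, 4, cfg, np.random.default_rng(0))
        ch.eval()
        mf, df, degrees, spd = make_inputs()
        out = ch(Tensor(mf), Tensor(df), degrees, spd, rng0)
        expected = ch.input_encoder(Tensor(mf), Tensor(df), degrees)
        np.testing.assert_allclose(out.data, expected.data, atol=1e-12)

    def test_matches_vanilla_transformer_oracle(self):
        cfg = small_cfg(use_graph_attrs=False)
        ch = TransformerChannel(5, 4, cfg, np.random.default_rng(0))
        ch.eval()
        mf, df, degrees, spd = make_inputs()
        out = ch(Tensor(mf), Tensor(df), degrees, spd, rng0)
        x = np.concatenate(
            [
                mf @ ch.input_encoder.proj_m.weight.data + ch.input_encoder.proj_m.bias.data,
                df @ ch.input_encoder.proj_d.weight.data + ch.input_encoder.proj_d.bias.data,
            ]
        )
        oracle = vanilla_transformer_oracle(x, ch)
        np.testing.assert_allclose(out.data, oracle, atol=1e-5)

    def test_deterministic_in_eval_mode(self):
        cfg = small_cfg(dropout=0.5)
        ch = TransformerChannel(5, 4, cfg, np.random.default_rng(0))
        ch.eval()
        mf, df, degrees, spd = make_inputs()
        out1 = ch(Tensor(mf), Tensor(df), degrees, spd, np.random.default_rng(1))
        out2 = ch(Tensor(mf), Tensor(df), degrees, spd, np.random.default_rng(2))
        np.testing.assert_array_equal(out1.data, out2.data)

    def test_strict_no_residual_mode(self):
        cfg = small_cfg(strict_no_residual=True, layers=1)
        ch = TransformerChannel(5, 4, cfg, np.random.default_rng(0))
        ch.eval()
        mf, df, degrees, spd = make_inputs()
        out = ch(Tensor(mf), Tensor(df), degrees, spd, rng0)
        assert np.isfinite(out.data).all()
        # post-LN contract: rows normalized before affine
        layer = ch.enc_layers[0]
        assert out.shape == (9, cfg.model_dim)
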