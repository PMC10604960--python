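"""Channel 2: self-attention encoder over all nodes.

Positional information is replaced by graph attributes: a learned
degree-bucket embedding added to the input features, and a learned scalar
bias per shortest-path-distance bucket added to every attention logit.
"""

from __future__ import annotations

import numpy as np

from ..config import TransformerConfig
from ..graphs import degree_bucket
from ..nn import Embedding, LayerNorm, Linear, Module, Tensor
from ..nn import autograd as ag
from ..nn.layers import glorot

__all__ = ["InputEncoder", "StructuralAttention", "EncoderLayer", "TransformerChannel"]


class InputEncoder(Module):
    """Projects the two similarity feature matrices to the model width and
    adds the degree-centrality embedding per node."""

    def __init__(self, m_dim: int, d_dim: int, cfg: TransformerConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.proj_m = Linear(m_dim, cfg.model_dim, rng)
        self.proj_d = Linear(d_dim, cfg.model_dim, rng)
        self.deg_embed = Embedding(cfg.degree_max_bucket + 1, cfg.model_dim, rng)

    def __call__(self, mf: Tensor, df: Tensor, degrees: np.ndarray) -> Tensor:
        fmd = ag.concat([self.proj_m(mf), self.proj_d(df)], axis=0)
        if fmd.data.shape[0] != degrees.shape[0]:
            raise ValueError("degree vector not aligned with stacked features")
        if self.cfg.use_graph_attrs:
            buckets = degree_bucket(degrees, self.cfg.degree_max_bucket)
            fmd = ag.add(fmd, self.deg_embed(buckets))
        return fmd


class StructuralAttention(Module):
    """Multi-head scaled dot-product attention with an additive learned
    bias indexed by the SPD bucket of each node pair."""

    def __init__(self, cfg: TransformerConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        d, h = cfg.model_dim, cfg.heads
        hd = d // h
        self.w_q = [Tensor(glorot(rng, d, hd)) for _ in range(h)]
        self.w_k = [Tensor(glorot(rng, d, hd)) for _ in range(h)]
        self.w_v = [Tensor(glorot(rng, d, hd)) for _ in range(h)]
        self.w_o = Linear(d, d, rng)
        n_buckets = cfg.spd_clip + 2  # 0..clip plus unreachable sentinel
        n_tables = h if cfg.per_head_bias else 1
        # learned; initialized distance-decaying so attention starts local
        init = cfg.spd_bias_init * np.arange(n_buckets, dtype=float)
        self.spd_bias = [Tensor(init.copy()) for _ in range(n_tables)]

    def head_attention(self, fmd: Tensor, spd: np.ndarray, k: int) -> tuple[Tensor, Tensor]:
        """(attention row-stochastic matrix, value projection) for head k."""
        hd = self.cfg.model_dim // self.cfg.heads
        q = ag.matmul(fmd, self.w_q[k])
        key = ag.matmul(fmd, self.w_k[k])
        v = ag.matmul(fmd, self.w_v[k])
        logits = ag.scale(ag.matmul(q, ag.transpose(key)), 1.0 / np.sqrt(hd))
        if self.cfg.use_graph_attrs:
            table = self.spd_bias[k if self.cfg.per_head_bias else 0]
            logits = ag.add(logits, ag.gather(table, spd))
        att = ag.softmax(logits)
        if not np.isfinite(att.data).all():
            raise FloatingPointError("non-finite attention weights")
        return att, v

    def __call__(self, fmd: Tensor, spd: np.ndarray) -> Tensor:
        heads = []
        for k in range(self.cfg.heads):
            att, v = self.head_attention(fmd, spd, k)
            heads.append(ag.matmul(att, v))
        return self.w_o(ag.concat(heads, axis=-1))


class EncoderLayer(Module):
    """Post-LN block: attention sub-layer then two-linear ReLU feed-forward,
    each followed by layer normalization (residuals on by default)."""

    def __init__(self, cfg: TransformerConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.attn = StructuralAttention(cfg, rng)
        self.ln1 = LayerNorm(cfg.model_dim)
        self.ln2 = LayerNorm(cfg.model_dim)
        self.ffn1 = Linear(cfg.model_dim, cfg.ffn_hidden, rng)
        self.ffn2 = Linear(cfg.ffn_hidden, cfg.model_dim, rng)

    def __call__(self, fmd: Tensor, spd: np.ndarray, rng: np.random.Generator) -> Tensor:
        a = self.attn(fmd, spd)
        a = ag.dropout(a, self.cfg.dropout, rng, self.training)
        h = self.ln1(a if self.cfg.strict_no_residual else ag.add(fmd, a))
        f = self.ffn2(ag.relu(self.ffn1(h)))
        f = ag.dropout(f, self.cfg.dropout, rng, self.training)
        return self.ln2(f if self.cfg.strict_no_residual else ag.add(h, f))


class TransformerChannel(Module):
    """Stacked encoder layers over the (M+N)-node feature matrix."""

    def __init__(self, m_dim: int, d_dim: int, cfg: TransformerConfig, rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        self.input_encoder = InputEncoder(m_dim, d_dim, cfg, rng)
        self.enc_layers = [EncoderLayer(cfg, rng) for _ in range(cfg.layers)]

    def __call__(
        self,
        mf: Tensor,
        df: Tensor,
        degrees: np.ndarray,
        spd: np.ndarray,
        rng: np.random.Generator,
    ) -> Tensor:
        h = self.input_encoder(mf, df, degrees)
        for layer in self.enc_layers:
            h = layer(h, spd, rng)
        return h
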