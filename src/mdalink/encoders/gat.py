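"""Channel 1: GCN pre-encoding of the similarity networks followed by
multi-head graph attention over the heterogeneous graph, with the per-layer
outputs merged by a jumping-knowledge linear map.
"""

from __future__ import annotations

import numpy as np

from ..config import GATConfig
from ..nn import Linear, Module, Tensor
from ..nn import autograd as ag
from ..nn.layers import glorot

__all__ = ["GCNPreEncoder", "GATLayer", "JumpingKnowledge", "GATChannel", "gcn_normalize"]

_NEG_INF = -1e9


def gcn_normalize(adjacency: np.ndarray) -> np.ndarray:
    """Symmetric normalization D^-1/2 (A + I) D^-1/2 with self-loops."""
    a = np.asarray(adjacency, dtype=float) + np.eye(adjacency.shape[0])
    dinv = 1.0 / np.sqrt(a.sum(axis=1))
    return a * dinv[:, None] * dinv[None, :]


class GCNPreEncoder(Module):
    """Propagates one node family's similarity features over its own
    similarity adjacency and projects them to the common embedding width."""

    def __init__(self, in_dim: int, cfg: GATConfig, rng: np.random.Generator):
        super().__init__()
        dims = [in_dim] + [cfg.embed_dim] * cfg.gcn_layers
        self.layers = [Linear(dims[i], dims[i + 1], rng) for i in range(cfg.gcn_layers)]

    def __call__(self, features: Tensor, norm_adj: np.ndarray) -> Tensor:
        h = features
        prop = Tensor(norm_adj)
        for layer in self.layers:
            h = ag.elu(ag.matmul(prop, layer(h)))
        return h


class GATLayer(Module):
    """One multi-head attention layer over a fixed neighborhood mask."""

    def __init__(self, in_dim: int, cfg: GATConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        head_dim = cfg.embed_dim // cfg.heads
        self.weights = [Tensor(glorot(rng, in_dim, head_dim)) for _ in range(cfg.heads)]
        # attention vector a, split into source/destination halves
        self.att_src = [Tensor(glorot(rng, head_dim, 1)) for _ in range(cfg.heads)]
        self.att_dst = [Tensor(glorot(rng, head_dim, 1)) for _ in range(cfg.heads)]

    def attention(self, h: Tensor, mask: np.ndarray) -> list[tuple[Tensor, Tensor]]:
        """Per head: (softmax-normalized coefficients, transformed features).

        ``mask`` marks allowed (i, j) pairs; non-neighbors get a large
        negative logit so their coefficient is numerically zero.
        """
        bias = np.where(mask, 0.0, _NEG_INF)
        out = []
        for k in range(self.cfg.heads):
            wh = ag.matmul(h, self.weights[k])  # n x head_dim
            logits_src = ag.matmul(wh, self.att_src[k])  # n x 1
            logits_dst = ag.matmul(wh, self.att_dst[k])  # n x 1
            logits = ag.leaky_relu(
                ag.add(logits_src, ag.transpose(logits_dst)), self.cfg.negative_slope
            )
            coeff = ag.softmax(ag.add(logits, Tensor(bias)))
            out.append((coeff, wh))
        return out

    def __call__(self, h: Tensor, mask: np.ndarray, rng: np.random.Generator) -> Tensor:
        h = ag.dropout(h, self.cfg.dropout, rng, self.training)
        heads = [ag.matmul(coeff, wh) for coeff, wh in self.attention(h, mask)]
        return ag.elu(ag.concat(heads, axis=-1))


class JumpingKnowledge(Module):
    """Concatenate every layer's output and map back to the embedding width."""

    def __init__(self, n_layers: int, embed_dim: int, rng: np.random.Generator):
        super().__init__()
        self.linear = Linear(n_layers * embed_dim, embed_dim, rng)

    def __call__(self, layer_outputs: list[Tensor]) -> Tensor:
        if not layer_outputs:
            raise ValueError("need at least one layer output")
        rows = {t.data.shape[0] for t in layer_outputs}
        if len(rows) > 1:
            raise ValueError("layer outputs disagree on row count")
        return self.linear(ag.concat(layer_outputs, axis=-1))


class GATChannel(Module):
    """Full graph-attention channel producing (M+N) x embed_dim features.

    Inputs per forward pass: miRNA/disease feature matrices, their
    GCN-normalized similarity adjacencies, and the heterogeneous-graph
    neighborhood mask (self-loops included).
    """

    def __init__(self, m_dim: int, d_dim: int, cfg: GATConfig, rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        if cfg.vanilla:
            self.proj_m = Linear(m_dim, cfg.embed_dim, rng)
            self.proj_d = Linear(d_dim, cfg.embed_dim, rng)
        else:
            self.gcn_m = GCNPreEncoder(m_dim, cfg, rng)
            self.gcn_d = GCNPreEncoder(d_dim, cfg, rng)
        self.gat_layers = [GATLayer(cfg.embed_dim, cfg, rng) for _ in range(cfg.layers)]
        if not cfg.vanilla:
            self.jk = JumpingKnowledge(cfg.layers, cfg.embed_dim, rng)

    def __call__(
        self,
        mf: Tensor,
        df: Tensor,
        gm_norm: np.ndarray,
        gd_norm: np.ndarray,
        mask: np.ndarray,
        rng: np.random.Generator,
    ) -> Tensor:
        if self.cfg.vanilla:
            h = ag.concat([self.proj_m(mf), self.proj_d(df)], axis=0)
        else:
            h = ag.concat([self.gcn_m(mf, gm_norm), self.gcn_d(df, gd_norm)], axis=0)
        outputs = []
        for layer in self.gat_layers:
            h = layer(h, mask, rng)
            outputs.append(h)
        if self.cfg.vanilla:
            return outputs[-1]
        return self.jk(outputs)


def neighborhood_mask(adjacency: np.ndarray) -> np.ndarray:
    """Attention mask over the heterogeneous graph with self-loops added,
    so isolated nodes attend to themselves."""
    return (np.asarray(adjacency) + np.eye(adjacency.shape[0], dtype=int)) > 0
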