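"""Channel fusion, pair scoring, and the training loss.

The two channel embeddings are fused elementwise (max by default, with the
lin/dot/mean/add variants config-selectable) and each (miRNA, disease) pair
is scored by a one-hidden-layer MLP on the concatenated node rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .embeddings import NodeEmbeddings
from .nn import Linear, Module, Tensor
from .nn import autograd as ag
from .pipeline import FeatureBundle

__all__ = ["PairScores", "fuse_embeddings", "bce_loss", "PairScorer", "DotScorer", "DualChannelModel"]

CLAMP_EPS = 1e-7


@dataclass
class PairScores:
    """Predicted association probabilities for a list of node pairs."""

    pairs: list[tuple[str, str]]
    probabilities: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.probabilities = np.clip(
            np.asarray(self.probabilities, dtype=float), CLAMP_EPS, 1.0 - CLAMP_EPS
        )
        if len(self.probabilities) != len(self.pairs):
            raise ValueError("probabilities and pairs lengths disagree")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(self.pairs):
                raise ValueError("labels and pairs lengths disagree")


def fuse_embeddings(
    h_gat: NodeEmbeddings,
    h_trf: NodeEmbeddings,
    mode: str = "max",
    lin_weights: np.ndarray | None = None,
) -> NodeEmbeddings:
    """Combine the two channel embeddings position-wise.

    Modes: ``max`` (default, keeps the stronger feature), ``mean``, ``add``,
    ``dot`` (elementwise product) and ``lin`` (linear map of the
    concatenation; requires ``lin_weights`` of shape (2w, w)).
    """
    if h_gat.rows.shape != h_trf.rows.shape or h_gat.ids != h_trf.ids:
        raise ValueError("channel embeddings must share shape and registry")
    a, b = h_gat.rows, h_trf.rows
    if mode == "max":
        rows = np.maximum(a, b)
    elif mode == "mean":
        rows = (a + b) / 2.0
    elif mode == "add":
        rows = a + b
    elif mode == "dot":
        rows = a * b
    elif mode == "lin":
        if lin_weights is None:
            raise ValueError("mode 'lin' needs learned weights (2w x w)")
        rows = np.concatenate([a, b], axis=1) @ lin_weights
    else:
        raise ValueError(f"unknown fusion mode {mode!r}")
    return NodeEmbeddings(list(h_gat.ids), rows, "FUSED")


def bce_loss(scores: PairScores) -> float:
    """Mean binary cross-entropy of clamped probabilities against labels."""
    if scores.labels is None:
        raise ValueError("bce_loss requires labels")
    p = scores.probabilities
    y = scores.labels.astype(float)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


class PairScorer(Module):
    """MLP on concat(mirna row, disease row): 2w -> w -> 1 logit."""

    def __init__(self, width: int, rng: np.random.Generator):
        super().__init__()
        self.hidden = Linear(2 * width, width, rng)
        self.out = Linear(width, 1, rng)

    def __call__(self, fused: Tensor, m_idx: np.ndarray, node_d_idx: np.ndarray) -> Tensor:
        xm = ag.gather(fused, np.asarray(m_idx))
        xd = ag.gather(fused, np.asarray(node_d_idx))
        h = ag.relu(self.hidden(ag.concat([xm, xd], axis=-1)))
        return self.out(h)  # n_pairs x 1 logits


class DotScorer(Module):
    """Feature-weighted inner product of the two node rows, plus a bias.

    Converges faster than the concat MLP because the pair interaction is
    built in rather than learned.
    """

    def __init__(self, width: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(np.full((width, 1), 1.0 / np.sqrt(width)))
        self.bias = Tensor(np.zeros(1))

    def __call__(self, fused: Tensor, m_idx: np.ndarray, node_d_idx: np.ndarray) -> Tensor:
        xm = ag.gather(fused, np.asarray(m_idx))
        xd = ag.gather(fused, np.asarray(node_d_idx))
        return ag.add(ag.matmul(ag.mul(xm, xd), self.weight), self.bias)


class DualChannelModel(Module):
    """End-to-end model: both encoder channels, fusion, and pair scoring.

    Channel selection and fusion mode come from the run configuration;
    single-channel ablations skip fusion entirely.
    """

    def __init__(self, m_dim: int, d_dim: int, cfg: RunConfig, seed: int = 0):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        self.channels = tuple(cfg.train.channels)
        if len(self.channels) == 2 and cfg.gat.embed_dim != cfg.trf.model_dim:
            raise ValueError("dual-channel fusion needs gat.embed_dim == trf.model_dim")
        self.rng = np.random.default_rng(seed)
        width = cfg.gat.embed_dim if "gat" in self.channels else cfg.trf.model_dim

        from .encoders.gat import GATChannel
        from .encoders.transformer import TransformerChannel

        self.gat = GATChannel(m_dim, d_dim, cfg.gat, self.rng) if "gat" in self.channels else None
        self.trf = (
            TransformerChannel(m_dim, d_dim, cfg.trf, self.rng) if "trf" in self.channels else None
        )
        self.fuse_lin = (
            Linear(2 * width, width, self.rng, bias=False)
            if len(self.channels) == 2 and cfg.train.fusion == "lin"
            else None
        )
        scorer_cls = DotScorer if cfg.train.scorer == "dot" else PairScorer
        self.scorer = scorer_cls(width, self.rng)

    def fused_tensor(self, bundle: FeatureBundle) -> Tensor:
        mf, df = Tensor(bundle.mf), Tensor(bundle.df)
        outs: dict[str, Tensor] = {}
        if self.gat is not None:
            outs["gat"] = self.gat(mf, df, bundle.gm_norm, bundle.gd_norm, bundle.mask, self.rng)
        if self.trf is not None:
            outs["trf"] = self.trf(mf, df, bundle.degrees, bundle.spd, self.rng)
        if len(outs) == 1:
            return next(iter(outs.values()))
        a, b = outs["gat"], outs["trf"]
        mode = self.cfg.train.fusion
        if mode == "max":
            return ag.maximum(a, b)
        if mode == "mean":
            return ag.scale(ag.add(a, b), 0.5)
        if mode == "add":
            return ag.add(a, b)
        if mode == "dot":
            return ag.mul(a, b)
        return self.fuse_lin(ag.concat([a, b], axis=-1))

    def pair_logits(self, bundle: FeatureBundle, m_idx: np.ndarray, d_idx: np.ndarray) -> Tensor:
        fused = self.fused_tensor(bundle)
        return self.scorer(fused, m_idx, np.asarray(d_idx) + bundle.n_mirna)

    def node_embeddings(self, bundle: FeatureBundle) -> NodeEmbeddings:
        """Fused per-node embeddings in evaluation mode (no dropout)."""
        was_training = self.training
        self.eval()
        rows = self.fused_tensor(bundle).data
        if was_training:
            self.train()
        return NodeEmbeddings(bundle.node_ids, rows, "FUSED")

    def score_pairs(
        self,
        bundle: FeatureBundle,
        pairs: list[tuple[str, str]],
        labels: np.ndarray | None = None,
    ) -> PairScores:
        """Association probabilities for explicit id pairs (eval mode)."""
        midx = {m: i for i, m in enumerate(bundle.mirna_ids)}
        didx = {d: j for j, d in enumerate(bundle.disease_ids)}
        try:
            m_idx = np.array([midx[m] for m, _ in pairs], dtype=np.int64)
            d_idx = np.array([didx[d] for _, d in pairs], dtype=np.int64)
        except KeyError as e:
            from .similarity import IdentifierError

            raise IdentifierError(e.args[0]) from None
        was_training = self.training
        self.eval()
        logits = self.pair_logits(bundle, m_idx, d_idx).data.ravel()
        if was_training:
            self.train()
        probs = 1.0 / (1.0 + np.exp(-logits))
        return PairScores(list(pairs), probs, labels)
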