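"""Per-node embedding container shared by both encoder channels."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NodeEmbeddings"]

_CHANNELS = {"GAT", "TRF", "FUSED"}


@dataclass
class NodeEmbeddings:
    """Dense feature rows for the M miRNA + N disease nodes of one channel."""

    ids: list[str]
    rows: np.ndarray
    channel: str

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        if self.channel not in _CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.rows.ndim != 2 or self.rows.shape[0] != len(self.ids):
            raise ValueError("row count must equal number of node ids")
        if not np.isfinite(self.rows).all():
            raise ValueError("embeddings contain non-finite values")

    @property
    def width(self) -> int:
        return self.rows.shape[1]
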