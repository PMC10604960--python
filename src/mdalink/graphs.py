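"""Structural encodings of the heterogeneous graph.

Degree statistics feed the transformer channel's centrality embedding and
the `stats` CLI report; the clipped shortest-path-distance matrix indexes
the learned attention-bias table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .similarity import AssociationMatrix, StructureError

__all__ = [
    "HeteroGraph",
    "GraphStats",
    "degree_vector",
    "graph_stats",
    "graph_density",
    "shortest_path_matrix",
    "degree_bucket",
]


@dataclass
class HeteroGraph:
    """Symmetric binary graph over M miRNA + N disease nodes with SPD cache."""

    adjacency: np.ndarray
    spd_clip: int = 8

    degrees: np.ndarray = field(init=False)
    spd: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise StructureError(f"adjacency must be square, got {adj.shape}")
        if not np.array_equal(adj, adj.T):
            raise StructureError("adjacency must be symmetric")
        if not np.isin(adj, (0, 1)).all():
            raise StructureError("adjacency must be binary")
        if self.spd_clip < 1:
            raise StructureError("spd_clip must be >= 1")
        self.adjacency = adj.astype(np.int8)
        self.degrees = self.adjacency.sum(axis=1).astype(np.int64)
        self.spd = shortest_path_matrix(self.adjacency, self.spd_clip)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def unreachable_code(self) -> int:
        return self.spd_clip + 1


def degree_vector(adjacency: np.ndarray) -> np.ndarray:
    """Row sums of a binary symmetric adjacency."""
    return np.asarray(adjacency).sum(axis=1).astype(np.int64)


def shortest_path_matrix(adjacency: np.ndarray, clip: int = 8) -> np.ndarray:
    """All-pairs unweighted shortest paths, clipped at ``clip``.

    Distances > clip are stored as ``clip``; unreachable pairs as the
    sentinel ``clip + 1``; the diagonal is 0.
    """
    sparse = csr_matrix(np.asarray(adjacency, dtype=np.int8))
    dist = shortest_path(sparse, method="D", unweighted=True, directed=False)
    out = np.full(dist.shape, clip + 1, dtype=np.int64)
    reachable = np.isfinite(dist)
    out[reachable] = np.minimum(dist[reachable], clip).astype(np.int64)
    return out


def degree_bucket(degrees: np.ndarray, max_bucket: int) -> np.ndarray:
    """Clip integer degrees into embedding-table indices 0..max_bucket."""
    if max_bucket < 1:
        raise ValueError("max_bucket must be >= 1")
    degrees = np.asarray(degrees)
    if (degrees < 0).any():
        raise StructureError("negative degree")
    return np.minimum(degrees, max_bucket).astype(np.int64)


def graph_density(assoc: AssociationMatrix) -> float:
    """Bipartite density E / (M * N)."""
    return assoc.n_associations / (assoc.n_mirna * assoc.n_disease)


@dataclass(frozen=True)
class GraphStats:
    """Dataset summary in the layout of a node/edge/degree/centrality table."""

    n_mirna: int
    n_disease: int
    n_edges: int

    @property
    def n_nodes(self) -> int:
        return self.n_mirna + self.n_disease

    @property
    def density(self) -> float:
        return self.n_edges / (self.n_mirna * self.n_disease)

    @property
    def mean_degree(self) -> float:
        return 2 * self.n_edges / self.n_nodes

    @property
    def mean_mirna_degree(self) -> float:
        return self.n_edges / self.n_mirna

    @property
    def mean_disease_degree(self) -> float:
        return self.n_edges / self.n_disease

    @property
    def mean_centrality(self) -> float:
        return self.mean_degree / (self.n_nodes - 1)

    @property
    def mean_mirna_centrality(self) -> float:
        return self.mean_mirna_degree / (self.n_nodes - 1)

    @property
    def mean_disease_centrality(self) -> float:
        return self.mean_disease_degree / (self.n_nodes - 1)

    def as_table(self) -> str:
        rows = [
            ("Property", "Full Data", "miRNA", "Disease"),
            ("# nodes", str(self.n_nodes), str(self.n_mirna), str(self.n_disease)),
            ("# edges", f"{self.n_edges:,}", "-", "-"),
            ("# density", f"{self.density:.4f}", "-", "-"),
            (
                "# degree",
                f"{self.mean_degree:.3f}",
                f"{self.mean_mirna_degree:.3f}",
                f"{self.mean_disease_degree:.3f}",
            ),
            (
                "# Ave_cen",
                f"{self.mean_centrality:.4f}",
                f"{self.mean_mirna_centrality:.4f}",
                f"{self.mean_disease_centrality:.4f}",
            ),
        ]
        return "\n".join("\t".join(r) for r in rows)


def graph_stats(assoc: AssociationMatrix) -> GraphStats:
    return GraphStats(assoc.n_mirna, assoc.n_disease, assoc.n_associations)
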