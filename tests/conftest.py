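import numpy as np
import pytest

from mdalink.similarity import AssociationMatrix, DiseaseDAG


@pytest.fixture
def chain_dag() -> DiseaseDAG:
    """A is-a P, P is-a R."""
    return DiseaseDAG(terms=["A", "P", "R"], parent_edges={("A", "P"), ("P", "R")})


@pytest.fixture
def diamond_dag() -> DiseaseDAG:
    """A is-a P1 and P2; both are-a R."""
    return DiseaseDAG(
        terms=["A", "P1", "P2", "R"],
        parent_edges={("A", "P1"), ("A", "P2"), ("P1", "R"), ("P2", "R")},
    )


@pytest.fixture
def sibling_dag() -> DiseaseDAG:
    """A and B are both children of P; P is-a R."""
    return DiseaseDAG(
        terms=["A", "B", "P", "R"],
        parent_edges={("A", "P"), ("B", "P"), ("P", "R")},
    )


@pytest.fixture
def toy_assoc() -> AssociationMatrix:
    entries = np.array(
        [
            [1, 0, 1],
            [0, 1, 0],
            [1, 1, 0],
            [0, 0, 1],
        ]
    )
    return AssociationMatrix(["m1", "m2", "m3", "m4"], ["A", "B", "C"], entries)


def random_dag(rng: np.random.Generator, n_terms: int, decay: float = 0.5) -> DiseaseDAG:
    """Random DAG: node i may take parents among nodes < i (acyclic by construction)."""
    terms = [f"t{i}" for i in range(n_terms)]
    edges = set()
    for i in range(1, n_terms):
        n_parents = rng.integers(0, min(i, 3) + 1)
        for p in rng.choice(i, size=n_parents, replace=False):
            edges.add((terms[i], terms[int(p)]))
    return DiseaseDAG(terms=terms, parent_edges=edges, decay=decay)


def oracle_semantic_contributions(dag: DiseaseDAG, root: str) -> dict[str, float]:
    """Exhaustive path enumeration: every root-to-ancestor path contributes
    decay^length; each node keeps its best path score."""
    best: dict[str, float] = {}

    def dfs(node: str, score: float) -> None:
        best[node] = max(best.get(node, 0.0), score)
        for parent in dag.parents_of(node):
            dfs(parent, score * dag.decay)

    dfs(root, 1.0)
    return best


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    """Independent all-pairs shortest-path oracle (pre-clip), inf if unreachable."""
    n = adj.shape[0]
    d = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    return d
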