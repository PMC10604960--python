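"""Similarity kernels and network assembly for the bipartite association graph.

Implements the four similarity measures used to featurize miRNA and disease
nodes — ontology-based disease semantic similarity, best-match-average miRNA
functional similarity, and Gaussian interaction-profile (GIP) kernels on both
axes — plus the aggregation of primary/fallback similarities into initial
node feature matrices and the assembly of binary similarity adjacencies and
the (M+N)-node heterogeneous adjacency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "DiseaseDAG",
    "AssociationMatrix",
    "SimilarityMatrix",
    "SemanticProfile",
    "semantic_profile",
    "disease_semantic_similarity",
    "semantic_similarity_matrix",
    "mirna_functional_similarity",
    "functional_similarity_matrix",
    "gip_bandwidth",
    "gip_similarity",
    "aggregate_similarity",
    "build_similarity_adjacency",
    "build_hetero_adjacency",
]


class IdentifierError(KeyError):
    """An id is not present in the relevant registry."""


class StructureError(ValueError):
    """A graph violates a structural requirement (cycle, bad edge, ...)."""


class DegenerateBandwidthError(ZeroDivisionError):
    """All interaction profiles are zero; the GIP bandwidth is undefined."""


def _check_registry(ids: Sequence[str]) -> dict[str, int]:
    index = {t: i for i, t in enumerate(ids)}
    if len(index) != len(ids):
        raise ValueError("duplicate identifiers in registry")
    return index


@dataclass
class DiseaseDAG:
    """Directed acyclic 'is-a' hierarchy over disease terms.

    ``parent_edges`` contains (child, parent) pairs; semantic contributions
    decay by ``decay`` per hop toward the ancestors.
    """

    terms: list[str]
    parent_edges: set[tuple[str, str]]
    decay: float = 0.5

    _index: dict[str, int] = field(init=False, repr=False)
    _parents: dict[str, list[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.decay <= 1.0):
            raise ValueError(f"decay must be in (0, 1], got {self.decay}")
        self._index = _check_registry(self.terms)
        self._parents = {t: [] for t in self.terms}
        for child, parent in sorted(self.parent_edges):
            if child not in self._index or parent not in self._index:
                raise StructureError(f"edge ({child}, {parent}) has unregistered endpoint")
            self._parents[child].append(parent)
        self._assert_acyclic()

    def _assert_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(t: str) -> None:
            stack = [(t, iter(self._parents[t]))]
            state[t] = 0
            while stack:
                node, it = stack[-1]
                for p in it:
                    if state.get(p) == 0:
                        raise StructureError("cycle detected in disease hierarchy")
                    if p not in state:
                        state[p] = 0
                        stack.append((p, iter(self._parents[p])))
                        break
                else:
                    state[node] = 1
                    stack.pop()

        for t in self.terms:
            if t not in state:
                visit(t)

    def parents_of(self, term: str) -> list[str]:
        if term not in self._index:
            raise IdentifierError(term)
        return list(self._parents[term])

    def ancestors(self, term: str) -> set[str]:
        """The term itself plus every node reachable via is-a edges."""
        if term not in self._index:
            raise IdentifierError(term)
        seen = {term}
        frontier = [term]
        while frontier:
            nxt = []
            for t in frontier:
                for p in self._parents[t]:
                    if p not in seen:
                        seen.add(p)
                        nxt.append(p)
            frontier = nxt
        return seen


@dataclass
class AssociationMatrix:
    """Binary M×N miRNA-by-disease incidence with id registries."""

    mirna_ids: list[str]
    disease_ids: list[str]
    entries: np.ndarray
    provenance: str = "observed"

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries)
        m, n = len(self.mirna_ids), len(self.disease_ids)
        if m < 1 or n < 1:
            raise ValueError("registries must be non-empty")
        _check_registry(self.mirna_ids)
        _check_registry(self.disease_ids)
        if self.entries.shape != (m, n):
            raise ValueError(f"entries shape {self.entries.shape} != ({m}, {n})")
        if not np.isin(self.entries, (0, 1)).all():
            raise ValueError("entries must be exactly 0 or 1")
        self.entries = self.entries.astype(np.int8)

    @property
    def n_mirna(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_disease(self) -> int:
        return len(self.disease_ids)

    @property
    def n_associations(self) -> int:
        return int(self.entries.sum())

    def mirna_index(self, mid: str) -> int:
        try:
            return self.mirna_ids.index(mid)
        except ValueError:
            raise IdentifierError(mid) from None

    def disease_index(self, did: str) -> int:
        try:
            return self.disease_ids.index(did)
        except ValueError:
            raise IdentifierError(did) from None

    def pairs(self) -> list[tuple[str, str]]:
        mi, di = np.nonzero(self.entries)
        return [(self.mirna_ids[i], self.disease_ids[j]) for i, j in zip(mi, di)]

    def without_pairs(self, pairs: Iterable[tuple[str, str]], provenance: str = "training-fold") -> "AssociationMatrix":
        """Copy with the given positive pairs removed (for fold-wise retraining)."""
        entries = self.entries.copy()
        midx = {m: i for i, m in enumerate(self.mirna_ids)}
        didx = {d: j for j, d in enumerate(self.disease_ids)}
        for m, d in pairs:
            entries[midx[m], didx[d]] = 0
        return AssociationMatrix(list(self.mirna_ids), list(self.disease_ids), entries, provenance)


_VALID_KINDS = {"DSS", "MFS", "DGS", "MGS", "MF", "DF"}
_UNIT_DIAGONAL_KINDS = {"DSS", "DGS", "MGS", "MF", "DF"}


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity over one node family, values in [0, 1]."""

    ids: list[str]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in _VALID_KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        _check_registry(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"values shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("similarity matrix is not symmetric")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("similarity values outside [0, 1]")
        if self.kind in _UNIT_DIAGONAL_KINDS and not np.allclose(np.diag(self.values), 1.0, atol=1e-9):
            raise ValueError(f"kind {self.kind} requires unit diagonal")

    def value(self, a: str, b: str) -> float:
        idx = {t: i for i, t in enumerate(self.ids)}
        try:
            return float(self.values[idx[a], idx[b]])
        except KeyError as e:
            raise IdentifierError(e.args[0]) from None


@dataclass
class SemanticProfile:
    """Decayed ancestor contributions of one disease and their sum."""

    root: str
    contributions: dict[str, float]
    semantic_value: float


def semantic_profile(dag: DiseaseDAG, root: str) -> SemanticProfile:
    """Contribution of every ancestor of ``root`` (including itself).

    The score of the root is 1; the score of any other term t in the
    root-anchored sub-DAG is ``decay`` times the best score among t's
    children restricted to that sub-DAG.
    """
    members = dag.ancestors(root)  # raises IdentifierError on unknown root
    # children of t restricted to the sub-DAG anchored at root
    children: dict[str, list[str]] = {t: [] for t in members}
    for t in members:
        for p in dag.parents_of(t):
            if p in members:
                children[p].append(t)

    contributions: dict[str, float] = {}

    def score(t: str) -> float:
        if t in contributions:
            return contributions[t]
        if t == root:
            contributions[t] = 1.0
        else:
            contributions[t] = dag.decay * max(score(c) for c in children[t])
        return contributions[t]

    for t in members:
        score(t)
    return SemanticProfile(root, contributions, float(sum(contributions.values())))


def disease_semantic_similarity(dag: DiseaseDAG, di: str, dj: str) -> float:
    """Shared-ancestor similarity between two disease terms."""
    pi, pj = semantic_profile(dag, di), semantic_profile(dag, dj)
    shared = set(pi.contributions) & set(pj.contributions)
    if not shared:
        return 0.0
    num = sum(pi.contributions[t] + pj.contributions[t] for t in shared)
    return num / (pi.semantic_value + pj.semantic_value)


def semantic_similarity_matrix(dag: DiseaseDAG, ids: Sequence[str] | None = None) -> SimilarityMatrix:
    """Full pairwise semantic similarity over ``ids`` (default: all DAG terms)."""
    ids = list(ids) if ids is not None else list(dag.terms)
    profiles = {d: semantic_profile(dag, d) for d in ids}
    n = len(ids)
    values = np.eye(n)
    for i in range(n):
        pi = profiles[ids[i]]
        for j in range(i + 1, n):
            pj = profiles[ids[j]]
            shared = set(pi.contributions) & set(pj.contributions)
            if shared:
                num = sum(pi.contributions[t] + pj.contributions[t] for t in shared)
                values[i, j] = values[j, i] = num / (pi.semantic_value + pj.semantic_value)
    return SimilarityMatrix(ids, values, "DSS")


class DomainError(ValueError):
    """A value is outside the operation's domain (e.g. isolated miRNA)."""


def _best_match_average(dss_block: np.ndarray) -> float:
    # dss_block: |D(mi)| x |D(mj)| slice of the DSS matrix
    return float(dss_block.max(axis=1).sum() + dss_block.max(axis=0).sum()) / (
        dss_block.shape[0] + dss_block.shape[1]
    )


def mirna_functional_similarity(dss: SimilarityMatrix, assoc: AssociationMatrix, mi: str, mj: str) -> float:
    """Best-match average of disease semantic similarity over two miRNAs' disease sets."""
    if dss.kind != "DSS":
        raise ValueError(f"expected DSS matrix, got {dss.kind}")
    idx = {d: k for k, d in enumerate(dss.ids)}
    rows = {}
    for m in (mi, mj):
        i = assoc.mirna_index(m)
        ds = [idx[assoc.disease_ids[j]] for j in np.nonzero(assoc.entries[i])[0]]
        if not ds:
            raise DomainError(f"miRNA {m} has no associated disease")
        rows[m] = ds
    return _best_match_average(dss.values[np.ix_(rows[mi], rows[mj])])


def functional_similarity_matrix(dss: SimilarityMatrix, assoc: AssociationMatrix) -> SimilarityMatrix:
    """Pairwise functional similarity for all miRNAs; isolated miRNAs get zero rows.

    Zero rows signal "no information" and are meant to be backfilled from the
    GIP kernel by :func:`aggregate_similarity`.
    """
    if dss.kind != "DSS":
        raise ValueError(f"expected DSS matrix, got {dss.kind}")
    idx = {d: k for k, d in enumerate(dss.ids)}
    disease_lists = []
    for i in range(assoc.n_mirna):
        ds = [idx[assoc.disease_ids[j]] for j in np.nonzero(assoc.entries[i])[0]]
        disease_lists.append(ds)
    m = assoc.n_mirna
    values = np.zeros((m, m))
    for i in range(m):
        if not disease_lists[i]:
            continue
        values[i, i] = 1.0
        for j in range(i + 1, m):
            if not disease_lists[j]:
                continue
            block = dss.values[np.ix_(disease_lists[i], disease_lists[j])]
            values[i, j] = values[j, i] = _best_match_average(block)
    return SimilarityMatrix(list(assoc.mirna_ids), values, "MFS")


def gip_bandwidth(profiles: np.ndarray | Sequence[Sequence[float]]) -> float:
    """Inverse mean squared norm of the binary interaction profiles."""
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[0] < 1:
        raise ValueError("need at least one profile of common length")
    mean_sq = float((profiles**2).sum(axis=1).mean())
    if mean_sq == 0.0:
        raise DegenerateBandwidthError("all interaction profiles are zero")
    return 1.0 / mean_sq


def gip_similarity(assoc: AssociationMatrix, axis: str) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel over rows (mirna) or columns (disease)."""
    if axis == "disease":
        profiles = assoc.entries.T.astype(float)
        ids, kind = list(assoc.disease_ids), "DGS"
    elif axis == "mirna":
        profiles = assoc.entries.astype(float)
        ids, kind = list(assoc.mirna_ids), "MGS"
    else:
        raise ValueError(f"axis must be 'disease' or 'mirna', got {axis!r}")
    theta = gip_bandwidth(profiles)
    sq = cdist(profiles, profiles, metric="sqeuclidean")
    values = np.exp(-theta * sq)
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(ids, values, kind)


_AGG_KIND = {("MFS", "MGS"): "MF", ("DSS", "DGS"): "DF"}


def aggregate_similarity(primary: SimilarityMatrix, fallback: SimilarityMatrix) -> SimilarityMatrix:
    """Entrywise: primary where nonzero, fallback elsewhere."""
    if primary.ids != fallback.ids:
        raise ValueError("registry mismatch between primary and fallback")
    try:
        kind = _AGG_KIND[(primary.kind, fallback.kind)]
    except KeyError:
        raise ValueError(f"cannot aggregate kinds ({primary.kind}, {fallback.kind})") from None
    values = np.where(primary.values != 0, primary.values, fallback.values)
    return SimilarityMatrix(list(primary.ids), values, kind)


def build_similarity_adjacency(sim: SimilarityMatrix, threshold: float = 0.0) -> np.ndarray:
    """Binary adjacency: 1 where similarity exceeds threshold, self-loops excluded."""
    if not (0.0 <= threshold < 1.0):
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    adj = (sim.values > threshold).astype(np.int8)
    np.fill_diagonal(adj, 0)
    return adj


def build_hetero_adjacency(assoc: AssociationMatrix) -> np.ndarray:
    """(M+N)x(M+N) block matrix [[0, A], [A^T, 0]], miRNAs first."""
    a = assoc.entries
    m, n = a.shape
    g = np.zeros((m + n, m + n), dtype=np.int8)
    g[:m, m:] = a
    g[m:, :m] = a.T
    return g
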