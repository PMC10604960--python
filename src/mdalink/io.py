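"""Readers and writers for the delimited-text interchange formats."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .similarity import AssociationMatrix, DiseaseDAG, SimilarityMatrix

__all__ = [
    "read_association_edges",
    "read_dag_edges",
    "mesh_tree_to_edges",
    "read_mesh_tree",
    "read_similarity_matrix",
    "write_similarity_matrix",
]


def _read_two_columns(path, sep: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 delimited columns")
    df = df.iloc[:, :2]
    df.columns = ["a", "b"]
    # tolerate an optional header line
    first = df.iloc[0]
    if {first["a"].lower(), first["b"].lower()} & {"mirna", "disease", "child", "parent"}:
        df = df.iloc[1:]
    return df.reset_index(drop=True)


def read_association_edges(path, sep: str = "\t") -> AssociationMatrix:
    """2-column (miRNA id, disease id) edge list; registries keep first-seen order."""
    df = _read_two_columns(path, sep)
    mirna_ids = list(dict.fromkeys(df["a"]))
    disease_ids = list(dict.fromkeys(df["b"]))
    entries = np.zeros((len(mirna_ids), len(disease_ids)), dtype=np.int8)
    midx = {m: i for i, m in enumerate(mirna_ids)}
    didx = {d: j for j, d in enumerate(disease_ids)}
    for m, d in zip(df["a"], df["b"]):
        entries[midx[m], didx[d]] = 1
    return AssociationMatrix(mirna_ids, disease_ids, entries, "observed")


def read_dag_edges(path, sep: str = "\t", decay: float = 0.5) -> DiseaseDAG:
    """2-column (child term, parent term) edge list."""
    df = _read_two_columns(path, sep)
    edges = {(c, p) for c, p in zip(df["a"], df["b"])}
    terms = list(dict.fromkeys(list(df["a"]) + list(df["b"])))
    return DiseaseDAG(terms=terms, parent_edges=edges, decay=decay)


def mesh_tree_to_edges(records: list[tuple[str, str]]) -> tuple[list[str], set[tuple[str, str]]]:
    """Convert (term, dot-separated tree code) records into parent edges.

    The parent of a code is the code with its last dot segment removed; a
    term may carry several codes and therefore several parents.
    """
    code_to_term = {code: term for term, code in records}
    terms = list(dict.fromkeys(term for term, _ in records))
    edges: set[tuple[str, str]] = set()
    for term, code in records:
        if "." not in code:
            continue
        parent_code = code.rsplit(".", 1)[0]
        parent = code_to_term.get(parent_code)
        if parent is not None and parent != term:
            edges.add((term, parent))
    return terms, edges


def read_mesh_tree(path, sep: str = "\t", decay: float = 0.5) -> DiseaseDAG:
    """2-column (term, tree code) file in MeSH tree-number style."""
    df = _read_two_columns(path, sep)
    terms, edges = mesh_tree_to_edges(list(zip(df["a"], df["b"])))
    return DiseaseDAG(terms=terms, parent_edges=edges, decay=decay)


def write_similarity_matrix(sim: SimilarityMatrix, path, sep: str = "\t") -> None:
    df = pd.DataFrame(sim.values, index=sim.ids, columns=sim.ids)
    df.to_csv(path, sep=sep, float_format="%.17g")


def read_similarity_matrix(path, kind: str, sep: str = "\t") -> SimilarityMatrix:
    df = pd.read_csv(path, sep=sep, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row/column registries differ")
    return SimilarityMatrix(list(df.index), df.to_numpy(dtype=float), kind)
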