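"""Desk-scale synthetic datasets with the structure the model assumes.

A rooted random DAG over disease terms (block-mates share an ancestor
subtree) induces semantic similarity, and a latent-block bipartite matrix
provides a learnable, relational association signal of tunable density.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .config import ConfigError, SynthConfig
from .similarity import AssociationMatrix, DiseaseDAG

__all__ = ["simulate_dag", "simulate_associations", "write_fixture", "read_fixture"]


def _disease_ids(n: int) -> list[str]:
    return [f"d{i:04d}" for i in range(n)]


def _mirna_ids(n: int) -> list[str]:
    return [f"m{i:04d}" for i in range(n)]


def simulate_dag(cfg: SynthConfig) -> DiseaseDAG:
    """Random DAG forest: one anchor-rooted subtree per latent block; each
    disease term attaches to 1-2 parents drawn from its own block's subtree.

    Blocks are disjoint trees (as with top-level ontology categories), so
    semantic similarity is positive within a block and zero across blocks.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    diseases = _disease_ids(cfg.n_disease)
    if cfg.n_disease == 1:
        return DiseaseDAG(terms=diseases, parent_edges=set())
    anchors = [f"anchor{k}" for k in range(cfg.n_blocks)]
    terms = anchors + diseases
    edges: set[tuple[str, str]] = set()
    # probability of a second parent grows with the branching knob
    p_two = float(np.clip(cfg.dag_branching - 1.0, 0.0, 1.0))
    members: dict[int, list[str]] = {k: [anchors[k]] for k in range(cfg.n_blocks)}
    for i, d in enumerate(diseases):
        block = i % cfg.n_blocks
        pool = members[block]
        n_parents = min(1 + int(rng.random() < p_two), len(pool))
        for p in rng.choice(len(pool), size=n_parents, replace=False):
            edges.add((d, pool[p]))
        members[block].append(d)
    return DiseaseDAG(terms=terms, parent_edges=edges)


def block_of(index: int, n_blocks: int) -> int:
    return index % n_blocks


def simulate_associations(cfg: SynthConfig) -> AssociationMatrix:
    """Bernoulli block model over round-robin block assignments.

    Rows/columns that come out empty are redrawn so every node keeps at
    least one association.
    """
    cfg.validate()
    if cfg.p_within * (cfg.n_disease / cfg.n_blocks) < 0.05:
        raise ConfigError("expected within-block degree too small; raise p_within or sizes")
    rng = np.random.default_rng(cfg.seed)
    m, n, k = cfg.n_mirna, cfg.n_disease, cfg.n_blocks
    mb = np.arange(m) % k
    db = np.arange(n) % k
    probs = np.where(mb[:, None] == db[None, :], cfg.p_within, cfg.p_background)
    entries = (rng.random((m, n)) < probs).astype(np.int8)

    def redraw_rows(axis: int) -> None:
        for _ in range(1000):
            sums = entries.sum(axis=1 - axis)
            empty = np.nonzero(sums == 0)[0]
            if empty.size == 0:
                return
            for i in empty:
                p = probs[i] if axis == 0 else probs[:, i]
                draw = (rng.random(p.shape) < p).astype(np.int8)
                if axis == 0:
                    entries[i] = draw
                else:
                    entries[:, i] = draw
        # force one same-block association for stubborn nodes
        sums = entries.sum(axis=1 - axis)
        for i in np.nonzero(sums == 0)[0]:
            if axis == 0:
                choices = np.nonzero(db == mb[i])[0]
                entries[i, rng.choice(choices)] = 1
            else:
                choices = np.nonzero(mb == db[i])[0]
                entries[rng.choice(choices), i] = 1

    redraw_rows(0)
    redraw_rows(1)
    return AssociationMatrix(_mirna_ids(m), _disease_ids(n), entries, "synthetic")


def write_fixture(dag: DiseaseDAG, assoc: AssociationMatrix, directory, cfg: SynthConfig | None = None) -> dict[str, Path]:
    """Write edge lists plus a manifest so read-back reproduces the objects."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "associations": directory / "associations.tsv",
        "dag": directory / "dag.tsv",
        "manifest": directory / "manifest.json",
    }
    with open(paths["associations"], "w") as fh:
        fh.write("mirna\tdisease\n")
        for mde, d in assoc.pairs():
            fh.write(f"{mde}\t{d}\n")
    with open(paths["dag"], "w") as fh:
        fh.write("child\tparent\n")
        for child, parent in sorted(dag.parent_edges):
            fh.write(f"{child}\t{parent}\n")
    manifest = {
        "mirna_ids": list(assoc.mirna_ids),
        "disease_ids": list(assoc.disease_ids),
        "dag_terms": list(dag.terms),
        "decay": dag.decay,
        "provenance": assoc.provenance,
        "config": None if cfg is None else cfg.__dict__,
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2)
    return paths


def read_fixture(directory) -> tuple[DiseaseDAG, AssociationMatrix, dict]:
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    edges = set()
    with open(directory / "dag.tsv") as fh:
        next(fh)
        for line in fh:
            child, parent = line.rstrip("\n").split("\t")
            edges.add((child, parent))
    dag = DiseaseDAG(terms=list(manifest["dag_terms"]), parent_edges=edges, decay=manifest["decay"])
    mirna_ids = list(manifest["mirna_ids"])
    disease_ids = list(manifest["disease_ids"])
    entries = np.zeros((len(mirna_ids), len(disease_ids)), dtype=np.int8)
    midx = {m: i for i, m in enumerate(mirna_ids)}
    didx = {d: j for j, d in enumerate(disease_ids)}
    with open(directory / "associations.tsv") as fh:
        next(fh)
        for line in fh:
            m, d = line.rstrip("\n").split("\t")
            entries[midx[m], didx[d]] = 1
    assoc = AssociationMatrix(mirna_ids, disease_ids, entries, manifest.get("provenance", "synthetic"))
    return dag, assoc, manifest
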