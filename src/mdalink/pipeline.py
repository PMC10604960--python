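"""Assembly of model inputs from an association matrix and a disease DAG.

Everything downstream of the raw edge lists is derived here: similarity
matrices, aggregated node features, similarity adjacencies, the
heterogeneous adjacency, degrees and the clipped SPD matrix. During
cross-validation this is recomputed per fold from training positives only,
so GIP profiles and the graph never see validation edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoders.gat import gcn_normalize, neighborhood_mask
from .graphs import degree_vector, shortest_path_matrix
from .similarity import (
    AssociationMatrix,
    DiseaseDAG,
    SimilarityMatrix,
    aggregate_similarity,
    build_hetero_adjacency,
    build_similarity_adjacency,
    functional_similarity_matrix,
    gip_similarity,
    semantic_similarity_matrix,
)

__all__ = ["FeatureBundle", "build_features"]


@dataclass
class FeatureBundle:
    """All fixed (non-learned) model inputs for one association matrix."""

    mirna_ids: list[str]
    disease_ids: list[str]
    mf: np.ndarray  # M x M initial miRNA features
    df: np.ndarray  # N x N initial disease features
    gm_norm: np.ndarray  # GCN-normalized miRNA similarity adjacency
    gd_norm: np.ndarray  # GCN-normalized disease similarity adjacency
    adjacency: np.ndarray  # (M+N) x (M+N) heterogeneous adjacency
    mask: np.ndarray  # adjacency + self-loops, boolean
    degrees: np.ndarray
    spd: np.ndarray  # clipped shortest-path buckets

    @property
    def n_mirna(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_disease(self) -> int:
        return len(self.disease_ids)

    @property
    def node_ids(self) -> list[str]:
        return list(self.mirna_ids) + list(self.disease_ids)


def build_features(
    assoc: AssociationMatrix,
    dag: DiseaseDAG | None = None,
    mfs: SimilarityMatrix | None = None,
    sim_threshold: float = 0.0,
    spd_clip: int = 8,
) -> FeatureBundle:
    """Derive every model input from the (training) associations.

    The disease feature matrix aggregates semantic similarity (primary)
    with the GIP kernel (fallback); the miRNA feature matrix aggregates
    functional similarity — supplied precomputed or derived best-match from
    the semantic matrix — with the miRNA GIP kernel. Without a DAG both
    families fall back to pure GIP features.
    """
    dgs = gip_similarity(assoc, "disease")
    mgs = gip_similarity(assoc, "mirna")

    if dag is not None:
        dss = semantic_similarity_matrix(dag, assoc.disease_ids)
        df = aggregate_similarity(dss, dgs)
        if mfs is None:
            mfs = functional_similarity_matrix(dss, assoc)
        mf = aggregate_similarity(mfs, mgs)
    elif mfs is not None:
        dss = None
        df = dgs
        mf = aggregate_similarity(mfs, mgs)
    else:
        dss = None
        df = dgs
        mf = mgs

    # GM/GD come from the sparse similarity networks (functional/semantic),
    # which have genuine zeros; the aggregated MF/DF are GIP-backfilled and
    # therefore dense, which would make the convolution graph complete.
    gm = build_similarity_adjacency(mfs if mfs is not None else mf, sim_threshold)
    gd = build_similarity_adjacency(dss if dss is not None else df, sim_threshold)
    adjacency = build_hetero_adjacency(assoc)
    return FeatureBundle(
        mirna_ids=list(assoc.mirna_ids),
        disease_ids=list(assoc.disease_ids),
        mf=mf.values,
        df=df.values,
        gm_norm=gcn_normalize(gm),
        gd_norm=gcn_normalize(gd),
        adjacency=adjacency,
        mask=neighborhood_mask(adjacency),
        degrees=degree_vector(adjacency),
        spd=shortest_path_matrix(adjacency, spd_clip),
    )
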