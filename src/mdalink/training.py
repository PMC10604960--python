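"""Negative sampling, dataset splits, the training loop, and evaluation.

Splits are stratified by label. During cross-validation each fold's
validation positives are removed from the association matrix before any
feature is derived, so the heterogeneous graph, similarity adjacencies and
GIP profiles never leak held-out edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .config import RunConfig
from .nn import Adam
from .nn.autograd import bce_with_logits
from .pipeline import FeatureBundle, build_features
from .predictor import DualChannelModel, PairScores
from .similarity import AssociationMatrix, DiseaseDAG, SimilarityMatrix

__all__ = [
    "LabeledEdgeSet",
    "EvalReport",
    "sample_negatives",
    "build_labeled_set",
    "five_fold_split",
    "independent_split",
    "evaluate",
    "report_from_confusion",
    "train_model",
    "cross_validate",
    "CVResult",
]

logger = logging.getLogger("mdalink")

Pair = tuple[str, str]


@dataclass
class LabeledEdgeSet:
    """Balanced positive/negative (miRNA, disease) pairs."""

    positives: list[Pair]
    negatives: list[Pair]
    seed: int = 0

    def __post_init__(self) -> None:
        overlap = set(self.positives) & set(self.negatives)
        if overlap:
            raise ValueError(f"{len(overlap)} pairs are both positive and negative")

    def __len__(self) -> int:
        return len(self.positives) + len(self.negatives)

    def pairs_and_labels(self) -> tuple[list[Pair], np.ndarray]:
        pairs = list(self.positives) + list(self.negatives)
        labels = np.concatenate(
            [np.ones(len(self.positives), dtype=int), np.zeros(len(self.negatives), dtype=int)]
        )
        return pairs, labels


def sample_negatives(assoc: AssociationMatrix, n: int, seed: int) -> list[Pair]:
    """Uniform sample without replacement of n zero cells of the incidence."""
    zero_m, zero_d = np.nonzero(assoc.entries == 0)
    if n > zero_m.size:
        raise ValueError(f"requested {n} negatives but only {zero_m.size} zero cells exist")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(zero_m.size, size=n, replace=False)
    return [(assoc.mirna_ids[zero_m[k]], assoc.disease_ids[zero_d[k]]) for k in chosen]


def build_labeled_set(assoc: AssociationMatrix, seed: int) -> LabeledEdgeSet:
    """All observed positives plus an equal number of sampled negatives."""
    positives = assoc.pairs()
    negatives = sample_negatives(assoc, len(positives), seed)
    return LabeledEdgeSet(positives, negatives, seed)


def _chunks(items: list, k: int, rng: np.random.Generator) -> list[list]:
    order = rng.permutation(len(items))
    return [[items[i] for i in part] for part in np.array_split(order, k)]


def five_fold_split(edges: LabeledEdgeSet, seed: int, n_folds: int = 5) -> list[LabeledEdgeSet]:
    """Label-stratified partition into n_folds disjoint folds.

    Positive chunks are paired with negative chunks in reverse size order so
    fold sizes stay within one sample of the ideal even split.
    """
    if len(edges) < n_folds:
        raise ValueError("fewer labeled pairs than folds")
    rng = np.random.default_rng(seed)
    pos_chunks = _chunks(edges.positives, n_folds, rng)
    neg_chunks = _chunks(edges.negatives, n_folds, rng)[::-1]
    return [LabeledEdgeSet(p, n, seed) for p, n in zip(pos_chunks, neg_chunks)]


def independent_split(
    edges: LabeledEdgeSet, test_fraction: float, seed: int
) -> tuple[LabeledEdgeSet, LabeledEdgeSet]:
    """Stratified train/test split; test size = round(total * fraction)."""
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_total_test = round(len(edges) * test_fraction)
    n_pos_test = min(round(len(edges.positives) * test_fraction), n_total_test)
    n_neg_test = n_total_test - n_pos_test
    pos = [edges.positives[i] for i in rng.permutation(len(edges.positives))]
    neg = [edges.negatives[i] for i in rng.permutation(len(edges.negatives))]
    test = LabeledEdgeSet(pos[:n_pos_test], neg[:n_neg_test], seed)
    train = LabeledEdgeSet(pos[n_pos_test:], neg[n_neg_test:], seed)
    return train, test


@dataclass
class EvalReport:
    """Threshold metrics plus ranking metrics for one batch of scores."""

    auc: float
    aupr: float
    acc: float
    f1: float
    precision: float
    recall: float
    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float = 0.5

    def as_row(self) -> dict[str, float]:
        return {
            "auc": self.auc,
            "aupr": self.aupr,
            "acc": self.acc,
            "f1": self.f1,
            "precision": self.precision,
            "recall": self.recall,
        }


def report_from_confusion(
    tp: int, fn: int, fp: int, tn: int, auc: float = float("nan"), aupr: float = float("nan"), threshold: float = 0.5
) -> EvalReport:
    """Derive ACC / F1 / precision / recall from confusion counts.

    Precision is TP/(TP+FP) and recall TP/(TP+FN), following the metric
    definitions rather than any table that may list them swapped.
    """
    total = tp + fn + fp + tn
    acc = (tp + tn) / total if total else float("nan")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return EvalReport(auc, aupr, acc, f1, precision, recall, tp, fp, tn, fn, threshold)


def evaluate(scores: PairScores, threshold: float = 0.5) -> EvalReport:
    """Full metric suite at the given decision threshold.

    AUC is the rank statistic over score/label pairs; AUPR integrates the
    precision-recall curve.
    """
    if scores.labels is None:
        raise ValueError("evaluate requires labels")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    y = np.asarray(scores.labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined for single-class labels")
    p = scores.probabilities
    pred = (p >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    auc = float(roc_auc_score(y, p))
    aupr = float(average_precision_score(y, p))
    return report_from_confusion(tp, fn, fp, tn, auc, aupr, threshold)


def _pair_indices(bundle: FeatureBundle, pairs: list[Pair]) -> tuple[np.ndarray, np.ndarray]:
    midx = {m: i for i, m in enumerate(bundle.mirna_ids)}
    didx = {d: j for j, d in enumerate(bundle.disease_ids)}
    m = np.array([midx[a] for a, _ in pairs], dtype=np.int64)
    d = np.array([didx[b] for _, b in pairs], dtype=np.int64)
    return m, d


@dataclass
class TrainResult:
    model: DualChannelModel
    bundle: FeatureBundle
    losses: list[float] = field(default_factory=list)
    val_aucs: list[float] = field(default_factory=list)


def _training_assoc(template: AssociationMatrix, positives: list[Pair]) -> AssociationMatrix:
    entries = np.zeros((template.n_mirna, template.n_disease), dtype=np.int8)
    midx = {m: i for i, m in enumerate(template.mirna_ids)}
    didx = {d: j for j, d in enumerate(template.disease_ids)}
    for m, d in positives:
        entries[midx[m], didx[d]] = 1
    return AssociationMatrix(
        list(template.mirna_ids), list(template.disease_ids), entries, "training-fold"
    )


def train_model(
    cfg: RunConfig,
    train_set: LabeledEdgeSet,
    template: AssociationMatrix,
    dag: DiseaseDAG | None = None,
    mfs: SimilarityMatrix | None = None,
    val_set: LabeledEdgeSet | None = None,
    seed: int = 0,
) -> TrainResult:
    """Adam optimization of the cross-entropy objective on one edge split.

    The association matrix used for every derived feature contains the
    training positives only. Early stopping monitors validation AUC with
    the configured patience; the best parameters are restored.
    """
    cfg.validate()
    if not train_set.positives:
        raise ValueError("training set has no positive edges")
    train_assoc = _training_assoc(template, train_set.positives)
    bundle = build_features(
        train_assoc, dag, mfs, cfg.train.sim_threshold, cfg.trf.spd_clip
    )
    model = DualChannelModel(bundle.mf.shape[1], bundle.df.shape[1], cfg, seed)
    optimizer = Adam(model.parameters(), lr=cfg.train.lr)

    pairs, labels = train_set.pairs_and_labels()
    m_idx, d_idx = _pair_indices(bundle, pairs)
    labels = labels.reshape(-1, 1).astype(float)

    val_pairs = val_labels = None
    if val_set is not None:
        val_pairs, val_labels = val_set.pairs_and_labels()

    result = TrainResult(model, bundle)
    best_auc, best_state, stale = -np.inf, None, 0
    for epoch in range(cfg.train.epochs):
        model.train()
        optimizer.zero_grad()
        logits = model.pair_logits(bundle, m_idx, d_idx)
        loss = bce_with_logits(logits, labels)
        if not np.isfinite(loss.data):
            raise RuntimeError(f"training diverged at epoch {epoch}: loss={loss.data}")
        loss.backward()
        optimizer.step()
        result.losses.append(float(loss.data))

        if val_set is not None:
            scored = model.score_pairs(bundle, val_pairs, val_labels)
            auc = float(roc_auc_score(val_labels, scored.probabilities))
            result.val_aucs.append(auc)
            if auc > best_auc + 1e-6:
                best_auc, stale = auc, 0
                best_state = {k: p.data.copy() for k, p in model.named_parameters().items()}
            else:
                stale += 1
                if stale >= cfg.train.patience:
                    logger.info("early stop at epoch %d (best val AUC %.4f)", epoch, best_auc)
                    break
        if epoch % 20 == 0:
            logger.info("epoch %d loss %.4f", epoch, result.losses[-1])
    if best_state is not None:
        for k, p in model.named_parameters().items():
            p.data = best_state[k]
    model.eval()
    return result


@dataclass
class CVResult:
    reports: list[EvalReport]

    def mean(self, metric: str) -> float:
        return float(np.mean([r.as_row()[metric] for r in self.reports]))

    def std(self, metric: str) -> float:
        return float(np.std([r.as_row()[metric] for r in self.reports]))

    def summary(self) -> dict[str, tuple[float, float]]:
        keys = ["auc", "aupr", "acc", "f1", "precision", "recall"]
        return {k: (self.mean(k), self.std(k)) for k in keys}


def cross_validate(
    cfg: RunConfig,
    assoc: AssociationMatrix,
    dag: DiseaseDAG | None = None,
    mfs: SimilarityMatrix | None = None,
    seed: int = 0,
    n_folds: int = 5,
) -> CVResult:
    """Stratified n-fold cross-validation with fold-wise feature rebuilds."""
    edges = build_labeled_set(assoc, seed)
    folds = five_fold_split(edges, seed, n_folds)
    reports = []
    for i, fold in enumerate(folds):
        train_pos = [p for j, f in enumerate(folds) if j != i for p in f.positives]
        train_neg = [p for j, f in enumerate(folds) if j != i for p in f.negatives]
        train_set = LabeledEdgeSet(train_pos, train_neg, seed)
        result = train_model(cfg, train_set, assoc, dag, mfs, val_set=fold, seed=seed + i)
        val_pairs, val_labels = fold.pairs_and_labels()
        scored = result.model.score_pairs(result.bundle, val_pairs, val_labels)
        report = evaluate(scored, cfg.train.threshold)
        logger.info("fold %d: AUC %.4f AUPR %.4f ACC %.4f", i, report.auc, report.aupr, report.acc)
        reports.append(report)
    return CVResult(reports)


def degree_null_scores(
    bundle: FeatureBundle, pairs: list[Pair], labels: np.ndarray | None = None
) -> PairScores:
    """Null ranking baseline: score(m, d) proportional to deg(m) * deg(d)."""
    m_idx, d_idx = _pair_indices(bundle, pairs)
    deg = bundle.degrees.astype(float)
    raw = deg[m_idx] * deg[d_idx + bundle.n_mirna]
    probs = raw / (raw.max() + 1.0) if raw.max() > 0 else np.full(len(pairs), 0.5)
    return PairScores(list(pairs), np.clip(probs, 1e-6, 1 - 1e-6), labels)
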