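"""Training loop, imbalanced 5-fold cross-validation and ranking metrics.

Known miRNA-target pairs are the positives; every other miRNA x target
combination is unknown and treated as negative. Positives are shuffled and
split into five near-equal parts. Each fold trains on four parts plus an
equal number of negatives sampled uniformly (without replacement, seeded)
from the unknown pairs, and tests on the held-out positives against *all*
remaining unknown pairs — the test set is therefore heavily imbalanced,
which is why the threshold-free AUROC and AUPRC are the primary metrics.

The objective is binary cross-entropy plus an L2 penalty,

    L = B + lambda/(2N) * sum_w w^2,

minimised full-batch with Adam. Per-fold graphs contain only training-fold
positives in the association block, so no held-out edge is visible to the
encoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .graph import HeterogeneousGraph, SimilarityNetwork, assemble_graph, normalize, similarity_network
from .io_formats import AssociationList, SequenceRecord
from .kmer import KmerConfig, frequency_matrix
from .model import GCNConfig, LinkModel
from .sdnn import EmbeddingMatrix, SDNNConfig, embed, train_sdnn
from ._optim import Adam

__all__ = [
    "TrainConfig",
    "FoldSplit",
    "MetricsReport",
    "bce_loss",
    "l2_penalty",
    "make_folds",
    "compute_metrics",
    "train_fold",
    "run_cv",
    "aggregate_metrics",
]

_EPS = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings and graph-ablation switches.

    Defaults follow the grid-search optima: learning rate 1e-4, 3000 epochs,
    L2 coefficient 5e-4. Ablations: ``use_node_features=False`` replaces the
    embedding attributes with one-hot identity rows; the similarity switches
    zero out the corresponding within-role adjacency block.
    ``test_neg_cap`` optionally subsamples test negatives (seeded) for
    desk-scale runs — a deviation from the full-unknown test protocol.
    """

    learning_rate: float = 1e-4
    epochs: int = 3000
    l2_lambda: float = 5e-4
    seed: int = 0
    use_node_features: bool = True
    use_mirna_similarity: bool = True
    use_target_similarity: bool = True
    test_neg_cap: int | None = None
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be >= 0")

    @property
    def variant_name(self) -> str:
        """Ablation-variant label: which graph components are in play."""
        parts = ["miT"]
        if self.use_target_similarity:
            parts.append("TT")
        if self.use_mirna_similarity:
            parts.append("mimi")
        if self.use_node_features:
            parts.append("feat")
        return "+".join(parts)


@dataclass
class FoldSplit:
    """One CV fold; all pair sets are lists of (miRNA_id, target_id)."""

    fold_id: int
    train_pos: list[tuple[str, str]]
    train_neg: list[tuple[str, str]]
    test_pos: list[tuple[str, str]]
    test_neg: list[tuple[str, str]]


def bce_loss(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean binary cross-entropy; predictions are clipped to [eps, 1-eps]."""
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValueError(f"label/prediction length mismatch: {y.shape} vs {y_hat.shape}")
    p = np.clip(y_hat, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def l2_penalty(weight_matrices: list[np.ndarray], lam: float, N: int) -> float:
    """lambda/(2N) times the summed squared weight elements (biases excluded)."""
    if N < 1:
        raise ValueError("N must be >= 1")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    total = sum(float(np.sum(np.square(w))) for w in weight_matrices)
    return lam / (2.0 * N) * total


def make_folds(
    positives: AssociationList,
    mirna_ids: list[str],
    target_ids: list[str],
    seed: int,
    n_folds: int = 5,
) -> list[FoldSplit]:
    """Partition positives into ``n_folds`` test sets and sample negatives.

    The test-positive sets are disjoint, exhaust all positives and differ in
    size by at most one. Per fold, training negatives are drawn uniformly
    without replacement from the unknown pairs, matched 1:1 to the training
    positives; test negatives are every remaining unknown pair.
    """
    pos = list(positives)
    if len(pos) < n_folds:
        raise ValueError(f"need >= {n_folds} positives, got {len(pos)}")
    pos_set = set(pos)
    universe = [(m, t) for m in mirna_ids for t in target_ids]
    unknown = [p for p in universe if p not in pos_set]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pos))
    shuffled = [pos[i] for i in order]
    # near-equal contiguous chunks
    bounds = np.linspace(0, len(pos), n_folds + 1).astype(int)
    folds: list[FoldSplit] = []
    for f in range(n_folds):
        test_pos = shuffled[bounds[f] : bounds[f + 1]]
        train_pos = shuffled[: bounds[f]] + shuffled[bounds[f + 1] :]
        neg_idx = rng.choice(len(unknown), size=len(train_pos), replace=False)
        train_neg = [unknown[i] for i in neg_idx]
        train_neg_set = set(train_neg)
        test_neg = [p for p in unknown if p not in train_neg_set]
        folds.append(
            FoldSplit(
                fold_id=f + 1,
                train_pos=train_pos,
                train_neg=train_neg,
                test_pos=test_pos,
                test_neg=test_neg,
            )
        )
    return folds


@dataclass
class MetricsReport:
    """Confusion counts at a fixed threshold plus threshold-free areas."""

    TP: int
    FP: int
    FN: int
    TN: int
    AUROC: float
    AUPRC: float
    ACC: float
    REC: float
    PRE: float
    F1: float
    zero_denominator: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def compute_metrics(
    y: np.ndarray, y_hat: np.ndarray, threshold: float = 0.5
) -> MetricsReport:
    """Confusion metrics at ``threshold`` plus AUROC/AUPRC over the ranking.

    ACC = (TP+TN)/(TP+TN+FP+FN), REC = TP/(TP+FN), PRE = TP/(TP+FP),
    F1 = 2*REC*PRE/(REC+PRE). Metrics with a zero denominator are reported
    as 0 and flagged. AUROC/AUPRC require both classes present.
    """
    y = np.asarray(y, dtype=int)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes for AUROC/AUPRC")
    pred = (y_hat >= threshold).astype(int)
    TP = int(np.sum((pred == 1) & (y == 1)))
    FP = int(np.sum((pred == 1) & (y == 0)))
    FN = int(np.sum((pred == 0) & (y == 1)))
    TN = int(np.sum((pred == 0) & (y == 0)))
    flags: list[str] = []

    def _safe(num: float, den: float, name: str) -> float:
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    acc = _safe(TP + TN, TP + TN + FP + FN, "ACC")
    rec = _safe(TP, TP + FN, "REC")
    pre = _safe(TP, TP + FP, "PRE")
    f1 = _safe(2.0 * rec * pre, rec + pre, "F1")
    return MetricsReport(
        TP=TP,
        FP=FP,
        FN=FN,
        TN=TN,
        AUROC=float(roc_auc_score(y, y_hat)),
        AUPRC=float(average_precision_score(y, y_hat)),
        ACC=acc,
        REC=rec,
        PRE=pre,
        F1=f1,
        zero_denominator=flags,
    )


def _pair_indices(
    pairs: list[tuple[str, str]], graph: HeterogeneousGraph
) -> list[tuple[int, int]]:
    m_index = {mid: i for i, mid in enumerate(graph.mirna_ids)}
    t_index = {tid: j for j, tid in enumerate(graph.target_ids)}
    return [(m_index[m], t_index[t]) for m, t in pairs]


def train_fold(
    graph: HeterogeneousGraph,
    fold: FoldSplit,
    config: TrainConfig,
    gcn_config: GCNConfig | None = None,
) -> tuple[LinkModel, list[dict]]:
    """Fit the link model on one fold's training edges.

    The graph must already contain only this fold's training positives in its
    association block. Returns the trained model and a per-epoch trace of
    ``{"bce", "l2", "total"}`` with total = bce + l2 exactly.
    """
    gcn_config = gcn_config or GCNConfig(seed=config.seed + fold.fold_id)
    P = normalize(graph).P
    model = LinkModel(
        P, graph.node_features.values, graph.n_mirna, config=gcn_config
    )
    pairs = _pair_indices(fold.train_pos + fold.train_neg, graph)
    y = np.concatenate(
        [np.ones(len(fold.train_pos)), np.zeros(len(fold.train_neg))]
    )
    n_pairs = len(pairs)
    opt = Adam(model.params.flat(), lr=config.learning_rate)
    trace: list[dict] = []
    for epoch in range(config.epochs):
        prob, caches = model.forward(pairs)
        b = bce_loss(y, prob)
        l2 = l2_penalty(model.params.weight_matrices(), config.l2_lambda, n_pairs)
        total = b + l2
        if not np.isfinite(total):
            raise FloatingPointError(f"training loss diverged at epoch {epoch}")
        trace.append({"bce": b, "l2": l2, "total": total})
        grads = model.backward(pairs, y, caches, l2_lambda=config.l2_lambda)
        opt.step(grads)
    return model, trace


def _identity_features(emb: EmbeddingMatrix) -> EmbeddingMatrix:
    n = emb.values.shape[0]
    return EmbeddingMatrix(
        values=np.eye(n), row_ids=list(emb.row_ids), n_mirna=emb.n_mirna
    )


def _ablate_similarity(S: SimilarityNetwork, keep: bool) -> SimilarityNetwork:
    if keep:
        return S
    return SimilarityNetwork(
        values=np.zeros_like(S.values), metric=S.metric, threshold=S.threshold
    )


def build_inputs(
    mirnas: list[SequenceRecord],
    targets: list[SequenceRecord],
    kmer_config: KmerConfig | None = None,
    sdnn_config: SDNNConfig | None = None,
    metric: str = "cosine",
    sim_threshold: float = 0.5,
    similarity_source: str = "frequency",
):
    """Shared label-free pipeline stages: frequencies, embeddings, similarities.

    Similarity defaults to the raw k-mer frequency rows;
    ``similarity_source="embedding"`` uses the SDNN embedding rows instead.
    Everything here is independent of the association labels, so it is
    computed once and reused across CV folds and ablation variants.
    """
    kmer_config = kmer_config or KmerConfig()
    sdnn_config = sdnn_config or SDNNConfig()
    freqs = frequency_matrix(list(mirnas) + list(targets), kmer_config)
    encoder, sdnn_trace = train_sdnn(freqs, sdnn_config)
    emb = embed(encoder, freqs)
    nm = freqs.n_mirna
    source = emb.values if similarity_source == "embedding" else freqs.values
    S_mirna = similarity_network(source[:nm], metric=metric, threshold=sim_threshold)
    S_target = similarity_network(source[nm:], metric=metric, threshold=sim_threshold)
    return freqs, emb, S_mirna, S_target, sdnn_trace


def run_cv(
    mirnas: list[SequenceRecord],
    targets: list[SequenceRecord],
    associations: AssociationList,
    train_config: TrainConfig | None = None,
    kmer_config: KmerConfig | None = None,
    sdnn_config: SDNNConfig | None = None,
    gcn_config: GCNConfig | None = None,
    metric: str = "cosine",
    sim_threshold: float = 0.5,
    similarity_source: str = "frequency",
    n_folds: int = 5,
    precomputed=None,
) -> dict:
    """End-to-end cross-validated evaluation.

    Builds the label-free inputs once, then per fold assembles the graph from
    training positives only, trains the link model and scores the held-out
    positives against the remaining unknown pairs. Returns a report with
    per-fold metrics and fold-mean +/- 0.95 confidence interval.
    ``precomputed`` accepts the tuple returned by :func:`build_inputs` to
    share the expensive stages across ablation variants.
    """
    train_config = train_config or TrainConfig()
    if precomputed is None:
        precomputed = build_inputs(
            mirnas,
            targets,
            kmer_config=kmer_config,
            sdnn_config=sdnn_config or SDNNConfig(seed=train_config.seed),
            metric=metric,
            sim_threshold=sim_threshold,
            similarity_source=similarity_source,
        )
    freqs, emb, S_mirna, S_target, _ = precomputed
    features = emb if train_config.use_node_features else _identity_features(emb)
    S_m = _ablate_similarity(S_mirna, train_config.use_mirna_similarity)
    S_t = _ablate_similarity(S_target, train_config.use_target_similarity)

    mirna_ids = [r.id for r in mirnas]
    target_ids = [r.id for r in targets]
    folds = make_folds(
        associations, mirna_ids, target_ids, seed=train_config.seed, n_folds=n_folds
    )
    per_fold = []
    rng = np.random.default_rng(train_config.seed + 10_000)
    for fold in folds:
        graph = assemble_graph(
            S_m, S_t, AssociationList(pairs=fold.train_pos), features
        )
        model, trace = train_fold(graph, fold, train_config, gcn_config=gcn_config)
        test_neg = fold.test_neg
        if (
            train_config.test_neg_cap is not None
            and len(test_neg) > train_config.test_neg_cap
        ):
            keep = rng.choice(
                len(test_neg), size=train_config.test_neg_cap, replace=False
            )
            test_neg = [test_neg[i] for i in keep]
        test_pairs = fold.test_pos + test_neg
        y = np.concatenate([np.ones(len(fold.test_pos)), np.zeros(len(test_neg))])
        prob = model.forward(_pair_indices(test_pairs, graph))[0]
        report = compute_metrics(y, prob, threshold=train_config.threshold)
        per_fold.append(
            {
                "fold": fold.fold_id,
                "metrics": report.to_dict(),
                "final_loss": trace[-1]["total"],
            }
        )
    summary = aggregate_metrics([pf["metrics"] for pf in per_fold])
    return {
        "variant": train_config.variant_name,
        "n_folds": n_folds,
        "per_fold": per_fold,
        "summary": summary,
    }


def aggregate_metrics(fold_metrics: list[dict]) -> dict:
    """Fold mean and 0.95 t-based confidence half-width per metric."""
    from scipy import stats

    out: dict[str, dict[str, float]] = {}
    n = len(fold_metrics)
    for key in ("AUROC", "AUPRC", "ACC", "REC", "PRE", "F1"):
        vals = np.array([fm[key] for fm in fold_metrics], dtype=float)
        mean = float(vals.mean())
        if n > 1:
            half = float(
                stats.t.ppf(0.975, n - 1) * vals.std(ddof=1) / np.sqrt(n)
            )
        else:
            half = 0.0
        out[key] = {"mean": mean, "ci95": half}
    return out
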