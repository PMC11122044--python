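import math

import numpy as np
import pytest

from mirtargraph.graph import assemble_graph, similarity_network
from mirtargraph.io_formats import AssociationList
from mirtargraph.model import GCNConfig
from mirtargraph.sdnn import EmbeddingMatrix
from mirtargraph.training import (
    FoldSplit,
    TrainConfig,
    bce_loss,
    compute_metrics,
    l2_penalty,
    make_folds,
    train_fold,
)


class TestBCE:
    def test_confident_correct_is_near_zero(self):
        assert bce_loss([1.0], [1.0 - 1e-7]) == pytest.approx(0.0, abs=1e-6)
        assert bce_loss([0.0], [1e-7]) == pytest.approx(0.0, abs=1e-6)

    def test_uninformative_prediction_is_ln2(self):
        assert bce_loss([1.0, 0.0], [0.5, 0.5]) == pytest.approx(math.log(2), abs=1e-12)

    def test_matches_elementwise_brute_force(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 101))
            y = rng.integers(0, 2, size=n).astype(float)
            p = rng.uniform(1e-6, 1 - 1e-6, size=n)
            expected = -sum(
                yi * math.log(pi) + (1 - yi) * math.log(1 - pi) for yi, pi in zip(y, p)
            ) / n
            assert bce_loss(y, p) == pytest.approx(expected, abs=1e-10)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bce_loss([1.0], [0.5, 0.5])


class TestL2:
    def test_zero_lambda(self):
        assert l2_penalty([np.ones((3, 3))], 0.0, 10) == 0.0

    def test_single_weight_hand_value(self):
        # lambda/(2N) * omega^2 = 1/(2*1) * 4 = 2
        assert l2_penalty([np.array([[2.0]])], 1.0, 1) == pytest.approx(2.0)

    def test_matches_direct_summation(self, rng):
        mats = [rng.standard_normal((3, 4)), rng.standard_normal((2, 2))]
        lam, N = 0.37, 13
        direct = lam / (2 * N) * sum((m**2).sum() for m in mats)
        assert l2_penalty(mats, lam, N) == pytest.approx(direct, rel=1e-12)


class TestMakeFolds:
    def _ids(self):
        return [f"m{i}" for i in range(2)], [f"t{j}" for j in range(10)]

    def test_ten_positives_arithmetic(self):
        ms, ts = self._ids()
        pos = AssociationList(pairs=[("m0", t) for t in ts])
        folds = make_folds(pos, ms, ts, seed=0)
        assert len(folds) == 5
        for f in folds:
            assert len(f.test_pos) == 2
            assert len(f.train_pos) == 8
            assert len(f.train_neg) == 8
            # 2*10 pairs total, 10 positives -> 10 unknown; minus 8 train_neg
            assert len(f.test_neg) == 2

    def test_test_sets_partition_positives(self):
        ms, ts = self._ids()
        pos = AssociationList(pairs=[("m0", t) for t in ts[:6]] + [("m1", t) for t in ts[6:]])
        folds = make_folds(pos, ms, ts, seed=3)
        seen = [p for f in folds for p in f.test_pos]
        assert len(seen) == len(set(seen)) == 10
        assert set(seen) == pos.pair_set

    def test_train_and_test_disjoint(self):
        ms, ts = self._ids()
        pos = AssociationList(pairs=[("m0", t) for t in ts])
        for f in make_folds(pos, ms, ts, seed=1):
            train = set(f.train_pos) | set(f.train_neg)
            test = set(f.test_pos) | set(f.test_neg)
            assert not (train & test)

    def test_too_few_positives(self):
        ms, ts = self._ids()
        with pytest.raises(ValueError, match=">= 5"):
            make_folds(AssociationList(pairs=[("m0", "t0")] * 3), ms, ts, seed=0)

    def test_seeded_reproducibility(self):
        ms, ts = self._ids()
        pos = AssociationList(pairs=[("m0", t) for t in ts])
        a = make_folds(pos, ms, ts, seed=9)
        b = make_folds(pos, ms, ts, seed=9)
        for fa, fb in zip(a, b):
            assert fa.train_neg == fb.train_neg
            assert fa.test_pos == fb.test_pos


class TestComputeMetrics:
    def test_hand_confusion_example(self):
        # TP=3, FP=1, FN=2, TN=4 at threshold 0.5
        y = [1, 1, 1, 0, 1, 1, 0, 0, 0, 0]
        p = [0.9, 0.8, 0.7, 0.6, 0.4, 0.3, 0.2, 0.2, 0.1, 0.1]
        r = compute_metrics(y, p)
        assert (r.TP, r.FP, r.FN, r.TN) == (3, 1, 2, 4)
        assert r.ACC == pytest.approx(0.7)
        assert r.REC == pytest.approx(0.6)
        assert r.PRE == pytest.approx(0.75)
        assert r.F1 == pytest.approx(2 / 3)

    def test_symmetric_quarter_confusion(self):
        y = [1] * 50 + [0] * 50
        p = ([0.9] * 25 + [0.1] * 25) + ([0.9] * 25 + [0.1] * 25)
        r = compute_metrics(y, p)
        assert (r.TP, r.FP, r.FN, r.TN) == (25, 25, 25, 25)
        for v in (r.ACC, r.REC, r.PRE, r.F1):
            assert v == pytest.approx(0.5)

    def test_perfect_ranking(self):
        r = compute_metrics([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
        assert r.AUROC == 1.0
        assert r.AUPRC == 1.0

    def test_auroc_matches_concordance_counting(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 51))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            p = rng.random(n)
            conc = 0.0
            npairs = 0
            for i in np.flatnonzero(y == 1):
                for j in np.flatnonzero(y == 0):
                    npairs += 1
                    if p[i] > p[j]:
                        conc += 1
                    elif p[i] == p[j]:
                        conc += 0.5
            assert compute_metrics(y, p).AUROC == pytest.approx(conc / npairs, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            compute_metrics([1, 1], [0.4, 0.9])

    def test_zero_denominator_flagged(self):
        r = compute_metrics([1, 0], [0.1, 0.2])  # no positive predictions
        assert r.PRE == 0.0
        assert "PRE" in r.zero_denominator


def _tiny_graph(seed=0, n_m=2, n_t=5):
    rng = np.random.default_rng(seed)
    feats = EmbeddingMatrix(
        values=rng.standard_normal((n_m + n_t, 6)),
        row_ids=[f"m{i}" for i in range(n_m)] + [f"t{j}" for j in range(n_t)],
        n_mirna=n_m,
    )
    S_m = similarity_network(np.eye(n_m), "cosine", 0.5)
    S_t = similarity_network(np.eye(n_t), "cosine", 0.5)
    return feats, S_m, S_t


class TestTrainFold:
    def test_overfits_single_edge_without_regularization(self):
        feats, S_m, S_t = _tiny_graph()
        assoc = AssociationList(pairs=[("m0", "t0")])
        graph = assemble_graph(S_m, S_t, assoc, feats)
        fold = FoldSplit(
            fold_id=1,
            train_pos=[("m0", "t0")],
            train_neg=[("m1", "t4")],
            test_pos=[],
            test_neg=[],
        )
        cfg = TrainConfig(learning_rate=1e-2, epochs=500, l2_lambda=0.0, seed=0)
        model, trace = train_fold(
            graph, fold, cfg, gcn_config=GCNConfig(gcn_dims=(6, 4, 4), mlp_hidden=(4, 2), seed=0)
        )
        prob = model.forward([(0, 0)])[0]
        assert prob[0] > 0.9

    def test_loss_trace_decomposes_exactly(self):
        feats, S_m, S_t = _tiny_graph(seed=2)
        assoc = AssociationList(pairs=[("m0", "t0"), ("m1", "t1")])
        graph = assemble_graph(S_m, S_t, assoc, feats)
        fold = FoldSplit(
            fold_id=1,
            train_pos=list(assoc),
            train_neg=[("m0", "t2"), ("m1", "t3")],
            test_pos=[],
            test_neg=[],
        )
        cfg = TrainConfig(epochs=20, seed=1)
        _, trace = train_fold(
            graph, fold, cfg, gcn_config=GCNConfig(gcn_dims=(4, 3, 3), mlp_hidden=(3,), seed=1)
        )
        assert len(trace) == 20
        for rec in trace:
            assert rec["total"] == rec["bce"] + rec["l2"]

    def test_fixed_seed_identical_trace(self):
        feats, S_m, S_t = _tiny_graph(seed=3)
        assoc = AssociationList(pairs=[("m0", "t0"), ("m1", "t1")])
        graph = assemble_graph(S_m, S_t, assoc, feats)
        fold = FoldSplit(
            fold_id=2,
            train_pos=list(assoc),
            train_neg=[("m0", "t3"), ("m1", "t2")],
            test_pos=[],
            test_neg=[],
        )
        cfg = TrainConfig(epochs=30, seed=5)
        g = GCNConfig(gcn_dims=(4, 3, 3), mlp_hidden=(3,), seed=5)
        _, t1 = train_fold(graph, fold, cfg, gcn_config=g)
        _, t2 = train_fold(graph, fold, cfg, gcn_config=g)
        assert t1 == t2


def test_fold_graph_never_contains_test_edges():
    """Leakage guard: held-out positives are absent from the fold adjacency."""
    ms = [f"m{i}" for i in range(3)]
    ts = [f"t{j}" for j in range(8)]
    pos = AssociationList(pairs=[(ms[i % 3], t) for i, t in enumerate(ts)])
    folds = make_folds(pos, ms, ts, seed=4)
    rng = np.random.default_rng(0)
    feats = EmbeddingMatrix(
        values=rng.standard_normal((11, 4)), row_ids=ms + ts, n_mirna=3
    )
    S_m = similarity_network(np.eye(3), "cosine", 0.5)
    S_t = similarity_network(np.eye(8), "cosine", 0.5)
    for fold in folds:
        graph = assemble_graph(S_m, S_t, AssociationList(pairs=fold.train_pos), feats)
        for m, t in fold.test_pos:
            i, j = ms.index(m), ts.index(t)
            assert graph.association_block[i, j] == 0.0
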