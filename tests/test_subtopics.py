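"""RBM/DBN features, softmax head, fine-tuning and subtopic discovery."""

import numpy as np
import pytest
from scipy.special import expit

from socialsurv.subtopics import (
    DBNFeatures, FinetuneConfig, RBMLayer, SoftmaxHead, SubtopicModel,
    discover_subtopics, dbn_features, finetune, finetune_cost,
    label_clusters, rank_subtopics, softmax_forward,
)


def _prototype_data(rng, n=500, d=16, k=8):
    protos = rng.integers(0, 2, size=(k, d)).astype(float)
    return protos[rng.integers(0, k, n)]


class TestRBM:
    def test_reconstruction_error_decreases(self, rng):
        X = _prototype_data(rng)
        rbm = RBMLayer(20, epochs=15, learning_rate=0.2, seed=1).fit(X)
        errs = rbm.reconstruction_errors_
        assert errs[-1] < errs[0]

    def test_zero_learning_rate_freezes_weights(self, rng):
        X = _prototype_data(rng, n=50)
        a = RBMLayer(8, epochs=0, seed=3).fit(X)
        b = RBMLayer(8, epochs=10, learning_rate=0.0, seed=3).fit(X)
        np.testing.assert_array_equal(a.weights_, b.weights_)
        np.testing.assert_array_equal(a.hidden_bias_, b.hidden_bias_)

    def test_seeded_reproducibility(self, rng):
        X = _prototype_data(rng, n=100)
        a = RBMLayer(8, epochs=5, seed=7).fit(X)
        b = RBMLayer(8, epochs=5, seed=7).fit(X)
        np.testing.assert_array_equal(a.weights_, b.weights_)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            RBMLayer(4).fit(np.zeros((0, 3)))


class TestDBNFeatures:
    def test_zero_weights_give_half_activations(self):
        layer = RBMLayer(3)
        layer.weights_ = np.zeros((4, 3))
        layer.visible_bias_ = np.zeros(4)
        layer.hidden_bias_ = np.zeros(3)
        dbn = DBNFeatures((3,))
        dbn.layers_ = [layer]
        np.testing.assert_allclose(dbn_features(dbn, np.zeros(4)), 0.5)

    def test_activations_in_unit_interval(self, rng):
        X = _prototype_data(rng, n=60, d=10)
        dbn = DBNFeatures((6, 4), epochs=3, seed=0).fit(X)
        f = dbn.transform(X)
        assert np.all((f > 0) & (f < 1))

    def test_matches_hand_computed_sigmoids(self):
        layer = RBMLayer(2)
        layer.weights_ = np.array([[0.5, -1.0], [2.0, 0.25]])
        layer.visible_bias_ = np.zeros(2)
        layer.hidden_bias_ = np.array([0.1, -0.2])
        dbn = DBNFeatures((2,))
        dbn.layers_ = [layer]
        v = np.array([1.0, 1.0])
        expected = expit(np.array([0.5 + 2.0 + 0.1, -1.0 + 0.25 - 0.2]))
        np.testing.assert_allclose(dbn_features(dbn, v)[0], expected,
                                   atol=1e-12)

    def test_width_mismatch_rejected(self, rng):
        X = _prototype_data(rng, n=30, d=10)
        dbn = DBNFeatures((4,), epochs=1, seed=0).fit(X)
        with pytest.raises(ValueError):
            dbn.layers_[0].transform(np.zeros((1, 7)))


class TestSoftmaxForward:
    def test_identical_weights_uniform(self):
        head = SoftmaxHead(np.ones((4, 3)))
        np.testing.assert_allclose(softmax_forward(head, np.array([1., 2., 3.])),
                                   0.25, atol=1e-12)

    def test_sums_to_one(self, rng):
        head = SoftmaxHead(rng.normal(size=(5, 6)))
        for _ in range(10):
            p = softmax_forward(head, rng.normal(size=6))
            assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_bruteforce(self, rng):
        import math
        head = SoftmaxHead(rng.normal(size=(4, 6)))
        m = rng.normal(size=6)
        p = softmax_forward(head, m)
        raw = [math.exp(sum(head.weights[t][i] * m[i] for i in range(6)))
               for t in range(4)]
        z = sum(raw)
        np.testing.assert_allclose(p, [r / z for r in raw], atol=1e-9)

    def test_shift_invariance(self, rng):
        head = SoftmaxHead(rng.normal(size=(3, 4)))
        m = rng.normal(size=4)
        p0 = softmax_forward(head, m)
        p1 = softmax_forward(SoftmaxHead(head.weights + 3.3), m)
        np.testing.assert_allclose(p0, p1, atol=1e-12)

    def test_nonfinite_rejected(self):
        head = SoftmaxHead(np.ones((2, 2)))
        with pytest.raises(ValueError):
            softmax_forward(head, np.array([np.nan, 1.0]))


class TestFinetune:
    def test_gradient_matches_finite_differences(self, rng):
        W = rng.normal(size=(3, 5))
        M = rng.normal(size=(20, 5))
        y = rng.integers(0, 3, 20)
        Y = np.eye(3)[y]
        _, g = finetune_cost(W, M, Y, penalty=2.0)
        eps = 1e-6
        for i in range(3):
            for j in range(5):
                Wp, Wm = W.copy(), W.copy()
                Wp[i, j] += eps
                Wm[i, j] -= eps
                num = (finetune_cost(Wp, M, Y, 2.0)[0]
                       - finetune_cost(Wm, M, Y, 2.0)[0]) / (2 * eps)
                assert abs(g[i, j] - num) / max(abs(num), 1e-8) < 1e-5

    def test_zero_penalty_reduces_to_cross_entropy(self, rng):
        W = rng.normal(size=(3, 4))
        M = rng.normal(size=(10, 4))
        y = rng.integers(0, 3, 10)
        Y = np.eye(3)[y]
        J, _ = finetune_cost(W, M, Y, penalty=0.0)
        from scipy.special import softmax as sm
        P = sm(M @ W.T, axis=1)
        ce = -np.mean(np.log(P[np.arange(10), y]))
        assert J == pytest.approx(ce, abs=1e-12)

    def test_separable_toy_reaches_perfect_accuracy(self, rng):
        centers = np.eye(3) * 6
        M = np.vstack([centers[i] + rng.normal(0, 0.1, size=(30, 3))
                       for i in range(3)])
        y = np.repeat([0, 1, 2], 30)
        head, _ = finetune(None, SoftmaxHead(np.zeros((3, 3))), M, y,
                           FinetuneConfig(penalty=0.0))
        pred = np.argmax(softmax_forward(head, M), axis=1)
        assert (pred == y).mean() == 1.0

    def test_gd_and_lbfgs_agree_on_convex_toy(self, rng):
        M = rng.normal(size=(40, 4))
        y = rng.integers(0, 3, 40)
        head0 = SoftmaxHead(np.zeros((3, 4)))
        cfg_gd = FinetuneConfig(optimizer="gradient-descent", max_iter=500,
                                tol=1e-10)
        cfg_lb = FinetuneConfig(optimizer="l-bfgs", max_iter=500, tol=1e-12)
        _, tr_gd = finetune(None, head0, M, y, cfg_gd)
        _, tr_lb = finetune(None, head0, M, y, cfg_lb)
        assert abs(tr_gd[-1] - tr_lb[-1]) < 1e-3

    def test_gd_trace_non_increasing(self, rng):
        M = rng.normal(size=(30, 4))
        y = rng.integers(0, 2, 30)
        _, tr = finetune(None, SoftmaxHead(np.zeros((2, 4))), M, y,
                         FinetuneConfig(optimizer="gradient-descent"))
        assert all(a >= b - 1e-12 for a, b in zip(tr, tr[1:]))

    def test_empty_labels_rejected(self):
        with pytest.raises(ValueError):
            finetune(None, SoftmaxHead(np.zeros((2, 2))),
                     np.zeros((0, 2)), [])

    def test_deep_finetune_improves_cost(self, rng):
        X = _prototype_data(rng, n=80, d=10, k=3)
        y = rng.integers(0, 3, 80)
        dbn = DBNFeatures((6,), epochs=2, seed=0).fit(X)
        head = SoftmaxHead(rng.normal(0, 0.01, size=(3, 6)))
        _, tr = finetune(dbn, head, X, y,
                         FinetuneConfig(penalty=0.0, update_layers=True,
                                        optimizer="gradient-descent",
                                        max_iter=50))
        assert tr[-1] < tr[0]


class TestDiscovery:
    def _two_vocab_docs(self, rng, n=200):
        docs, truth = [], []
        for i in range(n):
            g = i % 2
            base = "flu" if g == 0 else "sport"
            docs.append([f"{base}tok{rng.integers(6)}" for _ in range(8)])
            truth.append(g)
        return docs, np.array(truth)

    def test_separated_vocabularies_cluster_purely(self, rng):
        from socialsurv.topics import build_vocabulary, to_matrix
        docs, truth = self._two_vocab_docs(rng)
        M = to_matrix(docs, build_vocabulary(docs, 1))
        dbn = DBNFeatures((12,), epochs=10, learning_rate=0.2, seed=0).fit(M)
        assign = discover_subtopics(dbn.transform(M), 2, seed=0)
        purity = max(
            np.mean((assign == truth)), np.mean((assign == 1 - truth)))
        assert purity >= 0.95

    def test_degenerate_k_equals_n(self, rng):
        feats = rng.random(size=(12, 4))
        assign = discover_subtopics(feats, 12, seed=0)
        assert len(set(assign.tolist())) == 12  # every cluster a singleton

    def test_seeded_partition_identical(self, rng):
        feats = rng.random(size=(50, 4))
        a = discover_subtopics(feats, 5, seed=3)
        b = discover_subtopics(feats, 5, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            discover_subtopics(np.zeros((3, 2)), 4)

    def test_cluster_labels_by_lift(self, rng):
        docs = [["flu", "common"]] * 10 + [["sport", "common"]] * 10
        assign = np.array([0] * 10 + [1] * 10)
        labels = label_clusters(assign, docs)
        assert labels == {0: "flu", 1: "sport"}


class TestRanking:
    def test_percentage_formatting(self):
        r = rank_subtopics(["flu"] * 7 + ["other"] * 193, "health")
        assert ("flu", 3.50) in r.entries

    def test_single_subtopic(self):
        assert rank_subtopics(["flu"], "health").entries == [("flu", 100.0)]

    def test_percentages_partition(self):
        r = rank_subtopics(["a"] * 3 + ["b"] * 5 + ["c"] * 2, "t")
        assert sum(p for _, p in r.entries) == pytest.approx(100.0, abs=0.01)
        assert [p for _, p in r.entries] == \
            sorted((p for _, p in r.entries), reverse=True)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_subtopics([], "health")


def test_emergent_subtopic_recovered_end_to_end(rng):
    """An injected flu/fever/breathing vocabulary within a health stream is
    discovered as the top-ranked subtopic with its defining tokens."""
    event_vocab = [f"{w}{j}" for w in ("flu", "fever", "breathing")
                   for j in range(4)]
    docs = []
    for i in range(2000):
        if i % 10 < 6:  # emergent subtopic dominates the window
            pool = event_vocab
        elif i % 10 < 8:
            pool = [f"checkup{j}" for j in range(8)]
        else:
            pool = [f"diet{j}" for j in range(8)]
        docs.append([pool[rng.integers(len(pool))] for _ in range(8)])
    model = SubtopicModel(k=3, layer_sizes=(16,), epochs=8,
                          learning_rate=0.2, penalty=0.01, seed=0).fit(docs)
    pred = model.predict(docs)
    ranking = rank_subtopics(pred, "health")
    top_name = ranking.entries[0][0]
    top_members = [d for d, p in zip(docs, pred) if p == top_name]
    covered = {t for d in top_members for t in d}
    recall = sum(1 for w in event_vocab if w in covered) / len(event_vocab)
    assert top_name in set(event_vocab)
    assert recall >= 0.9
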