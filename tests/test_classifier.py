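import numpy as np
import pandas as pd
import pytest

from circmilink.classifier import (
    CapacityError,
    DegenerateLabelsError,
    assemble_pair_features,
    binary_cross_entropy,
    predict_scores,
    rank_candidate_pairs,
    sample_negatives,
    train_dnn,
)
from circmilink.corpus_io import AdjacencyMatrix


def small_adj():
    P = np.array([[1, 0, 1], [0, 1, 0]], dtype=np.int8)
    return AdjacencyMatrix(P, ["c1", "c2"], ["m1", "m2", "m3"])


class TestSampleNegatives:
    def test_exclusion_and_count(self):
        labeled = sample_negatives(small_adj(), ratio=1.0, seed=0)
        pos = {p for p, l in zip(labeled.pairs, labeled.labels) if l == 1}
        neg = {p for p, l in zip(labeled.pairs, labeled.labels) if l == 0}
        assert len(pos) == 3 and len(neg) == 3
        assert pos.isdisjoint(neg)

    def test_capacity_error_on_full_matrix(self):
        adj = AdjacencyMatrix(np.ones((2, 2), dtype=np.int8),
                              ["c1", "c2"], ["m1", "m2"])
        with pytest.raises(CapacityError):
            sample_negatives(adj, ratio=1.0, seed=0)

    def test_deterministic_per_seed(self):
        a = sample_negatives(small_adj(), seed=5)
        b = sample_negatives(small_adj(), seed=5)
        assert a.pairs == b.pairs
        assert np.array_equal(a.labels, b.labels)


class TestAssemble:
    def _frames(self, d_attr=4, d_beh=2):
        idx_c, idx_m = ["c1", "c2"], ["m1", "m2", "m3"]
        mk = lambda idx, d, o: pd.DataFrame(
            np.arange(len(idx) * d).reshape(len(idx), d) + o, index=idx
        )
        return (mk(idx_c, d_attr, 0), mk(idx_c, d_beh, 100),
                mk(idx_m, d_attr, 200), mk(idx_m, d_beh, 300))

    def test_width_and_segment_order(self):
        fc, bc, fm, bm = self._frames()
        X, layout = assemble_pair_features(fc, bc, fm, bm, [("c1", "m2")])
        assert layout.width == 12 and X.shape == (1, 12)
        assert np.array_equal(X[0, :4], fc.loc["c1"])
        assert np.array_equal(X[0, 4:6], bc.loc["c1"])
        assert np.array_equal(X[0, 6:10], fm.loc["m2"])
        assert np.array_equal(X[0, 10:], bm.loc["m2"])

    def test_default_dims_width_384(self):
        idx_c, idx_m = ["c1"], ["m1"]
        z = lambda idx, d: pd.DataFrame(np.zeros((len(idx), d)), index=idx)
        X, layout = assemble_pair_features(
            z(idx_c, 128), z(idx_c, 64), z(idx_m, 128), z(idx_m, 64),
            [("c1", "m1")],
        )
        assert layout.width == 384 and X.shape[1] == 384

    def test_swapping_pairs_swaps_rows(self):
        fc, bc, fm, bm = self._frames()
        X1, _ = assemble_pair_features(fc, bc, fm, bm,
                                       [("c1", "m1"), ("c2", "m3")])
        X2, _ = assemble_pair_features(fc, bc, fm, bm,
                                       [("c2", "m3"), ("c1", "m1")])
        assert np.array_equal(X1, X2[::-1])

    def test_missing_id_error(self):
        fc, bc, fm, bm = self._frames()
        with pytest.raises(KeyError, match="m9"):
            assemble_pair_features(fc, bc, fm, bm, [("c1", "m9")])


class TestTrainDNN:
    def test_bce_hand_value(self):
        assert np.isclose(binary_cross_entropy([1.0], [0.5]), np.log(2))

    def test_bce_matches_elementwise_oracle(self, rng):
        y = (rng.random(1000) < 0.5).astype(float)
        p = rng.uniform(0.01, 0.99, 1000)
        oracle = -np.mean([yi * np.log(pi) + (1 - yi) * np.log(1 - pi)
                           for yi, pi in zip(y, p)])
        assert abs(binary_cross_entropy(y, p) - oracle) < 1e-12

    def test_bce_near_zero_at_perfect_fit(self):
        y = np.array([0.0, 1.0, 1.0])
        assert binary_cross_entropy(y, [1e-9, 1 - 1e-9, 1 - 1e-9]) < 1e-6

    def test_separable_blobs_learned(self, rng):
        n = 250
        X = np.vstack([rng.normal(-2, 1, (n, 8)), rng.normal(2, 1, (n, 8))])
        y = np.r_[np.zeros(n), np.ones(n)]
        model = train_dnn(X, y, hidden_layers=(16,), max_epochs=50, seed=0)
        acc = ((predict_scores(model, X) >= 0.5) == y).mean()
        assert acc >= 0.95

    def test_single_class_rejected(self, rng):
        with pytest.raises(DegenerateLabelsError):
            train_dnn(rng.random((10, 3)), np.ones(10))

    def test_deterministic_per_seed(self, rng):
        X = rng.random((40, 6))
        y = (rng.random(40) < 0.5).astype(float)
        y[:2], y[-2:] = 0, 1
        a = train_dnn(X, y, hidden_layers=(8,), max_epochs=3, seed=9)
        b = train_dnn(X, y, hidden_layers=(8,), max_epochs=3, seed=9)
        assert all(np.array_equal(w1, w2)
                   for w1, w2 in zip(a.weights, b.weights))

    def test_label_shuffle_gives_chance_auc(self, rng):
        from circmilink.metrics import roc_auc

        aucs = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = r.normal(size=(300, 10))
            y = r.permutation(np.r_[np.zeros(150), np.ones(150)])
            tr, te = np.arange(200), np.arange(200, 300)
            model = train_dnn(X[tr], y[tr], hidden_layers=(16,),
                              max_epochs=20, seed=seed)
            aucs.append(roc_auc(y[te], predict_scores(model, X[te])))
        assert 0.4 <= np.mean(aucs) <= 0.6


class TestPredictScores:
    @pytest.fixture
    def model(self):
        rng = np.random.default_rng(0)
        X = rng.random((30, 5))
        y = np.r_[np.zeros(15), np.ones(15)]
        return train_dnn(X, y, hidden_layers=(4,), max_epochs=2, seed=0)

    def test_zero_final_layer_gives_half(self, model, rng):
        model.weights[-1][:] = 0
        model.biases[-1][:] = 0
        assert np.allclose(predict_scores(model, rng.random((4, 5))), 0.5)

    def test_scores_open_interval_and_pure(self, model, rng):
        X = rng.random((10, 5))
        s1, s2 = predict_scores(model, X), predict_scores(model, X)
        assert ((s1 > 0) & (s1 < 1)).all()
        assert np.array_equal(s1, s2)

    def test_order_invariance(self, model, rng):
        X = rng.random((10, 5))
        perm = rng.permutation(10)
        assert np.allclose(predict_scores(model, X[perm]),
                           predict_scores(model, X)[perm])

    def test_output_bias_shift_monotone(self, model, rng):
        X = rng.random((10, 5))
        base = predict_scores(model, X)
        model.biases[-1][:] += 1.0
        assert (predict_scores(model, X) > base).all()

    def test_width_mismatch(self, model, rng):
        with pytest.raises(ValueError):
            predict_scores(model, rng.random((2, 7)))


class TestRanking:
    def _model(self):
        rng = np.random.default_rng(1)
        X = rng.random((20, 3))
        y = np.r_[np.zeros(10), np.ones(10)]
        return train_dnn(X, y, hidden_layers=(4,), max_epochs=2, seed=1)

    def test_descending_order(self):
        model = self._model()
        cands = [("c1", "m1"), ("c2", "m1"), ("c3", "m1")]
        X = np.random.default_rng(2).random((3, 3))
        df = rank_candidate_pairs(model, cands, X)
        assert (np.diff(df["score"].to_numpy()) <= 0).all()
        assert list(df.index) == [1, 2, 3]

    def test_tie_broken_lexicographically(self):
        model = self._model()
        X = np.zeros((3, 3))  # identical features -> identical scores
        cands = [("c2", "m1"), ("c1", "m2"), ("c1", "m1")]
        df = rank_candidate_pairs(model, cands, X)
        assert list(zip(df["circRNA_id"], df["miRNA_id"])) == [
            ("c1", "m1"), ("c1", "m2"), ("c2", "m1")
        ]

    def test_top_k_truncation_and_empty(self):
        model = self._model()
        X = np.random.default_rng(3).random((30, 3))
        cands = [(f"c{i}", "m1") for i in range(30)]
        assert len(rank_candidate_pairs(model, cands, X, top_k=10)) == 10
        assert rank_candidate_pairs(model, [], np.empty((0, 3))).empty
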