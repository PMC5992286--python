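"""Feature ranking, consensus, tensor features, metrics, and leakage-safe CV."""

import numpy as np
import pytest

from mlfc.classify import (
    TSAProjector,
    consensus_features,
    crossvalidate,
    edge_feature_matrix,
    metrics,
    multilayer_edge_feature_matrix,
    rank_features_mi,
    run_fold,
)
from mlfc.bands import coupling_modes, DEFAULT_BANDS
from mlfc.connectivity import SLFCG


class TestRankFeaturesMi:
    def test_label_copy_ranked_first(self, rng):
        y = np.array([1] * 20 + [2] * 20)
        X = rng.normal(size=(40, 10))
        X[:, 7] = y
        assert rank_features_mi(X, y, k=3)[0] == 7

    def test_duplicate_of_top_demoted(self, rng):
        """With an imperfect top feature duplicated, the redundancy
        penalty promotes an informative independent feature to rank 2."""
        y = np.array([1] * 30 + [2] * 30)
        top = y + rng.normal(0, 0.3, 60)  # strong but imperfect
        other = (y == 2).astype(float) + rng.normal(0, 0.8, 60)
        X = np.c_[top, top.copy(), other]
        ranking = rank_features_mi(X, y, k=2)
        assert ranking[0] == 0
        assert ranking[1] == 2

    def test_constant_feature_is_not_an_error(self, rng):
        y = np.array([1, 1, 2, 2] * 5)
        X = np.c_[np.ones(20), rng.normal(size=(20, 2))]
        ranking = rank_features_mi(X, y, k=3)
        assert sorted(ranking) == [0, 1, 2]

    def test_k_exceeding_features_errors(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            rank_features_mi(rng.normal(size=(10, 3)), np.array([1, 2] * 5), k=5)

    def test_all_noise_top1_roughly_uniform(self, rng):
        """On pure noise every feature should top the ranking about
        equally often (100 label redraws, 8 features)."""
        counts = np.zeros(8)
        X = rng.normal(size=(40, 8))
        for p in range(100):
            yp = np.random.default_rng(p).permutation([1] * 20 + [2] * 20)
            counts[rank_features_mi(X, yp, k=1)[0]] += 1
        # binomial(100, 1/8) 95% interval, with continuity slack
        assert counts.max() <= 12.5 + 1.96 * np.sqrt(100 * (1 / 8) * (7 / 8)) + 1


class TestConsensus:
    def test_identical_rankings(self):
        folds = [["a", "b", "c"]] * 4
        assert [f for f, _ in consensus_features(folds, 2)] == ["a", "b"]

    def test_majority_kept_over_dissent(self):
        folds = [["a", "b"], ["a", "b"], ["a", "c"]]
        top = [f for f, _ in consensus_features(folds, 2)]
        assert top[0] == "a" and top[1] == "b"

    def test_tie_broken_by_mean_rank(self):
        """Frequencies {a:5, b:5, c:4} with m=2 keep {a, b}."""
        folds = [["a", "b", "c"]] * 4 + [["b", "a", "x"]]
        sel = consensus_features(folds, 2)
        assert {f for f, _ in sel} == {"a", "b"}
        assert all(n == 5 for _, n in sel)

    def test_overflow_returns_all_with_warning(self):
        with pytest.warns(UserWarning, match="distinct"):
            sel = consensus_features([["a", "b"]], 5)
        assert len(sel) == 2


class TestTsa:
    def test_output_dimensionality(self, rng):
        graphs = [rng.normal(size=(20, 20)) for _ in range(12)]
        y = np.array([1, 2] * 6)
        F = TSAProjector(6, 6).fit(graphs, y).transform(graphs)
        assert F.shape == (12, 36)

    def test_full_rank_identity_limit(self, rng):
        """At d1=d2=N the orthonormal bases are complete, so the bilinear
        projection is invertible: U U' W V V' == W."""
        graphs = [rng.normal(size=(6, 6)) for _ in range(10)]
        y = np.array([1] * 5 + [2] * 5)
        p = TSAProjector(6, 6).fit(graphs, y)
        W = graphs[3]
        assert np.allclose(p.U @ p.U.T @ W @ p.V @ p.V.T, W, atol=1e-8)

    def test_planted_block_separates(self, rng):
        """Graphs differing by a rank-1 block between groups become
        linearly separable after projection (training accuracy 1)."""
        from sklearn.svm import SVC

        graphs, y = [], []
        for g in (1, 2):
            for _ in range(10):
                W = rng.normal(size=(12, 12)) * 0.1
                W = (W + W.T) / 2
                if g == 2:
                    W[:4, :4] += 0.8
                graphs.append(W)
                y.append(g)
        y = np.array(y)
        F = TSAProjector(6, 6).fit(graphs, y).transform(graphs)
        acc = SVC(kernel="linear").fit(F, y).score(F, y)
        assert acc == 1.0

    def test_oversized_projection_rejected(self, rng):
        with pytest.raises(ValueError, match="exceed"):
            TSAProjector(8, 8).fit([rng.normal(size=(6, 6))] * 4, np.array([1, 1, 2, 2]))


class TestMetrics:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((10, 0, 10, 0), (1.0, 1.0, 1.0)),
            ((0, 10, 10, 0), (0.0, 1.0, 0.5)),
            ((7, 3, 6, 4), (0.7, 0.6, 0.65)),
        ],
    )
    def test_hand_cases(self, counts, expected):
        m = metrics(*counts)
        assert (m.sensitivity, m.specificity, m.accuracy) == pytest.approx(expected)

    def test_empty_class_flagged(self):
        with pytest.warns(UserWarning, match="sensitivity"):
            m = metrics(0, 0, 5, 5)
        assert np.isnan(m.sensitivity)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics(-1, 0, 0, 1)


class TestFeatureMatrices:
    def test_edge_count_closed_form(self, rng):
        for n in (10, 20, 90):
            mats = [np.zeros((n, n)) for _ in range(2)]
            fm = edge_feature_matrix(mats, np.array([1, 2]), "alpha1")
            assert fm.X.shape[1] == n * (n - 1) // 2
        assert fm.X.shape[1] == 4005  # N=90 single layer

    def test_multilayer_edge_count(self):
        n = 10
        modes = coupling_modes(DEFAULT_BANDS)
        layers = [[SLFCG("iplv", m, np.zeros((n, n))) for m in modes] for _ in range(2)]
        fm = multilayer_edge_feature_matrix(layers, np.array([1, 2]))
        assert fm.X.shape[1] == 28 * n * (n - 1) // 2
        # at N=90 the same construction gives 28 * 4005 = 112,140 features
        assert 28 * 90 * 89 // 2 == 112140


class TestCrossvalidate:
    def test_separable_feature_perfect_loocv(self, rng):
        X = np.c_[np.r_[np.zeros(10), np.ones(10)], rng.normal(size=(20, 5))]
        y = np.array([1] * 10 + [2] * 10)
        res = crossvalidate(X, y, scheme="loocv", route="edge", k_rank=3)
        assert (res.sensitivity, res.specificity, res.accuracy) == (1.0, 1.0, 1.0)

    def test_loocv_accuracy_equals_pooled_confusion(self, rng):
        X = rng.normal(size=(16, 8))
        y = np.array([1, 2] * 8)
        res = crossvalidate(X, y, scheme="loocv", route="edge", k_rank=4)
        tp, fn, tn, fp = res.confusion
        assert res.accuracy == pytest.approx((tp + tn) / 16)
        assert res.accuracy == pytest.approx(np.mean(res.y_true == res.y_pred))

    def test_fold_artifacts_blind_to_heldout_labels(self, rng):
        """Corrupting the held-out labels changes neither the selected
        features nor the predictions of a fold (no leakage)."""
        X = rng.normal(size=(20, 12))
        y = np.array([1] * 10 + [2] * 10)
        train = np.arange(16)
        test = np.arange(16, 20)
        sel1, pred1 = run_fold(X, y, train, test, "edge", k_rank=5)
        y_corrupt = y.copy()
        y_corrupt[test] = 1
        sel2, pred2 = run_fold(X, y_corrupt, train, test, "edge", k_rank=5)
        assert sel1 == sel2
        assert np.array_equal(pred1, pred2)
        # tensor route: same property on graph stacks
        G = rng.normal(size=(20, 8, 8))
        _, p1 = run_fold(G, y, train, test, "tensor", d1=4, d2=4)
        _, p2 = run_fold(G, y_corrupt, train, test, "tensor", d1=4, d2=4)
        assert np.array_equal(p1, p2)

    def test_missing_class_in_training_fold_errors(self, rng):
        X = rng.normal(size=(6, 4))
        y = np.array([1, 1, 1, 1, 2, 2])
        with pytest.raises(ValueError, match="absent"):
            run_fold(X, y, np.array([0, 1, 2, 3]), np.array([4, 5]), "edge", k_rank=2)

    def test_five_fold_reports_sd(self, rng):
        X = rng.normal(size=(30, 10))
        X[:, 0] = np.r_[np.zeros(15), np.ones(15)] + rng.normal(0, 0.1, 30)
        y = np.array([1] * 15 + [2] * 15)
        res = crossvalidate(X, y, scheme="5fold", route="edge", k_rank=3, seed=0)
        assert res.accuracy_sd is not None
        assert 0.0 <= res.accuracy <= 1.0
        assert len(res.fold_rankings) == 5

    def test_feature_matrix_input_carries_ids(self, rng):
        mats = [rng.normal(size=(6, 6)) for _ in range(12)]
        mats = [(W + W.T) / 2 for W in mats]
        y = np.array([1, 2] * 6)
        fm = edge_feature_matrix(mats, y, "alpha2")
        res = crossvalidate(fm, scheme="loocv", route="edge", k_rank=3, m_consensus=3)
        assert all(fid[0] == "alpha2" for fid, _ in res.consensus_features)

    def test_two_classes_required(self, rng):
        with pytest.raises(ValueError, match="2 classes"):
            crossvalidate(rng.normal(size=(6, 3)), np.ones(6), scheme="loocv", route="edge")
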