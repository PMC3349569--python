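import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_auc_score

from coremod import (
    ConsensusFeatureEliminator,
    ConsensusMarkerSelector,
    auc,
    consensus_feature_elimination,
    select_final_markers,
    train_lda,
    train_linear_svm,
)
from oracles import pair_count_auc


def planted_problem(seed, n=60, p=20, effect=2.0, sep_noise=0.3):
    """One informative feature (column 0) among pure-noise features."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = np.array([1] * (n // 2) + [-1] * (n - n // 2))
    X[:, 0] = y * effect + rng.normal(0, sep_noise, n)
    return X, y


class TestLda:
    def test_weight_sign_follows_mean_difference(self):
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.normal(2, 1, 100), rng.normal(-2, 1, 100)])[:, None]
        y = np.array([1] * 100 + [-1] * 100)
        clf = train_lda(X, y)
        assert clf.weights[0] > 0

    def test_agrees_with_sklearn_shrinkage_lda(self):
        X, y = planted_problem(1, p=8)
        mine = train_lda(X, y)
        sk = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto").fit(X, y)
        cos = mine.weights @ sk.coef_[0] / (
            np.linalg.norm(mine.weights) * np.linalg.norm(sk.coef_[0]))
        assert cos > 0.99

    def test_duplicated_feature_decisions_match_single(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100) + np.array([1] * 50 + [-1] * 50) * 1.5
        y = np.array([1] * 50 + [-1] * 50)
        single = train_lda(x[:, None], y)
        dup = train_lda(np.column_stack([x, x]), y)
        d1, d2 = single.decision(x[:, None]), dup.decision(np.column_stack([x, x]))
        assert np.corrcoef(d1, d2)[0, 1] > 0.999
        assert np.array_equal(np.sign(d1), np.sign(d2))
        # pseudo-inverse oracle splits the weight between the two copies
        assert dup.weights[0] == pytest.approx(dup.weights[1], rel=1e-6)

    def test_no_signal_gives_chance_auc(self):
        rng = np.random.default_rng(3)
        Xtr, Xte = rng.normal(size=(80, 5)), rng.normal(size=(80, 5))
        y = np.array([1] * 40 + [-1] * 40)
        clf = train_lda(Xtr, y)
        assert abs(auc(clf.decision(Xte), y) - 0.5) < 0.15


class TestSvm:
    def test_separable_two_points(self):
        X = np.array([[1.0], [1.1], [-1.0], [-1.1]])
        y = np.array([1, 1, -1, -1])
        clf = train_linear_svm(X, y)
        assert np.array_equal(clf.predict(X), y)

    def test_feature_scaling_halves_weights_at_large_c(self):
        X, y = planted_problem(4, p=3, effect=3.0, sep_noise=0.1)
        w1 = train_linear_svm(X, y, c=1e6).weights
        w2 = train_linear_svm(2 * X, y, c=1e6).weights
        assert np.allclose(w2, w1 / 2, rtol=1e-3, atol=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_linear_svm(np.zeros((4, 2)), np.ones(4))


class TestAuc:
    def test_known_values(self):
        assert auc([0.9, 0.8, 0.3, 0.1], [1, 1, -1, -1]) == 1.0
        assert auc([0.9, 0.8, 0.3, 0.1], [1, -1, 1, -1]) == 0.75
        assert auc([0.5, 0.5, 0.5, 0.5], [1, 1, -1, -1]) == 0.5

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_matches_pair_counting_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        scores = rng.choice([0.1, 0.2, 0.5, 0.7, 0.7, 0.9], size=n)
        y = rng.choice([-1, 1], size=n)
        if len(set(y)) < 2:
            y[0], y[1] = 1, -1
        assert auc(scores, y) == pytest.approx(pair_count_auc(scores, y),
                                               abs=1e-12)
        assert auc(scores, y) == pytest.approx(roc_auc_score(y == 1, scores),
                                               abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])


class TestConsensusFeatureElimination:
    def test_planted_feature_recovered(self):
        X, y = planted_problem(7)
        res = consensus_feature_elimination(X, y, n_splits=20, seed=1)
        assert 0 in res.selected_features
        assert res.max_mean_auc > 0.95
        assert len(res.auc_trajectory) == X.shape[1]  # every step reported
        assert all(0 <= a <= 1 for a in res.auc_trajectory)

    def test_bit_reproducible_with_fixed_seed(self):
        X, y = planted_problem(8, p=6)
        a = consensus_feature_elimination(X, y, n_splits=10, seed=42)
        b = consensus_feature_elimination(X, y, n_splits=10, seed=42)
        assert a.auc_trajectory == b.auc_trajectory
        assert a.selected_features == b.selected_features
        assert a.removed_order == b.removed_order

    def test_single_feature_trajectory(self):
        X, y = planted_problem(9, p=1)
        res = consensus_feature_elimination(X, y, n_splits=10, seed=0)
        assert res.selected_features == [0]
        assert len(res.auc_trajectory) == 1

    def test_lda_and_svm_agree_on_strong_feature_sign(self):
        X, y = planted_problem(10, p=4)
        w_lda = train_lda(X, y).weights
        w_svm = train_linear_svm(X, y).weights
        assert np.sign(w_lda[0]) == np.sign(w_svm[0]) == 1

    def test_too_few_samples_per_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        y = np.array([1, 1, 1, -1, -1, -1])
        with pytest.raises(ValueError, match="n_folds"):
            ConsensusFeatureEliminator(n_folds=5).fit(X, y)

    def test_feature_names_from_dataframe(self):
        import pandas as pd
        X, y = planted_problem(11, p=4)
        frame = pd.DataFrame(X, columns=["sig", "n1", "n2", "n3"])
        elim = ConsensusFeatureEliminator(n_splits=10, random_state=0).fit(frame, y)
        assert "sig" in elim.selected_features_
        assert elim.transform(frame).shape[1] == len(elim.selected_features_)


class TestFinalMarkers:
    def test_separable_problem_unanimous(self):
        X, y = planted_problem(12, p=3, effect=4.0, sep_noise=0.05)
        selected, freqs, sel = select_final_markers(
            X, y, n_repeats=10, n_splits=10, seed=5)
        assert selected == [0]
        assert sel.set_counts_[frozenset([0])] == 10
        assert freqs[0] == 1.0

    def test_tie_goes_to_smaller_then_lexicographic_set(self):
        from coremod.cfe import most_frequent_set
        counts = {frozenset(["b"]): 3, frozenset(["a"]): 3,
                  frozenset(["a", "b"]): 3, frozenset(["c", "d"]): 1}
        assert most_frequent_set(counts) == frozenset(["a"])
        assert most_frequent_set({frozenset([1, 2]): 2,
                                  frozenset([3]): 1}) == frozenset([1, 2])

    def test_deterministic_under_master_seed(self):
        X, y = planted_problem(13, p=5)
        a = select_final_markers(X, y, n_repeats=4, n_splits=5, seed=9)[0]
        b = select_final_markers(X, y, n_repeats=4, n_splits=5, seed=9)[0]
        assert a == b
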