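"""Attention pooling algebra, AUC oracle, CV machinery and signal recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ihcmil.attn_mil import (AttentionMILParams, CVResult, TrainConfig, auc,
                             attention_pool, cross_validate, ensemble_predict,
                             predict_bag, select_explainability_model,
                             stratified_kfold, train_fold)
from ihcmil.synthdata import generate_feature_bags


def _params(dim=8, hidden=4, seed=0, random_head=True):
    p = AttentionMILParams.init(dim, hidden=hidden, seed=seed)
    if random_head:
        rng = np.random.default_rng(seed + 50)
        p.W_c = rng.normal(0, 0.5, dim)
        p.b = 0.3
    return p


class TestAttentionPool:
    def test_identical_tiles_uniform_attention(self):
        h = np.ones((5, 8)) * 0.7
        z, a = attention_pool(h, _params())
        np.testing.assert_allclose(a, 0.2)
        np.testing.assert_allclose(z, h[0])

    def test_single_instance(self):
        h = np.random.default_rng(1).normal(size=(1, 8))
        z, a = attention_pool(h, _params())
        np.testing.assert_allclose(a, [1.0])
        np.testing.assert_allclose(z, h[0])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        h = rng.normal(size=(12, 8))
        p = _params()
        z1, a1 = attention_pool(h, p)
        perm = rng.permutation(12)
        z2, a2 = attention_pool(h[perm], p)
        np.testing.assert_allclose(z1, z2, atol=1e-12)
        np.testing.assert_allclose(a1[perm], a2, atol=1e-12)

    def test_empty_bag_raises(self):
        with pytest.raises(ValueError, match="empty bag"):
            attention_pool(np.zeros((0, 8)), _params())

    @given(n=st.integers(1, 30), seed=st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_attention_is_a_distribution(self, n, seed):
        h = np.random.default_rng(seed).normal(size=(n, 8))
        _, a = attention_pool(h, _params(seed=seed % 7))
        assert np.all(a >= 0)
        assert a.sum() == pytest.approx(1.0, abs=1e-9)


class TestPredictBag:
    def test_zero_head_scores_half(self):
        h = np.random.default_rng(3).normal(size=(6, 8))
        p = _params(random_head=False)   # W_c = 0, b = 0
        assert predict_bag(h, p).score == pytest.approx(0.5)

    def test_dimension_mismatch_names_both(self):
        with pytest.raises(ValueError, match="16.*8|8.*16"):
            predict_bag(np.zeros((3, 16)), _params(dim=8))

    def test_instance_duplication_invariance(self):
        rng = np.random.default_rng(4)
        h = rng.normal(size=(7, 8))
        p = _params(seed=5)
        single = predict_bag(h, p)
        doubled = predict_bag(np.vstack([h, h]), p)
        assert doubled.score == pytest.approx(single.score, abs=1e-12)
        np.testing.assert_allclose(doubled.attention[:7] * 2, single.attention,
                                   atol=1e-12)

    def test_score_in_unit_interval(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            h = rng.normal(0, 5, size=(4, 8))
            s = predict_bag(h, _params(seed=int(rng.integers(100)))).score
            assert 0.0 <= s <= 1.0


class TestAUC:
    def test_hand_example(self):
        assert auc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]) == 0.75

    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_half(self):
        assert auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            auc([0.1, 0.2], [1, 1])

    def test_matches_bruteforce_pairwise_oracle(self):
        """Midrank formula equals explicit pair counting, ties counted half."""
        rng = np.random.default_rng(13)
        for _ in range(100):
            n = int(rng.integers(4, 51))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                y[0], y[1] = 0, 1
            s = np.round(rng.random(n), 1)   # coarse grid forces ties
            pos, neg = s[y == 1], s[y == 0]
            brute = np.mean((pos[:, None] > neg[None, :]) +
                            0.5 * (pos[:, None] == neg[None, :]))
            assert auc(s, y) == pytest.approx(brute, abs=1e-12)


class TestStratifiedKFold:
    def test_balanced_counts_per_fold(self):
        labels = np.r_[np.ones(50, int), np.zeros(50, int)]
        splits = stratified_kfold(labels, k=5, seed=1)
        for sp in splits:
            assert sp.test_idx.size == 20
            assert labels[sp.test_idx].sum() == 10

    def test_test_folds_partition_cohort(self):
        labels = np.r_[np.ones(30, int), np.zeros(33, int)]
        splits = stratified_kfold(labels, k=5, seed=2)
        all_test = np.concatenate([sp.test_idx for sp in splits])
        assert np.array_equal(np.sort(all_test), np.arange(63))
        for sp in splits:
            assert not set(sp.train_idx) & set(sp.val_idx)
            assert not set(sp.train_idx) & set(sp.test_idx)
            assert not set(sp.val_idx) & set(sp.test_idx)

    def test_k1_rejected(self):
        with pytest.raises(ValueError, match="k must be"):
            stratified_kfold(np.r_[np.ones(5, int), np.zeros(5, int)], k=1)

    def test_small_class_rejected(self):
        labels = np.r_[np.ones(3, int), np.zeros(40, int)]
        with pytest.raises(ValueError, match="needs >= k"):
            stratified_kfold(labels, k=5)

    def test_same_seed_same_splits(self):
        labels = np.r_[np.ones(20, int), np.zeros(20, int)]
        a = stratified_kfold(labels, k=4, seed=9)
        b = stratified_kfold(labels, k=4, seed=9)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.test_idx, sb.test_idx)
            np.testing.assert_array_equal(sa.val_idx, sb.val_idx)

    def test_patient_groups_never_straddle_test(self):
        labels = np.r_[np.ones(20, int), np.zeros(20, int)]
        groups = np.repeat(np.arange(20), 2)
        splits = stratified_kfold(labels, k=4, seed=3, groups=groups)
        for sp in splits:
            test_groups = set(groups[sp.test_idx])
            rest = np.concatenate([sp.train_idx, sp.val_idx])
            assert not test_groups & set(groups[rest])


@pytest.fixture(scope="module")
def separable():
    return generate_feature_bags(80, bag_size=30, dim=16,
                                 positive_instance_fraction=0.1,
                                 separation=6.0, seed=5)


class TestTraining:
    def test_recovers_planted_signal(self, separable):
        cv = cross_validate(separable.bags, separable.labels, k=4, seed=5)
        assert cv.mean_auc >= 0.9

    def test_positive_bag_scores_above_half(self, separable):
        cv = cross_validate(separable.bags, separable.labels, k=4, seed=5)
        pure_pos = separable.bags[int(np.argmax(separable.labels))].copy()
        pure_pos[:, 0] += 6.0    # every instance carries the signal
        scores = ensemble_predict([pure_pos], cv.params)
        assert scores[0] > 0.5

    def test_determinism(self, separable):
        splits = stratified_kfold(separable.labels, k=4, seed=5)
        p1 = train_fold(separable.bags, separable.labels, splits[0], seed=1)
        p2 = train_fold(separable.bags, separable.labels, splits[0], seed=1)
        np.testing.assert_array_equal(p1.V, p2.V)
        np.testing.assert_array_equal(p1.W_c, p2.W_c)

    def test_single_class_train_split_raises(self, separable):
        splits = stratified_kfold(separable.labels, k=4, seed=5)
        labels = np.zeros_like(separable.labels)
        with pytest.raises(ValueError, match="degenerate split"):
            train_fold(separable.bags, labels, splits[0], seed=0)

    def test_shuffled_labels_no_signal(self, separable):
        """Permutation null: out-of-fold AUC stays near chance."""
        rng = np.random.default_rng(0)
        aucs = []
        for rep in range(3):
            lab = rng.permutation(separable.labels)
            cv = cross_validate(separable.bags, lab, k=4, seed=rep)
            aucs.append(cv.mean_auc)
        assert 0.3 < np.mean(aucs) < 0.7


class TestEnsembleAndSelection:
    def test_ensemble_of_identical_models(self):
        rng = np.random.default_rng(7)
        bag = rng.normal(size=(5, 8))
        p = _params(seed=2)
        single = predict_bag(bag, p).score
        ens = ensemble_predict([bag], [p, p, p, p, p])
        assert ens[0] == pytest.approx(single)

    def test_ensemble_is_arithmetic_mean(self):
        bag = np.random.default_rng(8).normal(size=(5, 8))
        p1, p2 = _params(seed=3), _params(seed=4)
        s1, s2 = predict_bag(bag, p1).score, predict_bag(bag, p2).score
        assert ensemble_predict([bag], [p1, p2])[0] == pytest.approx((s1 + s2) / 2)

    def test_empty_params_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ensemble_predict([np.zeros((2, 8))], [])

    def test_explainability_selection_first_max(self):
        cv = CVResult(fold_aucs=[0.8, 0.9, 0.7, 0.9, 0.6], mean_auc=0.78,
                      sd_auc=0.1, params=[f"m{i}" for i in range(5)],
                      oof_scores=np.zeros(1),
                      train_aucs=[0.8, 0.9, 0.7, 0.9, 0.6], splits=[])
        assert select_explainability_model(cv) == "m1"
        cv.train_aucs = [0.5]
        cv.params = ["only"]
        assert select_explainability_model(cv) == "only"
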