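"""Neighbor classifiers: fused KNN, evidential KNN, and the sklearn adapters."""

import itertools
from collections import Counter

import numpy as np
import pytest

from memdetect.classifiers import (
    EvidentialKNN,
    EvidentialParams,
    FusedEvidentialKNN,
    MajorityVoteKNN,
    bank_layout,
    fit_adapter,
    knn_vote_predict,
    oetknn_fused_predict,
    oetknn_predict,
    train_classifier_bank,
)
from memdetect.synth import SynthConfig, gen_dataset, gen_profiles


def brute_force_fused_knn(train_X, train_y, q, k_max):
    """Exhaustive fused-KNN: enumerate every K, majority with K=1 fallback."""
    d = np.linalg.norm(np.asarray(train_X, dtype=float) - np.asarray(q, dtype=float), axis=1)
    order = np.argsort(d, kind="stable")
    labels = np.asarray(train_y)[order]
    sub = []
    for k in range(1, min(k_max, len(labels)) + 1):
        count = Counter(labels[:k])
        if count[0] == count[1]:
            sub.append(int(labels[0]))
        else:
            sub.append(int(count[1] > count[0]))
    count = Counter(sub)
    label = int(sub[0]) if count[0] == count[1] else int(count[1] > count[0])
    return label, count[1] / len(sub)


def brute_force_dempster(distances, labels, alpha0, gamma_by_class):
    """Enumerate all focal-set products of the neighbor mass functions.

    Each neighbor mass has focal sets ({own class}: alpha) and (frame:
    1-alpha); the combination iterates every selection, intersects, and
    renormalizes away the conflict.
    """
    masses = []
    for d, c in zip(distances, labels):
        alpha = alpha0 * np.exp(-gamma_by_class[int(c)] * d**2)
        masses.append([({int(c)}, alpha), ({0, 1}, 1 - alpha)])
    combined = {frozenset({0}): 0.0, frozenset({1}): 0.0, frozenset({0, 1}): 0.0}
    conflict = 0.0
    for picks in itertools.product(*masses):
        inter = {0, 1}
        weight = 1.0
        for focal, w in picks:
            inter &= focal
            weight *= w
        if inter:
            combined[frozenset(inter)] += weight
        else:
            conflict += weight
    norm = 1.0 - conflict
    m_pos = combined[frozenset({1})] / norm
    m_frame = combined[frozenset({0, 1})] / norm
    return m_pos + m_frame / 2.0  # pignistic probability of the positive class


class TestMajorityVoteKNN:
    def test_unanimous_training_labels(self):
        X = np.arange(6, dtype=float)[:, None]
        label, score = knn_vote_predict(X, np.ones(6, dtype=int), [2.5])
        assert (label, score) == (1, 1.0)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 15))
            X = rng.normal(size=(n, 3))
            y = rng.integers(0, 2, size=n)
            q = rng.normal(size=3)
            got = knn_vote_predict(X, y, q, k_max=10)
            want = brute_force_fused_knn(X, y, q, k_max=10)
            assert got[0] == want[0]
            assert got[1] == pytest.approx(want[1])

    def test_tie_resolves_to_nearest_neighbor_label(self):
        # 1-D layout where K=1..4 sub-votes split 2-2; K=1 label is positive
        X = np.array([[0.0], [1.0], [1.1], [1.2]])
        y = np.array([1, 0, 0, 1])
        clf = MajorityVoteKNN(k_max=4).fit(X, y)
        # sub-votes: K=1 ->1, K=2 ->1 (tie->nearest), K=3 ->0, K=4 ->0 (2-2 tie->1)... enumerate:
        got = brute_force_fused_knn(X, y, [-0.1], 4)
        assert clf.predict([[-0.1]])[0] == got[0]

    def test_empty_training_set_errors(self):
        with pytest.raises(ValueError):
            MajorityVoteKNN().fit(np.empty((0, 2)), np.empty(0))


class TestEvidentialKNN:
    def test_single_training_sample(self):
        label, score = oetknn_predict([[0.0]], [1], [5.0], k=1)
        assert label == 1 and score > 0.5

    def test_two_agreeing_neighbors_reinforce(self):
        label, score = oetknn_predict([[0.0], [1.0]], [0, 0], [0.2], k=2)
        assert label == 0 and score < 0.5

    def test_matches_brute_force_dempster_enumeration(self, rng):
        params = EvidentialParams(alpha0=0.95, gamma={0: 1.0, 1: 1.0})
        for _ in range(200):
            n = int(rng.integers(2, 8))
            k = int(rng.integers(1, min(n, 4) + 1))
            X = rng.normal(size=(n, 2))
            y = rng.integers(0, 2, size=n)
            q = rng.normal(size=2)
            _, score = oetknn_predict(X, y, q, k=k, params=params)
            d = np.linalg.norm(X - q, axis=1)
            order = np.argsort(d, kind="stable")[:k]
            want = brute_force_dempster(d[order], y[order], 0.95, {0: 1.0, 1: 1.0})
            assert score == pytest.approx(want, abs=1e-9)

    def test_specific_three_neighbor_fixture(self):
        # neighbors (d, class) = (1, pos), (1, neg), (2, pos)
        X = np.array([[1.0], [-1.0], [2.0], [50.0]])
        y = np.array([1, 0, 1, 0])
        params = EvidentialParams(alpha0=0.95, gamma={0: 1.0, 1: 1.0})
        label, score = oetknn_predict(X, y, [0.0], k=3, params=params)
        want = brute_force_dempster([1.0, 1.0, 2.0], [1, 0, 1], 0.95, {0: 1.0, 1: 1.0})
        assert score == pytest.approx(want, abs=1e-9)
        assert label == int(want > 0.5)

    def test_vacuous_limit_large_gamma(self, rng):
        # gamma -> inf drives every mass to the vacuous one (all weight on
        # the frame): pignistic probabilities approach 0.5 and the decision
        # falls back to the nearest neighbor's label
        X = rng.normal(size=(8, 2))
        y = np.array([0, 1] * 4)
        huge = EvidentialParams(alpha0=0.95, gamma={0: 1e9, 1: 1e9})
        for _ in range(10):
            q = rng.normal(size=2)
            label, score = oetknn_predict(X, y, q, k=5, params=huge)
            assert score == pytest.approx(0.5, abs=1e-6)
            nn = int(np.argmin(np.linalg.norm(X - q, axis=1)))
            assert label == y[nn]

    def test_k_bounds_error(self):
        with pytest.raises(ValueError):
            oetknn_predict([[0.0]], [1], [1.0], k=2)
        with pytest.raises(ValueError):
            oetknn_predict([[0.0]], [1], [1.0], k=0)

    def test_permutation_invariance(self, rng):
        X = rng.normal(size=(12, 3))
        y = rng.integers(0, 2, size=12)
        q = rng.normal(size=(4, 3))
        base = EvidentialKNN(n_neighbors=4, gamma={0: 0.7, 1: 1.3}).fit(X, y)
        perm = rng.permutation(12)
        shuffled = EvidentialKNN(n_neighbors=4, gamma={0: 0.7, 1: 1.3}).fit(X[perm], y[perm])
        np.testing.assert_allclose(base.predict_score(q), shuffled.predict_score(q))


class TestFusedEvidentialKNN:
    def test_equals_majority_of_individual_calls(self, rng):
        X = rng.normal(size=(15, 3))
        y = rng.integers(0, 2, size=15)
        params = EvidentialParams(gamma={0: 1.0, 1: 1.0})
        for _ in range(10):
            q = rng.normal(size=3)
            sub = [oetknn_predict(X, y, q, k=k, params=params)[0] for k in range(1, 11)]
            label, score = oetknn_fused_predict(X, y, q, params=params)
            pos = sum(sub)
            assert score == pytest.approx(pos / 10)
            assert label == (sub[0] if pos == 5 else int(pos > 5))

    def test_unanimous_sub_votes(self):
        X = np.linspace(0, 1, 8)[:, None]
        label, _ = oetknn_fused_predict(X, np.ones(8, dtype=int), [0.5])
        assert label == 1


class TestAdapters:
    def test_single_class_training_errors(self):
        with pytest.raises(ValueError):
            fit_adapter("SVM", np.random.rand(6, 2), np.ones(6, dtype=int))

    @pytest.mark.parametrize("algorithm", ["SVM", "GBM", "RF"])
    def test_separable_data_fits_perfectly(self, algorithm, rng):
        X = np.vstack([rng.normal(-3, 0.3, size=(15, 2)), rng.normal(3, 0.3, size=(15, 2))])
        y = np.array([0] * 15 + [1] * 15)
        clf = fit_adapter(algorithm, X, y)
        assert (clf.predict(X) == y).all()
        scores = clf.predict_score(X)
        assert scores.shape == (30,) and ((0 <= scores) & (scores <= 1)).all()

    def test_grid_of_one_point_is_selected(self, rng):
        X = rng.normal(size=(20, 2))
        y = (X[:, 0] > 0).astype(int)
        clf = fit_adapter("SVM", X, y, hyper_grid={"C": [2.0], "gamma": [0.5]})
        assert clf.model.C == 2.0 and clf.model.gamma == 0.5

    def test_rbf_svm_separates_xor(self, rng):
        base = rng.integers(0, 2, size=(80, 2))
        X = base + rng.normal(0, 0.1, size=(80, 2))
        y = base[:, 0] ^ base[:, 1]
        clf = fit_adapter("SVM", X, y, hyper_grid={"C": [1.0, 10.0], "gamma": [1.0, 10.0]})
        assert (clf.predict(X) == y).mean() > 0.9


class TestBank:
    def test_layout_cardinalities(self):
        assert len(bank_layout("OETKNN", range(50), per_k=False)) == 50
        assert len(bank_layout("OETKNN", range(50), per_k=True)) == 500
        with pytest.raises(ValueError):
            bank_layout("SVM", range(50), per_k=True)

    def test_trained_bank_sizes_and_index(self, small_dataset):
        bank = train_classifier_bank(small_dataset, "OETKNN", lambdas=range(3), per_k=False)
        assert bank.size == 3
        bank = train_classifier_bank(small_dataset, "OETKNN", lambdas=range(3), per_k=True)
        assert bank.size == 30
        assert bank.index()[:3] == [(0, 1), (0, 2), (0, 3)]

    def test_lambda_exceeding_shortest_sequence_names_record(self):
        cfg = SynthConfig(n_per_class=3, length_range=(50, 60), seed=3)
        ds = gen_dataset(cfg)
        ds.profiles = gen_profiles(ds, cfg)
        with pytest.raises(ValueError, match="lambda=55"):
            train_classifier_bank(ds, "OETKNN", lambdas=[0, 55])

    def test_empty_dataset_errors(self):
        from memdetect.seqio import LabeledDataset

        with pytest.raises(ValueError):
            train_classifier_bank(LabeledDataset([], {}), "OETKNN", lambdas=[0])
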