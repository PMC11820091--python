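import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gutmet.chem import Fingerprint, tanimoto
from gutmet.encoders import cosine_similarity
from gutmet.models import (
    auc_score,
    bac_from_rates,
    compute_metrics,
    enzyme_count_sweep,
    f1_from,
    knn_classify,
    knn_rank_neighbors,
    kpca_reduce,
    stratified_folds,
    train_rf_cv,
)


def brute_force_auc(y_true, y_score):
    """Concordant-pair count over positive x negative pairs, half credit for ties."""
    pos = [s for s, t in zip(y_score, y_true) if t == 1]
    neg = [s for s, t in zip(y_score, y_true) if t == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestMetrics:
    def test_bac_identity_from_printed_rates(self):
        # Sensitivity 0.775, false-positive rate 0.200 -> BAC 0.7875
        assert bac_from_rates(0.775, 0.200) == pytest.approx(0.7875)
        assert round(bac_from_rates(0.775, 0.200), 3) == 0.788

    def test_f1_harmonic_mean(self):
        assert f1_from(0.799, 0.775) == pytest.approx(0.787, abs=5e-4)

    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        s = np.array([0.1, 0.2, 0.8, 0.9])
        m = compute_metrics(y, s)
        assert m.auc == 1.0 and m.mcc == 1.0 and m.bac == 1.0

    def test_threshold_tie_classifies_negative(self):
        m = compute_metrics(np.array([1, 0, 1]), np.array([0.5, 0.1, 0.9]))
        assert m.tpr == 0.5  # the score-0.5 positive counted as a miss

    def test_internal_bac_identity(self, rng):
        """bac == (tpr + 1 - fpr)/2 on arbitrary scored data."""
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        s = rng.random(50)
        m = compute_metrics(y, s)
        assert m.bac == pytest.approx(bac_from_rates(m.tpr, m.fpr))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.ones(4, dtype=int), np.linspace(0, 1, 4))

    @given(st.integers(0, 10_000))
    def test_auc_equals_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 31))
        y = rng.integers(0, 2, n)
        y[:2] = [0, 1]
        s = np.round(rng.random(n), 1)  # coarse grid to force ties
        assert auc_score(y, s) == pytest.approx(brute_force_auc(y, s))


class TestStratifiedFolds:
    def test_balanced_classes_split_evenly(self):
        y = np.array([0] * 100 + [1] * 100)
        folds = stratified_folds(y, 5, seed=0)
        for f in range(5):
            assert (y[folds == f] == 1).sum() == 20
            assert (y[folds == f] == 0).sum() == 20

    def test_pigeonhole_on_uneven_classes(self):
        y = np.array([1] * 7 + [0] * 13)
        folds = stratified_folds(y, 5, seed=1)
        per_fold_pos = [(y[folds == f] == 1).sum() for f in range(5)]
        assert set(per_fold_pos) <= {1, 2}

    def test_seed_reproducibility(self):
        y = np.array([0, 1] * 20)
        np.testing.assert_array_equal(
            stratified_folds(y, 4, seed=9), stratified_folds(y, 4, seed=9)
        )

    def test_too_small_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_folds(np.array([1, 0, 0, 0, 0, 0]), 5)


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(3)
    X = np.vstack([rng.normal(0, 1, (60, 8)), rng.normal(2.5, 1, (60, 8))])
    y = np.array([0] * 60 + [1] * 60)
    return X, y


class TestTrainRFCV:
    def test_learns_separable_data(self, separable):
        X, y = separable
        result = train_rf_cv(X, y, n_trees=50, seed=0)
        assert result.median_bac >= 0.9
        assert len(result.per_fold) == 5

    def test_identical_seed_identical_result(self, separable):
        X, y = separable
        a = train_rf_cv(X, y, n_trees=25, seed=4)
        b = train_rf_cv(X, y, n_trees=25, seed=4)
        assert [m.bac for m in a.per_fold] == [m.bac for m in b.per_fold]
        np.testing.assert_array_equal(a.fold_assignment, b.fold_assignment)

    def test_fold_assignment_partitions_instances(self, separable):
        X, y = separable
        result = train_rf_cv(X, y, n_trees=25, seed=0)
        assert sorted(np.unique(result.fold_assignment)) == [0, 1, 2, 3, 4]
        assert result.fold_assignment.size == y.size


class TestEnzymeCountSweep:
    def test_rows_and_fold_reuse(self):
        rng = np.random.default_rng(5)
        base = np.vstack([rng.normal(0, 1, (40, 6)), rng.normal(2, 1, (40, 6))])
        y = np.array([0] * 40 + [1] * 40)

        def builder(k):
            return base[:, : min(k, 6)]

        sweep = enzyme_count_sweep(builder, y, counts=(1, 2, 3), n_trees=25, seed=0)
        assert [row[0] for row in sweep.rows] == [1, 2, 3]
        assert all(len(row[1]) == 5 for row in sweep.rows)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            enzyme_count_sweep(lambda k: np.zeros((4, 1)), np.array([0, 0, 1, 1]), counts=())


class TestKPCA:
    def test_linear_kernel_matches_pca_distances(self, rng):
        """Full-rank linear KPCA preserves the pairwise distances of centered
        PCA projections on a 50x20 toy."""
        from sklearn.decomposition import PCA
        from scipy.spatial.distance import pdist

        X = rng.normal(size=(50, 20))
        Z, _ = kpca_reduce(X, X[:0], "linear", n_components=20)
        P = PCA(n_components=20).fit_transform(X)
        np.testing.assert_allclose(pdist(Z), pdist(P), atol=1e-6)

    def test_component_cap_enforced(self, rng):
        X = rng.normal(size=(10, 5))
        with pytest.raises(ValueError, match="exceeds"):
            kpca_reduce(X, X, "rbf", n_components=6)

    def test_deterministic_with_fixed_sign_convention(self, rng):
        X = rng.normal(size=(30, 8))
        Z1, _ = kpca_reduce(X, X[:0], "rbf", n_components=4)
        Z2, _ = kpca_reduce(X, X[:0], "rbf", n_components=4)
        np.testing.assert_array_equal(Z1, Z2)

    def test_apply_set_projected_with_train_map(self, rng):
        X_train = rng.normal(size=(30, 8))
        X_test = rng.normal(size=(10, 8))
        Z_train, Z_test = kpca_reduce(X_train, X_test, "cosine", n_components=3)
        assert Z_train.shape == (30, 3) and Z_test.shape == (10, 3)

    def test_unknown_kernel_rejected(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.raises(ValueError):
            kpca_reduce(X, X, "laplacian", 2)

    def test_reduced_model_close_to_full_on_planted_signal(self, rng):
        """Kernel-PCA reduction costs at most a modest accuracy margin on
        well-separated data: best reduced median BAC <= full + 0.05."""
        from gutmet.models import kpca_sweep

        X = np.vstack([rng.normal(0, 1, (50, 30)), rng.normal(1.5, 1, (50, 30))])
        y = np.array([0] * 50 + [1] * 50)
        full = train_rf_cv(X, y, n_trees=50, seed=0).median_bac
        sweep = kpca_sweep(
            X, y, kernels=("linear", "rbf"), component_grid=(8, 16),
            n_trees=50, seed=0,
        )
        _, _, best = sweep.best()
        assert best <= full + 0.05


class TestKNN:
    def _toy(self):
        fps = [
            Fingerprint(frozenset({0, 1, 2})),
            Fingerprint(frozenset({0, 1, 2})),
            Fingerprint(frozenset({5, 6})),
            Fingerprint(frozenset({0, 2, 7})),
            Fingerprint(frozenset({9})),
        ]
        enz = np.array(
            [[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.8, 0.2], [0.1, 0.9]]
        )
        return fps, enz

    def test_duplicate_training_instance_ranks_first(self):
        fps, enz = self._toy()
        ranked = knn_rank_neighbors(fps[0], enz[0], fps[1:], enz[1:])
        assert ranked[0] == (0.0, 0)  # index 0 of the training list = the duplicate

    def test_ranking_matches_exhaustive_sort_oracle(self):
        fps, enz = self._toy()
        query_fp, query_enz = fps[0], enz[0]
        ranked = knn_rank_neighbors(query_fp, query_enz, fps[1:], enz[1:])
        oracle = sorted(
            (
                float(
                    np.hypot(
                        1 - tanimoto(query_fp, fps[1 + i]),
                        1 - cosine_similarity(query_enz, enz[1 + i]),
                    )
                ),
                i,
            )
            for i in range(4)
        )
        assert ranked == oracle

    def test_odd_k_has_no_vote_ties(self):
        rng = np.random.default_rng(2)
        fps = [Fingerprint(frozenset(rng.choice(64, 8, replace=False))) for _ in range(30)]
        enz = rng.normal(size=(30, 4))
        y = np.array([0, 1] * 15)
        result = knn_classify(fps, enz, y, k_neighbors=3, n_folds=5, seed=0)
        for m in result.per_fold:
            assert m.tpr in (0.0, 1 / 3, 2 / 3, 1.0)

    def test_k_not_smaller_than_train_rejected(self):
        fps, enz = self._toy()
        y = np.array([0, 1, 0, 1, 0])
        with pytest.raises(ValueError, match="smaller than the training split"):
            knn_classify(
                fps, enz, y, k_neighbors=4, seed=0,
                fold_assignment=np.array([0, 1, 1, 1, 1]),
            )
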