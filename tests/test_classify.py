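"""Welch-t ranking, classifiers, cross-validation and metrics."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.preprocessing import StandardScaler

from echocad.classify import (
    CLASSIFIER_NAMES,
    ParzenWindowClassifier,
    cross_validate,
    incremental_selection,
    make_classifier,
    metrics_from_confusion,
    rank_features,
    train_predict,
    welch_t,
)


class TestWelchT:
    def test_equal_means_give_zero_t_unit_p(self):
        t, p = welch_t(1.0, 0.5, 10, 1.0, 0.3, 12)
        assert t == 0.0 and p == 1.0

    @pytest.mark.parametrize(
        "moments, expected",
        [
            ((0.0228, 0.0771, 51, -0.0091, 0.0425, 61), 2.6400),
            ((-0.0363, 0.0388, 51, 0.0457, 0.0467, 61), 10.1429),
            ((0.0210, 0.0311, 51, -0.0049, 0.0740, 61), 2.4877),
        ],
    )
    def test_reported_group_moments_reproduce_t(self, moments, expected):
        # inputs rounded to 4 decimals bound the achievable agreement
        t, _ = welch_t(*moments)
        assert t == pytest.approx(expected, abs=0.05)

    def test_degenerate_variances_rejected(self):
        with pytest.raises(ValueError):
            welch_t(0.0, 0.0, 10, 1.0, 0.0, 10)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        st.integers(0, 2**32 - 1),
        st.floats(-5, 5),
        st.floats(0.1, 10),
    )
    def test_t_invariant_under_shared_shift_and_positive_scale(self, seed, shift, scale):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 20)
        b = rng.normal(1, 2, 25)
        t1, _ = welch_t(a.mean(), a.std(ddof=1), 20, b.mean(), b.std(ddof=1), 25)
        a2, b2 = a * scale + shift, b * scale + shift
        t2, _ = welch_t(a2.mean(), a2.std(ddof=1), 20, b2.mean(), b2.std(ddof=1), 25)
        assert t1 == pytest.approx(t2, rel=1e-9)


class TestRankFeatures:
    def test_identical_feature_ranked_last_with_zero_t(self, rng):
        X = rng.normal(0, 1, (40, 3))
        X[:, 1] = 0.7  # identical across classes
        X[20:, 0] += 3.0
        y = np.array([0] * 20 + [1] * 20)
        ranked = rank_features(X, y)
        assert ranked.order[-1] == 1
        assert ranked.stats[-1].t == 0.0

    def test_order_follows_class_mean_gap(self, rng):
        n = 2000
        gaps = [3.0, 1.0, 2.0]
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        X = rng.normal(0, 1, (n, 3))
        for j, g in enumerate(gaps):
            X[y == 1, j] += g
        assert rank_features(X, y).order.tolist() == [0, 2, 1]

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            rank_features(rng.random((10, 2)), np.zeros(10))


def _xor_data(rng, n, sigma=0.3):
    corners = np.array([[-1, -1], [1, -1], [-1, 1], [1, 1]], dtype=float)
    labels = np.array([0, 1, 1, 0])
    idx = np.tile(np.arange(4), n // 4)
    return corners[idx] + rng.normal(0, sigma, (idx.size, 2)), labels[idx]


class TestTrainPredict:
    def test_one_nearest_neighbour_memorizes_training_set(self, rng):
        X, y = _xor_data(rng, 200)
        pred = train_predict("kNN", X, y, X, n_neighbors=1)
        assert (pred == y).mean() == 1.0

    def test_linear_svm_separates_linearly_separable_clusters(self, rng):
        Xtr = np.vstack([rng.normal(0, 0.3, (40, 2)), rng.normal(5, 0.3, (40, 2))])
        ytr = np.array([0] * 40 + [1] * 40)
        Xte = np.vstack([rng.normal(0, 0.3, (20, 2)), rng.normal(5, 0.3, (20, 2))])
        yte = np.array([0] * 20 + [1] * 20)
        pred = train_predict("svmPoly_1", Xtr, ytr, Xte)
        assert (pred == yte).mean() == 1.0

    def test_quadratic_kernel_solves_xor_linear_kernel_does_not(self, rng):
        # best linear rule on a 4-corner XOR is the corner cut at 75%
        Xtr, ytr = _xor_data(rng, 400)
        Xte, yte = _xor_data(rng, 200)
        scaler = StandardScaler().fit(Xtr)
        Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
        acc1 = (train_predict("svmPoly_1", Xtr, ytr, Xte) == yte).mean()
        acc2 = (train_predict("svmPoly_2", Xtr, ytr, Xte) == yte).mean()
        assert acc1 <= 0.80
        assert acc2 >= 0.95
        assert acc2 - acc1 >= 0.15

    def test_unknown_spec_rejected(self, rng):
        with pytest.raises(ValueError):
            make_classifier("superNet")

    def test_parzen_window_recovers_gaussian_classes(self, rng):
        Xtr = np.vstack([rng.normal(0, 1, (50, 3)), rng.normal(4, 1, (50, 3))])
        ytr = np.array([0] * 50 + [1] * 50)
        clf = ParzenWindowClassifier(sigma=0.5).fit(Xtr, ytr)
        assert (clf.predict(Xtr) == ytr).mean() > 0.95


class TestMetrics:
    def test_perfect_classifier_at_study_class_sizes(self):
        assert metrics_from_confusion(61, 0, 51, 0) == (100.0, 100.0, 100.0, 100.0)

    def test_single_error_on_112_gives_9911(self):
        acc, ppv, sens, spec = metrics_from_confusion(60, 0, 51, 1)
        assert acc == pytest.approx(100 * 111 / 112)
        assert round(acc, 2) == 99.11
        assert spec == 100.0

    def test_degenerate_counts_warn_with_nan_ppv(self):
        with pytest.warns(UserWarning, match="PPV"):
            acc, ppv, sens, spec = metrics_from_confusion(0, 0, 51, 61)
        assert sens == 0.0 and np.isnan(ppv)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(0, 0, 0, 0)


@pytest.fixture(scope="module")
def separable_data():
    rng = np.random.default_rng(5)
    X = np.vstack([rng.normal(0, 1, (51, 5)), rng.normal(8, 1, (61, 5))])
    y = np.array(["normal"] * 51 + ["htn"] * 61)
    return X, y


class TestCrossValidate:
    def test_fold_sizes_partition_and_balance(self, separable_data):
        from sklearn.model_selection import StratifiedKFold

        X, y = separable_data
        sizes, pos = [], []
        for _, te in StratifiedKFold(10, shuffle=True, random_state=17).split(X, y):
            sizes.append(len(te))
            pos.append((y[te] == "htn").sum())
        assert sum(sizes) == 112
        assert max(pos) - min(pos) <= 1

    @pytest.mark.parametrize("clf", CLASSIFIER_NAMES)
    def test_every_classifier_perfect_on_separable_clusters(self, separable_data, clf):
        X, y = separable_data
        report = cross_validate(X, y, clf, n_folds=10, seed=17)
        assert report.accuracy == 100.0
        assert report.n == 112

    def test_seed_reproducibility_and_seed_independence_when_separable(
        self, separable_data
    ):
        X, y = separable_data
        a = cross_validate(X, y, "DT", seed=3)
        b = cross_validate(X, y, "DT", seed=3)
        c = cross_validate(X, y, "DT", seed=4)
        assert vars(a) == vars(b)
        assert c.accuracy == 100.0

    def test_permuted_labels_score_at_chance(self):
        rng = np.random.default_rng(11)
        X = rng.normal(0, 1, (112, 5))
        y = np.array(["normal"] * 51 + ["htn"] * 61)
        accs = [
            cross_validate(X, np.random.default_rng(s).permutation(y), "DT", seed=s).accuracy
            for s in range(20)
        ]
        assert 35.0 <= np.mean(accs) <= 65.0

    def test_pooled_accuracy_equals_weighted_fold_mean(self, separable_data, rng):
        X, y = separable_data
        X = X + rng.normal(0, 4, X.shape)  # imperfect classes
        report = cross_validate(X, y, "DT", n_folds=10, seed=2)
        fold_sizes = [12, 12, 11, 11, 11, 11, 11, 11, 11, 11]
        weighted = 100 * np.average(report.fold_accuracies, weights=fold_sizes)
        assert report.accuracy == pytest.approx(weighted)

    def test_class_smaller_than_fold_count_rejected(self, rng):
        X = rng.random((12, 3))
        y = np.array([0] * 3 + [1] * 9)
        with pytest.raises(ValueError, match="fold"):
            cross_validate(X, y, "DT", n_folds=10)


class TestIncrementalSelection:
    def test_perfectly_separating_first_feature_needs_one(self, rng):
        X = rng.normal(0, 1, (60, 4))
        y = np.array([0] * 30 + [1] * 30)
        X[y == 1, 0] += 20.0
        best_k, reports = incremental_selection(X, y, "DT", max_features=4)
        assert best_k == 1
        assert len(reports) == 4
        assert all(0 <= r.accuracy <= 100 for r in reports)

    def test_ring_versus_core_needs_both_plane_features(self, rng):
        # classes separate only in the (f1, f2) plane; f3 is noise
        n = 60
        theta = rng.uniform(0, 2 * np.pi, n)
        ring = np.column_stack([2 * np.cos(theta), 2 * np.sin(theta)])
        core = rng.normal(0, 0.4, (n, 2))
        X = np.vstack([ring, core])
        X = np.column_stack([X, rng.normal(0, 1, 2 * n)])
        y = np.array([0] * n + [1] * n)
        best_k, _ = incremental_selection(X, y, "DT", max_features=3, seed=1)
        assert best_k == 2
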