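"""Feature selection: standardization contracts, NCA weight learning, ranking,
the iterative subset sweep, index transfer, and the no-leakage property."""

import numpy as np
import pytest

from exemplarnet.errors import ConfigurationError, DataError, InputError
from exemplarnet.inca import (
    KNNOracleConfig,
    NCAConfig,
    apply_selection,
    iterative_selection,
    load_selection,
    nca_objective,
    nca_weights,
    rank_features,
    save_selection,
    standardize_apply,
    standardize_fit,
)


class TestStandardize:
    def test_train_columns_centered_and_scaled(self, rng):
        X = rng.normal(3.0, 2.5, size=(50, 4))
        Z = standardize_apply(X, standardize_fit(X))
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-12)

    def test_constant_column_maps_to_zero(self, rng):
        X = np.column_stack([np.full(20, 7.0), rng.normal(size=20)])
        Z = standardize_apply(X, standardize_fit(X))
        np.testing.assert_array_equal(Z[:, 0], 0.0)

    def test_test_rows_use_train_statistics(self, rng):
        train = rng.normal(0.0, 1.0, size=(100, 3))
        test = rng.normal(5.0, 1.0, size=(40, 3))
        stats = standardize_fit(train)
        Z = standardize_apply(test, stats)
        # shifted test data stays shifted: its own mean is NOT removed
        assert np.all(Z.mean(axis=0) > 3.0)


def toy_two_feature_problem(seed):
    """Feature 0 separates the classes cleanly; feature 1 is pure noise."""
    rng = np.random.default_rng(seed)
    n = 40
    y = np.repeat([0, 1], n // 2)
    x0 = np.where(y == 0, -1.0, 1.0) + 0.1 * rng.normal(size=n)
    x1 = rng.normal(size=n)
    return np.column_stack([x0, x1]), y


class TestNCAWeights:
    @pytest.mark.parametrize("seed", range(5))
    def test_informative_feature_outweighs_noise(self, seed):
        X, y = toy_two_feature_problem(seed)
        w = nca_weights(X, y, NCAConfig(seed=seed)).w
        assert w[0] ** 2 > w[1] ** 2

    def test_objective_improves_over_initialization(self, rng):
        """Brute-force objective check on a small problem."""
        X = np.vstack([rng.normal(-1, 0.5, size=(10, 3)),
                       rng.normal(+1, 0.5, size=(10, 3))])
        y = np.repeat([0, 1], 10)
        lam = 1.0 / 20
        result = nca_weights(X, y, NCAConfig(seed=2, regularization=lam))
        assert (nca_objective(X, y, result.w, lam)
                >= nca_objective(X, y, np.ones(3), lam))

    def test_single_class_rejected(self, rng):
        with pytest.raises(DataError):
            nca_weights(rng.normal(size=(10, 2)), np.zeros(10), NCAConfig())

    def test_single_feature_ranking_trivial(self, rng):
        X = rng.normal(size=(12, 1))
        y = np.repeat([0, 1], 6)
        w = nca_weights(X, y, NCAConfig(seed=0))
        np.testing.assert_array_equal(rank_features(w), [0])


class TestRankFeatures:
    def test_hand_example(self):
        assert list(rank_features(np.array([0.1, 0.9, 0.5]))) == [1, 2, 0]

    def test_all_equal_weights_keep_original_order(self):
        assert list(rank_features(np.ones(5))) == [0, 1, 2, 3, 4]

    def test_matches_full_sort_oracle(self, rng):
        w = rng.normal(size=200)
        order = rank_features(w)
        oracle = sorted(range(200), key=lambda i: (-(w[i] ** 2), i))
        assert list(order) == oracle

    def test_non_finite_weights_rejected(self):
        with pytest.raises(InputError):
            rank_features(np.array([1.0, np.nan]))


def separable_fixture(rng, n=60, d=30, informative=6):
    y = np.repeat([0, 1, 2], n // 3)
    X = rng.normal(size=(n, d))
    X[:, :informative] += 2.0 * (y - 1)[:, None]
    return X, y


class TestIterativeSelection:
    def test_candidate_count_matches_range(self, rng):
        X, y = separable_fixture(rng)
        res = iterative_selection(X, y, np.arange(30), iv=5, fv=25,
                                  oracle_config=KNNOracleConfig(seed=0))
        assert len(res.mcv) == 25 - 5 + 1
        assert res.iv == 5 and res.fv == 25

    def test_single_candidate_range(self, rng):
        X, y = separable_fixture(rng)
        ranking = np.arange(30)
        res = iterative_selection(X, y, ranking, iv=7, fv=7)
        assert res.best_size == 7
        np.testing.assert_array_equal(res.selected, ranking[:7])

    def test_minimum_matches_exhaustive_rescan(self, rng):
        """Oracle: re-evaluating every subset from scratch reproduces the curve
        and its (first) minimum."""
        from exemplarnet.inca import _cv_knn_error_from_dist, _encode_labels
        from exemplarnet.shallow import stratified_folds
        from scipy.spatial.distance import squareform, pdist
        X, y = separable_fixture(rng)
        ranking = rank_features(nca_weights(X, y, NCAConfig(seed=1, iterations=5)))
        res = iterative_selection(X, y, ranking, iv=3, fv=20,
                                  oracle_config=KNNOracleConfig(seed=4))
        plan = stratified_folds(y, n_folds=10, seed=4)
        enc = _encode_labels(y)
        rescan = []
        for a in range(3, 21):
            D = squareform(pdist(X[:, ranking[:a]], metric="cityblock"))
            rescan.append(_cv_knn_error_from_dist(D, enc, plan.assignments, k=1))
        np.testing.assert_allclose(res.mcv, rescan, atol=1e-12)
        assert res.mcv[res.best_size - res.iv] == min(rescan)
        first_min = 3 + int(np.argmin(rescan))
        assert res.best_size == first_min

    def test_subsets_are_nested_ranking_prefixes(self, rng):
        X, y = separable_fixture(rng)
        ranking = np.arange(30)[::-1].copy()
        res = iterative_selection(X, y, ranking, iv=4, fv=12)
        np.testing.assert_array_equal(res.selected, ranking[: res.best_size])

    def test_invalid_ranges_rejected(self, rng):
        X, y = separable_fixture(rng)
        with pytest.raises(ConfigurationError):
            iterative_selection(X, y, np.arange(30), iv=10, fv=40)
        with pytest.raises(ConfigurationError):
            iterative_selection(X, y, np.arange(30), iv=12, fv=10)
        with pytest.raises(ConfigurationError):
            iterative_selection(X, y, np.arange(30), iv=0, fv=10)

    def test_seed_determinism(self, rng):
        X, y = separable_fixture(rng)
        ranking = rank_features(nca_weights(X, y, NCAConfig(seed=3, iterations=5)))
        a = iterative_selection(X, y, ranking, iv=3, fv=15,
                                oracle_config=KNNOracleConfig(seed=8))
        b = iterative_selection(X, y, ranking, iv=3, fv=15,
                                oracle_config=KNNOracleConfig(seed=8))
        np.testing.assert_array_equal(a.selected, b.selected)
        np.testing.assert_array_equal(a.mcv, b.mcv)


class TestApplySelection:
    def test_identity_when_all_columns_selected(self, rng):
        X = rng.normal(size=(5, 7))
        np.testing.assert_array_equal(apply_selection(X, np.arange(7)), X)

    def test_zero_row_matrix(self):
        out = apply_selection(np.empty((0, 9)), np.array([1, 3]))
        assert out.shape == (0, 2)

    def test_transfer_to_test_matrix(self, rng):
        sel = np.array([4, 1, 6])
        out = apply_selection(rng.normal(size=(11, 8)), sel)
        assert out.shape == (11, 3)

    def test_out_of_range_rejected(self, rng):
        with pytest.raises(InputError):
            apply_selection(rng.normal(size=(3, 4)), np.array([4]))


class TestNoLeakage:
    def test_selection_path_ignores_test_rows(self, rng):
        """The full selection pipeline consumes only training rows: swapping
        the test matrix for all-NaN garbage changes nothing."""
        X_train, y_train = separable_fixture(rng, n=45, d=20, informative=5)
        stats = standardize_fit(X_train)
        Z = standardize_apply(X_train, stats)
        w = nca_weights(Z, y_train, NCAConfig(seed=6, iterations=10))
        res = iterative_selection(Z, y_train, rank_features(w), iv=3, fv=15,
                                  oracle_config=KNNOracleConfig(seed=2))
        X_test_nan = np.full((9, 20), np.nan)
        reduced = apply_selection(standardize_apply(X_test_nan, stats), res.selected)
        assert reduced.shape == (9, res.best_size)
        # rerun with a different "test set": identical selection
        w2 = nca_weights(Z, y_train, NCAConfig(seed=6, iterations=10))
        res2 = iterative_selection(Z, y_train, rank_features(w2), iv=3, fv=15,
                                   oracle_config=KNNOracleConfig(seed=2))
        np.testing.assert_array_equal(res.selected, res2.selected)


class TestSelectionArtifact:
    def test_round_trip_one_based(self, rng, tmp_path):
        X, y = separable_fixture(rng)
        res = iterative_selection(X, y, np.arange(30), iv=4, fv=12)
        path = tmp_path / "selection.txt"
        save_selection(res, path)
        text = path.read_text()
        assert str(int(res.selected[0]) + 1) in text.splitlines()
        back = load_selection(path)
        np.testing.assert_array_equal(back["selected"], res.selected)
        np.testing.assert_allclose(back["mcv"], res.mcv)
        assert back["iv"] == 4 and back["fv"] == 12
        assert back["best_size"] == res.best_size
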