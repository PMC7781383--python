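"""Sparse PLS-DA core: soft thresholding, NIPALS fit, projection, filtering."""

import numpy as np
import pandas as pd
import pytest

from aptamarkers import SparsePLSDA, soft_threshold_keep


def brute_force_soft_threshold(v, keep):
    """Enumerate candidate thresholds; pick the one leaving `keep` nonzeros."""
    v = np.asarray(v, dtype=float)
    candidates = sorted(np.abs(v).tolist() + [0.0])
    for lam in candidates:
        w = np.sign(v) * np.maximum(np.abs(v) - lam, 0.0)
        if np.count_nonzero(w) == keep:
            return w / np.linalg.norm(w)
    return None


def standardized(X):
    return (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)


def make_problem(rng, n=20, p=8):
    y = np.array(["neg", "pos"])[rng.integers(0, 2, size=n)]
    while np.unique(y).size < 2:
        y = np.array(["neg", "pos"])[rng.integers(0, 2, size=n)]
    X = standardized(rng.normal(size=(n, p)))
    return X, y


class TestSoftThreshold:
    def test_documented_example(self):
        w = soft_threshold_keep(np.array([0.9, 0.5, 0.1]), keep=2)
        expected = np.array([0.8, 0.4, 0.0])
        np.testing.assert_allclose(w, expected / np.linalg.norm(expected))

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            v = rng.normal(size=rng.integers(2, 12))
            keep = int(rng.integers(1, v.size + 1))
            w = soft_threshold_keep(v, keep)
            brute = brute_force_soft_threshold(v, keep)
            if brute is not None:  # distinct |v|: unique answer
                np.testing.assert_allclose(w, brute, atol=1e-12)
            assert np.count_nonzero(w) <= keep
            assert np.linalg.norm(w) == pytest.approx(1.0)

    def test_keep_all_preserves_direction(self):
        v = np.array([3.0, -1.0, 2.0])
        np.testing.assert_allclose(
            soft_threshold_keep(v, 3), v / np.linalg.norm(v)
        )

    def test_full_tie_falls_back_to_first_indices(self):
        w = soft_threshold_keep(np.array([1.0, 1.0, 1.0]), keep=2)
        assert np.count_nonzero(w) == 2
        assert w[2] == 0.0

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            soft_threshold_keep(np.zeros(3), 1)


class TestFit:
    def test_single_indicator_column(self):
        y = np.array(["neg"] * 5 + ["pos"] * 5)
        x = np.where(y == "pos", 1.0, -1.0)
        X = standardized(x[:, None])
        m = SparsePLSDA(keep_x=1).fit(X, y)
        np.testing.assert_allclose(np.abs(m.x_loadings_[:, 0]), [1.0])
        scores = m.scores_[:, 0]
        assert scores[y == "pos"].min() > scores[y == "neg"].max()

    def test_dense_fit_matches_svd_oracle(self):
        """keepX=p weight equals the leading right singular vector of Y'X."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            X, y = make_problem(rng)
            m = SparsePLSDA(keep_x=X.shape[1]).fit(X, y)
            yc = np.where(y == "pos", 1.0, -1.0)
            yc = yc - yc.mean()
            _, _, vt = np.linalg.svd(yc[None, :] @ X, full_matrices=False)
            cos = abs(float(m.x_loadings_[:, 0] @ vt[0]))
            assert cos > 1 - 1e-8

    def test_dense_fit_matches_sklearn_pls_direction(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(77)
        X, y = make_problem(rng, n=30, p=6)
        m = SparsePLSDA(keep_x=6).fit(X, y)
        yc = (y == "pos").astype(float)
        ref = PLSRegression(n_components=1, scale=False).fit(X, yc)
        w_ref = ref.x_weights_[:, 0] / np.linalg.norm(ref.x_weights_[:, 0])
        cos = abs(float(m.x_loadings_[:, 0] @ w_ref))
        assert cos > 1 - 1e-8

    def test_keepx_one_single_nonzero(self):
        rng = np.random.default_rng(2)
        X, y = make_problem(rng)
        m = SparsePLSDA(keep_x=1).fit(X, y)
        assert np.count_nonzero(m.x_loadings_[:, 0]) == 1

    def test_unit_norm_and_sparsity_invariants(self):
        rng = np.random.default_rng(3)
        X, y = make_problem(rng, n=25, p=10)
        m = SparsePLSDA(n_components=2, keep_x=[4, 3]).fit(X, y)
        for k, keep in enumerate([4, 3]):
            assert np.linalg.norm(m.x_loadings_[:, k]) == pytest.approx(1.0)
            assert np.count_nonzero(m.x_loadings_[:, k]) == keep

    def test_label_swap_negates_loadings(self):
        rng = np.random.default_rng(4)
        X, y = make_problem(rng)
        swapped = np.where(y == "pos", "neg", "pos")
        a = SparsePLSDA(keep_x=4).fit(X, y)
        b = SparsePLSDA(keep_x=4).fit(X, swapped)
        np.testing.assert_allclose(
            a.x_loadings_[:, 0], -b.x_loadings_[:, 0], atol=1e-10
        )

    def test_column_permutation_permutes_loadings(self):
        rng = np.random.default_rng(5)
        X, y = make_problem(rng)
        names = [f"f{i}" for i in range(X.shape[1])]
        perm = rng.permutation(X.shape[1])
        a = SparsePLSDA(keep_x=3).fit(pd.DataFrame(X, columns=names), y)
        b = SparsePLSDA(keep_x=3).fit(
            pd.DataFrame(X[:, perm], columns=[names[i] for i in perm]), y
        )
        pd.testing.assert_series_equal(
            a.loadings_series(0).sort_index(), b.loadings_series(0).sort_index()
        )

    def test_sign_convention_positive_class_scores_higher(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            X, y = make_problem(rng)
            m = SparsePLSDA(keep_x=4).fit(X, y)
            s = m.scores_[:, 0]
            assert s[y == "pos"].mean() > s[y == "neg"].mean()

    def test_single_class_raises(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(6, 3))
        with pytest.raises(ValueError, match="two-class"):
            SparsePLSDA(keep_x=1).fit(X, np.array(["pos"] * 6))

    def test_keepx_clamped_with_warning(self):
        rng = np.random.default_rng(10)
        X, y = make_problem(rng, p=4)
        with pytest.warns(UserWarning, match="clamped"):
            m = SparsePLSDA(keep_x=99).fit(X, y)
        assert m.keep_x_ == [4]


class TestPredictScores:
    def test_training_scores_reproduced(self):
        rng = np.random.default_rng(11)
        X, y = make_problem(rng, n=25, p=10)
        m = SparsePLSDA(n_components=2, keep_x=5).fit(X, y)
        np.testing.assert_allclose(m.transform(X), m.scores_, atol=1e-10)

    def test_zero_row_scores_zero(self):
        rng = np.random.default_rng(12)
        X, y = make_problem(rng)
        m = SparsePLSDA(keep_x=4).fit(X, y)
        assert m.decision_function(np.zeros((1, X.shape[1])))[0] == pytest.approx(0.0)

    def test_duplicated_rows_identical_scores(self):
        rng = np.random.default_rng(13)
        X, y = make_problem(rng)
        m = SparsePLSDA(keep_x=4).fit(X, y)
        double = np.vstack([X[:1], X[:1]])
        s = m.decision_function(double)
        assert s[0] == s[1]

    def test_feature_mismatch_raises_with_names(self):
        rng = np.random.default_rng(14)
        X, y = make_problem(rng, p=3)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        m = SparsePLSDA(keep_x=2).fit(df, y)
        with pytest.raises(ValueError, match="c"):
            m.decision_function(df[["a", "b"]])


class TestFilterByLoading:
    def test_zero_cutoff_keeps_model(self):
        rng = np.random.default_rng(15)
        X, y = make_problem(rng)
        m = SparsePLSDA(keep_x=5).fit(X, y)
        f = m.filter_by_loading(0.0)
        np.testing.assert_allclose(f.x_loadings_, m.x_loadings_, atol=1e-12)
        np.testing.assert_allclose(f.scores_, m.scores_, atol=1e-10)

    def test_pattern_after_cutoff(self):
        rng = np.random.default_rng(16)
        X, y = make_problem(rng, p=6)
        m = SparsePLSDA(keep_x=6).fit(X, y)
        cutoff = float(np.sort(np.abs(m.x_loadings_[:, 0]))[1])  # drop 2 smallest
        f = m.filter_by_loading(cutoff)
        assert np.count_nonzero(f.x_loadings_[:, 0]) == 4
        assert f.n_retained_ == 4
        assert np.linalg.norm(f.x_loadings_[:, 0]) == pytest.approx(1.0)

    def test_small_cutoff_preserves_heldout_confusion(self):
        """Filtering at a tiny cutoff leaves held-out calls unchanged."""
        from aptamarkers import classify, evaluate

        rng = np.random.default_rng(17)
        n, p = 40, 10
        y = np.array(["neg", "pos"] * 20)  # interleaved so splits stay mixed
        signal = np.where(y == "pos", 1.0, -1.0)
        X = rng.normal(size=(n, p))
        X[:, :3] += signal[:, None]
        X = standardized(X)
        tr, te = np.arange(30), np.arange(30, 40)
        m = SparsePLSDA(keep_x=p).fit(X[tr], y[tr])
        f = m.filter_by_loading(1e-6)

        def confusion(model):
            calls = [
                classify(s, {str(k): v for k, v in model.class_stats_.items()}).call
                for s in model.decision_function(X[te])
            ]
            return evaluate(calls, y[te])

        assert confusion(m) == confusion(f)

    def test_removing_everything_raises(self):
        rng = np.random.default_rng(18)
        X, y = make_problem(rng)
        m = SparsePLSDA(keep_x=3).fit(X, y)
        with pytest.raises(ValueError, match="every variable"):
            m.filter_by_loading(1.1)


class TestSerialization:
    def test_json_round_trip_predicts_identically(self):
        rng = np.random.default_rng(19)
        X, y = make_problem(rng, n=24, p=7)
        df = pd.DataFrame(X, columns=[f"f{i}" for i in range(7)])
        m = SparsePLSDA(n_components=2, keep_x=3).fit(df, y)
        clone = SparsePLSDA.from_dict(m.to_dict())
        np.testing.assert_allclose(clone.transform(df), m.transform(df), atol=1e-12)
        assert list(clone.predict(df)) == list(m.predict(df))

    def test_sklearn_params_interface(self):
        m = SparsePLSDA(n_components=2, keep_x=5)
        assert m.get_params()["keep_x"] == 5
        m.set_params(keep_x=3)
        assert m.keep_x == 3
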