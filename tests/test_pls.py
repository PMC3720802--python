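"""NIPALS PLS regression and its leave-one-out statistics."""

import numpy as np
import pytest

import nnaaindex as nx
from nnaaindex.pls import loo_press_profile


def _ols_fit(X, y):
    Xd = np.column_stack([np.ones(X.shape[0]), X])
    beta = np.linalg.lstsq(Xd, y, rcond=None)[0]
    return lambda Xn: np.column_stack([np.ones(Xn.shape[0]), Xn]) @ beta


class TestQ2Formula:
    def test_mean_prediction_gives_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert nx.q2_score(y, np.full(4, y.mean())) == pytest.approx(0.0)

    def test_perfect_prediction_gives_one(self):
        y = np.array([1.0, 2.0, 3.0])
        assert nx.q2_score(y, y) == pytest.approx(1.0)

    def test_hand_value(self):
        assert nx.q2_score([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_external_reference_mean(self):
        # Q2 against a supplied (training) mean, not the sample's own mean
        assert nx.q2_score([0.0, 2.0], [0.0, 2.0], y_mean=5.0) == 1.0
        assert nx.q2_score([0.0, 2.0], [5.0, 5.0], y_mean=1.0) < 0


class TestFitPLS:
    def test_single_column_exact_relation(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((15, 1))
        y = 2.5 * X[:, 0] - 1.0
        model = nx.fit_pls(X, y, 1)
        assert model.fit_stats.r2 == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_full_rank_equals_ols(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((20, 5))
        y = X @ rng.standard_normal(5) + rng.standard_normal(20)
        model = nx.fit_pls(X, y, 5)
        ols = _ols_fit(X, y)
        np.testing.assert_allclose(model.predict(X), ols(X), atol=1e-8)
        Xn = rng.standard_normal((6, 5))
        np.testing.assert_allclose(model.predict(Xn), ols(Xn), atol=1e-8)

    def test_scores_orthogonal(self, dipeptide_dataset):
        _, X, y, _ = dipeptide_dataset
        model = nx.fit_pls(X, y, 4)
        G = model.x_scores.T @ model.x_scores
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0.0, atol=1e-8)

    def test_column_rescaling_invariance(self, dipeptide_dataset):
        _, X, y, _ = dipeptide_dataset
        base = nx.fit_pls(X, y, 2).predict(X)
        X2 = X.copy()
        X2[:, 3] = 100.0 * X2[:, 3] - 7.0
        again = nx.fit_pls(X2, y, 2).predict(X2)
        np.testing.assert_allclose(base, again, atol=1e-8)

    def test_hand_two_by_two(self):
        """One component on a 2-variable system against explicit algebra."""
        X = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        y = np.array([1.0, -1.0, 0.5, -0.5])
        model = nx.fit_pls(X, y, 1)
        # autoscaled X has identical columns up to the y pattern; w from X'y
        Xs = X / X.std(axis=0, ddof=1)
        ys = y / y.std(ddof=1)
        w = Xs.T @ ys
        w /= np.linalg.norm(w)
        t = Xs @ w
        q = ys @ t / (t @ t)
        manual = q * t * y.std(ddof=1)
        np.testing.assert_allclose(model.predict(X), manual, atol=1e-10)

    def test_rank_exceeded_errors(self):
        X = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0], [4.0, 8.0]])
        y = np.array([1.0, 2.0, 3.0, 4.5])
        with pytest.raises(ValueError, match="rank"):
            nx.fit_pls(X, y, 2)

    def test_constant_y_errors(self):
        X = np.random.default_rng(0).standard_normal((6, 2))
        with pytest.raises(ValueError, match="constant"):
            nx.fit_pls(X, np.ones(6), 1)

    def test_duplicated_row_same_prediction(self, dipeptide_dataset):
        _, X, y, _ = dipeptide_dataset
        model = nx.fit_pls(X, y, 2)
        preds = model.predict(np.vstack([X[0], X[0]]))
        assert preds[0] == pytest.approx(preds[1])

    def test_column_count_mismatch(self, dipeptide_dataset):
        _, X, y, _ = dipeptide_dataset
        model = nx.fit_pls(X, y, 2)
        with pytest.raises(ValueError, match="columns"):
            model.predict(X[:, :5])


class TestLOO:
    def test_q2_not_above_r2(self, dipeptide_dataset):
        _, X, y, _ = dipeptide_dataset
        stats = nx.loo_q2(X, y, 2)
        assert stats.q2 <= stats.r2 + 1e-9
        assert stats.q2 <= 1.0 and stats.r2 <= 1.0

    def test_batched_matches_explicit_refits(self, dipeptide_dataset):
        """The vectorized LOO path equals literal per-fold refits."""
        _, X, y, _ = dipeptide_dataset
        X, y = X[:20], y[:20]
        press, preds = loo_press_profile(X, y, 3)
        n = len(y)
        for A in (1, 2, 3):
            manual = np.empty(n)
            for i in range(n):
                keep = np.arange(n) != i
                m = nx.fit_pls(X[keep], y[keep], A)
                manual[i] = m.predict(X[i:i + 1])[0]
            np.testing.assert_allclose(preds[:, A - 1], manual, atol=1e-8)
            assert press[A - 1] == pytest.approx(((y - manual) ** 2).sum())

    def test_reordering_invariance(self, dipeptide_dataset):
        _, X, y, _ = dipeptide_dataset
        stats = nx.loo_q2(X, y, 2)
        rng = np.random.default_rng(4)
        perm = rng.permutation(len(y))
        stats_perm = nx.loo_q2(X[perm], y[perm], 2)
        assert stats.q2 == pytest.approx(stats_perm.q2, abs=1e-10)

    def test_rms_is_sqrt_press_over_n(self, dipeptide_dataset):
        _, X, y, _ = dipeptide_dataset
        stats = nx.loo_q2(X, y, 2)
        assert stats.rms == pytest.approx(np.sqrt(stats.press / stats.n))


class TestSelectComponents:
    def test_noise_free_rank_two(self):
        rng = np.random.default_rng(2)
        T = rng.standard_normal((40, 2))
        X = T @ rng.standard_normal((2, 8))
        y = T @ np.array([1.0, -2.0])
        assert nx.select_components(X, y, 5) == 2

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_collinear_block_stays_small(self, seed):
        """With one informative direction shared by collinear columns, the
        PRESS-optimal component count stays small and is stable across
        regenerated noise."""
        rng = np.random.default_rng(seed)
        base = rng.standard_normal(40)
        X = np.column_stack(
            [base + 0.01 * rng.standard_normal(40) for _ in range(6)])
        y = 2.0 * base + 0.1 * rng.standard_normal(40)
        assert nx.select_components(X, y, 5) <= 2

    def test_ties_break_toward_smaller(self):
        # duplicated informative column: extra components cannot reduce PRESS
        rng = np.random.default_rng(3)
        base = rng.standard_normal(30)
        X = np.column_stack([base, base])
        y = base * 2.0
        assert nx.select_components(X, y, 2) == 1


def test_model_json_roundtrip(tmp_path, dipeptide_dataset):
    from nnaaindex import io as io_mod
    _, X, y, _ = dipeptide_dataset
    model = nx.fit_pls(X, y, 2)
    path = tmp_path / "model.json"
    io_mod.save_model(model, path)
    back = io_mod.load_model(path)
    np.testing.assert_allclose(back.predict(X), model.predict(X), atol=1e-12)


def test_against_sklearn_cross_check(dipeptide_dataset):
    """Independent oracle: scikit-learn's NIPALS PLS gives the same fitted
    values on autoscaled data."""
    from sklearn.cross_decomposition import PLSRegression
    _, X, y, _ = dipeptide_dataset
    ours = nx.fit_pls(X, y, 2).predict(X)
    sk = PLSRegression(n_components=2, scale=True).fit(X, y)
    np.testing.assert_allclose(ours, sk.predict(X).ravel(), atol=1e-6)
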