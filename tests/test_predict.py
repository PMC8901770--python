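"""AUC identity, PLS1 regression, component selection and KNN + LIME."""

import numpy as np
import pytest
from scipy import stats

from abstinet import (
    auc,
    fit_pls1,
    knn_lime_importance,
    select_components,
)


class TestAUC:
    def test_perfect_separation(self):
        assert auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0

    def test_inversion_symmetry(self):
        rng = np.random.default_rng(0)
        s = rng.standard_normal(50)
        y = rng.integers(0, 2, 50)
        y[0], y[1] = 0, 1
        assert auc(-s, y) == pytest.approx(1 - auc(s, y))

    def test_mann_whitney_identity(self):
        """Rank AUC equals U/(n1*n0) exactly, ties included."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = 1000
            s = rng.integers(0, 50, n).astype(float)  # heavy ties
            y = rng.integers(0, 2, n)
            y[:2] = [0, 1]
            u = stats.mannwhitneyu(s[y == 1], s[y == 0]).statistic
            assert auc(s, y) == pytest.approx(u / ((y == 1).sum() * (y == 0).sum()))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        s = rng.standard_normal(200)
        y = (s + rng.standard_normal(200) > 0).astype(int)
        assert auc(np.exp(s), y) == pytest.approx(auc(s, y))
        assert auc(3 * s - 7, y) == pytest.approx(auc(s, y))

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auc([1.0, 2.0], [1, 1])


class TestFitPLS1:
    def test_perfect_predictor(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(80)
        y = (x > 0).astype(float)
        model = fit_pls1(x[:, None] * 1.0 + 0.0, y, n_components=1)
        assert model.beta[0] > 0
        assert model.auc == 1.0

    def test_ols_equivalence_full_rank(self):
        """PLS1 with as many components as predictors reproduces least
        squares on orthonormal X (tolerance 1e-8)."""
        rng = np.random.default_rng(4)
        n, p = 60, 5
        X = np.linalg.qr(rng.standard_normal((n, p)))[0]
        y = rng.standard_normal(n) + X @ rng.standard_normal(p)
        model = fit_pls1(X, (y > np.median(y)).astype(float), n_components=p, scale=False)
        ols = np.linalg.lstsq(
            X - X.mean(0), (y > np.median(y)).astype(float) - (y > np.median(y)).mean(), rcond=None
        )[0]
        assert np.allclose(model.beta, ols, atol=1e-8)

    def test_odds_ratio_is_exp_of_unrounded_beta(self):
        """|OR - exp(beta)| <= 0.01 on synthetic fits (the reporting
        convention applies exp to the unrounded coefficient)."""
        rng = np.random.default_rng(5)
        X = rng.standard_normal((120, 8))
        y = (X[:, 0] + 0.5 * rng.standard_normal(120) > 0).astype(float)
        model = fit_pls1(X, y, n_components=3)
        assert np.all(np.abs(model.odds_ratio - np.exp(model.beta)) <= 0.01)
        assert np.all(model.ci_low <= model.odds_ratio)
        assert np.all(model.odds_ratio <= model.ci_high)

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((50, 4))
        X[:, 2] = 7.0
        y = (X[:, 0] > 0).astype(float)
        with pytest.warns(UserWarning, match="constant"):
            model = fit_pls1(X, y, n_components=2, feature_names=list("abcd"))
        assert model.dropped == ["c"]
        assert model.feature_names == ["a", "b", "d"]

    def test_summary_table_columns(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((60, 3))
        y = (X.sum(1) > 0).astype(float)
        table = fit_pls1(X, y, n_components=2).summary()
        assert list(table.columns) == ["variable", "beta", "OR", "ci_low", "ci_high", "t", "p"]
        assert len(table) == 3


class TestSelectComponents:
    def test_oracle_feature_selects_one_component(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((150, 10))
        y = rng.integers(0, 2, 150)
        y[:2] = [0, 1]
        X[:, 3] = y
        best, curve = select_components(X, y, seed=0)
        assert best == 1
        assert curve[0] > 0.99

    def test_null_cv_auc_near_half(self):
        """y independent of X: mean selected CV-AUC stays near 0.5."""
        selected = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((200, 20))
            y = rng.integers(0, 2, 200)
            best, curve = select_components(X, y, seed=seed)
            selected.append(curve[best - 1])
        assert abs(np.mean(selected) - 0.5) <= 0.05

    def test_recovers_four_planted_directions(self):
        """Outcome loading on four factor directions with distinct
        variances needs about four PLS components (median over seeds)."""
        picks = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n, p = 400, 20
            sds = np.array([4.0, 2.8, 2.0, 1.4])
            Z = rng.standard_normal((n, 4)) * sds
            W = np.linalg.qr(rng.standard_normal((p, 4)))[0]
            X = Z @ W.T + 0.3 * rng.standard_normal((n, p))
            w = np.array([0.2, -0.5, 0.9, -1.6])
            y = (Z @ w + 0.3 * rng.standard_normal(n) > 0).astype(int)
            best, _ = select_components(X, y, max_components=10, seed=seed)
            picks.append(best)
        assert np.median(picks) in (3, 4, 5)

    def test_small_minority_reduces_folds(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((30, 5))
        y = np.zeros(30, dtype=int)
        y[:4] = 1
        with pytest.warns(UserWarning, match="folds"):
            best, _ = select_components(X, y, folds=10, seed=0)
        assert best >= 1


class TestKnnLime:
    @staticmethod
    def _correlated_series(rng, n=150):
        # shared longitudinal factor, as in real cumulative forum series
        f = rng.standard_normal((n, 1))
        X = 0.95 * f + 0.3 * rng.standard_normal((n, 144))
        return X

    def test_planted_signal_recovered(self):
        """y driven by feature 1, months 1-3: those three cells carry the
        largest |importance| with positive sign (majority over seeds)."""
        hits = sign_ok = 0
        seeds = range(5)
        for seed in seeds:
            rng = np.random.default_rng(seed)
            X = self._correlated_series(rng)
            X[:, 0:3] = rng.standard_normal((len(X), 3))
            y = (X[:, 0:3].mean(axis=1) > 0).astype(int)
            imp = knn_lime_importance(X, y, k=5, seed=seed, n_perturb=400)
            flat = np.abs(imp.values).ravel()
            hits += set(np.argsort(flat)[-3:]) <= {0, 1, 2}
            sign_ok += bool((imp.values.ravel()[:3] > 0).all())
            assert imp.values.shape == (4, 36)
        assert hits > len(seeds) / 2
        assert sign_ok > len(seeds) / 2

    def test_planted_cells_stand_off_null_floor(self):
        """Planted-cell importances exceed the attribution noise floor of
        an independent-outcome fit by a factor >= 3 (majority of seeds)."""
        wins = 0
        seeds = range(3)
        for seed in seeds:
            rng = np.random.default_rng(seed)
            X = self._correlated_series(rng)
            X[:, 0:3] = rng.standard_normal((len(X), 3))
            y = (X[:, 0:3].mean(axis=1) > 0).astype(int)
            imp = knn_lime_importance(X, y, k=5, seed=seed, n_perturb=400)
            y0 = rng.integers(0, 2, len(X))
            imp0 = knn_lime_importance(X, y0, k=5, seed=seed, n_perturb=400)
            planted = np.abs(imp.values.ravel()[:3]).mean()
            floor = np.abs(imp0.values).mean()
            wins += planted >= 3 * floor
        assert wins > len(seeds) / 2

    def test_constant_input_gives_zero_importance(self):
        X = np.ones((30, 144))
        y = np.arange(30) % 2
        imp = knn_lime_importance(X, y, k=3, seed=0, n_perturb=50)
        assert (imp.values == 0).all()

    def test_k_must_be_smaller_than_n(self):
        rng = np.random.default_rng(11)
        with pytest.raises(ValueError):
            knn_lime_importance(rng.standard_normal((5, 144)), np.array([0, 1, 0, 1, 0]), k=5)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(12)
        X = self._correlated_series(rng, n=40)
        y = (X[:, 0] > 0).astype(int)
        a = knn_lime_importance(X, y, k=3, seed=5, n_perturb=100)
        b = knn_lime_importance(X, y, k=3, seed=5, n_perturb=100)
        assert np.array_equal(a.values, b.values)
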