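"""Tests for mean-centering and behavioral PLS with resampling inference."""

import numpy as np
import pytest

from boldvar.pls_engine import (
    behavioral_pls,
    bootstrap,
    mean_centering_pls,
    permutation_test,
)


@pytest.fixture
def two_group_data(rng):
    n, p = 30, 8
    X = rng.standard_normal((n, p))
    labels = np.array(["a"] * 15 + ["b"] * 15)
    X[labels == "b", :3] += 1.0  # planted group contrast in 3 variables
    return X, labels


@pytest.fixture
def planted_behavioral(rng):
    """100 subjects, 12 brain vars; behaviors driven by the first 4 columns."""
    n, p = 100, 12
    X = rng.standard_normal((n, p))
    w = np.zeros(p)
    w[:4] = 0.5
    s = X @ w
    Y = np.column_stack(
        [s + 0.2 * rng.standard_normal(n), -s + 0.2 * rng.standard_normal(n)]
    )
    return X, Y, w


class TestMeanCenteringPls:
    def test_identical_group_means_all_zero(self):
        X = np.tile(np.arange(4.0), (6, 1))
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        res = mean_centering_pls(X, labels)
        assert np.allclose(res.singular_values, 0, atol=1e-12)

    def test_two_group_one_variable_closed_form(self):
        """Centered means are ±(a-b)/2, so the singular value is |a-b|/sqrt(2)."""
        X = np.array([[1.0], [1.0], [4.0], [4.0]])
        labels = np.array(["a", "a", "b", "b"])
        res = mean_centering_pls(X, labels)
        assert res.singular_values[0] == pytest.approx(3 / np.sqrt(2), abs=1e-12)

    def test_collinear_condition_means_rank_one(self, rng):
        """Three condition means on a line put ~100% covariance in LV1."""
        base = rng.standard_normal(5)
        direction = rng.standard_normal(5)
        X = np.vstack(
            [base + t * direction + 1e-6 * rng.standard_normal((4, 5))
             for t in (0.0, 1.0, 2.0)]
        )
        labels = np.repeat(["c1", "c2", "c3"], 4)
        res = mean_centering_pls(X, labels)
        assert res.covariance_explained[0] > 0.999

    def test_scores_are_projections(self, two_group_data):
        X, labels = two_group_data
        res = mean_centering_pls(X, labels)
        assert np.allclose(res.brain_scores, X @ res.brain_saliences, atol=1e-12)

    def test_single_group_raises(self, rng):
        with pytest.raises(ValueError):
            mean_centering_pls(rng.standard_normal((5, 3)), np.zeros(5))


class TestBehavioralPls:
    def test_rank_one_identity_behavior(self, rng):
        """Y equal to one brain column: LV1 explains all covariance and the
        brain salience concentrates on that column."""
        X = rng.standard_normal((25, 5))
        Y = X[:, [2]].copy()
        res = behavioral_pls(X, Y)
        assert res.covariance_explained[0] == pytest.approx(1.0, abs=1e-10)
        assert np.argmax(np.abs(res.brain_saliences[:, 0])) == 2

    def test_hand_svd_two_brain_vars(self):
        """One behavior, 2 brain vars: the singular value equals the norm of
        the correlation 2-vector and the salience its normalization."""
        X = np.array([[0.0, 1.0], [1.0, 0.0], [2.0, 3.0], [3.0, 2.0]])
        Y = np.array([[0.0], [1.0], [2.0], [3.0]])
        r = np.array(
            [np.corrcoef(Y[:, 0], X[:, j])[0, 1] for j in range(2)]
        )
        res = behavioral_pls(X, Y)
        assert res.singular_values[0] == pytest.approx(np.linalg.norm(r))
        assert np.allclose(
            np.abs(res.brain_saliences[:, 0]), np.abs(r) / np.linalg.norm(r),
            atol=1e-12,
        )

    def test_single_group_reduces_to_correlation_vector(self, rng):
        X = rng.standard_normal((30, 6))
        Y = (X[:, 0] - X[:, 3] + 0.5 * rng.standard_normal(30))[:, None]
        res = behavioral_pls(X, Y)
        r = np.array([np.corrcoef(Y[:, 0], X[:, j])[0, 1] for j in range(6)])
        v = res.brain_saliences[:, 0]
        sign = np.sign(v @ r)
        assert np.allclose(v * sign, r / np.linalg.norm(r), atol=1e-10)

    def test_energy_conservation(self, planted_behavioral):
        X, Y, _ = planted_behavioral
        res = behavioral_pls(X, Y)
        # sum of squared singular values = squared Frobenius norm of the
        # cross-block correlation matrix
        zx = (X - X.mean(0)) / X.std(0, ddof=1)
        zy = (Y - Y.mean(0)) / Y.std(0, ddof=1)
        cross = zy.T @ zx / (X.shape[0] - 1)
        assert np.sum(res.singular_values**2) == pytest.approx(
            np.sum(cross**2), abs=1e-10
        )

    def test_saliences_orthonormal(self, planted_behavioral):
        X, Y, _ = planted_behavioral
        res = behavioral_pls(X, Y)
        for block in (res.brain_saliences, res.design_saliences):
            gram = block.T @ block
            assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-10)

    def test_planted_salience_recovered(self, planted_behavioral):
        X, Y, w = planted_behavioral
        res = behavioral_pls(X, Y)
        cos = abs(res.brain_saliences[:, 0] @ (w / np.linalg.norm(w)))
        assert cos >= 0.9

    def test_covariance_explained_sums_to_one(self, planted_behavioral):
        X, Y, _ = planted_behavioral
        res = behavioral_pls(X, Y)
        assert res.covariance_explained.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_column_named(self, rng):
        X = rng.standard_normal((10, 3))
        Y = np.ones((10, 1))
        with pytest.raises(ValueError, match="behavior"):
            behavioral_pls(X, Y, behavior_names=("flat",))

    def test_refit_is_deterministic(self, planted_behavioral):
        X, Y, _ = planted_behavioral
        r1 = behavioral_pls(X, Y)
        r2 = behavioral_pls(X, Y)
        assert np.array_equal(r1.brain_saliences, r2.brain_saliences)
        assert np.array_equal(r1.design_saliences, r2.design_saliences)


class TestPermutationTest:
    def test_collinear_data_minimum_p(self, rng):
        X = rng.standard_normal((20, 4))
        Y = X[:, [0]].copy()
        res = behavioral_pls(X, Y)
        res = permutation_test(res, X, Y, n_perm=99, seed=0)
        assert res.perm_p[0] == pytest.approx(1 / 100)

    def test_seed_reproducibility(self, planted_behavioral):
        X, Y, _ = planted_behavioral
        res = behavioral_pls(X, Y)
        p1 = permutation_test(res, X, Y, n_perm=50, seed=11).perm_p
        p2 = permutation_test(res, X, Y, n_perm=50, seed=11).perm_p
        assert np.array_equal(p1, p2)

    def test_unsmoothed_proportion(self, planted_behavioral):
        X, Y, _ = planted_behavioral
        res = behavioral_pls(X, Y)
        p = permutation_test(res, X, Y, n_perm=50, seed=3,
                             smoothed=False).perm_p
        assert np.all((p * 50) % 1 == pytest.approx(0, abs=1e-9))

    def test_invalid_n_perm(self, planted_behavioral):
        X, Y, _ = planted_behavioral
        res = behavioral_pls(X, Y)
        with pytest.raises(ValueError):
            permutation_test(res, X, Y, n_perm=0)

    def test_mean_centering_group_contrast_detected(self, two_group_data):
        X, labels = two_group_data
        res = mean_centering_pls(X, labels)
        res = permutation_test(res, X, labels, n_perm=200, seed=5)
        assert res.perm_p[0] < 0.05


class TestBootstrap:
    def test_noiseless_rank_one_large_bsr(self, rng):
        X = rng.standard_normal((24, 5))
        Y = (2 * X[:, 0] - X[:, 1])[:, None]
        res = behavioral_pls(X, Y)
        res = bootstrap(res, X, Y, n_boot=50, seed=1)
        assert np.all(np.abs(res.bsr[:2, 0]) > 5)
        # uninvolved variables are far less stable than the involved ones
        assert np.abs(res.bsr[:2, 0]).min() > np.abs(res.bsr[2:, 0]).max()

    def test_planted_support_sensitivity(self, planted_behavioral):
        X, Y, w = planted_behavioral
        res = behavioral_pls(X, Y)
        res = bootstrap(res, X, Y, n_boot=100, seed=2)
        hits = np.abs(res.bsr[w > 0, 0]) >= 2
        assert hits.mean() >= 0.8

    def test_seed_reproducibility(self, planted_behavioral):
        X, Y, _ = planted_behavioral
        res = behavioral_pls(X, Y)
        b1 = bootstrap(res, X, Y, n_boot=40, seed=9)
        b2 = bootstrap(res, X, Y, n_boot=40, seed=9)
        assert np.array_equal(b1.bsr, b2.bsr)
        assert np.array_equal(b1.behavior_ci, b2.behavior_ci)

    def test_ci_brackets_original(self, planted_behavioral):
        X, Y, _ = planted_behavioral
        res = behavioral_pls(X, Y)
        res = bootstrap(res, X, Y, n_boot=200, seed=4)
        lo, hi = res.behavior_ci
        u = res.design_saliences
        # LV1 saliences should sit inside their own bootstrap CI
        assert np.all(lo[:, 0] <= u[:, 0] + 1e-9)
        assert np.all(u[:, 0] <= hi[:, 0] + 1e-9)

    def test_stratified_groups_preserved(self, rng):
        X = rng.standard_normal((20, 6))
        Y = X[:, :2] + 0.2 * rng.standard_normal((20, 2))
        labels = np.array(["a"] * 10 + ["b"] * 10)
        res = behavioral_pls(X, Y, labels=labels)
        out = bootstrap(res, X, Y, labels=labels, n_boot=30, seed=6)
        assert out.bsr.shape == (6, res.n_lv)
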