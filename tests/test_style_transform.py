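import numpy as np
import pytest

from conftest import random_labels
from srmkl import (InputError, StyleGroupedDataset, StyleModel, init_style,
                   materialize_A_linear, solve_lssvm_dual, style_penalty,
                   transformed_cross, transformed_gram, update_style)


def random_style_instance(seed, n_max=30, d_max=5, n_groups_max=3):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, n_max + 1))
    d = int(rng.integers(2, d_max + 1))
    N = int(rng.integers(1, n_groups_max + 1))
    X = rng.standard_normal((n, d))
    g = rng.integers(1, N + 1, n)
    model = StyleModel(alpha_style=rng.standard_normal(n),
                       alpha_w=rng.standard_normal(n),
                       lam=float(np.exp(rng.uniform(-1, 1))),
                       gamma=float(np.exp(rng.uniform(-2, 1))),
                       group=g)
    return X, model


def explicit_transformed_gram(X, model):
    """Oracle: materialize every A_j and form x_a' A_{g(a)} A_{g(b)}' x_b."""
    A = materialize_A_linear(model, X)
    n = X.shape[0]
    rows = np.vstack([X[i] @ A[int(model.group[i])] for i in range(n)])
    return rows @ rows.T


class TestInitAndIdentity:
    def test_identity_model_leaves_gram_unchanged(self, rng):
        X = rng.standard_normal((10, 3))
        ds = StyleGroupedDataset(X, random_labels(rng, 10), np.repeat([1, 2], 5))
        model = init_style(ds, lam=2.0, gamma=3.0)
        K = X @ X.T
        np.testing.assert_array_equal(transformed_gram(model, K), K)
        assert style_penalty(model, K) == 0.0

    def test_scale_field(self, rng):
        ds = StyleGroupedDataset(rng.standard_normal((4, 2)),
                                 [1, -1, 1, -1], [1, 1, 2, 2])
        assert init_style(ds, 1.0, 1.0).scale == 0.5

    def test_zero_classifier_dual_behaves_as_identity(self, rng):
        X = rng.standard_normal((8, 2))
        g = np.repeat([1, 2], 4)
        model = StyleModel(rng.standard_normal(8), np.zeros(8), 1.0, 1.0, g)
        K = X @ X.T
        np.testing.assert_array_equal(transformed_gram(model, K), K)
        for A in materialize_A_linear(model, X).values():
            np.testing.assert_array_equal(A, np.eye(2))

    def test_nonpositive_parameters_rejected(self, rng):
        ds = StyleGroupedDataset(rng.standard_normal((4, 2)),
                                 [1, -1, 1, -1], [1, 1, 2, 2])
        with pytest.raises(InputError):
            init_style(ds, lam=0.0, gamma=1.0)
        with pytest.raises(InputError):
            init_style(ds, lam=1.0, gamma=-1.0)


class TestKernelTrickConsistency:
    @pytest.mark.parametrize("seed", range(25))
    def test_transformed_gram_equals_explicit_feature_computation(self, seed):
        X, model = random_style_instance(seed)
        K = X @ X.T
        np.testing.assert_allclose(transformed_gram(model, K),
                                   explicit_transformed_gram(X, model), atol=1e-6)

    def test_transformed_gram_symmetric(self):
        X, model = random_style_instance(99)
        Khat = transformed_gram(model, X @ X.T)
        np.testing.assert_allclose(Khat, Khat.T, atol=1e-12)

    def test_transformed_cross_matches_explicit_features(self):
        X, model = random_style_instance(7)
        K = X @ X.T
        A = materialize_A_linear(model, X)
        Z = np.random.default_rng(8).standard_normal((4, X.shape[1]))
        g0 = int(model.group[0])
        K_tn = X @ Z.T
        got = transformed_cross(model, K, K_tn, g0)
        rows = np.vstack([X[i] @ A[int(model.group[i])] for i in range(X.shape[0])])
        cols = Z @ A[g0]  # new samples inherit the known group's matrix
        np.testing.assert_allclose(got, rows @ cols.T, atol=1e-8)

    def test_cross_with_unknown_group_rejected(self):
        X, model = random_style_instance(3)
        with pytest.raises(InputError):
            transformed_cross(model, X @ X.T, X @ X[:2].T, new_group=999)


class TestUpdateStyle:
    def _instance(self, seed, n=16, d=3, N=3, gamma=0.7, lam=1.3):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, d))
        g = rng.integers(1, N + 1, n)
        y = random_labels(rng, n)
        K = X @ X.T
        dual = solve_lssvm_dual(K, y, lam)
        return X, y, g, K, dual, gamma

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_explicit_ridge_qp_over_matrix_entries(self, seed):
        """The kernelized update must agree with an independent solve of the
        per-group subproblem parametrized by all d*d entries of A_j."""
        X, y, g, K, dual, gamma = self._instance(seed)
        model = update_style(K, y, dual, g, gamma)
        A = materialize_A_linear(model, X)
        w = X.T @ dual.alpha
        rho = y - (K @ dual.alpha + dual.bias)
        d = X.shape[1]
        for gid in np.unique(g):
            idx = np.flatnonzero(g == gid)
            M = np.array([np.outer(w, X[i]).ravel() for i in idx])
            vec = np.linalg.solve(M.T @ M + 2.0 * gamma * np.eye(d * d), M.T @ rho[idx])
            A_ref = (vec.reshape(d, d) + np.eye(d)).T
            np.testing.assert_allclose(A[int(gid)], A_ref, atol=1e-6)

    def test_zero_dual_reduces_to_identity(self, rng):
        X = rng.standard_normal((6, 2))
        g = np.repeat([1, 2], 3)
        y = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        from srmkl.lssvm_core import DualSolution
        model = update_style(X @ X.T, y, DualSolution(np.zeros(6), 0.0, 1.0), g, 1.0)
        assert model.is_identity

    def test_large_gamma_pins_matrices_at_identity(self):
        X, y, g, K, dual, _ = self._instance(1)
        model = update_style(K, y, dual, g, gamma=1e6)
        for A in materialize_A_linear(model, X).values():
            assert np.linalg.norm(A - np.eye(X.shape[1])) < 1e-3

    def test_length_mismatch_rejected(self):
        X, y, g, K, dual, gamma = self._instance(2)
        with pytest.raises(InputError):
            update_style(K, y, dual, g[:-1], gamma)


class TestGammaScalingAndPenalty:
    def test_doubling_gamma_halves_deviation_for_fixed_coefficients(self):
        X, model = random_style_instance(5)
        d = X.shape[1]
        base = materialize_A_linear(model, X)
        doubled = StyleModel(model.alpha_style, model.alpha_w, model.lam,
                             2.0 * model.gamma, model.group)
        for gid, A in materialize_A_linear(doubled, X).items():
            np.testing.assert_allclose(A - np.eye(d), (base[gid] - np.eye(d)) / 2.0,
                                       atol=1e-12)

    def test_deviation_non_increasing_in_gamma(self):
        X, model = random_style_instance(6)
        d = X.shape[1]
        norms = []
        for gamma in 10.0 ** np.arange(-2, 4):
            m = StyleModel(model.alpha_style, model.alpha_w, model.lam, gamma,
                           model.group)
            norms.append(max(np.linalg.norm(A - np.eye(d))
                             for A in materialize_A_linear(m, X).values()))
        assert np.all(np.diff(norms) <= 1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_penalty_matches_explicit_frobenius_norms(self, seed):
        X, model = random_style_instance(seed + 40)
        d = X.shape[1]
        explicit = sum(np.linalg.norm(A.T - np.eye(d)) ** 2
                       for A in materialize_A_linear(model, X).values())
        assert style_penalty(model, X @ X.T) == pytest.approx(explicit, abs=1e-8)
        assert style_penalty(model, X @ X.T) >= 0.0


class TestStyleGroupedDataset:
    def test_invariants_enforced(self, rng):
        with pytest.raises(InputError):
            StyleGroupedDataset(rng.standard_normal((3, 2)), [1, -1, 2], [1, 1, 1])
        with pytest.raises(InputError):
            StyleGroupedDataset(rng.standard_normal((3, 2)), [1, -1, 1], [0, 1, 1])
        with pytest.raises(InputError):
            StyleGroupedDataset(rng.standard_normal((3, 2)), [1, -1], [1, 1, 1])

    def test_group_bookkeeping(self, rng):
        ds = StyleGroupedDataset(rng.standard_normal((5, 2)),
                                 [1, -1, 1, -1, 1], [2, 2, 1, 1, 1])
        assert ds.group_sizes == {1: 3, 2: 2}
        assert ds.subset(np.array([0, 1])).n == 2
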