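"""Spectral graph machinery: Laplacian closed forms, Fourier round trips,
Chebyshev convolution against the exact spectral-filtering oracle."""

import json

import numpy as np
import pytest

import dfcgn
from dfcgn.graph import (
    SpectralGraph,
    build_graph,
    cheb_conv,
    cheb_polynomial_values,
    correlation_adjacency,
    graph_fourier,
    inverse_graph_fourier,
    spectral_filter,
    threshold_adjacency,
)


def random_graph(rng, n=None, density=0.7):
    n = n or int(rng.integers(2, 9))
    W = rng.random((n, n))
    W = (W + W.T) / 2
    W[rng.random((n, n)) > density] = 0
    W = np.triu(W, 1)
    W = W + W.T
    return build_graph(W)


class TestCorrelationAdjacency:
    def test_duplicate_channel_fully_connected(self):
        x = np.random.default_rng(0).normal(size=1000)
        C = correlation_adjacency(np.stack([x, x])[None])
        assert C[0, 1] == pytest.approx(1.0)
        assert C[0, 0] == 0.0

    def test_anticorrelated_channel_scores_one(self):
        x = np.random.default_rng(0).normal(size=1000)
        C = correlation_adjacency(np.stack([x, -x])[None])
        assert C[0, 1] == pytest.approx(1.0)

    def test_independent_noise_scores_near_zero(self):
        rng = np.random.default_rng(42)
        ep = rng.normal(size=(1, 2, 76_800))
        C = correlation_adjacency(ep)
        assert C[0, 1] <= 0.02

    def test_zero_variance_channel_warns_and_zeroes(self):
        ep = np.stack([np.zeros(100), np.random.default_rng(0).normal(size=100)])
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            C = correlation_adjacency(ep[None])
        assert C[0, 1] == 0.0


class TestThreshold:
    def test_zero_threshold_is_identity_off_diagonal(self):
        C = np.array([[0, 0.8, 0.3], [0.8, 0, 0.6], [0.3, 0.6, 0]])
        np.testing.assert_array_equal(threshold_adjacency(C, 0.0), C)

    def test_elementwise_rule(self):
        C = np.array([[0, 0.8, 0.3], [0.8, 0, 0.6], [0.3, 0.6, 0]])
        W = threshold_adjacency(C, 0.5)
        np.testing.assert_array_equal(
            W, np.array([[0, 0.8, 0], [0.8, 0, 0.6], [0, 0.6, 0]]))

    def test_binarize_flag(self):
        C = np.array([[0, 0.8], [0.8, 0]])
        np.testing.assert_array_equal(
            threshold_adjacency(C, 0.5, binarize=True), np.array([[0, 1], [1, 0]]))

    def test_tau_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="tau"):
            threshold_adjacency(np.zeros((2, 2)), 1.0 + 1e-9)


class TestBuildGraph:
    def test_two_node_path_closed_form(self):
        G = build_graph(np.array([[0.0, 1.0], [1.0, 0.0]]))
        np.testing.assert_array_equal(G.D, np.eye(2))
        np.testing.assert_array_equal(G.L, [[1, -1], [-1, 1]])
        np.testing.assert_allclose(G.lam, [0.0, 2.0], atol=1e-12)

    def test_empty_graph_convention(self):
        G = build_graph(np.zeros((3, 3)))
        assert np.allclose(G.lam, 0.0)
        np.testing.assert_array_equal(G.L_scaled, -np.eye(3))

    def test_triangle_spectrum(self):
        K3 = np.ones((3, 3)) - np.eye(3)
        G = build_graph(K3)
        np.testing.assert_allclose(G.lam, [0.0, 3.0, 3.0], atol=1e-12)

    @pytest.mark.parametrize("bad", [
        np.array([[0.0, 1.0], [0.5, 0.0]]),       # asymmetric
        np.array([[0.0, -1.0], [-1.0, 0.0]]),     # negative
        np.array([[0.5, 1.0], [1.0, 0.0]]),       # nonzero diagonal
    ])
    def test_invalid_adjacency_rejected(self, bad):
        with pytest.raises(ValueError):
            build_graph(bad)

    def test_laplacian_invariants_on_random_graphs(self, rng):
        for _ in range(20):
            G = random_graph(rng)
            ones = np.ones(G.n_nodes)
            assert np.allclose(G.L @ ones, 0.0, atol=1e-8)
            assert G.lam[0] >= -1e-8
            assert np.allclose(G.U.T @ G.U, np.eye(G.n_nodes), atol=1e-8)
            assert np.allclose(G.U @ np.diag(G.lam) @ G.U.T, G.L, atol=1e-8)
            ls = np.linalg.eigvalsh(G.L_scaled)
            assert ls.min() >= -1 - 1e-9 and ls.max() <= 1 + 1e-9


class TestGraphFourier:
    def test_eigenvector_maps_to_basis_vector(self):
        G = build_graph(np.array([[0.0, 1.0], [1.0, 0.0]]))
        for k in range(2):
            q_hat = graph_fourier(G.U[:, k], G)
            np.testing.assert_allclose(q_hat, np.eye(2)[k], atol=1e-12)

    def test_round_trip(self, rng):
        G = random_graph(rng, n=6)
        q = rng.normal(size=6)
        back = inverse_graph_fourier(graph_fourier(q, G), G)
        assert np.max(np.abs(back - q)) < 1e-8

    def test_zero_maps_to_zero_and_shape_checked(self):
        G = build_graph(np.zeros((3, 3)))
        np.testing.assert_array_equal(graph_fourier(np.zeros(3), G), np.zeros(3))
        with pytest.raises(ValueError, match="length"):
            graph_fourier(np.zeros(4), G)


class TestSpectralFilter:
    def test_identity_filter(self, rng):
        G = random_graph(rng, n=5)
        x = rng.normal(size=5)
        np.testing.assert_allclose(spectral_filter(x, lambda l: np.ones_like(l), G),
                                   x, atol=1e-10)

    def test_lambda_filter_is_laplacian(self, rng):
        G = random_graph(rng, n=5)
        x = rng.normal(size=5)
        np.testing.assert_allclose(spectral_filter(x, lambda l: l, G), G.L @ x,
                                   atol=1e-10)

    def test_lambda_squared_on_path(self):
        G = build_graph(np.array([[0.0, 1.0], [1.0, 0.0]]))
        y = spectral_filter(np.array([1.0, 0.0]), lambda l: l**2, G)
        np.testing.assert_allclose(y, [2.0, -2.0], atol=1e-10)


class TestChebConv:
    def test_order_one_identity_coefficients(self, rng):
        G = random_graph(rng, n=4)
        X = rng.normal(size=(4, 3))
        theta = np.eye(3)[None]
        np.testing.assert_allclose(cheb_conv(X, theta, G), X, atol=1e-12)

    def test_zero_input_zero_output(self, rng):
        G = random_graph(rng, n=4)
        theta = rng.normal(size=(3, 2, 5))
        assert np.allclose(cheb_conv(np.zeros((4, 2)), theta, G), 0.0)

    def test_matches_exact_spectral_filtering(self, rng):
        """Scalar-feature Chebyshev conv equals U g(Λ) Uᵀ x for the induced g."""
        for _ in range(30):
            G = random_graph(rng)
            Q = int(rng.integers(1, 6))
            coef = rng.normal(size=Q)
            x = rng.normal(size=(G.n_nodes, 1))
            got = cheb_conv(x, coef[:, None, None], G)
            want = spectral_filter(
                x, lambda lam: cheb_polynomial_values(coef, lam, G.lambda_max), G)
            denom = max(np.abs(want).max(), 1e-12)
            assert np.abs(got - want).max() / denom < 1e-6

    def test_permutation_equivariance(self, rng):
        G = random_graph(rng, n=6)
        X = rng.normal(size=(6, 4))
        theta = rng.normal(size=(3, 4, 4))
        perm = rng.permutation(6)
        Gp = build_graph(G.W[np.ix_(perm, perm)])
        got = cheb_conv(X[perm], theta, Gp)
        want = cheb_conv(X, theta, G)[perm]
        np.testing.assert_allclose(got, want, atol=1e-8)

    def test_order_cap_guard(self, rng):
        G = random_graph(rng, n=3)
        theta = np.zeros((26, 1, 1))
        with pytest.raises(ValueError, match="cap"):
            cheb_conv(np.zeros((3, 1)), theta, G)


def test_graph_json_round_trip(tmp_path, rng):
    G = random_graph(rng, n=4)
    G.node_labels = ["a", "b", "c", "d"]
    path = tmp_path / "graph.json"
    G.to_json(path, tau=0.5)
    G2 = SpectralGraph.from_json(path)
    np.testing.assert_allclose(G2.W, G.W, atol=1e-12)
    np.testing.assert_allclose(G2.U, G.U, atol=1e-10)
    assert G2.node_labels == G.node_labels
    assert json.loads(path.read_text())["tau"] == 0.5


def test_graph_from_epochs_uses_channel_labels(epochs_small):
    G = dfcgn.graph_from_epochs(epochs_small, tau=0.5)
    assert G.node_labels == ["FP1", "Pz", "Fz"]
    assert G.n_nodes == 3
    assert (G.W >= 0).all() and np.allclose(G.W, G.W.T)
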