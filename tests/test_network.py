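import numpy as np
import pytest
import scipy.sparse as sp

from sidmgf import _autodiff as ad
from sidmgf.datatypes import CellGraph
from sidmgf.graphs import normalize_adjacency
from sidmgf.network import (
    MultigraphAutoencoder,
    ZinbParams,
    attention_fuse,
    gcn_forward,
    spatial_reconstruction_loss,
    total_loss,
    zinb_nll,
)

from naive_oracles import naive_zinb_nll


def _graph(adj):
    g = CellGraph(sp.csr_matrix(np.asarray(adj, float)), kind="spatial",
                  weighted=False)
    return normalize_adjacency(g)


def _empty_graph(n):
    return _graph(np.zeros((n, n)))


class TestGcnForward:
    def test_identity_propagation_reduces_to_dense_layer(self, rng):
        X = np.abs(rng.normal(size=(4, 3)))
        out = gcn_forward(X, _empty_graph(4), np.eye(3), activation="relu")
        np.testing.assert_allclose(out.data, X, atol=1e-12)

    def test_two_node_hand_case(self):
        g = _graph([[0, 1], [1, 0]])
        X = np.array([[2.0, 0.0], [0.0, 4.0]])
        out = gcn_forward(X, g, np.eye(2), activation="relu")
        np.testing.assert_allclose(
            out.data, [[1.0, 2.0], [1.0, 2.0]], atol=1e-12
        )

    def test_relu_zeroes_negative_preactivations(self):
        out = gcn_forward(
            np.array([[-3.0, 2.0]]), _empty_graph(1), np.eye(2),
            activation="relu",
        )
        np.testing.assert_allclose(out.data, [[0.0, 2.0]])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gcn_forward(np.zeros((2, 3)), _empty_graph(2), np.zeros((4, 2)))

    def test_unnormalized_graph_rejected(self):
        g = CellGraph(sp.csr_matrix((2, 2)), kind="spatial", weighted=False)
        with pytest.raises(ValueError, match="normalize"):
            gcn_forward(np.zeros((2, 2)), g, np.eye(2))


class TestAttention:
    def _head(self, d, a, rng=None, zero=False):
        if zero:
            make = lambda *s: np.zeros(s)
        else:
            make = lambda *s: rng.normal(size=s)
        return {
            b: (ad.Tensor(make(d, a)), ad.Tensor(make(a)), ad.Tensor(make(a, 1)))
            for b in ("spatial", "signal")
        }

    def test_equal_logits_give_half_weights(self, rng):
        H_s = rng.normal(size=(5, 3))
        H_a = rng.normal(size=(5, 3))
        fused, alpha = attention_fuse(H_s, H_a, self._head(3, 2, zero=True))
        np.testing.assert_allclose(alpha, 0.5)
        np.testing.assert_allclose(fused.data, 0.5 * (H_s + H_a), atol=1e-12)

    def test_saturation_selects_one_branch(self, rng):
        H_s = rng.normal(size=(4, 2))
        H_a = rng.normal(size=(4, 2))
        head = self._head(2, 1, zero=True)
        # drive the spatial logit to +50: alpha_s -> 1
        head["spatial"] = (
            ad.Tensor(np.zeros((2, 1))),
            ad.Tensor(np.full(1, 100.0)),
            ad.Tensor(np.full((1, 1), 50.0 / np.tanh(100.0))),
        )
        fused, alpha = attention_fuse(H_s, H_a, head)
        np.testing.assert_allclose(alpha[:, 0], 1.0, atol=1e-12)
        np.testing.assert_allclose(fused.data, H_s, atol=1e-10)

    def test_single_cell_hand_computation(self):
        H_s = np.array([[1.0, -2.0]])
        H_a = np.array([[3.0, 0.5]])
        W1 = np.array([[0.2], [-0.1]])
        b = np.array([0.05])
        W2 = np.array([[0.7]])
        head = {
            "spatial": (ad.Tensor(W1), ad.Tensor(b), ad.Tensor(W2)),
            "signal": (ad.Tensor(W1), ad.Tensor(b), ad.Tensor(W2)),
        }
        logit_s = 0.7 * np.tanh(1.0 * 0.2 + (-2.0) * (-0.1) + 0.05)
        logit_a = 0.7 * np.tanh(3.0 * 0.2 + 0.5 * (-0.1) + 0.05)
        es, ea = np.exp(logit_s), np.exp(logit_a)
        a_s = es / (es + ea)
        expected = a_s * H_s + (1 - a_s) * H_a
        fused, alpha = attention_fuse(H_s, H_a, head)
        np.testing.assert_allclose(alpha[0, 0], a_s, atol=1e-10)
        np.testing.assert_allclose(fused.data, expected, atol=1e-10)

    def test_weights_sum_to_one_on_any_forward(self, rng):
        net = MultigraphAutoencoder(n_genes=6, hidden_dims=(5, 4),
                                    latent_dim=3, seed=3)
        X = rng.normal(size=(7, 6))
        tri = np.triu((rng.random((7, 7)) < 0.4), 1) * 1.0
        g = _graph(tri + tri.T)
        _, alpha, _ = net.forward(X, g, g)
        np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-12)
        assert (alpha >= 0).all()


class TestSpatialLoss:
    def test_perfect_reconstruction_limit(self):
        # strongly negative logits against an empty graph: loss -> 0
        Z = ad.Tensor(np.full((3, 3), -40.0))
        loss = ad.bce_logits_mean(Z, np.zeros((3, 3)))
        assert loss.item() == pytest.approx(0.0, abs=1e-12)

    def test_zero_embedding_gives_ln2_per_pair(self):
        H = np.zeros((4, 2))
        loss = spatial_reconstruction_loss(H, _empty_graph(4))
        assert loss.item() == pytest.approx(np.log(2.0), abs=1e-12)

    def test_two_cell_hand_sum(self):
        g = _graph([[0, 1], [1, 0]])
        H = np.array([[1.0, 0.5], [-0.25, 2.0]])
        Z = H @ H.T
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        expected = 0.0
        for i in range(2):
            for j in range(2):
                z, y = Z[i, j], A[i, j]
                expected += np.log1p(np.exp(z)) - z * y
        expected /= 4
        loss = spatial_reconstruction_loss(H, g)
        assert loss.item() == pytest.approx(expected, abs=1e-10)


class TestZinb:
    def test_hand_case_zero_count(self):
        params = ZinbParams(pi=[[0.5]], mu=[[1.0]], theta=[[1.0]])
        # NB(0) = (1/2)^1; pmf = 0.5 + 0.5 * 0.5 = 0.75
        assert zinb_nll(np.array([[0.0]]), params) == pytest.approx(
            -np.log(0.75), abs=1e-12
        )

    def test_pi_to_zero_reduces_to_nb(self, rng):
        x = rng.poisson(3.0, size=(3, 4)).astype(float)
        mu = rng.uniform(0.5, 4.0, size=(3, 4))
        theta = rng.uniform(0.5, 3.0, size=(3, 4))
        from scipy.stats import nbinom

        nb_nll = -nbinom.logpmf(x, theta, theta / (theta + mu)).sum()
        ours = zinb_nll(x, ZinbParams(np.full_like(mu, 1e-14), mu, theta))
        assert ours == pytest.approx(nb_nll, rel=1e-9)

    def test_matches_oracle_on_random_grid(self, rng):
        x = rng.poisson(2.0, size=(10, 10)).astype(float)
        pi = rng.uniform(0.05, 0.9, size=(10, 10))
        mu = rng.uniform(0.1, 8.0, size=(10, 10))
        theta = rng.uniform(0.2, 5.0, size=(10, 10))
        ours = zinb_nll(x, ZinbParams(pi, mu, theta))
        naive = naive_zinb_nll(x, pi, mu, theta)
        assert ours == pytest.approx(naive, abs=1e-8)

    def test_pmf_normalizes(self):
        pi, mu, theta = 0.3, 2.5, 1.7
        xs = np.arange(0, 500, dtype=float).reshape(-1, 1)
        lp = -np.array(
            [
                zinb_nll(
                    np.array([[x]]),
                    ZinbParams([[pi]], [[mu]], [[theta]]),
                )
                for x in xs.ravel()
            ]
        )
        assert np.exp(lp).sum() == pytest.approx(1.0, abs=1e-6)

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError):
            zinb_nll(
                np.array([[1.5]]), ZinbParams([[0.2]], [[1.0]], [[1.0]])
            )

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ZinbParams([[1.2]], [[1.0]], [[1.0]])
        with pytest.raises(ValueError):
            ZinbParams([[0.5]], [[-1.0]], [[1.0]])
        with pytest.raises(ValueError):
            ZinbParams([[0.5]], [[1.0]], [[0.0]])


class TestTotalLoss:
    def test_lambda_zero_keeps_zinb_only(self):
        assert total_loss(4.2, 9.9, 0.0) == 4.2

    def test_simple_sum(self):
        assert total_loss(2.0, 3.0, 1.0) == 5.0

    def test_linear_in_lambda(self):
        l_z, l_s = 1.3, 0.7
        vals = [(lam, total_loss(l_z, l_s, lam)) for lam in (0.0, 1.0, 2.0)]
        slope = np.polyfit([v[0] for v in vals], [v[1] for v in vals], 1)[0]
        assert slope == pytest.approx(l_s, abs=1e-12)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            total_loss(1.0, 1.0, -0.5)


class TestTrainingStep:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_one_small_step_decreases_loss(self, seed):
        rng = np.random.default_rng(seed)
        n, g = 12, 8
        X = rng.normal(size=(n, g))
        raw = rng.poisson(2.0, size=(n, g)).astype(float)
        sf = np.ones(n)
        adj = np.triu(rng.random((n, n)) < 0.3, 1) * 1.0
        graph = _graph(adj + adj.T)
        net = MultigraphAutoencoder(n_genes=g, hidden_dims=(6, 4),
                                    latent_dim=3, seed=seed)
        opt = ad.Adam(net.params, lr=1e-4)
        loss0, _, _, _ = net.loss(X, raw, graph, graph, sf)
        loss0.backward()
        opt.step()
        loss1, _, _, _ = net.loss(X, raw, graph, graph, sf)
        assert loss1.item() < loss0.item()
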