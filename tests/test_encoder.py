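"""Mean-pooling encoder, classification head, BCE loss and gradients."""

import numpy as np
import pytest
import scipy.sparse as sp

from cliqueflux import EncoderModel, bce_loss, encode, mean_pool_layer, predict
from cliqueflux import encoder as enc

from conftest import adjacency_from_edges, random_graph


def finite_difference_grads(x, p, model, y, batch, eps=1e-6):
    """Central finite differences of the full batched loss w.r.t. every
    parameter entry; independent of the analytic backward pass."""
    grads = {}
    for name in ("theta1", "theta2", "head_weights"):
        arr = getattr(model, name)
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            old = arr[idx]
            arr[idx] = old + eps
            lp, _ = enc.forward_loss(x, p, model, y, batch)
            arr[idx] = old - eps
            lm, _ = enc.forward_loss(x, p, model, y, batch)
            arr[idx] = old
            g[idx] = (lp - lm) / (2 * eps)
        grads[name] = g
    old = model.head_bias
    model.head_bias = old + eps
    lp, _ = enc.forward_loss(x, p, model, y, batch)
    model.head_bias = old - eps
    lm, _ = enc.forward_loss(x, p, model, y, batch)
    model.head_bias = old
    grads["head_bias"] = (lp - lm) / (2 * eps)
    return grads


class TestMeanPool:
    def test_isolated_node_identity(self):
        a = sp.csr_matrix((1, 1))
        h = np.array([[2.0, 3.0]])
        out = mean_pool_layer(h, a, np.eye(2))
        np.testing.assert_allclose(out, h)

    def test_zero_theta_zero_output(self):
        a = adjacency_from_edges(3, [(0, 1), (1, 2)])
        out = mean_pool_layer(np.random.default_rng(0).normal(size=(3, 4)), a, np.zeros((4, 2)))
        assert (out == 0).all()

    def test_two_node_average(self):
        a = adjacency_from_edges(2, [(0, 1)])
        out = mean_pool_layer(np.array([[2.0], [4.0]]), a, np.eye(1))
        np.testing.assert_allclose(out, [[3.0], [3.0]])  # (self + neighbour)/2

    def test_rows_of_propagation_sum_to_one(self):
        for seed in range(20):
            g = random_graph(15, 0.3, seed=seed)
            w = g.adjacency.astype(float)
            w.data *= np.random.default_rng(seed).integers(1, 6, size=w.nnz)
            p = enc.normalized_propagation(w)
            np.testing.assert_allclose(np.asarray(p.sum(axis=1)).ravel(), 1.0, atol=1e-9)

    def test_dimension_mismatch_rejected(self):
        a = adjacency_from_edges(2, [(0, 1)])
        with pytest.raises(ValueError, match="theta"):
            mean_pool_layer(np.ones((2, 3)), a, np.eye(4))

    def test_clique_weight_pulls_toward_neighbour(self):
        # node 0 linked to nodes 1 (weight w) and 2 (weight 1); raising w
        # moves node 0's pre-activation strictly toward x_1.
        x = np.array([[0.0], [10.0], [-10.0]])
        vals = []
        for w in (1, 3, 9):
            a = adjacency_from_edges(3, [(0, 1, w), (0, 2, 1)])
            p = enc.normalized_propagation(a)
            vals.append((p @ x)[0, 0])
        assert vals[0] < vals[1] < vals[2]


class TestEncodePredictLoss:
    def test_zero_parameters_zero_embeddings(self):
        a = adjacency_from_edges(3, [(0, 1)])
        m = EncoderModel(theta1=np.zeros((2, 4)), theta2=np.zeros((4, 4)),
                         head_weights=np.zeros(4), head_bias=0.0)
        assert (encode(np.ones((3, 2)), a, m) == 0).all()

    def test_edgeless_graph_is_per_node_mlp(self):
        x = np.random.default_rng(1).normal(size=(6, 5))
        m = EncoderModel.init(5, 4, seed=2)
        a = sp.csr_matrix((6, 6))
        got = encode(x, a, m)
        expect = np.maximum(np.maximum(x @ m.theta1, 0) @ m.theta2, 0)
        np.testing.assert_allclose(got, expect)

    def test_symmetric_pair_equal_embeddings(self):
        x = np.vstack([np.ones(3), np.ones(3)])
        m = EncoderModel.init(3, 4, seed=0)
        a = adjacency_from_edges(2, [(0, 1)])
        e = encode(x, a, m)
        np.testing.assert_allclose(e[0], e[1])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        g = random_graph(12, 0.4, seed=5)
        x = rng.normal(size=(12, 6))
        m = EncoderModel.init(6, 4, seed=6)
        perm = rng.permutation(12)
        pm = sp.csr_matrix((np.ones(12), (np.arange(12), perm)), shape=(12, 12))
        a_perm = pm @ g.adjacency @ pm.T
        # relabelled graph: node i holds old node perm[i] -> embeddings permute
        np.testing.assert_allclose(
            encode(x[perm], a_perm, m), encode(x, g.adjacency, m)[perm], atol=1e-12
        )

    def test_predict_zero_gives_half_and_clamped(self):
        m = EncoderModel(theta1=np.eye(2), theta2=np.eye(2), head_weights=np.zeros(2), head_bias=0.0)
        p = predict(np.zeros((4, 2)), m)
        np.testing.assert_allclose(p.scores, 0.5)
        m.head_bias = 1e9
        s = predict(np.zeros((4, 2)), m).scores
        assert (s < 1.0).all() and (s >= 1.0 - 2e-7).all()

    @pytest.mark.parametrize(
        "scores, labels, expected",
        [
            ([1 - 1e-7, 1e-7], [1, 0], pytest.approx(0.0, abs=1e-6)),
            ([0.5, 0.5, 0.5], [1, 0, 1], pytest.approx(np.log(2))),
            ([0.9, 0.1], [1, 0], pytest.approx(-np.log(0.9))),
        ],
    )
    def test_bce_known_values(self, scores, labels, expected):
        assert bce_loss(np.array(scores), np.array(labels)) == expected

    def test_bce_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            bce_loss(np.array([0.5]), np.array([1, 0]))


class TestGradients:
    def test_analytic_matches_finite_differences(self):
        """Full loss (BCE o predict o encode) on a 5-node instance: relative
        error below 1e-4 for every parameter block."""
        rng = np.random.default_rng(42)
        g = random_graph(5, 0.6, seed=42)
        x = rng.normal(size=(5, 3))
        y = np.array([1, 0, 1, 0, 1])
        m = EncoderModel.init(3, 4, seed=43)
        p = enc.normalized_propagation(g.adjacency)
        batch = np.arange(5)
        _, cache = enc.forward_loss(x, p, m, y, batch)
        analytic = enc.backward(p, m, cache)
        numeric = finite_difference_grads(x, p, m, y, batch)
        for name in ("theta1", "theta2", "head_weights", "head_bias"):
            a = np.atleast_1d(np.asarray(analytic[name]))
            n = np.atleast_1d(np.asarray(numeric[name]))
            denom = np.maximum(np.maximum(np.abs(a), np.abs(n)), 1e-8)
            assert (np.abs(a - n) / denom).max() < 1e-4

    def test_adam_reduces_loss(self):
        rng = np.random.default_rng(3)
        g = random_graph(20, 0.3, seed=3)
        x = rng.normal(size=(20, 6))
        y = (rng.random(20) < 0.5).astype(int)
        m = EncoderModel.init(6, 8, seed=4)
        p = enc.normalized_propagation(g.adjacency)
        opt = enc.Adam(m, lr=0.01)
        batch = np.arange(20)
        first, _ = enc.forward_loss(x, p, m, y, batch)
        for _ in range(200):
            loss, cache = enc.forward_loss(x, p, m, y, batch)
            opt.step(m, enc.backward(p, m, cache))
        assert loss < first * 0.5
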