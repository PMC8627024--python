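"""GCN layers, readout, full forward pass and analytic gradients."""

import numpy as np
import pytest

from moltox import (
    GCNConfig,
    GraphBatch,
    gcn_layer_forward,
    init_weights,
    load_checkpoint,
    model_forward,
    normalized_adjacency,
    readout,
    save_checkpoint,
    smiles_to_graph,
)
from moltox.gcn import backward, forward, trainable_keys
from moltox.mean_teacher import _classification_loss_grad


def random_graph(rng, n):
    A = np.triu((rng.random((n, n)) < 0.5).astype(float), 1)
    return A + A.T


class TestNormalizedAdjacency:
    def test_isolated_node(self):
        assert np.allclose(normalized_adjacency(np.zeros((1, 1))), [[1.0]])

    def test_single_edge_pair(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert np.allclose(normalized_adjacency(A), 0.5 * np.ones((2, 2)))

    def test_symmetric_nonnegative(self, rng):
        for n in (2, 3, 5, 8):
            A_hat = normalized_adjacency(random_graph(rng, n))
            assert np.allclose(A_hat, A_hat.T)
            assert np.all(A_hat >= 0)

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError):
            normalized_adjacency(np.array([[0.0, 1.0], [0.0, 0.0]]))

    def test_rejects_self_loops(self):
        with pytest.raises(ValueError):
            normalized_adjacency(np.eye(2))


class TestConvLayer:
    def test_single_node_identity_weights(self, rng):
        h = rng.normal(size=(1, 4))
        out = gcn_layer_forward(h, np.zeros((1, 1)), np.eye(4), np.zeros(4))
        assert np.allclose(out, np.maximum(h, 0.0))

    def test_two_connected_nodes_average(self, rng):
        H = rng.normal(size=(2, 3))
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        out = gcn_layer_forward(H, A, np.eye(3), np.zeros(3))
        expected = np.maximum((H[0] + H[1]) / 2.0, 0.0)
        assert np.allclose(out[0], expected) and np.allclose(out[1], expected)

    def test_nodewise_sum_matches_matrix_form(self, rng):
        """The per-node neighbourhood sum (self included, weights
        1/sqrt(|N(i)||N(j)|)) equals the normalised matrix product."""
        for _ in range(100):
            n = int(rng.integers(1, 6))
            A = random_graph(rng, n)
            H = rng.normal(size=(n, 3))
            W = rng.normal(size=(3, 2))
            b = rng.normal(size=2)
            deg = A.sum(axis=1) + 1.0  # neighbourhood size including self
            expected = np.empty((n, 2))
            for i in range(n):
                acc = np.zeros(2)
                for j in range(n):
                    if A[i, j] or i == j:
                        acc += (H[j] @ W) / np.sqrt(deg[i] * deg[j])
                expected[i] = np.maximum(b + acc, 0.0)
            got = gcn_layer_forward(H, A, W, b)
            assert np.max(np.abs(got - expected)) <= 1e-10

    def test_outputs_nonnegative(self, rng):
        out = gcn_layer_forward(rng.normal(size=(4, 3)), random_graph(rng, 4),
                                rng.normal(size=(3, 5)), rng.normal(size=5))
        assert np.all(out >= 0)


class TestReadout:
    def test_single_node_halves(self, rng):
        h = rng.normal(size=(1, 3))
        gw, gb = rng.normal(size=(3, 1)), np.array([0.1])
        out = readout(h, gw, gb)
        gate = 1.0 / (1.0 + np.exp(-(h @ gw).ravel() - 0.1))
        assert np.allclose(out[:3], h[0])
        assert np.allclose(out[3:], gate * h[0])
        assert 0.0 < gate < 1.0

    def test_permutation_invariance(self, rng):
        H = rng.normal(size=(5, 4))
        gw, gb = rng.normal(size=(4, 1)), np.array([-0.3])
        perm = rng.permutation(5)
        assert np.allclose(readout(H, gw, gb), readout(H[perm], gw, gb))

    def test_forced_gates_hand_example(self):
        H = np.array([[1.0, 0.0], [0.0, 1.0]])
        # very large bias forces every gate to ~1
        out = readout(H, np.zeros((2, 1)), np.array([500.0]))
        assert np.allclose(out, [1.0, 1.0, 1.0, 1.0])


@pytest.fixture(scope="module")
def setup():
    cfg = GCNConfig(hidden_dims=(8, 8), dropout_rates=(0.2, 0.2),
                    mlp_hidden_dim=6)
    params = init_weights(cfg, np.random.default_rng(0))
    return cfg, params


class TestModelForward:
    def test_probabilities_sum_to_one(self, setup):
        cfg, params = setup
        p = model_forward(smiles_to_graph("CCO"), params, cfg)
        assert p.shape == (2,)
        assert abs(p.sum() - 1.0) < 1e-12

    def test_eval_mode_deterministic(self, setup):
        cfg, params = setup
        g = smiles_to_graph("c1ccccc1O")
        assert np.array_equal(model_forward(g, params, cfg),
                              model_forward(g, params, cfg))

    def test_prediction_invariant_to_atom_relabeling(self, setup):
        """Different SMILES spellings of one molecule score identically."""
        cfg, params = setup
        for a, b in [("OCC", "CCO"), ("c1ccccc1C", "Cc1ccccc1")]:
            pa = model_forward(smiles_to_graph(a), params, cfg)
            pb = model_forward(smiles_to_graph(b), params, cfg)
            assert np.max(np.abs(pa - pb)) < 1e-8

    def test_conv_permutation_equivariance(self, rng):
        H = rng.normal(size=(5, 3))
        A = random_graph(rng, 5)
        W, b = rng.normal(size=(3, 4)), rng.normal(size=4)
        perm = rng.permutation(5)
        P = np.eye(5)[perm]
        out = gcn_layer_forward(H, A, W, b)
        out_p = gcn_layer_forward(H[perm], P @ A @ P.T, W, b)
        assert np.allclose(out_p, out[perm])


def test_gradients_match_finite_differences():
    """Analytic backward pass vs central differences through the full net."""
    rng = np.random.default_rng(7)
    cfg = GCNConfig(hidden_dims=(6, 6), dropout_rates=(0.25, 0.25),
                    mlp_hidden_dim=5)
    graphs = [smiles_to_graph(s) for s in ("CCO", "c1ccccc1", "CC(=O)O")]
    batch = GraphBatch.from_graphs(graphs)
    params = init_weights(cfg, rng)
    labels = np.array([0.0, 1.0, np.nan])

    def loss(p):
        z, cache = forward(p, batch, cfg, mode="train",
                           rng=np.random.default_rng(99), update_stats=False)
        l, dl = _classification_loss_grad(z, labels)
        return l, dl, cache

    _, dl, cache = loss(params)
    grads = backward(params, cache, dl)
    eps = 1e-6
    for key in trainable_keys(params):
        g = grads[key]
        for flat in rng.choice(g.size, size=min(4, g.size), replace=False):
            idx = np.unravel_index(flat, g.shape)
            p2 = {k: v.copy() for k, v in params.items()}
            p2[key][idx] += eps
            lp, _, _ = loss(p2)
            p2[key][idx] -= 2 * eps
            lm, _, _ = loss(p2)
            assert abs((lp - lm) / (2 * eps) - g[idx]) < 1e-6, key


def test_checkpoint_roundtrip(tmp_path):
    cfg = GCNConfig(hidden_dims=(4, 4), dropout_rates=(0.0, 0.0),
                    mlp_hidden_dim=3)
    params = init_weights(cfg, np.random.default_rng(1))
    path = tmp_path / "model.json"
    save_checkpoint(path, params, cfg)
    params2, cfg2 = load_checkpoint(path)
    assert cfg2 == cfg
    assert all(np.array_equal(params[k], params2[k]) for k in params)
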