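"""Graph convolutional classifier over molecular graphs.

The network follows the standard symmetric-normalised propagation rule

    H^(l+1) = ReLU(b^(l) + D̃^{-1/2} (A + I) D̃^{-1/2} H^(l) W^(l))

stacked in blocks of graph convolution -> ReLU -> dropout -> batch
normalisation, followed by a permutation-invariant readout (per-dimension
max-pool concatenated with a sigmoid-gated weighted sum over nodes) and a
two-layer perceptron emitting softmax probabilities over the two classes.

The forward and backward passes are implemented directly in NumPy over a
block-diagonal batch of graphs; gradient correctness is pinned down by
finite-difference tests rather than a framework autograd.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.sparse as sp

from .features import FEATURE_WIDTH, MolecularGraph, smiles_to_graph

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1  # fraction of the batch statistic blended into running stats


@dataclass
class GCNConfig:
    """Architecture hyperparameters of the GCN classifier."""

    n_conv_blocks: int = 2
    hidden_dims: tuple[int, ...] = (64, 64)
    dropout_rates: tuple[float, ...] = (0.1, 0.1)
    mlp_hidden_dim: int = 64
    n_classes: int = 2
    in_dim: int = FEATURE_WIDTH

    def __post_init__(self):
        self.hidden_dims = tuple(self.hidden_dims)
        self.dropout_rates = tuple(self.dropout_rates)
        if self.n_conv_blocks < 1:
            raise ValueError("n_conv_blocks must be >= 1")
        if len(self.hidden_dims) != self.n_conv_blocks:
            raise ValueError("hidden_dims length must equal n_conv_blocks")
        if len(self.dropout_rates) != self.n_conv_blocks:
            raise ValueError("dropout_rates length must equal n_conv_blocks")
        if any(not (0.0 <= p < 1.0) for p in self.dropout_rates):
            raise ValueError("dropout rates must lie in [0, 1)")


def normalized_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric-normalised propagation matrix D̃^{-1/2}(A+I)D̃^{-1/2}.

    ``A`` must be a symmetric 0/1 matrix with zero diagonal; the self-loop is
    added here, so the neighbourhood of every node includes itself.
    """
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(A) != 0):
        raise ValueError("adjacency must have zero diagonal (self-loops are implicit)")
    A_tilde = A + np.eye(A.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(A_tilde.sum(axis=1))
    return A_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def gcn_layer_forward(
    H: np.ndarray, A: np.ndarray, W: np.ndarray, b: np.ndarray
) -> np.ndarray:
    """One graph-convolution layer: ReLU(b + Â H W) on a single graph."""
    H = np.asarray(H, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    if H.shape[1] != W.shape[0]:
        raise ValueError(f"signal width {H.shape[1]} != weight rows {W.shape[0]}")
    A_hat = normalized_adjacency(A)
    return np.maximum(0.0, b + A_hat @ H @ W)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def readout(H: np.ndarray, gate_W: np.ndarray, gate_b: np.ndarray) -> np.ndarray:
    """Graph-level readout for a single graph: concat(max-pool, gated sum).

    The gated sum weights every node signal by a sigmoid of a learned linear
    map of that signal; both halves are invariant to node permutation.
    """
    H = np.asarray(H, dtype=np.float64)
    if H.ndim != 2 or H.shape[0] < 1:
        raise ValueError("readout requires at least one node")
    gates = _sigmoid(H @ gate_W.reshape(-1) + float(np.asarray(gate_b).reshape(())))
    return np.concatenate([H.max(axis=0), (gates[:, None] * H).sum(axis=0)])


# ---------------------------------------------------------------------------
# parameters

def init_weights(cfg: GCNConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Glorot-uniform initialisation of all learnable parameters.

    Batch-norm running statistics live in the same dictionary (keys ending in
    ``bn_mean`` / ``bn_var``) but are excluded from gradient updates.
    """
    params: dict[str, np.ndarray] = {}

    def glorot(d_in, d_out):
        limit = np.sqrt(6.0 / (d_in + d_out))
        return rng.uniform(-limit, limit, size=(d_in, d_out))

    d_prev = cfg.in_dim
    for l, d in enumerate(cfg.hidden_dims):
        params[f"conv{l}.W"] = glorot(d_prev, d)
        params[f"conv{l}.b"] = np.zeros(d)
        params[f"conv{l}.bn_gamma"] = np.ones(d)
        params[f"conv{l}.bn_beta"] = np.zeros(d)
        params[f"conv{l}.bn_mean"] = np.zeros(d)
        params[f"conv{l}.bn_var"] = np.ones(d)
        d_prev = d

    params["readout.gate_W"] = glorot(d_prev, 1)
    params["readout.gate_b"] = np.zeros(1)

    params["mlp.W1"] = glorot(2 * d_prev, cfg.mlp_hidden_dim)
    params["mlp.b1"] = np.zeros(cfg.mlp_hidden_dim)
    params["mlp.W2"] = glorot(cfg.mlp_hidden_dim, cfg.n_classes)
    params["mlp.b2"] = np.zeros(cfg.n_classes)
    return params


def trainable_keys(params: dict[str, np.ndarray]) -> list[str]:
    return [k for k in params if not (k.endswith("bn_mean") or k.endswith("bn_var"))]


def copy_weights(params: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    return {k: v.copy() for k, v in params.items()}


# ---------------------------------------------------------------------------
# batching

@dataclass
class GraphBatch:
    """Block-diagonal stacking of several molecular graphs."""

    X: np.ndarray              # (N_total, in_dim) stacked node features
    A_hat: sp.csr_matrix       # (N_total, N_total) block-diagonal propagation
    graph_ids: np.ndarray      # (N_total,) graph index per node
    n_graphs: int

    @classmethod
    def from_graphs(cls, graphs: list[MolecularGraph]) -> "GraphBatch":
        if not graphs:
            raise ValueError("empty batch")
        X = np.vstack([g.features for g in graphs])
        A_hat = sp.block_diag(
            [sp.csr_matrix(normalized_adjacency(g.adjacency)) for g in graphs],
            format="csr",
        )
        graph_ids = np.concatenate(
            [np.full(g.n_atoms, i, dtype=np.int64) for i, g in enumerate(graphs)]
        )
        return cls(X=X, A_hat=A_hat, graph_ids=graph_ids, n_graphs=len(graphs))


def _segment_sum(values: np.ndarray, ids: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((n,) + values.shape[1:])
    np.add.at(out, ids, values)
    return out


# ---------------------------------------------------------------------------
# forward / backward

def forward(
    params: dict[str, np.ndarray],
    batch: GraphBatch,
    cfg: GCNConfig,
    mode: str = "eval",
    rng: np.random.Generator | None = None,
    update_stats: bool = True,
):
    """Batched forward pass.

    Returns ``(probs, cache)`` where ``probs`` is (n_graphs, n_classes) and
    ``cache`` holds every intermediate needed by :func:`backward`.  In train
    mode dropout is active (requires ``rng``) and batch normalisation uses
    batch statistics, optionally updating the running statistics in-place.
    Eval mode is deterministic and uses the running statistics.
    """
    if mode not in ("train", "eval"):
        raise ValueError(f"unknown mode {mode!r}")
    train = mode == "train"
    if train and rng is None:
        raise ValueError("train mode requires an rng for dropout")

    X = batch.X
    cache: dict = {"batch": batch, "cfg": cfg, "mode": mode, "blocks": []}
    for l in range(cfg.n_conv_blocks):
        W, b = params[f"conv{l}.W"], params[f"conv{l}.b"]
        AX = batch.A_hat @ X
        Z = AX @ W + b
        relu_mask = Z > 0
        R = Z * relu_mask

        p = cfg.dropout_rates[l]
        if train and p > 0.0:
            drop_mask = (rng.random(R.shape) >= p) / (1.0 - p)
        else:
            drop_mask = None
        D = R * drop_mask if drop_mask is not None else R

        gamma, beta = params[f"conv{l}.bn_gamma"], params[f"conv{l}.bn_beta"]
        if train:
            mu = D.mean(axis=0)
            var = D.var(axis=0)
            if update_stats:
                params[f"conv{l}.bn_mean"] *= 1.0 - _BN_MOMENTUM
                params[f"conv{l}.bn_mean"] += _BN_MOMENTUM * mu
                params[f"conv{l}.bn_var"] *= 1.0 - _BN_MOMENTUM
                params[f"conv{l}.bn_var"] += _BN_MOMENTUM * var
        else:
            mu = params[f"conv{l}.bn_mean"]
            var = params[f"conv{l}.bn_var"]
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        x_hat = (D - mu) * inv_std
        out = gamma * x_hat + beta

        cache["blocks"].append(
            dict(X=X, AX=AX, relu_mask=relu_mask, drop_mask=drop_mask,
                 x_hat=x_hat, inv_std=inv_std, l=l)
        )
        X = out

    # readout: per-graph max pool + sigmoid-gated weighted sum
    H = X
    ids = batch.graph_ids
    B, d = batch.n_graphs, H.shape[1]
    maxpool = np.full((B, d), -np.inf)
    np.maximum.at(maxpool, ids, H)
    # recover argmax rows for the backward routing; ties go to the first node
    is_max = H == maxpool[ids]
    node_index = np.arange(H.shape[0])
    argmax = np.full((B, d), H.shape[0], dtype=np.int64)
    for j in range(d):
        rows = node_index[is_max[:, j]]
        np.minimum.at(argmax[:, j], ids[rows], rows)

    gate_lin = H @ params["readout.gate_W"].reshape(-1) + params["readout.gate_b"][0]
    gates = _sigmoid(gate_lin)
    wsum = _segment_sum(gates[:, None] * H, ids, B)
    graph_vec = np.concatenate([maxpool, wsum], axis=1)

    h1 = graph_vec @ params["mlp.W1"] + params["mlp.b1"]
    r1 = np.maximum(0.0, h1)
    logits = r1 @ params["mlp.W2"] + params["mlp.b2"]
    shifted = logits - logits.max(axis=1, keepdims=True)
    expz = np.exp(shifted)
    probs = expz / expz.sum(axis=1, keepdims=True)

    cache.update(
        H=H, gates=gates, argmax=argmax, graph_vec=graph_vec,
        h1=h1, r1=r1, probs=probs,
    )
    return probs, cache


def backward(
    params: dict[str, np.ndarray], cache: dict, dlogits: np.ndarray
) -> dict[str, np.ndarray]:
    """Gradients of a scalar loss w.r.t. all trainable parameters.

    ``dlogits`` is the loss gradient at the pre-softmax logits (softmax and
    loss derivatives are folded together by the caller).
    """
    if cache["mode"] != "train":
        raise ValueError("backward requires a train-mode cache")
    batch: GraphBatch = cache["batch"]
    cfg: GCNConfig = cache["cfg"]
    ids = batch.graph_ids
    grads: dict[str, np.ndarray] = {}

    # MLP head
    r1, h1, graph_vec = cache["r1"], cache["h1"], cache["graph_vec"]
    grads["mlp.W2"] = r1.T @ dlogits
    grads["mlp.b2"] = dlogits.sum(axis=0)
    dr1 = dlogits @ params["mlp.W2"].T
    dh1 = dr1 * (h1 > 0)
    grads["mlp.W1"] = graph_vec.T @ dh1
    grads["mlp.b1"] = dh1.sum(axis=0)
    dgraph_vec = dh1 @ params["mlp.W1"].T

    # readout
    H, gates, argmax = cache["H"], cache["gates"], cache["argmax"]
    d = H.shape[1]
    dmax, dwsum = dgraph_vec[:, :d], dgraph_vec[:, d:]
    dH = np.zeros_like(H)
    cols = np.tile(np.arange(d), cache["probs"].shape[0])
    np.add.at(dH, (argmax.ravel(), cols), dmax.ravel())

    dw_per_node = dwsum[ids]                       # (N, d)
    dot = (dw_per_node * H).sum(axis=1)            # (N,)
    dgate = dot * gates * (1.0 - gates)            # (N,)
    gw = params["readout.gate_W"].reshape(-1)
    dH += gates[:, None] * dw_per_node + dgate[:, None] * gw[None, :]
    grads["readout.gate_W"] = (H.T @ dgate).reshape(-1, 1)
    grads["readout.gate_b"] = np.array([dgate.sum()])

    # conv blocks in reverse
    dout = dH
    for blk in reversed(cache["blocks"]):
        l = blk["l"]
        gamma = params[f"conv{l}.bn_gamma"]
        x_hat, inv_std = blk["x_hat"], blk["inv_std"]
        n_nodes = x_hat.shape[0]

        grads[f"conv{l}.bn_beta"] = dout.sum(axis=0)
        grads[f"conv{l}.bn_gamma"] = (dout * x_hat).sum(axis=0)
        dxhat = dout * gamma
        dD = inv_std * (
            dxhat
            - dxhat.mean(axis=0)
            - x_hat * (dxhat * x_hat).mean(axis=0)
        )
        if n_nodes == 1:
            # variance of a single sample is constant zero; only the shift acts
            dD = np.zeros_like(dD)

        dR = dD * blk["drop_mask"] if blk["drop_mask"] is not None else dD
        dZ = dR * blk["relu_mask"]
        grads[f"conv{l}.W"] = blk["AX"].T @ dZ
        grads[f"conv{l}.b"] = dZ.sum(axis=0)
        dAX = dZ @ params[f"conv{l}.W"].T
        dout = batch.A_hat.T @ dAX

    return grads


def model_forward(
    graph: MolecularGraph,
    params: dict[str, np.ndarray],
    cfg: GCNConfig,
    mode: str = "eval",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Class probabilities for a single molecular graph."""
    probs, _ = forward(params, GraphBatch.from_graphs([graph]), cfg, mode, rng,
                       update_stats=False)
    return probs[0]


def predict_proba(
    params: dict[str, np.ndarray],
    cfg: GCNConfig,
    graphs: list[MolecularGraph],
) -> np.ndarray:
    """Deterministic toxic-class probability for each graph (eval mode)."""
    probs, _ = forward(params, GraphBatch.from_graphs(graphs), cfg, mode="eval")
    return probs[:, 1]


def predict_smiles(
    params: dict[str, np.ndarray], cfg: GCNConfig, smiles: list[str]
) -> np.ndarray:
    return predict_proba(params, cfg, [smiles_to_graph(s) for s in smiles])


# ---------------------------------------------------------------------------
# checkpointing (JSON tensor dump)

def save_checkpoint(path, params: dict[str, np.ndarray], cfg: GCNConfig) -> None:
    payload = {
        "format_version": 1,
        "gcn_config": asdict(cfg),
        "params": {k: v.tolist() for k, v in params.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_checkpoint(path) -> tuple[dict[str, np.ndarray], GCNConfig]:
    with open(path) as fh:
        payload = json.load(fh)
    cfg = GCNConfig(**payload["gcn_config"])
    params = {k: np.asarray(v, dtype=np.float64) for k, v in payload["params"].items()}
    return params, cfg
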