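"""Mean-Teacher semi-supervised training for the GCN classifier.

Two shape-identical models are maintained: a *student*, trained by Adam on
the sum of a masked cross-entropy classification loss (labeled data) and a
ramped mean-squared consistency loss between the two models' probability
outputs (unlabeled data), and a *teacher*, whose weights are the exponential
moving average of the student's

    θ_t(i) = α_i θ_t(i-1) + (1 - α_i) θ_s(i).

Inputs are perturbed with independent Gaussian noise for the two forward
passes; the consistency coefficient follows the sigmoid-shaped ramp
w(t) = exp(-5 (1 - t)^2) with t the scaled training step.  The teacher is
the deployed model: early stopping and model selection use its validation
ROC-AUC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .features import MolecularGraph, smiles_to_graph
from .gcn import (
    GCNConfig,
    GraphBatch,
    backward,
    copy_weights,
    forward,
    init_weights,
    predict_proba,
    trainable_keys,
)

logger = logging.getLogger(__name__)

_CLAMP = 1e-12


@dataclass
class MTConfig:
    """Mean-Teacher training hyperparameters.

    ``r_u`` is the unlabeled-to-labeled data ratio; ``r_u = 0`` disables the
    consistency term entirely and the run degenerates to plain supervised
    training (the SL-GCN arm).  ``alpha_max`` caps the EMA smoothing
    coefficient, which warms up as α_i = min(1 - 1/(i+1), alpha_max).
    ``ramp_fraction`` is the fraction of the total training steps over which
    the consistency ramp rises from exp(-5) to 1.
    """

    r_u: float = 1.0
    noise_sigma: float = 0.1
    alpha_max: float = 0.999
    ramp_fraction: float = 1.0
    lr: float = 5e-3
    batch_size: int = 16
    max_epochs: int = 200
    patience: int = 30
    seed: int = 0
    consistency_on_labeled: bool = False

    def __post_init__(self):
        if self.r_u < 0:
            raise ValueError("r_u must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not (0.0 <= self.alpha_max < 1.0):
            raise ValueError("alpha_max must lie in [0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class TrainState:
    """Mutable state threaded through training steps."""

    step: int
    theta_s: dict[str, np.ndarray]
    theta_t: dict[str, np.ndarray]
    total_ramp_steps: int
    w: float = 0.0
    z: np.ndarray | None = None
    z_tilde: np.ndarray | None = None
    loss_cls: float = 0.0
    loss_con: float = 0.0
    best_val_auc: float = -np.inf
    epochs_since_best: int = 0


def perturb(
    features: np.ndarray, noise_sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Add i.i.d. Gaussian noise to a feature matrix (identity at σ = 0)."""
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if noise_sigma == 0.0:
        return features
    return features + rng.normal(0.0, noise_sigma, size=features.shape)


def consistency_weight(step: int, total_ramp_steps: int) -> float:
    """Ramp coefficient w = exp(-5 (1-t)^2) with t = min(step / total, 1)."""
    if step < 0:
        raise ValueError("step must be non-negative")
    if total_ramp_steps < 1:
        raise ValueError("total_ramp_steps must be >= 1")
    t = min(step / total_ramp_steps, 1.0)
    return math.exp(-5.0 * (1.0 - t) ** 2)


def classification_loss(z: np.ndarray, labels: np.ndarray) -> float:
    """Masked mean cross-entropy; missing labels (NaN) contribute nothing."""
    loss, _ = _classification_loss_grad(z, labels)
    return loss


def _classification_loss_grad(
    z: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    labels = np.asarray(labels, dtype=np.float64)
    mask = ~np.isnan(labels)
    observed = labels[mask]
    if observed.size and not np.all(np.isin(observed, (0.0, 1.0))):
        raise ValueError("labels must be 0, 1 or missing (NaN)")
    dlogits = np.zeros_like(z)
    n_eff = int(mask.sum())
    if n_eff == 0:
        return 0.0, dlogits
    y = observed.astype(np.int64)
    p_true = np.clip(z[mask, y], _CLAMP, 1.0)
    loss = float(-np.log(p_true).mean())
    onehot = np.zeros((n_eff, z.shape[1]))
    onehot[np.arange(n_eff), y] = 1.0
    dlogits[mask] = (z[mask] - onehot) / n_eff
    return loss, dlogits


def consistency_loss(z: np.ndarray, z_tilde: np.ndarray) -> float:
    """Mean squared difference between student and teacher probabilities."""
    if z.shape != z_tilde.shape:
        raise ValueError("student/teacher output shapes differ")
    return float(np.mean((z - z_tilde) ** 2))


def _consistency_grad(z: np.ndarray, z_tilde: np.ndarray) -> np.ndarray:
    """Gradient of the MSE consistency loss at the student's logits."""
    dprobs = 2.0 * (z - z_tilde) / z.size
    # softmax Jacobian: dlogit_j = p_j (dp_j - sum_k dp_k p_k)
    return z * (dprobs - (dprobs * z).sum(axis=1, keepdims=True))


def ema_update(
    theta_t: dict[str, np.ndarray],
    theta_s: dict[str, np.ndarray],
    alpha: float,
) -> dict[str, np.ndarray]:
    """One exponential-moving-average step over every array in the weights.

    Batch-norm running statistics are smoothed along with the learnable
    parameters, so the teacher's normalisation state is itself an EMA.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    if theta_t.keys() != theta_s.keys():
        raise ValueError("weight collections must share keys")
    return {k: alpha * theta_t[k] + (1.0 - alpha) * theta_s[k] for k in theta_t}


class Adam:
    """Plain Adam over a named parameter dictionary (updates in place)."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(params[k])
                self.v[k] = np.zeros_like(params[k])
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1 ** self.t)
            v_hat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _alpha_schedule(step: int, alpha_max: float) -> float:
    return min(1.0 - 1.0 / (step + 1), alpha_max)


def train_step(
    labeled_batch: tuple[GraphBatch, np.ndarray],
    unlabeled_batch: GraphBatch | None,
    state: TrainState,
    cfg: MTConfig,
    gcn_cfg: GCNConfig,
    optimizer: Adam,
    rng_student: np.random.Generator,
    rng_teacher: np.random.Generator,
) -> TrainState:
    """One Mean-Teacher step: student Adam update then teacher EMA update."""
    batch, labels = labeled_batch
    if batch.n_graphs == 0:
        logger.warning("empty labeled batch: skipping step (no gradient signal)")
        return state

    w = consistency_weight(state.step, state.total_ramp_steps)

    lbatch = GraphBatch(
        X=perturb(batch.X, cfg.noise_sigma, rng_student),
        A_hat=batch.A_hat, graph_ids=batch.graph_ids, n_graphs=batch.n_graphs,
    )
    z_l, cache_l = forward(state.theta_s, lbatch, gcn_cfg, mode="train",
                           rng=rng_student, update_stats=True)
    loss_cls, dlogits_l = _classification_loss_grad(z_l, labels)

    loss_con = 0.0
    cache_u = None
    dlogits_u = None
    z_u = z_tilde = None
    if unlabeled_batch is not None and unlabeled_batch.n_graphs > 0:
        ub = unlabeled_batch
        ub_s = GraphBatch(X=perturb(ub.X, cfg.noise_sigma, rng_student),
                          A_hat=ub.A_hat, graph_ids=ub.graph_ids,
                          n_graphs=ub.n_graphs)
        ub_t = GraphBatch(X=perturb(ub.X, cfg.noise_sigma, rng_teacher),
                          A_hat=ub.A_hat, graph_ids=ub.graph_ids,
                          n_graphs=ub.n_graphs)
        z_u, cache_u = forward(state.theta_s, ub_s, gcn_cfg, mode="train",
                               rng=rng_student, update_stats=False)
        z_tilde, _ = forward(state.theta_t, ub_t, gcn_cfg, mode="train",
                             rng=rng_teacher, update_stats=False)
        loss_con = consistency_loss(z_u, z_tilde)
        dlogits_u = w * _consistency_grad(z_u, z_tilde)
        if cfg.consistency_on_labeled:
            tb = GraphBatch(X=perturb(batch.X, cfg.noise_sigma, rng_teacher),
                            A_hat=batch.A_hat, graph_ids=batch.graph_ids,
                            n_graphs=batch.n_graphs)
            z_l_teacher, _ = forward(state.theta_t, tb, gcn_cfg, mode="train",
                                     rng=rng_teacher, update_stats=False)
            loss_con_l = consistency_loss(z_l, z_l_teacher)
            dlogits_l = dlogits_l + w * _consistency_grad(z_l, z_l_teacher)
            loss_con = 0.5 * (loss_con + loss_con_l)

    grads = backward(state.theta_s, cache_l, dlogits_l)
    if cache_u is not None:
        grads_u = backward(state.theta_s, cache_u, dlogits_u)
        for k, g in grads_u.items():
            grads[k] = grads[k] + g

    optimizer.step(state.theta_s, grads)

    alpha = _alpha_schedule(state.step, cfg.alpha_max)
    state.theta_t = ema_update(state.theta_t, state.theta_s, alpha)

    state.step += 1
    state.w = consistency_weight(state.step, state.total_ramp_steps)
    state.z, state.z_tilde = z_u, z_tilde
    state.loss_cls, state.loss_con = loss_cls, loss_con
    return state


# ---------------------------------------------------------------------------
# full training loops

def _featurize(smiles: list[str]) -> list[MolecularGraph]:
    return [smiles_to_graph(s) for s in smiles]


def _val_auc(params, gcn_cfg, val_graphs, val_labels) -> float:
    from .evaluation import roc_auc  # local import to avoid a cycle

    scores = predict_proba(params, gcn_cfg, val_graphs)
    return roc_auc(scores, val_labels)


def _labeled_arrays(dataset) -> tuple[list[str], np.ndarray]:
    return list(dataset.smiles), np.asarray(dataset.labels, dtype=np.float64)


def fit(
    train_ds,
    val_ds,
    unlabeled_smiles: list[str],
    cfg: MTConfig,
    gcn_cfg: GCNConfig | None = None,
) -> tuple[dict[str, np.ndarray], list[dict]]:
    """Train a Mean-Teacher GCN; return the best teacher weights and history.

    The teacher's validation ROC-AUC is evaluated after every epoch; training
    stops once it has not improved for ``cfg.patience`` epochs, and the
    teacher weights from the best epoch are returned.  With ``r_u = 0`` the
    unlabeled pool is ignored and the run is plain supervised training.
    """
    gcn_cfg = gcn_cfg or GCNConfig()
    if cfg.r_u > 0 and not unlabeled_smiles:
        raise ValueError("r_u > 0 requires a non-empty unlabeled pool")

    rng_init, rng_batch, rng_student, rng_teacher = (
        np.random.default_rng(cfg.seed).spawn(4)
    )

    train_smiles, train_labels = _labeled_arrays(train_ds)
    train_graphs = _featurize(train_smiles)
    val_smiles, val_labels = _labeled_arrays(val_ds)
    val_mask = ~np.isnan(val_labels)
    val_graphs = _featurize([s for s, m in zip(val_smiles, val_mask) if m])
    val_labels = val_labels[val_mask]

    pool_graphs = _featurize(unlabeled_smiles) if cfg.r_u > 0 else []

    n_train = len(train_graphs)
    steps_per_epoch = max(1, math.ceil(n_train / cfg.batch_size))
    total_ramp_steps = max(
        1, round(cfg.ramp_fraction * cfg.max_epochs * steps_per_epoch)
    )

    theta_s = init_weights(gcn_cfg, rng_init)
    state = TrainState(
        step=0,
        theta_s=theta_s,
        theta_t=copy_weights(theta_s),
        total_ramp_steps=total_ramp_steps,
        w=consistency_weight(0, total_ramp_steps),
    )
    optimizer = Adam(lr=cfg.lr)
    best_params = copy_weights(state.theta_t)
    history: list[dict] = []

    for epoch in range(cfg.max_epochs):
        perm = rng_batch.permutation(n_train)
        if pool_graphs:
            upool = rng_batch.permutation(len(pool_graphs))
            uptr = 0
        ep_cls, ep_con, n_steps = 0.0, 0.0, 0

        for start in range(0, n_train, cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            lbatch = GraphBatch.from_graphs([train_graphs[i] for i in idx])
            labels = train_labels[idx]

            ubatch = None
            if pool_graphs:
                m = min(round(cfg.r_u * len(idx)), len(pool_graphs))
                if m > 0:
                    if uptr + m > len(upool):
                        upool = rng_batch.permutation(len(pool_graphs))
                        uptr = 0
                    uidx = upool[uptr:uptr + m]
                    uptr += m
                    ubatch = GraphBatch.from_graphs([pool_graphs[i] for i in uidx])

            state = train_step((lbatch, labels), ubatch, state, cfg, gcn_cfg,
                               optimizer, rng_student, rng_teacher)
            ep_cls += state.loss_cls
            ep_con += state.loss_con
            n_steps += 1

        val_auc = _val_auc(state.theta_t, gcn_cfg, val_graphs, val_labels)
        history.append({
            "epoch": epoch,
            "loss_cls": ep_cls / n_steps,
            "loss_con": ep_con / n_steps,
            "w": state.w,
            "val_auc": val_auc,
        })
        # ties keep the most recent weights: with coarse validation AUCs a
        # near-initial model can otherwise be frozen by an early lucky tie
        if val_auc >= state.best_val_auc:
            best_params = copy_weights(state.theta_t)
        if val_auc > state.best_val_auc:
            state.best_val_auc = val_auc
            state.epochs_since_best = 0
        else:
            state.epochs_since_best += 1
            if state.epochs_since_best >= cfg.patience:
                break

    return best_params, history


def fit_supervised(
    train_ds,
    val_ds,
    cfg: MTConfig,
    gcn_cfg: GCNConfig | None = None,
) -> tuple[dict[str, np.ndarray], list[dict]]:
    """Plain supervised training (SL-GCN): Adam on the masked cross-entropy.

    Uses the same batching, perturbation and initialisation streams as
    :func:`fit`, so with ``r_u = 0``, ``noise_sigma = 0`` and ``alpha_max = 0``
    the two trainers produce bitwise-identical weight trajectories.
    """
    gcn_cfg = gcn_cfg or GCNConfig()
    rng_init, rng_batch, rng_student, _rng_teacher = (
        np.random.default_rng(cfg.seed).spawn(4)
    )

    train_smiles, train_labels = _labeled_arrays(train_ds)
    train_graphs = _featurize(train_smiles)
    val_smiles, val_labels = _labeled_arrays(val_ds)
    val_mask = ~np.isnan(val_labels)
    val_graphs = _featurize([s for s, m in zip(val_smiles, val_mask) if m])
    val_labels = val_labels[val_mask]

    n_train = len(train_graphs)
    params = init_weights(gcn_cfg, rng_init)
    optimizer = Adam(lr=cfg.lr)
    best_auc = -np.inf
    best_params = copy_weights(params)
    since_best = 0
    history: list[dict] = []

    for epoch in range(cfg.max_epochs):
        perm = rng_batch.permutation(n_train)
        ep_cls, n_steps = 0.0, 0
        for start in range(0, n_train, cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            batch = GraphBatch.from_graphs([train_graphs[i] for i in idx])
            batch = GraphBatch(
                X=perturb(batch.X, cfg.noise_sigma, rng_student),
                A_hat=batch.A_hat, graph_ids=batch.graph_ids,
                n_graphs=batch.n_graphs,
            )
            z, cache = forward(params, batch, gcn_cfg, mode="train",
                               rng=rng_student, update_stats=True)
            loss, dlogits = _classification_loss_grad(z, train_labels[idx])
            grads = backward(params, cache, dlogits)
            optimizer.step(params, grads)
            ep_cls += loss
            n_steps += 1

        val_auc = _val_auc(params, gcn_cfg, val_graphs, val_labels)
        history.append({
            "epoch": epoch, "loss_cls": ep_cls / n_steps,
            "loss_con": 0.0, "w": 0.0, "val_auc": val_auc,
        })
        if val_auc >= best_auc:
            best_params = copy_weights(params)
        if val_auc > best_auc:
            best_auc = val_auc
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break

    return best_params, history
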