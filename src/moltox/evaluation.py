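"""Evaluation protocol: ROC-AUC metric, repeated runs and hyperparameter search.

Experiments follow a fixed-split, five-repeat protocol: the scaffold split is
computed once per endpoint, every repeat retrains on identical splits with
seed = base_seed + repeat, and the teacher's test ROC-AUC is aggregated as
mean ± std.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .data import EndpointDataset, UnlabeledPool
from .gcn import GCNConfig, predict_smiles
from .mean_teacher import MTConfig, fit, fit_supervised

logger = logging.getLogger(__name__)


class UndefinedMetricError(ValueError):
    """ROC-AUC is undefined when only one class is present."""


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve.

    Equals the Mann-Whitney statistic P(score+ > score-) + ½ P(tie).
    """
    labels = np.asarray(labels, dtype=np.float64)
    scores = np.asarray(scores, dtype=np.float64)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("both classes must be present")
    return float(roc_auc_score(labels, scores))


@dataclass
class EvalReport:
    """Per-repeat test ROC-AUCs for one endpoint with their mean and std."""

    endpoint: str
    aucs: list[float]
    mean: float
    std: float
    config: dict

    @classmethod
    def from_aucs(cls, endpoint: str, aucs: list[float], config: dict) -> "EvalReport":
        arr = np.asarray(aucs, dtype=np.float64)
        return cls(endpoint=endpoint, aucs=list(map(float, arr)),
                   mean=float(arr.mean()),
                   std=float(arr.std()) if len(arr) > 1 else 0.0,
                   config=config)


def _test_auc(params, gcn_cfg, test_ds: EndpointDataset) -> float:
    labels = np.asarray(test_ds.labels, dtype=np.float64)
    mask = ~np.isnan(labels)
    smiles = [s for s, m in zip(test_ds.smiles, mask) if m]
    scores = predict_smiles(params, gcn_cfg, smiles)
    return roc_auc(scores, labels[mask])


def run_repeated(
    endpoint: str,
    train_ds: EndpointDataset,
    val_ds: EndpointDataset,
    test_ds: EndpointDataset,
    unlabeled: UnlabeledPool | None,
    mt_cfg: MTConfig,
    gcn_cfg: GCNConfig | None = None,
    n_repeats: int = 5,
    base_seed: int = 0,
    supervised: bool = False,
) -> EvalReport:
    """Retrain ``n_repeats`` models on identical splits and aggregate test AUC.

    Repeat ``r`` trains with seed ``base_seed + r``; ``supervised=True`` runs
    the SL-GCN arm (no teacher, no consistency term).
    """
    gcn_cfg = gcn_cfg or GCNConfig()
    pool_smiles = list(unlabeled.smiles) if unlabeled is not None else []
    aucs = []
    for r in range(n_repeats):
        cfg = dataclasses.replace(mt_cfg, seed=base_seed + r)
        if supervised:
            params, _ = fit_supervised(train_ds, val_ds, cfg, gcn_cfg)
        else:
            params, _ = fit(train_ds, val_ds, pool_smiles, cfg, gcn_cfg)
        aucs.append(_test_auc(params, gcn_cfg, test_ds))
    snapshot = {
        "mt": dataclasses.asdict(mt_cfg),
        "gcn": dataclasses.asdict(gcn_cfg),
        "n_repeats": n_repeats,
        "base_seed": base_seed,
        "supervised": supervised,
    }
    return EvalReport.from_aucs(endpoint, aucs, snapshot)


# ---------------------------------------------------------------------------
# hyperparameter search

@dataclass
class SearchSpace:
    """Named hyperparameter ranges over GCNConfig / MTConfig fields.

    ``params`` maps a field name to one of
    ``("uniform", lo, hi)``, ``("loguniform", lo, hi)``,
    ``("choice", [options...])``.  The trial budget defaults to 32.
    """

    params: dict[str, tuple]
    budget: int = 32

    def __post_init__(self):
        if self.budget < 1:
            raise ValueError("budget must be >= 1")
        if not self.params:
            raise ValueError("search space is empty")

    def sample(self, rng: np.random.Generator) -> dict:
        out = {}
        for name, spec in self.params.items():
            kind = spec[0]
            if kind == "uniform":
                out[name] = float(rng.uniform(spec[1], spec[2]))
            elif kind == "loguniform":
                out[name] = float(np.exp(rng.uniform(np.log(spec[1]),
                                                     np.log(spec[2]))))
            elif kind == "choice":
                out[name] = spec[1][int(rng.integers(len(spec[1])))]
            else:
                raise ValueError(f"unknown range kind {kind!r}")
        return out


def _apply_overrides(mt_cfg: MTConfig, gcn_cfg: GCNConfig, overrides: dict):
    mt_fields = {f.name for f in dataclasses.fields(MTConfig)}
    gcn_fields = {f.name for f in dataclasses.fields(GCNConfig)}
    mt_kwargs, gcn_kwargs = {}, {}
    for k, v in overrides.items():
        if k in mt_fields:
            mt_kwargs[k] = v
        elif k in gcn_fields:
            gcn_kwargs[k] = v
        else:
            raise ValueError(f"unknown hyperparameter {k!r}")
    return (dataclasses.replace(mt_cfg, **mt_kwargs),
            dataclasses.replace(gcn_cfg, **gcn_kwargs))


def tune(
    space: SearchSpace,
    train_ds: EndpointDataset,
    val_ds: EndpointDataset,
    unlabeled: UnlabeledPool | None,
    mt_cfg: MTConfig,
    gcn_cfg: GCNConfig | None = None,
    strategy: str = "random",
    seed: int = 0,
) -> tuple[dict, list[dict]]:
    """Search the hyperparameter space; return the best overrides and trial log.

    Each trial trains with early stopping and is scored by the best
    validation ROC-AUC reached.  The search strategy is pluggable; the
    default draws ``space.budget`` independent random configurations.
    """
    if strategy != "random":
        raise ValueError(f"unknown search strategy {strategy!r}")
    gcn_cfg = gcn_cfg or GCNConfig()
    rng = np.random.default_rng(seed)
    pool_smiles = list(unlabeled.smiles) if unlabeled is not None else []

    best_overrides, best_auc = None, -np.inf
    log: list[dict] = []
    for trial in range(space.budget):
        overrides = space.sample(rng)
        mt_trial, gcn_trial = _apply_overrides(mt_cfg, gcn_cfg, overrides)
        if mt_trial.r_u > 0 and pool_smiles:
            _, history = fit(train_ds, val_ds, pool_smiles, mt_trial, gcn_trial)
        else:
            _, history = fit_supervised(train_ds, val_ds, mt_trial, gcn_trial)
        val_auc = max(h["val_auc"] for h in history)
        log.append({"trial": trial, "overrides": overrides, "val_auc": val_auc})
        if val_auc > best_auc:
            best_auc, best_overrides = val_auc, overrides
    return best_overrides, log
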