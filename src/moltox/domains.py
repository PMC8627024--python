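"""Tanimoto kNN applicability domains over ECFP4 fingerprints.

Each unlabeled compound gets a similarity score SS_i: the mean Tanimoto
distance to its k nearest neighbours in the labeled set (k = 5 by default).
The labeled set defines reference statistics <d> and σ_d from the same
leave-self-out kNN scores, and cutoffs C_s(Z) = <d> + Z σ_d partition the
pool into *close* (SS ≤ C_s(0)), *normal* (C_s(0) < SS ≤ C_s(1)) and *far*
(SS > C_s(1)) domains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .features import SmilesParseError

DOMAINS = ("close", "normal", "far")


def ecfp4_fingerprint(smiles: str, n_bits: int = 2048) -> np.ndarray:
    """Radius-2 (diameter-4) circular fingerprint as a 0/1 uint8 vector."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in gen.GetFingerprint(mol).GetOnBits():
        arr[bit] = 1
    return arr


def tanimoto_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard distance 1 - |a∧b|/|a∨b|; two empty fingerprints are identical."""
    if a.shape != b.shape:
        raise ValueError("fingerprint lengths differ")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    inter = np.count_nonzero(a & b)
    return 1.0 - inter / union


def _distance_row(query: np.ndarray, references: np.ndarray) -> np.ndarray:
    """Tanimoto distances from one query to a (m, n_bits) reference stack."""
    inter = (references & query).sum(axis=1)
    union = (references | query).sum(axis=1)
    out = np.ones(len(references))
    nz = union > 0
    out[nz] = 1.0 - inter[nz] / union[nz]
    out[~nz] = 0.0  # both fingerprints empty
    return out


def knn_mean_distance(query: np.ndarray, references, k: int) -> float:
    """Mean distance to the k nearest references (all of them if fewer)."""
    refs = np.asarray(references)
    if refs.size == 0:
        raise ValueError("reference set is empty")
    if k < 1:
        raise ValueError("k must be >= 1")
    d = _distance_row(query, refs)
    k = min(k, len(d))
    return float(np.sort(d)[:k].mean())


def domain_cutoffs(
    labeled_fps, k: int = 5, method: str = "knn"
) -> tuple[float, float, float, float]:
    """Reference statistics (<d>, σ_d, C_s(0), C_s(1)) of the labeled set.

    With ``method="knn"`` (default) each labeled compound contributes its
    mean distance to its k nearest labeled neighbours, itself excluded; with
    ``method="pairwise"`` all pairwise distances contribute.  σ_d is the
    population standard deviation.
    """
    fps = np.asarray(labeled_fps)
    if len(fps) < 2:
        raise ValueError("need at least 2 labeled fingerprints")
    if method == "knn":
        scores = []
        for i in range(len(fps)):
            d = _distance_row(fps[i], fps)
            d = np.delete(d, i)
            kk = min(k, len(d))
            scores.append(np.sort(d)[:kk].mean())
        scores = np.asarray(scores)
    elif method == "pairwise":
        scores = np.concatenate(
            [_distance_row(fps[i], fps[i + 1:]) for i in range(len(fps) - 1)]
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    d_mean = float(scores.mean())
    d_std = float(scores.std())
    return d_mean, d_std, d_mean, d_mean + d_std


@dataclass
class SimilarityPartition:
    """Close/normal/far assignment of an unlabeled pool."""

    ss: np.ndarray             # per-compound kNN mean distance
    d_mean: float
    d_std: float
    cs0: float                 # C_s(Z=0)
    cs1: float                 # C_s(Z=1)
    domains: list[str]         # per-compound domain name
    k: int

    @property
    def counts(self) -> dict[str, int]:
        return {name: self.domains.count(name) for name in DOMAINS}


def assign_domain(ss: float, cs0: float, cs1: float) -> str:
    if ss <= cs0:
        return "close"
    if ss <= cs1:
        return "normal"
    return "far"


def partition_unlabeled(pool, labeled_fps, k: int = 5,
                        method: str = "knn") -> SimilarityPartition:
    """Assign every pool compound to exactly one similarity domain.

    ``pool`` is an :class:`~moltox.data.UnlabeledPool` (or any object with a
    ``smiles`` list); labeled fingerprints define the cutoffs.
    """
    fps = np.asarray(labeled_fps)
    d_mean, d_std, cs0, cs1 = domain_cutoffs(fps, k=k, method=method)
    ss = np.array(
        [knn_mean_distance(ecfp4_fingerprint(s, n_bits=fps.shape[1]), fps, k)
         for s in pool.smiles]
    )
    domains = [assign_domain(v, cs0, cs1) for v in ss]
    return SimilarityPartition(ss=ss, d_mean=d_mean, d_std=d_std,
                               cs0=cs0, cs1=cs1, domains=domains, k=k)
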