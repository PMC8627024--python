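"""Endpoint-table loading, Bemis-Murcko scaffold splitting and unlabeled pools.

Labeled data follow the MoleculeNet Tox21 layout: a CSV with one SMILES
column and one column per toxicological endpoint holding 0, 1 or an empty
cell (label unknown).  Splitting is scaffold-based so that no Bemis-Murcko
framework straddles the train/validation/test boundary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .features import SmilesParseError, canonicalize

logger = logging.getLogger(__name__)

MISSING = float("nan")


@dataclass
class EndpointDataset:
    """Canonical SMILES with {0, 1, missing} labels for a single endpoint."""

    endpoint_name: str
    smiles: list[str]
    labels: np.ndarray  # float array; NaN marks a missing label

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.float64)
        if len(self.smiles) != len(self.labels):
            raise ValueError("smiles/labels length mismatch")
        if len(set(self.smiles)) != len(self.smiles):
            raise ValueError("canonical SMILES must be unique within a dataset")
        observed = self.labels[~np.isnan(self.labels)]
        if observed.size == 0:
            raise ValueError("dataset needs at least one non-missing label")
        if not np.all(np.isin(observed, (0.0, 1.0))):
            raise ValueError("labels must be 0, 1 or missing")

    def __len__(self) -> int:
        return len(self.smiles)

    def subset(self, indices) -> "EndpointDataset":
        return EndpointDataset(
            endpoint_name=self.endpoint_name,
            smiles=[self.smiles[i] for i in indices],
            labels=self.labels[list(indices)],
        )


@dataclass
class SplitIndices:
    """Disjoint train/validation/test index lists into an EndpointDataset."""

    train: list[int]
    validation: list[int]
    test: list[int]

    def to_json(self, path, endpoint: str) -> None:
        with open(path, "w") as fh:
            json.dump({endpoint: {"train": self.train,
                                  "validation": self.validation,
                                  "test": self.test}}, fh)

    @classmethod
    def from_json(cls, path, endpoint: str) -> "SplitIndices":
        with open(path) as fh:
            d = json.load(fh)[endpoint]
        return cls(train=d["train"], validation=d["validation"], test=d["test"])


@dataclass
class UnlabeledPool:
    """Deduplicated, label-free canonical SMILES disjoint from the labeled set."""

    smiles: list[str]

    def __len__(self) -> int:
        return len(self.smiles)


class TableFormatError(ValueError):
    pass


def load_endpoint_table(
    csv_path,
    smiles_column: str = "smiles",
    endpoint_columns: list[str] | None = None,
) -> dict[str, EndpointDataset]:
    """Read a MoleculeNet-layout CSV into one :class:`EndpointDataset` per endpoint.

    Empty endpoint cells become missing labels.  Rows whose SMILES cannot be
    parsed are skipped (counted and logged), as are duplicate canonical
    SMILES (first occurrence wins).
    """
    df = pd.read_csv(csv_path)
    if smiles_column not in df.columns:
        raise TableFormatError(
            f"column {smiles_column!r} not found in {csv_path}"
        )
    if endpoint_columns is None:
        endpoint_columns = [c for c in df.columns if c != smiles_column]
    missing_cols = [c for c in endpoint_columns if c not in df.columns]
    if missing_cols:
        raise TableFormatError(f"endpoint columns not found: {missing_cols}")

    n_skipped = 0
    n_dupes = 0
    seen: dict[str, int] = {}
    canon: list[str] = []
    keep_rows: list[int] = []
    for row, s in enumerate(df[smiles_column]):
        try:
            c = canonicalize(str(s))
        except SmilesParseError:
            n_skipped += 1
            continue
        if c in seen:
            n_dupes += 1
            continue
        seen[c] = row
        canon.append(c)
        keep_rows.append(row)
    if n_skipped:
        logger.warning("skipped %d unparseable SMILES rows", n_skipped)
    if n_dupes:
        logger.warning("dropped %d duplicate canonical SMILES rows", n_dupes)

    out: dict[str, EndpointDataset] = {}
    for col in endpoint_columns:
        values = pd.to_numeric(df[col].iloc[keep_rows], errors="raise")
        labels = values.to_numpy(dtype=np.float64)
        ds = EndpointDataset(endpoint_name=col, smiles=list(canon), labels=labels)
        ds.n_skipped = n_skipped  # bookkeeping attribute, not part of identity
        out[col] = ds
    return out


def murcko_scaffold(smiles: str) -> str:
    """Canonical Bemis-Murcko framework; empty string for acyclic molecules."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    return Chem.MolToSmiles(scaffold)


def scaffold_split(
    dataset: EndpointDataset,
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> SplitIndices:
    """Greedy largest-group-first scaffold split at the given ratios.

    Molecules are grouped by Murcko scaffold; groups are sorted by size
    (descending, ties by scaffold string) and poured greedily into train
    until it reaches its ratio, then validation, then test.  A scaffold
    therefore never straddles two subsets.
    """
    if any(r <= 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must be positive and sum to 1")

    groups: dict[str, list[int]] = {}
    for i, s in enumerate(dataset.smiles):
        groups.setdefault(murcko_scaffold(s), []).append(i)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))

    n = len(dataset)
    targets = [ratios[0] * n, ratios[1] * n, ratios[2] * n]
    subsets: list[list[int]] = [[], [], []]
    current = 0
    for _, idxs in ordered:
        subsets[current].extend(idxs)
        while current < 2 and len(subsets[current]) >= targets[current]:
            current += 1
    return SplitIndices(train=subsets[0], validation=subsets[1], test=subsets[2])


def build_unlabeled_pool(
    raw_smiles_sources,
    labeled: EndpointDataset,
    r_u: float,
    seed: int,
    n_labeled_train: int | None = None,
) -> UnlabeledPool:
    """Canonicalize, deduplicate and ratio-sample an unlabeled compound pool.

    ``raw_smiles_sources`` is an iterable of SMILES iterables (one per source
    dataset).  Compounds duplicating the labeled set or each other are
    removed (first occurrence kept, order preserved), then
    ``floor(r_u * n_labeled_train)`` compounds are drawn uniformly without
    replacement with the given seed.
    """
    if r_u < 0:
        raise ValueError("r_u must be >= 0")
    n_ref = len(labeled) if n_labeled_train is None else n_labeled_train

    labeled_set = set(labeled.smiles)
    seen: set[str] = set()
    pool: list[str] = []
    n_skipped = 0
    for source in raw_smiles_sources:
        for s in source:
            try:
                c = canonicalize(s)
            except SmilesParseError:
                n_skipped += 1
                continue
            if c in labeled_set or c in seen:
                continue
            seen.add(c)
            pool.append(c)
    if n_skipped:
        logger.warning("skipped %d unparseable pool SMILES", n_skipped)

    n_sample = int(np.floor(r_u * n_ref))
    if n_sample == 0:
        return UnlabeledPool(smiles=[])
    if n_sample > len(pool):
        raise ValueError(
            f"requested {n_sample} unlabeled compounds but pool holds {len(pool)}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=n_sample, replace=False)
    return UnlabeledPool(smiles=[pool[i] for i in chosen])
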