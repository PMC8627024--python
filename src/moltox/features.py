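"""SMILES -> molecular graph conversion with a 74-bit atom feature schema.

Molecules are represented as undirected heavy-atom graphs: one node per
non-hydrogen atom, one edge per covalent bond.  Each node carries a
74-dimensional feature vector built from eight blocks (atom type, degree,
implicit hydrogens, formal charge, radical electrons, hybridisation,
aromaticity, total hydrogens).  Hydrogens are never materialised as nodes;
they enter only through the hydrogen-count blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

#: Ordered 43-symbol atom-type vocabulary of the canonical molecular
#: featurizer; position defines the one-hot bit within block 1.
ATOM_TYPES: tuple[str, ...] = (
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca", "Fe",
    "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag", "Pd", "Co",
    "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn",
    "Zr", "Cr", "Pt", "Hg", "Pb",
)

DEGREES: tuple[int, ...] = tuple(range(11))          # 0..10
IMPLICIT_HS: tuple[int, ...] = tuple(range(7))       # 0..6
HYBRIDIZATIONS: tuple[str, ...] = ("SP", "SP2", "SP3", "SP3D", "SP3D2")
TOTAL_HS: tuple[int, ...] = tuple(range(5))          # 0..4

FEATURE_WIDTH = 74


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""

    def __init__(self, smiles: str):
        super().__init__(f"unparseable SMILES: {smiles!r}")
        self.smiles = smiles


class InvalidAtomDescriptorError(ValueError):
    """Raised for atom descriptors with negative counts."""


@dataclass(frozen=True)
class FeatureBlock:
    description: str
    start: int  # 1-based, inclusive
    stop: int   # 1-based, inclusive
    form: str   # "binary" (one-hot) or "numerical"

    @property
    def width(self) -> int:
        return self.stop - self.start + 1


@dataclass(frozen=True)
class AtomFeatureSchema:
    """The eight-block atom feature layout totalling 74 entries."""

    blocks: tuple[FeatureBlock, ...] = (
        FeatureBlock("atom type one-hot", 1, 43, "binary"),
        FeatureBlock("degree one-hot", 44, 54, "binary"),
        FeatureBlock("implicit H count one-hot", 55, 61, "binary"),
        FeatureBlock("formal charge", 62, 62, "numerical"),
        FeatureBlock("radical electron count", 63, 63, "numerical"),
        FeatureBlock("hybridization one-hot", 64, 68, "binary"),
        FeatureBlock("aromatic flag", 69, 69, "numerical"),
        FeatureBlock("total H count one-hot", 70, 74, "binary"),
    )

    @property
    def width(self) -> int:
        return sum(b.width for b in self.blocks)

    def validate(self) -> None:
        """Check contiguity, disjointness and exact coverage of 1..74."""
        pos = 1
        for b in self.blocks:
            if b.start != pos:
                raise ValueError(
                    f"block {b.description!r} starts at {b.start}, expected {pos}"
                )
            if b.stop < b.start:
                raise ValueError(f"block {b.description!r} has negative width")
            pos = b.stop + 1
        if pos - 1 != FEATURE_WIDTH:
            raise ValueError(f"schema covers 1..{pos - 1}, expected 1..{FEATURE_WIDTH}")


SCHEMA = AtomFeatureSchema()


def _one_hot(value, vocabulary, out: np.ndarray, offset: int, what: str) -> None:
    # Out-of-vocabulary values leave the block all-zero so the width stays fixed.
    try:
        idx = vocabulary.index(value)
    except ValueError:
        logger.warning("out-of-vocabulary %s %r encoded as all-zero block", what, value)
        return
    out[offset + idx] = 1.0


def featurize_atom(
    symbol: str,
    degree: int,
    implicit_hs: int,
    formal_charge: int,
    radical_electrons: int,
    hybridization: str,
    is_aromatic: bool,
    total_hs: int,
) -> np.ndarray:
    """Encode one atom descriptor as a 74-entry feature vector.

    One-hot blocks for values outside their vocabulary (e.g. an element not
    among the 43 supported symbols, or more than 4 total hydrogens) are left
    all-zero and a warning is logged.

    Raises
    ------
    InvalidAtomDescriptorError
        If any count (degree, hydrogen counts, radical electrons) is negative.
    """
    for name, v in (
        ("degree", degree),
        ("implicit_hs", implicit_hs),
        ("radical_electrons", radical_electrons),
        ("total_hs", total_hs),
    ):
        if v < 0:
            raise InvalidAtomDescriptorError(f"{name} must be non-negative, got {v}")

    vec = np.zeros(FEATURE_WIDTH, dtype=np.float64)
    _one_hot(symbol, list(ATOM_TYPES), vec, 0, "atom type")
    _one_hot(degree, list(DEGREES), vec, 43, "degree")
    _one_hot(implicit_hs, list(IMPLICIT_HS), vec, 54, "implicit H count")
    vec[61] = float(formal_charge)
    vec[62] = float(radical_electrons)
    _one_hot(str(hybridization), list(HYBRIDIZATIONS), vec, 63, "hybridization")
    vec[68] = 1.0 if is_aromatic else 0.0
    _one_hot(total_hs, list(TOTAL_HS), vec, 69, "total H count")
    return vec


@dataclass
class MolecularGraph:
    """Heavy-atom graph of one molecule.

    ``adjacency`` is the plain symmetric 0/1 bond matrix without self-loops;
    self-connections are added later by the normalised propagation operator.
    """

    n_atoms: int
    adjacency: np.ndarray      # (n, n) int
    features: np.ndarray       # (n, 74) float
    smiles: str

    def validate(self) -> None:
        if self.n_atoms < 1:
            raise ValueError("graph must contain at least one atom")
        a = self.adjacency
        if a.shape != (self.n_atoms, self.n_atoms):
            raise ValueError("adjacency shape mismatch")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency must have zero diagonal")
        if self.features.shape != (self.n_atoms, FEATURE_WIDTH):
            raise ValueError("feature matrix must be n_atoms x 74")

    def to_json_dict(self) -> dict:
        """Debug dump: adjacency list plus dense feature rows."""
        edges = [
            [int(i), int(j)]
            for i in range(self.n_atoms)
            for j in range(i + 1, self.n_atoms)
            if self.adjacency[i, j]
        ]
        return {
            "smiles": self.smiles,
            "n_atoms": self.n_atoms,
            "edges": edges,
            "features": self.features.tolist(),
        }


def canonicalize(smiles: str) -> str:
    """Return the canonical SMILES, raising :class:`SmilesParseError` on failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return Chem.MolToSmiles(mol)


def smiles_to_graph(smiles: str) -> MolecularGraph:
    """Convert a SMILES string into a :class:`MolecularGraph`.

    Atoms are emitted in canonical rank order so the same molecule written as
    different SMILES strings yields an identical graph.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)

    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True))
    order = sorted(range(mol.GetNumAtoms()), key=lambda i: ranks[i])
    pos = {atom_idx: row for row, atom_idx in enumerate(order)}

    n = mol.GetNumAtoms()
    features = np.zeros((n, FEATURE_WIDTH), dtype=np.float64)
    for atom in mol.GetAtoms():
        features[pos[atom.GetIdx()]] = featurize_atom(
            symbol=atom.GetSymbol(),
            degree=atom.GetDegree(),
            implicit_hs=atom.GetNumImplicitHs(),
            formal_charge=atom.GetFormalCharge(),
            radical_electrons=atom.GetNumRadicalElectrons(),
            hybridization=str(atom.GetHybridization()),
            is_aromatic=atom.GetIsAromatic(),
            total_hs=atom.GetTotalNumHs(),
        )

    adjacency = np.zeros((n, n), dtype=np.int64)
    for bond in mol.GetBonds():
        i = pos[bond.GetBeginAtomIdx()]
        j = pos[bond.GetEndAtomIdx()]
        adjacency[i, j] = 1
        adjacency[j, i] = 1

    graph = MolecularGraph(
        n_atoms=n,
        adjacency=adjacency,
        features=features,
        smiles=Chem.MolToSmiles(mol),
    )
    graph.validate()
    return graph
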