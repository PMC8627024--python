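"""Seeded synthetic molecule libraries with a planted structure-toxicity rule.

The generator enumerates small drug-like molecules from a fixed grammar of
ring scaffolds (benzene, pyridine, cyclohexane, furan, thiophene,
naphthalene, piperidine, tetrahydrofuran) decorated with common substituents
(halogens, alkyl chains, hydroxyl, methoxy, nitrile, trifluoromethyl, ...).
Toxicity is planted as a substructure rule: a molecule is positive iff it
carries the toxicophore (a nitro group by default), after which labels can
be flipped (assay noise) or blanked (missing measurements).  This emulates
the shape of public toxicity panels - heavy class imbalance, missing labels
and a large unlabeled pool overlapping the labeled chemical space - without
any chemical database.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .data import EndpointDataset, SplitIndices, UnlabeledPool, scaffold_split
from .features import canonicalize

NITRO = "[N+](=O)[O-]"

#: ring cores used as SMILES prefixes; a substituent fragment may be appended.
_SUFFIX_SCAFFOLDS = (
    "c1ccccc1",
    "c1ccncc1",
    "C1CCCCC1",
    "c1ccoc1",
    "c1ccsc1",
    "c1ccc2ccccc2c1",
    "C1CCNCC1",
    "C1CCOC1",
    "c1cncnc1",
    "c1ccc(-c2ccccc2)cc1",
)

#: templates with format slots for multiply substituted rings; all slots but
#: the trailing suffix take non-empty fragments.
_MULTI_TEMPLATES = (
    "c1cc({})ccc1{}",      # 1,4-benzene
    "c1ccc({})c({})c1",    # 1,2-benzene
    "c1cc({})cc({})c1",    # 1,3-benzene
    "c1cc({})cnc1{}",      # pyridine
    "c1nc({})ccc1{}",      # pyridine, second isomer
    "c1cc({})sc1{}",       # thiophene
    "c1cc({})oc1{}",       # furan
    "C1CC({})CCC1{}",      # cyclohexane
    "C1CC({})NCC1{}",      # piperidine
    "c1ccc2cc({})ccc2c1{}",  # naphthalene
    "c1c({})cc({})cc1{}",  # 1,3,5-benzene
)

#: benign substituent fragments ("" = unsubstituted, suffix position only).
_BENIGN = (
    "", "C", "CC", "CCC", "CCCC", "C(C)C", "O", "OC", "OCC", "F", "Cl", "Br",
    "N", "NC", "C(F)(F)F", "C#N", "CO", "C(=O)O", "C(=O)C", "CCO",
)
_BENIGN_NONEMPTY = tuple(s for s in _BENIGN if s)


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic labeled/unlabeled benchmark."""

    n_labeled: int = 60
    n_unlabeled: int = 240
    toxicophore: str = NITRO
    label_noise: float = 0.1
    missing_rate: float = 0.0
    imbalance_target: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for name in ("label_noise", "missing_rate", "imbalance_target"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_labeled < 0 or self.n_unlabeled < 0:
            raise ValueError("counts must be >= 0")


def _assemble(rng: np.random.Generator, toxic: bool) -> str:
    """Build one molecule; toxic molecules carry exactly one nitro group."""
    use_multi = rng.random() < 0.5
    if use_multi:
        template = _MULTI_TEMPLATES[rng.integers(len(_MULTI_TEMPLATES))]
        n_slots = template.count("{}")
        subs = [_BENIGN_NONEMPTY[rng.integers(len(_BENIGN_NONEMPTY))]
                for _ in range(n_slots - 1)]
        if template.endswith("{}"):
            # trailing suffix position may be empty (unsubstituted)
            subs.append(_BENIGN[rng.integers(len(_BENIGN))])
        else:
            subs.append(_BENIGN_NONEMPTY[rng.integers(len(_BENIGN_NONEMPTY))])
        if toxic:
            subs[rng.integers(n_slots)] = NITRO
        return template.format(*subs)
    scaffold = _SUFFIX_SCAFFOLDS[rng.integers(len(_SUFFIX_SCAFFOLDS))]
    sub = NITRO if toxic else _BENIGN[rng.integers(len(_BENIGN))]
    return scaffold + sub


def generate_library(
    n: int, seed: int, positive_fraction: float = 0.0
) -> list[str]:
    """Generate ``n`` unique, valid canonical SMILES from the fixed grammar.

    A fraction ``positive_fraction`` of draws (in expectation) carries the
    nitro toxicophore.  Deterministic given the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    # fix the positive count by one binomial draw, then fill each class by
    # rejection; a single mixed loop would skew the class balance because
    # benign draws collide with earlier duplicates more often than toxic ones
    n_toxic = int(rng.binomial(n, positive_fraction)) if positive_fraction else 0
    seen: set[str] = set()
    out: list[str] = []

    def fill(count: int, toxic: bool) -> None:
        attempts, produced = 0, 0
        max_attempts = 4000 * max(count, 10) + 20000
        while produced < count:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    f"grammar exhausted after {attempts} attempts "
                    f"({produced}/{count} unique molecules, toxic={toxic})"
                )
            mol = Chem.MolFromSmiles(_assemble(rng, toxic))
            if mol is None:
                continue
            canon = Chem.MolToSmiles(mol)
            if canon in seen:
                continue
            seen.add(canon)
            out.append(canon)
            produced += 1

    fill(n_toxic, True)
    fill(n - n_toxic, False)
    return [out[i] for i in rng.permutation(n)]


def assign_labels(smiles_list: list[str], spec: FixtureSpec) -> EndpointDataset:
    """Label molecules by toxicophore substructure, then add noise and gaps.

    A molecule is positive iff it matches ``spec.toxicophore``; each label is
    then flipped with probability ``label_noise`` and blanked (made missing)
    with probability ``missing_rate``.
    """
    pattern = Chem.MolFromSmarts(spec.toxicophore)
    if pattern is None:
        raise ValueError(f"invalid toxicophore pattern {spec.toxicophore!r}")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    labels = np.empty(len(smiles_list))
    for i, s in enumerate(smiles_list):
        mol = Chem.MolFromSmiles(s)
        y = float(mol.HasSubstructMatch(pattern))
        if rng.random() < spec.label_noise:
            y = 1.0 - y
        if rng.random() < spec.missing_rate:
            y = np.nan
        labels[i] = y
    return EndpointDataset(endpoint_name="synthetic-toxicophore",
                           smiles=list(smiles_list), labels=labels)


def _has_both_classes(ds: EndpointDataset) -> bool:
    observed = ds.labels[~np.isnan(ds.labels)]
    return observed.size > 0 and len(np.unique(observed)) == 2


def make_ssl_benchmark(
    spec: FixtureSpec,
) -> tuple[dict[str, EndpointDataset], UnlabeledPool]:
    """Build a scaffold-split labeled benchmark plus an overlapping unlabeled pool.

    Returns ``({"train", "validation", "test"}, pool)``.  The pool is drawn
    from the same grammar (labels discarded) and deduplicated against the
    labeled set; its default size supports unlabeled-to-labeled ratios up to
    4.  Generation deterministically probes successive sub-seeds until the
    scaffold split leaves both classes in validation and test, so the
    benchmark is always evaluable.
    """
    if spec.n_labeled < 30:
        raise ValueError("n_labeled must be >= 30 for a usable benchmark")

    for attempt in range(50):
        sub_seed = int(
            np.random.SeedSequence([spec.seed, attempt]).generate_state(1)[0]
            % (2 ** 31)
        )
        library = generate_library(spec.n_labeled, sub_seed,
                                   positive_fraction=spec.imbalance_target)
        sub_spec = FixtureSpec(**{**spec.__dict__, "seed": sub_seed})
        labeled = assign_labels(library, sub_spec)
        split = scaffold_split(labeled)
        subsets = {
            "train": labeled.subset(split.train),
            "validation": labeled.subset(split.validation),
            "test": labeled.subset(split.test),
        }
        if all(len(s) > 0 and _has_both_classes(s) for s in subsets.values()):
            break
    else:
        raise RuntimeError("could not build an evaluable benchmark split")

    labeled_set = set(labeled.smiles)
    pool: list[str] = []
    pool_seed = int(
        np.random.SeedSequence([spec.seed, 9999]).generate_state(1)[0] % (2 ** 31)
    )
    # oversample, then drop overlaps with the labeled set
    candidates = generate_library(
        spec.n_unlabeled + spec.n_labeled, pool_seed,
        positive_fraction=spec.imbalance_target,
    )
    for s in candidates:
        if s not in labeled_set:
            pool.append(s)
        if len(pool) == spec.n_unlabeled:
            break
    if len(pool) < spec.n_unlabeled:
        raise RuntimeError("unlabeled pool too small after deduplication")
    return subsets, UnlabeledPool(smiles=pool)
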