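# Methods

## Molecular graphs and atom features

Molecules are parsed from SMILES with RDKit and converted to heavy-atom
graphs: one node per non-hydrogen atom, one undirected edge per covalent
bond, atoms emitted in canonical rank order so that any SMILES spelling of a
molecule yields the identical graph. Each node carries a 74-entry feature
vector built from eight contiguous blocks:

| block | entries | form |
|---|---|---|
| atom type (43-symbol vocabulary) | 1–43 | one-hot |
| degree 0–10 | 44–54 | one-hot |
| implicit hydrogens 0–6 | 55–61 | one-hot |
| formal charge | 62 | numeric |
| radical electrons | 63 | numeric |
| hybridisation {SP, SP2, SP3, SP3D, SP3D2} | 64–68 | one-hot |
| aromatic flag | 69 | numeric |
| total hydrogens 0–4 | 70–74 | one-hot |

The 43-element vocabulary is the canonical ordered list of the standard
molecular featurizer (C, N, O, S, F, Si, P, Cl, Br, Mg, Na, …, Hg, Pb) and
is exposed as `moltox.ATOM_TYPES` so it is auditable. Categorical values
outside a block's vocabulary (an unusual element, more than four total
hydrogens) encode as an all-zero block and log a warning; this keeps the
width fixed at 74 without reserving "other" bits. Hydrogens are never
materialised as nodes — they enter only through the hydrogen-count blocks.
Aromaticity is RDKit's default perception. Features are used raw, with no
scaling. 3-D geometry, bond features and chirality are out of scope.

## The GCN classifier

Graph convolutions use the symmetric-normalised propagation operator with
self-loops, Â = D̃^{-1/2}(A+I)D̃^{-1/2}; equivalently, node *i* receives the
sum of h_j W / √(|N(i)||N(j)|) over its neighbourhood including itself,
plus a bias, through a ReLU. Both forms are implemented and their
equivalence is asserted to 1e-10 against a dense-arithmetic oracle. Two
conv blocks (convolution → ReLU → dropout → batch-norm) feed a readout that
concatenates a per-dimension max-pool with a sigmoid-gated weighted sum
over nodes — both halves permutation-invariant — followed by a two-layer
perceptron and a two-class softmax.

Defaults when no hyperparameter search is run: hidden width 64 per block,
dropout 0.1, MLP hidden width 64. These are visible in `GCNConfig`, not
hard-coded; per-endpoint tuning is expected to override them.

All linear algebra is NumPy (batches are block-diagonal sparse stacks of
per-molecule propagation matrices); the backward pass is written by hand
and pinned down by central-difference gradient checks at 1e-6 tolerance.
Batch normalisation uses ε = 1e-5 and running-statistics momentum 0.1,
computed over all nodes in a batch; eval mode uses the running statistics
and is fully deterministic.

## Mean-Teacher training

Each step draws a labeled batch (size 16 by default) and an unlabeled batch
of size round(R_u · |labeled batch|), cycling through a shuffled pool so the
two streams stay in ratio R_u per epoch. Student inputs are perturbed with
i.i.d. Gaussian noise (σ = 0.1 by default) on the feature matrix; the
teacher sees an independently perturbed copy from its own RNG stream. The
loss is masked mean cross-entropy over labeled items (missing labels
contribute nothing; an all-missing batch contributes zero) plus the ramped
mean-squared difference between student and teacher probability outputs on
the unlabeled batch. The ramp is w(t) = exp(−5(1−t)²) with
t = step / (ramp_fraction · total steps), rising from e⁻⁵ ≈ 0.0067 to 1.
After each Adam update (lr 5e-3, β = (0.9, 0.999)) the teacher is updated
per-parameter by θ_t ← α θ_t + (1−α) θ_s with the warm-up schedule
α_i = min(1 − 1/(i+1), α_max), α_max = 0.999. Batch-norm running statistics
are smoothed along with the weights, so the teacher's normalisation state
is itself an EMA; teacher and student forward passes on unlabeled batches
never touch the running statistics.

Design choices where the design was genuinely open:

- **Consistency scope.** The consistency loss is computed on unlabeled data
  only by default; a flag (`consistency_on_labeled`) extends it to labeled
  inputs as in the original Mean-Teacher formulation.
- **EMA schedule and noise magnitude** are not dictated by the protocol the
  package implements; the standard warm-up and σ = 0.1 are config-exposed
  defaults.
- **Early stopping** reads "no validation improvement for `patience`
  epochs" (default 30) on the teacher's validation ROC-AUC, and the teacher
  weights from the best epoch are returned. Ties keep the **most recent**
  weights: validation sets can be small enough that AUC takes only a
  handful of distinct values, and preferring the later of two equal-scoring
  epochs avoids freezing a near-initialisation teacher that got lucky at
  epoch 0 while the patience window runs out.
- **R_u = 1** is the package default, the middle of the studied
  0.5–4 range.

With R_u = 0, σ = 0 and α = 0 the trainer provably collapses to plain
supervised training; `fit_supervised` (the SL-GCN arm) shares the batching,
initialisation and RNG-stream layout so that collapse is exact to the bit,
which the test suite asserts.

## Data pipeline

Endpoint tables follow the MoleculeNet Tox21 layout. SMILES are
canonicalised on load; unparseable rows are skipped (counted and logged)
and duplicate canonical SMILES are dropped, first occurrence winning.
Canonical-SMILES equality defines "duplicate" throughout.

Scaffold splitting groups molecules by canonical Bemis–Murcko framework
(acyclic molecules share the empty scaffold), sorts groups largest-first
(ties by scaffold string, so the split is deterministic), and pours them
greedily into train until it reaches 0.8·n, then validation to 0.9·n, then
test. Subset sizes therefore deviate from the exact ratios only by
whole-group granularity. Splits are computed once per endpoint and
persisted; repeated runs retrain on identical splits.

Unlabeled pools are canonicalised, deduplicated within themselves and
against the labeled set, and sampled uniformly without replacement at
⌊R_u · n_train⌋ with a fixed seed.

## Similarity domains

Compounds are fingerprinted with 2048-bit ECFP4 (radius-2 Morgan) and
compared by Tanimoto (Jaccard) distance; two empty fingerprints count as
identical. Each unlabeled compound's score SS_i is the mean distance to its
k = 5 nearest labeled neighbours. The labeled reference statistic ⟨d⟩ is
the mean over labeled compounds of the same leave-self-out kNN score and σ
its population standard deviation — this reading makes SS_i and the cutoff
C_s(Z) = ⟨d⟩ + Zσ commensurable; an all-pairwise variant is available via
`method="pairwise"`. The pool partitions exactly into close
(SS ≤ C_s(0)), normal (C_s(0) < SS ≤ C_s(1)) and far (SS > C_s(1)).

## Evaluation protocol

ROC-AUC (scikit-learn's trapezoidal implementation behind the package
surface) is asserted against a brute-force Mann–Whitney pair-counting
oracle; it is undefined and raises when only one class is present.
`run_repeated` retrains n = 5 models on identical splits with seeds
base+0…base+4 and reports mean and population standard deviation of the
teacher's test AUC. The hyperparameter search harness evaluates up to 32
trials (each trained with early stopping, scored by best validation AUC);
the search strategy is pluggable and defaults to seeded random sampling.

## Synthetic fixtures

The generator enumerates molecules from a fixed grammar — ten ring cores
used as SMILES prefixes plus eleven multiply-substituted ring templates,
decorated from a twenty-fragment substituent list — guaranteeing validity
and controllable scaffold diversity without any chemical database. Toxicity
is planted as a substructure rule (nitro group by default): a molecule is
positive iff it matches, after which labels are flipped with probability
`label_noise` and blanked with probability `missing_rate`. The positive
count is fixed by a single binomial draw before generation because a mixed
rejection loop would skew the class balance (benign draws collide with
earlier duplicates more often than toxic ones). The nitro rule is
deliberately easy: nitrogen/oxygen formal charges sit directly in the
74-entry feature schema, so learnability of the planted rule is a sanity
floor, not a chemistry claim.

The default benchmark (`FixtureSpec`) uses 60 labeled molecules, a
240-molecule unlabeled pool (supporting R_u up to 4), 10% label noise and a
30% positive fraction. The 1:17 imbalance typical of real toxicity panels
is emulated and tested at larger n (3600), but not in the 60-molecule
benchmark, where ~3 positives would leave validation and test AUC undefined
for most scaffold splits. Benchmark construction deterministically probes
successive generator sub-seeds until the scaffold split leaves both classes
in validation and test, so the benchmark is always evaluable.

What passing on these fixtures does *not* show: real assay biology,
stereochemistry, activity cliffs, or the million-compound scale of public
corpora. The synthetic benchmark exercises the machinery — masking,
ramping, EMA, splitting, domain assignment — at desk scale (tests plus the
reproduction script complete in a few minutes on one CPU; problem sizes of
30–500 molecules for structural checks and the 60/240 benchmark with five
repeats for the training comparison). On the benchmark the supervised arm
often saturates (test AUC 1.0), so the semi-supervised comparison is
asserted directionally (teacher mean ≥ supervised mean over 5 seeds), with
equality the common outcome on easy draws.

## Degenerate inputs and numerical details

- Cross-entropy clamps probabilities at 1e-12 before the log.
- A single-node graph has Â = [[1]]; a single-node batch's batch-norm
  variance is zero and its gradient is treated as the shift-only case.
- Empty labeled batches skip the step with a warning (no gradient signal);
  an empty unlabeled pool with R_u > 0 is a configuration error.
- `assign_labels` with `missing_rate = 1` raises: a dataset with no
  observed labels violates the dataset contract and cannot train anything.
- Checkpoints are JSON tensor dumps (weights plus architecture config),
  portable and diffable.

## Known limitations

- No bond features, 3-D information or chirality in the graph encoding.
- Batch-norm over nodes couples molecules within a batch during training;
  very small batches make the batch statistics noisy.
- The NumPy implementation targets CPU and desk-scale data; it is not
  optimised for the 50k-compound pools of public corpora, though nothing in
  the API precludes them.
- The random-search harness does not implement tree-structured Bayesian
  optimisation; the `strategy` argument is the extension point.
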