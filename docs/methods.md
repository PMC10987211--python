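# Methods

## Molecular graphs and features

A SMILES string is canonicalized with RDKit and converted to a heavy-atom
graph: hydrogens are implicit, every chemical bond contributes two directed
edges, and both directions carry identical bond features. Atom vectors are
the canonical 74-dimensional scheme (element one-hot over 43 common
elements, degree 0–10, implicit valence 0–6, formal charge, radical
electrons, hybridization SP/SP2/SP3/SP3D/SP3D2, aromaticity flag, total H
0–4); bond vectors are 12-dimensional (type, conjugation, ring membership,
stereo). A value outside any one-hot block's vocabulary falls into the
block's last slot, so featurization is total: exotic chemistry degrades
gracefully instead of failing. Graphs are batched as disjoint unions with a
node-to-graph index for the readout, and atoms with no bonds are legal —
every aggregation over an empty neighborhood returns a zero vector.

## The hybrid layer

Each layer receives node and edge embedding matrices of a shared hidden
width d (default 32; the input 74/12 features are first embedded linearly
to d) and composes up to four blocks in a fixed order, with a defined
pass-through for each absent block:

- **Node branch.** With node attention on: GATv2-style scores
  `a · LeakyReLU(W_l h_i + W_r h_j)` over neighbors j of i, softmax per
  destination node, message `Σ_j α_ij (W_r h_j)`. Off: the unweighted
  degree-normalized neighbor mean. No self-loops — a node's coefficient
  mass is spent entirely on its neighborhood, and singleton neighborhoods
  get coefficient exactly 1.
- **Edge branch** (only when edge attention is on): scores
  `LeakyReLU(a_e · (W₁ h_i + W₂ e_j))` over incident edges, softmax,
  then `σ(Σ α_ij W₂ e_j)`. The combination inside the score is an
  elementwise sum, and the normalizer is the standard softmax.
- **Weave branch** (only when weave is on): a node-side term
  `σ(n2n(h_i) + e2n(ē_i))` with ē_i the mean incident-edge embedding, plus
  the edge update `e' = σ(ue(n2e(h_src) + e2e(e)))`. Weave is the only
  block that updates edge embeddings; otherwise edges pass through.
- **Combine.** The active branches are concatenated and mixed by the "un"
  linear layer. Concatenation (rather than summation) was chosen so the
  combining layer can weigh branches independently; this widens `un_W` to
  (number of branches × d) → d.
- **Update.** With the GRU block on, a standard gated recurrent unit merges
  the combined message (input) with the node's previous embedding (hidden
  state); off, the message replaces the embedding through a ReLU.

This wiring makes the named reductions literal: all blocks off is a plain
GCN layer (neighbor mean → linear → ReLU); node attention alone is a GAT
layer; weave alone is a weave layer on the GCN frame; the GRU alone is an
MPNN-style gated update; all four together is the hybrid (HGNN) layer. The
test suite checks each reduction against independently coded single-block
references with shared weights, and checks every mixed configuration
against a full independent recomputation.

Nonlinearities: LeakyReLU with slope 0.2 inside attention scores, ReLU
elsewhere. Attention is single-head. Defaults: 2 message-passing layers,
hidden width 32, mean readout (least scale-sensitive for variable-size
molecules; sum and max are available), one hidden layer in the prediction
head, sigmoid/BCE for binary classification and linear/MSE for regression.
One integer seed fixes parameter initialization, fold shuffling and batch
order; two builds from the same spec and seed are bitwise identical.

## Numerical core

The layers run on a minimal reverse-mode autodiff engine over float64 NumPy
arrays (elementwise ops with broadcasting, matmul, reductions, row gather,
segment sum, segment softmax with per-segment max subtraction for
stability). Binary cross-entropy is computed in the softplus-of-logits form
to avoid overflow, and the logistic function via tanh for the same reason.
Gradients of every primitive are tested against central finite differences;
optimization is Adam (default lr 5e-3 for training runs in the tests and
acceptance script, 8e-3 where noted). Softmax over an empty neighborhood is
defined as the empty coefficient list, never a division by zero.

## Evaluation protocol

Cross-validation is stratified for classification (plain k-fold for
regression), with per-repeat reshuffling; every example appears in exactly
one test fold per repeat, per-fold class proportions stay within one
example of the global proportion, and the entire procedure is a pure
function of one seed. A fresh model is initialized per fold from a
fold-specific seed. The per-fold panel is ACC, AP, F1, MCC, AUC, TPR, TNR,
PRE for classification and R², MAE, RMSE for regression; AUC uses the
Mann–Whitney rank estimator with half credit for ties (scikit-learn's
trapezoidal estimator serves as the independent cross-check in tests), AP
uses scikit-learn's step-sum. A metric with a vanishing denominator is
reported as NaN and flagged, never as zero. External, non-GNN models plug
into the same protocol through a `model_factory` with fit/predict.

The comprehensive score ranks models within each (dataset, metric) cell
using fold-mean metric values: the best value receives the largest rank,
MAE and RMSE rank ascending, ties get the mean of tied ranks (which makes
the score invariant to report order), and the score is the grand mean rank
across cells. Ranking fold-mean values per cell — rather than pooling
predictions per dataset — was a design choice where either reading was
defensible.

## Dataset cleaning

Four rules, applied in order: canonicalize and deduplicate (first
occurrence wins; a molecule appearing with contradictory labels is dropped
entirely and counted in its own category, so counts always sum to the
input size); remove molecules containing metals (alkali, alkaline-earth,
transition, post-transition, lanthanide/actinide elements — the metalloids
B, Si, Ge, As, Sb, Te are deliberately not metals here, and the list is a
parameter); remove molecules with fewer than two heavy atoms; unreadable
records count as removals of their own category rather than failures.
Parse failure under the single toolchain parser stands in for
"unreadable": the rule's intent is parseability by the tools in use.
Cleaning is idempotent and the survivor set is independent of input order.
The train/test split holds out round((1−ratio)·n) records, stratified by
label by default (a toggle), and is reproducible from its seed.

## Attention export and substructure mining

After a forward pass the last layer's coefficients are arranged into an
atom × atom matrix: entry (i, j) is destination i's attention on neighbor j
(node attention) or on bond i–j (edge attention); non-bonded pairs are
exactly zero and rows over neighbors sum to 1. The matrix is generally
asymmetric, so a bonded pair qualifies when the *max* of its two directed
coefficients exceeds the threshold (default 0.5; mean is available as a
stricter alternative). The miner enumerates simple paths over qualifying
bonds by DFS and by default reports only maximal paths (no qualifying
extension at either end), suppressing the combinatorial blow-up of
sub-paths; an "all" mode reports every qualifying path, and in that mode
raising the threshold can only shrink the path set. Node attention feeds
the miner by default; edge attention is available. Each path becomes the
canonical SMILES of its atoms and consecutive bonds, so records pooled
from many molecules deduplicate by string equality with occurrence counts.
Mining is validated against exhaustive path enumeration (networkx) on all
graphs up to 8 atoms.

## Synthetic data

The separable classification set plants a clean rule: class 1 molecules
end in a nitro group, class 0 in a hydroxyl, on randomly branched alkyl or
aryl scaffolds (2–6 chain carbons, 30% methyl-branch and 30% aryl-head
probabilities), with balanced classes. Nitro versus hydroxyl differs in
element, charge and degree features, so the task is learnable by any of
the 16 configurations at small training budgets; a substructure match on
the nitro group recovers the labels exactly, which the tests use as the
label-consistency oracle. The regression set draws 4–9 carbon chains with
0–3 hydroxyl branches and sets y = 0.5·n_heavy + 1.5·n_OH + N(0, σ²),
σ = 0.3 by default, giving a known noise ceiling
var(signal)/(var(signal)+σ²) for R² recovery tests. Random graph fixtures
(spanning tree plus Bernoulli extra edges, uniform random features of the
canonical 74/12 widths) deliberately bypass chemical validity: layer
arithmetic is chemistry-agnostic, and random features exercise it more
broadly than valid molecules.

What the synthetic sets do not emulate: the scale, class imbalance, label
noise and structural diversity of real bitter/sweet or ADMET datasets.
Passing the suites shows the machinery is correct (layers compute the
stated formulas, the protocol is leakage-free and reproducible, the miner
is exact), not that any configuration ranks above another on real
chemistry. Problem sizes used throughout — 200-molecule training sets,
hidden width 16, 2 layers, 30–40 epochs, 5-fold single-repeat CV — were
chosen as the package's own desk-scale defaults for its reference runs;
full-scale benchmark comparisons (tens of thousands of molecules, repeated
5×5 CV over 21 models) use the identical code paths with larger settings.

## Known limitations

- Single-head attention only (a head-count hyperparameter is stubbed for
  extension, not implemented).
- The NumPy core is single-threaded; it is sized for desk-scale runs, not
  GPU-scale benchmark sweeps.
- The miner's "maximal path" default and the max pair rule are one
  reasonable reading of "continuous path of qualifying atom pairs"; both
  alternatives ("all" mode, mean rule) are provided because fragment
  counts depend on the choice.
- Weave edge updates transform each directed edge with its own source
  node, so the two directions of a bond may diverge after the first weave
  layer; downstream aggregation treats them independently.
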