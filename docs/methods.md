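# Methods

## The prediction problem

For a compound–protein pair, `cpinet` predicts two coupled quantities:

1. **Non-covalent interaction sites** — a pairwise probability matrix
   `y ∈ (0,1)^{N_m × N_p}` where entry (i, j) is the probability that heavy
   atom i of the compound contacts residue j of the protein.  Ground truth
   is a binary pairwise interaction matrix `PIM ∈ {0,1}^{N_m × N_p}` built
   from sparse (atom, residue) contact triplets.
2. **Binding affinity** — a scalar `y_a` on the −log10 Ki/Kd scale
   (regression; no unit conversion is ever applied inside the package).

Proteins enter the model through two channels: a precomputed per-residue
self-supervised embedding matrix `P_0 ∈ R^{N_p × d_0}` (the kind a
structure- or sequence-pretrained language model produces; d_0 = 768 or
1900 in common use), and the raw sequence encoded row-wise by BLOSUM62.
The package never runs embedding-model inference; embeddings are inputs.

## Model

**Protein representations.** Two convolutional towers, each N = 4 layers
of same-length 1-D convolution + LeakyReLU along the residue axis
(`P_K = LeakyReLU(Conv1d(P_{K−1}))`), produce

* `P_embed ∈ R^{N_p × d_1}` from `P_0` (first layer reduces d_0 → d_1,
  the remaining N−1 preserve d_1), and
* `P_evo ∈ R^{N_p × d_1}` from the BLOSUM62 encoding (input width 20).

They are blended convexly: `P_combine = α·P_embed + (1−α)·P_evo`, with
α = 0.5 the default operating point.  The site head reads `P_combine`,
the affinity head reads `P_evo`; both routings are configurable
(`combine | evo | embed` per head).

**Compound encoder.** The SMILES is parsed (RDKit) into a heavy-atom
graph: 28-dim atom features (element / degree / formal charge /
implicit-H one-hots + aromatic flag) and 6-dim bond features (order
one-hot + conjugation + ring).  Three stacked layers each apply (a) a
message-passing update — atom i receives
`Σ_j W_msg·[h_j; bond_ij]` from bonded neighbours, added to `W_self·h_i`
and passed through LeakyReLU — and (b) a gated "warp" exchange with a
molecule-level super node: sigmoid gates mix each state with a tanh
candidate computed from the other side
(`s′ = g_s ⊙ tanh(W_a·meanpool(h)) + (1−g_s) ⊙ s`, and symmetrically for
atoms).  The super node starts as the mean of the projected atom features
and ends as the global compound feature used by the affinity head.  The
warp equations are this package's minimal gated instantiation of
super-node exchange; they are isolated behind one operation so an
alternative can be swapped in.

**Heads.**

* Sites: `y_ij = sigmoid(fc_c(atom_i) · fc_p(residue_j))` — a factorized
  per-side fully connected map followed by a dot product, O((N_m+N_p)·d_1)
  memory rather than a full bilinear tensor.
* Affinity: a dual attention over the bilinear compatibility
  `A = tanh(H_atoms W_att H_res^T)`; atom weights are a softmax over the
  row maxima of A, residue weights a softmax over the column maxima; the
  two weighted sums (compound context, protein context) plus the super
  node feed a 1-hidden-layer fully connected stack with a linear output.
  This max-pooled bilinear form is chosen because its degenerate cases
  (single atom, identical rows) have closed forms the tests assert.

## Loss and optimisation

`L_total = λ·L_p + L_a` with λ = 0.1.  `L_p` is the binary cross-entropy
**summed** over all cells of a pair's matrix (probabilities clipped to
[1e-7, 1−1e-7]) and averaged over the pairs of the batch; `L_a` is the
squared affinity error averaged over the *labelled* pairs of the batch.
Missing labels are masked out of numerator and denominator, so site
supervision uses every pair while affinity supervision uses the labelled
subset — the one-loop realisation of joint training with partial labels.

Adam (β = 0.9/0.999), initial learning rate 5e-4, stepped every 20
epochs by a factor `lr_gamma`.  **Default `lr_gamma` = 0.9**: over a
200-epoch run a step factor of 0.5 would shrink the rate by 2^10 ≈ 1000×
and freeze optimisation halfway through; 0.9 leaves the final rate at
~0.35× the initial and lets long runs keep making progress.  Batches
(default 16) are processed pair-by-pair with gradient accumulation, so
variable-size interaction matrices are never padded.  Gradients come from
the package's own reverse-mode autodiff engine over NumPy arrays
(`cpinet.autodiff`); a test compares every parameter's backpropagated
gradient against central finite differences (≤1e-4 relative).

Key defaults: d_1 = 128, N = 4 protein conv layers (kernel 7, symmetric
zero padding), 3 graph layers, α = 0.5, λ = 0.1, LeakyReLU slope 0.01.
BLOSUM62 rows are used as raw integer scores; a per-column z-scoring
toggle (`standardize_blosum`) records the alternative reading.  'X'
residues encode as zero rows.

## Cold-split cross-validation

Generalisation to unseen chemistry/biology is estimated with
clustering-based splits.  Distances: compounds, 1 − Tanimoto similarity
of Morgan fingerprints (radius 2, 2048 bits); proteins, 1 − identity
fraction of a global alignment (BLOSUM62, gap open −11 / extend −1).
Single-linkage clusters at cut height t (edges where dist < t, strict
inequality as the documented tie rule; t ∈ [0.3, 0.6] is the useful
range) equal connected components of the thresholded graph.  Folds:

* **new-compound / new-protein** (5-fold): clusters are greedily
  assigned to the currently lightest fold in decreasing pair-count order
  (seeded shuffle breaks ties); a test pair's cluster never trains.
* **both-new** (9-fold): compound clusters and protein clusters are each
  partitioned into 3 balanced groups; a fold is one cell of the 3×3
  grid and training uses only cells sharing neither row nor column.

Every returned assignment is audited exhaustively (train/test cluster
intersection must be empty) before it is handed to the caller.

## Evaluation

Site AUC uses the Mann–Whitney formulation (ties count 1/2), computed
per pair on the flattened matrix, undefined for pairs with no positive
or no negative cell, and macro-averaged over defined pairs; a micro
(pooled) mode is available because the aggregation convention is a known
ambiguity.  Affinity uses Pearson r and RMSE over labelled pairs.
Case-study reporting ranks residues by the maximum predicted probability
over atoms (mean mode available), 1-based ranks, ties to the lower
residue index, with top-k hit counting against truly contacted residues.

## Synthetic data: what it emulates, and what it does not

The generator produces complete datasets with a planted, learnable rule:

* Sequences are uniform over the 20 residues, lengths 30–80.  Each
  residue has a hidden class in {0,1,2}; its embedding row is the class's
  direction vector plus isotropic Gaussian noise (sd 0.5).  The three
  directions are fixed orthonormal vectors in R^d0 scaled to norm 6.0 —
  chosen so the between-class separation (6√2) dominates the chance
  fluctuations of high-dimensional noise and k-means recovers the
  classes from raw rows (≥90% agreement is asserted in the tests).
* Atom i contacts residue j with probability 0.8 if the residue is
  class 0 and the atom is a heteroatom (N/O/S), else 0.02.
* Affinity = 2·log(1+contacts) + 4 + N(0, 0.3), missing with
  probability 0.4 (mirroring corpora where only a subset of pairs carries
  a measured Ki/Kd).
* Compounds come from a bundled vocabulary of 32 drug-like SMILES
  (guaranteed parseable; random SMILES generation is fragile).

The class signal lives **only in the embeddings** — the sequence is
independent of the classes — so the embedding pathway is specifically
exercisable: an α = 1 model sees the signal directly, an α = 0 model can
only fit the labels through sequence context.  Identical generator specs
regenerate byte-identical files.

What passing tests on this data show: the pipeline is wired correctly,
the losses and gradients are right, the architecture has the capacity to
fit both objectives jointly, and the split machinery is leakage-free.
What they do not show: performance on real structure-derived contacts
(spatial correlation between residues, realistic affinity distributions,
binding-pocket geometry are all absent), so no claim about real-data
accuracy follows from the synthetic results.

Two caveats discovered while characterising the fixture are worth
stating explicitly.  First, scoring with the planted probabilities
themselves (the Bayes scorer) attains a per-pair AUC of ~0.88, not
higher: with a two-valued score, the 20% of hi-cells that realize as
negatives can only tie, which caps the Mann–Whitney statistic; the tests
assert the exact closed-form ceiling.  A trained model can exceed the
ceiling on *training* data only by memorising realised noise.  Second,
on training data the advantage of the embedding pathway is transient: a
d_1 = 128 sequence CNN (receptive field 25) eventually memorises each
protein's class-0 positions from its near-unique local sequence
contexts, so after long training the α = 1 vs α = 0 gap in training AUC
shrinks to ~0.02 even though the ordering stays consistent.  A held-out
evaluation would not be subject to this effect.

## Numerical and degenerate-input choices

* Probabilities are clipped at 1e-7 inside the BCE and at 1e-12 in
  reported predictions (entries stay strictly inside (0,1)).
* A batch with no labelled affinities contributes L_a = 0.
* Residue-ranking ties break to the lower index; AUC is undefined (and
  excluded from means) for degenerate labels; Pearson is undefined for
  zero variance.
* Single-residue proteins and single-atom or disconnected compounds are
  legal inputs (isolated atoms receive zero messages; salts keep one
  graph with no inter-component edges, preserving atom indexing).
* Weight init is uniform Kaiming-style scaled by fan-in, from a seeded
  generator; training, generation and splitting are deterministic given
  their seeds (the engine is single-threaded NumPy).

## Problem sizes used by the test suite and acceptance script

Unit tests run at reduced widths (d_0 = 6–32, d_1 = 4–16) where the
checks are scale-free (closed forms, oracles, invariances).  The
end-to-end checks run the reference configuration (d_0 = 768,
d_1 = 128, 200 epochs) on a 20-pair planted fixture — small enough for a
single CPU, large enough to exercise every component at full width — and
the split audit uses a 60-pair fixture.  These sizes are the package's
validation protocol; scaling studies on real corpora are out of scope.

## Known limitations

* The warp-unit and dual-attention forms are minimal instantiations of
  mechanisms whose reference formulations live in their original
  implementations; both are isolated behind single operations.
* The exact atom/bond feature composition is a documented package choice
  (28/6 dims); alternative schemes change f_atom/f_bond but nothing else.
* No GPU path, no padded batching, no distributed training; throughput
  is adequate for the fixture scale this package targets.
* Checkpoints store weights + config only (no optimizer state), so
  resumed training restarts Adam moments.
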