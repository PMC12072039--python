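# Methods

## Model

The predictor treats GO annotation as large-scale multi-label classification:
for each ontology domain (MFO, BPO or CCO) a separate model maps each protein
to scores over that domain's M terms. One model is trained per domain because
term vocabularies, label densities and the optimal operating point differ
substantially between domains.

Inputs are (1) a confidence-weighted PPI adjacency A (entries in (0, 1];
STRING integer scores are detected by any weight > 1 and divided by 1000),
(2) sparse nonnegative initial node features X (InterPro-style indicators;
the data model admits frequency-valued features since presence/absence is not
the only convention in the wild), and (3) precomputed protein language-model
embeddings — either protein-level vectors or residue-level matrices that are
mean-pooled over the residue axis. The package deliberately starts *after*
the language model: running or fine-tuning a pLM is upstream preprocessing
with its own heavyweight tooling, so embeddings are consumed "offline".

### The two graph branches

Stacking message-passing layers to widen a GCN's receptive field causes
over-smoothing: node representations converge and become indistinguishable.
The architecture therefore separates the two length scales:

* **Local**: two residual GCN layers over Â = D̃^{-1/2}(A + I)D̃^{-1/2} with the
  residual added *outside* the nonlinearity, H^(l+1) = H^(l) + σ(Â H^(l) W^(l)).
  Edge confidences weight the aggregation, so a 0.95-confidence interaction
  contributes more than a 0.15 one.
* **Global**: one softmax-free attention layer. With Frobenius-normalized
  Q̃, K̃ the update is D⁻¹[V + (1/N)Q̃(K̃ᵀV)] + H⁰ where
  D = diag(1_N + (1/N)Q̃(K̃ᵀ1_N)). Associating the product as Q̃(K̃ᵀV) makes the
  cost linear in N; the implementation never materializes the N×N score
  matrix (the dense-oracle twin that does is guarded to N ≤ 2048 and exists
  only for cross-checking). The encoder then applies per-row layer
  normalization and a two-layer MLP.

Design points that the source formulation leaves open, and how this package
resolves them:

* **Normalizer D**: computed from the *normalized* Q̃, K̃ (the normalization is
  specified to happen before the attention computation). Diagonal entries of
  D with magnitude below 1e-6 raise a hard error rather than being clamped —
  silent clamping would hide a degenerate attention state.
* **Residual placement in the encoder**: the +H⁰ residual is part of the
  attention output itself, and the encoder is MLP(LN(SGA(H⁰))) with no second
  residual. A config flag `encoder_outer_residual` enables the alternative
  reading MLP(LN(SGA(H⁰) + H⁰)) for comparison.
* **Nonlinearity**: ReLU everywhere an unspecified activation appears (node
  embedding, GCN layers, encoder MLP, sequence projection), the convention of
  this model family; every operation accepts an identity hook for algebraic
  tests.
* **GCN biases**: none (the layer equation shows none).
* **Attention heads/layers**: fixed at one; multi-head is out of scope.
* **Layer norm**: variance epsilon 1e-5; a constant row normalizes to the
  shift vector.
* **Initialization**: seeded uniform Glorot for all weight matrices, zero
  biases. Weight matrices are stored C-contiguous so that a saved/loaded
  model reproduces forward passes bitwise (BLAS results differ at the ULP
  level between contiguous and transposed-view operands).

### Classifier and loss

Scores are ŷ = logistic(W_out · (emb^PPI ‖ emb^Seq) + b_out). The logistic
squashing is a design choice: the loss is binary cross-entropy, which needs
scores in (0, 1). The loss averages over all B·M cells of a batch (not per
protein), as the 1/(BM) prefactor of the published form prescribes; scores
are clipped to [1e-7, 1 − 1e-7] before the logarithms.

### Training protocol

Adam (default lr 5e-4, weight decay 0 — chosen from the published search
grids {1e-5 … 5e-4} × {1e-5, 1e-6, 0} as the configuration that trains
fastest at desk scale; `grid_search` sweeps the full grids), batch size 1024,
dropout (default 0.2) applied after the node-embedding layer and inside the
encoder MLP during training only, maximum 1000 epochs, early stopping with
patience 15: training stops once validation loss has gone 15 consecutive
epochs without a *strict* improvement (ties count as no improvement), and the
best-epoch parameters are restored. Because the model is network-based, the
training list is first intersected with the PPI catalog
(`restrict_training_to_network`); validation and test lists are untouched.
The graph branches always run full-graph; a batch selects which labeled
proteins enter the loss, with gradients flowing through the shared graph
computation. This is the simplest faithful reading of a fixed batch size with
no stated sampling scheme, and is exact (no neighborhood sampling noise) at
the scales this package targets. If the validation list is empty the training
loss is monitored instead, which supports deliberate-overfitting fixtures.

The model runs on a small reverse-mode automatic-differentiation core over
numpy (`gtgo._autodiff`) with a hand-written Adam. Gradients are validated
against central finite differences both op-by-op and through the composed
classifier loss.

## Evaluation

Protein-centric CAFA-style metrics. At threshold τ, precision is averaged
over the N(τ) proteins with at least one score ≥ τ; recall is averaged over
all evaluated proteins. Proteins with no true annotation in the evaluated
domain are excluded (their recall denominator would be zero). Fmax scans
τ ∈ {0, 0.01, …, 1.00} (both endpoints; at τ = 0 every term counts as
predicted) and returns the smallest maximizing τ; thresholds where precision
is undefined are skipped, not zero-filled, to avoid spurious Fmax deflation.
AUPR is *micro*: all (protein, term) cells are flattened and ranked, average
precision is computed with tied scores handled as one group, and the report
labels the flavor. Test-subset reports (e.g. STRING-resident vs homologous
proteins) recompute identical metrics on supplied tag lists; homology itself
is never inferred.

## Synthetic benchmark

`gtgo.synthetic` generates the coupled structure the method exploits:

* **Network**: planted partition — edge probability p_in within a module,
  p_out between, confidences uniform on [weight_low, weight_high]. A
  degree-corrected model was deliberately not used: planted partition is the
  simplest structure that makes both the local (GCN) and global (attention)
  branches informative.
* **Features**: module k owns a block of feature columns; members switch each
  owned feature on with `feature_on_prob`, non-members with
  `feature_noise_prob`.
* **Labels**: module k's members are positive for its owned terms; every cell
  then flips with `label_flip_prob`.
* **Sequence embeddings**: Normal(μ_k, I) with orthogonal means
  μ_k = s·e_k, so one separation knob s controls exactly how much signal the
  sequence branch carries (centroid distance s√2).

Defaults — 4 modules × 25 proteins, p_in 0.5, p_out 0.05, confidences
0.4–0.95, 10 owned features per module (on-prob 0.8, noise 0.02), 5 owned
terms per module out of 20, noise-free labels, embedding separation 4.0,
dimension 1024 — define the study conditions for the end-to-end checks: a
clearly learnable but non-trivial benchmark in which network, features and
embeddings all carry module signal. All generators draw from independent
substreams fanned out from one global seed, so runs are bitwise reproducible
and changing one view's draw leaves the others untouched.

What the benchmark does **not** emulate: STRING's heavy-tailed degree
distribution, the GO DAG hierarchy (no true-path propagation anywhere in the
package — consistent with the flat multi-label formulation), correlated label
noise, inter-module feature sharing, and actual sequences. Passing the
end-to-end checks therefore shows the pipeline can extract module-level
signal jointly present in network, features and embeddings — not that it
reaches any particular accuracy on real GOA data.

## Problem sizes and numerical choices

Library defaults follow the published configuration (hidden d = 1024, batch
1024); the test suite, quickstart and acceptance script use d = 16–64 on
60–100-protein fixtures, the package's chosen desk-scale operating point —
training there takes seconds while exercising every code path. Oracle
tolerances: linear vs dense attention 1e-5, matrix vs node-wise GCN 1e-6
(both observed at ~1e-15, i.e. pure floating-point noise); prediction
round-trip 1e-6 (scores printed with 6 significant digits).

## Known limitations

* Full-graph forward only: memory is O(E·d + N·d²); graphs that exceed it
  would need neighborhood sampling, which is out of scope.
* The attention degenerate-state error (|D_ii| < 1e-6) aborts rather than
  recovers; it has never triggered under Glorot initialization at tested
  scales.
* Scores clipped at 1e-7 bound the achievable loss below by ~2e-7; perfect
  separation reports a small positive loss.
* `load_annotations` orders proteins/terms by first appearance, so matrix
  layout (not content) depends on row order of the input file.
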