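# gtgo — protein function prediction from PPI networks and protein language models

`gtgo` predicts Gene Ontology (GO) annotations for proteins by combining two
complementary sources of evidence:

* a **weighted protein–protein interaction (PPI) network** (STRING-style
  confidence-weighted edges), modeled by a *dual-branch graph transformer*, and
* **sequence embeddings from a pretrained protein language model** (SeqVec-class
  1024-d vectors), consumed as precomputed input.

It is aimed at computational biologists who want a compact, fully testable
implementation of this class of network-based GO predictors, together with a
seeded synthetic benchmark generator so every stage can be exercised and
verified at desk scale without the multi-gigabyte STRING/UniProt/GOA stack.

## The model

Proteins are nodes of a graph G with weighted adjacency A ∈ R^{N×N} (a_ij =
interaction confidence) and sparse initial features X ∈ R^{N×m} (InterPro-style
domain indicators). A node embedding layer forms

    H⁰ = σ(X W⁰ + b⁰) ∈ R^{N×d}

which feeds two branches:

**Global branch — linear attention.** A single softmax-free attention layer
(simple global attention, SGA) with Frobenius-normalized queries and keys
Q̃, K̃:

    D   = diag(1_N + (1/N) Q̃ (K̃ᵀ 1_N))
    SGA = D⁻¹ [ V + (1/N) Q̃ (K̃ᵀ V) ] + H⁰
    H_Trans = MLP(LN(SGA))

Evaluated strictly as chained N×d / d×d products, this costs O(N d²) time and
O(N d) memory — the N×N attention matrix is never materialized — so any protein
can influence any other without stacking message-passing layers (and without
the over-smoothing that stacking causes).

**Local branch — residual edge-weighted GCN.** Two layers of

    H^(l+1) = H^(l) + σ(D̃^{-1/2} (A + I) D̃^{-1/2} H^(l) W^(l))

with weighted degrees D̃ including the self-loop, capture direct-interaction
neighborhoods.

The branches concatenate into H_PPI = H_GCN^(2) ‖ H_Trans (N×2d). Each
protein's pooled language-model vector h^Seq is projected by a one-layer MLP to
emb^Seq = f(W h^Seq + b) (d), fused as emb = emb^PPI ‖ emb^Seq (3d), and scored
against all M GO terms by a fully connected classifier with logistic output.
Training minimizes mean binary cross-entropy with Adam and early stopping on
validation loss (patience 15); only training proteins resident in the PPI
network contribute to the loss.

**Evaluation** is protein-centric CAFA style: Fmax (maximum over a 0.01-step
threshold grid of the harmonic mean of protein-averaged precision and recall)
and micro AUPR (pair-flattened average precision). Every numerical stage has a
brute-force oracle twin (dense attention, per-node GCN loop, first-principles
metrics) asserted in the test suite.

## Worked example

Simulate a benchmark of 4 functional modules × 25 proteins (planted-partition
network with p_in = 0.5 / p_out = 0.05, module-owned features and GO terms,
module-separated Gaussian "sequence" embeddings), train, predict, evaluate:

```sh
cat > sim.cfg <<'EOF'
n_modules = 4
proteins_per_module = 25
emb_dim = 1024
EOF
cat > train.cfg <<'EOF'
hidden_d = 64
learning_rate = 0.0005
dropout = 0.2
max_epochs = 250
EOF
gtgo simulate --config sim.cfg --seed 1 --out fixture
gtgo train --network fixture/network.tsv --features fixture/features.tsv \
  --annotations fixture/annotations.tsv --seq-emb fixture/seq_embeddings.tsv \
  --splits fixture --config train.cfg --seed 1 --out run
gtgo predict --model run/model.npz --network fixture/network.tsv \
  --features fixture/features.tsv --annotations fixture/annotations.tsv \
  --seq-emb fixture/seq_embeddings.tsv --proteins fixture/test.txt --out pred.tsv
gtgo evaluate --truth fixture/annotations.tsv --pred pred.tsv
```

prints

```
wrote fixture set (100 proteins) to fixture
stopped after 250 epochs (max_epochs); best valid loss 0.0210 at epoch 250
scored 20 proteins x 20 terms -> pred.tsv
proteins_evaluated      20
fmax    1.0000  tau     0.34
aupr    1.0000  (micro (pair-flattened average precision))
```

i.e. on this noise-free, well-separated benchmark the trained model recovers
the module-defined GO annotations of the 20 held-out proteins perfectly
(Fmax = AUPR = 1.0 at decision threshold τ = 0.34), while the label-prior
baseline — scoring every protein with each term's training frequency — only
reaches Fmax 0.40. The whole run takes a few seconds on one CPU. Real GOA-style
data is far noisier; see `docs/methods.md` for what this benchmark does and
does not exercise.

The same workflow runs on real inputs: a STRING detailed-links edge list,
a two-column (protein, GO term) table, triplet/dense feature TSVs, and TSV or
HDF5 embedding containers (`gtgo pool` mean-pools residue-level matrices to
protein vectors).

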