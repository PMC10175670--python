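# mdgcn

Prediction of miRNA–disease associations from a heterogeneous similarity
network, with a dual autoencoder for feature compression and a two-layer
graph convolutional network (GCN) for link scoring.

Experimentally validating which microRNAs are involved in which diseases
is slow and expensive, so curated catalogues (such as HMDD) cover only a
sparse corner of the true association matrix: the benchmark-scale matrix
this package is sized for holds 5430 validated pairs over 495 miRNAs and
383 diseases — about 97.14 % of cells unobserved. `mdgcn` ranks the
unobserved pairs by fusing what is known about node *similarity* with
the *topology* of the known association graph. It is a library plus a
small CLI, aimed at method developers and computational biologists who
want a fully reproducible, download-free pipeline: a synthetic-data
module generates ontologies, association matrices with planted low-rank
structure, and functional-similarity matrices at any scale.

## Model

Let `A ∈ {0,1}^{n_m × n_d}` be the association matrix.

**Disease semantic similarity.** Each disease term `d` induces a DAG of
its ontology ancestors. Scheme 1 weights ancestor `x` by geometric decay,
`W1_d(d) = 1`, `W1_d(x) = max{Δ · W1_d(x′) : x′ ∈ children(x)}` with
Δ = 0.5; scheme 2 uses information content, `W2_d(x) = −ln(n(x)/|D|)`,
where `n(x)` counts disease DAGs containing `x`. With semantic value
`Df(d) = Σ_x W_d(x)`, the similarity of diseases A and B is

    FS(A,B) = Σ_{x ∈ v(A) ∩ v(B)} (W_A(x) + W_B(x)) / (Df(A) + Df(B)),

averaged over the two schemes.

**Gaussian interaction-profile (GIP) kernel.** With interaction profiles
`p_a` (rows/columns of `A`) and bandwidth `γ = γ′ / mean‖p‖²` (γ′ = 1),

    K(a, b) = exp(−γ ‖p_a − p_b‖²).

**Integration.** `SD = (FS + GD)/2` where semantic similarity is defined
for the pair, else `GD`; `SM = (FM + GM)/2` where a supplied functional
similarity exists, else `GM`.

**Features, compression, propagation.** Each node's feature vector is
its similarity row concatenated with its association profile (length
`n_m + n_d` for both classes). Two independent sigmoid autoencoders
(input → 512 → 128 at reference scale) compress each class to a shared
code width by minimising `Σ‖x − x̂‖²`. The codes `H_0` are propagated on
the unified bipartite graph `[[0, A], [Aᵀ, 0]]` through

    H_{i+1} = σ( D̂^{-1/2} (A + I) D̂^{-1/2} H_i W_i ),    i = 0, 1,

and a pair (m, d) is scored by the inner-product decoder
`sigmoid(⟨h_m, h_d⟩)`, trained with binary cross-entropy on balanced
(1:1) positive/negative pair sets.

**Evaluation.** k-fold cross-validation over the known positives with
balanced negative sampling; per-fold AUC, AUPR, MCC, F1, Precision
(TP/(TP+FP)) and recall, with mean and both SD conventions.

## Worked example

Generate the demo-scale synthetic dataset (200 miRNAs × 150 diseases,
rank-5 planted structure, density 0.03) and cross-validate:

```
$ mdgcn simulate --preset demo --seed 1 --out-dir data
wrote 200x150 associations (900 positives, sparsity 97.00%) to data

$ cat > config.yaml <<EOF
ae:
  code_dim: 64
  hidden_dims: [256]
  epochs: 300
  learning_rate: 0.003
gcn:
  layer_dims: [64, 32, 16]
  epochs: 400
EOF

$ mdgcn evaluate --associations data/associations.tsv \
    --ontology data/ontology.tsv --fm data/fm.tsv \
    --config config.yaml --k 5 --seed 1 --out-dir cv
5-fold CV: mean AUC 0.8719, AUPR 0.8694, precision 0.8598
```

The mean AUC of ~0.87 says the pipeline recovers most of the planted
low-rank signal from 80 % of the positives; precision ~0.86 is the
fraction of pairs scored above 0.5 that are true held-out positives.
Per-fold metrics land in `cv/folds.tsv`, the full summary with seeds and
the resolved configuration in `cv/summary.json` and
`cv/resolved_config.yaml`. (Calling the library directly on the
in-memory dataset yields a slightly higher AUC ≈ 0.92: the edge-list
round trip drops nodes with no known association, which removes the
easiest negatives; see `docs/methods.md`.)

`mdgcn train` + `mdgcn predict --mirna <id> --candidates <file>` produce
a ranked candidate table for one anchor node, the case-study workflow.

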