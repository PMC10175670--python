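# Methods

This note records the modelling assumptions, numerical choices and known
limitations of the pipeline. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Similarity construction

**Ontology semantic similarity.** The ontology is a parent DAG over
opaque term identifiers; each disease term's induced DAG is its ancestor
closure (including itself). Scheme-1 contributions are computed by
dynamic programming over a topological order of the induced DAG; with a
uniform decay Δ the weight of an ancestor equals Δ^h for h the minimum
downward hop count, and the max in the recurrence makes the result
independent of traversal order. Δ defaults to 0.5 and is exposed in
configuration. Scheme-2 contributions use the information-content
reading: `n(x)` is the number of disease DAGs containing `x` (document
frequency), and the logarithm is natural. Any fixed log base rescales
all scheme-2 weights by the same constant, which cancels in the
similarity ratio, so the choice is immaterial to FS2 — it only affects
the reported raw weights. Diseases absent from the ontology get an
empty ancestor set: their semantic similarity is undefined (logged as a
warning), and similarity integration falls back to the interaction
kernel for every pair involving them.

**GIP kernel bandwidth.** The bandwidth is γ′ divided by the mean
squared profile norm, which makes the kernel scale-free in the number of
recorded interactions; γ′ defaults to 1. The multiplicative convention
(γ′ times the mean squared norm) is available behind
`bandwidth_convention="multiply"` for comparison but is not recommended:
it makes the kernel sharper as annotation density grows. An all-zero
profile set falls back to a bandwidth of 1. Isolated nodes (all-zero
profiles) are permitted; their kernel similarity to a node with profile
p is exp(−γ‖p‖²).

**Integration.** The averaged branch applies where the feature-based
similarity is *defined*: for diseases, both ends have non-empty ancestor
DAGs; for miRNAs, the pair is present (non-missing) in the supplied
functional-similarity matrix. A provenance mask (1 = averaged,
0 = kernel fallback) is written alongside every integrated matrix. A
supplied functional-similarity matrix that covers a different identifier
set than the association matrix is reindexed; pairs it does not cover
become fallback pairs.

## Features and node order

Feature vectors are the concatenation [similarity row ‖ association
profile], giving both node classes the same dimension n_m + n_d and
making the three blocks (SD/SM/A) recoverable from the features. An
alternative product fusion (similarity · association matrix) is kept
behind `fusion="product"` for comparison only. Node order everywhere is
miRNAs sorted lexicographically, then diseases sorted lexicographically;
the unified graph, the stacked embedding matrix and checkpoints all use
this order.

## Autoencoders

Two autoencoders share one architecture and never share parameters. All
layers are sigmoid; the decoder mirrors the encoder; the loss is the
summed squared reconstruction error; optimisation is full-batch Adam
with Glorot-uniform initialisation from a recorded seed. The
128-dimensional *encoder* output is the node embedding passed onward —
the decoder exists only to shape the code during training. Reference
scale defaults: input → 512 → 128, learning rate 1e-3, 200 epochs. At
the demo scale (feature dimension 350) the defaults are 350 → 256 → 64
with learning rate 3e-3 and 300 epochs: the smaller matrices are
noticeably under-converged at the reference-scale settings (5-fold AUC
0.85 instead of 0.92, below the 0.91 of a rank-5 truncated-SVD
completion baseline), and the shorter, slightly hotter schedule reaches
a converged reconstruction in seconds. A non-finite loss raises a
divergence error naming the learning rate.

## GCN link predictor

Exactly two propagation layers on D̂^{-1/2}(A+I)D̂^{-1/2} (self-loops
added once), ReLU between the layers and identity before the decoder,
Glorot initialisation, full-batch Adam (default lr 0.01, 200 epochs
reference / 400 demo). The score head is the inner-product decoder with
a sigmoid, trained by binary cross-entropy on a balanced 1:1 pair set;
the hidden widths default to 128 → 64 → 32 (demo: 64 → 32 → 16). The
association-derived inputs — kernels, features, autoencoder codes and
the propagation graph — are all rebuilt from the training matrix with
test edges removed, and `fit` rejects any negative training pair that is
an edge of the propagation graph, so no test label can leak into
training. Training is staged: autoencoders first (then frozen), GCN
second; the stages are independent optimisation problems and the staged
order matches the pipeline's three-part construction.

## Cross-validation protocol

Positives are shuffled with the run seed and partitioned into k
near-equal folds; negatives are drawn uniformly without replacement from
the zero cells of the *full* matrix, disjointly for the train and test
roles, at 1:1 ratio with the positives of each role. Per-fold seeds are
derived deterministically from the run seed and fold index, so a rerun
with identical configuration and seed reproduces the summary JSON byte
for byte. The shuffled-label null permutes the positive/negative labels
over the training pair set (the whole pipeline then sees the permuted
matrix) and over the test labels; held-out AUC under this null sits in
the chance band, which calibrates the signal-recovery claim. Precision
is reported as TP/(TP+FP) at threshold 0.5, with recall alongside; both
population and sample standard deviations are emitted because fold-mean
SD conventions vary across publications.

## Synthetic data

The generator emulates three curated inputs. (1) Ontology: a complete
`branching`-ary tree of the given depth whose shuffled leaves are
renamed to the disease identifiers (surplus leaves stay plain terms),
plus a fraction of extra child→parent edges to strictly shallower
levels, keeping acyclicity while making ancestor DAGs non-tree-shaped.
(2) Associations: latent factors U, V with unit-normal entries; the top
`density · n_m · n_d` cells of U·Vᵀ become positives. The thresholded
(rather than logistically sampled) construction makes positives a
deterministic function of the seed, so fold-level tests are stable, and
signal strength is controlled by rank and density alone. The
benchmark preset uses density 5430/(495·383), reproducing exactly
5430 positives and the 97.14 % sparsity of the benchmark matrix; the
demo preset (200×150, rank 5, density 0.03) runs the full pipeline in
tens of seconds. (3) Functional similarity: cosine similarity of the U
rows plus symmetrised uniform noise, clipped to [0,1], diagonal 1, with
a symmetric random fraction of pairs marked missing to exercise the
kernel fallback.

What the synthetic world does *not* emulate: real identifier
vocabularies, the long-tailed degree distributions of curated
databases, annotation biases correlated with disease popularity, and
ontology depth heterogeneity. Passing the planted-signal tests shows
the pipeline recovers structure that is genuinely low-rank and noise
free at the planted cells; it does not certify performance on curated
data, whose signal is weaker and confounded with annotation effort.

## Case-study harness

The held-out panel mirrors how database case studies are composed: the
anchor is the most heavily annotated miRNA, the seven positive
candidates are its most heavily annotated partner diseases (their
held-out edges have graph support through shared neighbours, as the
well-studied diseases of a real panel do), and the three negatives are
sampled non-partners of ordinary annotation depth that are also clear
negatives under the planted truth (below the anchor row's median latent
score) — near-threshold latent cells are excluded because they are
ambiguous by construction, not hard negatives. Panel edges are hidden
from training. Optionally the score matrices of a few models trained
from consecutive seeds are averaged (`n_models`); across generator
seeds the panel accuracy is 9–10 of 10, and the fixed-seed
configuration exercised by the tests classifies 10/10.

## Edge-list IO and isolated nodes

Association input is an edge list (curated exports are edge lists), so
nodes with no known association do not survive a write/read round trip;
the dense in-memory matrix may therefore contain zero-degree nodes that
the file-based CLI pipeline never sees. This is why the CLI worked
example reports a slightly lower AUC than the in-memory run on the same
generated data: dropping isolated nodes removes the easiest negatives.
A dense-matrix reader is provided for square similarity matrices with
missing-cell masks.

## Problem sizes

Tests and the acceptance script use the demo scale (200×150, 5 folds,
~35 s per cross-validation run) and a 40×30 configuration for
smoke/determinism tests; the reference 495×383 scale is exercised
structurally (graph shape, sparsity, fold sizes) without full training.

## Known limitations

- The GCN is transductive: scoring uses embeddings propagated on the
  training graph; a new node requires retraining.
- Inner-product decoders inherit a degree (popularity) bias; the
  case-study section above is explicit about how the panel composition
  interacts with it.
- The 0.5 threshold is only meaningful under balanced training; under
  other class ratios the threshold metrics need recalibration.
- Negative "samples" are unverified non-associations, as in all curated
  benchmarks of this kind — some may be undiscovered positives.
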