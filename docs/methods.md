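# Methods

`foldgo` predicts Gene Ontology (GO) terms for proteins from predicted 3D
structures. This note documents the model, the design decisions behind the
implementation, the synthetic data the package tests itself on, and what the
tests do and do not establish.

## From structure to graph

Each protein is reduced to its Cα trace. Two residues are *in contact* when
their Cα atoms lie strictly closer than 10 Å; the contact graph has one node
per residue and one undirected edge per contact pair. The inequality is
strict (a pair at exactly 10 Å is not an edge), self-contacts are excluded,
and sequence neighbours are treated like any other pair. Multi-chain files
default to the first chain; for disordered atoms the first alternate
location is used; residues lacking a Cα are skipped with a warning. No
model-confidence (pLDDT) filtering is applied.

## Node features

Per-residue features concatenate two blocks (56 columns total):

* **Structural embedding (30-d).** node2vec on the contact graph:
  second-order random walks with return parameter p = 0.8, in-out parameter
  q = 1.2, walk length 30, 10 walks per node, then skip-gram with negative
  sampling (window 5, 5 negatives, 5 epochs, linearly decaying learning
  rate from 0.025). Walks from isolated nodes are singletons and such nodes
  receive exact zero vectors. The walk/skip-gram hyperparameters beyond
  (p, q, walk length, dimension) are conventional node2vec defaults and are
  configurable.

  Embeddings are trained **per protein**. A skip-gram embedding is defined
  only up to a rotation of the embedding space, so raw coordinates from
  independently trained models are not comparable across proteins — a
  shared-weight classifier downstream would see pure noise in that block.
  Each protein's embedding matrix is therefore rotated onto its own
  principal axes with a deterministic sign convention (each column's third
  moment made non-negative). This canonicalization preserves all
  within-protein similarities and row norms; it only fixes the coordinate
  frame. In our diagnostics it is the difference between the structural
  block carrying no cross-protein signal at all and carrying most of the
  planted structural signal.

* **Residue identity (26-d one-hot).** The 20 standard amino acids in the
  fixed order `ACDEFGHIKLMNPQRSTVWY`, then six special tokens
  `B Z J U O X`; `X` is the catch-all for unknown characters.

Protein-level sequence embeddings (1024-d, from a pretrained protein
language model) are consumed from TSV tables. For fully offline operation a
deterministic stub maps composition + length features through a fixed
seed-derived random projection into 1024-d and adds small hash-seeded
noise. The stub emulates the one property of real language-model embeddings
the pipeline depends on — they are strongly informative of residue
composition — and nothing else (no positional, evolutionary or long-range
information).

## GO label machinery

Annotations are read from GAF 2.x, rows with a NOT qualifier dropped, and
only experimentally supported evidence codes retained
(EXP, IDA, IPI, IMP, IGI, IEP, IC, TAS by default; the set is
configurable). Each annotation is propagated to all is_a/part_of ancestors
(true-path rule), excluding the namespace roots, which are uninformative
after closure. A branch's label space keeps the terms annotated to at least
`min_count` distinct proteins after propagation, ordered by descending
count with ties broken by term id. Proteins with no label inside the space
are dropped from training (configurable).

## Model

For node features `X ∈ R^{N×56}`:

1. **Channel attention.** `f_avg` and `f_max` are the column-wise mean and
   maximum over nodes. A two-layer perceptron (shared between the two
   pooling paths, reduction ratio r: 56 → 56/r → 56) maps each, and
   `A_c = σ(MLP(f_avg) + MLP(f_max))` rescales the feature columns.
   Default r = 2: with only 56 channels, stronger reduction left the gate
   network too weak to be useful at small sample sizes.
2. **Spatial attention.** Per node, the mean and max over its features
   feed a small perceptron (2 → 8 → 1); `A_s = σ(·)` rescales each node's
   row. Channel then spatial attention are applied sequentially.
   Both attention output layers are initialized at zero weight with a
   positive bias, so the gates open uniformly near σ(2) ≈ 0.88 and the
   module starts as an almost-transparent rescaling; recalibration is
   learned rather than injected as random multiplicative noise at
   initialization.
3. **Graph convolutions.** Two mean-aggregation layers
   `h_i = relu(W_self x_i + W_neigh · mean_{j∈N(i)} x_j + b)`
   (56 → 128 → 128). Isolated nodes keep only the self term.
4. **Dual-head scoring and top-k pooling.** Two independent scalar-output
   graph-convolution heads (identity activation) score every node; the
   scores are averaged and the top ⌈k·N⌉ nodes retained (k = 0.5, floor of
   one node, ties to the lower index) together with their induced
   subgraph. Retained features are gated by tanh of their score by
   default. The pure binary-mask alternative (rows copied verbatim) is
   available behind a flag and is the semantics of the standalone pooling
   operation; it is not the model default because a discrete selection
   passes zero gradient to the scoring heads, leaving them untrainable —
   the averaging of two *learned* score distributions is the point of the
   dual-head design.
5. **Readout and classification.** Column-wise mean ‖ max over retained
   nodes (256-d), concatenated with the 1024-d sequence embedding, through
   one hidden rectified layer (512) to L per-term sigmoids.

Ablation flags zero the structural block (`use_structure=False`), zero the
one-hot block (`use_onehot=False`), or bypass the attention module
(`use_cbam=False`, exact identity).

## Training

Mean elementwise binary cross-entropy, Adam (lr 1e-3, β = 0.9/0.999),
graph-level minibatches of 32 proteins, up to 120 epochs. Two measures
against memorization on small datasets: inverted dropout on the classifier
input (0.3 on both the graph-readout and sequence blocks, separately
configurable), and a Polyak/exponential moving average of the weights
(decay 0.98 per optimizer step) — validation is evaluated on the
averaged weights, the best-validation averaged weights are restored, and
training stops early after 30 epochs without validation improvement.
Everything is single-threaded and bit-reproducible under a seed. A
non-finite loss aborts with a diagnostic.

Data are split 8:1:1 (train/validation/test) by seeded shuffle and
largest-remainder rounding. One model is trained per GO branch; model
selection uses the validation protein-centric Fmax.

## Evaluation

* **Fmax** — protein-centric CAFA-style: thresholds 0.01…1.00 in steps of
  0.01; precision(t) averaged over proteins with ≥1 predicted term at t;
  recall(t) averaged over proteins with ≥1 true label; report the maximum
  F1 and the lowest threshold attaining it.
* **AUPR** — micro-averaged over all protein-term cells,
  non-interpolated step rule, tie groups as blocks (macro available).
* **AUC** — term-centric ROC with midrank ties, macro-averaged over terms
  with both classes (micro available).

## Synthetic benchmark

The generator emulates every input format the pipeline reads, at desk
scale, with planted ground truth:

* **Chains** are self-avoiding 3D walks with 3.8 Å steps (standard trans
  peptide Cα-Cα distance), a clash radius of 3 Å, and a centroid-pull bias
  whose strength is the `compactness` parameter (interpreted as the pull
  weight in [0,1); higher pull produces denser contact graphs). Per-protein
  compactness is drawn uniformly ±0.12 around the spec value (default
  0.35), the way real folds range from extended to globular — this
  variation is what couples structural density to anything observable.
  Residues are uniform over the 20 standard amino acids.
* **Ontology**: a 12-term rooted DAG with three parallel subtrees under
  the root; later terms attach (mostly single-parent, occasional diamond)
  to the least-used earlier term, spreading the subtrees so that an
  internal term covers few leaves. After closure an ancestor is then a
  noisy copy of a small rule set rather than a wide union of unrelated
  rules — wide unions proved essentially unlearnable at this scale, which
  flattened all model/baseline differences.
* **Annotations**: six deterministic rules planted on leaf terms — mean
  contact degree ≥ 25.0 / 26.5, hydrophobic fraction (Kyte-Doolittle
  positive set AVLICMF) ≥ 0.38 / 0.41, and presence of the 2-residue
  motifs `CW` / `WC`. Thresholds sit at the median/upper quartile of the
  generator's measured geometry so each rule has mid-range prevalence.
  Motif rules are listed early so they are planted even on leaf-poor DAGs:
  they are the only predicates whose signal lives exclusively in local
  residue-identity patterns, which is what makes the one-hot ablation
  direction testable. Leaf labels are propagated through the DAG, then
  every (protein, term) cell is flipped independently with probability
  ε = 0.05. A few decoy rows with a non-experimental evidence code (IEA)
  are added for the evidence filter to remove.

What passing the synthetic benchmark shows: the pipeline is wired
correctly end-to-end, the model extracts planted structural and chemical
signal well beyond the prevalence baseline, and removing the structural
block measurably hurts. What it does not show: performance on real
proteins — real GO label structure is far larger and more correlated,
real structures are not random coils, real language-model embeddings
carry information the stub lacks, and a ~30-protein test partition
measures Fmax with substantial variance (a few hundredths). Ablation
differences at this scale are small. Two honest caveats: the attention
module needs large datasets before its recalibration pays off, so at desk
scale its contribution is near neutral; and because the sequence stub is
composition-bearing, the one-hot block is largely redundant with it on
synthetic data — its unique contribution (local motif patterns) is small,
and its ablation can come out neutral or even slightly favorable here,
unlike in full-scale settings.

## Numerical details

* Seeds: every stochastic component (chain generation, DAG, noise, walks,
  skip-gram, initialization, batching, dropout) derives from explicit
  integer seeds; derived seeds are masked to 31 bits.
* Pooling size ⌈k·N⌉ is clamped to ≥1; score ties break to the lower node
  index; the Fmax threshold sweep breaks ties toward the lower threshold.
* Sigmoid inputs are evaluated with `scipy.special.expit`; BCE clips
  probabilities at 1e-12 for the loss value only (gradients are computed
  analytically from the logits).
* Degenerate inputs: empty graphs are rejected; an empty label space
  raises; metrics raise `UndefinedMetricError` on truth without both
  classes rather than returning a silent default.

## Known limitations

* No pLDDT or quality filtering of structures; all-atom and side-chain
  contact definitions are out of scope.
* The skip-gram trainer is a minimal single-thread implementation tuned
  for desk-scale graphs (≤ a few hundred nodes per protein).
* Training is CPU-only and scales linearly in proteins × epochs; the
  package targets method development and desk-scale experiments, not
  proteome-scale production runs.
* Hierarchical consistency of *predictions* is not enforced; predicted
  scores may violate the true-path rule even though training labels never
  do.
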