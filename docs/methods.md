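# Methods

## Graph representation

A drug–gene interaction dataset is a list of (drug, gene, relation)
triples. `reindex_nodes` maps the external identifiers onto consecutive
integers — drugs `0..|D|−1`, genes `|D|..N−1`, lexicographic within each
type, relation labels to classes `0..C−1` in lexicographic order — so a
run is reproducible from the edge list alone. A pair appearing with two
different labels is rejected with a report; exact duplicates collapse.

The adjacency is binary: the relation class is the supervision target,
not an edge weight. Every node receives a self-loop before symmetric
normalization, `Â = D^{-1/2}(A + I)D^{-1/2}`, which gives two properties
the tests pin down exactly: `Â` is symmetric, and `D^{1/2}1` is an
eigenvector with eigenvalue 1 (so repeated propagation neither explodes
nor collapses by degree alone). Isolated nodes keep `Â_ii = 1` and remain
embeddable, which the transductive contract requires.

The higher-order branch consumes an incidence structure with one
hyperedge per observed interaction. The hyperedge notion is deliberately
minimal — size-2 node sets — because a bipartite interaction is exactly a
drug–gene pair; richer hyperedges (e.g. full neighborhoods) would change
the inductive bias without a principled reason, and the pairwise choice
keeps the node→edge→node pass interpretable as second-order message
passing (information reaches a node from the *other* endpoints of its
partner's edges).

## Encoders

**Attention branch (GATLite).** One shared projection decouples feature
transformation from attention scoring; the attention logit is
`aᵀ[z_i ‖ z_j]` with LeakyReLU slope 0.2 (the conventional value), one
attention head (the design goal is a small parameter budget; multiple
heads would defeat it). Softmax runs over the self-looped neighborhood,
so every node attends to at least itself. Outputs pass through ELU and
row L2 normalization with a 1e-12 guard; an exactly-zero aggregate maps
to the zero vector rather than NaN. During training, attention weights
are dropped out (default rate 0.1) and renormalized; self-loop weights
are exempt so no row is left without support.

**Gated branch (GatedGCN).** Node MLP → node-to-hyperedge mean →
hyperedge MLP → hyperedge-to-node aggregation → sigmoid gate. Both MLPs
are two layers with ELU after the hidden layer and hidden width F. The
node-to-hyperedge step uses the mean (for size-2 hyperedges, sum and mean
differ only by a factor 2; mean keeps scales stable). The
hyperedge-to-node aggregation follows the configured mode (sum default;
mean/min/max available), with isolated nodes receiving a zero structural
term. The gate input is `[h_i ‖ z'_i]` and the fusion blends `z'_i` (the
aggregated higher-order term) with `h_i`; using the *pre-aggregation*
projection in the fusion instead would disconnect the hyperedge pass from
the output entirely, so the aggregated term is used in both places.

The two branches run in parallel from the same embedding table; depth is
shared (default 2 layers at desk scale; deeper and wider settings help on
large networks when compute allows). Their outputs combine elementwise
under the configured aggregation (sum default) into the representation
the pair-classification head consumes.

## Objectives

The contrastive term is the multi-positive NT-Xent written in the README.
Design points:

* The denominator excludes the anchor itself — with it, `exp(1/τ)`
  self-similarity dominates every ratio and the loss saturates.
* Representations are L2-normalized inside the loss, so similarity is
  cosine; the attention branch already emits unit rows, the gated branch
  is normalized at loss time only (its magnitudes carry signal for the
  head).
* Positives for an anchor are the other-branch view of the same node plus
  any further batch entries with the same node identity. Anchors with no
  positive are excluded with a warning.
* A per-row max shift inside the softmax keeps small temperatures finite.

L2 regularization covers weight matrices only: in a featureless model the
embedding norms encode topology (hub nodes legitimately grow longer
vectors) and shrinking them would erase signal. Biases are excluded as
usual. AdamW's decoupled weight decay (1e-4) acts on the same set; the
explicit `L_reg` term (α = 1e-4) is kept as a separately weighted,
monitorable component.

Cross-entropy takes probability rows (validated to 1e-6) and clamps a
zero true-class probability at 1e-12 with a warning instead of producing
infinities. The total objective is `α·L_reg + β·L_cl + γ·L_ce`.

### Default weights

γ = 1, α = 1e-4, β = 0.05, τ = 1.0, contrastive batch 128 nodes per
epoch. The supervised term dominates by design. The contrastive weight,
temperature and batch were calibrated once on the planted benchmark: a
sharper or stronger contrast (τ = 0.5, β ≥ 0.1, full-graph batches)
measurably degrades desk-scale accuracy, because instance discrimination
repels nodes of the same latent block that classification needs close
together. On large sparse networks, where supervision per node is thin,
larger β is worth revisiting.

## Training

Full batch: the graphs this package targets fit in memory, and full-batch
gradients remove a whole axis of stochasticity. Message passing uses the
training edges only, for every split's predictions — held-out
interactions must not leak through the propagation structure.

* **Optimizer** AdamW (β₁ = 0.9, β₂ = 0.999, decay 1e-4) with
  global-norm gradient clipping at 5.0. Clipping matters: without it, a
  fraction of runs diverges after the model has already fit the data,
  when a learning-rate peak coincides with large contrastive gradients.
* **Schedule** Triangular cyclic learning rate, base 1e-3 → peak 5e-3,
  cycle 50 epochs, starting at the base rate. The base rate is the
  conventional Adam starting point; the cyclic peaks exist to escape the
  long saddle this model faces early (embeddings must break symmetry
  before the pair head can learn a block rule, an XOR-like problem).
* **Initialization** Embeddings ~ N(0, 1/√F). The head's output layer is
  zero-initialized so training starts from exactly uniform class
  probabilities (cross-entropy log C at epoch 0 — a useful sanity check).
  The gated branch's MLP output layers start at 0.1× scale: sum
  aggregation over hub nodes (degree ~10²) otherwise saturates the gate
  and the head before learning begins.
* **Selection** The parameters of the best validation-accuracy epoch are
  kept (latest on ties); without a validation set, the final epoch.
* **Determinism** A single seed drives initialization, dropout and batch
  subsampling through one `numpy` generator; identical configs reproduce
  bit-identical checkpoints on one machine.
* **Ablations** `use_contrastive=False` forces β = 0 and skips the term;
  `use_gat` / `use_gate` disable a branch (the contrastive loss needs two
  views, so single-branch configurations imply β = 0).

Ensembles train `n_members` models differing only by seed and vote by
majority over argmax classes; ties resolve toward the class with the
highest mean probability, then the lowest index — fully deterministic.

## Data pipeline

**Transductive splits.** Edges are shuffled 80/20 into train/test, then
10% of the training set becomes validation. Any held-out edge whose drug
or gene would vanish from the training graph is swapped with a same-class
training edge whose endpoints stay covered; when no such partner exists
it moves into training. This keeps ratios within about ±2% on graphs of
mean degree ≥ 3; a star graph (all partners degree 1) degenerates to
everything-in-train, which is the only transductively valid answer.

**Frequency-smoothed negative sampling.** Non-interacting pairs are drawn
with node probabilities ∝ `(degree + 1)^{-λ}`, λ = 0.75 — the classic
word-frequency smoothing exponent; the +1 shift keeps zero-degree nodes
finite. Collisions with positives and duplicates are rejected and
redrawn; the rejection budget raises an instructive error on graphs too
dense for the requested count.

**Synthetic generator.** Node propensities are Pareto with tail exponent
`degree_exponent − 1`, so realized degrees have a power-law tail of
exponent `degree_exponent` (default 2.5, the typical range for curated
interaction databases). Every node is seeded one edge first — the
transductive split requires degree ≥ 1 — and the remainder are placed by
propensity-weighted sampling without duplicates. Each node carries a
latent block; an edge's class is `class_rule[drug_block, gene_block]`
(default `(b_d + b_g) mod C`, the XOR rule for 2×2), flipped to a random
other class with probability `label_noise`. The defaults (50 drugs × 200
genes, 2,000 edges, 2 classes, 5% noise) are the study conditions used
throughout the tests and the acceptance script: small enough to train in
~20 s on one CPU, hard enough that chance is 0.5 and the noise ceiling is
≈ 0.95 on clean-rule agreement (≈ 0.93 against noisy test labels).

What the generator does *not* emulate: relation-class imbalance of real
databases (blocks are uniform), correlated multi-relation structure
(e.g. inhibitor/substrate co-occurrence), and the extreme hub asymmetry
of curated data (top hubs with 25% of all edges). Passing the planted
benchmark therefore demonstrates that the machinery recovers structural
signal through topology alone — not that real-database accuracy figures
transfer.

## Metrics

Accuracy, macro-F1 (0 convention when precision + recall = 0), macro
one-vs-rest AUROC (rank-based, ties at 0.5), macro one-vs-rest AUPR
(step-wise summation, not trapezoidal — avoids optimistic interpolation)
and MCC. Multi-class MCC uses the standard multi-category correlation,
which reduces to the familiar binary confusion-matrix formula at C = 2
(asserted to 1e-12 in the tests); classes absent from the labels are
skipped with a warning in the ranking metrics. All five are verified
against brute-force oracles and scikit-learn.

## Numerical choices

Float64 throughout. Softmax and the contrastive loss subtract detached
row maxima. The L2-normalization guard is 1e-12 (zero rows stay zero).
Sigmoid uses the two-sided stable form. Segment min/max route gradients
to the first-occurrence winner, matching numpy tie-breaking.

## Known limitations

* Transductive only: unseen drugs or genes raise an error by design.
* Full-batch training assumes the graph fits in memory; at 10⁵+ edges a
  mini-batched port would be needed.
* The desk-scale default (F = 64, 2 layers) underfits large multi-relational
  networks; widen and deepen when compute allows.
* On the planted benchmark the contrastive term does not improve over the
  supervised-only ablation (both sit at the label-noise ceiling); its
  value is expected on sparse, weakly supervised graphs rather than in
  this saturated regime.
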