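# topolink

Topology-only prediction of multi-class drug–gene interactions on
bipartite networks.

## The problem

Drug–gene interaction (DGI) networks record how compounds act on genes —
upregulation, inhibition, agonism, binding and so on. Predicting the
relation class of an *unobserved* drug–gene pair guides drug repurposing
and mechanism studies, but feature-based predictors fail for the many
entities (antibodies, complexes, novel compounds) that lack chemical or
sequence annotations. `topolink` predicts interaction classes from the
network topology alone: the only learnable inputs are per-node embedding
vectors, shaped by two complementary graph encoders. Learning is
transductive — every node scored at test time must appear in the training
graph; only edges are held out.

## The model

The drug set and gene set are unified into one node set and the binary
bipartite adjacency is self-looped and symmetrically normalized,
`Â = D^{-1/2}(A + I)D^{-1/2}`. Two encoders run in parallel from the same
embedding table `H`:

* **Lightweight attention branch.** A single shared projection
  `z_i = W h_i` feeds both messages and attention logits
  `e_ij = LeakyReLU(aᵀ[z_i ‖ z_j])`, normalized by a softmax over the
  self-looped neighborhood; the aggregate `Σ_j α_ij z_j` passes through
  ELU and row-wise L2 normalization. One head, so the parameter count
  stays near that of a plain graph convolution.
* **Gated higher-order branch.** Node features flow through an MLP to
  hyperedges (one per observed interaction), are transformed and
  propagated back, and a sigmoid gate `g_i = σ(W_g[h_i ‖ z'_i] + b_g)`
  blends the structural signal with the node's own features:
  `h_i ← g_i ⊙ z'_i + (1−g_i) ⊙ h_i`.

The two views of each node are tied by a **multi-positive NT-Xent**
contrastive loss

```
L = −(1/|A|) Σ_i log [ Σ_{j∈P(i)} exp(sim(i,j)/τ) / Σ_{k≠i} exp(sim(i,k)/τ) ]
```

with `sim` the cosine similarity and `P(i)` the batch entries sharing node
`i`'s identity (its other-branch view, plus duplicates). A two-layer
perceptron head scores each (drug, gene) pair from the concatenated
combined representations, trained with cross-entropy; the total objective
is `α·L_reg + β·L_cl + γ·L_ce` under AdamW with a triangular cyclic
learning rate. Several seed-varied models can be combined by majority
vote. Evaluation reports accuracy, macro-F1, macro one-vs-rest AUROC and
AUPR, and the multi-class Matthews correlation coefficient.

Because no deep-learning framework is required, the model runs on a small
bundled reverse-mode autodiff engine over numpy (`topolink.autodiff`),
gradient-checked against finite differences.

## Worked example

`examples/03_train_and_evaluate.py` trains the full model on a planted
synthetic network (30 drugs × 100 genes, 900 edges, 2 relation classes
derived from latent node blocks, 5% label noise) and prints:

```
epoch   0: total=1.044 ce=0.693 cl=5.730 val_acc=0.403
best ep 104: total=0.375 ce=0.074 cl=5.195 val_acc=0.944

test metrics on 180 held-out pairs (chance accuracy = 0.5):
  acc=0.894  macro_f1=0.894  auroc=0.916  aupr=0.894  mcc=0.789
```

The cross-entropy starts at `log 2` (the head is initialized uniform) and
the model recovers the planted block rule far above the 0.5 chance level;
the residual gap to the 0.95 noise ceiling reflects nodes whose block
membership is weakly determined by their few training edges. The other
scripts in `examples/` walk through graph construction, synthetic data
and transductive splitting, negative sampling, single-pair prediction and
ensemble voting.

The same workflows are available from the shell:

```bash
topolink simulate --config cfg.json --out data/
topolink split    --edges data/edges.tsv --out splits/ --seed 0
topolink train    --edges data/edges.tsv --splits splits/ --out run/ --seed 0
topolink evaluate --checkpoint run/checkpoint.npz --edges splits/test.tsv \
                  --out run/metrics.json
```

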