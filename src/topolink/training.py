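"""Model composition, optimization, checkpointing and ensembling.

The full model is: a learnable embedding table (the only "features"), the
two parallel encoder stacks, an elementwise combination of their outputs,
and a two-layer perceptron head that scores a (drug, gene) pair from the
concatenated node representations with a softmax over relation classes.

Training is full batch: each epoch forwards both branches on the graph
built from *training edges only* (held-out edges never shape the message
passing), computes the composite loss on the training pairs, and steps
AdamW under a triangular cyclic learning rate. The parameters of the best
validation-accuracy epoch are retained. Everything is driven by a single
seed, so identical configs reproduce identical checkpoints bit for bit.

Transductive contract: prediction is only defined for node ids present in
the checkpoint's node map; an unknown id raises a named error.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .data import SplitSpec
from .encoders import (EncoderConfig, GATLiteParams, GatedGCNParams, MLPParams,
                       combine_views, init_embeddings, stack_encoders)
from .graph import (BipartiteGraph, build_incidence, build_normalized_adjacency)
from .metrics import MetricsReport, evaluate_predictions
from .objectives import (LossWeights, PositivePairIndex, cross_entropy,
                         l2_regularization, multipos_ntxent, total_loss)

__all__ = [
    "ModelConfig",
    "Checkpoint",
    "EnsembleSpec",
    "TransductiveViolation",
    "score_edges",
    "train",
    "predict",
    "predict_pairs",
    "evaluate_checkpoint",
    "ensemble_vote",
    "train_ensemble",
]


class TransductiveViolation(KeyError):
    """A prediction was requested for a node absent from the training graph."""


@dataclass
class ModelConfig:
    """Everything needed to reproduce a training run.

    The default is the small desk-scale configuration (64-dim embeddings,
    2 layers); accuracy on real networks benefits from larger settings
    (1024-dim, 4 layers) when compute allows.
    """

    embedding_dim: int = 64
    num_layers: int = 2
    aggregation: str = "sum"
    loss: LossWeights = field(default_factory=LossWeights)
    base_lr: float = 1e-3
    max_lr: float = 5e-3
    cycle_len: int = 50
    weight_decay: float = 1e-4
    grad_clip: float = 5.0
    epochs: int = 200
    seed: int = 0
    attention_dropout: float = 0.1
    leaky_slope: float = 0.2
    contrastive_batch: int = 128
    use_contrastive: bool = True
    use_gat: bool = True
    use_gate: bool = True
    use_vote: bool = False
    n_members: int = 5

    def __post_init__(self):
        if isinstance(self.loss, dict):
            self.loss = LossWeights(**self.loss)
        if self.embedding_dim < 1:
            raise ValueError("embedding_dim must be >= 1")
        if self.base_lr <= 0 or self.max_lr <= 0:
            raise ValueError("learning rates must be positive")
        if not (self.use_gat or self.use_gate):
            raise ValueError("at least one encoder branch must be enabled")

    def encoder_config(self) -> EncoderConfig:
        return EncoderConfig(num_layers=self.num_layers,
                             aggregation=self.aggregation)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


@dataclass
class EnsembleSpec:
    """Member seeds and the voting rule (majority; ties by mean probability)."""

    member_seeds: list

    def __post_init__(self):
        if len(self.member_seeds) < 2:
            raise ValueError("voting needs at least 2 members")


# ------------------------------------------------------------------ params

def _init_params(n_nodes: int, cfg: ModelConfig, n_classes: int,
                 rng: np.random.Generator) -> dict:
    f = cfg.embedding_dim
    params: dict = {"embeddings": init_embeddings(n_nodes, f, rng)}
    for layer in range(cfg.num_layers):
        gat = GATLiteParams.init(f, f, rng, leaky_slope=cfg.leaky_slope,
                                 attention_dropout=cfg.attention_dropout)
        params[f"gat{layer}.W"] = gat.projection
        params[f"gat{layer}.a"] = gat.attention_vector
        gg = GatedGCNParams.init(f, rng)
        # damp the MLP output layers: sum aggregation over high-degree nodes
        # otherwise saturates the gate and the head at initialization
        gg.node_mlp.w2.data *= 0.1
        gg.edge_mlp.w2.data *= 0.1
        params[f"gated{layer}.node.w1"] = gg.node_mlp.w1
        params[f"gated{layer}.node.b1"] = gg.node_mlp.b1
        params[f"gated{layer}.node.w2"] = gg.node_mlp.w2
        params[f"gated{layer}.node.b2"] = gg.node_mlp.b2
        params[f"gated{layer}.edge.w1"] = gg.edge_mlp.w1
        params[f"gated{layer}.edge.b1"] = gg.edge_mlp.b1
        params[f"gated{layer}.edge.w2"] = gg.edge_mlp.w2
        params[f"gated{layer}.edge.b2"] = gg.edge_mlp.b2
        params[f"gated{layer}.Wg"] = gg.gate_weight
        params[f"gated{layer}.bg"] = gg.gate_bias
    head = MLPParams.init(2 * f, 2 * f, n_classes, rng)
    # zero output layer: training starts from uniform class probabilities
    head.w2.data[:] = 0.0
    params["head.w1"], params["head.b1"] = head.w1, head.b1
    params["head.w2"], params["head.b2"] = head.w2, head.b2
    return params


def _layer_params(params: dict, cfg: ModelConfig):
    gat, gated = [], []
    for layer in range(cfg.num_layers):
        gat.append(GATLiteParams(params[f"gat{layer}.W"], params[f"gat{layer}.a"],
                                 cfg.leaky_slope, cfg.attention_dropout))
        gated.append(GatedGCNParams(
            MLPParams(params[f"gated{layer}.node.w1"], params[f"gated{layer}.node.b1"],
                      params[f"gated{layer}.node.w2"], params[f"gated{layer}.node.b2"]),
            MLPParams(params[f"gated{layer}.edge.w1"], params[f"gated{layer}.edge.b1"],
                      params[f"gated{layer}.edge.w2"], params[f"gated{layer}.edge.b2"]),
            params[f"gated{layer}.Wg"], params[f"gated{layer}.bg"]))
    return gat, gated


def _head_params(params: dict) -> MLPParams:
    return MLPParams(params["head.w1"], params["head.b1"],
                     params["head.w2"], params["head.b2"])


def _weight_matrices(params: dict) -> list:
    """Weight parameters covered by L2 regularization.

    Embedding table and biases are excluded: embedding norms carry the
    topology signal in a featureless model.
    """
    out = []
    for name, t in params.items():
        if name == "embeddings" or ".b" in name:
            continue
        out.append(t)
    return out


# ------------------------------------------------------------------- head

def score_edges(drug_reps: Tensor, gene_reps: Tensor, pairs,
                head: MLPParams) -> Tensor:
    """Softmax class distributions for (drug_index, gene_index) pairs.

    ``drug_reps``/``gene_reps`` are the combined two-branch representations
    of the drug block and the gene block respectively; the head is a
    two-layer perceptron over the concatenated pair representation.
    """
    pairs = np.asarray(pairs, dtype=np.int64)
    if pairs.size and (pairs[:, 0].max() >= drug_reps.data.shape[0]
                       or pairs[:, 1].max() >= gene_reps.data.shape[0]
                       or pairs.min() < 0):
        raise IndexError("pair index out of range")
    x = ad.concat([ad.rows(drug_reps, pairs[:, 0]),
                   ad.rows(gene_reps, pairs[:, 1])], axis=1)
    logits = head(x)
    shift = logits.data.max(axis=1, keepdims=True)
    ex = (logits - shift).exp()
    return ex / ex.sum(axis=1, keepdims=True)


def _slice_rows(t: Tensor, start: int, stop: int) -> Tensor:
    return ad.rows(t, np.arange(start, stop))


# ---------------------------------------------------------------- optimizer

class AdamW:
    """Decoupled-weight-decay Adam over a named parameter dict."""

    def __init__(self, params: dict, weight_decay: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 decay_exempt=("embeddings",)):
        self.params = params
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.decay_exempt = set(decay_exempt)
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def clip_gradients(self, max_norm: float) -> float:
        """Global-norm gradient clipping; returns the pre-clip norm."""
        total = 0.0
        for p in self.params.values():
            if p.grad is not None:
                total += float((p.grad ** 2).sum())
        norm = float(np.sqrt(total))
        if max_norm > 0 and norm > max_norm:
            scale = max_norm / norm
            for p in self.params.values():
                if p.grad is not None:
                    p.grad *= scale
        return norm

    def step(self, lr: float) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            m_hat = self.m[k] / (1 - self.b1 ** self.t)
            v_hat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= lr * m_hat / (np.sqrt(v_hat) + self.eps)
            if k not in self.decay_exempt and ".b" not in k:
                p.data -= lr * self.weight_decay * p.data

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def cyclic_lr(epoch: int, base_lr: float, max_lr: float, cycle_len: int) -> float:
    """Triangular schedule: starts at ``base_lr``, peaks mid-cycle."""
    if cycle_len <= 1:
        return max_lr
    phase = (epoch % cycle_len) / cycle_len
    tri = 1.0 - abs(2.0 * phase - 1.0)   # 0 at cycle start/end, 1 mid-cycle
    return base_lr + (max_lr - base_lr) * tri


# ---------------------------------------------------------------- training

@dataclass
class Checkpoint:
    """A trained model: config, parameters, node map and history."""

    config: ModelConfig
    params: dict                  # name -> np.ndarray
    drug_ids: tuple
    gene_ids: tuple
    class_labels: tuple
    train_edges: np.ndarray       # (E_train, 3) needed to rebuild the graph
    history: list
    best_epoch: int

    def graph(self) -> BipartiteGraph:
        return BipartiteGraph(self.drug_ids, self.gene_ids, self.train_edges,
                              len(self.class_labels), self.class_labels)

    def save(self, path) -> None:
        meta = {
            "format": "topolink-checkpoint",
            "version": 1,
            "config": self.config.to_dict(),
            "drug_ids": list(self.drug_ids),
            "gene_ids": list(self.gene_ids),
            "class_labels": list(self.class_labels),
            "history": self.history,
            "best_epoch": self.best_epoch,
            "param_names": list(self.params.keys()),
        }
        arrays = {f"param__{k}": v for k, v in self.params.items()}
        np.savez(path, meta=json.dumps(meta), train_edges=self.train_edges,
                 **arrays)

    @classmethod
    def load(cls, path) -> "Checkpoint":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            if meta.get("format") != "topolink-checkpoint":
                raise ValueError(f"{path}: not a topolink checkpoint")
            params = {k: z[f"param__{k}"] for k in meta["param_names"]}
            train_edges = z["train_edges"]
        return cls(
            config=ModelConfig.from_dict(meta["config"]),
            params=params,
            drug_ids=tuple(meta["drug_ids"]),
            gene_ids=tuple(meta["gene_ids"]),
            class_labels=tuple(meta["class_labels"]),
            train_edges=train_edges,
            history=meta["history"],
            best_epoch=meta["best_epoch"],
        )


def _forward_combined(params: dict, cfg: ModelConfig, adj, inc,
                      training: bool = False,
                      rng: np.random.Generator | None = None):
    gat_list, gated_list = _layer_params(params, cfg)
    gat_view, gated_view = stack_encoders(
        params["embeddings"], adj, inc, cfg.encoder_config(),
        gat_list, gated_list, training=training, rng=rng,
        use_gat=cfg.use_gat, use_gate=cfg.use_gate)
    if gat_view is None:
        combined = gated_view
    elif gated_view is None:
        combined = gat_view
    else:
        combined = combine_views(gat_view, gated_view, cfg.aggregation)
    return gat_view, gated_view, combined


def _pair_probs(combined: Tensor, g: BipartiteGraph, pairs: np.ndarray,
                head: MLPParams) -> Tensor:
    n_d = g.n_drugs
    drug_reps = _slice_rows(combined, 0, n_d)
    gene_reps = _slice_rows(combined, n_d, g.n_nodes)
    return score_edges(drug_reps, gene_reps, pairs, head)


def train(graph: BipartiteGraph, splits: SplitSpec, cfg: ModelConfig,
          log_fn=None) -> Checkpoint:
    """Full-batch training with validation-accuracy model selection.

    Message passing uses only the training edges for every split's
    predictions, so held-out interactions never leak through the graph
    structure. Aborts with diagnostics on a non-finite loss.
    """
    splits.validate(graph)
    rng = np.random.default_rng(cfg.seed)
    train_graph = graph.replace_edges(graph.edges[splits.train])
    adj = build_normalized_adjacency(train_graph)
    inc = build_incidence(train_graph)
    train_pairs = graph.edges[splits.train][:, :2]
    train_labels = graph.edges[splits.train][:, 2]
    val_pairs = graph.edges[splits.val][:, :2]
    val_labels = graph.edges[splits.val][:, 2]

    params = _init_params(graph.n_nodes, cfg, graph.num_classes, rng)
    opt = AdamW(params, weight_decay=cfg.weight_decay)
    head = _head_params(params)

    use_cl = cfg.use_contrastive and cfg.use_gat and cfg.use_gate
    contrast_nodes = np.unique(np.concatenate(
        [train_pairs[:, 0], train_pairs[:, 1] + graph.n_drugs]))

    history: list = []
    best = {"val_acc": -1.0, "epoch": -1, "params": None}
    for epoch in range(cfg.epochs):
        opt.zero_grad()
        gat_view, gated_view, combined = _forward_combined(
            params, cfg, adj, inc, training=True, rng=rng)
        probs = _pair_probs(combined, graph, train_pairs, head)
        ce = cross_entropy(probs, train_labels)
        reg = l2_regularization(_weight_matrices(params))

        if use_cl:
            nodes = contrast_nodes
            if len(nodes) > cfg.contrastive_batch:
                nodes = rng.choice(nodes, size=cfg.contrastive_batch,
                                   replace=False)
            reps = ad.concat([ad.rows(gat_view, nodes),
                              ad.rows(gated_view, nodes)], axis=0)
            node_ids = np.concatenate([nodes, nodes])
            pp = PositivePairIndex.from_node_ids(node_ids)
            cl = multipos_ntxent(reps, pp, cfg.loss.temperature)
            cl_val = float(cl.data)
        else:
            cl = Tensor(0.0)
            cl_val = 0.0

        loss = total_loss(reg, cl, ce, cfg.loss)
        loss_val = float(loss.data)
        if not np.isfinite(loss_val):
            raise RuntimeError(
                f"non-finite loss at epoch {epoch}: total={loss_val}, "
                f"ce={float(ce.data)}, cl={cl_val}, reg={float(reg.data)}")
        loss.backward()
        opt.clip_gradients(cfg.grad_clip)
        lr = cyclic_lr(epoch, cfg.base_lr, cfg.max_lr, cfg.cycle_len)
        opt.step(lr)

        # validation pass without dropout
        _, _, combined_eval = _forward_combined(params, cfg, adj, inc,
                                                training=False)
        if len(val_pairs):
            val_probs = _pair_probs(combined_eval, graph, val_pairs, head)
            val_acc = float((val_probs.data.argmax(axis=1) == val_labels).mean())
        else:
            val_acc = float("nan")
        entry = {"epoch": epoch, "lr": lr, "loss_total": loss_val,
                 "loss_ce": float(ce.data), "loss_cl": cl_val,
                 "loss_reg": float(reg.data), "val_acc": val_acc}
        history.append(entry)
        if log_fn is not None:
            log_fn(entry)
        # keep the best validation-accuracy epoch (latest on ties); without
        # a validation set, keep the final epoch
        improved = (np.isnan(val_acc) or best["epoch"] < 0
                    or val_acc >= best["val_acc"])
        if improved:
            best = {"val_acc": -1.0 if np.isnan(val_acc) else val_acc,
                    "epoch": epoch,
                    "params": {k: p.data.copy() for k, p in params.items()}}

    return Checkpoint(
        config=cfg,
        params=best["params"],
        drug_ids=graph.drug_ids,
        gene_ids=graph.gene_ids,
        class_labels=graph.class_labels,
        train_edges=graph.edges[splits.train].copy(),
        history=history,
        best_epoch=best["epoch"],
    )


# --------------------------------------------------------------- inference

def _ckpt_tensors(ckpt: Checkpoint) -> dict:
    return {k: Tensor(v.copy(), requires_grad=False)
            for k, v in ckpt.params.items()}


def predict_pairs(ckpt: Checkpoint, pairs: np.ndarray) -> np.ndarray:
    """Class distributions for internal (drug_index, gene_index) pairs."""
    g = ckpt.graph()
    adj = build_normalized_adjacency(g)
    inc = build_incidence(g)
    params = _ckpt_tensors(ckpt)
    _, _, combined = _forward_combined(params, ckpt.config, adj, inc,
                                       training=False)
    head = _head_params(params)
    return _pair_probs(combined, g, np.asarray(pairs, dtype=np.int64),
                       head).data


def predict(ckpt: Checkpoint, pairs):
    """Predicted labels + class distributions for external-id pairs.

    ``pairs`` is a sequence of (drug_id, gene_id). Unknown ids raise
    :class:`TransductiveViolation` naming the offending id.
    """
    g = ckpt.graph()
    internal = []
    for d, gi in pairs:
        if d not in g._drug_index:
            raise TransductiveViolation(
                f"transductive violation: drug id {d!r} not in the training graph")
        if gi not in g._gene_index:
            raise TransductiveViolation(
                f"transductive violation: gene id {gi!r} not in the training graph")
        internal.append((g.drug_index(d), g.gene_index(gi)))
    probs = predict_pairs(ckpt, np.array(internal, dtype=np.int64))
    labels = [ckpt.class_labels[c] for c in probs.argmax(axis=1)]
    return labels, probs


def evaluate_checkpoint(ckpt: Checkpoint, eval_edges: np.ndarray) -> MetricsReport:
    """Score held-out (drug_index, gene_index, class) edges."""
    eval_edges = np.asarray(eval_edges, dtype=np.int64)
    probs = predict_pairs(ckpt, eval_edges[:, :2])
    return evaluate_predictions(probs, eval_edges[:, 2])


# ---------------------------------------------------------------- ensemble

def ensemble_vote(member_predictions, spec: EnsembleSpec | None = None) -> np.ndarray:
    """Majority vote on members' argmax classes; ties by mean probability.

    ``member_predictions`` is a list of (n_pairs, C) probability arrays in
    aligned pair order. Remaining ties resolve to the lowest class index,
    keeping the vote deterministic.
    """
    if len(member_predictions) < 2:
        raise ValueError("voting needs at least 2 members")
    mats = [np.asarray(p, dtype=np.float64) for p in member_predictions]
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("misaligned member predictions")
    votes = np.stack([m.argmax(axis=1) for m in mats])       # (k, n)
    mean_probs = np.mean(mats, axis=0)                       # (n, C)
    n, c = shape
    out = np.empty(n, dtype=np.int64)
    for i in range(n):
        counts = np.bincount(votes[:, i], minlength=c)
        top = counts.max()
        tied = np.flatnonzero(counts == top)
        if len(tied) == 1:
            out[i] = tied[0]
        else:
            out[i] = tied[np.argmax(mean_probs[i, tied])]
    return out


def train_ensemble(graph: BipartiteGraph, splits: SplitSpec, cfg: ModelConfig,
                   log_fn=None):
    """Train ``cfg.n_members`` members differing by seed; return them."""
    members = []
    for k in range(cfg.n_members):
        member_cfg = ModelConfig.from_dict({**cfg.to_dict(),
                                            "seed": cfg.seed + k,
                                            "use_vote": False})
        members.append(train(graph, splits, member_cfg, log_fn=log_fn))
    return members
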