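"""The two topology encoders and their stacking.

GATLite — a lightweight graph attention layer. A single shared projection
``z_i = W h_i`` feeds both the messages and the attention logits
``e_ij = LeakyReLU(a^T [z_i || z_j])``, which are softmax-normalized over
the self-looped neighborhood N(i). The aggregate ``sum_j alpha_ij z_j`` is
passed through ELU and row-wise L2 normalization, so every output row has
unit norm (or is exactly zero for a zero aggregate). One attention head:
the design goal is low parameter count. During training, attention weights
are dropped out and renormalized; self-loop weights are never dropped so
each row keeps at least one neighbor.

GatedGCN — a higher-order pass over the incidence structure. Node features
go through an MLP, flow to hyperedges (mean over the member nodes), are
transformed by a second MLP, and flow back to nodes under a configurable
aggregation (sum by default). A sigmoid gate computed from
``[h_i || z'_i]`` blends the aggregated structural signal ``z'_i`` with the
node's own features: ``out_i = g_i * z'_i + (1 - g_i) * h_i``.

Both branches run in parallel from the same embedding table; their outputs
are the two "views" fed to the contrastive loss, and are combined by the
configured aggregation into the final representation for classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .graph import IncidenceStructure, NormalizedAdjacency

__all__ = [
    "GATLiteParams",
    "MLPParams",
    "GatedGCNParams",
    "EncoderConfig",
    "init_embeddings",
    "gatlite_forward",
    "gatedgcn_forward",
    "stack_encoders",
    "combine_views",
    "l2_normalize_rows",
]

_AGGREGATIONS = ("sum", "mean", "min", "max")
_NORM_EPS = 1e-12


@dataclass
class GATLiteParams:
    """Per-layer parameters of the lightweight attention encoder."""

    projection: Tensor           # (F_out, F_in)
    attention_vector: Tensor     # (2 * F_out,)
    leaky_slope: float = 0.2
    attention_dropout: float = 0.1

    @classmethod
    def init(cls, f_in: int, f_out: int, rng: np.random.Generator,
             leaky_slope: float = 0.2, attention_dropout: float = 0.1):
        w = rng.normal(0.0, 1.0 / np.sqrt(f_in), size=(f_out, f_in))
        a = rng.normal(0.0, 1.0 / np.sqrt(2 * f_out), size=(2 * f_out,))
        return cls(Tensor(w, requires_grad=True), Tensor(a, requires_grad=True),
                   leaky_slope, attention_dropout)

    def weights(self) -> list:
        return [self.projection, self.attention_vector]


@dataclass
class MLPParams:
    """A two-layer perceptron with ELU after the hidden layer."""

    w1: Tensor
    b1: Tensor
    w2: Tensor
    b2: Tensor

    @classmethod
    def init(cls, f_in: int, f_hidden: int, f_out: int, rng: np.random.Generator):
        return cls(
            Tensor(rng.normal(0, 1.0 / np.sqrt(f_in), (f_hidden, f_in)), requires_grad=True),
            Tensor(np.zeros(f_hidden), requires_grad=True),
            Tensor(rng.normal(0, 1.0 / np.sqrt(f_hidden), (f_out, f_hidden)), requires_grad=True),
            Tensor(np.zeros(f_out), requires_grad=True),
        )

    def __call__(self, x: Tensor) -> Tensor:
        h = ad.elu(x @ self.w1.T + self.b1)
        return h @ self.w2.T + self.b2

    def weights(self) -> list:
        return [self.w1, self.w2]

    def biases(self) -> list:
        return [self.b1, self.b2]


@dataclass
class GatedGCNParams:
    """Per-layer parameters of the gated higher-order encoder."""

    node_mlp: MLPParams
    edge_mlp: MLPParams
    gate_weight: Tensor   # (F, 2F)
    gate_bias: Tensor     # (F,)

    @classmethod
    def init(cls, f: int, rng: np.random.Generator):
        return cls(
            MLPParams.init(f, f, f, rng),
            MLPParams.init(f, f, f, rng),
            Tensor(rng.normal(0, 1.0 / np.sqrt(2 * f), (f, 2 * f)), requires_grad=True),
            Tensor(np.zeros(f), requires_grad=True),
        )

    def weights(self) -> list:
        return self.node_mlp.weights() + self.edge_mlp.weights() + [self.gate_weight]

    def biases(self) -> list:
        return self.node_mlp.biases() + self.edge_mlp.biases() + [self.gate_bias]


@dataclass
class EncoderConfig:
    """Depth, aggregation and per-layer widths for both encoder stacks."""

    num_layers: int = 2
    aggregation: str = "sum"
    dims: list = field(default_factory=list)   # per-layer F; empty = keep input dim

    def __post_init__(self):
        if self.num_layers < 1:
            raise ValueError("num_layers must be >= 1")
        if self.aggregation not in _AGGREGATIONS:
            raise ValueError(f"aggregation must be one of {_AGGREGATIONS}")


def init_embeddings(n_nodes: int, dim: int, rng: np.random.Generator) -> Tensor:
    """Learnable per-node vectors, N(0, 1/sqrt(F)); the model's only features."""
    return Tensor(rng.normal(0.0, 1.0 / np.sqrt(dim), size=(n_nodes, dim)),
                  requires_grad=True)


def l2_normalize_rows(x: Tensor) -> Tensor:
    """Rows mapped to unit L2 norm; an exactly-zero row stays zero."""
    ss = (x * x).sum(axis=1, keepdims=True)
    norm = (ss + _NORM_EPS ** 2).sqrt()
    return x / (norm + _NORM_EPS)


def gatlite_forward(h: Tensor, adj: NormalizedAdjacency, p: GATLiteParams,
                    training: bool = False,
                    rng: np.random.Generator | None = None) -> Tensor:
    """One lightweight-attention layer over the self-looped neighborhoods.

    Returns the attention-aggregated, ELU-activated, row-normalized
    representations. With ``training=True`` attention weights are dropped
    out (Bernoulli, self-loops exempt) and renormalized; ``rng`` is then
    required.
    """
    f_in = h.data.shape[1]
    if p.projection.data.shape[1] != f_in:
        raise ValueError(
            f"projection expects input dim {p.projection.data.shape[1]}, got {f_in}")
    if p.attention_vector.data.shape[0] != 2 * p.projection.data.shape[0]:
        raise ValueError("attention vector length must be 2 * output dim")
    n = adj.order
    src, dst = adj.att_src, adj.att_dst   # entry k: node src attends to dst

    z = h @ p.projection.T
    f_out = z.data.shape[1]
    a_self = Tensor(p.attention_vector.data[:f_out],
                    parents=(p.attention_vector,),
                    backward=lambda g: p.attention_vector._accum(
                        np.concatenate([g, np.zeros(f_out)])))
    a_nbr = Tensor(p.attention_vector.data[f_out:],
                   parents=(p.attention_vector,),
                   backward=lambda g: p.attention_vector._accum(
                       np.concatenate([np.zeros(f_out), g])))
    s_self = (z * a_self).sum(axis=1)
    s_nbr = (z * a_nbr).sum(axis=1)
    e = ad.leaky_relu(ad.rows(s_self, src) + ad.rows(s_nbr, dst), p.leaky_slope)

    # numerically stable segment softmax; the per-segment max shift is a
    # constant w.r.t. the gradient of a softmax
    seg_max = np.full(n, -np.inf)
    np.maximum.at(seg_max, src, e.data)
    ex = (e - seg_max[src]).exp()
    denom = scatter_sum_vec(ex, src, n)
    alpha = ex / ad.rows(denom, src)

    if training and p.attention_dropout > 0.0:
        if rng is None:
            raise ValueError("training with attention dropout requires rng")
        keep = rng.random(len(src)) >= p.attention_dropout
        keep |= src == dst   # never drop the self-loop
        alpha = alpha * keep.astype(np.float64)
        renorm = scatter_sum_vec(alpha, src, n)
        alpha = alpha / ad.rows(renorm, src)

    msgs = ad.rows(z, dst) * reshape_col(alpha)
    agg = ad.scatter_sum(msgs, src, n)
    return l2_normalize_rows(ad.elu(agg))


def scatter_sum_vec(v: Tensor, idx: np.ndarray, n: int) -> Tensor:
    """scatter_sum for 1-D tensors (segment sums of attention weights)."""
    col = reshape_col(v)
    out = ad.scatter_sum(col, idx, n)
    return reshape_flat(out)


def reshape_col(v: Tensor) -> Tensor:
    out = Tensor(v.data[:, None], parents=(v,),
                 backward=lambda g: v._accum(g[:, 0]))
    return out


def reshape_flat(v: Tensor) -> Tensor:
    out = Tensor(v.data[:, 0], parents=(v,),
                 backward=lambda g: v._accum(g[:, None]))
    return out


def gatedgcn_forward(h: Tensor, inc: IncidenceStructure, p: GatedGCNParams,
                     aggregation: str = "sum") -> Tensor:
    """One gated higher-order layer over the incidence structure.

    Steps: node MLP -> node-to-hyperedge mean -> hyperedge MLP ->
    hyperedge-to-node aggregation (sum/mean/min/max; isolated nodes get a
    zero structural term) -> sigmoid gate blending structure with the input.
    """
    if aggregation not in _AGGREGATIONS:
        raise ValueError(f"aggregation must be one of {_AGGREGATIONS}")
    if p.gate_weight.data.shape[1] != 2 * h.data.shape[1]:
        raise ValueError("gate weight expects concatenated [h || z'] input")
    n = inc.n_nodes

    u = p.node_mlp(h)
    m = (ad.rows(u, inc.hyperedges[:, 0]) + ad.rows(u, inc.hyperedges[:, 1])) * 0.5
    m = p.edge_mlp(m)

    gathered = ad.rows(m, inc.incidence_edge)
    if aggregation == "sum":
        z_struct = ad.scatter_sum(gathered, inc.incidence_node, n)
    elif aggregation == "mean":
        counts = np.zeros(n)
        np.add.at(counts, inc.incidence_node, 1.0)
        z_struct = ad.scatter_sum(gathered, inc.incidence_node, n) / \
            np.maximum(counts, 1.0)[:, None]
    elif aggregation == "max":
        z_struct = ad.segment_max(gathered, inc.incidence_node, n)
    else:
        z_struct = ad.segment_min(gathered, inc.incidence_node, n)

    gate = ad.sigmoid(ad.concat([h, z_struct], axis=1) @ p.gate_weight.T + p.gate_bias)
    return gate * z_struct + (1.0 - gate) * h


def combine_views(view_a: Tensor, view_b: Tensor, aggregation: str = "sum") -> Tensor:
    """Merge the two branch outputs into the classification representation."""
    if aggregation == "sum":
        return view_a + view_b
    if aggregation == "mean":
        return (view_a + view_b) * 0.5
    if aggregation == "max":
        return ad.maximum(view_a, view_b)
    if aggregation == "min":
        return ad.minimum(view_a, view_b)
    raise ValueError(f"aggregation must be one of {_AGGREGATIONS}")


def stack_encoders(h0: Tensor, adj: NormalizedAdjacency, inc: IncidenceStructure,
                   cfg: EncoderConfig, gat_params: list, gated_params: list,
                   training: bool = False,
                   rng: np.random.Generator | None = None,
                   use_gat: bool = True, use_gate: bool = True):
    """Run both branches in parallel from the same embedding table.

    Returns ``(gat_view, gated_view)`` after ``cfg.num_layers`` layers each;
    a disabled branch returns ``None``. The two views feed the contrastive
    loss and are combined (see :func:`combine_views`) for classification.
    """
    gat_view = gated_view = None
    if use_gat:
        if len(gat_params) != cfg.num_layers:
            raise ValueError("need one GATLiteParams per layer")
        gat_view = h0
        for p in gat_params:
            gat_view = gatlite_forward(gat_view, adj, p, training=training, rng=rng)
    if use_gate:
        if len(gated_params) != cfg.num_layers:
            raise ValueError("need one GatedGCNParams per layer")
        gated_view = h0
        for p in gated_params:
            gated_view = gatedgcn_forward(gated_view, inc, p,
                                          aggregation=cfg.aggregation)
    if gat_view is None and gated_view is None:
        raise ValueError("at least one encoder branch must be enabled")
    return gat_view, gated_view
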