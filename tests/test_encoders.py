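"""Encoder behavior against dense / scalar-loop oracles and invariants."""

import numpy as np
import pytest

import topolink.autodiff as ad
from topolink import (EncoderConfig, build_incidence,
                      build_normalized_adjacency, combine_views,
                      gatedgcn_forward, gatlite_forward, init_embeddings,
                      stack_encoders)
from topolink.autodiff import Tensor
from topolink.encoders import GATLiteParams, GatedGCNParams, MLPParams

from conftest import random_bipartite


# ----------------------------------------------------------------- oracles

def dense_attention_reference(h, adj, W, a, slope):
    """Dense masked-softmax attention oracle.

    Computes e_ij for ALL node pairs, masks non-neighbors with -inf,
    softmaxes each row over the self-looped neighborhood, aggregates,
    then applies ELU and row L2 normalization.
    """
    n = adj.order
    z = h @ W.T
    f = W.shape[0]
    e = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            s = a[:f] @ z[i] + a[f:] @ z[j]
            e[i, j] = s if s > 0 else slope * s
    mask = np.full((n, n), -np.inf)
    dense_adj = adj.matrix.toarray() > 0   # pattern of A~ (self loops incl.)
    mask[dense_adj] = 0.0
    e = e + mask
    e -= e.max(axis=1, keepdims=True)
    alpha = np.exp(e)
    alpha[~dense_adj] = 0.0
    alpha /= alpha.sum(axis=1, keepdims=True)
    agg = alpha @ z
    out = np.where(agg > 0, agg, np.exp(np.minimum(agg, 0)) - 1)
    norms = np.linalg.norm(out, axis=1, keepdims=True)
    return out / np.where(norms > 1e-9, norms, 1.0), alpha


def scalar_gatedgcn_reference(h, inc, p, aggregation="sum"):
    """Straight-line scalar re-evaluation of the six gated-conv steps."""
    def mlp(m, x):
        hidden = x @ m.w1.data.T + m.b1.data
        hidden = np.where(hidden > 0, hidden, np.exp(np.minimum(hidden, 0)) - 1)
        return hidden @ m.w2.data.T + m.b2.data

    n, f = h.shape
    u = mlp(p.node_mlp, h)                                   # (1) node MLP
    m_e = np.array([(u[a] + u[b]) / 2 for a, b in inc.hyperedges])  # (2)
    m_e = mlp(p.edge_mlp, m_e)                               # (3) edge MLP
    z = np.zeros((n, f))                                     # (4) back to nodes
    for i in range(n):
        incident = [e for e, (a, b) in enumerate(inc.hyperedges) if i in (a, b)]
        if not incident:
            continue
        vals = m_e[incident]
        z[i] = {"sum": vals.sum(0), "mean": vals.mean(0),
                "max": vals.max(0), "min": vals.min(0)}[aggregation]
    gate_in = np.concatenate([h, z], axis=1)
    g = 1 / (1 + np.exp(-(gate_in @ p.gate_weight.data.T + p.gate_bias.data)))
    return g * z + (1 - g) * h                               # (5)+(6)


def graph_parts(seed, **kw):
    g = random_bipartite(seed, **kw)
    return g, build_normalized_adjacency(g), build_incidence(g)


# ----------------------------------------------------------------- GATLite

class TestGATLite:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_dense_masked_softmax_reference(self, seed):
        rng = np.random.default_rng(seed)
        g, adj, _ = graph_parts(seed, n_drugs=5, n_genes=9, n_edges=20)
        assert adj.order <= 30
        f = 6
        h = rng.normal(size=(adj.order, f))
        p = GATLiteParams.init(f, f, rng)
        out = gatlite_forward(Tensor(h), adj, p)
        ref, _ = dense_attention_reference(h, adj, p.projection.data,
                                           p.attention_vector.data,
                                           p.leaky_slope)
        assert np.abs(out.data - ref).max() < 1e-5

    def test_attention_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        g, adj, _ = graph_parts(4, n_drugs=6, n_genes=10, n_edges=30)
        f = 5
        h = rng.normal(size=(adj.order, f))
        p = GATLiteParams.init(f, f, rng)
        _, alpha = dense_attention_reference(h, adj, p.projection.data,
                                             p.attention_vector.data, 0.2)
        assert np.abs(alpha.sum(axis=1) - 1).max() < 1e-9

    def test_single_neighbor_gets_full_attention(self):
        # an isolated node's only neighbor is its self-loop: softmax of one
        from topolink.graph import BipartiteGraph
        g = BipartiteGraph(("d1", "d2"), ("g1",), [(0, 0, 0)], 1, ("x",))
        adj = build_normalized_adjacency(g)
        rng = np.random.default_rng(0)
        h = rng.normal(size=(3, 4))
        p = GATLiteParams.init(4, 4, rng)
        _, alpha = dense_attention_reference(h, adj, p.projection.data,
                                             p.attention_vector.data, 0.2)
        assert alpha[1, 1] == pytest.approx(1.0)

    def test_identical_neighbors_share_attention_equally(self):
        from topolink.graph import BipartiteGraph
        # drug 0 connected to two genes given identical embeddings
        g = BipartiteGraph(("d",), ("g1", "g2"), [(0, 0, 0), (0, 1, 0)], 1, ("x",))
        adj = build_normalized_adjacency(g)
        rng = np.random.default_rng(1)
        h = rng.normal(size=(3, 4))
        h[2] = h[1]   # the two genes coincide
        h[0] = h[1]   # and the self-loop target too: all of N(0) identical
        p = GATLiteParams.init(4, 4, rng)
        _, alpha = dense_attention_reference(h, adj, p.projection.data,
                                             p.attention_vector.data, 0.2)
        assert np.allclose(alpha[0, :], [1 / 3, 1 / 3, 1 / 3])

    def test_output_rows_unit_or_zero_norm(self):
        rng = np.random.default_rng(5)
        g, adj, _ = graph_parts(6)
        f = 8
        h = rng.normal(size=(adj.order, f))
        p = GATLiteParams.init(f, f, rng)
        out = gatlite_forward(Tensor(h), adj, p)
        norms = np.linalg.norm(out.data, axis=1)
        assert np.all((np.abs(norms - 1) < 1e-6) | (norms < 1e-6))

    def test_dropout_renormalizes_rows(self):
        rng = np.random.default_rng(7)
        g, adj, _ = graph_parts(8)
        f = 4
        h = Tensor(rng.normal(size=(adj.order, f)))
        p = GATLiteParams.init(f, f, rng, attention_dropout=0.5)
        # reach into the forward path: with heavy dropout the output rows
        # must still be unit/zero norm (renormalized attention)
        out = gatlite_forward(h, adj, p, training=True,
                              rng=np.random.default_rng(0))
        norms = np.linalg.norm(out.data, axis=1)
        assert np.all((np.abs(norms - 1) < 1e-6) | (norms < 1e-6))

    def test_dimension_mismatch_raises(self):
        rng = np.random.default_rng(0)
        g, adj, _ = graph_parts(0)
        p = GATLiteParams.init(4, 4, rng)
        with pytest.raises(ValueError):
            gatlite_forward(Tensor(np.zeros((adj.order, 5))), adj, p)


# ---------------------------------------------------------------- GatedGCN

class TestGatedGCN:
    def test_zero_gate_params_blend_half_half(self):
        rng = np.random.default_rng(0)
        g, _, inc = graph_parts(1)
        f = 4
        h = rng.normal(size=(g.n_nodes, f))
        p = GatedGCNParams.init(f, rng)
        p.gate_weight.data[:] = 0.0
        p.gate_bias.data[:] = 0.0
        out = gatedgcn_forward(Tensor(h), inc, p)
        ref = scalar_gatedgcn_reference(h, inc, p)
        # sigma(0) = 0.5: output is the midpoint of structure and input
        z = 2 * ref - h   # recover z' from the blend
        assert np.abs(out.data - 0.5 * z - 0.5 * h).max() < 1e-9

    def test_large_negative_bias_is_identity_passthrough(self):
        rng = np.random.default_rng(1)
        g, _, inc = graph_parts(2)
        f = 4
        h = rng.normal(size=(g.n_nodes, f))
        p = GatedGCNParams.init(f, rng)
        p.gate_weight.data[:] = 0.0
        p.gate_bias.data[:] = -30.0
        out = gatedgcn_forward(Tensor(h), inc, p)
        assert np.abs(out.data - h).max() < 1e-9

    @pytest.mark.parametrize("aggregation", ["sum", "mean", "min", "max"])
    def test_matches_scalar_loop_reference(self, aggregation):
        rng = np.random.default_rng(1)
        g, _, inc = graph_parts(3, n_drugs=4, n_genes=6, n_edges=14)
        f = 4
        h = rng.normal(size=(g.n_nodes, f))
        p = GatedGCNParams.init(f, rng)
        out = gatedgcn_forward(Tensor(h), inc, p, aggregation=aggregation)
        ref = scalar_gatedgcn_reference(h, inc, p, aggregation)
        assert np.abs(out.data - ref).max() < 1e-6

    def test_gate_values_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(2)
        g, _, inc = graph_parts(4)
        f = 4
        h = Tensor(rng.normal(size=(g.n_nodes, f)))
        p = GatedGCNParams.init(f, rng)
        gate = ad.sigmoid(
            ad.concat([h, Tensor(np.zeros_like(h.data))], axis=1)
            @ p.gate_weight.T + p.gate_bias)
        assert np.all(gate.data > 0) and np.all(gate.data < 1)

    def test_isolated_node_keeps_input_scaled_by_gate(self):
        from topolink.graph import BipartiteGraph, build_incidence
        g = BipartiteGraph(("d1", "d2"), ("g1",), [(0, 0, 0)], 1, ("x",))
        inc = build_incidence(g)
        rng = np.random.default_rng(3)
        h = rng.normal(size=(3, 4))
        p = GatedGCNParams.init(4, rng)
        out = gatedgcn_forward(Tensor(h), inc, p)
        ref = scalar_gatedgcn_reference(h, inc, p)
        assert np.abs(out.data[1] - ref[1]).max() < 1e-9   # node d2 isolated


# ----------------------------------------------------------------- stacking

class TestStacking:
    def _params(self, f, layers, rng):
        gat = [GATLiteParams.init(f, f, rng) for _ in range(layers)]
        gated = [GatedGCNParams.init(f, rng) for _ in range(layers)]
        return gat, gated

    def test_single_layer_equals_direct_forward(self):
        rng = np.random.default_rng(0)
        g, adj, inc = graph_parts(5)
        f = 4
        h = Tensor(np.random.default_rng(1).normal(size=(g.n_nodes, f)))
        gat, gated = self._params(f, 1, rng)
        v1, v2 = stack_encoders(h, adj, inc, EncoderConfig(num_layers=1),
                                gat, gated)
        direct1 = gatlite_forward(h, adj, gat[0])
        direct2 = gatedgcn_forward(h, inc, gated[0])
        assert np.array_equal(v1.data, direct1.data)
        assert np.array_equal(v2.data, direct2.data)

    def test_sum_combination_is_elementwise_addition(self):
        rng = np.random.default_rng(2)
        a = Tensor(rng.normal(size=(5, 3)))
        b = Tensor(rng.normal(size=(5, 3)))
        assert np.array_equal(combine_views(a, b, "sum").data, a.data + b.data)
        assert np.array_equal(combine_views(a, b, "max").data,
                              np.maximum(a.data, b.data))

    @pytest.mark.parametrize("layers", [1, 2])
    def test_two_branch_forward_is_permutation_equivariant(self, layers):
        # relabeling external ids permutes the internal order; both branch
        # outputs must commute with that permutation
        from topolink import reindex_nodes
        rng = np.random.default_rng(4)
        raw = [("da", "gx", "u"), ("da", "gy", "v"), ("db", "gy", "u"),
               ("dc", "gx", "u"), ("dc", "gz", "v")]
        g1 = reindex_nodes(raw)
        renamed = {"da": "dz", "db": "da", "dc": "dm"}
        g2 = reindex_nodes([(renamed[d], gi, lab) for d, gi, lab in raw])
        # node permutation: g1 index -> g2 index
        perm = np.empty(g1.n_nodes, dtype=int)
        for i, d in enumerate(g1.drug_ids):
            perm[i] = g2.drug_index(renamed[d])
        for j, gi in enumerate(g1.gene_ids):
            perm[g1.gene_node(j)] = g2.gene_node(g2.gene_index(gi))

        f = 4
        h1 = rng.normal(size=(g1.n_nodes, f))
        h2 = np.empty_like(h1)
        h2[perm] = h1
        gat, gated = self._params(f, layers, np.random.default_rng(9))
        cfg = EncoderConfig(num_layers=layers)
        out1 = stack_encoders(Tensor(h1), build_normalized_adjacency(g1),
                              build_incidence(g1), cfg, gat, gated)
        out2 = stack_encoders(Tensor(h2), build_normalized_adjacency(g2),
                              build_incidence(g2), cfg, gat, gated)
        for v1, v2 in zip(out1, out2):
            assert np.abs(v2.data[perm] - v1.data).max() < 1e-9

    def test_layer_count_must_match_params(self):
        g, adj, inc = graph_parts(6)
        rng = np.random.default_rng(0)
        gat, gated = self._params(4, 1, rng)
        h = Tensor(np.zeros((g.n_nodes, 4)))
        with pytest.raises(ValueError):
            stack_encoders(h, adj, inc, EncoderConfig(num_layers=2), gat, gated)
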