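"""Bipartite drug-gene interaction graphs and their normalized operators.

A drug-gene interaction network is modelled as a bipartite graph whose two
node types (drugs, genes) are unified into a single consecutively indexed
node set: drugs occupy indices ``0..|D|-1`` (lexicographic order of external
ids), genes ``|D|..N-1``. Each observed interaction carries a relation class
(e.g. upregulation / downregulation, or one of 14 pharmacological relation
types), which is a supervision target, not an adjacency weight: the
adjacency is binary regardless of class.

Both encoders consume derived views of the same topology:

* :class:`NormalizedAdjacency` — the self-looped, symmetrically normalized
  operator ``A_hat = D^{-1/2} (A + I) D^{-1/2}`` stored sparse, plus the
  edge arrays of the self-looped graph used for sparse attention.
* :class:`IncidenceStructure` — one hyperedge per observed interaction pair
  (a size-2 node set), with a reverse node-to-hyperedge index, used by the
  gated higher-order propagation pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "BipartiteGraph",
    "NormalizedAdjacency",
    "IncidenceStructure",
    "ConflictingLabelError",
    "reindex_nodes",
    "build_normalized_adjacency",
    "build_incidence",
]


class ConflictingLabelError(ValueError):
    """Raised when one (drug, gene) pair appears with different labels."""

    def __init__(self, conflicts):
        self.conflicts = conflicts
        lines = [f"  ({d!r}, {g!r}): labels {sorted(labels)}"
                 for (d, g), labels in conflicts.items()]
        super().__init__(
            "conflicting labels for duplicate (drug, gene) pairs:\n" + "\n".join(lines)
        )


@dataclass(frozen=True)
class BipartiteGraph:
    """Re-indexed bipartite interaction graph; the single source of topology.

    ``edges`` is an ``(E, 3)`` int array of (drug_index, gene_index,
    relation_class) with drug_index in ``[0, n_drugs)`` and gene_index in
    ``[0, n_genes)``. The global node index of gene ``j`` is ``n_drugs + j``.
    """

    drug_ids: tuple
    gene_ids: tuple
    edges: np.ndarray
    num_classes: int
    class_labels: tuple
    _drug_index: dict = field(repr=False, default_factory=dict)
    _gene_index: dict = field(repr=False, default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "edges", np.asarray(self.edges, dtype=np.int64))
        if self.edges.ndim != 2 or self.edges.shape[1] != 3:
            raise ValueError("edges must be an (E, 3) array")
        if not self._drug_index:
            object.__setattr__(self, "_drug_index",
                               {d: i for i, d in enumerate(self.drug_ids)})
            object.__setattr__(self, "_gene_index",
                               {g: i for i, g in enumerate(self.gene_ids)})
        self._validate()

    def _validate(self):
        e = self.edges
        if len(e) and (e[:, 0].min() < 0 or e[:, 0].max() >= self.n_drugs):
            raise ValueError("drug index out of range")
        if len(e) and (e[:, 1].min() < 0 or e[:, 1].max() >= self.n_genes):
            raise ValueError("gene index out of range")
        if len(e) and (e[:, 2].min() < 0 or e[:, 2].max() >= self.num_classes):
            raise ValueError("relation class out of range")
        pairs = e[:, 0] * self.n_genes + e[:, 1]
        if len(np.unique(pairs)) != len(pairs):
            raise ValueError("duplicate (drug, gene) pairs in edge list")

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_nodes(self) -> int:
        return self.n_drugs + self.n_genes

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def drug_index(self, drug_id) -> int:
        return self._drug_index[drug_id]

    def gene_index(self, gene_id) -> int:
        return self._gene_index[gene_id]

    def gene_node(self, gene_index: int) -> int:
        """Global node index of a gene."""
        return self.n_drugs + gene_index

    def node_type(self, node: int) -> str:
        return "drug" if node < self.n_drugs else "gene"

    def external_id(self, node: int):
        if node < self.n_drugs:
            return self.drug_ids[node]
        return self.gene_ids[node - self.n_drugs]

    def replace_edges(self, edges: np.ndarray) -> "BipartiteGraph":
        """Same node set and classes, different edge subset."""
        return BipartiteGraph(self.drug_ids, self.gene_ids, edges,
                              self.num_classes, self.class_labels)


@dataclass(frozen=True)
class NormalizedAdjacency:
    """Self-looped symmetric-normalized adjacency of the unified node set.

    ``matrix`` holds A_hat in CSR form; ``degree_vector`` the degrees of the
    self-looped graph. ``att_src``/``att_dst`` enumerate the nonzeros of the
    self-looped adjacency (including the diagonal) as directed (target,
    source) pairs: entry k means node ``att_src[k]`` attends to neighbor
    ``att_dst[k]``.
    """

    order: int
    matrix: sp.csr_matrix
    degree_vector: np.ndarray
    att_src: np.ndarray
    att_dst: np.ndarray


@dataclass(frozen=True)
class IncidenceStructure:
    """One size-2 hyperedge per observed interaction, plus a reverse index.

    ``hyperedges`` is an ``(E, 2)`` array of (drug_node, gene_node) global
    indices; ``incidence_node`` / ``incidence_edge`` are flattened parallel
    arrays enumerating every (node, hyperedge) membership.
    """

    n_nodes: int
    hyperedges: np.ndarray
    incidence_node: np.ndarray
    incidence_edge: np.ndarray

    @property
    def n_hyperedges(self) -> int:
        return len(self.hyperedges)

    def node_to_hyperedges(self) -> list:
        """Reverse index: for each node, the hyperedges containing it."""
        out = [[] for _ in range(self.n_nodes)]
        for n, e in zip(self.incidence_node, self.incidence_edge):
            out[n].append(int(e))
        return out


def reindex_nodes(raw_edges) -> BipartiteGraph:
    """Map external (drug_id, gene_id, label) triples onto consecutive indices.

    The bijection is deterministic: drugs first, lexicographic order of the
    external id strings within each type; labels are mapped to classes
    ``0..C-1`` in lexicographic order of their string form. Exact duplicate
    triples are collapsed; a pair appearing with two different labels is a
    conflict and rejected with a report of every offending pair.
    """
    raw_edges = list(raw_edges)
    if not raw_edges:
        raise ValueError("empty edge list")
    pair_labels: dict = {}
    for d, g, lab in raw_edges:
        pair_labels.setdefault((d, g), set()).add(lab)
    conflicts = {p: labs for p, labs in pair_labels.items() if len(labs) > 1}
    if conflicts:
        raise ConflictingLabelError(conflicts)

    drug_ids = tuple(sorted({d for d, _, _ in raw_edges}, key=str))
    gene_ids = tuple(sorted({g for _, g, _ in raw_edges}, key=str))
    labels = tuple(sorted({lab for _, _, lab in raw_edges}, key=str))
    d_of = {d: i for i, d in enumerate(drug_ids)}
    g_of = {g: i for i, g in enumerate(gene_ids)}
    c_of = {lab: i for i, lab in enumerate(labels)}

    edges = np.array(
        sorted((d_of[d], g_of[g], c_of[next(iter(labs))])
               for (d, g), labs in pair_labels.items()),
        dtype=np.int64,
    )
    return BipartiteGraph(drug_ids, gene_ids, edges, len(labels), labels)


def build_normalized_adjacency(g: BipartiteGraph) -> NormalizedAdjacency:
    """A_hat = D^{-1/2} (A + I) D^{-1/2} over the unified node set.

    The off-diagonal blocks are binary (1 iff any interaction exists between
    the pair, regardless of relation class); every node carries a self-loop,
    so isolated nodes get A_hat[i, i] = 1 and stay embeddable.
    """
    n = g.n_nodes
    d_idx = g.edges[:, 0]
    g_idx = g.edges[:, 1] + g.n_drugs
    row = np.concatenate([d_idx, g_idx, np.arange(n)])
    col = np.concatenate([g_idx, d_idx, np.arange(n)])
    data = np.ones(len(row), dtype=np.float64)
    a_tilde = sp.coo_matrix((data, (row, col)), shape=(n, n)).tocsr()
    a_tilde.sum_duplicates()

    degree = np.asarray(a_tilde.sum(axis=1)).ravel()
    inv_sqrt = 1.0 / np.sqrt(degree)
    a_hat = sp.diags(inv_sqrt) @ a_tilde @ sp.diags(inv_sqrt)
    a_hat = a_hat.tocsr()

    coo = a_tilde.tocoo()
    order = np.lexsort((coo.col, coo.row))
    return NormalizedAdjacency(
        order=n,
        matrix=a_hat,
        degree_vector=degree.astype(np.int64),
        att_src=coo.row[order].astype(np.int64),
        att_dst=coo.col[order].astype(np.int64),
    )


def build_incidence(g: BipartiteGraph) -> IncidenceStructure:
    """One hyperedge per observed (drug, gene) interaction pair."""
    drug_nodes = g.edges[:, 0]
    gene_nodes = g.edges[:, 1] + g.n_drugs
    hyperedges = np.stack([drug_nodes, gene_nodes], axis=1)
    e_idx = np.arange(len(hyperedges))
    incidence_node = np.concatenate([drug_nodes, gene_nodes])
    incidence_edge = np.concatenate([e_idx, e_idx])
    return IncidenceStructure(
        n_nodes=g.n_nodes,
        hyperedges=hyperedges,
        incidence_node=incidence_node,
        incidence_edge=incidence_edge,
    )
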