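"""Edge-list I/O, transductive splits, negative sampling and synthetic graphs.

The synthetic generator emulates the statistical shape of curated
drug-gene interaction databases: heavy-tailed (power-law) node degree
distributions, a bipartite drug/gene node split, and a small number of
relation classes. Because the model is topology-only, the generator plants
a structural signal the model can recover: each node belongs to a latent
block, and an edge's relation class is a deterministic function of its
endpoint blocks (optionally corrupted by label noise). A perfect classifier
therefore exists, and headroom above chance is controlled by the noise rate.

Splits are transductive: every node incident to a validation or test edge
must also be incident to at least one training edge, while the edge sets
themselves are disjoint. Negative sampling is frequency-smoothed: node
draw probabilities are proportional to ``(degree + 1)^(-lambda)``, so
low-degree nodes are over-represented among sampled non-edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .graph import BipartiteGraph, reindex_nodes

__all__ = [
    "SplitSpec",
    "SyntheticConfig",
    "read_edge_list",
    "write_edge_list",
    "write_node_map",
    "make_transductive_split",
    "negative_sample",
    "generate_synthetic",
]


@dataclass
class SplitSpec:
    """Disjoint train/val/test edge-index lists covering the input edges."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    fractions: tuple = (0.8, 0.1)   # test share = 1 - fractions[0]; val = frac of train
    seed: int = 0

    def __post_init__(self):
        self.train = np.asarray(self.train, dtype=np.int64)
        self.val = np.asarray(self.val, dtype=np.int64)
        self.test = np.asarray(self.test, dtype=np.int64)

    def validate(self, g: BipartiteGraph) -> None:
        """Check disjointness, coverage and the transductive constraint."""
        allidx = np.concatenate([self.train, self.val, self.test])
        if len(np.unique(allidx)) != len(allidx):
            raise ValueError("split sets overlap")
        if sorted(allidx) != list(range(g.n_edges)):
            raise ValueError("splits do not cover the edge set exactly")
        train_edges = g.edges[self.train]
        train_drugs = set(train_edges[:, 0])
        train_genes = set(train_edges[:, 1])
        for name, idx in (("val", self.val), ("test", self.test)):
            for d, gi, _ in g.edges[idx]:
                if d not in train_drugs or gi not in train_genes:
                    raise ValueError(
                        f"transductive violation: {name} edge ({d},{gi}) has a "
                        "node absent from training edges")


@dataclass
class SyntheticConfig:
    """Planted-block bipartite graph with power-law degrees.

    Defaults are the small planted study graph used throughout the test
    suite: 50 drugs x 200 genes, 2,000 edges, 2 relation classes from a
    2x2 block rule, 5% label noise, degree-distribution tail exponent 2.5.
    """

    n_drugs: int = 50
    n_genes: int = 200
    n_edges: int = 2000
    n_classes: int = 2
    degree_exponent: float = 2.5
    n_blocks: int = 2
    label_noise: float = 0.05
    seed: int = 0
    class_rule: np.ndarray | None = None   # (n_blocks, n_blocks) -> class

    def __post_init__(self):
        if self.n_edges > self.n_drugs * self.n_genes:
            raise ValueError("n_edges exceeds the number of possible pairs")
        if not (0.0 <= self.label_noise < 1.0):
            raise ValueError("label_noise must be in [0, 1)")
        if self.degree_exponent <= 1.0:
            raise ValueError("degree_exponent must exceed 1")
        if self.class_rule is not None:
            rule = np.asarray(self.class_rule, dtype=np.int64)
            if rule.shape != (self.n_blocks, self.n_blocks):
                raise ValueError("class_rule must be (n_blocks, n_blocks)")
            if rule.min() < 0 or rule.max() >= self.n_classes:
                raise ValueError("class_rule entries must be valid classes")
            self.class_rule = rule

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if d.get("class_rule") is not None:
            d["class_rule"] = np.asarray(d["class_rule"], dtype=np.int64)
        return cls(**d)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "n_drugs", "n_genes", "n_edges", "n_classes", "degree_exponent",
            "n_blocks", "label_noise", "seed")}
        d["class_rule"] = None if self.class_rule is None else self.class_rule.tolist()
        return d


# --------------------------------------------------------------------- I/O

_HEADER = "drug_id\tgene_id\tlabel"


def read_edge_list(path) -> BipartiteGraph:
    """Parse a TSV edge list (header ``drug_id  gene_id  label``, # comments)."""
    raw = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected 3 tab-separated columns, "
                    f"got {len(parts)}")
            if not header_seen:
                if [p.strip() for p in parts] != _HEADER.split("\t"):
                    raise ValueError(
                        f"{path}: line {lineno}: expected header '{_HEADER}'")
                header_seen = True
                continue
            raw.append(tuple(parts))
    if not raw:
        raise ValueError(f"{path}: no edges found")
    return reindex_nodes(raw)


def write_edge_list(g: BipartiteGraph, path) -> None:
    """Write canonicalized TSV (edges sorted by drug id, then gene id)."""
    order = np.lexsort((g.edges[:, 1], g.edges[:, 0]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_HEADER + "\n")
        for d, gi, c in g.edges[order]:
            fh.write(f"{g.drug_ids[d]}\t{g.gene_ids[gi]}\t{g.class_labels[c]}\n")


def write_node_map(g: BipartiteGraph, path) -> None:
    """Export the external-id -> internal-index bijection."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("external_id\tinternal_index\tnode_type\n")
        for i, d in enumerate(g.drug_ids):
            fh.write(f"{d}\t{i}\tdrug\n")
        for j, gi in enumerate(g.gene_ids):
            fh.write(f"{gi}\t{g.n_drugs + j}\tgene\n")


# ------------------------------------------------------------------- splits

def make_transductive_split(g: BipartiteGraph, fractions=(0.8, 0.1),
                            seed: int = 0) -> SplitSpec:
    """Random edge split with transductive repair.

    ``fractions = (train_share, val_share_of_train)``; the test share is
    ``1 - train_share``. Any held-out edge whose drug or gene would be
    absent from training is swapped with a same-class training edge whose
    endpoints stay covered, else moved into training. The validation set is
    then carved from training the same way. Raises if the graph is too
    small to satisfy the constraints.
    """
    train_frac, val_frac = fractions
    if not (0 < train_frac < 1) or not (0 <= val_frac < 1):
        raise ValueError("fractions out of range")
    edges = g.edges
    n = len(edges)
    if n < 5:
        raise ValueError("graph too small to split: need at least 5 edges")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = int(round(n * (1 - train_frac)))
    test = list(perm[:n_test])
    train = list(perm[n_test:])

    def degrees(idx_list):
        dd = np.zeros(g.n_drugs, dtype=np.int64)
        dg = np.zeros(g.n_genes, dtype=np.int64)
        for i in idx_list:
            dd[edges[i, 0]] += 1
            dg[edges[i, 1]] += 1
        return dd, dg

    def repair(eval_set, train_set):
        """Make every eval edge's endpoints covered by train_set."""
        dd, dg = degrees(train_set)
        changed = True
        while changed:
            changed = False
            for k, ei in enumerate(list(eval_set)):
                d, gi, c = edges[ei]
                if dd[d] > 0 and dg[gi] > 0:
                    continue
                swap_done = False
                order = rng.permutation(len(train_set))
                for tj in order:
                    ti = train_set[tj]
                    td, tg, tc = edges[ti]
                    if tc != c:
                        continue
                    # removing ti must keep its endpoints covered
                    # (the incoming eval edge may itself cover them)
                    dd2 = dd[td] - 1 + (1 if td == d else 0)
                    dg2 = dg[tg] - 1 + (1 if tg == gi else 0)
                    if dd2 < 1 or dg2 < 1:
                        continue
                    train_set[tj] = ei
                    eval_set[k] = ti
                    dd[td] -= 1
                    dg[tg] -= 1
                    dd[d] += 1
                    dg[gi] += 1
                    swap_done = changed = True
                    break
                if not swap_done:
                    train_set.append(ei)
                    eval_set.pop(k)
                    dd[d] += 1
                    dg[gi] += 1
                    changed = True
                    break
        return eval_set, train_set

    test, train = repair(test, train)
    n_val = int(round(len(train) * val_frac))
    rng.shuffle(train)
    val = train[:n_val]
    train = train[n_val:]
    val, train = repair(val, train)

    spec = SplitSpec(np.sort(train), np.sort(val), np.sort(test),
                     fractions=fractions, seed=seed)
    try:
        spec.validate(g)
    except ValueError as exc:   # pragma: no cover - defensive
        raise ValueError(f"could not construct a valid transductive split: {exc}")
    if len(spec.val) == 0 and val_frac > 0 and n >= 20:
        raise ValueError("graph too small: validation set came out empty")
    return spec


# --------------------------------------------------------- negative sampling

def negative_sample(g: BipartiteGraph, n: int, smoothing: float = 0.75,
                    seed: int = 0) -> np.ndarray:
    """Draw ``n`` distinct non-interacting (drug_index, gene_index) pairs.

    Drugs and genes are sampled independently with probability proportional
    to ``(degree + 1)^(-smoothing)``, so low-degree nodes are preferred.
    Pairs colliding with positives or earlier draws are rejected and
    redrawn. Raises when the rejection budget is exhausted (dense graphs).
    """
    n_possible = g.n_drugs * g.n_genes - g.n_edges
    if n > n_possible:
        raise ValueError(f"requested {n} negatives but only {n_possible} "
                         "non-edges exist")
    rng = np.random.default_rng(seed)
    deg_d = np.zeros(g.n_drugs, dtype=np.int64)
    deg_g = np.zeros(g.n_genes, dtype=np.int64)
    np.add.at(deg_d, g.edges[:, 0], 1)
    np.add.at(deg_g, g.edges[:, 1], 1)
    w_d = (deg_d + 1.0) ** (-smoothing)
    w_g = (deg_g + 1.0) ** (-smoothing)
    w_d /= w_d.sum()
    w_g /= w_g.sum()

    positives = set(map(tuple, g.edges[:, :2]))
    taken: set = set()
    out = []
    budget = max(50 * n, 10_000)
    drawn = 0
    while len(out) < n:
        batch = min(max(2 * (n - len(out)), 64), budget - drawn)
        if batch <= 0:
            raise RuntimeError(
                "negative-sampling rejection budget exhausted (graph too "
                "dense for the requested count); try a smaller n")
        ds = rng.choice(g.n_drugs, size=batch, p=w_d)
        gs = rng.choice(g.n_genes, size=batch, p=w_g)
        drawn += batch
        for d, gi in zip(ds, gs):
            pair = (int(d), int(gi))
            if pair in positives or pair in taken:
                continue
            taken.add(pair)
            out.append(pair)
            if len(out) == n:
                break
    return np.array(out, dtype=np.int64)


# ------------------------------------------------------------------ synthetic

def generate_synthetic(cfg: SyntheticConfig):
    """Planted-block power-law bipartite graph.

    Returns ``(graph, truth)`` where ``truth`` carries the block
    assignments, the clean (pre-noise) classes and the class rule. Node
    degree propensities are Pareto-distributed with tail exponent
    ``degree_exponent - 1``, which yields an asymptotic degree-distribution
    exponent of ``degree_exponent``; each node is guaranteed at least one
    edge so that transductive splits are always possible.
    """
    rng = np.random.default_rng(cfg.seed)
    nd, ng, ne = cfg.n_drugs, cfg.n_genes, cfg.n_edges
    if ne < nd + ng:
        warnings.warn("n_edges < n_drugs + n_genes: min-degree seeding will "
                      "dominate the degree distribution", stacklevel=2)

    # Pareto propensities: P(W > w) = w^-(gamma-1)  =>  degree tail ~ gamma
    def propensities(k):
        u = rng.random(k)
        return (1.0 - u) ** (-1.0 / (cfg.degree_exponent - 1.0))

    w_d = propensities(nd)
    w_g = propensities(ng)
    p_d = w_d / w_d.sum()
    p_g = w_g / w_g.sum()

    taken: set = set()
    pairs = []

    def add_pair(d, gi) -> bool:
        key = (int(d), int(gi))
        if key in taken:
            return False
        taken.add(key)
        pairs.append(key)
        return True

    # guarantee min degree 1 per node
    for d in range(nd):
        add_pair(d, rng.choice(ng, p=p_g))
    gene_deg = np.zeros(ng, dtype=bool)
    for _, gi in pairs:
        gene_deg[gi] = True
    for gi in np.flatnonzero(~gene_deg):
        for _ in range(1000):
            if add_pair(rng.choice(nd, p=p_d), gi):
                break

    budget = 200 * ne + 10_000
    drawn = 0
    while len(pairs) < ne and drawn < budget:
        batch = min(2 * (ne - len(pairs)) + 32, budget - drawn)
        ds = rng.choice(nd, size=batch, p=p_d)
        gs = rng.choice(ng, size=batch, p=p_g)
        drawn += batch
        for d, gi in zip(ds, gs):
            if add_pair(d, gi) and len(pairs) == ne:
                break
    if len(pairs) < ne:
        # dense regime: weighted rejection stalls; fill uniformly from the
        # remaining non-edges
        warnings.warn("degree-weighted sampling stalled; filling remaining "
                      "edges uniformly from non-edges", stacklevel=2)
        all_pairs = {(d, gi) for d in range(nd) for gi in range(ng)}
        remaining = np.array(sorted(all_pairs - taken), dtype=np.int64)
        pick = rng.choice(len(remaining), size=ne - len(pairs), replace=False)
        for d, gi in remaining[pick]:
            add_pair(d, gi)

    drug_blocks = rng.integers(cfg.n_blocks, size=nd)
    gene_blocks = rng.integers(cfg.n_blocks, size=ng)
    if cfg.class_rule is not None:
        rule = cfg.class_rule
    else:
        bi, bj = np.meshgrid(np.arange(cfg.n_blocks), np.arange(cfg.n_blocks),
                             indexing="ij")
        rule = (bi + bj) % cfg.n_classes

    pairs_arr = np.array(pairs, dtype=np.int64)
    clean = rule[drug_blocks[pairs_arr[:, 0]], gene_blocks[pairs_arr[:, 1]]]
    labels = clean.copy()
    if cfg.label_noise > 0 and cfg.n_classes > 1:
        flip = rng.random(len(labels)) < cfg.label_noise
        offs = rng.integers(1, cfg.n_classes, size=len(labels))
        labels[flip] = (labels[flip] + offs[flip]) % cfg.n_classes

    digits_d = max(4, len(str(nd)))
    digits_g = max(4, len(str(ng)))
    drug_ids = tuple(f"D{i:0{digits_d}d}" for i in range(nd))
    gene_ids = tuple(f"G{j:0{digits_g}d}" for j in range(ng))
    class_labels = tuple(f"class_{c}" for c in range(cfg.n_classes))
    edges = np.column_stack([pairs_arr, labels])
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    edges = edges[order]
    clean = clean[order]
    graph = BipartiteGraph(drug_ids, gene_ids, edges, cfg.n_classes, class_labels)
    truth = {
        "drug_blocks": drug_blocks,
        "gene_blocks": gene_blocks,
        "clean_classes": clean,
        "class_rule": rule,
        "config": cfg.to_dict(),
    }
    return graph, truth
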