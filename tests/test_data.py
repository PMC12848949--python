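"""Data pipeline: I/O round trips, transductive splits, sampling, generator."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from topolink import (SyntheticConfig, generate_synthetic,
                      make_transductive_split, negative_sample,
                      read_edge_list, reindex_nodes, write_edge_list)

from conftest import random_bipartite


class TestEdgeListIO:
    @pytest.mark.parametrize("seed", range(5))
    def test_round_trip_identity(self, tmp_path, seed):
        g = random_bipartite(seed)
        p = tmp_path / "edges.tsv"
        write_edge_list(g, p)
        g2 = read_edge_list(p)
        assert g2.drug_ids == g.drug_ids
        assert g2.gene_ids == g.gene_ids
        assert np.array_equal(np.sort(g2.edges, axis=0), np.sort(g.edges, axis=0))
        # write o read is byte-identical on canonicalized files
        p2 = tmp_path / "edges2.tsv"
        write_edge_list(g2, p2)
        assert p.read_bytes() == p2.read_bytes()

    def test_missing_column_names_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("drug_id\tgene_id\tlabel\nd1\tg1\tup\nd2\tg2\n")
        with pytest.raises(ValueError, match="line 3"):
            read_edge_list(p)

    def test_crlf_and_lf_parse_identically(self, tmp_path):
        body = "drug_id\tgene_id\tlabel\nd1\tg1\tup\nd2\tg1\tdown\n"
        p_lf = tmp_path / "lf.tsv"
        p_crlf = tmp_path / "crlf.tsv"
        p_lf.write_bytes(body.encode())
        p_crlf.write_bytes(body.replace("\n", "\r\n").encode())
        g1 = read_edge_list(p_lf)
        g2 = read_edge_list(p_crlf)
        assert np.array_equal(g1.edges, g2.edges)
        assert g1.drug_ids == g2.drug_ids

    def test_comments_and_blank_lines_skipped(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("# a comment\ndrug_id\tgene_id\tlabel\n\nd1\tg1\tup\n")
        assert read_edge_list(p).n_edges == 1

    def test_missing_header_rejected(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("d1\tg1\tup\n")
        with pytest.raises(ValueError, match="header"):
            read_edge_list(p)


class TestTransductiveSplit:
    def test_ratio_100_edges(self):
        g = random_bipartite(0, n_drugs=10, n_genes=20, n_edges=100)
        spec = make_transductive_split(g, seed=0)
        # 80/20 then 10% of train to val: 72/8/20 up to repair moves
        assert abs(len(spec.test) - 20) <= 2
        assert abs(len(spec.val) - 8) <= 2
        assert abs(len(spec.train) - 72) <= 4

    def test_degree_one_nodes_never_in_eval(self):
        # star: every gene has degree 1, so all edges are forced to train
        raw = [("d1", f"g{k}", "x") for k in range(12)]
        g = reindex_nodes(raw)
        spec = make_transductive_split(g, seed=0)
        spec.validate(g)
        for idx in np.concatenate([spec.val, spec.test]):
            gi = g.edges[idx, 1]
            assert (g.edges[:, 1] == gi).sum() > 1

    @pytest.mark.parametrize("seed", range(25))
    def test_invariants_on_random_graphs(self, seed):
        g = random_bipartite(seed, n_drugs=10, n_genes=25, n_edges=140)
        spec = make_transductive_split(g, seed=seed)
        spec.validate(g)   # disjoint + covering + transductive

    def test_determinism(self):
        g = random_bipartite(2, n_drugs=10, n_genes=20, n_edges=100)
        s1 = make_transductive_split(g, seed=5)
        s2 = make_transductive_split(g, seed=5)
        assert np.array_equal(s1.train, s2.train)
        assert np.array_equal(s1.val, s2.val)
        assert np.array_equal(s1.test, s2.test)

    def test_too_small_graph_rejected(self):
        g = reindex_nodes([("d1", "g1", "x"), ("d1", "g2", "x")])
        with pytest.raises(ValueError):
            make_transductive_split(g)


class TestNegativeSampling:
    def test_only_candidate_is_found(self):
        # complete bipartite minus one pair: the sampler must return it
        raw = [(f"d{i}", f"g{j}", "x") for i in range(3) for j in range(3)
               if not (i == 1 and j == 2)]
        g = reindex_nodes(raw)
        out = negative_sample(g, 1, seed=0)
        assert out.shape == (1, 2)
        d, gi = out[0]
        assert (g.drug_ids[d], g.gene_ids[gi]) == ("d1", "g2")

    @pytest.mark.parametrize("seed", range(5))
    def test_no_collisions_with_positives_or_duplicates(self, seed):
        g = random_bipartite(seed, n_drugs=10, n_genes=20, n_edges=80)
        out = negative_sample(g, 100, seed=seed)
        pos = set(map(tuple, g.edges[:, :2]))
        drawn = set(map(tuple, out))
        assert len(drawn) == 100
        assert not drawn & pos

    def test_degree_anticorrelated_sampling(self):
        cfg = SyntheticConfig(n_drugs=100, n_genes=200, n_edges=1500,
                              label_noise=0.0, seed=0)
        g, _ = generate_synthetic(cfg)
        out = negative_sample(g, 10_000, seed=0)
        deg = np.zeros(g.n_drugs)
        np.add.at(deg, g.edges[:, 0], 1)
        freq = np.bincount(out[:, 0], minlength=g.n_drugs)
        rho = spearmanr(deg, freq).statistic
        assert rho < 0

    def test_sampled_frequencies_follow_smoothed_weights(self):
        # empirical drug frequencies vs the analytic (deg+1)^-0.75 marginal:
        # chi-square below its 99.9% quantile (pool large enough that
        # duplicate rejection barely distorts the marginal)
        from scipy.stats import chi2
        cfg = SyntheticConfig(n_drugs=100, n_genes=1000, n_edges=3000,
                              label_noise=0.0, seed=1)
        g, _ = generate_synthetic(cfg)
        n = 10_000
        out = negative_sample(g, n, seed=2)
        deg = np.zeros(g.n_drugs)
        np.add.at(deg, g.edges[:, 0], 1)
        w = (deg + 1.0) ** -0.75
        expect = w / w.sum() * n
        freq = np.bincount(out[:, 0], minlength=g.n_drugs)
        stat = ((freq - expect) ** 2 / expect).sum()
        assert stat < chi2.ppf(0.999, g.n_drugs - 1)

    def test_infeasible_count_rejected(self):
        g = reindex_nodes([("d1", "g1", "x")])
        with pytest.raises(ValueError):
            negative_sample(g, 5)


class TestSyntheticGenerator:
    def test_noise_free_rule_is_perfectly_classifiable(self):
        cfg = SyntheticConfig(n_drugs=20, n_genes=40, n_edges=200,
                              n_blocks=2, n_classes=2, label_noise=0.0, seed=3)
        g, truth = generate_synthetic(cfg)
        db, gb = truth["drug_blocks"], truth["gene_blocks"]
        rule = truth["class_rule"]
        # oracle classifier from the planted blocks scores accuracy 1.0
        pred = rule[db[g.edges[:, 0]], gb[g.edges[:, 1]]]
        assert np.array_equal(pred, g.edges[:, 2])
        # the default 2x2 rule is the XOR of the two block bits
        assert np.array_equal(rule, np.array([[0, 1], [1, 0]]))

    def test_multirelational_database_scale_generates(self):
        # the 14-relation-type regime: ~1,185 drugs x ~1,664 genes with
        # ~11,366 interactions
        cfg = SyntheticConfig(n_drugs=1185, n_genes=1664, n_edges=11366,
                              n_classes=14, n_blocks=14, seed=0)
        g, _ = generate_synthetic(cfg)
        assert g.n_edges == 11366
        assert g.num_classes == 14
        assert len(np.unique(g.edges[:, 2])) > 1

    @pytest.mark.parametrize("gamma", [2.2, 2.5, 2.8])
    def test_degree_tail_exponent_recovered(self, gamma):
        cfg = SyntheticConfig(n_drugs=2000, n_genes=4000, n_edges=20000,
                              degree_exponent=gamma, label_noise=0.0, seed=0)
        g, _ = generate_synthetic(cfg)
        deg = np.zeros(g.n_nodes)
        np.add.at(deg, g.edges[:, 0], 1)
        np.add.at(deg, g.edges[:, 1] + g.n_drugs, 1)
        # continuous Hill / maximum-likelihood fit on the tail (x_min = 5,
        # past the min-degree-1 seeding bulk)
        x_min = 5
        d = deg[deg >= x_min]
        alpha = 1 + len(d) / np.sum(np.log(d / (x_min - 0.5)))
        assert abs(alpha - gamma) < 0.3

    def test_reproducibility_byte_identical(self, tmp_path):
        cfg = SyntheticConfig(seed=11)
        g1, _ = generate_synthetic(cfg)
        g2, _ = generate_synthetic(SyntheticConfig(seed=11))
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_edge_list(g1, p1)
        write_edge_list(g2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_every_node_has_degree_at_least_one(self):
        g, _ = generate_synthetic(SyntheticConfig(seed=5))
        assert len(np.unique(g.edges[:, 0])) == g.n_drugs
        assert len(np.unique(g.edges[:, 1])) == g.n_genes

    def test_label_noise_rate_close_to_nominal(self):
        cfg = SyntheticConfig(n_drugs=100, n_genes=300, n_edges=5000,
                              label_noise=0.1, seed=2)
        g, truth = generate_synthetic(cfg)
        flipped = (g.edges[:, 2] != truth["clean_classes"]).mean()
        assert abs(flipped - 0.1) < 0.02

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_drugs=3, n_genes=3, n_edges=100)
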