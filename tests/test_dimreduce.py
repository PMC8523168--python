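import numpy as np
import pandas as pd
import pytest

from invasim.data import OtuTable
from invasim.dimreduce import (aggregate_taxonomy, jsd_matrix, pcoa,
                               run_all_reductions)
from invasim.netgroups import (AGGREGATION, SEGREGATION,
                               FunctionalGroupPartition, build_signed_network,
                               detect_functional_groups,
                               functional_group_abundances, partition_density)
from invasim.sparcc import sparcc_correlations

RANKS = ("species", "genus", "family", "order", "class", "phylum")


def _tagged_table(counts, genus):
    arr = np.asarray(counts)
    otus = [f"OTU_{j}" for j in range(arr.shape[1])]
    tax = pd.DataFrame({r: genus if r == "genus" else [f"{r}_x"] * len(otus)
                        for r in RANKS}, index=otus)
    return OtuTable(counts=pd.DataFrame(
        arr, index=[f"s{i}" for i in range(arr.shape[0])], columns=otus),
        taxonomy=tax)


class TestAggregateTaxonomy:
    def test_sums_within_label(self):
        t = _tagged_table([[5, 2, 1]], ["A", "A", "B"])
        agg = aggregate_taxonomy(t, "genus")
        assert agg.loc["s0", "A"] == 7
        assert agg.loc["s0", "B"] == 1

    def test_distinct_labels_identity(self):
        t = _tagged_table([[5, 2, 1]], ["A", "B", "C"])
        agg = aggregate_taxonomy(t, "genus")
        assert sorted(agg.loc["s0"]) == [1, 2, 5]

    def test_row_sums_conserved_at_every_rank(self, small_dataset):
        table = small_dataset["otu_table"]
        for rank in ("genus", "family", "order", "class", "phylum"):
            agg = aggregate_taxonomy(table, rank)
            pd.testing.assert_series_equal(agg.sum(axis=1),
                                           table.counts.sum(axis=1),
                                           check_names=False)

    def test_missing_labels_become_unclassified(self):
        t = _tagged_table([[5, 2]], ["A", None])
        agg = aggregate_taxonomy(t, "genus")
        assert "unclassified" in agg.columns

    def test_unknown_rank_rejected(self):
        t = _tagged_table([[1]], ["A"])
        with pytest.raises(ValueError):
            aggregate_taxonomy(t, "kingdom")


class TestJsd:
    def test_self_divergence_zero(self):
        X = np.array([[0.2, 0.3, 0.5], [0.2, 0.3, 0.5]])
        assert jsd_matrix(X)[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support_is_ln2(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert jsd_matrix(X)[0, 1] == pytest.approx(np.log(2), abs=1e-9)

    def test_half_overlap_value(self):
        X = np.array([[0.5, 0.5], [1.0, 0.0]])
        # direct evaluation: H(m) - (H(p)+H(q))/2 with m = (0.75, 0.25)
        m = np.array([0.75, 0.25])
        expected = (-(m * np.log(m)).sum()) - 0.5 * np.log(2)
        assert jsd_matrix(X)[0, 1] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.21576, abs=1e-4)

    def test_bounds_and_symmetry(self):
        rng = np.random.default_rng(0)
        X = rng.dirichlet(np.ones(6), size=10)
        D = jsd_matrix(X)
        assert np.allclose(D, D.T)
        assert (D >= -1e-12).all() and (D <= np.log(2) + 1e-12).all()
        assert np.allclose(np.diag(D), 0.0)

    def test_non_simplex_rejected(self):
        with pytest.raises(ValueError):
            jsd_matrix(np.array([[0.5, 0.6]]))


class TestPcoa:
    def test_collinear_points_single_axis(self):
        pts = np.array([0.0, 1.0, 2.0])
        D = np.abs(pts[:, None] - pts[None, :])
        coords, eigvals = pcoa(D, k=2)
        assert (eigvals > 1e-9).sum() == 1
        d1 = np.abs(coords.iloc[:, 0].to_numpy()[:, None]
                    - coords.iloc[:, 0].to_numpy()[None, :])
        np.testing.assert_allclose(d1, D, atol=1e-9)

    def test_planted_2d_configuration_reconstructed(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(4, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        coords, _ = pcoa(D, k=2)
        rec = np.linalg.norm(coords.to_numpy()[:, None]
                             - coords.to_numpy()[None, :], axis=-1)
        np.testing.assert_allclose(rec, D, atol=1e-9)

    def test_zero_matrix_gives_zero_coordinates(self):
        coords, _ = pcoa(np.zeros((4, 4)), k=2)
        assert np.allclose(coords.to_numpy(), 0.0)

    def test_asymmetric_rejected(self):
        D = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError):
            pcoa(D, k=1)

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(6, 3))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        c1, _ = pcoa(D, k=3)
        c2, _ = pcoa(D, k=3)
        pd.testing.assert_frame_equal(c1, c2)
        for col in c1.columns:
            v = c1[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0


class TestSparcc:
    def test_null_data_has_weak_correlations(self):
        rng = np.random.default_rng(5)
        basis = rng.lognormal(0, 1, (200, 50))
        counts = np.array([rng.multinomial(20000, f / f.sum()) for f in basis])
        rho, _ = sparcc_correlations(counts, n_bootstrap=0, seed=1)
        off = np.abs(rho[np.triu_indices(50, 1)])
        assert off.mean() < 0.1

    def test_planted_pair_recovered(self):
        rng = np.random.default_rng(6)
        basis = rng.lognormal(0, 1, (200, 22))
        basis[:, 1] = basis[:, 0] * rng.lognormal(0, 0.05, 200)
        counts = np.array([rng.multinomial(20000, f / f.sum()) for f in basis])
        rho, _ = sparcc_correlations(counts, n_bootstrap=0, seed=1)
        assert rho[0, 1] > 0.8

    def test_too_few_otus_rejected(self):
        counts = np.random.default_rng(0).integers(1, 100, (20, 3))
        with pytest.raises(ValueError):
            sparcc_correlations(counts)

    def test_too_few_communities_rejected(self):
        counts = np.random.default_rng(0).integers(1, 100, (5, 10))
        with pytest.raises(ValueError):
            sparcc_correlations(counts)

    def test_pseudo_pvalues_calibrated(self):
        rng = np.random.default_rng(7)
        basis = rng.lognormal(0, 1, (100, 12))
        counts = np.array([rng.multinomial(5000, f / f.sum()) for f in basis])
        _, pvals = sparcc_correlations(counts, n_bootstrap=50, seed=2)
        off = pvals[np.triu_indices(12, 1)]
        # null data: p-values should not pile up near zero
        assert (off < 0.05).mean() < 0.25


class TestSignedNetwork:
    def test_edge_rules(self):
        corr = np.array([[1.0, 0.5, -0.3, 0.5],
                         [0.5, 1.0, 0.1, 0.0],
                         [-0.3, 0.1, 1.0, 0.0],
                         [0.5, 0.0, 0.0, 1.0]])
        pvals = np.array([[0.0, 0.001, 0.005, 0.02],
                          [0.001, 0.0, 0.001, 0.5],
                          [0.005, 0.001, 0.0, 0.5],
                          [0.02, 0.5, 0.5, 0.0]])
        g = build_signed_network(corr, pvals, otu_ids=list("abcd"))
        assert g.edges["a", "b"]["type"] == AGGREGATION
        assert g.edges["a", "c"]["type"] == SEGREGATION
        assert not g.has_edge("a", "d")  # p = 0.02 not < 0.01
        assert not g.has_edge("b", "c")  # |r| = 0.1 not > 0.2

    def test_thresholds_strict(self):
        corr = np.array([[1.0, 0.2], [0.2, 1.0]])
        pvals = np.array([[0.0, 0.001], [0.001, 0.0]])
        g = build_signed_network(corr, pvals, otu_ids=["a", "b"])
        assert g.number_of_edges() == 0


def _clique_graph(blocks, edge_type=AGGREGATION):
    import networkx as nx
    g = nx.Graph()
    for nodes in blocks:
        for i, u in enumerate(nodes):
            for v in nodes[i + 1:]:
                g.add_edge(u, v, r=0.5, p=0.001, type=edge_type)
    return g


class TestFunctionalGroups:
    def test_disjoint_cliques_recovered_with_density_one(self):
        g = _clique_graph([[f"N{i}" for i in range(4)],
                           [f"M{i}" for i in range(4)]])
        part = detect_functional_groups(g)
        assert part.partition_density == pytest.approx(1.0)
        groups = list(part.groups.values())
        assert sorted(map(sorted, groups)) == [
            [f"M{i}" for i in range(4)], [f"N{i}" for i in range(4)]]

    def test_star_leaves_cluster_apart_from_hub(self):
        import networkx as nx
        g = nx.Graph()
        for i in range(5):
            g.add_edge("hub", f"leaf{i}", r=0.5, p=0.001, type=AGGREGATION)
        part = detect_functional_groups(g)
        groups = {frozenset(v) for v in part.groups.values()}
        assert frozenset(f"leaf{i}" for i in range(5)) in groups
        assert frozenset(["hub"]) in groups

    def test_planted_three_block_recovery(self):
        rng = np.random.default_rng(8)
        blocks = [[f"A{i}" for i in range(8)], [f"B{i}" for i in range(8)],
                  [f"C{i}" for i in range(8)]]
        import networkx as nx
        g = nx.Graph()
        for b, nodes in enumerate(blocks):
            for i, u in enumerate(nodes):
                for v in nodes[i + 1:]:
                    if rng.random() < 0.9:
                        g.add_edge(u, v, r=0.5, p=0.001,
                                   type=AGGREGATION if b != 1 else SEGREGATION)
        for u in blocks[0]:
            for v in blocks[1]:
                if rng.random() < 0.05:
                    g.add_edge(u, v, r=0.3, p=0.001, type=AGGREGATION)
        part = detect_functional_groups(g)
        truth = {n: b for b, nodes in enumerate(blocks) for n in nodes}
        pred = part.membership
        nodes = [n for n in truth if n in pred]
        same_t = np.array([[truth[u] == truth[v] for v in nodes] for u in nodes])
        same_p = np.array([[pred[u] == pred[v] for v in nodes] for u in nodes])
        iu = np.triu_indices(len(nodes), 1)
        rand = (same_t[iu] == same_p[iu]).mean()
        assert rand > 0.9

    def test_relabeling_invariance(self):
        g = _clique_graph([["x1", "x2", "x3", "x4"], ["y1", "y2", "y3", "y4"]])
        part1 = detect_functional_groups(g)
        import networkx as nx
        mapping = {n: f"z{i}" for i, n in enumerate(sorted(g.nodes))}
        g2 = nx.relabel_nodes(g, mapping)
        part2 = detect_functional_groups(g2)
        relabeled = {frozenset(mapping[n] for n in v)
                     for v in part1.groups.values()}
        assert relabeled == {frozenset(v) for v in part2.groups.values()}

    def test_empty_network_rejected(self):
        import networkx as nx
        with pytest.raises(ValueError):
            detect_functional_groups(nx.Graph())


class TestGroupAbundances:
    @staticmethod
    def _table(n_otus=9, n_comm=4, seed=0):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 50, size=(n_comm, n_otus))
        return OtuTable(counts=pd.DataFrame(
            counts, index=[f"s{i}" for i in range(n_comm)],
            columns=[f"OTU_{j}" for j in range(n_otus)]))

    @staticmethod
    def _partition(sizes):
        membership, k = {}, 0
        for gid, size in enumerate(sizes):
            for _ in range(size):
                membership[f"OTU_{k}"] = gid
                k += 1
        return FunctionalGroupPartition(membership=membership,
                                        partition_density=1.0, n_edges=1)

    def test_small_groups_fall_into_remainder(self):
        feats = functional_group_abundances(self._table(), self._partition(
            [4, 3, 2]), min_size=3)
        assert set(feats.columns) == {"group_00", "group_01", "remainder"}

    def test_feature_is_mean_count(self):
        counts = pd.DataFrame([[10, 20, 30]], index=["s0"],
                              columns=["OTU_0", "OTU_1", "OTU_2"])
        table = OtuTable(counts=counts)
        feats = functional_group_abundances(table, self._partition([3]),
                                            min_size=3)
        assert feats.loc["s0", "group_00"] == pytest.approx(20.0)

    def test_empty_remainder_is_zero(self):
        feats = functional_group_abundances(self._table(), self._partition(
            [9]), min_size=3)
        assert (feats["remainder"] == 0.0).all()

    def test_merge_rule_rescues_small_groups(self):
        feats = functional_group_abundances(
            self._table(), self._partition([4, 3, 2]), min_size=3,
            merge_rules={"special": [2]})
        assert "special" in feats.columns

    def test_min_size_validated(self):
        with pytest.raises(ValueError):
            functional_group_abundances(self._table(), self._partition([9]),
                                        min_size=0)


def test_run_all_reductions_cardinality(small_dataset, small_config):
    table = small_dataset["otu_table"]
    red = run_all_reductions(table, k_pcoa=3, n_bootstrap=100, seed=0)
    assert set(red.tables) == {"genus", "family", "order", "class", "phylum",
                               "jsd_pcoa", "functional_groups"}
    assert red.tables["jsd_pcoa"].shape[1] == 3
    for name, meta in red.metadata.items():
        assert meta["n_features"] == red.tables[name].shape[1]
    # synthetic taxonomy: one genus per planted group
    assert red.tables["genus"].shape[1] == small_config.n_groups
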