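import dendropy
import networkx as nx
import numpy as np
import pytest

from dupdyn.family_clustering import (
    build_graph,
    filter_hits,
    family_matrix,
    group_ages,
    group_specific_families,
    lineage_specific_rate,
    mcl_cluster,
    summarize_families,
)
from dupdyn.io_formats import GeneFamily, SimilarityHit


def make_hit(q, s, evalue=1e-20, aln=100, ident=80.0, bits=100.0):
    return SimilarityHit(
        query=q, subject=s, pct_identity=ident, aln_length=aln, mismatch=0,
        gapopen=0, qstart=1, qend=aln, sstart=1, send=aln,
        evalue=evalue, bitscore=bits,
    )


class TestFilterHits:
    LENGTHS = {"a": 100, "b": 80}

    def test_evalue_threshold_is_strict(self):
        assert filter_hits([make_hit("a", "b", evalue=1e-4)], self.LENGTHS) == []
        assert filter_hits([make_hit("a", "b", evalue=1e-5)], self.LENGTHS) == []
        assert len(filter_hits([make_hit("a", "b", evalue=9e-6)], self.LENGTHS)) == 1

    def test_coverage_over_longest_sequence(self):
        # 40 of max(100, 80) residues -> 0.40 < 0.5
        assert filter_hits([make_hit("a", "b", aln=40)], self.LENGTHS) == []
        assert len(filter_hits([make_hit("a", "b", aln=60)], self.LENGTHS)) == 1

    def test_self_hits_removed_and_unknown_length_errors(self):
        assert filter_hits([make_hit("a", "a")], self.LENGTHS) == []
        with pytest.raises(KeyError):
            filter_hits([make_hit("a", "zzz")], self.LENGTHS)


class TestBuildGraph:
    def test_weight_is_neglog10_evalue(self):
        g = build_graph([make_hit("a", "b", evalue=1e-50)])
        assert g["a"]["b"]["weight"] == pytest.approx(50.0)

    def test_zero_evalue_capped_at_200(self):
        g = build_graph([make_hit("a", "b", evalue=0.0)])
        assert g["a"]["b"]["weight"] == 200.0

    def test_reciprocal_hits_merge_by_max(self):
        g = build_graph(
            [make_hit("a", "b", evalue=1e-30), make_hit("b", "a", evalue=1e-40)]
        )
        assert g.number_of_edges() == 1
        assert g["a"]["b"]["weight"] == pytest.approx(40.0)


class TestMcl:
    def triangle(self, names):
        g = nx.Graph()
        for i in range(3):
            for j in range(i + 1, 3):
                g.add_edge(names[i], names[j], weight=1.0)
        return g

    def test_disjoint_triangles_give_two_clusters(self):
        g = nx.compose(self.triangle("abc"), self.triangle("xyz"))
        res = mcl_cluster(g)
        got = sorted(sorted(x for _, x in f.members) for f in res.families)
        assert got == [["a", "b", "c"], ["x", "y", "z"]]

    def test_isolated_node_becomes_singleton(self):
        g = self.triangle("abc")
        g.add_node("solo")
        res = mcl_cluster(g)
        assert {frozenset(x for _, x in f.members) for f in res.families} == {
            frozenset("abc"), frozenset(["solo"])
        }

    def test_partition_and_relabel_invariance(self):
        rng = np.random.default_rng(7)
        g = nx.Graph()
        for i in range(4):
            for j in range(i + 1, 4):
                g.add_edge(f"a{i}", f"a{j}", weight=5.0)
                g.add_edge(f"b{i}", f"b{j}", weight=5.0)
        g.add_edge("a0", "b0", weight=0.2)
        res = mcl_cluster(g)
        all_genes = [x for f in res.families for _, x in f.members]
        assert sorted(all_genes) == sorted(g.nodes)  # disjoint + covering
        # relabel nodes and permute edge insertion order
        mapping = {v: f"z{ord(v[0])}{v[1]}" for v in g.nodes}
        edges = list(g.edges(data=True))
        rng.shuffle(edges)
        h = nx.Graph()
        h.add_edges_from(
            (mapping[u], mapping[v], {"weight": d["weight"]}) for u, v, d in edges
        )
        res2 = mcl_cluster(h)
        remapped = {
            frozenset(mapping[x] for _, x in f.members) for f in res.families
        }
        assert remapped == {
            frozenset(x for _, x in f.members) for f in res2.families
        }

    def test_planted_separated_families_recovered(self):
        # high within-family, zero between-family similarity
        rng = np.random.default_rng(3)
        g = nx.Graph()
        truth = []
        for fam in range(5):
            size = int(rng.integers(2, 6))
            names = [f"SP{fam % 2}|f{fam}_{i}" for i in range(size)]
            truth.append(frozenset(names))
            for i in range(size):
                for j in range(i + 1, size):
                    g.add_edge(names[i], names[j], weight=float(rng.uniform(20, 60)))
        res = mcl_cluster(g)
        got = {frozenset(x for _, x in f.members) for f in res.families}
        assert got == set(truth)


class TestSummaries:
    FAMS = [
        GeneFamily("F1", frozenset({("A", "A|g1"), ("A", "A|g2"), ("B", "B|g1")})),
        GeneFamily("F2", frozenset({("B", "B|g2")})),
    ]

    def test_multi_copy_requires_two_members_of_species(self):
        df = summarize_families(self.FAMS, {"A": 2, "B": 3})
        assert df.loc["A", "multi_copy"] == 2
        assert df.loc["A", "single_copy"] == 0
        assert df.loc["B", "multi_copy"] == 0
        # B|g1 + B|g2 single copy, 1 unclustered
        assert df.loc["B", "single_copy"] == 3
        assert df.loc["B", "unclustered"] == 1

    def test_all_singletons_give_no_multicopy(self):
        fams = [
            GeneFamily("F1", frozenset({("A", "A|g1")})),
            GeneFamily("F2", frozenset({("A", "A|g2")})),
        ]
        df = summarize_families(fams, {"A": 2})
        assert df.loc["A", "multi_copy"] == 0

    def test_family_matrix_row_sums_are_family_sizes(self):
        m = family_matrix(self.FAMS)
        assert m.loc["F1"].sum() == 3
        assert m.loc["F2"].sum() == 1

    def test_group_specific(self):
        only_a = group_specific_families(self.FAMS, {"A"})
        assert only_a == []
        both = group_specific_families(self.FAMS, {"A", "B"})
        assert {f.family_id for f in both} == {"F1", "F2"}


class TestLineageRate:
    def test_direct_division(self, toy_tree):
        # group {A, B}: stem 0.5, crown 0.5 -> denominator 1.0
        assert lineage_specific_rate(120, toy_tree, {"A", "B"}) == pytest.approx(120.0)

    def test_zero_count_zero_rate(self, toy_tree):
        assert lineage_specific_rate(0, toy_tree, {"A", "B"}) == 0.0

    def test_single_species_crown_is_zero(self, toy_tree):
        stem, crown = group_ages(toy_tree, {"C"})
        assert (stem, crown) == (0.3, 0.0)

    def test_non_monophyletic_group_rejected(self, toy_tree):
        with pytest.raises(ValueError, match="monophyletic"):
            lineage_specific_rate(5, toy_tree, {"A", "C"})

    def test_ages_agree_with_root_distance_oracle(self):
        rng = np.random.default_rng(11)

        def random_newick(labels):
            if len(labels) == 1:
                return f"{labels[0]}:{rng.uniform(0.1, 1.0):.4f}"
            k = int(rng.integers(1, len(labels)))
            left, right = labels[:k], labels[k:]
            return (
                f"({random_newick(left)},{random_newick(right)})"
                f":{rng.uniform(0.1, 1.0):.4f}"
            )

        for _ in range(10):
            labels = [f"t{i}" for i in range(10)]
            rng.shuffle(labels)
            tree = dendropy.Tree.get(
                data=random_newick(labels) + ";",
                schema="newick",
                rooting="default-rooted",
            )
            # pick a random internal clade
            internals = [
                nd for nd in tree.preorder_internal_node_iter()
                if nd is not tree.seed_node
            ]
            node = internals[int(rng.integers(len(internals)))]
            group = {lf.taxon.label for lf in node.leaf_iter()}
            stem, crown = group_ages(tree, group)
            # oracle: ages from dendropy root distances
            tree.calc_node_root_distances()
            mrca = tree.mrca(taxa=[t for t in tree.taxon_namespace if t.label in group])
            crown_oracle = max(
                lf.root_distance for lf in mrca.leaf_iter()
            ) - mrca.root_distance
            assert stem == pytest.approx(mrca.edge.length)
            assert crown == pytest.approx(crown_oracle)
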