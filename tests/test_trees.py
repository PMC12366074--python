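"""Tree model, I/O, LCA services, lca-mapping, and event inference."""

import numpy as np
import pytest

import plrdist as P
from conftest import clade, naive_dist, naive_lca, simulate_pool


class TestParsing:
    def test_species_tree_structure(self):
        S = P.parse_species_tree("((C,D)z1,(A,B)z2)z0;")
        assert sorted(S.leaf_names) == ["A", "B", "C", "D"]
        assert S.root.name == "z0"
        assert len(S) == 7

    def test_two_leaf_tree(self):
        S = P.parse_species_tree("(A,B)r;")
        assert len(S.leaves) == 2

    def test_non_binary_species_tree_rejected(self):
        with pytest.raises(P.TreeError, match="binary"):
            P.parse_species_tree("((A,B),C,D);")

    def test_duplicate_leaf_names_rejected(self):
        with pytest.raises(P.TreeError, match="duplicate"):
            P.parse_species_tree("(A,A);")

    def test_malformed_newick_rejected(self):
        with pytest.raises(P.TreeError):
            P.parse_species_tree("((A,B;")

    def test_unnamed_internal_nodes_get_stable_ids(self):
        S = P.parse_species_tree("((A,B),(C,D));")
        names = [v.name for v in S.nodes]
        assert len(set(names)) == len(names)
        assert all(n for n in names)

    def test_reconciled_nhx_round_trip(self, fig1):
        r1, _, S = fig1
        text = P.write_reconciled_tree(r1)
        back = P.parse_reconciled_tree(text, S)
        assert P.is_isomorphic(r1, back)

    def test_reconciled_missing_event_rejected(self):
        S = P.parse_species_tree("(A,B)X;")
        bad = "(u[&&NHX:S=A],v[&&NHX:S=B])p[&&NHX:S=X];"
        with pytest.raises(P.TreeError, match="event"):
            P.parse_reconciled_tree(bad, S)

    def test_reconciled_unknown_species_rejected(self):
        S = P.parse_species_tree("(A,B)X;")
        bad = "(u[&&NHX:S=A],v[&&NHX:S=Q])p[&&NHX:S=X:Ev=spec];"
        with pytest.raises(P.TreeError, match="no node named"):
            P.parse_reconciled_tree(bad, S)

    def test_leaf_with_internal_event_rejected(self):
        S = P.parse_species_tree("(A,B)X;")
        bad = "(u[&&NHX:S=A:Ev=dup],v[&&NHX:S=B])p[&&NHX:S=X:Ev=spec];"
        with pytest.raises(P.TreeError, match="carries event"):
            P.parse_reconciled_tree(bad, S)

    def test_single_leaf_reconciliation(self):
        S = P.parse_species_tree("(A,B)X;")
        rec = P.parse_reconciled_tree("a[&&NHX:S=A];", S)
        assert P.validate_reconciliation(rec) == []

    def test_tsv_annotation_input(self, fig1):
        r1, _, S = fig1
        newick = P.write_newick(r1.gene_tree)
        rows = "\n".join(
            f"{v.name}\t{r1.mu[v].name}\t{r1.events[v]}"
            for v in r1.gene_tree.nodes
        )
        back = P.parse_reconciled_tree_tsv(newick, rows, S)
        assert P.is_isomorphic(r1, back)

    def test_tsv_missing_node_rejected(self):
        S = P.parse_species_tree("(A,B)X;")
        with pytest.raises(P.TreeError, match="missing"):
            P.parse_reconciled_tree_tsv("(u,v)p;", "u\tA\textant", S)


class TestLcaAndDist:
    def test_lca_examples(self, fig1):
        _, _, S = fig1
        assert S.lca(S.node("C"), S.node("D")).name == "z1"
        assert S.lca(S.root, S.node("A")) is S.root
        assert S.lca(S.node("A"), S.node("A")) is S.node("A")

    def test_depth_of_root_is_zero(self, fig1):
        _, _, S = fig1
        assert S.depth(S.root) == 0

    def test_lca_matches_naive_oracle_on_random_tree(self):
        S = P.random_species_tree(200, seed=11)
        rng = np.random.default_rng(0)
        nodes = S.nodes
        for _ in range(2000):
            u, v = (
                nodes[int(rng.integers(len(nodes)))],
                nodes[int(rng.integers(len(nodes)))],
            )
            assert S.lca(u, v) is naive_lca(u, v)

    def test_dist_matches_naive_path_length(self):
        S = P.random_species_tree(60, seed=3)
        nodes = S.nodes
        for u in nodes[::3]:
            for v in nodes[::4]:
                assert P.dist(S, u, v) == naive_dist(u, v)

    def test_dist_examples(self, fig1):
        _, _, S = fig1
        assert P.dist(S, S.node("z1"), S.node("z0")) == 1
        assert P.dist(S, S.node("A"), S.node("A")) == 0

    def test_caterpillar_deepest_internal_distance(self):
        n = 5
        S = P.parse_species_tree("((((A,B),C),D),E);")
        deepest = max(
            (v for v in S.nodes if not v.is_leaf), key=S.depth
        )
        assert P.dist(S, deepest, S.root) == n - 2

    def test_cross_tree_query_rejected(self, fig1):
        _, _, S = fig1
        other = P.parse_species_tree("(A,B)X;")
        with pytest.raises(P.TreeError):
            S.lca(S.root, other.root)


class TestLcaMapping:
    def test_fig1_caption_values(self, fig1):
        r1, _, S = fig1
        mu = P.lca_map_to_species(
            r1.gene_tree, S, {"a": "A", "b": "B", "c": "C", "d": "D"}
        )
        g = r1.gene_tree
        assert mu[g.node("x0")].name == "z0"
        assert mu[g.node("x1")].name == "z1"
        assert mu[g.node("x2")].name == "z2"

    def test_single_species_family_maps_to_that_leaf(self):
        S = P.parse_species_tree("(A,B)X;")
        g = P.parse_gene_tree("((u,v),w);")
        mu = P.lca_map_to_species(g, S, {x: "A" for x in "uvw"})
        assert all(mu[v].name == "A" for v in g.nodes)

    def test_matches_naive_per_node_lca(self, small_pool):
        recs, S = small_pool
        for rec in recs[:5]:
            g = rec.gene_tree
            leaf_sp = rec.leaf_species()
            mu = P.lca_map_to_species(g, S, leaf_sp)
            for v in g.nodes:
                species = [S.node(leaf_sp[x]) for x in clade(v)]
                expect = species[0]
                for s in species[1:]:
                    expect = naive_lca(expect, s)
                assert mu[v] is expect

    def test_unassigned_leaf_rejected(self):
        S = P.parse_species_tree("(A,B)X;")
        g = P.parse_gene_tree("(u,v);")
        with pytest.raises(P.TreeError, match="no assigned species"):
            P.lca_map_to_species(g, S, {"u": "A"})


class TestEventInference:
    def test_same_species_cherry_is_duplication(self):
        S = P.parse_species_tree("(A,B)X;")
        g = P.parse_gene_tree("(a1,a2)p;")
        mu = P.lca_map_to_species(g, S, {"a1": "A", "a2": "A"})
        ev = P.infer_event_labels(g, S, mu)
        assert ev[g.node("p")] == P.DUP

    def test_cross_species_cherry_is_speciation(self):
        S = P.parse_species_tree("(A,B)X;")
        g = P.parse_gene_tree("(a,b)p;")
        mu = P.lca_map_to_species(g, S, {"a": "A", "b": "B"})
        ev = P.infer_event_labels(g, S, mu)
        assert ev[g.node("p")] == P.SPEC

    def test_polytomy_is_never_speciation(self):
        S = P.parse_species_tree("((A,B)X,C)Y;")
        g = P.parse_gene_tree("(a,b,c)p;")
        mu = P.lca_map_to_species(g, S, {"a": "A", "b": "B", "c": "C"})
        ev = P.infer_event_labels(g, S, mu)
        assert ev[g.node("p")] == P.DUP

    def test_lca_reconciliation_always_validates(self):
        for seed in range(5):
            recs, S = simulate_pool(6, 3, 2, seed=seed)
            for rec in recs:
                relabeled = P.reconcile_lca(
                    rec.gene_tree, S, rec.leaf_species()
                )
                assert P.validate_reconciliation(relabeled) == []


class TestValidation:
    def test_fig1_trees_are_valid(self, fig1):
        r1, r2, _ = fig1
        assert P.validate_reconciliation(r1) == []
        assert P.validate_reconciliation(r2) == []

    def test_spec_with_three_children_flagged(self):
        S = P.parse_species_tree("((A,B)X,C)Y;")
        g = P.parse_gene_tree("(a,b,c)p;")
        mu = P.lca_map_to_species(g, S, {"a": "A", "b": "B", "c": "C"})
        ev = dict(P.infer_event_labels(g, S, mu))
        ev[g.node("p")] = P.SPEC
        bad = P.ReconciledGeneTree(g, S, mu, ev)
        rules = {v.rule for v in P.validate_reconciliation(bad)}
        assert "speciations-separate-species" in rules

    def test_child_above_parent_flagged(self):
        S = P.parse_species_tree("((A,B)X,C)Y;")
        g = P.parse_gene_tree("((a,b)q,c)p;")
        mu = P.lca_map_to_species(g, S, {"a": "A", "b": "B", "c": "C"})
        ev = P.infer_event_labels(g, S, mu)
        mu = dict(mu)
        mu[g.node("p")] = S.node("X")  # q maps to X but so does p's sibling-of c
        mu[g.node("q")] = S.node("Y")  # child strictly above its parent
        bad = P.ReconciledGeneTree(g, S, mu, ev)
        rules = {v.rule for v in P.validate_reconciliation(bad)}
        assert "time-consistency" in rules

    def test_leaf_mapped_to_internal_species_flagged(self):
        S = P.parse_species_tree("(A,B)X;")
        g = P.parse_gene_tree("(u,v)p;")
        mu = {g.node("u"): S.node("X"), g.node("v"): S.node("B"), g.node("p"): S.root}
        ev = {g.node("u"): P.EXTANT, g.node("v"): P.EXTANT, g.node("p"): P.DUP}
        bad = P.ReconciledGeneTree(g, S, mu, ev)
        rules = {v.rule for v in P.validate_reconciliation(bad)}
        assert "leaves-extant" in rules


class TestChildOrderInvariance:
    def test_measure_invariant_under_child_reordering(self, fig1):
        r1, r2, S = fig1
        base = P.d_plr(r1, r2, 0.5).d_plr
        flipped = r1.copy()
        for v in flipped.gene_tree.nodes:
            v.children.reverse()
        flipped.gene_tree = P.GeneTree(flipped.gene_tree.root)
        assert P.d_plr(flipped, r2, 0.5).d_plr == base
        assert P.validate_reconciliation(flipped) == []
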