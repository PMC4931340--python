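"""Duplication tagging, congruence and ortholog/paralog classification."""

import itertools

import numpy as np
import pytest

from dictycomp.io_formats import SPECIES_CODES, read_newick
from dictycomp.orthology import (
    classify_homologs,
    compare_architecture,
    congruent_with_species_tree,
    conservation_category,
    tag_duplications,
)
from dictycomp.simulate import (
    SimulationConfig,
    default_species_tree,
    simulate_family,
)

SPECIES_TREE = default_species_tree()


def history_to_newick(root):
    """Render a simulator gene history as a Newick string."""

    def fmt(node):
        if node.kind == "leaf":
            return f"{node.gene_id}:{max(node.edge_len, 1e-6)}"
        inner = ",".join(fmt(c) for c in node.children)
        return f"({inner}):{max(node.edge_len, 1e-6)}"

    if root.kind == "leaf":
        return f"({root.gene_id}:1);"
    inner = ",".join(fmt(c) for c in root.children)
    return f"({inner});"


def lca_reconciliation_labels(gene_tree, species_tree, species_map):
    """Independent brute-force oracle: LCA-mapping reconciliation.

    Each gene-tree node maps to the species-tree LCA of its leaf
    species; a node is a duplication iff it maps to the same
    species-tree node as one of its children.
    """
    sp_nodes = {}
    for node in species_tree.postorder_node_iter():
        key = frozenset(lf.taxon.label for lf in node.leaf_iter())
        sp_nodes[key] = node
    depth = {}
    for node in species_tree.preorder_node_iter():
        depth[id(node)] = 0 if node.parent_node is None else depth[id(node.parent_node)] + 1

    def sp_lca(species):
        nodes = [sp_nodes[frozenset({s})] for s in species]
        while len({id(n) for n in nodes}) > 1:
            deepest = max(nodes, key=lambda n: depth[id(n)])
            nodes = [n.parent_node if id(n) == id(deepest) else n for n in nodes]
        return nodes[0]

    mapping, labels = {}, {}
    for node in gene_tree.postorder_node_iter():
        if node.is_leaf():
            mapping[id(node)] = sp_lca({species_map[node.taxon.label]})
            continue
        species = {species_map[lf.taxon.label] for lf in node.leaf_iter()}
        mapping[id(node)] = sp_lca(species)
        dup = any(mapping[id(c)] is mapping[id(node)] for c in node.child_nodes())
        labels[node] = "duplication" if dup else "speciation"
    return labels


class TestTagDuplications:
    def test_forced_duplication_root(self):
        tree = read_newick("((A1:1,B1:1):1,(A2:1,B2:1):1);", rooted=True)
        sp = {"A1": "A", "A2": "A", "B1": "B", "B2": "B"}
        labels = tag_duplications(tree, sp)
        by_leafset = {frozenset(lf.taxon.label for lf in n.leaf_iter()): lab
                      for n, lab in labels.items()}
        assert by_leafset[frozenset({"A1", "B1", "A2", "B2"})] == "duplication"
        assert by_leafset[frozenset({"A1", "B1"})] == "speciation"
        assert by_leafset[frozenset({"A2", "B2"})] == "speciation"

    def test_single_copy_tree_no_duplications(self):
        tree = read_newick("(((A1:1,B1:1):1,C1:1):1,D1:1);", rooted=True)
        sp = {x: x[0] for x in ("A1", "B1", "C1", "D1")}
        labels = tag_duplications(tree, sp)
        assert set(labels.values()) == {"speciation"}

    def test_unmapped_leaf_rejected(self):
        tree = read_newick("(A:1,B:1);", rooted=True)
        with pytest.raises(ValueError, match="B"):
            tag_duplications(tree, {"A": "A"})

    def test_matches_reconciliation_oracle_on_lossless_histories(self):
        """Species overlap equals LCA reconciliation on true histories
        without losses."""
        cfg = SimulationConfig(dup_rate=0.3, loss_rate=0.0, seq_length=10, seed=21)
        rng = np.random.default_rng(21)
        for i in range(50):
            fam = simulate_family(cfg, rng, f"F{i}")
            tree = read_newick(history_to_newick(fam.truth.history), rooted=True)
            sp = {r.id: r.species for r in fam.records}
            ours = tag_duplications(tree, sp)
            oracle = lca_reconciliation_labels(tree, SPECIES_TREE, sp)
            by_set = lambda labels: {
                frozenset(lf.taxon.label for lf in n.leaf_iter()): lab
                for n, lab in labels.items()}
            assert by_set(ours) == by_set(oracle)

    def test_duplication_count_matches_event_log_without_losses(self):
        cfg = SimulationConfig(dup_rate=0.3, loss_rate=0.0, seq_length=10, seed=22)
        rng = np.random.default_rng(22)
        for i in range(100):
            fam = simulate_family(cfg, rng, f"F{i}")
            tree = read_newick(history_to_newick(fam.truth.history), rooted=True)
            sp = {r.id: r.species for r in fam.records}
            labels = tag_duplications(tree, sp)
            n_tagged = sum(1 for v in labels.values() if v == "duplication")
            n_events = sum(1 for e in fam.truth.events if e[0] == "duplication")
            assert n_tagged == n_events

    def test_known_divergence_from_lca_oracle_with_conflicting_topology(self):
        # a gene tree that cannot arise from duplication/loss alone:
        # overlap says speciation everywhere, LCA-mapping sees a
        # duplication at the root
        gene = read_newick("((a:1,d:1):1,(b:1,c:1):1);", rooted=True)
        stree = read_newick("(((A:1,B:1):1,C:1):1,D:1);", rooted=True)
        sp = {"a": "A", "b": "B", "c": "C", "d": "D"}
        ours = tag_duplications(gene, sp)
        oracle = lca_reconciliation_labels(gene, stree, sp)
        assert set(ours.values()) == {"speciation"}
        root_label = [lab for n, lab in oracle.items()
                      if n.parent_node is None]
        assert root_label == ["duplication"]


class TestCongruence:
    def test_single_copy_matching_topology_congruent(self):
        cfg = SimulationConfig(dup_rate=0, loss_rate=0, seed=23)
        fam = simulate_family(cfg, np.random.default_rng(23), "F")
        tree = read_newick(history_to_newick(fam.truth.history), rooted=True)
        sp = {r.id: r.species for r in fam.records}
        res = congruent_with_species_tree(tree, SPECIES_TREE,
                                          [r.id for r in fam.records], sp)
        assert res.congruent and not res.unresolved

    def test_forced_incongruence_detected(self):
        gene = read_newick(
            "((((g_DL:1,g_PP:1):1,g_DD:1):1,g_DP:1):1,g_DF:1);", rooted=True)
        sp = {f"g_{s}": s for s in ("DD", "DP", "DL", "PP", "DF")}
        res = congruent_with_species_tree(gene, SPECIES_TREE, list(sp), sp)
        assert not res.congruent

    def test_all_supports_below_minimum_vacuously_congruent(self):
        gene = read_newick(
            "((((g_DL:1,g_PP:1)0.3:1,g_DD:1)0.2:1,g_DP:1)0.1:1,g_DF:1);",
            rooted=True)
        sp = {f"g_{s}": s for s in ("DD", "DP", "DL", "PP", "DF")}
        res = congruent_with_species_tree(gene, SPECIES_TREE, list(sp), sp,
                                          support_min=0.7)
        assert res.congruent and res.unresolved

    def test_duplicate_species_in_subset_rejected(self):
        gene = read_newick("((a:1,b:1):1,c:1);", rooted=True)
        sp = {"a": "DD", "b": "DD", "c": "DP"}
        with pytest.raises(ValueError, match="more than one gene"):
            congruent_with_species_tree(gene, SPECIES_TREE, ["a", "b", "c"], sp)


class TestClassifyHomologs:
    def test_paralogs_called_when_grouping_with_different_focal_copy(self):
        # PP and DL copies attach to a second DD gene: paralogs of focal
        gene = read_newick(
            "((dd1:0.1,dp1:0.1):0.5,((pp1:0.1,dl1:0.1):0.1,dd2:0.1):0.5);",
            rooted=True)
        sp = {"dd1": "DD", "dd2": "DD", "dp1": "DP", "pp1": "PP", "dl1": "DL"}
        calls = classify_homologs("dd1", gene, SPECIES_TREE, sp)
        assert calls["PP"].call == "paralog"
        assert calls["DL"].call == "paralog"
        assert calls["DP"].call == "ortholog"

    def test_single_copy_congruent_family_all_orthologs(self):
        cfg = SimulationConfig(dup_rate=0, loss_rate=0, seed=24)
        fam = simulate_family(cfg, np.random.default_rng(24), "F")
        tree = read_newick(history_to_newick(fam.truth.history), rooted=True)
        sp = {r.id: r.species for r in fam.records}
        calls = classify_homologs("F_DD_1", tree, SPECIES_TREE, sp)
        assert all(c.call == "ortholog" for c in calls.values())

    def test_focal_absent_rejected(self):
        gene = read_newick("(a:1,b:1);", rooted=True)
        with pytest.raises(ValueError, match="absent"):
            classify_homologs("zz", gene, SPECIES_TREE, {"a": "DD", "b": "DP"})

    def test_no_false_paralogs_on_zero_duplication_simulations(self):
        cfg = SimulationConfig(dup_rate=0, loss_rate=0.05, seed=25)
        rng = np.random.default_rng(25)
        for i in range(30):
            fam = simulate_family(cfg, rng, f"F{i}")
            dd = [r.id for r in fam.records if r.species == "DD"]
            if not dd:
                continue
            tree = read_newick(history_to_newick(fam.truth.history), rooted=True)
            if len(fam.records) < 3:
                continue
            sp = {r.id: r.species for r in fam.records}
            calls = classify_homologs(dd[0], tree, SPECIES_TREE, sp)
            assert all(c.call != "paralog" for c in calls.values())

    def test_aberrant_branch_length_flagged(self):
        gene = read_newick(
            "((dd1:0.1,dp1:0.1):0.1,(dl1:0.1,pp1:30.0):0.1);", rooted=True)
        sp = {"dd1": "DD", "dp1": "DP", "dl1": "DL", "pp1": "PP"}
        calls = classify_homologs("dd1", gene, SPECIES_TREE, sp,
                                  branch_length_factor=3.0)
        assert calls["PP"].branch_length_flag
        assert not calls["DP"].branch_length_flag


class TestCompareArchitecture:
    @pytest.mark.parametrize("a,b,expected", [
        (["PA14", "Dicty_CTDC"], ["PA14", "Dicty_CTDC"], True),
        (["EGF", "EGF", "EGF", "TIG"], ["EGF", "TIG"], True),
        (["SigP", "Kinase"], ["Kinase", "SigP"], False),
        ([], [], True),
        (["PA14"], [], False),
    ])
    def test_collapse_and_order(self, a, b, expected):
        assert compare_architecture(a, b) is expected


class TestConservationCategory:
    def test_group4_label(self):
        calls = {sp: "absent" for sp in SPECIES_CODES}
        calls["DD"] = calls["DP"] = "ortholog"
        cat = conservation_category(calls)
        assert cat.only == "4" and cat.category == "4"
        assert cat.multi_only and not cat.uni_plus_multi

    def test_branch_ii_label(self):
        calls = {sp: "absent" for sp in SPECIES_CODES}
        for sp in ("DD", "DP", "DL"):
            calls[sp] = "ortholog"
        assert conservation_category(calls).only == "II"

    def test_all5_with_unicellular_presence(self):
        calls = {sp: "ortholog" for sp in ("DD", "DP", "DL", "PP", "DF")}
        calls.update({"PhyP": "homolog_unresolved", "AC": "absent", "EH": "absent"})
        cat = conservation_category(calls)
        assert cat.all5_ortholog and cat.uni_plus_multi and not cat.multi_only
        assert cat.category == "all5_ortholog"

    def test_total_over_all_presence_patterns(self):
        # every one of the 2^8 presence patterns yields a category
        for bits in itertools.product([0, 1], repeat=8):
            calls = {sp: ("ortholog" if b else "absent")
                     for sp, b in zip(SPECIES_CODES, bits)}
            cat = conservation_category(calls)
            assert cat.category in ("all5_ortholog", "DD_only", "4", "II", "other")
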