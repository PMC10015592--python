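"""Tests for lineage-tree construction, the exhaustive oracle and transitions."""

import itertools

import dendropy
import networkx as nx
import numpy as np
import pandas as pd
import pytest

from bcrclone.lineage import (
    GERMLINE_ID,
    LineageNode,
    LineageTree,
    ancestor_progeny_transitions,
    annotate_overlap_nodes,
    build_parsimony_tree,
    collapse_identical,
    exhaustive_parsimony,
    informative_positions,
    node_distance,
    select_top_clones,
    transition_matrix,
)
from bcrclone.simulate import simulate_lineage, simulate_rearrangement

GERM = "ACGTACGTACGTACGT"


def _node(node_id, seq, labels=(), size=1):
    return LineageNode(node_id=node_id, sequence=seq,
                       labels=frozenset(labels), size=size)


def _mutate(seq, *changes):
    chars = list(seq)
    for pos, base in changes:
        chars[pos] = base
    return "".join(chars)


def _members(rows):
    return pd.DataFrame([
        {"sequence_id": sid, "population": pop, "isotype": iso,
         "sequence_alignment": seq, "duplicate_count": 1}
        for sid, pop, iso, seq in rows
    ])


class TestCollapse:
    def test_identical_sequences_merge_with_union_labels(self):
        members = _members([
            ("a", "GC", "IgM", GERM),
            ("b", "MBC3", "IgM", GERM),
        ])
        nodes = collapse_identical(members)
        assert len(nodes) == 1
        assert nodes[0].labels == {("GC", "IgM"), ("MBC3", "IgM")}
        assert nodes[0].is_overlap
        assert nodes[0].node_id == "a"

    def test_distinct_sequences_stay_separate(self):
        members = _members([
            ("a", "GC", "IgM", GERM),
            ("b", "GC", "IgM", _mutate(GERM, (0, "T"))),
        ])
        nodes = collapse_identical(members)
        assert len(nodes) == 2
        assert not any(n.is_overlap for n in nodes)

    def test_overlap_nodes_match_truth_scan(self, repertoire, analysis):
        grouped = analysis["grouped"]
        clone = grouped[grouped["clone_id"] == grouped["clone_id"].mode()[0]]
        nodes = collapse_identical(clone)
        expected_overlap = {
            min(grp["sequence_id"])
            for _, grp in clone.groupby("sequence_alignment")
            if grp["population"].nunique() >= 2
        }
        observed = {n.node_id for n in nodes if n.is_overlap}
        assert observed == expected_overlap


class TestParsimonyTrees:
    def test_single_node_identical_to_germline_scores_zero(self):
        tree = build_parsimony_tree([_node("a", GERM)], GERM)
        assert tree.parsimony_score == 0
        assert tree.parent("a") == GERMLINE_ID

    def test_two_separate_single_mutants_are_root_children(self):
        a = _node("a", _mutate(GERM, (0, "T")))
        b = _node("b", _mutate(GERM, (5, "A")))
        tree = build_parsimony_tree([a, b], GERM)
        score, _ = exhaustive_parsimony([a, b], GERM)
        assert tree.parsimony_score == score == 2
        assert tree.parent("a") == GERMLINE_ID
        assert tree.parent("b") == GERMLINE_ID

    def test_chain_recovered(self):
        """A descendant carrying its ancestor's mutation plus one more hangs
        below the ancestor, not beside it."""
        a = _node("a", _mutate(GERM, (0, "T")), size=2)
        b = _node("b", _mutate(GERM, (0, "T"), (5, "A")))
        score, best = exhaustive_parsimony([a, b], GERM)
        assert score == 2
        assert best.parent("a") == GERMLINE_ID
        assert best.parent("b") == "a"
        tree = build_parsimony_tree([a, b], GERM)
        assert tree.parsimony_score == 2
        assert tree.parent("b") == "a"

    def test_single_node_score_is_distance_to_germline(self):
        seq = _mutate(GERM, (0, "T"), (3, "C"), (8, "G"))
        score, tree = exhaustive_parsimony([_node("x", seq)], GERM)
        positions = informative_positions(GERM)
        assert score == node_distance(seq, GERM, positions) == 3

    def test_exhaustive_invariant_to_node_order(self):
        nodes = [
            _node("a", _mutate(GERM, (0, "T"))),
            _node("b", _mutate(GERM, (0, "T"), (5, "A"))),
            _node("c", _mutate(GERM, (9, "C"))),
        ]
        scores = {
            exhaustive_parsimony(list(perm), GERM)[0]
            for perm in itertools.permutations(nodes)
        }
        assert len(scores) == 1

    def test_masked_positions_excluded_from_distances(self):
        germ = GERM[:8] + "NNNN" + GERM[12:]
        a = _node("a", _mutate(GERM, (9, "C")))  # only masked change
        tree = build_parsimony_tree([a], germ)
        assert tree.parsimony_score == 0

    def test_refusal_above_node_limit(self):
        nodes = [_node(f"n{i}", GERM) for i in range(7)]
        with pytest.raises(ValueError):
            exhaustive_parsimony(nodes, GERM)

    def test_heuristic_matches_exhaustive_on_random_clones(self, germlines):
        """Heuristic score equals the exhaustive optimum on most small
        random clones and never undercuts it."""
        rng = np.random.default_rng(43)
        equal = total = 0
        while total < 25:
            founder = simulate_rearrangement(germlines, rng)
            size = int(rng.integers(2, 7))
            records, _ = simulate_lineage(
                founder, size, ["GC"] * size, {"GC": 1.2}, rng,
                clone_id=f"C{total}", junction_rate=0.0)
            members = pd.DataFrame(records)
            nodes = collapse_identical(members)
            germ = founder.sequence
            total_muts = sum(
                node_distance(n.sequence, germ, informative_positions(germ))
                for n in nodes)
            if len(nodes) > 6 or total_muts > 8:
                continue
            total += 1
            heuristic = build_parsimony_tree(nodes, germ).parsimony_score
            optimum, _ = exhaustive_parsimony(nodes, germ)
            assert heuristic >= optimum
            equal += heuristic == optimum
        assert equal >= round(0.95 * total)

    def test_score_lower_bound_distinct_positions(self, germlines):
        """Parsimony score >= number of distinct mutated positions."""
        rng = np.random.default_rng(47)
        founder = simulate_rearrangement(germlines, rng)
        records, _ = simulate_lineage(
            founder, 8, ["GC"] * 8, {"GC": 2.0}, rng, junction_rate=0.0)
        nodes = collapse_identical(pd.DataFrame(records))
        tree = build_parsimony_tree(nodes, founder.sequence)
        positions = informative_positions(founder.sequence)
        distinct = {
            i for n in nodes for i in positions
            if n.sequence[i] != founder.sequence[i]
        }
        assert tree.parsimony_score >= len(distinct)

    def test_newick_round_trips_through_dendropy(self):
        a = _node("a", _mutate(GERM, (0, "T")), size=2)
        b = _node("b", _mutate(GERM, (0, "T"), (5, "A")))
        c = _node("c", _mutate(GERM, (9, "C")))
        tree = build_parsimony_tree([a, b, c], GERM)
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert parsed.length() == tree.parsimony_score
        taxa = {leaf.taxon.label for leaf in parsed.leaf_node_iter()}
        assert taxa <= {"a", "b", "c"}


class TestAnnotation:
    def test_isotype_mix_without_overlap(self):
        node = _node("a", GERM, labels=[("MBC1", "IgM"), ("MBC1", "IgG")])
        assert node.isotype_mix and not node.is_overlap

    def test_three_population_overlap(self):
        node = _node("a", GERM,
                     labels=[("GC", "IgM"), ("MBC2", "IgM"), ("MBC3", "IgM")])
        assert node.is_overlap and not node.isotype_mix

    def test_flag_counts_match_label_scan(self, analysis):
        grouped = analysis["grouped"]
        clone = grouped[grouped["clone_id"] == grouped["clone_id"].mode()[0]]
        nodes = collapse_identical(clone)
        tree = build_parsimony_tree(nodes, clone.iloc[0]["germline_alignment"])
        table = annotate_overlap_nodes(tree)
        scan = sum(1 for n in nodes if len({p for p, _ in n.labels}) >= 2)
        assert int(table["is_overlap"].sum()) == scan


class TestTransitions:
    def _chain_tree(self, labels_by_node):
        g = nx.DiGraph()
        g.add_node(GERMLINE_ID, node=LineageNode(
            node_id=GERMLINE_ID, sequence=GERM, is_germline=True))
        prev = GERMLINE_ID
        for i, labels in enumerate(labels_by_node):
            nid = f"n{i}"
            g.add_node(nid, node=_node(nid, GERM, labels=labels))
            g.add_edge(prev, nid, weight=1)
            prev = nid
        return LineageTree(graph=g)

    def test_direct_edge_reading(self):
        tree = self._chain_tree([[("MBC3", "IgM")], [("GC", "IgM")]])
        counts = ancestor_progeny_transitions(tree, mode="edge")
        assert len(counts) == 1
        row = counts.iloc[0]
        assert (row["ancestor_population"], row["descendant_population"]) == \
            ("MBC3", "GC")
        assert row["count"] == 1 and not row["isotype_switch"]

    def test_star_tree_has_no_transitions(self):
        g = nx.DiGraph()
        g.add_node(GERMLINE_ID, node=LineageNode(
            node_id=GERMLINE_ID, sequence=GERM, is_germline=True))
        for i, pop in enumerate(("GC", "MBC1", "MBC3")):
            nid = f"n{i}"
            g.add_node(nid, node=_node(nid, GERM, labels=[(pop, "IgM")]))
            g.add_edge(GERMLINE_ID, nid, weight=1)
        counts = ancestor_progeny_transitions(LineageTree(graph=g), mode="edge")
        assert counts["count"].sum() == 0

    def test_path_mode_counts_all_ancestor_pairs(self):
        tree = self._chain_tree(
            [[("MBC3", "IgM")], [("GC", "IgM")], [("MBC1", "IgG")]])
        edge = ancestor_progeny_transitions(tree, mode="edge")
        path = ancestor_progeny_transitions(tree, mode="path")
        assert edge["count"].sum() == 2
        assert path["count"].sum() == 3
        switches = path[path["isotype_switch"]]
        assert switches["count"].sum() == 2  # MBC3->MBC1 and GC->MBC1

    def test_multilabel_nodes_contribute_all_combinations(self):
        tree = self._chain_tree([
            [("GC", "IgM"), ("MBC3", "IgM")],
            [("MBC1", "IgM")],
        ])
        counts = ancestor_progeny_transitions(tree, mode="edge")
        mat = transition_matrix(counts, isotype="IgM")
        assert mat.loc["GC", "MBC1"] == 1
        assert mat.loc["MBC3", "MBC1"] == 1

    def test_unknown_mode_rejected(self):
        tree = self._chain_tree([[("GC", "IgM")]])
        with pytest.raises(ValueError):
            ancestor_progeny_transitions(tree, mode="bogus")

    def test_truth_forest_oracle(self, repertoire):
        """Edge-mode counts on the truth forest equal a direct enumeration
        of labelled parent-child pairs in the truth table."""
        airr = repertoire["airr"]
        truth = repertoire["truth_records"]
        info = airr.set_index("sequence_id")[["population", "isotype"]]
        clone_id = truth["true_clone_id"].iloc[0]
        sub = truth[truth["true_clone_id"] == clone_id]

        g = nx.DiGraph()
        g.add_node(GERMLINE_ID, node=LineageNode(
            node_id=GERMLINE_ID, sequence="", is_germline=True))
        g.add_node(f"{clone_id}-founder", node=LineageNode(
            node_id=f"{clone_id}-founder", sequence=""))
        g.add_edge(GERMLINE_ID, f"{clone_id}-founder", weight=0)
        for row in sub.itertuples():
            pop, iso = info.loc[row.sequence_id]
            g.add_node(row.sequence_id,
                       node=_node(row.sequence_id, "", labels=[(pop, iso)]))
        for row in sub.itertuples():
            g.add_edge(row.true_parent_id, row.sequence_id,
                       weight=row.true_mutation_count)
        counts = ancestor_progeny_transitions(LineageTree(graph=g), mode="edge")

        # oracle: walk each member up to its nearest sampled ancestor
        parent = dict(zip(sub["sequence_id"], sub["true_parent_id"]))
        sampled = set(sub["sequence_id"])
        expected: dict[tuple, int] = {}
        for sid in sub["sequence_id"]:
            anc = parent[sid]
            while anc not in sampled and anc in parent:
                anc = parent[anc]
            if anc in sampled:
                key = (tuple(info.loc[anc]), tuple(info.loc[sid]))
                expected[key] = expected.get(key, 0) + 1
        observed = {
            ((r.ancestor_population, r.ancestor_isotype),
             (r.descendant_population, r.descendant_isotype)): r.count
            for r in counts.itertuples()
        }
        assert observed == expected


class TestTopClones:
    def test_ranking(self):
        df = pd.DataFrame({"clone_id": ["x", "y", "z"],
                           "sequence_count": [5, 9, 2]})
        top = select_top_clones(df, n=10)
        assert top["sequence_count"].tolist() == [9, 5, 2]
        assert len(select_top_clones(df, n=2)) == 2

    def test_tie_breaks_by_clone_id(self):
        df = pd.DataFrame({"clone_id": ["b", "a"], "sequence_count": [4, 4]})
        assert select_top_clones(df)["clone_id"].tolist() == ["a", "b"]

    def test_matches_sort_oracle(self, analysis):
        summary = (analysis["grouped"].groupby("clone_id")
                   .size().rename("sequence_count").reset_index())
        top = select_top_clones(summary, n=5)
        oracle = sorted(summary.itertuples(index=False),
                        key=lambda r: (-r.sequence_count, r.clone_id))[:5]
        assert top["clone_id"].tolist() == [r.clone_id for r in oracle]
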