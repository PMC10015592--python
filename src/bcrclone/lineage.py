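"""Germline-rooted maximum-parsimony lineage trees for clonal groups.

Identical sequences are collapsed into labelled nodes (a node carries the
(population, isotype) pairs of every collapsed member; a node with >= 2
populations is an *overlap* node). Trees are rooted at the reconstructed
germline and searched by a sequential-addition heuristic with local
rearrangement, in the spirit of dnapars-style vertical lineages: observed
sequences may occupy internal positions (ancestor nodes), and edge weights
are nucleotide hamming distances with junction-masked and gap positions
excluded (the germline is unknowable there).

The search space is trees over the germline plus the observed collapsed
sequences; no unobserved intermediate sequences are inferred. An exhaustive
enumerator over all rooted topologies (Pruefer-sequence enumeration, <= 6
nodes) serves as the testing oracle; the heuristic can never score below it
because both optimize over the same space.

Determinism: all tie-breaks resolve to the smallest node id.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import AlignmentError
from .io import NUCLEOTIDES


@dataclass
class LineageNode:
    """One collapsed sequence (or the germline root) in a lineage tree."""

    node_id: str
    sequence: str
    labels: frozenset = frozenset()   # {(population, isotype)}
    size: int = 0                     # collapsed unique-sequence count
    duplicate_count: int = 0
    is_germline: bool = False

    @property
    def populations(self) -> frozenset:
        return frozenset(p for p, _ in self.labels)

    @property
    def is_overlap(self) -> bool:
        return len(self.populations) >= 2

    @property
    def isotype_mix(self) -> bool:
        return len({iso for _, iso in self.labels}) >= 2


GERMLINE_ID = "GL"


def collapse_identical(members: pd.DataFrame) -> list[LineageNode]:
    """One node per distinct nucleotide sequence among a clone's members.

    Labels are the union of (population, isotype) over collapsed members;
    node id is the smallest member sequence_id. Sorted by decreasing
    abundance, then id (the tree-building insertion order).
    """
    nodes = []
    for seq, grp in members.groupby("sequence_alignment", sort=True):
        labels = frozenset(zip(grp["population"], grp["isotype"]))
        nodes.append(LineageNode(
            node_id=min(grp["sequence_id"]),
            sequence=seq,
            labels=labels,
            size=len(grp),
            duplicate_count=int(grp["duplicate_count"].sum()),
        ))
    nodes.sort(key=lambda n: (-n.size, n.node_id))
    return nodes


def informative_positions(germline_sequence: str) -> np.ndarray:
    """Alignment positions where the germline is a plain base (not gap/mask)."""
    return np.array([i for i, c in enumerate(germline_sequence) if c in NUCLEOTIDES],
                    dtype=int)


def node_distance(seq_a: str, seq_b: str, positions: np.ndarray) -> int:
    """Hamming distance restricted to germline-informative positions where
    both sequences carry a plain base."""
    if len(seq_a) != len(seq_b):
        raise AlignmentError("sequences must be length-aligned")
    d = 0
    for i in positions:
        a, b = seq_a[i], seq_b[i]
        if a in NUCLEOTIDES and b in NUCLEOTIDES and a != b:
            d += 1
    return d


@dataclass
class LineageTree:
    """Germline-rooted tree; edges carry nucleotide-difference weights."""

    graph: nx.DiGraph
    root: str = GERMLINE_ID

    @property
    def parsimony_score(self) -> int:
        return int(sum(w for _, _, w in self.graph.edges.data("weight")))

    def node(self, node_id: str) -> LineageNode:
        return self.graph.nodes[node_id]["node"]

    def parent(self, node_id: str) -> str | None:
        preds = list(self.graph.predecessors(node_id))
        return preds[0] if preds else None

    def children(self, node_id: str) -> list[str]:
        return sorted(self.graph.successors(node_id))

    def to_newick(self) -> str:
        """Newick string with internal node names and branch lengths."""
        def render(node_id: str) -> str:
            kids = self.children(node_id)
            label = node_id
            if node_id == self.root:
                return (f"({','.join(render(k) for k in kids)}){label}"
                        if kids else label)
            weight = self.graph.edges[self.parent(node_id), node_id]["weight"]
            if kids:
                return f"({','.join(render(k) for k in kids)}){label}:{weight}"
            return f"{label}:{weight}"

        return render(self.root) + ";"

    def node_table(self) -> pd.DataFrame:
        rows = []
        for node_id in sorted(self.graph.nodes):
            n: LineageNode = self.node(node_id)
            rows.append({
                "node_id": node_id,
                "is_germline": n.is_germline,
                "labels": ";".join(sorted(f"{p}|{i}" for p, i in n.labels)),
                "is_overlap": n.is_overlap,
                "isotype_mix": n.isotype_mix,
                "size": n.size,
                "duplicate_count": n.duplicate_count,
                "parent": self.parent(node_id) or "",
                "distance_to_parent": (
                    self.graph.edges[self.parent(node_id), node_id]["weight"]
                    if self.parent(node_id) else 0
                ),
            })
        return pd.DataFrame(rows)


def _distance_matrix(nodes: list[LineageNode], germline_sequence: str,
                     positions: np.ndarray) -> np.ndarray:
    seqs = [germline_sequence] + [n.sequence for n in nodes]
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), -1)
    arr = arr[:, positions]
    valid = np.isin(arr, np.frombuffer(b"ACGT", dtype="S1"))
    diff = (arr[:, None, :] != arr[None, :, :]) & valid[:, None, :] & valid[None, :, :]
    return diff.sum(axis=2).astype(int)


def _assemble(nodes, germline_sequence, parent_of, dist, ids) -> LineageTree:
    g = nx.DiGraph()
    g.add_node(GERMLINE_ID, node=LineageNode(
        node_id=GERMLINE_ID, sequence=germline_sequence, is_germline=True))
    for n in nodes:
        g.add_node(n.node_id, node=n)
    for child, parent in parent_of.items():
        g.add_edge(ids[parent], ids[child], weight=int(dist[parent, child]))
    return LineageTree(graph=g)


def build_parsimony_tree(nodes: list[LineageNode],
                         germline_sequence: str) -> LineageTree:
    """Heuristic parsimony tree over germline + collapsed observed sequences.

    Nodes are inserted in decreasing-abundance order, each attached to the
    current vertex at minimum distance; a local-rearrangement pass then
    re-grafts nodes wherever that lowers the total score, until no move
    improves it. Tie-breaking is by smallest node id throughout, so the
    result is deterministic.
    """
    if not nodes:
        raise ValueError("need at least one node")
    for n in nodes:
        if len(n.sequence) != len(germline_sequence):
            raise AlignmentError(f"node {n.node_id} not aligned to germline")
    order = sorted(range(len(nodes)), key=lambda i: (-nodes[i].size, nodes[i].node_id))
    positions = informative_positions(germline_sequence)
    dist = _distance_matrix(nodes, germline_sequence, positions)
    ids = [GERMLINE_ID] + [n.node_id for n in nodes]

    # order of preference among candidate parents: germline first, then ids
    pref = {0: ("",)}
    pref.update({i + 1: (nodes[i].node_id,) for i in range(len(nodes))})

    parent_of: dict[int, int] = {}
    in_tree = [0]
    for idx in order:
        v = idx + 1
        best = min(in_tree, key=lambda u: (dist[u, v], pref[u]))
        parent_of[v] = best
        in_tree.append(v)

    def descendants(v: int) -> set[int]:
        out, stack = set(), [v]
        while stack:
            u = stack.pop()
            out.add(u)
            stack.extend(c for c, p in parent_of.items() if p == u)
        return out

    improved = True
    while improved:
        improved = False
        for v in sorted(parent_of, key=lambda i: ids[i]):
            blocked = descendants(v)
            current = dist[parent_of[v], v]
            best_u, best_d = parent_of[v], current
            for u in range(len(ids)):
                if u in blocked:
                    continue
                if dist[u, v] < best_d or (
                        dist[u, v] == best_d and pref[u] < pref[best_u]):
                    best_u, best_d = u, dist[u, v]
            if best_u != parent_of[v] and best_d < current:
                parent_of[v] = best_u
                improved = True
    return _assemble(nodes, germline_sequence, parent_of, dist, ids)


def exhaustive_parsimony(nodes: list[LineageNode], germline_sequence: str,
                         max_nodes: int = 6) -> tuple[int, LineageTree]:
    """Minimum-score tree by enumerating every rooted topology.

    All labelled trees on germline + n nodes are enumerated via Pruefer
    sequences (each node may be internal or a leaf; germline is the root);
    the summed hamming edge weights are minimized. Refuses n > max_nodes.
    """
    n = len(nodes)
    if n == 0:
        raise ValueError("need at least one node")
    if n > max_nodes:
        raise ValueError(f"exhaustive search limited to {max_nodes} nodes, got {n}")
    positions = informative_positions(germline_sequence)
    dist = _distance_matrix(nodes, germline_sequence, positions)
    ids = [GERMLINE_ID] + [n_.node_id for n_ in nodes]
    m = n + 1  # vertices

    if m == 2:
        parent_of = {1: 0}
        tree = _assemble(nodes, germline_sequence, parent_of, dist, ids)
        return tree.parsimony_score, tree

    best_score, best_edges = None, None
    for pruefer in itertools.product(range(m), repeat=m - 2):
        tree_graph = nx.from_prufer_sequence(list(pruefer))
        edges = sorted(tuple(sorted(e)) for e in tree_graph.edges)
        score = int(sum(dist[u, v] for u, v in edges))
        if best_score is None or score < best_score or (
                score == best_score and edges < best_edges):
            best_score, best_edges = score, edges

    parent_of = _orient(best_edges)
    tree = _assemble(nodes, germline_sequence, parent_of, dist, ids)
    return best_score, tree


def _orient(edges) -> dict[int, int]:
    """Root an undirected tree at vertex 0; child -> parent map."""
    adjacency: dict[int, list[int]] = {}
    for u, v in edges:
        adjacency.setdefault(u, []).append(v)
        adjacency.setdefault(v, []).append(u)
    parent_of: dict[int, int] = {}
    stack, seen = [0], {0}
    while stack:
        u = stack.pop()
        for v in adjacency.get(u, []):
            if v not in seen:
                seen.add(v)
                parent_of[v] = u
                stack.append(v)
    return parent_of


# ---------------------------------------------------------------------------
# Annotation and ancestor/progeny transitions
# ---------------------------------------------------------------------------

def annotate_overlap_nodes(tree: LineageTree) -> pd.DataFrame:
    """Materialize the overlap / isotype-mix flags as graph attributes.

    The flags themselves are derived properties of each node's labels; this
    records them on the graph and returns the node table.
    """
    for node_id in tree.graph.nodes:
        n = tree.node(node_id)
        tree.graph.nodes[node_id]["is_overlap"] = n.is_overlap
        tree.graph.nodes[node_id]["isotype_mix"] = n.isotype_mix
    return tree.node_table()


def ancestor_progeny_transitions(tree: LineageTree, mode: str = "edge") -> pd.DataFrame:
    """Ordered (ancestor population, descendant population) transition counts.

    ``mode="edge"`` links every labelled node to its nearest labelled
    ancestor (unlabelled inferred nodes and the germline are transparently
    skipped); ``mode="path"`` counts all labelled ancestor/descendant pairs
    on root-to-tip paths. Multi-label nodes contribute every label
    combination. Rows carry both population and isotype on each side, so
    isotype-switch transitions (IgM ancestor -> IgG descendant) can be
    tabulated separately.
    """
    if mode not in ("edge", "path"):
        raise ValueError(f"unknown mode {mode!r}")

    def labelled_ancestors(node_id: str):
        out = []
        current = tree.parent(node_id)
        while current is not None:
            if tree.node(current).labels:
                out.append(current)
                if mode == "edge":
                    break
            current = tree.parent(current)
        return out

    counts: dict[tuple, int] = {}
    for node_id in sorted(tree.graph.nodes):
        labels = tree.node(node_id).labels
        if not labels:
            continue
        for anc_id in labelled_ancestors(node_id):
            for anc_label in tree.node(anc_id).labels:
                for desc_label in labels:
                    key = anc_label + desc_label
                    counts[key] = counts.get(key, 0) + 1
    rows = [
        {"ancestor_population": ap, "ancestor_isotype": ai,
         "descendant_population": dp, "descendant_isotype": di,
         "count": c, "isotype_switch": ai != di}
        for (ap, ai, dp, di), c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=[
        "ancestor_population", "ancestor_isotype", "descendant_population",
        "descendant_isotype", "count", "isotype_switch",
    ])


def transition_matrix(transitions: pd.DataFrame, isotype: str | None = None,
                      switch_only: bool = False) -> pd.DataFrame:
    """Population x population matrix view of a transition table."""
    t = transitions
    if switch_only:
        t = t[t["isotype_switch"]]
    elif isotype is not None:
        t = t[(t["ancestor_isotype"] == isotype) & (t["descendant_isotype"] == isotype)]
    return t.pivot_table(index="ancestor_population", columns="descendant_population",
                         values="count", aggfunc="sum", fill_value=0)


def select_top_clones(clone_summary: pd.DataFrame, n: int = 10) -> pd.DataFrame:
    """Rank clonal groups by total sequence count (both isotypes pooled).

    ``clone_summary`` needs columns ``clone_id`` and ``sequence_count``;
    ties break by clone id.
    """
    ranked = clone_summary.sort_values(
        ["sequence_count", "clone_id"], ascending=[False, True], kind="mergesort"
    )
    return ranked.head(n).reset_index(drop=True)
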