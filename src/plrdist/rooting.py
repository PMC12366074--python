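"""Rooting-hypothesis evaluation.

An unrooted gene tree with m edges admits m rootings (subdivide an edge and
make the new node the root).  Each rooting is reconciled with the known
species tree through the lca-mapping and its implied event labels, and scored
by PLR against a reference reconciliation.  The *Best set* is the set of
rootings that minimize the dissimilarity; ties are never broken — their count
is itself a quantity of interest, since a measure that frequently leaves a
unique best rooting discriminates hypotheses better.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import measure
from .trees import (
    GeneTree,
    Node,
    ReconciledGeneTree,
    SpeciesTree,
    Tree,
    TreeError,
    reconcile_lca,
)


class UnrootedTree:
    """An unrooted tree as an adjacency structure over named vertices.

    Leaves are degree-1 vertices with unique names; degree-2 vertices are
    rejected (they would make rootings ambiguous).
    """

    def __init__(self, adjacency: dict[str, list[str]]):
        self.adj = {u: list(vs) for u, vs in adjacency.items()}
        for u, vs in self.adj.items():
            if len(vs) == 2:
                raise TreeError(f"degree-2 vertex {u!r} in unrooted tree")
            for v in vs:
                if u not in self.adj.get(v, ()):
                    raise TreeError("adjacency is not symmetric")
        self.leaves = sorted(u for u, vs in self.adj.items() if len(vs) == 1)

    @classmethod
    def from_rooted(cls, tree: Tree | Node) -> "UnrootedTree":
        """Unroot a rooted tree; a binary root (degree 2) is suppressed."""
        root = tree.root if isinstance(tree, Tree) else tree
        adj: dict[str, list[str]] = {}
        for v in root.preorder():
            adj.setdefault(v.name, [])
            for c in v.children:
                adj[v.name].append(c.name)
                adj.setdefault(c.name, []).append(v.name)
        if len(adj[root.name]) == 2:
            a, b = adj.pop(root.name)
            adj[a] = [x if x != root.name else b for x in adj[a]]
            adj[b] = [x if x != root.name else a for x in adj[b]]
        return cls(adj)

    @classmethod
    def from_newick(cls, text: str) -> "UnrootedTree":
        from .trees import _parse_newick

        root, _ = _parse_newick(text)
        return cls.from_rooted(root)

    def edges(self) -> list[tuple[str, str]]:
        out = []
        for u, vs in self.adj.items():
            for v in vs:
                if u < v:
                    out.append((u, v))
        return sorted(out)

    def _subtree(self, v: str, away_from: str) -> Node:
        nbrs = [w for w in self.adj[v] if w != away_from]
        node = Node(v if not nbrs else None)
        for w in nbrs:
            node.add_child(self._subtree(w, v))
        return node


def enumerate_rootings(T: UnrootedTree) -> list[tuple[tuple[str, str], GeneTree]]:
    """One rooted gene tree per edge of T, each with a binary root.

    Returns (edge, rooted tree) pairs; internal vertex names of T are not
    preserved in the rootings (only leaf names matter downstream).
    """
    out = []
    for u, v in T.edges():
        root = Node(None)
        root.add_child(T._subtree(u, away_from=v))
        root.add_child(T._subtree(v, away_from=u))
        out.append(((u, v), GeneTree(root)))
    return out


def reconcile_rooting(
    rooted: GeneTree, S: SpeciesTree, leaf_species: dict[str, str]
) -> ReconciledGeneTree:
    """Reconcile a candidate rooting with S via the lca-mapping; labels are
    the ones implied by the mapping (spec wherever permitted)."""
    return reconcile_lca(rooted, S, leaf_species)


@dataclass
class RootingCandidate:
    edge: tuple[str, str]
    reconciliation: ReconciledGeneTree
    result: measure.DissimilarityResult

    @property
    def d_plr(self) -> float:
        return self.result.d_plr


@dataclass
class RootingReport:
    candidates: list[RootingCandidate]
    best_value: float
    best_set: list[int]  # indices into candidates

    @property
    def best_size(self) -> int:
        return len(self.best_set)

    @property
    def unique_best(self) -> bool:
        return self.best_size == 1


def best_rootings(
    T: UnrootedTree,
    reference: ReconciledGeneTree,
    alpha: float | str = 0.5,
) -> RootingReport:
    """Score every rooting of T against the reference and report the Best set.

    All candidates sharing the exact minimal d_plr are kept; exact integer
    components make tie detection safe for any rational alpha.
    """
    S = reference.species_tree
    leaf_species = reference.leaf_species()
    if set(T.leaves) != set(leaf_species):
        raise TreeError("unrooted tree and reference have different leafsets")
    candidates = []
    for edge, rooted in enumerate_rootings(T):
        rec = reconcile_rooting(rooted, S, leaf_species)
        res = measure.d_plr(rec, reference, alpha)
        candidates.append(RootingCandidate(edge, rec, res))
    best = min(c.d_plr for c in candidates)
    best_set = [i for i, c in enumerate(candidates) if c.d_plr == best]
    return RootingReport(candidates, best, best_set)
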