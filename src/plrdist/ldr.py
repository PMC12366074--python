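"""Least-duplication-resolved (LDR) normal forms and reconciliation equivalence.

A gene-tree edge uv is *redundant* when both endpoints are duplications
mapped to the same species: a chain of same-species duplications carries no
topological signal, so the chain's internal resolution is arbitrary.
Contracting every redundant edge yields the unique least-duplication-resolved
form LR(G).  Two reconciliations are LDR-equivalent when their LR forms are
isomorphic; the PLR dissimilarity is a semi-metric under exactly this
equivalence (zero dissimilarity at alpha in (0,1) implies LDR-equivalence,
and contraction never increases the dissimilarity).
"""

from __future__ import annotations

from typing import NamedTuple

from .trees import DUP, GeneTree, Node, ReconciledGeneTree, TreeError


class RedundantEdge(NamedTuple):
    parent: Node
    child: Node


def redundant_edges(rec: ReconciledGeneTree) -> list[RedundantEdge]:
    """All edges uv with mu(u) = mu(v) and l(u) = l(v) = dup."""
    out = []
    for v in rec.gene_tree.nodes:
        p = v.parent
        if (
            p is not None
            and rec.events[p] == DUP
            and rec.events[v] == DUP
            and rec.mu[p] is rec.mu[v]
        ):
            out.append(RedundantEdge(p, v))
    return out


def _contract_inplace(rec: ReconciledGeneTree, parent: Node, child: Node) -> None:
    # the parent subsumes the child: the child's children are re-attached in place
    i = parent.children.index(child)
    for c in child.children:
        c.parent = parent
    parent.children[i : i + 1] = child.children
    child.parent = None
    del rec.mu[child]
    del rec.events[child]


def contract_edge(rec: ReconciledGeneTree, edge: RedundantEdge) -> ReconciledGeneTree:
    """Contract one redundant edge, returning a new reconciliation.

    The surviving node keeps the parent's identity; mu and the labeling are
    restricted to the remaining nodes.
    """
    p, v = edge
    if not (
        rec.events.get(p) == DUP
        and rec.events.get(v) == DUP
        and rec.mu.get(p) is rec.mu.get(v)
        and v.parent is p
    ):
        raise TreeError(f"edge {p.name!r}-{v.name!r} is not redundant")
    new = rec.copy()
    np_, nv = new.gene_tree.node(p.name), new.gene_tree.node(v.name)
    _contract_inplace(new, np_, nv)
    new.gene_tree = GeneTree(new.gene_tree.root)
    return new


def least_duplication_resolved(rec: ReconciledGeneTree) -> ReconciledGeneTree:
    """LR(G): contract redundant edges to a fixpoint.

    The result is independent of contraction order; repeated scans are used
    because a contraction can expose further redundant edges along the same
    duplication chain.
    """
    new = rec.copy()
    changed = True
    while changed:
        changed = False
        for p, v in redundant_edges(new):
            if v.parent is p:  # still present after earlier contractions
                _contract_inplace(new, p, v)
                changed = True
    new.gene_tree = GeneTree(new.gene_tree.root)
    return new


def _canonical(rec: ReconciledGeneTree, v: Node):
    sp = rec.mu[v].name
    ev = rec.events[v]
    if v.is_leaf:
        return ("leaf", v.name, sp, ev)
    kids = tuple(sorted(_canonical(rec, c) for c in v.children))
    return ("node", sp, ev, kids)


def is_isomorphic(r1: ReconciledGeneTree, r2: ReconciledGeneTree) -> bool:
    """Leaf-fixing isomorphism preserving topology, species maps, and labels.

    Because leaves are uniquely named and shared, the bijection is forced by
    clades; a canonical bottom-up form decides isomorphism without any
    general graph-isomorphism machinery.
    """
    if r1.species_tree is not r2.species_tree:
        return False
    if set(r1.gene_tree.leaf_names) != set(r2.gene_tree.leaf_names):
        return False
    return _canonical(r1, r1.gene_tree.root) == _canonical(r2, r2.gene_tree.root)


def is_ldr_equivalent(r1: ReconciledGeneTree, r2: ReconciledGeneTree) -> bool:
    """True iff LR(r1) and LR(r2) are isomorphic."""
    return is_isomorphic(
        least_duplication_resolved(r1), least_duplication_resolved(r2)
    )
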