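"""Rooted-tree data model, reconciliation validity, Newick/NHX I/O, and LCA services.

The central object is :class:`ReconciledGeneTree`, the tuple (G, S, mu, l): a
gene tree G, a binary species tree S, a total gene-node -> species-node map
``mu``, and an event labeling ``l`` over {dup, spec, extant}.  A valid
reconciliation satisfies three requirements:

* *leaves are extant*: every gene leaf maps to a species leaf and is labeled
  ``extant``; internal nodes are ``dup`` or ``spec``;
* *time-consistency*: descendants in G map to descendants-or-equal in S;
* *speciations separate species*: a ``spec`` node maps to an internal species
  node, has exactly two children, and the children's species lie under the two
  distinct children of its own species.

Distances within a tree are edge counts (unit branch lengths), with
``depth(root) = 0``.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np

DUP = "dup"
SPEC = "spec"
EXTANT = "extant"
EVENTS = frozenset({DUP, SPEC, EXTANT})


class TreeError(ValueError):
    """Malformed tree input or invalid tree operation."""


class Node:
    """A node of a rooted tree: a name, a parent link, and ordered children.

    Child order is preserved from input but carries no meaning; every
    operation in this package is invariant under reordering.
    """

    __slots__ = ("name", "parent", "children")

    def __init__(self, name: str | None = None, children=()):
        self.name = name
        self.parent: Node | None = None
        self.children: list[Node] = []
        for c in children:
            self.add_child(c)

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self):
        stack = [self]
        while stack:
            v = stack.pop()
            yield v
            stack.extend(reversed(v.children))

    def postorder(self):
        out = list(self.preorder())
        return reversed(out)

    def leaves(self):
        return (v for v in self.preorder() if v.is_leaf)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<Node {self.name!r}>"


class Tree:
    """A rooted tree over :class:`Node` handles, with name lookup and an LCA index."""

    def __init__(self, root: Node):
        self.root = root
        self._assign_names()
        self.nodes: list[Node] = list(root.preorder())
        self.leaves: list[Node] = [v for v in self.nodes if v.is_leaf]
        self.leaf_names: list[str] = [v.name for v in self.leaves]
        seen = set()
        for name in self.leaf_names:
            if not name:
                raise TreeError("every leaf must be named")
            if name in seen:
                raise TreeError(f"duplicate leaf name {name!r}")
            seen.add(name)
        self._by_name: dict[str, Node] = {}
        for v in self.nodes:
            if v.name is not None:
                self._by_name.setdefault(v.name, v)
        self._lca_index: LcaIndex | None = None

    def _assign_names(self) -> None:
        # unnamed internal nodes get deterministic preorder ids so that node
        # identity survives serialization round-trips
        taken = {v.name for v in self.root.preorder() if v.name}
        for i, v in enumerate(self.root.preorder()):
            if not v.name:
                name = f"n{i}"
                while name in taken:
                    name = "_" + name
                v.name = name
                taken.add(name)

    def node(self, name: str) -> Node:
        try:
            return self._by_name[name]
        except KeyError:
            raise TreeError(f"no node named {name!r}") from None

    @property
    def lca_index(self) -> "LcaIndex":
        if self._lca_index is None:
            self._lca_index = build_lca_index(self)
        return self._lca_index

    def lca(self, u: Node, v: Node) -> Node:
        return self.lca_index.lca(u, v)

    def depth(self, u: Node) -> int:
        return self.lca_index.depth(u)

    def __contains__(self, v: Node) -> bool:
        return v in self.lca_index._first

    def __len__(self) -> int:
        return len(self.nodes)


class SpeciesTree(Tree):
    """A rooted *binary* species tree with uniquely named extant species at the leaves."""

    def __init__(self, root: Node):
        super().__init__(root)
        for v in self.nodes:
            if v.children and len(v.children) != 2:
                raise TreeError(
                    f"species tree must be binary; node {v.name!r} has "
                    f"{len(v.children)} children"
                )


class GeneTree(Tree):
    """A rooted gene tree; internal nodes have at least two children (polytomies allowed)."""

    def __init__(self, root: Node):
        super().__init__(root)
        for v in self.nodes:
            if len(v.children) == 1:
                raise TreeError(f"gene tree node {v.name!r} has a single child")


class LcaIndex:
    """Constant-time lowest-common-ancestor queries via Euler tour + sparse table.

    Preprocessing is O(n log n); each query afterwards is O(1), which meets the
    amortized contract of answering q queries in O(q).  ``query_count`` tracks
    the number of lca() calls, used to audit the linear-time bound of the
    gene-gene correspondence map.
    """

    def __init__(self, root: Node):
        tour: list[Node] = []
        depths: list[int] = []
        first: dict[Node, int] = {}
        node_depth: dict[Node, int] = {}
        # iterative Euler tour
        stack: list[tuple[Node, int, int]] = [(root, 0, 0)]
        while stack:
            v, d, child_i = stack.pop()
            if child_i == 0:
                node_depth[v] = d
                first[v] = len(tour)
            tour.append(v)
            depths.append(d)
            if child_i < len(v.children):
                stack.append((v, d, child_i + 1))
                stack.append((v.children[child_i], d + 1, 0))
        self._tour = tour
        self._first = first
        self._depths = node_depth
        self.query_count = 0

        arr = np.asarray(depths, dtype=np.int64)
        m = len(arr)
        k = max(1, m.bit_length())
        sparse = np.empty((k, m), dtype=np.int64)  # argmin positions
        sparse[0] = np.arange(m)
        j = 1
        while (1 << j) <= m:
            half = 1 << (j - 1)
            left = sparse[j - 1, : m - (1 << j) + 1]
            right = sparse[j - 1, half : m - (1 << j) + 1 + half]
            sparse[j, : m - (1 << j) + 1] = np.where(
                arr[left] <= arr[right], left, right
            )
            j += 1
        self._sparse = sparse
        self._log = np.zeros(m + 1, dtype=np.int64)
        for i in range(2, m + 1):
            self._log[i] = self._log[i // 2] + 1

    def depth(self, v: Node) -> int:
        try:
            return self._depths[v]
        except KeyError:
            raise TreeError(f"node {v.name!r} is not in this tree") from None

    def lca(self, u: Node, v: Node) -> Node:
        self.query_count += 1
        try:
            i, j = self._first[u], self._first[v]
        except KeyError:
            raise TreeError("lca query with a node from a different tree") from None
        if i > j:
            i, j = j, i
        k = int(self._log[j - i + 1])
        a = self._sparse[k, i]
        b = self._sparse[k, j - (1 << k) + 1]
        arr_a, arr_b = self._depths[self._tour[a]], self._depths[self._tour[b]]
        pos = a if arr_a <= arr_b else b
        return self._tour[pos]


def build_lca_index(tree: Tree | Node) -> LcaIndex:
    root = tree.root if isinstance(tree, Tree) else tree
    return LcaIndex(root)


def dist(tree: Tree, u: Node, v: Node) -> int:
    """Undirected path length between two nodes of the same tree.

    Computed as depth(u) + depth(v) - 2 depth(lca(u, v)).
    """
    idx = tree.lca_index
    return idx.depth(u) + idx.depth(v) - 2 * idx.depth(idx.lca(u, v))


# ---------------------------------------------------------------------------
# Reconciled gene trees
# ---------------------------------------------------------------------------


@dataclass
class ReconciledGeneTree:
    """The tuple (G, S, mu, l).

    ``mu`` maps every gene node to a species node; ``events`` labels every
    gene node with one of dup/spec/extant.  Construction does not enforce
    the reconciliation requirements; call :func:`validate_reconciliation`.
    """

    gene_tree: GeneTree
    species_tree: SpeciesTree
    mu: dict[Node, Node]
    events: dict[Node, str]

    def copy(self) -> "ReconciledGeneTree":
        mapping: dict[Node, Node] = {}

        def clone(v: Node) -> Node:
            w = Node(v.name)
            mapping[v] = w
            for c in v.children:
                w.add_child(clone(c))
            return w

        new_root = clone(self.gene_tree.root)
        g = GeneTree(new_root)
        mu = {mapping[v]: s for v, s in self.mu.items()}
        ev = {mapping[v]: e for v, e in self.events.items()}
        return ReconciledGeneTree(g, self.species_tree, mu, ev)

    def leaf_species(self) -> dict[str, str]:
        """Gene leaf name -> species leaf name."""
        return {x.name: self.mu[x].name for x in self.gene_tree.leaves}


@dataclass
class Violation:
    rule: str
    node: str
    detail: str = ""


def validate_reconciliation(rec: ReconciledGeneTree) -> list[Violation]:
    """Check the three reconciliation requirements; violations are data, not errors."""
    out: list[Violation] = []
    G, S = rec.gene_tree, rec.species_tree
    idx = S.lca_index
    for v in G.nodes:
        s = rec.mu.get(v)
        ev = rec.events.get(v)
        if s is None or ev is None:
            out.append(Violation("total-maps", v.name, "missing mu or event"))
            continue
        if v.is_leaf:
            if not s.is_leaf or ev != EXTANT:
                out.append(
                    Violation(
                        "leaves-extant",
                        v.name,
                        f"leaf maps to {s.name!r} with label {ev!r}",
                    )
                )
        else:
            if ev not in (DUP, SPEC):
                out.append(Violation("leaves-extant", v.name, f"internal label {ev!r}"))
        for c in v.children:
            sc = rec.mu.get(c)
            if sc is not None and idx.lca(sc, s) is not s:
                out.append(
                    Violation(
                        "time-consistency",
                        c.name,
                        f"child species {sc.name!r} not under parent species {s.name!r}",
                    )
                )
        if ev == SPEC:
            if s.is_leaf:
                out.append(
                    Violation("speciations-separate-species", v.name, "spec at a species leaf")
                )
            elif len(v.children) != 2:
                out.append(
                    Violation(
                        "speciations-separate-species",
                        v.name,
                        f"spec node with {len(v.children)} children",
                    )
                )
            else:
                s1, s2 = s.children
                c1, c2 = v.children
                m1, m2 = rec.mu.get(c1), rec.mu.get(c2)
                if m1 is None or m2 is None:
                    continue
                under1 = (idx.lca(m1, s1) is s1, idx.lca(m1, s2) is s2)
                under2 = (idx.lca(m2, s1) is s1, idx.lca(m2, s2) is s2)
                ok = (under1[0] and under2[1]) or (under1[1] and under2[0])
                if not ok:
                    out.append(
                        Violation(
                            "speciations-separate-species",
                            v.name,
                            "children's species do not lie under distinct "
                            f"children of {s.name!r}",
                        )
                    )
    return out


def lca_map_to_species(
    G: GeneTree, S: SpeciesTree, leaf_species: dict[str, str]
) -> dict[Node, Node]:
    """The lca-mapping: mu(v) = lca_S of the species of v's descendant leaves.

    Computed bottom-up with one lca query per child edge, so the whole map
    costs O(|G|) queries.
    """
    idx = S.lca_index
    mu: dict[Node, Node] = {}
    for v in G.root.postorder():
        if v.is_leaf:
            try:
                sp_name = leaf_species[v.name]
            except KeyError:
                raise TreeError(f"gene leaf {v.name!r} has no assigned species") from None
            sp = S.node(sp_name)
            if not sp.is_leaf:
                raise TreeError(f"{sp_name!r} is not an extant species")
            mu[v] = sp
        else:
            acc = mu[v.children[0]]
            for c in v.children[1:]:
                acc = idx.lca(acc, mu[c])
            mu[v] = acc
    return mu


def infer_event_labels(
    G: GeneTree, S: SpeciesTree, mu: dict[Node, Node]
) -> dict[Node, str]:
    """Event labels implied by an lca-mapping.

    A binary internal node is a speciation iff its species differs from both
    children's species; otherwise (including every polytomy) it is a
    duplication.  Leaves are extant.
    """
    events: dict[Node, str] = {}
    for v in G.nodes:
        if v.is_leaf:
            events[v] = EXTANT
        elif len(v.children) == 2 and all(
            mu[v] is not mu[c] for c in v.children
        ):
            events[v] = SPEC
        else:
            events[v] = DUP
    return events


def reconcile_lca(
    G: GeneTree, S: SpeciesTree, leaf_species: dict[str, str]
) -> ReconciledGeneTree:
    """Reconcile G with S via the lca-mapping and its implied event labels."""
    mu = lca_map_to_species(G, S, leaf_species)
    events = infer_event_labels(G, S, mu)
    return ReconciledGeneTree(G, S, mu, events)


# ---------------------------------------------------------------------------
# Newick / NHX I/O
# ---------------------------------------------------------------------------


def _parse_newick(text: str) -> tuple[Node, dict[str, dict[str, str]]]:
    """Parse rooted Newick; returns the root and per-node NHX tag dicts (by name)."""
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            extract_comment_metadata=False,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise TreeError(f"malformed Newick: {exc}") from None

    tags: dict[int, dict[str, str]] = {}

    def convert(dn) -> Node:
        name = dn.taxon.label if dn.taxon is not None else dn.label
        node = Node(name)
        nhx = {}
        for comment in dn.comments:
            if comment.startswith("&&NHX"):
                for part in comment.split(":")[1:]:
                    if "=" in part:
                        k, _, val = part.partition("=")
                        nhx[k] = val
        tags[id(node)] = nhx
        for dc in dn.child_nodes():
            node.add_child(convert(dc))
        return node

    root = convert(dtree.seed_node)
    # a comment trailing the final token (e.g. on a single-leaf tree) is
    # attached to the tree itself by the reader; it belongs to the root
    for comment in dtree.comments:
        if comment.startswith("&&NHX"):
            for part in comment.split(":")[1:]:
                if "=" in part:
                    k, _, val = part.partition("=")
                    tags[id(root)].setdefault(k, val)
    # name unnamed nodes now so tags can be keyed by name
    taken = {v.name for v in root.preorder() if v.name}
    for i, v in enumerate(root.preorder()):
        if not v.name:
            name = f"n{i}"
            while name in taken:
                name = "_" + name
            v.name = name
            taken.add(name)
    by_name = {v.name: tags[id(v)] for v in root.preorder()}
    return root, by_name


def parse_species_tree(text: str) -> SpeciesTree:
    root, _ = _parse_newick(text)
    return SpeciesTree(root)


def parse_gene_tree(text: str) -> GeneTree:
    root, _ = _parse_newick(text)
    return GeneTree(root)


def parse_reconciled_tree(text: str, species: SpeciesTree) -> ReconciledGeneTree:
    """Read a reconciled gene tree from Newick with NHX tags ``S=`` and ``Ev=``.

    Every node needs a species tag; internal nodes need an event tag in
    {dup, spec}; on leaves ``Ev=extant`` may be omitted.  Validity of the
    reconciliation itself is not enforced here.
    """
    root, tags = _parse_newick(text)
    G = GeneTree(root)
    mu: dict[Node, Node] = {}
    events: dict[Node, str] = {}
    for v in G.nodes:
        t = tags.get(v.name, {})
        if "S" not in t:
            raise TreeError(f"node {v.name!r} lacks a species annotation")
        mu[v] = species.node(t["S"])
        ev = t.get("Ev")
        if v.is_leaf:
            if ev not in (None, EXTANT):
                raise TreeError(f"leaf {v.name!r} carries event {ev!r}")
            events[v] = EXTANT
        else:
            if ev is None:
                raise TreeError(f"internal node {v.name!r} lacks an event annotation")
            if ev not in (DUP, SPEC):
                raise TreeError(f"unknown event {ev!r} on node {v.name!r}")
            events[v] = ev
    return ReconciledGeneTree(G, species, mu, events)


def parse_reconciled_tree_tsv(
    newick: str, table: str, species: SpeciesTree
) -> ReconciledGeneTree:
    """Alternate input: plain Newick plus a ``node_id<TAB>species<TAB>event`` table."""
    root, _ = _parse_newick(newick)
    G = GeneTree(root)
    rows: dict[str, tuple[str, str]] = {}
    for line in io.StringIO(table):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise TreeError(f"bad annotation row: {line!r}")
        rows[parts[0]] = (parts[1], parts[2])
    mu: dict[Node, Node] = {}
    events: dict[Node, str] = {}
    for v in G.nodes:
        if v.name not in rows:
            raise TreeError(f"node {v.name!r} missing from annotation table")
        sp, ev = rows[v.name]
        mu[v] = species.node(sp)
        if ev not in EVENTS:
            raise TreeError(f"unknown event {ev!r} on node {v.name!r}")
        if v.is_leaf != (ev == EXTANT):
            raise TreeError(f"event {ev!r} inconsistent with node {v.name!r}")
        events[v] = ev
    return ReconciledGeneTree(G, species, mu, events)


def write_newick(tree: Tree, internal_names: bool = True) -> str:
    def fmt(v: Node) -> str:
        if v.is_leaf:
            return v.name
        inner = ",".join(fmt(c) for c in v.children)
        label = v.name if internal_names else ""
        return f"({inner}){label}"

    return fmt(tree.root) + ";"


def write_reconciled_tree(rec: ReconciledGeneTree) -> str:
    """Serialize as Newick with NHX ``S=``/``Ev=`` tags on every node."""

    def fmt(v: Node) -> str:
        tag = f"[&&NHX:S={rec.mu[v].name}:Ev={rec.events[v]}]"
        if v.is_leaf:
            return v.name + tag
        inner = ",".join(fmt(c) for c in v.children)
        return f"({inner}){v.name}{tag}"

    return fmt(rec.gene_tree.root) + ";"
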