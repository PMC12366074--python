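"""Random reconciliation scenarios and deterministic worked-example fixtures.

The simulator builds a reconciled gene tree bottom-up over a fixed gene set:
starting from the extant genes, it repeatedly draws an unordered pair from
the active set with probability proportional to exp(-decay_rate * d), where d
is the species-tree distance between the species of the two elements, and
replaces the pair by a new parent.  The parent's species is the lca of its
children's species (so the output uses the lca-mapping), and its event is
forced to ``dup`` when it shares a species with a child; otherwise ``spec``
is drawn with probability ``spec_probability``.  The exponential kernel keeps
nearby genes coalescing first, which prevents most internal nodes from being
pushed to the root and turning into duplications.

Every simulator output satisfies the three reconciliation requirements by
construction; the test suite audits this.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .rooting import UnrootedTree
from .trees import (
    DUP,
    EXTANT,
    SPEC,
    GeneTree,
    Node,
    ReconciledGeneTree,
    SpeciesTree,
    TreeError,
    dist,
    parse_species_tree,
)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_species_tree(n: int, seed=None) -> SpeciesTree:
    """Random binary species tree on n leaves (s1..sn) by uniform sequential
    attachment: each new leaf is grafted onto a uniformly chosen node,
    including the root position."""
    if n < 2:
        raise TreeError("need at least 2 species")
    rng = _rng(seed)
    root = Node(None, [Node("s1"), Node("s2")])
    nodes = [root, root.children[0], root.children[1]]
    for i in range(3, n + 1):
        target = nodes[int(rng.integers(len(nodes)))]
        new_leaf = Node(f"s{i}")
        new_internal = Node(None)
        parent = target.parent
        if parent is None:
            new_internal.add_child(target)
            new_internal.add_child(new_leaf)
            root = new_internal
        else:
            j = parent.children.index(target)
            parent.children[j] = new_internal
            new_internal.parent = parent
            new_internal.add_child(target)
            new_internal.add_child(new_leaf)
        nodes.append(new_internal)
        nodes.append(new_leaf)
    return SpeciesTree(root)


def random_gene_set(
    S: SpeciesTree, max_per_species: int = 1, seed=None
) -> tuple[list[str], dict[str, str]]:
    """Draw per-species gene counts uniformly from {1, ..., max_per_species}.

    Gene names encode their species (``<species>_<index>``), so the
    species assignment is recoverable from names alone.
    """
    if max_per_species < 1:
        raise TreeError("max_per_species must be >= 1")
    rng = _rng(seed)
    genes: list[str] = []
    assignment: dict[str, str] = {}
    for sp in S.leaf_names:
        k = int(rng.integers(1, max_per_species + 1))
        for i in range(1, k + 1):
            g = f"{sp}_{i}"
            genes.append(g)
            assignment[g] = sp
    return genes, assignment


@dataclass
class SimulationConfig:
    """Parameters of the bottom-up reconciliation generator."""

    species_tree: SpeciesTree
    genes: list[str]
    species_assignment: dict[str, str]
    decay_rate: float = 0.7
    spec_probability: float = 0.5
    seed: int | None = None

    def __post_init__(self):
        if self.decay_rate <= 0:
            raise TreeError("decay_rate must be positive")
        if not 0 <= self.spec_probability <= 1:
            raise TreeError("spec_probability must lie in [0, 1]")
        leaf_names = set(self.species_tree.leaf_names)
        for g in self.genes:
            sp = self.species_assignment.get(g)
            if sp not in leaf_names:
                raise TreeError(f"gene {g!r} assigned to unknown species {sp!r}")


def simulate_reconciliation(cfg: SimulationConfig) -> ReconciledGeneTree:
    """Run the bottom-up generator; the output is binary with |genes|-1
    internal nodes and uses the lca-mapping."""
    if not cfg.genes:
        raise TreeError("empty gene set")
    rng = _rng(cfg.seed)
    S = cfg.species_tree
    idx = S.lca_index

    active: list[Node] = []
    mu: dict[Node, Node] = {}
    events: dict[Node, str] = {}
    for g in cfg.genes:
        leaf = Node(g)
        active.append(leaf)
        mu[leaf] = S.node(cfg.species_assignment[g])
        events[leaf] = EXTANT

    counter = itertools.count(1)
    while len(active) > 1:
        pairs = list(itertools.combinations(range(len(active)), 2))
        d = np.array(
            [dist(S, mu[active[i]], mu[active[j]]) for i, j in pairs], dtype=float
        )
        w = np.exp(-cfg.decay_rate * d)
        p = w / w.sum()
        i, j = pairs[int(rng.choice(len(pairs), p=p))]
        x1, x2 = active[i], active[j]
        parent = Node(f"i{next(counter)}", [x1, x2])
        mu[parent] = idx.lca(mu[x1], mu[x2])
        if mu[parent] is mu[x1] or mu[parent] is mu[x2]:
            events[parent] = DUP
        else:
            events[parent] = (
                SPEC if rng.random() < cfg.spec_probability else DUP
            )
        active = [v for k, v in enumerate(active) if k not in (i, j)]
        active.append(parent)

    g = GeneTree(active[0])
    return ReconciledGeneTree(g, S, mu, events)


# ---------------------------------------------------------------------------
# Worked-example fixtures
# ---------------------------------------------------------------------------


def _rec(
    S: SpeciesTree,
    root: Node,
    species: dict[str, str],
    labels: dict[str, str],
) -> ReconciledGeneTree:
    g = GeneTree(root)
    mu = {v: S.node(species[v.name]) for v in g.nodes}
    ev = {
        v: (EXTANT if v.is_leaf else labels[v.name]) for v in g.nodes
    }
    return ReconciledGeneTree(g, S, mu, ev)


def fig1_fixture() -> tuple[ReconciledGeneTree, ReconciledGeneTree, SpeciesTree]:
    """The four-species worked example: two reconciliations over leaves
    a, b, c, d that disagree in topology, one species assignment, and two
    event labels (d_path 1/0, d_lbl 2/2, d_plr 2.5 at alpha=0.5)."""
    S = parse_species_tree("((C,D)z1,(A,B)z2)z0;")
    # G1 = ((c,d)x1, (a,b)x2)x0 with the lca-mapping
    g1 = Node(
        "x0",
        [
            Node("x1", [Node("c"), Node("d")]),
            Node("x2", [Node("a"), Node("b")]),
        ],
    )
    r1 = _rec(
        S,
        g1,
        {"x0": "z0", "x1": "z1", "x2": "z2", "a": "A", "b": "B", "c": "C", "d": "D"},
        {"x0": SPEC, "x1": DUP, "x2": SPEC},
    )
    # G2 = (d, (c, (a,b)y2)y1)y0 with the lca-mapping
    g2 = Node(
        "y0",
        [
            Node("d"),
            Node("y1", [Node("c"), Node("y2", [Node("a"), Node("b")])]),
        ],
    )
    r2 = _rec(
        S,
        g2,
        {"y0": "z0", "y1": "z0", "y2": "z2", "a": "A", "b": "B", "c": "C", "d": "D"},
        {"y0": DUP, "y1": SPEC, "y2": DUP},
    )
    return r1, r2, S


def fig2_fixture() -> tuple[ReconciledGeneTree, ReconciledGeneTree, SpeciesTree]:
    """Two reconciliations whose every disagreement sits inside same-species
    duplication chains (in species A, B and in the ancestral species X), so
    their PLR dissimilarity is 0 and their LDR forms are isomorphic."""
    S = parse_species_tree("(A,B)X;")

    def chain(x, y, z, names):
        # ((x,y)inner, z)outer duplication chain
        return Node(names[1], [Node(names[0], [Node(x), Node(y)]), Node(z)])

    # G1: A-chain ((a1,a2),a3), B-chain ((b1,b2),b5), spec at X,
    # then an X duplication chain picking up b3 and b4
    g1 = Node(
        "u0",
        [
            Node(
                "u1",
                [
                    Node(
                        "sp1",
                        [
                            chain("a1", "a2", "a3", ["pA", "qA"]),
                            chain("b1", "b2", "b5", ["pB", "qB"]),
                        ],
                    ),
                    Node("b3"),
                ],
            ),
            Node("b4"),
        ],
    )
    sp_map1 = {
        "u0": "X", "u1": "X", "sp1": "X",
        "pA": "A", "qA": "A", "pB": "B", "qB": "B",
        "a1": "A", "a2": "A", "a3": "A",
        "b1": "B", "b2": "B", "b3": "B", "b4": "B", "b5": "B",
    }
    lab1 = {"u0": DUP, "u1": DUP, "sp1": SPEC, "pA": DUP, "qA": DUP, "pB": DUP, "qB": DUP}
    r1 = _rec(S, g1, sp_map1, lab1)

    # G2: same genes, chains resolved differently, b3/b4 swapped in the X chain
    g2 = Node(
        "v0",
        [
            Node(
                "v1",
                [
                    Node(
                        "sp2",
                        [
                            chain("a2", "a3", "a1", ["rA", "sA"]),
                            chain("b2", "b5", "b1", ["rB", "sB"]),
                        ],
                    ),
                    Node("b4"),
                ],
            ),
            Node("b3"),
        ],
    )
    sp_map2 = {
        "v0": "X", "v1": "X", "sp2": "X",
        "rA": "A", "sA": "A", "rB": "B", "sB": "B",
        "a1": "A", "a2": "A", "a3": "A",
        "b1": "B", "b2": "B", "b3": "B", "b4": "B", "b5": "B",
    }
    lab2 = {"v0": DUP, "v1": DUP, "sp2": SPEC, "rA": DUP, "sA": DUP, "rB": DUP, "sB": DUP}
    r2 = _rec(S, g2, sp_map2, lab2)
    return r1, r2, S


def fig3_fixture(
    k: int = 2,
) -> tuple[
    ReconciledGeneTree, ReconciledGeneTree, ReconciledGeneTree, SpeciesTree
]:
    """The triangle-inequality violation construction.

    Species tree ((A,B)X,C)Y.  G1's root is a duplication at Y whose children
    are k >= 2 copies of an ((a,b),(a,b)) duplication-at-X subtree plus a leaf
    c.  G2 hangs all 2k (a,b) speciation cherries under a single duplication
    at X, below a speciation at Y with c.  G3 groups all a-genes and all
    b-genes into duplication polytomies under a speciation at X, below a
    speciation at Y with c.  All three use the lca-mapping, yet
    d_plr(G1, G3) > d_plr(G1, G2) + d_plr(G2, G3) for every alpha in [0, 1].
    """
    if k < 2:
        raise TreeError("the construction needs k >= 2")
    S = parse_species_tree("((A,B)X,C)Y;")
    a = [f"a{i}" for i in range(1, 2 * k + 1)]
    b = [f"b{i}" for i in range(1, 2 * k + 1)]

    sp_map = {"c": "C"}
    sp_map.update({g: "A" for g in a})
    sp_map.update({g: "B" for g in b})

    # G1: root dup at Y over k X-duplication subtrees, each two (a,b) cherries
    g1_children = []
    lab1 = {"root1": DUP}
    sp1 = dict(sp_map)
    for i in range(k):
        c1 = Node(f"s{2 * i + 1}", [Node(a[2 * i]), Node(b[2 * i])])
        c2 = Node(f"s{2 * i + 2}", [Node(a[2 * i + 1]), Node(b[2 * i + 1])])
        d_node = Node(f"d{i + 1}", [c1, c2])
        g1_children.append(d_node)
        lab1[c1.name] = SPEC
        lab1[c2.name] = SPEC
        lab1[d_node.name] = DUP
        sp1[c1.name] = "X"
        sp1[c2.name] = "X"
        sp1[d_node.name] = "X"
    g1 = Node("root1", g1_children + [Node("c")])
    sp1["root1"] = "Y"
    r1 = _rec(S, g1, sp1, lab1)

    # G2: spec at Y over c and a single dup at X with 2k (a,b) spec cherries
    cherries = [
        Node(f"t{i + 1}", [Node(a[i]), Node(b[i])]) for i in range(2 * k)
    ]
    g2 = Node("root2", [Node("dx", cherries), Node("c")])
    sp2 = dict(sp_map)
    sp2.update({"root2": "Y", "dx": "X"})
    lab2 = {"root2": SPEC, "dx": DUP}
    for ch in cherries:
        sp2[ch.name] = "X"
        lab2[ch.name] = SPEC
    r2 = _rec(S, g2, sp2, lab2)

    # G3: spec at Y over c and a spec at X joining an all-a and an all-b
    # duplication polytomy
    g3 = Node(
        "root3",
        [
            Node(
                "sx",
                [
                    Node("da", [Node(x) for x in a]),
                    Node("db", [Node(x) for x in b]),
                ],
            ),
            Node("c"),
        ],
    )
    sp3 = dict(sp_map)
    sp3.update({"root3": "Y", "sx": "X", "da": "A", "db": "B"})
    lab3 = {"root3": SPEC, "sx": SPEC, "da": DUP, "db": DUP}
    r3 = _rec(S, g3, sp3, lab3)
    return r1, r2, r3, S


def fig4_fixture() -> tuple[
    tuple[UnrootedTree, dict[str, str]], tuple[UnrootedTree, dict[str, str]]
]:
    """A pair of unrooted event-labeled trees on five leaves with two internal
    edges each, illustrating the ELRF diameter bound: transforming one into
    the other by label-respecting contractions/extensions and label flips
    takes 3n - 8 = 7 operations.
    """
    adj = {
        "l1": ["i1"], "l2": ["i1"],
        "i1": ["l1", "l2", "i2"],
        "l3": ["i2"],
        "i2": ["i1", "l3", "i3"],
        "l4": ["i3"], "l5": ["i3"],
        "i3": ["i2", "l4", "l5"],
    }
    t1 = (UnrootedTree(adj), {"i1": SPEC, "i2": DUP, "i3": SPEC})
    t2 = (UnrootedTree(adj), {"i1": DUP, "i2": SPEC, "i3": DUP})
    return t1, t2
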