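"""The Path-Label Reconciliation (PLR) dissimilarity.

Two reconciled gene trees over the same species tree and leafset are compared
through the gene-gene correspondence m(v) = lca_G2(L(v)), the lowest node of
the second tree ancestral to v's whole clade.  Each node is penalized by the
species-tree distance between its species and its correspondent's species
(the *path* component) and by an event-label mismatch (the *label*
component):

    d_path(G1, G2) = sum_v dist_S(mu1(v), mu2(m(v)))
    d_lbl(G1, G2)  = |{v : l1(v) != l2(m(v))}|
    d_asym         = alpha * d_path + (1 - alpha) * d_lbl
    d_plr          = d_asym(G1, G2) + d_asym(G2, G1)

Incomparable inputs (different species tree or leafset) give an infinite
d_plr.  With the lca indexes preprocessed, a pairwise evaluation is linear in
the sizes of the two gene trees.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trees import GeneTree, Node, ReconciledGeneTree, SpeciesTree, TreeError, dist


@dataclass
class GeneGeneMap:
    """The correspondence m(v) = lca_target(L(v)) from source to target gene nodes."""

    source: ReconciledGeneTree
    target: ReconciledGeneTree
    m: dict[Node, Node]
    lca_queries: int = 0


@dataclass
class DissimilarityResult:
    """Both directed components plus the symmetric d_plr.

    ``d_path``/``d_lbl`` are exact integers; only the alpha-weighting
    introduces floats.  ``one_gene_per_species`` records whether both trees
    carry exactly one gene per extant species, the regime in which the
    theoretical diameter (and hence theoretical normalization) applies.
    """

    alpha: float
    d_path_12: int
    d_lbl_12: int
    d_path_21: int
    d_lbl_21: int
    comparable: bool
    one_gene_per_species: bool = False

    @property
    def d_asym_12(self) -> float:
        return self.alpha * self.d_path_12 + (1 - self.alpha) * self.d_lbl_12

    @property
    def d_asym_21(self) -> float:
        return self.alpha * self.d_path_21 + (1 - self.alpha) * self.d_lbl_21

    @property
    def d_plr(self) -> float:
        if not self.comparable:
            return math.inf
        return self.d_asym_12 + self.d_asym_21


def resolve_alpha(alpha: float | str, S: SpeciesTree) -> float:
    """Resolve a literal weight or the symbolic ``"1/n"`` (n = species count)."""
    if isinstance(alpha, str):
        a = alpha.strip()
        if a.startswith("1/"):
            denom = a[2:]
            n = len(S.leaves) if denom == "n" else int(denom)
            return 1.0 / n
        alpha = float(a)
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    return float(alpha)


def are_comparable(
    r1: ReconciledGeneTree,
    r2: ReconciledGeneTree,
    require_leaf_species_equal: bool = True,
) -> tuple[bool, list[str]]:
    """Comparability: same species tree, same leafset, and (by default) each
    shared leaf mapped to the same species in both trees.

    The last condition may be relaxed (``require_leaf_species_equal=False``)
    to compare reconciliations that disagree even on the species of extant
    genes; leaves then contribute to the path component.
    """
    problems: list[str] = []
    if r1.species_tree is not r2.species_tree:
        problems.append("different species trees")
    l1 = set(r1.gene_tree.leaf_names)
    l2 = set(r2.gene_tree.leaf_names)
    if l1 != l2:
        diff = sorted(l1 ^ l2)
        problems.append(f"leafsets differ: {diff}")
    elif require_leaf_species_equal:
        for x in r1.gene_tree.leaves:
            y = r2.gene_tree.node(x.name)
            if r1.mu[x] is not r2.mu[y]:
                problems.append(
                    f"leaf {x.name!r} maps to {r1.mu[x].name!r} vs {r2.mu[y].name!r}"
                )
    return (not problems, problems)


def gene_gene_lca_map(
    r1: ReconciledGeneTree, r2: ReconciledGeneTree
) -> GeneGeneMap:
    """Compute m bottom-up: m(leaf x) is the equally named leaf of the target,
    and m(v) folds the children's images through target-tree lca queries.

    Uses one query per child edge beyond the first, so fewer queries than
    edges of the source tree.
    """
    ok, problems = are_comparable(r1, r2, require_leaf_species_equal=False)
    if not ok:
        raise TreeError("incomparable reconciliations: " + "; ".join(problems))
    g2 = r2.gene_tree
    idx = g2.lca_index
    start = idx.query_count
    m: dict[Node, Node] = {}
    for v in r1.gene_tree.root.postorder():
        if v.is_leaf:
            m[v] = g2.node(v.name)
        else:
            acc = m[v.children[0]]
            for c in v.children[1:]:
                acc = idx.lca(acc, m[c])
            m[v] = acc
    return GeneGeneMap(r1, r2, m, lca_queries=idx.query_count - start)


def d_path(
    r1: ReconciledGeneTree, r2: ReconciledGeneTree, m: GeneGeneMap | None = None
) -> int:
    """Directed path component: sum over V(G1) of dist_S(mu1(v), mu2(m(v)))."""
    if m is None:
        m = gene_gene_lca_map(r1, r2)
    S = r1.species_tree
    return sum(dist(S, r1.mu[v], r2.mu[m.m[v]]) for v in r1.gene_tree.nodes)


def d_lbl(
    r1: ReconciledGeneTree, r2: ReconciledGeneTree, m: GeneGeneMap | None = None
) -> int:
    """Directed label component: number of nodes of G1 whose event label
    differs from their correspondent's."""
    if m is None:
        m = gene_gene_lca_map(r1, r2)
    return sum(
        1 for v in r1.gene_tree.nodes if r1.events[v] != r2.events[m.m[v]]
    )


def d_asym(
    r1: ReconciledGeneTree, r2: ReconciledGeneTree, alpha: float | str = 0.5
) -> float:
    """Directed dissimilarity alpha*d_path + (1-alpha)*d_lbl."""
    a = resolve_alpha(alpha, r1.species_tree)
    m = gene_gene_lca_map(r1, r2)
    return a * d_path(r1, r2, m) + (1 - a) * d_lbl(r1, r2, m)


def _one_gene_per_species(r: ReconciledGeneTree) -> bool:
    species = [r.mu[x] for x in r.gene_tree.leaves]
    return len(species) == len(set(map(id, species))) == len(
        r.species_tree.leaves
    )


def d_plr(
    r1: ReconciledGeneTree,
    r2: ReconciledGeneTree,
    alpha: float | str = 0.5,
    require_leaf_species_equal: bool = True,
) -> DissimilarityResult:
    """The symmetric PLR dissimilarity with full component breakdown.

    Incomparability is a result state (``comparable=False``, infinite
    ``d_plr``), not an exception.  With ``require_leaf_species_equal=False``
    leaves mapped to different species are allowed and contribute their
    species distance to the path components.
    """
    a = resolve_alpha(alpha, r1.species_tree)
    ok, _ = are_comparable(r1, r2, require_leaf_species_equal)
    if not ok:
        return DissimilarityResult(a, 0, 0, 0, 0, comparable=False)
    m12 = gene_gene_lca_map(r1, r2)
    m21 = gene_gene_lca_map(r2, r1)
    res = DissimilarityResult(
        alpha=a,
        d_path_12=d_path(r1, r2, m12),
        d_lbl_12=d_lbl(r1, r2, m12),
        d_path_21=d_path(r2, r1, m21),
        d_lbl_21=d_lbl(r2, r1, m21),
        comparable=True,
        one_gene_per_species=_one_gene_per_species(r1)
        and _one_gene_per_species(r2),
    )
    return res


def pairwise_matrix(
    recs: list[ReconciledGeneTree], alpha: float | str = 0.5
) -> np.ndarray:
    """Symmetric matrix of d_plr values over C(n,2) unordered computations.

    Incomparable pairs yield ``inf`` entries; the diagonal is zero.
    """
    n = len(recs)
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        out[i, j] = out[j, i] = d_plr(recs[i], recs[j], alpha).d_plr
    return out


def pairwise_table(
    recs: list[ReconciledGeneTree],
    alpha: float | str = 0.5,
    names: list[str] | None = None,
) -> pd.DataFrame:
    """Long-form table of all unordered pairs with component columns."""
    if names is None:
        names = [f"tree{i}" for i in range(len(recs))]
    rows = []
    for i, j in itertools.combinations(range(len(recs)), 2):
        r = d_plr(recs[i], recs[j], alpha)
        rows.append(
            {
                "tree1": names[i],
                "tree2": names[j],
                "d_path_12": r.d_path_12,
                "d_lbl_12": r.d_lbl_12,
                "d_path_21": r.d_path_21,
                "d_lbl_21": r.d_lbl_21,
                "alpha": r.alpha,
                "d_plr": r.d_plr,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "tree1",
            "tree2",
            "d_path_12",
            "d_lbl_12",
            "d_path_21",
            "d_lbl_21",
            "alpha",
            "d_plr",
        ],
    )
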