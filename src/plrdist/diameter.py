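"""Diameters and normalization constants for reconciliation dissimilarities.

For a fixed binary species tree S with n leaves and gene trees carrying
exactly one gene per species, the maximum attainable PLR value is

    diam(d_plr, S) = 2 alpha H(S) + (1 - alpha)(2n - 2)

where H(S) is the sum of root-to-internal-node distances.  H(S) is maximized
by the caterpillar, where it equals (n-1)(n-2)/2.  The bound is attained by a
concrete pair of reconciliations (see :func:`extremal_pair`), which makes
division by the diameter a sound [0, 1] normalization in that regime.  Upper
bounds for the label-respecting Robinson-Foulds variants (ELRF: 3n-8, LRF:
2n-5) are exposed as normalization constants only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .measure import DissimilarityResult, resolve_alpha
from .trees import (
    EXTANT,
    DUP,
    SPEC,
    GeneTree,
    Node,
    ReconciledGeneTree,
    SpeciesTree,
    TreeError,
    lca_map_to_species,
)


def h_sum(S: SpeciesTree) -> int:
    """H(S): sum of distances from the root to each internal node."""
    idx = S.lca_index
    return sum(idx.depth(v) for v in S.nodes if not v.is_leaf)


def plr_diameter(S: SpeciesTree, alpha: float | str) -> float:
    """Closed-form diameter 2*alpha*H(S) + (1-alpha)*(2n-2), one gene per species."""
    n = len(S.leaves)
    if n < 2:
        raise TreeError("diameter requires at least 2 species")
    a = resolve_alpha(alpha, S)
    return 2 * a * h_sum(S) + (1 - a) * (2 * n - 2)


def elrf_diameter_bound(n: int) -> int:
    """Upper bound 3n-8 on the ELRF diameter over labeled trees with n leaves."""
    if n < 3:
        raise ValueError("ELRF diameter bound requires n >= 3")
    return 3 * n - 8


def lrf_diameter_bound(n: int) -> int:
    """Upper bound 2n-5 on the LRF diameter over labeled trees with n leaves."""
    if n < 3:
        raise ValueError("LRF diameter bound requires n >= 3")
    return 2 * n - 5


@dataclass
class DiameterReport:
    n_species: int
    alpha: float
    h_sum: int
    plr_diameter: float
    elrf_bound: int | None
    lrf_bound: int | None


def diameter_report(S: SpeciesTree, alpha: float | str = 0.5) -> DiameterReport:
    n = len(S.leaves)
    a = resolve_alpha(alpha, S)
    return DiameterReport(
        n_species=n,
        alpha=a,
        h_sum=h_sum(S),
        plr_diameter=plr_diameter(S, a),
        elrf_bound=elrf_diameter_bound(n) if n >= 3 else None,
        lrf_bound=lrf_diameter_bound(n) if n >= 3 else None,
    )


def _copy_topology(v: Node) -> Node:
    w = Node(v.name if v.is_leaf else None)
    for c in v.children:
        w.add_child(_copy_topology(c))
    return w


def extremal_pair(
    S: SpeciesTree,
) -> tuple[ReconciledGeneTree, ReconciledGeneTree]:
    """A pair of one-gene-per-species reconciliations attaining the diameter.

    Both gene trees copy the topology of S, with one gene per species named
    after it.  The first uses the lca-mapping with every internal node a
    speciation; the second maps every internal node to the root as a
    duplication.  Every internal label then differs, and the path terms sum
    to 2 H(S).
    """
    if len(S.leaves) < 2:
        raise TreeError("need at least 2 species")
    leaf_species = {name: name for name in S.leaf_names}

    g1 = GeneTree(_copy_topology(S.root))
    mu1 = lca_map_to_species(g1, S, leaf_species)
    ev1 = {v: (EXTANT if v.is_leaf else SPEC) for v in g1.nodes}
    r1 = ReconciledGeneTree(g1, S, mu1, ev1)

    g2 = GeneTree(_copy_topology(S.root))
    mu2 = {}
    ev2 = {}
    for v in g2.nodes:
        if v.is_leaf:
            mu2[v] = S.node(v.name)
            ev2[v] = EXTANT
        else:
            mu2[v] = S.root
            ev2[v] = DUP
    r2 = ReconciledGeneTree(g2, S, mu2, ev2)
    return r1, r2


def normalize(
    result: DissimilarityResult | float,
    S: SpeciesTree | None = None,
    mode: str = "theoretical",
    pool=None,
    alpha: float | str | None = None,
) -> float:
    """Map a dissimilarity to [0, 1].

    ``theoretical`` divides by diam(d_plr, S); it is only sound in the
    one-gene-per-species regime and refuses anything else rather than
    extrapolating.  ``empirical_max`` divides by the maximum of a pool of
    observed values.
    """
    if isinstance(result, DissimilarityResult):
        value = result.d_plr
        if alpha is None:
            alpha = result.alpha
        one_gene = result.one_gene_per_species
    else:
        value = float(result)
        one_gene = None

    if mode == "theoretical":
        if S is None or alpha is None:
            raise ValueError("theoretical normalization needs S and alpha")
        if one_gene is False:
            raise TreeError(
                "theoretical normalization applies only to one-gene-per-species pairs"
            )
        diam = plr_diameter(S, alpha)
        if diam == 0:
            raise TreeError("zero diameter")
        return value / diam
    if mode in ("empirical", "empirical_max"):
        if pool is None:
            raise ValueError("empirical normalization needs a pool of values")
        mx = max(float(x) for x in pool)
        if not math.isfinite(mx) or mx <= 0:
            raise ValueError("empirical pool must have a positive finite maximum")
        return value / mx
    raise ValueError(f"unknown normalization mode {mode!r}")
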