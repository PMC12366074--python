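"""Shared fixtures and brute-force oracles.

The oracles deliberately avoid the package's fast paths: lca by parent-link
path marking, node distance by path walking, and the gene-gene correspondence
by exhaustive clade enumeration, so they can certify the indexed
implementations on small random inputs.
"""

from __future__ import annotations

import numpy as np
import pytest

import plrdist as P


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def naive_lca(u: P.Node, v: P.Node) -> P.Node:
    seen = set()
    x = u
    while x is not None:
        seen.add(id(x))
        x = x.parent
    x = v
    while id(x) not in seen:
        x = x.parent
    return x


def naive_dist(u: P.Node, v: P.Node) -> int:
    a = naive_lca(u, v)

    def up(x):
        d = 0
        while x is not a:
            x = x.parent
            d += 1
        return d

    return up(u) + up(v)


def clade(v: P.Node) -> frozenset[str]:
    return frozenset(x.name for x in v.leaves())


def naive_gene_gene_map(g1: P.GeneTree, g2: P.GeneTree) -> dict[P.Node, P.Node]:
    """m(v) = smallest clade of g2 containing v's clade, by enumeration."""
    clades2 = [(clade(w), w) for w in g2.nodes]
    out = {}
    for v in g1.nodes:
        cv = clade(v)
        best = min(
            (c2 for c2 in clades2 if cv <= c2[0]), key=lambda t: len(t[0])
        )
        out[v] = best[1]
    return out


# ---------------------------------------------------------------------------
# simulation helpers
# ---------------------------------------------------------------------------


def simulate_pool(
    n_species: int,
    max_per_species: int,
    count: int,
    seed: int,
    decay_rate: float = 0.7,
    spec_probability: float = 0.5,
) -> tuple[list[P.ReconciledGeneTree], P.SpeciesTree]:
    """A pool of comparable reconciliations over one species tree and gene set."""
    rng = np.random.default_rng(seed)
    S = P.random_species_tree(n_species, rng)
    genes, assignment = P.random_gene_set(S, max_per_species, rng)
    recs = [
        P.simulate_reconciliation(
            P.SimulationConfig(
                S,
                genes,
                assignment,
                decay_rate=decay_rate,
                spec_probability=spec_probability,
                seed=rng,
            )
        )
        for _ in range(count)
    ]
    return recs, S


@pytest.fixture(scope="session")
def fig1():
    return P.fig1_fixture()


@pytest.fixture(scope="session")
def fig2():
    return P.fig2_fixture()


@pytest.fixture(scope="session")
def small_pool():
    """Twenty comparable 8-species one-gene-per-species reconciliations."""
    return simulate_pool(n_species=8, max_per_species=1, count=20, seed=42)
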