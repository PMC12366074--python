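# Methods

## The objects

A reconciliation is a tuple 𝒢 = (G, S, μ, l): a rooted gene tree G (internal
nodes have ≥ 2 children; polytomies allowed), a rooted *binary* species tree
S, a total map μ from gene nodes to species nodes, and an event labeling l
over {dup, spec, extant}.  Three requirements make it valid: leaves are
extant genes in extant species; μ is monotone (descendants map to
descendants-or-equal, "time-consistency"); and a speciation node has exactly
two children whose species lie under the two distinct children of its own
species.  `validate_reconciliation` checks each requirement independently
and returns violations as data rather than raising, so invalid inputs can be
reported in full.

μ need not be the lca-mapping — a duplication may be mapped above the lca of
its descendant species — but the lca-mapping is the canonical choice and the
one produced by `lca_map_to_species` / `reconcile_lca`.  Event labels implied
by an lca-mapping (`infer_event_labels`) call a binary node a speciation iff
its species differs from both children's species; every polytomy is a
duplication, since a speciation must have exactly two children.

## The dissimilarity

For comparable 𝒢₁, 𝒢₂ (same S, same leaves, and by default the same species
for each extant gene), each node v of G₁ corresponds to
m(v) = lca_{G₂}(L(v)).  The directed components are

* d_path = Σ_v dist_S(μ₁(v), μ₂(m(v))) — how far each node's species drifted;
* d_lbl = number of v with l₁(v) ≠ l₂(m(v)).

They are blended by α into d_asym = α·d_path + (1−α)·d_lbl, and
d_plr = d_asym(𝒢₁,𝒢₂) + d_asym(𝒢₂,𝒢₁).  Incomparable pairs get d_plr = ∞,
carried as an explicit `comparable=False` state with an IEEE infinity
numeric view so matrices stay numeric without losing the reason.

Properties the implementation maintains (and the test suite asserts):
identity and exact symmetry; positivity whenever the least-duplication-
resolved forms differ and α ∈ (0, 1); monotonicity under redundant-edge
contraction; d_path ≤ H(S) per direction for one-gene-per-species families;
and failure of the triangle inequality on non-binary trees, reproduced by a
parametric fixture (`fig3_fixture(k)`) where the two-step path has length
4 − α but the direct distance is k(1−α) + 2α + 3 ≥ 5.

### Choice of α

d_path can scale like n·m (n species, m genes) while d_lbl is O(m), so a
constant α lets the path term dominate on large species trees.  The default
is α = 0.5 (equal weighting); the symbolic spelling `"1/n"` resolves n as
the number of species-tree leaves at call time and balances the
linear-versus-quadratic growth.  Components are returned as exact integers
alongside the blended values, so integer assertions never touch floating
point; with α from {0, ¼, ½, ¾, 1} all blended arithmetic is itself exact in
binary floating point.

### Complexity

All three trees are preprocessed for constant-time lca queries (Euler tour +
sparse table; O(n log n) preprocessing, O(1) per query — the strictly linear
preprocessing known in the literature buys nothing at the scales this
package targets).  The m-map is folded bottom-up with one query per child
edge beyond the first, so fewer queries than G₁ has edges; the index keeps a
query counter and the test suite asserts this bound.  One d_plr evaluation
is linear in |G₁| + |G₂| after preprocessing.

## LDR normal forms

An edge uv is redundant iff μ(u) = μ(v) and both are duplications.  `LR(𝒢)`
contracts redundant edges to a fixpoint; the parent subsumes the child, so
clades of surviving nodes are unchanged.  Fixpoint iteration with repeated
scans was chosen over a single clever pass because it is trivially
order-independent (asserted by randomized contraction orders in the tests).
In an LDR tree any strict ancestor/descendant pair differs in species or in
label, which is the structural fact behind positivity.  Isomorphism of
reconciliations is decided by canonical bottom-up forms: leaves are uniquely
named and fixed by the bijection, so sorting canonical child forms gives a
sound and complete check without graph-isomorphism machinery.

## Diameters and normalization

With S fixed and exactly one gene per species, the maximum of d_plr is
2αH(S) + (1−α)(2n−2), where H(S) = Σ dist_S(x, r(S)) over internal x.  The
bound is attained by `extremal_pair(S)`: two copies of S's topology, one
lca-mapped and all-speciation, the other with every internal node a
duplication at the root.  H(S) ≤ (n−1)(n−2)/2 with equality exactly for
caterpillars, so the caterpillar maximizes the diameter at fixed n.
`normalize(..., mode="theoretical")` divides by this diameter and *refuses*
multi-copy families instead of extrapolating — the closed form is only
proved in the one-gene-per-species regime; `mode="empirical_max"` divides by
the maximum of a supplied pool and serves the general case.  The ELRF (3n−8)
and LRF (2n−5) diameter bounds are exposed purely as normalization
constants; those distances themselves are out of scope, and the bounds are
treated strictly as upper bounds (their tightness is open).

## The simulator

`simulate_reconciliation` grows a reconciled tree bottom-up over a fixed
gene set Γ with species assignment σ: at each step an unordered pair of
active nodes is drawn with probability ∝ exp(−decay_rate · d), d the
species-tree distance between their current species, and replaced by a new
parent whose species is the lca of the pair.  The label is forced to `dup`
when the parent shares a species with a child (the speciation rule would be
violated), otherwise `spec` is drawn with probability `spec_probability`.
Defaults: decay_rate = 0.7 — the exponential kernel keeps nearby genes
coalescing first, preventing most internal nodes from collapsing to
root-level duplications — and spec_probability = 0.5, an unprejudiced coin
where both events are legal.  Weights are normalized over all current pairs
each iteration; all randomness flows through a single seeded generator, so
identical configurations reproduce identical trees bit-for-bit.

Outputs are binary, use the lca-mapping, and always satisfy the three
validity requirements (audited over hundreds of seeds).  The companion
generators are deliberately simple: `random_species_tree` uses uniform
sequential leaf attachment (shape diversity is all the distance experiments
need), and `random_gene_set` draws per-species gene counts uniformly from
{1..j} with names `<species>_<i>` so σ is recoverable from names.

What the simulator does *not* emulate: gene loss (every family is complete),
horizontal transfer, birth–death branch lengths, sequence evolution, and
reconstruction error.  Tests passing on simulated data therefore certify
the algebra and the algorithmic contracts of the measure, not its behavior
on noisy, loss-pruned gene trees inferred from alignments.

## Rooting evaluation

Every edge of an unrooted gene tree yields one rooting (subdivide and root);
a binary former root is suppressed when unrooting, so rooting the edge it
occupied recovers the original topology.  Each candidate is reconciled by
the lca-mapping with inferred labels and scored by d_plr against a
reference; the Best set keeps *all* minimizers — tie counts are a
measurement, not a nuisance, so ties are never broken.  When the reference
is itself the lca-reconciliation of one candidate's topology, that candidate
scores exactly 0 (self-recovery, asserted across 100 simulated scenarios).
Note the simulator may label a node `dup` where `spec` was permitted;
self-recovery is therefore stated for lca-reconciled references, whose
labels the candidates can actually reproduce.

## Problem sizes and numerical conventions

The randomized suites run at desk scale, chosen to finish in seconds while
still exercising every claimed regime: species trees up to 50 leaves for
diameter attainment, gene trees up to ~100 leaves for the oracle
cross-checks, pools of 50 reconciliations (1225 pairs) for the distribution
experiment, and 500+ simulated pairs for the semi-metric properties.
Depth of the root is 0; distances are edge counts (branch lengths are not
used — adapting d_path to weighted species trees would be a straightforward
extension but is out of scope).  Single-leaf gene trees are valid
reconciliations and have d_plr = 0 against themselves.  Non-binary species
trees are rejected outright rather than resolved.

## Serialization

No standard format exists for reconciled gene trees; this package uses
rooted Newick with NHX-style comment tags `S=<species>` and
`Ev=dup|spec|extant` on every node (round-trips through common viewers), and
accepts an alternate two-column TSV (`node_id`, species, event) next to a
plain Newick.  Unnamed internal nodes receive deterministic preorder ids at
parse time so node identity is stable across the round-trip.
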