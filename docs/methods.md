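# Methods

## Network model

A metabolic network is a directed simple graph of reaction identifiers.
Self-loops are rejected; reciprocal edges a→b and b→a are two distinct
edges (reversible neighborhood relations occur in real reaction graphs).
Every node of a level-*x* network carries a *member set* of 1…2^*x*
level-0 reactions; the member sets of any level partition the original
node set, which `CompressionHierarchy.validate` enforces.

## MDS compression

One compression level repeatedly (i) finds the minimum positive *active*
degree — degree counted only towards nodes not yet compressed in this
level, with deg = indeg + outdeg so a reciprocal neighbor counts twice —
(ii) merges the selected node with one of its non-compressed neighbors
into a supernode, re-attaching external edges with deduplication, and
(iii) marks both constituents compressed. The level ends when all active
degrees are 0; leftover nodes carry over as single-child supernodes.

Where the procedure says "take the first" without defining an order, this
implementation fixes the lexicographic order on identifiers: the smallest
minimum-degree node is selected and its smallest non-compressed neighbor
merged. This makes `mds_compress` a pure function of the input. The
randomized variant replaces only the node selection by a seeded uniform
draw from the minimum-degree set; compressed sizes are insensitive to the
choice, which `tests` exercise on tie-free and tied instances. Supernode
identifiers are the sorted child identifiers joined by `+`, unique within
a hierarchy because member sets are disjoint. Edges absorbed between the
two children become `internal_edges` of the supernode and never surface
as self-loops, so they contribute to no degree. An edgeless level still
increments the level counter, keeping the 2^*x* bound and the planner
arithmetic consistent.

## Optimality analysis

OPT — the best compression under "each node merges at most once per
level" — is exactly a maximum-cardinality matching for a single level;
`opt_one_level` delegates to the blossom matching in networkx and an
in-repo exhaustive matcher cross-checks it on small graphs. Across
several levels no polynomial algorithm is known, so `opt_multi_level`
searches all per-level matchings exhaustively with memoization, guarded
to ≤ 10 nodes. The bounds tracked per run: a merge taken while some node
has degree 1 is optimal; any other merge wastes at most one pairing,
giving OPT ≤ min(2·MDS, s + MDS) with *s* the count of steps lacking a
degree-1 node. Because MDS selects a *global* minimum-positive-degree
node, *s* equals the number of steps whose selected node had degree > 1.
The idealized halving estimates (n − Σ n/2^x and its MDS analogue) are
reported as descriptive fields only: substituting an upper bound on the
OPT step count into the MDS size expression is not a logically valid
bound, so the package asserts only the directly provable ones.

The "exhaustive enumeration of small connected digraphs" used by the
bound suites is canonical rather than label-exhaustive (all labeled
digraphs on 6 nodes would number 2³⁰): every connected undirected graph
on 2–6 nodes up to isomorphism (142 graphs, from the networkx atlas) in
three canonical orientations — all-reciprocal, low-to-high, high-to-low —
plus two seeded random orientations per graph, about 700 instances after
deduplication. The bounds are theorems, so enlarging the enumeration can
only re-confirm them; the random orientations guard against orientation-
specific blind spots.

## Base aligner

Subnetworks are node sets whose induced undirected graph is connected,
enumerated exhaustively up to size *k*. Candidate mappings pair a
singleton with a subnetwork (one-to-many); their homology is the mean of
reaction-pair similarities over the cross product of the member sets —
the conservative choice, configurable to `max`. For supernodes the member
sets are the level-0 reactions, so the same similarity matrix drives
every level.

A mapping (R, R̄) supports (Q, Q̄) when Q contains a forward neighbor of
R and Q̄ a forward neighbor of R̄, or both contain backward neighbors
(forward/backward neighborhood of a subnetwork is defined element-wise;
this extends the single-node definition the toy example uses). Each
column splits one unit of support equally over its supported mappings; a
column with none gets self-support 1, keeping the matrix column-
stochastic — a zero column would behave identically after the homology
term but break the normalization invariant. Scores iterate
s ← γ·S s + (1 − γ)·h from s = h with γ = 0.7, tol = 1e-6, max 100
iterations (the combination rule is a documented default of this
implementation; the referenced base method keeps its own). The iteration
preserves the vector sum, so no renormalization drift occurs.

Extraction is greedy by descending score with lexicographic tie-break,
yielding a maximal conflict-free set; an exhaustive maximizer over ≤ 12
candidates serves as a test oracle. Greedy extraction is a heuristic:
on adversarial score vectors it can be suboptimal, but on the small
oracle instances it attains the optimum.

## Refinement and planner

Refinement reuses the top-level *k* and γ for every recursive call (one
parameter set end to end). The similarity passed down is the original
reaction-level matrix; restriction to the block happens implicitly
through the member sets. At recursion depth *c − x* the two sides hold at
most *k*·2^*x* and 2^*x* reactions, asserted at every call. Supernode
members without a partner after a block alignment are dropped, mirroring
the base aligner's partial alignments. Final mapping scores are those of
the deepest (level-0) alignment calls; the compressed-domain result is
retained alongside for evaluation.

`optimal_c` floors its nearest-integer answer at 0 and swaps arguments so
n ≤ m. The compress decision uses the inclusive threshold y ≤ 0.5.

## Evaluation

Accuracy of a compressed run is the Pearson correlation between the
scores of *all* compressed-domain candidate mappings and their
back-projections: the mean of original-domain reaction-pair scores
(singleton–singleton candidates of an uncompressed base run) over the
member cross product, with never-scored pairs contributing 0 — the most
conservative reading. At c = 0 and k = 1 the two vectors coincide and
r = 1 exactly. Degree analytics (exact histograms, hub fraction =
share of nodes with out-degree above a threshold, default 15) and
per-level mean node/edge tables round out the reporting.

## Synthetic generator

`scale_free_network` grows a connected directed graph one node at a time:
with probability 0.5 the new reaction extends the current chain (linear
pathways), otherwise it attaches preferentially with weight
degree^1.5 (superlinear attachment concentrates connectivity into a few
hub nodes, the currency-metabolite signature); a second preferential edge
is added with probability 0.25 and 5% of edges become reciprocal. Edge
orientation is uniform. These defaults produce ensembles in which ~90% of
nodes have total degree ≤ 4 while hubs exceed degree 10 at n = 200, and
one MDS level compresses to ~60% of the original size — the regime the
method targets. The generator does not model stoichiometry, compound
identity, or pathway modularity, so passing trend suites demonstrate
topology-driven behavior, not biochemical fidelity.

Problem sizes in the stochastic suites — 20 pairs of ~40-node networks
for the accuracy trend, 20 networks of 300 nodes for the hub and
compression-rate trends — are chosen so each ensemble exhibits the
phenomenon of interest (out-degrees reaching past the hub threshold,
stable compression-rate means) while the full suite stays interactive.

## Worked-example fixture

The 5- and 4-reaction toy networks are reconstructed from their described
neighborhoods (b's backward neighbor a; forward neighbors c, d; d′
reached from both b′ and c′) and from the refinement walk-through that
decompresses (e,d)–(c′,d′) into d→e and c′→d′. The fixture similarity
(1.0 same-letter, 0.1 otherwise) is a repository convention that makes
the letter-matched reaction-level alignment the unique optimum. Under
this convention the compressed-domain aligner selects c–(c′,d′) over
(d,e)–(c′,d′): both receive identical topological support, and mean
homology favors the former (0.55 vs 0.325). Tests on this toy therefore
assert mapping counts and the doubly supported (a,b)–(a′,b′) mapping, not
the full compressed-domain mapping set, which depends on the (out of
scope) biochemical similarity.

## Known limitations

- Greedy conflict resolution and greedy MDS are heuristics; only the
  documented bounds are guaranteed.
- The multi-level OPT oracle is exponential and guarded at 10 nodes.
- The accuracy statistic needs variance in both score vectors; uniform
  similarity on symmetric instances can make it undefined.
- Compression quality degrades as compression deepens and hubs emerge;
  the planner's closed form assumes perfect halving and constant
  subnetwork density, so treat its suggestion as a starting point.
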