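"""Seeded generators for test networks and similarity matrices.

``scale_free_network`` emulates the degree structure reported for
reaction-based metabolic networks — long pathway chains of low-degree
reactions joined through a few heavily connected hubs — by mixing chain
extension with superlinear preferential attachment.  It does not emulate
stoichiometry, compound sharing, or pathway modularity, so conclusions
drawn from it concern topology-driven behavior only.

``toy_instance`` reconstructs the two small didactic networks used
throughout the worked examples: P with reactions a..e and P-bar with
a'..d'.  The edge sets are inferred from the described neighborhoods
(b's backward neighbor is a; its forward neighbors are c and d; d' has
backward neighbors b' and c') and from the refinement walk-through, which
decompresses the supernode pair (e,d)-(c',d') into the small networks
d -> e and c' -> d'.  The similarity convention (1.0 for same-letter
pairs, 0.1 otherwise) is a fixture choice that makes the letter-matched
alignment the unique reaction-level optimum.
"""

from __future__ import annotations

import random
from typing import Iterable

from .network import NetworkError, ReactionNetwork
from .similarity import DictSimilarity

__all__ = ["scale_free_network", "toy_instance", "random_similarity"]

# Generator defaults.  Reaction networks are dominated by linear pathway
# chains stitched together through a few highly connected currency hubs,
# so each arriving reaction either extends the most recent chain (prob.
# _CHAIN_PROB) or attaches preferentially (superlinear, producing the
# hubs); a second preferential edge (prob. _SECOND_EDGE_PROB) adds the
# cross-links, and a small fraction of edges is reciprocal (reversible
# neighborhood relations).
_CHAIN_PROB = 0.5
_SECOND_EDGE_PROB = 0.25
_RECIPROCAL_PROB = 0.05


def scale_free_network(
    n: int, attachment_exponent: float = 1.5, seed: int = 0
) -> ReactionNetwork:
    """Connected directed network with a heavy-tailed degree distribution.

    Nodes arrive one at a time and either extend the current chain or
    attach to an existing node with probability proportional to
    (total degree)**attachment_exponent; orientation of each new edge is
    uniform.  Pure function of the seed.
    """
    if n < 2:
        raise NetworkError(f"need at least 2 nodes, got {n}")
    rng = random.Random(seed)
    width = len(str(n - 1))
    ids = [f"r{i:0{width}d}" for i in range(n)]
    degree = {ids[0]: 0, ids[1]: 0}
    edges: set[tuple[str, str]] = set()

    def add_edge(u: str, v: str) -> None:
        edges.add((u, v))
        degree[u] = degree.get(u, 0) + 1
        degree[v] = degree.get(v, 0) + 1

    def preferential_choice(pool: list[str]) -> str:
        weights = [degree[v] ** attachment_exponent for v in pool]
        total = sum(weights)
        if total <= 0:
            return pool[rng.randrange(len(pool))]
        pick = rng.random() * total
        acc = 0.0
        for v, w in zip(pool, weights):
            acc += w
            if pick <= acc:
                return v
        return pool[-1]

    first = (ids[0], ids[1]) if rng.random() < 0.5 else (ids[1], ids[0])
    add_edge(*first)
    previous = ids[1]

    for i in range(2, n):
        new = ids[i]
        degree[new] = 0
        existing = ids[:i]
        targets: set[str] = set()
        if rng.random() < _CHAIN_PROB:
            targets.add(previous)
        else:
            targets.add(preferential_choice(existing))
        if rng.random() < _SECOND_EDGE_PROB:
            pool = [v for v in existing if v not in targets]
            if pool:
                targets.add(preferential_choice(pool))
        for t in sorted(targets):
            if rng.random() < 0.5:
                add_edge(new, t)
            else:
                add_edge(t, new)
            if rng.random() < _RECIPROCAL_PROB:
                u, v = (new, t) if (new, t) not in edges else (t, new)
                if (u, v) not in edges:
                    add_edge(u, v)
        previous = new
    return ReactionNetwork(edges=edges, level=0)


def toy_instance() -> tuple[ReactionNetwork, ReactionNetwork, DictSimilarity]:
    """The two 5- and 4-reaction worked-example networks plus similarities."""
    p = ReactionNetwork(
        edges=[("a", "b"), ("b", "c"), ("b", "d"), ("d", "e")], level=0
    )
    pbar = ReactionNetwork(
        edges=[("a'", "b'"), ("b'", "c'"), ("b'", "d'"), ("c'", "d'")], level=0
    )
    table = {}
    for u in sorted(p.nodes):
        for v in sorted(pbar.nodes):
            table[(u, v)] = 1.0 if v == u + "'" else 0.1
    return p, pbar, DictSimilarity(table)


def random_similarity(
    ids_left: Iterable[str], ids_right: Iterable[str], seed: int = 0
) -> DictSimilarity:
    """Uniform [0, 1] similarities per pair; symmetric in identifier order."""
    rng = random.Random(seed)
    table = {}
    for a in sorted(set(ids_left)):
        for b in sorted(set(ids_right)):
            table[(a, b)] = rng.random()
    return DictSimilarity(table)
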