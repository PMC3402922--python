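"""Optimality oracles and bounds for MDS compression.

``OPT`` is the hypothetical best compression under the rule that each
non-compressed node merges with at most one other per level.  One level of
OPT is therefore exactly a maximum-cardinality matching of the underlying
undirected graph; over several levels no polynomial characterization is
known, so the multi-level oracle is an exhaustive search guarded by a hard
size limit.  The bounds follow the structure: a step taken when a degree-1
node exists is optimal, any other step wastes at most one merge, hence

    OPT <= min(2 * MDS, s + MDS)

where ``s`` counts the MDS steps taken with no degree-1 node available.
Connected components are handled by decomposition and summation.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import networkx as nx

from .network import CompressionHierarchy, NetworkError, ReactionNetwork

__all__ = [
    "opt_one_level",
    "opt_one_level_exhaustive",
    "opt_multi_level",
    "OptimalityReport",
    "optimality_report",
    "size_ratio",
    "enumerate_connected_digraphs",
]

_EXHAUSTIVE_MAX_NODES = 12
_MULTI_LEVEL_MAX_NODES = 10


def opt_one_level(net: ReactionNetwork) -> int:
    """Maximum number of merges achievable in one compression level.

    Equals the size of a maximum-cardinality matching of the underlying
    undirected simple graph.
    """
    matching = nx.max_weight_matching(net.undirected(), maxcardinality=True)
    return len(matching)


def _all_matchings(edges: list[tuple[str, str]]):
    """Yield every matching (as a tuple of edges) of the given edge list."""

    def rec(i: int, used: set[str], chosen: list[tuple[str, str]]):
        yield tuple(chosen)
        for j in range(i, len(edges)):
            u, v = edges[j]
            if u in used or v in used:
                continue
            chosen.append(edges[j])
            yield from rec(j + 1, used | {u, v}, chosen)
            chosen.pop()

    yield from rec(0, set(), [])


def _undirected_edges(net: ReactionNetwork) -> list[tuple[str, str]]:
    return sorted({tuple(sorted((u, v))) for u, v in net.edges})


def opt_one_level_exhaustive(net: ReactionNetwork) -> int:
    """Brute-force maximum matching; cross-check oracle for small graphs."""
    if net.n_nodes > _EXHAUSTIVE_MAX_NODES:
        raise NetworkError(
            f"exhaustive one-level OPT limited to {_EXHAUSTIVE_MAX_NODES} nodes"
        )
    return max(len(m) for m in _all_matchings(_undirected_edges(net)))


def opt_multi_level(net: ReactionNetwork, c: int) -> int:
    """Exact maximum total merges over ``c`` levels (exhaustive search)."""
    if net.n_nodes > _MULTI_LEVEL_MAX_NODES:
        raise NetworkError(
            f"multi-level OPT search limited to {_MULTI_LEVEL_MAX_NODES} nodes"
        )
    if c < 0:
        raise NetworkError("compression level must be non-negative")

    memo: dict = {}

    def best(edges: frozenset[tuple[str, str]], levels: int) -> int:
        if levels == 0 or not edges:
            return 0
        key = (edges, levels)
        if key in memo:
            return memo[key]
        edge_list = sorted(edges)
        result = 0
        for matching in _all_matchings(edge_list):
            merged = len(matching)
            if merged == 0:
                continue
            # Contract matched pairs; supernode label = joined constituents.
            label = {}
            for u, v in matching:
                label[u] = label[v] = "+".join(sorted((u, v)))
            contracted = set()
            for u, v in edge_list:
                cu, cv = label.get(u, u), label.get(v, v)
                if cu != cv:
                    contracted.add(tuple(sorted((cu, cv))))
            result = max(result, merged + best(frozenset(contracted), levels - 1))
        memo[key] = result
        return result

    return best(frozenset(_undirected_edges(net)), c)


@dataclass
class OptimalityReport:
    """Theorem-style bookkeeping for one MDS run.

    ``eq3_*`` fields are the closed-form size estimates derived from the
    idealized n/2^x halving assumption; they are descriptive only (the
    second one is not a provable bound), unlike the combined bound.
    """

    mds_steps: int
    opt_steps: int | None
    s: int
    bound_2mds: int
    bound_s_plus: int
    combined_bound: int
    n_mds: int
    n_opt_lower: int
    eq3_n_opt_estimate: float
    eq3_n_mds_estimate: float


def optimality_report(
    h: CompressionHierarchy, exact_opt: int | None = None
) -> OptimalityReport:
    """Summarize MDS merges, the s statistic, and the optimality bounds."""
    h.validate()
    n = h.levels[0].n_nodes
    mds_steps = len(h.steps)
    s = sum(1 for step in h.steps if not step.degree_one_available)
    bound_2mds = 2 * mds_steps
    bound_s_plus = s + mds_steps
    combined = min(bound_2mds, bound_s_plus)
    if exact_opt is not None and not mds_steps <= exact_opt <= combined:
        raise NetworkError(
            f"exact OPT {exact_opt} outside [{mds_steps}, {combined}]; "
            "hierarchy and oracle disagree"
        )
    c = h.c
    halving = sum(n / 2**x for x in range(1, c + 1))
    return OptimalityReport(
        mds_steps=mds_steps,
        opt_steps=exact_opt,
        s=s,
        bound_2mds=bound_2mds,
        bound_s_plus=bound_s_plus,
        combined_bound=combined,
        n_mds=h.levels[-1].n_nodes,
        n_opt_lower=n - combined,
        eq3_n_opt_estimate=n - halving,
        eq3_n_mds_estimate=n - halving / 2,
    )


def size_ratio(h: CompressionHierarchy, exact_opt_steps: int) -> float:
    """Compressed-size ratio n_MDS / n_OPT (at most 1.5 for one level)."""
    n = h.levels[0].n_nodes
    n_mds = n - len(h.steps)
    n_opt = n - exact_opt_steps
    if n_opt <= 0:
        raise NetworkError("optimal compressed size is zero; ratio undefined")
    return n_mds / n_opt


def enumerate_connected_digraphs(
    max_nodes: int = 6, random_orientations: int = 2, seed: int = 0
):
    """Yield a canonical enumeration of small connected directed graphs.

    Every connected undirected graph on 2..max_nodes nodes (exhaustive up
    to isomorphism, from the networkx graph atlas; max_nodes <= 7) is
    emitted under three canonical orientations — all edges reciprocal, all
    oriented low-to-high label, all high-to-low — plus ``random_orientations``
    seeded assignments where each edge is independently forward, backward
    or reciprocal.
    """
    if not 2 <= max_nodes <= 7:
        raise NetworkError("atlas enumeration covers 2..7 nodes")
    rng = random.Random(seed)
    for g in nx.graph_atlas_g():
        n = g.number_of_nodes()
        if not 2 <= n <= max_nodes or not nx.is_connected(g):
            continue
        und = [tuple(sorted((f"v{u}", f"v{v}"))) for u, v in g.edges()]
        und.sort()
        variants: list[list[tuple[str, str]]] = [
            [e for uv in und for e in (uv, (uv[1], uv[0]))],  # reciprocal
            [uv for uv in und],  # low -> high
            [(v, u) for u, v in und],  # high -> low
        ]
        for _ in range(random_orientations):
            edges: list[tuple[str, str]] = []
            for u, v in und:
                mode = rng.randrange(3)
                if mode == 0:
                    edges.append((u, v))
                elif mode == 1:
                    edges.append((v, u))
                else:
                    edges.extend([(u, v), (v, u)])
            variants.append(edges)
        seen: set[frozenset] = set()
        for edges in variants:
            key = frozenset(edges)
            if key in seen:
                continue
            seen.add(key)
            yield ReactionNetwork(edges=edges, level=0)
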