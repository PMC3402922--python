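"""Minimum degree selection (MDS) compression.

One *level* of compression repeatedly takes the non-compressed node with the
smallest positive *active* degree (degree counted only towards other
non-compressed nodes), merges it with one of its non-compressed neighbors
into a supernode, and marks both constituents compressed for the rest of the
level.  The level ends when every non-compressed node has active degree 0.
Applying the pass ``c`` times yields supernodes containing between 1 and
``2**c`` reactions, so the compressed topology stays close to the original.

Tie-breaking (the deterministic variant): among minimum-positive-degree
nodes pick the lexicographically smallest identifier, and among its
non-compressed neighbors again the lexicographically smallest.  The
randomized variant replaces only the first choice by a seeded uniform draw
from the minimum-degree set; compressed sizes are empirically insensitive
to this choice.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .network import (
    CompressionHierarchy,
    MergeStep,
    NetworkError,
    ReactionNetwork,
    Supernode,
)

__all__ = [
    "active_degree",
    "LevelState",
    "mds_step",
    "mds_level",
    "mds_compress",
    "mds_compress_randomized",
    "decompress_block",
]

Selector = Callable[[Sequence[str]], str]


def _first(candidates: Sequence[str]) -> str:
    return candidates[0]


def active_degree(net: ReactionNetwork, node: str, compressed: set[str]) -> int:
    """In- plus out-degree of ``node`` counting only non-compressed endpoints.

    A reciprocal neighbor contributes one per edge (deg = indeg + outdeg).
    """
    net._require(node)
    deg = 0
    for u, v in net.edges:
        if u == node and v not in compressed:
            deg += 1
        elif v == node and u not in compressed:
            deg += 1
    return deg


@dataclass
class LevelState:
    """Mutable state of one compression level (the intermediate P_i^x)."""

    level: int  # level being produced (input network is level - 1)
    succ: dict[str, set[str]]
    pred: dict[str, set[str]]
    members: dict[str, frozenset[str]]
    compressed: set[str] = field(default_factory=set)
    supernodes: dict[str, Supernode] = field(default_factory=dict)
    steps: list[MergeStep] = field(default_factory=list)

    @classmethod
    def from_network(cls, net: ReactionNetwork) -> "LevelState":
        succ = {v: set(net.successors(v)) for v in net.nodes}
        pred = {v: set(net.predecessors(v)) for v in net.nodes}
        return cls(
            level=net.level + 1,
            succ=succ,
            pred=pred,
            members=dict(net.members),
        )

    def degree(self, node: str) -> int:
        return sum(1 for v in self.succ[node] if v not in self.compressed) + sum(
            1 for v in self.pred[node] if v not in self.compressed
        )

    def active_nodes(self) -> list[tuple[int, str]]:
        """(degree, node) for non-compressed nodes with positive active degree."""
        out = []
        for v in self.succ:
            if v in self.compressed:
                continue
            d = self.degree(v)
            if d > 0:
                out.append((d, v))
        return out


def mds_step(state: LevelState, selector: Selector = _first) -> LevelState:
    """Perform one compression step in place and return the state.

    Merges the selected minimum-positive-degree node with its first
    non-compressed neighbor; node count drops by exactly 1 and edge count
    by at least 1 (the internal edge(s) are absorbed into the supernode).
    """
    active = state.active_nodes()
    if not active:
        raise NetworkError("no non-compressed node with positive degree")
    min_deg = min(d for d, _ in active)
    candidates = sorted(v for d, v in active if d == min_deg)
    v_a = selector(candidates)
    nbrs = sorted(
        v
        for v in (state.succ[v_a] | state.pred[v_a])
        if v not in state.compressed
    )
    v_b = nbrs[0]

    internal = set()
    if v_b in state.succ[v_a]:
        internal.add((v_a, v_b))
    if v_a in state.succ[v_b]:
        internal.add((v_b, v_a))

    children = tuple(sorted((v_a, v_b)))
    new_id = "+".join(children)
    members = state.members[v_a] | state.members[v_b]
    sn = Supernode(
        id=new_id,
        level=state.level,
        children=children,
        members=frozenset(members),
        internal_edges=frozenset(internal),
    )

    # Re-attach external edges to the supernode with deduplication.
    new_succ = (state.succ[v_a] | state.succ[v_b]) - {v_a, v_b}
    new_pred = (state.pred[v_a] | state.pred[v_b]) - {v_a, v_b}
    for old in (v_a, v_b):
        for w in state.succ[old]:
            if w not in (v_a, v_b):
                state.pred[w].discard(old)
        for w in state.pred[old]:
            if w not in (v_a, v_b):
                state.succ[w].discard(old)
    for old in (v_a, v_b):
        del state.succ[old], state.pred[old], state.members[old]
    state.succ[new_id] = new_succ
    state.pred[new_id] = new_pred
    for w in new_succ:
        state.pred[w].add(new_id)
    for w in new_pred:
        state.succ[w].add(new_id)
    state.members[new_id] = frozenset(members)
    state.compressed.add(new_id)
    state.supernodes[new_id] = sn
    state.steps.append(
        MergeStep(
            level=state.level,
            selected=v_a,
            neighbor=v_b,
            supernode=new_id,
            degree_one_available=(min_deg == 1),
        )
    )
    return state


def mds_level(
    net: ReactionNetwork, selector: Selector = _first
) -> tuple[ReactionNetwork, list[MergeStep], dict[str, Supernode]]:
    """Run MDS steps until no non-compressed node has positive degree.

    Returns the level-(x+1) network, the merge log, and the supernode
    records (carried-over singletons included, with a single child).
    """
    state = LevelState.from_network(net)
    while state.active_nodes():
        mds_step(state, selector)

    # Carried-over singletons keep their identifier and gain a 1-child record.
    for v in list(state.succ):
        if v not in state.compressed:
            state.supernodes[v] = Supernode(
                id=v,
                level=state.level,
                children=(v,),
                members=state.members[v],
            )

    edges = {(u, w) for u, targets in state.succ.items() for w in targets}
    out = ReactionNetwork(
        edges=edges,
        nodes=state.succ.keys(),
        level=state.level,
        members=state.members,
    )
    return out, state.steps, state.supernodes


def mds_compress(
    net: ReactionNetwork, c: int, selector: Selector = _first
) -> CompressionHierarchy:
    """Compress ``net`` for ``c`` levels; ``c = 0`` returns the input alone."""
    if not isinstance(c, int) or c < 0:
        raise NetworkError(f"compression level must be a non-negative integer, got {c}")
    h = CompressionHierarchy(levels=[net])
    current = net
    for _ in range(c):
        current, steps, supernodes = mds_level(current, selector)
        h.levels.append(current)
        h.steps.extend(steps)
        for sn in supernodes.values():
            h.supernodes[(sn.level, sn.id)] = sn
    return h


def mds_compress_randomized(
    net: ReactionNetwork, c: int, seed: int
) -> CompressionHierarchy:
    """MDS with the minimum-degree node drawn uniformly (seeded) from ties."""
    rng = random.Random(seed)

    def selector(candidates: Sequence[str]) -> str:
        return candidates[rng.randrange(len(candidates))]

    return mds_compress(net, c, selector)


def decompress_block(
    h: CompressionHierarchy, level: int, node_ids: Iterable[str]
) -> ReactionNetwork:
    """Expand the given level-``level`` nodes one level down.

    Returns the level-(level-1) network induced by their children: the
    internal edge(s) of each supernode plus the level-(level-1) edges
    between children of different listed nodes.
    """
    if level < 1:
        raise NetworkError("cannot decompress below level 0")
    net = h.network(level)
    below = h.network(level - 1)
    children: set[str] = set()
    for node_id in node_ids:
        if node_id not in net.nodes:
            raise KeyError(f"no node {node_id!r} at level {level}")
        children.update(h.children_of(level, node_id))
    edges = {(u, v) for (u, v) in below.edges if u in children and v in children}
    return ReactionNetwork(
        edges=edges,
        nodes=children,
        level=level - 1,
        members={v: below.members[v] for v in children},
    )
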