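"""Reaction-network data model and serialization.

A metabolic network is modelled as a directed simple graph ``P = (V, E)``
whose nodes are reactions: an edge ``r_i -> r_j`` means at least one output
compound of ``r_i`` is an input of ``r_j``.  Multilevel compression replaces
connected node pairs by *supernodes*; a network at compression level ``x``
carries, for each node, the set of level-0 reactions it contains (between 1
and ``2**x`` of them).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "ReactionNetwork",
    "Supernode",
    "MergeStep",
    "CompressionHierarchy",
    "read_edge_list",
    "write_edge_list",
    "read_hierarchy",
    "write_hierarchy",
    "NetworkError",
]

HIERARCHY_SCHEMA_VERSION = 1


class NetworkError(ValueError):
    """Invalid network, hierarchy or input file."""


class ReactionNetwork:
    """Directed simple graph of reaction (or supernode) identifiers.

    Parameters
    ----------
    edges : iterable of (source, target) identifier pairs
    nodes : optional iterable of extra (possibly isolated) identifiers
    level : compression level of this network (0 = original domain)
    members : optional mapping node id -> set of level-0 reaction ids it
        contains.  Defaults to the identity (each node contains itself),
        which is the correct reading at level 0.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]] = (),
        nodes: Iterable[str] = (),
        level: int = 0,
        members: Mapping[str, Iterable[str]] | None = None,
    ):
        if level < 0:
            raise NetworkError(f"negative compression level: {level}")
        self.level = int(level)
        self.edges: set[tuple[str, str]] = set()
        self.nodes: set[str] = set(nodes)
        for edge in edges:
            u, v = edge
            if u == v:
                raise NetworkError(f"self-loop on node {u!r} is not allowed")
            self.edges.add((u, v))
            self.nodes.add(u)
            self.nodes.add(v)
        if members is None:
            self.members = {v: frozenset([v]) for v in self.nodes}
        else:
            self.members = {v: frozenset(members[v]) for v in self.nodes}
        bound = 2**self.level
        for v, mem in self.members.items():
            if not 1 <= len(mem) <= bound:
                raise NetworkError(
                    f"node {v!r} contains {len(mem)} reactions; "
                    f"allowed range at level {self.level} is [1, {bound}]"
                )
        self._succ: dict[str, set[str]] | None = None
        self._pred: dict[str, set[str]] | None = None

    # -- adjacency ---------------------------------------------------------

    def _build_adjacency(self) -> None:
        succ: dict[str, set[str]] = {v: set() for v in self.nodes}
        pred: dict[str, set[str]] = {v: set() for v in self.nodes}
        for u, v in self.edges:
            succ[u].add(v)
            pred[v].add(u)
        self._succ, self._pred = succ, pred

    def successors(self, node: str) -> set[str]:
        if self._succ is None:
            self._build_adjacency()
        self._require(node)
        return self._succ[node]

    def predecessors(self, node: str) -> set[str]:
        if self._pred is None:
            self._build_adjacency()
        self._require(node)
        return self._pred[node]

    def neighbors(self, node: str) -> set[str]:
        return self.successors(node) | self.predecessors(node)

    def _require(self, node: str) -> None:
        if node not in self.nodes:
            raise KeyError(f"unknown node {node!r}")

    # -- conveniences ------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def member_set(self, node: str) -> frozenset[str]:
        self._require(node)
        return self.members[node]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def undirected(self) -> nx.Graph:
        """Underlying undirected simple graph (reciprocal edges collapse)."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReactionNetwork):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.edges == other.edges
            and self.level == other.level
            and self.members == other.members
        )

    def __hash__(self):  # pragma: no cover - identity hashing is enough
        return id(self)

    def __repr__(self) -> str:
        return (
            f"ReactionNetwork(level={self.level}, nodes={self.n_nodes}, "
            f"edges={self.n_edges})"
        )


@dataclass(frozen=True)
class Supernode:
    """A node of a compressed network.

    ``children`` are the one or two constituent nodes at ``level - 1``;
    ``members`` is the flattened set of level-0 reactions;
    ``internal_edges`` are the level-(level-1) edges between the two
    children that were absorbed when the supernode was formed.
    """

    id: str
    level: int
    children: tuple[str, ...]
    members: frozenset[str]
    internal_edges: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self):
        if self.level < 1:
            raise NetworkError("supernodes exist only at level >= 1")
        if len(self.children) not in (1, 2):
            raise NetworkError(
                f"supernode {self.id!r} must have 1 or 2 children, "
                f"got {len(self.children)}"
            )
        if not 1 <= len(self.members) <= 2**self.level:
            raise NetworkError(
                f"supernode {self.id!r} at level {self.level} contains "
                f"{len(self.members)} reactions; allowed [1, {2 ** self.level}]"
            )


@dataclass(frozen=True)
class MergeStep:
    """One MDS compression step: minimum-degree node merged with a neighbor.

    ``degree_one_available`` records whether a non-compressed node with
    active degree exactly 1 existed when the step was taken; steps where it
    did not contribute to the optimality statistic ``s``.
    """

    level: int
    selected: str
    neighbor: str
    supernode: str
    degree_one_available: bool


@dataclass
class CompressionHierarchy:
    """Per-level networks P^0 .. P^c with supernode membership and merge log."""

    levels: list[ReactionNetwork]
    supernodes: dict[tuple[int, str], Supernode] = field(default_factory=dict)
    steps: list[MergeStep] = field(default_factory=list)

    @property
    def c(self) -> int:
        return len(self.levels) - 1

    def network(self, level: int) -> ReactionNetwork:
        if not 0 <= level <= self.c:
            raise KeyError(f"level {level} not in hierarchy (0..{self.c})")
        return self.levels[level]

    def members_of(self, level: int, node_id: str) -> frozenset[str]:
        """Level-0 reaction set contained in node ``node_id`` of level ``level``."""
        net = self.network(level)
        if node_id not in net.nodes:
            raise KeyError(f"no node {node_id!r} at level {level}")
        return net.members[node_id]

    def children_of(self, level: int, node_id: str) -> tuple[str, ...]:
        """Constituent level-(level-1) node(s) of a level-``level`` node."""
        if level < 1:
            raise KeyError("level-0 nodes have no children")
        sn = self.supernodes.get((level, node_id))
        if sn is None:
            raise KeyError(f"no supernode record for {node_id!r} at level {level}")
        return sn.children

    def validate(self) -> None:
        base = self.levels[0].nodes
        for x, net in enumerate(self.levels):
            if net.level != x:
                raise NetworkError(f"level {x} network labelled level {net.level}")
            flat: list[str] = []
            for v in net.nodes:
                flat.extend(net.members[v])
            if len(flat) != len(base) or set(flat) != base:
                raise NetworkError(
                    f"members at level {x} do not partition the level-0 node set"
                )
        for x in range(1, self.c + 1):
            n_steps = sum(1 for s in self.steps if s.level == x)
            if self.levels[x].n_nodes != self.levels[x - 1].n_nodes - n_steps:
                raise NetworkError(
                    f"node count at level {x} inconsistent with merge log"
                )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "version": HIERARCHY_SCHEMA_VERSION,
            "levels": [
                {
                    "level": net.level,
                    "nodes": sorted(net.nodes),
                    "edges": sorted(map(list, net.edges)),
                    "members": {v: sorted(net.members[v]) for v in sorted(net.nodes)},
                }
                for net in self.levels
            ],
            "supernodes": [
                {
                    "id": sn.id,
                    "level": sn.level,
                    "children": list(sn.children),
                    "members": sorted(sn.members),
                    "internal_edges": sorted(map(list, sn.internal_edges)),
                }
                for (_, _), sn in sorted(self.supernodes.items())
            ],
            "steps": [
                {
                    "level": s.level,
                    "selected": s.selected,
                    "neighbor": s.neighbor,
                    "supernode": s.supernode,
                    "degree_one_available": s.degree_one_available,
                }
                for s in self.steps
            ],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "CompressionHierarchy":
        version = doc.get("version")
        if version != HIERARCHY_SCHEMA_VERSION:
            raise NetworkError(
                f"unsupported hierarchy schema version {version!r} "
                f"(expected {HIERARCHY_SCHEMA_VERSION})"
            )
        levels = [
            ReactionNetwork(
                edges=[tuple(e) for e in entry["edges"]],
                nodes=entry["nodes"],
                level=entry["level"],
                members=entry["members"],
            )
            for entry in sorted(doc["levels"], key=lambda d: d["level"])
        ]
        supernodes = {}
        for entry in doc.get("supernodes", []):
            sn = Supernode(
                id=entry["id"],
                level=entry["level"],
                children=tuple(entry["children"]),
                members=frozenset(entry["members"]),
                internal_edges=frozenset(tuple(e) for e in entry["internal_edges"]),
            )
            supernodes[(sn.level, sn.id)] = sn
        steps = [
            MergeStep(
                level=entry["level"],
                selected=entry["selected"],
                neighbor=entry["neighbor"],
                supernode=entry["supernode"],
                degree_one_available=entry["degree_one_available"],
            )
            for entry in doc.get("steps", [])
        ]
        h = cls(levels=levels, supernodes=supernodes, steps=steps)
        h.validate()
        return h


def read_edge_list(path: str | Path) -> ReactionNetwork:
    """Read a level-0 network from a TSV edge list.

    Each non-comment, non-blank line holds two whitespace-separated
    reaction identifiers (source, target).  Duplicate edges collapse;
    self-loops are rejected.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise NetworkError(
                    f"{path}:{lineno}: expected two identifiers, got {len(parts)}"
                )
            u, v = parts
            if u == v:
                raise NetworkError(f"{path}:{lineno}: self-loop on {u!r}")
            edges.append((u, v))
    return ReactionNetwork(edges=edges, level=0)


def write_edge_list(net: ReactionNetwork, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# source_id\ttarget_id\n")
        for u, v in sorted(net.edges):
            fh.write(f"{u}\t{v}\n")
        # isolated nodes cannot be expressed in an edge list; none expected
        isolated = net.nodes - {u for u, _ in net.edges} - {v for _, v in net.edges}
        for v in sorted(isolated):
            fh.write(f"# isolated\t{v}\n")


def write_hierarchy(h: CompressionHierarchy, path: str | Path) -> None:
    Path(path).write_text(json.dumps(h.to_dict(), indent=1))


def read_hierarchy(path: str | Path) -> CompressionHierarchy:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise NetworkError(f"{path}: not valid hierarchy JSON: {exc}") from exc
    return CompressionHierarchy.from_dict(doc)
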