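"""Reference base aligner in the style of SubMAP.

Given two reaction networks and a bound ``k``, the aligner

1. enumerates every connected subnetwork of size at most ``k`` on each side;
2. forms candidate mappings pairing a single node on one side with a
   subnetwork on the other (the one-to-many constraint), each scored by a
   homology term from the reaction-pair similarities;
3. builds the column-stochastic *support matrix*: a mapping distributes one
   unit of support equally among the candidate mappings of its forward and
   backward neighbors;
4. iterates  s <- gamma * S s + (1 - gamma) * h  to a fixed point, blending
   topological support with homology;
5. greedily extracts a maximal conflict-free set of mappings (each node of
   either network in at most one mapping).

The aligner never looks at supernode internals, so it runs unchanged on
compressed networks whose nodes carry multi-reaction member sets — only the
homology term (a mean over member reaction pairs) knows about members.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .network import NetworkError, ReactionNetwork
from .similarity import Similarity, UniformSimilarity, subnetwork_similarity

__all__ = [
    "Subnetwork",
    "CandidateMapping",
    "SupportMatrix",
    "ScoredMapping",
    "AlignmentResult",
    "AlignParams",
    "enumerate_subnetworks",
    "candidate_mappings",
    "build_support",
    "iterate_scores",
    "extract_alignment",
    "extract_alignment_bruteforce",
    "align",
]


@dataclass(frozen=True)
class Subnetwork:
    """Connected node set of size <= k on one side of the alignment."""

    side: str  # "first" or "second"
    nodes: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "nodes", tuple(sorted(self.nodes)))

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass(frozen=True)
class CandidateMapping:
    left: Subnetwork
    right: Subnetwork
    homology: float

    @property
    def key(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        return (self.left.nodes, self.right.nodes)

    def __post_init__(self):
        if min(len(self.left), len(self.right)) != 1:
            raise NetworkError(
                "one side of a candidate mapping must be a single node"
            )


@dataclass
class SupportMatrix:
    """Column-stochastic topological-support matrix over candidate mappings."""

    matrix: sp.csr_matrix
    candidates: list[CandidateMapping]

    @property
    def dimension(self) -> int:
        return len(self.candidates)

    @property
    def memory_estimate(self) -> int:
        """Dense entry count |candidates|^2 (the base method's bottleneck)."""
        return self.dimension**2


@dataclass(frozen=True)
class ScoredMapping:
    left: tuple[str, ...]
    right: tuple[str, ...]
    score: float


@dataclass
class AlignmentResult:
    """Conflict-free mapping set plus the full scored candidate list."""

    mappings: list[ScoredMapping]
    candidates: list[CandidateMapping] = field(default_factory=list)
    scores: np.ndarray = field(default_factory=lambda: np.zeros(0))
    support_dimension: int = 0

    @property
    def left_cover(self) -> dict[str, int]:
        cover = {}
        for i, m in enumerate(self.mappings):
            for v in m.left:
                cover[v] = i
        return cover

    @property
    def right_cover(self) -> dict[str, int]:
        cover = {}
        for i, m in enumerate(self.mappings):
            for v in m.right:
                cover[v] = i
        return cover

    def candidate_scores(self) -> dict[tuple, float]:
        return {c.key: float(s) for c, s in zip(self.candidates, self.scores)}


@dataclass(frozen=True)
class AlignParams:
    gamma: float = 0.7
    tol: float = 1e-6
    max_iter: int = 100
    homology_mode: str = "mean"

    def __post_init__(self):
        if not 0.0 <= self.gamma < 1.0:
            raise NetworkError("gamma must satisfy 0 <= gamma < 1")


def enumerate_subnetworks(
    net: ReactionNetwork, k: int, side: str = "first"
) -> list[Subnetwork]:
    """All connected node sets of size at most ``k``, in deterministic order.

    Connectivity is in the induced *undirected* graph.
    """
    if k < 1:
        raise NetworkError(f"subnetwork size bound must be >= 1, got {k}")
    found: set[frozenset[str]] = set()

    def grow(current: frozenset[str]) -> None:
        if current in found:
            return
        found.add(current)
        if len(current) == k:
            return
        frontier = set()
        for v in current:
            frontier |= net.neighbors(v)
        for u in frontier - current:
            grow(current | {u})

    for v in net.nodes:
        grow(frozenset([v]))
    ordered = sorted(found, key=lambda s: (len(s), tuple(sorted(s))))
    return [Subnetwork(side=side, nodes=tuple(s)) for s in ordered]


def candidate_mappings(
    subs_left: Sequence[Subnetwork],
    subs_right: Sequence[Subnetwork],
    sim: Similarity,
    net_left: ReactionNetwork | None = None,
    net_right: ReactionNetwork | None = None,
    homology_mode: str = "mean",
) -> list[CandidateMapping]:
    """All subnetwork pairs with a singleton on at least one side.

    Homology of a pair is the mean (or max) of the reaction-pair
    similarities over the cross product of the level-0 member sets; the
    networks supply the member sets when their nodes are supernodes.
    """

    def reaction_members(sub: Subnetwork, net: ReactionNetwork | None) -> list[str]:
        if net is None:
            return list(sub.nodes)
        out: list[str] = []
        for v in sub.nodes:
            out.extend(net.member_set(v))
        return out

    cands = []
    for left in subs_left:
        for right in subs_right:
            if min(len(left), len(right)) != 1:
                continue
            h = subnetwork_similarity(
                reaction_members(left, net_left),
                reaction_members(right, net_right),
                sim,
                mode=homology_mode,
            )
            cands.append(CandidateMapping(left=left, right=right, homology=h))
    cands.sort(key=lambda c: c.key)
    return cands


def _neighbor_sets(net: ReactionNetwork, subs: Sequence[Subnetwork]):
    """Forward/backward neighbor nodes of each subnetwork, and a node index."""
    containing: dict[str, set[int]] = {v: set() for v in net.nodes}
    for i, sub in enumerate(subs):
        for v in sub.nodes:
            containing[v].add(i)
    fwd, bwd = [], []
    for sub in subs:
        inside = set(sub.nodes)
        f, b = set(), set()
        for v in sub.nodes:
            f |= net.successors(v) - inside
            b |= net.predecessors(v) - inside
        # subnetwork indices containing at least one forward/backward node
        fwd.append({i for u in f for i in containing[u]})
        bwd.append({i for u in b for i in containing[u]})
    return fwd, bwd


def build_support(
    cands: Sequence[CandidateMapping],
    net_left: ReactionNetwork,
    net_right: ReactionNetwork,
) -> SupportMatrix:
    """Build the column-stochastic support matrix over the candidate list.

    Mapping (R, R') supports (Q, Q') iff Q is a forward-neighbor
    subnetwork of R and Q' one of R', or both are backward neighbors; each
    column distributes 1/d to its d supported mappings, and a column with
    no neighbor mapping gets self-support 1 to stay stochastic.
    """
    if not cands:
        raise NetworkError("candidate list is empty")
    subs_left = sorted({c.left for c in cands}, key=lambda s: (len(s), s.nodes))
    subs_right = sorted({c.right for c in cands}, key=lambda s: (len(s), s.nodes))
    li = {s: i for i, s in enumerate(subs_left)}
    ri = {s: i for i, s in enumerate(subs_right)}
    fwd_l, bwd_l = _neighbor_sets(net_left, subs_left)
    fwd_r, bwd_r = _neighbor_sets(net_right, subs_right)
    index = {(li[c.left], ri[c.right]): j for j, c in enumerate(cands)}

    rows, cols, vals = [], [], []
    for j, cand in enumerate(cands):
        a, b = li[cand.left], ri[cand.right]
        supported = set()
        for qa in fwd_l[a]:
            for qb in fwd_r[b]:
                idx = index.get((qa, qb))
                if idx is not None:
                    supported.add(idx)
        for qa in bwd_l[a]:
            for qb in bwd_r[b]:
                idx = index.get((qa, qb))
                if idx is not None:
                    supported.add(idx)
        if supported:
            w = 1.0 / len(supported)
            for i in supported:
                rows.append(i)
                cols.append(j)
                vals.append(w)
        else:
            rows.append(j)
            cols.append(j)
            vals.append(1.0)
    n = len(cands)
    matrix = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return SupportMatrix(matrix=matrix, candidates=list(cands))


def iterate_scores(
    support: SupportMatrix,
    homology: np.ndarray,
    gamma: float = 0.7,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> np.ndarray:
    """Fixed point of s <- gamma * S s + (1-gamma) * h, starting from s = h.

    ``h`` is normalized to sum 1 (uniform if identically zero); the result
    is renormalized to sum 1.
    """
    if not 0.0 <= gamma < 1.0:
        raise NetworkError("gamma must satisfy 0 <= gamma < 1")
    h = np.asarray(homology, dtype=float)
    if h.shape != (support.dimension,):
        raise NetworkError("homology vector does not match candidate count")
    total = h.sum()
    h = h / total if total > 0 else np.full_like(h, 1.0 / len(h))
    s = h.copy()
    for _ in range(max_iter):
        s_new = gamma * (support.matrix @ s) + (1.0 - gamma) * h
        if not np.all(np.isfinite(s_new)):
            raise FloatingPointError("non-finite values in score iteration")
        delta = np.max(np.abs(s_new - s))
        s = s_new
        if delta < tol:
            break
    total = s.sum()
    return s / total if total > 0 else s


def extract_alignment(
    cands: Sequence[CandidateMapping],
    scores: np.ndarray,
    support_dimension: int | None = None,
) -> AlignmentResult:
    """Greedy conflict-free extraction in descending score order.

    Ties break lexicographically on the mapping key.  The result is
    maximal: every unselected candidate conflicts with a selected one.
    """
    order = sorted(range(len(cands)), key=lambda j: (-scores[j], cands[j].key))
    used_left: set[str] = set()
    used_right: set[str] = set()
    selected: list[ScoredMapping] = []
    for j in order:
        c = cands[j]
        if used_left.isdisjoint(c.left.nodes) and used_right.isdisjoint(c.right.nodes):
            selected.append(
                ScoredMapping(
                    left=c.left.nodes, right=c.right.nodes, score=float(scores[j])
                )
            )
            used_left.update(c.left.nodes)
            used_right.update(c.right.nodes)
    return AlignmentResult(
        mappings=selected,
        candidates=list(cands),
        scores=np.asarray(scores, dtype=float),
        support_dimension=(
            len(cands) if support_dimension is None else support_dimension
        ),
    )


def extract_alignment_bruteforce(
    cands: Sequence[CandidateMapping], scores: np.ndarray
) -> AlignmentResult:
    """Exhaustive maximum-total-score conflict-free selection (test oracle)."""
    if len(cands) > 12:
        raise NetworkError("brute-force extraction limited to 12 candidates")

    best: tuple[float, list[int]] = (-1.0, [])

    def rec(j: int, used_l: set, used_r: set, chosen: list[int], total: float):
        nonlocal best
        if total > best[0]:
            best = (total, list(chosen))
        if j == len(cands):
            return
        rec(j + 1, used_l, used_r, chosen, total)
        c = cands[j]
        if used_l.isdisjoint(c.left.nodes) and used_r.isdisjoint(c.right.nodes):
            chosen.append(j)
            rec(
                j + 1,
                used_l | set(c.left.nodes),
                used_r | set(c.right.nodes),
                chosen,
                total + float(scores[j]),
            )
            chosen.pop()

    rec(0, set(), set(), [], 0.0)
    selected = [
        ScoredMapping(
            left=cands[j].left.nodes,
            right=cands[j].right.nodes,
            score=float(scores[j]),
        )
        for j in sorted(best[1], key=lambda j: cands[j].key)
    ]
    return AlignmentResult(
        mappings=selected,
        candidates=list(cands),
        scores=np.asarray(scores, dtype=float),
        support_dimension=len(cands),
    )


def align(
    net_left: ReactionNetwork,
    net_right: ReactionNetwork,
    k: int,
    sim: Similarity | None = None,
    params: AlignParams = AlignParams(),
) -> AlignmentResult:
    """Full base alignment of two networks (original or compressed domain)."""
    if sim is None:
        sim = UniformSimilarity()
    subs_left = enumerate_subnetworks(net_left, k, side="first")
    subs_right = enumerate_subnetworks(net_right, k, side="second")
    cands = candidate_mappings(
        subs_left,
        subs_right,
        sim,
        net_left=net_left,
        net_right=net_right,
        homology_mode=params.homology_mode,
    )
    if not cands:
        return AlignmentResult(mappings=[])
    support = build_support(cands, net_left, net_right)
    h = np.array([c.homology for c in cands], dtype=float)
    scores = iterate_scores(
        support, h, gamma=params.gamma, tol=params.tol, max_iter=params.max_iter
    )
    return extract_alignment(cands, scores, support_dimension=support.dimension)
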