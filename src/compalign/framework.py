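"""Three-phase alignment framework: compress, align, refine — plus planner.

The framework compresses both query networks ``c`` levels with MDS, aligns
the compressed networks with the base aligner, and then refines each
supernode mapping recursively: decompress both sides one level, re-align
the small networks, and recurse on the resulting mappings until the
original domain is reached.  At recursion depth ``c - x`` the two sides
contain at most ``k * 2**x`` and ``2**x`` reactions.

The planner answers two questions before any alignment is run: *how much*
to compress — the closed-form level  c = log2(n m^2 / k^2) / 8  that
balances the alignment-phase cost (shrinking as 2^-4c) against the
refinement-phase cost (growing as 2^4c) — and *whether* to compress at
all: compression is predicted to pay off when the compressed-domain
subnetwork-count product drops to at most half the original,
y = (N_k^c M_k^c) / (N_k M_k) <= 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .aligner import (
    AlignmentResult,
    AlignParams,
    ScoredMapping,
    align,
    enumerate_subnetworks,
)
from .mds import decompress_block, mds_compress
from .network import CompressionHierarchy, NetworkError, ReactionNetwork
from .similarity import Similarity, UniformSimilarity

__all__ = [
    "PlannerInputs",
    "optimal_c",
    "should_compress",
    "planner_inputs",
    "refine",
    "FrameworkResult",
    "compress_align_refine",
]


@dataclass(frozen=True)
class PlannerInputs:
    """Subnetwork-count statistics driving the compress decision."""

    n: int
    m: int
    k: int
    N_k: int
    M_k: int
    N_k_c: int
    M_k_c: int

    @property
    def alpha_k(self) -> float:
        return self.N_k / self.n

    @property
    def beta_k(self) -> float:
        return self.M_k / self.m


def optimal_c(n: int, m: int, k: int) -> tuple[float, int]:
    """Compression level minimizing expected framework cost.

    Returns the real value  log2(n m^2 / k^2) / 8  (with n <= m by
    convention; arguments are swapped internally if needed) and its
    nearest integer, floored at 0.
    """
    if n < 1 or m < 1 or k < 1:
        raise NetworkError("n, m and k must be positive")
    if n > m:
        n, m = m, n
    real = math.log2(n * m * m / (k * k)) / 8.0
    rounded = max(0, math.floor(real + 0.5))
    return real, rounded


def should_compress(p: PlannerInputs) -> tuple[float, bool]:
    """Subnetwork-count ratio y and the decision y <= 0.5."""
    if min(p.N_k, p.M_k, p.N_k_c, p.M_k_c) <= 0:
        raise NetworkError("subnetwork counts must be positive")
    y = (p.N_k_c * p.M_k_c) / (p.N_k * p.M_k)
    return y, y <= 0.5


def planner_inputs(
    net_left: ReactionNetwork,
    net_right: ReactionNetwork,
    h_left: CompressionHierarchy,
    h_right: CompressionHierarchy,
    k: int,
) -> PlannerInputs:
    """Measure N_k, M_k on the originals and on the compressed networks."""
    return PlannerInputs(
        n=net_left.n_nodes,
        m=net_right.n_nodes,
        k=k,
        N_k=len(enumerate_subnetworks(net_left, k)),
        M_k=len(enumerate_subnetworks(net_right, k)),
        N_k_c=len(enumerate_subnetworks(h_left.levels[-1], k)),
        M_k_c=len(enumerate_subnetworks(h_right.levels[-1], k)),
    )


def refine(
    mapping: ScoredMapping,
    h_left: CompressionHierarchy,
    h_right: CompressionHierarchy,
    x: int,
    k: int,
    sim: Similarity | None = None,
    params: AlignParams = AlignParams(),
) -> list[ScoredMapping]:
    """Recursively expand a level-``x`` mapping down to reaction level.

    Each recursion decompresses both sides one level, re-aligns the two
    small networks with the base aligner, and recurses on every resulting
    mapping.  Mappings whose members find no partner are dropped.
    """
    if x == 0:
        return [mapping]
    if x < 0:
        raise NetworkError("refinement level must be >= 0")
    net_l = h_left.network(x)
    net_r = h_right.network(x)
    for v in mapping.left:
        if v not in net_l.nodes:
            raise NetworkError(f"mapping node {v!r} is not a level-{x} node")
    for v in mapping.right:
        if v not in net_r.nodes:
            raise NetworkError(f"mapping node {v!r} is not a level-{x} node")

    block_l = decompress_block(h_left, x, mapping.left)
    block_r = decompress_block(h_right, x, mapping.right)
    for block, width in ((block_l, len(mapping.left)), (block_r, len(mapping.right))):
        n_reactions = sum(len(block.members[v]) for v in block.nodes)
        bound = max(width, 1) * 2**x
        assert n_reactions <= bound and bound <= k * 2**x, (
            "refinement block exceeds the k*2^x / 2^x size bound"
        )

    result = align(block_l, block_r, k, sim=sim, params=params)
    refined: list[ScoredMapping] = []
    for sub in result.mappings:
        refined.extend(refine(sub, h_left, h_right, x - 1, k, sim, params))
    return refined


@dataclass
class FrameworkResult:
    """Final reaction-level alignment plus compressed-domain artifacts."""

    final: AlignmentResult
    compressed: AlignmentResult
    hierarchy_left: CompressionHierarchy
    hierarchy_right: CompressionHierarchy
    planner: PlannerInputs | None = None
    report: dict = field(default_factory=dict)


def compress_align_refine(
    net_left: ReactionNetwork,
    net_right: ReactionNetwork,
    c: int,
    k: int,
    sim: Similarity | None = None,
    params: AlignParams = AlignParams(),
) -> FrameworkResult:
    """Run the full three-phase pipeline.

    With ``c = 0`` the result is exactly the base aligner's output.
    Otherwise both networks are compressed ``c`` levels, aligned in the
    compressed domain, and every supernode mapping is refined back to a
    conflict-free reaction-level alignment.
    """
    if sim is None:
        sim = UniformSimilarity()
    h_left = mds_compress(net_left, c)
    h_right = mds_compress(net_right, c)

    compressed_result = align(
        h_left.levels[-1], h_right.levels[-1], k, sim=sim, params=params
    )
    if c == 0:
        final = compressed_result
    else:
        mappings: list[ScoredMapping] = []
        for m in compressed_result.mappings:
            mappings.extend(refine(m, h_left, h_right, c, k, sim, params))
        seen_l: set[str] = set()
        seen_r: set[str] = set()
        for m in mappings:
            overlap = seen_l.intersection(m.left) | seen_r.intersection(m.right)
            if overlap:
                raise NetworkError(
                    f"refined alignment is not conflict-free: {sorted(overlap)}"
                )
            seen_l.update(m.left)
            seen_r.update(m.right)
        final = AlignmentResult(mappings=mappings)

    planner = planner_inputs(net_left, net_right, h_left, h_right, k)
    if c >= 1 and min(planner.N_k, planner.M_k, planner.N_k_c, planner.M_k_c) > 0:
        y, decision = should_compress(planner)
    else:
        y, decision = 1.0, False
    report = {
        "c": c,
        "k": k,
        "n": net_left.n_nodes,
        "m": net_right.n_nodes,
        "n_compressed": h_left.levels[-1].n_nodes,
        "m_compressed": h_right.levels[-1].n_nodes,
        "support_dimension_compressed": compressed_result.support_dimension,
        "mappings_compressed": len(compressed_result.mappings),
        "mappings_final": len(final.mappings),
        "ratio_y": y,
        "should_compress": decision,
    }
    return FrameworkResult(
        final=final,
        compressed=compressed_result,
        hierarchy_left=h_left,
        hierarchy_right=h_right,
        planner=planner,
        report=report,
    )
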