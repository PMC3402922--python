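"""Accuracy and compression analytics.

Accuracy of compressed-domain alignment is measured against the base
aligner run in the original domain: every candidate mapping the framework
scores in the compressed domain is *back-projected* — its score is compared
with the mean of the original-domain reaction-pair scores over the cross
product of its member sets — and the Pearson correlation between the two
score vectors is reported.  The mean is a conservative choice: it dilutes a
good mapping with the low-similarity pairs inside the same supernodes, so
it tends to underestimate rather than inflate agreement.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .aligner import AlignmentResult, AlignParams, align
from .framework import compress_align_refine
from .network import CompressionHierarchy, NetworkError, ReactionNetwork
from .similarity import Similarity

__all__ = [
    "backproject_score",
    "original_pair_scores",
    "pearson",
    "accuracy",
    "degree_histogram",
    "hub_fraction",
    "compression_report",
]


def backproject_score(
    left_members: Sequence[str],
    right_members: Sequence[str],
    original_scores: Mapping[tuple[str, str], float],
) -> float:
    """Mean original-domain pair score over the member cross product.

    Reaction pairs the original run never scored contribute 0.
    """
    left = sorted(left_members)
    right = sorted(right_members)
    if not left or not right:
        raise NetworkError("member sets must be nonempty")
    total = 0.0
    for a in left:
        for b in right:
            total += original_scores.get((a, b), 0.0)
    return total / (len(left) * len(right))


def original_pair_scores(result: AlignmentResult) -> dict[tuple[str, str], float]:
    """Reaction-pair (singleton-singleton candidate) scores of a base run."""
    out: dict[tuple[str, str], float] = {}
    for cand, score in zip(result.candidates, result.scores):
        if len(cand.left) == 1 and len(cand.right) == 1:
            out[(cand.left.nodes[0], cand.right.nodes[0])] = float(score)
    return out


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation; undefined for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise NetworkError("need two equal-length vectors of size >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise NetworkError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def accuracy(
    net_left: ReactionNetwork,
    net_right: ReactionNetwork,
    c: int,
    k: int,
    sim: Similarity | None = None,
    params: AlignParams = AlignParams(),
) -> float:
    """Correlation between compressed-domain and back-projected scores.

    Runs the framework at level ``c`` and the base aligner uncompressed,
    back-projects each compressed-domain candidate mapping onto the
    original reaction-pair scores, and returns the Pearson correlation
    over the full candidate set.  At ``c = 0`` (and ``k = 1``) the two
    score vectors coincide and the correlation is exactly 1.
    """
    base = align(net_left, net_right, k, sim=sim, params=params)
    pair_scores = original_pair_scores(base)
    fw = compress_align_refine(net_left, net_right, c, k, sim=sim, params=params)
    members_l = fw.hierarchy_left.levels[-1].members
    members_r = fw.hierarchy_right.levels[-1].members
    compressed_scores = []
    projected = []
    for cand, score in zip(fw.compressed.candidates, fw.compressed.scores):
        mem_l: set[str] = set()
        for v in cand.left.nodes:
            mem_l |= members_l[v]
        mem_r: set[str] = set()
        for v in cand.right.nodes:
            mem_r |= members_r[v]
        compressed_scores.append(float(score))
        projected.append(backproject_score(sorted(mem_l), sorted(mem_r), pair_scores))
    return pearson(compressed_scores, projected)


def _degrees(net: ReactionNetwork, direction: str) -> dict[str, int]:
    if direction not in ("in", "out", "total"):
        raise NetworkError(f"direction must be in/out/total, got {direction!r}")
    deg = {v: 0 for v in net.nodes}
    for u, v in net.edges:
        if direction in ("out", "total"):
            deg[u] += 1
        if direction in ("in", "total"):
            deg[v] += 1
    return deg


def degree_histogram(
    net: ReactionNetwork, direction: str = "out", bins: range | None = None
) -> dict[int, int]:
    """Exact degree frequencies, optionally restricted to a degree range."""
    deg = _degrees(net, direction)
    counts: dict[int, int] = {}
    for d in deg.values():
        counts[d] = counts.get(d, 0) + 1
    if bins is not None:
        counts = {d: counts.get(d, 0) for d in bins}
    return dict(sorted(counts.items()))


def hub_fraction(net: ReactionNetwork, threshold: int = 15) -> float:
    """Fraction of nodes with out-degree strictly above ``threshold``."""
    if net.n_nodes == 0:
        return 0.0
    deg = _degrees(net, "out")
    return sum(1 for d in deg.values() if d > threshold) / net.n_nodes


def compression_report(
    hierarchies: Sequence[CompressionHierarchy],
    size_bins: Sequence[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Per-level mean node/edge counts, binned by original network size.

    ``size_bins`` are inclusive (lo, hi) intervals on the level-0 node
    count; a single catch-all bin is used when omitted.
    """
    if not hierarchies:
        raise NetworkError("no hierarchies given")
    c = hierarchies[0].c
    if any(h.c != c for h in hierarchies):
        raise NetworkError("all hierarchies must share the same depth")
    if size_bins is None:
        lo = min(h.levels[0].n_nodes for h in hierarchies)
        hi = max(h.levels[0].n_nodes for h in hierarchies)
        size_bins = [(lo, hi)]
    rows = []
    for lo, hi in size_bins:
        group = [h for h in hierarchies if lo <= h.levels[0].n_nodes <= hi]
        row: dict = {"size_lo": lo, "size_hi": hi, "count": len(group)}
        for x in range(c + 1):
            if group:
                row[f"nodes_c{x}"] = float(
                    np.mean([h.levels[x].n_nodes for h in group])
                )
                row[f"edges_c{x}"] = float(
                    np.mean([h.levels[x].n_edges for h in group])
                )
            else:
                row[f"nodes_c{x}"] = np.nan
                row[f"edges_c{x}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
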