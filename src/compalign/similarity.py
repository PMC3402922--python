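"""Reaction-pair similarity lookups.

The base aligner combines topology with a homology term derived from
pairwise reaction similarities in [0, 1].  Biochemical similarity scoring
is out of scope here; similarities are supplied by the user as a TSV, drawn
from a seeded generator, or taken uniform.  Identifier order is treated
symmetrically (sim(a, b) == sim(b, a)).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "Similarity",
    "DictSimilarity",
    "UniformSimilarity",
    "IdentitySimilarity",
    "read_similarity_tsv",
    "write_similarity_tsv",
    "subnetwork_similarity",
]


class Similarity:
    """Base lookup; subclasses implement ``pair``."""

    def pair(self, a: str, b: str) -> float:  # pragma: no cover - interface
        raise NotImplementedError


class UniformSimilarity(Similarity):
    def __init__(self, value: float = 1.0):
        self.value = float(value)

    def pair(self, a: str, b: str) -> float:
        return self.value


class IdentitySimilarity(Similarity):
    """1.0 for identical identifiers, a small background value otherwise."""

    def __init__(self, background: float = 0.0):
        self.background = float(background)

    def pair(self, a: str, b: str) -> float:
        return 1.0 if a == b else self.background


class DictSimilarity(Similarity):
    """Similarity backed by a pair table; missing pairs raise by default.

    With ``default`` set, missing pairs fall back to that value instead.
    """

    def __init__(
        self,
        table: Mapping[tuple[str, str], float],
        default: float | None = None,
    ):
        self._table: dict[tuple[str, str], float] = {}
        for (a, b), value in table.items():
            self._table[self._key(a, b)] = float(value)
        self.default = default

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def pair(self, a: str, b: str) -> float:
        key = self._key(a, b)
        if key in self._table:
            return self._table[key]
        if self.default is not None:
            return self.default
        raise KeyError(f"no similarity recorded for pair ({a!r}, {b!r})")


def read_similarity_tsv(path: str | Path, default: float | None = None) -> DictSimilarity:
    """Read a similarity TSV with columns id1, id2, value ('#' comments allowed)."""
    table: dict[tuple[str, str], float] = {}
    path = Path(path)
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 'id1 id2 value', got {len(parts)} fields"
                )
            table[(parts[0], parts[1])] = float(parts[2])
    return DictSimilarity(table, default=default)


def write_similarity_tsv(sim: DictSimilarity, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("# id1\tid2\tvalue\n")
        for (a, b), value in sorted(sim._table.items()):
            fh.write(f"{a}\t{b}\t{value:.10g}\n")


def subnetwork_similarity(
    left_members: Iterable[str],
    right_members: Iterable[str],
    sim: Similarity,
    mode: str = "mean",
) -> float:
    """Similarity of two (super)node sets from reaction-pair similarities.

    ``mean`` (the conservative default) averages over the full cross
    product of member reactions; ``max`` takes the best pair.
    """
    left = sorted(left_members)
    right = sorted(right_members)
    if not left or not right:
        raise ValueError("member sets must be nonempty")
    values = [sim.pair(a, b) for a in left for b in right]
    if mode == "mean":
        return sum(values) / len(values)
    if mode == "max":
        return max(values)
    raise ValueError(f"unknown homology mode {mode!r}")
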