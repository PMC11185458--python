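"""Mean dependency distance over chunked linear element sequences.

The score decomposes each dependency arc into a within-chunk contribution
(linear span, when both endpoints share a chunk) and a cross-chunk
contribution (linear span plus chunk-level distance, when they do not), and
averages the total over ``n - 1``. With a single chunk this reduces to the
classical mean dependency distance ``sum |v - u| / (n - 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["MddError", "DependencyStructure", "mean_dependency_distance"]


class MddError(ValueError):
    """Raised for invalid dependency structures."""


@dataclass(frozen=True)
class DependencyStructure:
    """Linear sequence of elements with chunk assignment and dependency arcs.

    Elements are 1-based positions ``1..n``; ``chunk_of[i-1]`` gives the chunk
    of element ``i``. Chunks must be contiguous runs. Arcs are ordered
    ``(head, dependent)`` pairs of distinct elements.
    """

    n: int
    chunk_of: tuple[int, ...]
    arcs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "chunk_of", tuple(int(c) for c in self.chunk_of))
        object.__setattr__(self, "arcs", tuple((int(u), int(v)) for u, v in self.arcs))
        if self.n < 1 or len(self.chunk_of) != self.n:
            raise MddError("chunk_of must assign a chunk to each of the n elements")
        diffs = np.diff(self.chunk_of)
        if len(diffs) and (np.any(diffs < 0) or np.any(diffs > 1)):
            raise MddError("chunk assignment must be contiguous and non-decreasing")
        for u, v in self.arcs:
            if u == v:
                raise MddError(f"self-arc ({u}, {v})")
            if not (1 <= u <= self.n and 1 <= v <= self.n):
                raise MddError(f"arc ({u}, {v}) references invalid elements")

    @property
    def n_chunks(self) -> int:
        return len(set(self.chunk_of))

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "DependencyStructure":
        """Build from a (element, chunk, head) table with 1-based indices.

        ``head == 0`` marks an element with no incoming arc (a root).
        """
        table = table.sort_values("element")
        n = len(table)
        chunk_of = tuple(table["chunk"].astype(int))
        arcs = tuple(
            (int(h), int(e))
            for e, h in zip(table["element"], table["head"])
            if int(h) != 0
        )
        return cls(n=n, chunk_of=chunk_of, arcs=arcs)


def mean_dependency_distance(
    structure: DependencyStructure, crossing: str = "span_plus_chunk"
) -> float:
    """Mean dependency distance of a chunked sequence.

    Within-chunk arcs contribute their linear span ``|v - u|``. Crossing arcs
    contribute, depending on ``crossing``:

    - ``"span_plus_chunk"`` (default): linear span plus chunk-level distance
      ``|chunk(v) - chunk(u)|``;
    - ``"chunk_only"``: the chunk-level distance alone.

    The summed contributions are divided by ``n - 1``.
    """
    if structure.n < 2:
        raise MddError("at least 2 elements are required")
    if not structure.arcs:
        raise MddError("at least one dependency arc is required")
    if crossing not in ("span_plus_chunk", "chunk_only"):
        raise MddError(f"unknown crossing mode: {crossing!r}")
    total = 0.0
    for u, v in structure.arcs:
        cu, cv = structure.chunk_of[u - 1], structure.chunk_of[v - 1]
        span = abs(v - u)
        if cu == cv:
            total += span
        else:
            chunk_dist = abs(cv - cu)
            total += span + chunk_dist if crossing == "span_plus_chunk" else chunk_dist
    return total / (structure.n - 1)
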