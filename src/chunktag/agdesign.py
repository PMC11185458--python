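"""Artificial-grammar designs: syllable inventories, streams, test trials, timing.

Event tables are plain :class:`pandas.DataFrame` objects with the columns in
:data:`EVENT_COLUMNS`. Onsets are computed on an integer-millisecond grid and
stored in seconds so that generated timelines are reproducible to the last
bit for a given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignError",
    "SyllableInventory",
    "TimingSpec",
    "EVENT_COLUMNS",
    "default_inventory",
    "make_within_stream",
    "make_across_stream",
    "make_test_trials",
    "chunk_rate",
    "epoch_length",
    "validate_events",
]


class DesignError(ValueError):
    """Raised for invalid design parameters (counts, parity, unknown pairs)."""


#: Columns of every event table, in order.
EVENT_COLUMNS = [
    "onset_s",
    "duration_s",
    "syllable",
    "chunk_index",
    "position",
    "condition",
    "phase",
    "role",
    "trial_index",
]

_TARGET_SYLLABLES = (
    "BA", "BO", "FA", "FI", "GU", "ME",
    "MI", "MO", "NA", "NO", "PU", "SU",
)
_FILLER_SYLLABLES = (
    "BI", "BU", "DE", "GO", "HE", "KI",
    "LE", "LI", "LU", "MA", "PE", "TU",
)
_DEPENDENCY_PAIRS = (("FU", "LA"), ("TA", "PI"), ("KE", "MÖ"), ("WE", "HO"))


@dataclass(frozen=True)
class SyllableInventory:
    """Fixed sets of syllables used to build streams.

    Parameters
    ----------
    target_syllables
        Twelve labels filling the free positions of target chunks.
    filler_syllables
        Twelve labels used for filler chunks.
    dependency_pairs
        Four ordered (first, second) dependency pairs, disjoint from both
        syllable lists.
    """

    target_syllables: tuple[str, ...]
    filler_syllables: tuple[str, ...]
    dependency_pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_syllables", tuple(self.target_syllables))
        object.__setattr__(self, "filler_syllables", tuple(self.filler_syllables))
        object.__setattr__(
            self, "dependency_pairs", tuple(tuple(p) for p in self.dependency_pairs)
        )
        if len(self.dependency_pairs) != 4:
            raise DesignError("exactly 4 dependency pairs are required")
        pair_members = [s for p in self.dependency_pairs for s in p]
        labels = (
            list(self.target_syllables) + list(self.filler_syllables) + pair_members
        )
        if len(set(labels)) != len(labels):
            raise DesignError("syllable labels must be pairwise distinct")
        overlap = set(pair_members) & (
            set(self.target_syllables) | set(self.filler_syllables)
        )
        if overlap:
            raise DesignError(f"pair members reused as target/filler: {overlap}")

    def pair_index(self, pair: Sequence[str]) -> int:
        """Index of ``pair`` in :attr:`dependency_pairs`; raises if unknown."""
        pair = tuple(pair)
        try:
            return self.dependency_pairs.index(pair)  # type: ignore[arg-type]
        except ValueError:
            raise DesignError(f"unknown dependency pair: {pair!r}") from None


@dataclass(frozen=True)
class TimingSpec:
    """Stream timing: isochronous syllables grouped in silence-bounded chunks."""

    syllable_dur_s: float = 0.250
    chunk_size: int = 6
    boundary_silence_s: float = 0.080

    def __post_init__(self) -> None:
        if self.syllable_dur_s <= 0 or self.boundary_silence_s < 0:
            raise DesignError("durations must be positive")
        if self.chunk_size < 1:
            raise DesignError("chunk_size must be >= 1")

    @property
    def chunk_period_s(self) -> float:
        """Chunk onset-to-onset interval (syllables plus boundary silence)."""
        return self.chunk_size * self.syllable_dur_s + self.boundary_silence_s

    @property
    def syllable_dur_ms(self) -> int:
        return int(round(self.syllable_dur_s * 1000))

    @property
    def boundary_silence_ms(self) -> int:
        return int(round(self.boundary_silence_s * 1000))


def default_inventory() -> SyllableInventory:
    """The stock 12 target + 12 filler syllables and 4 dependency pairs."""
    return SyllableInventory(_TARGET_SYLLABLES, _FILLER_SYLLABLES, _DEPENDENCY_PAIRS)


def chunk_rate(timing: TimingSpec) -> float:
    """Chunk presentation rate in Hz (reciprocal of the chunk period)."""
    return 1.0 / timing.chunk_period_s


def epoch_length(timing: TimingSpec, n_chunks: int) -> float:
    """Duration in seconds of an epoch spanning ``n_chunks`` chunks."""
    if n_chunks < 1:
        raise DesignError("n_chunks must be >= 1")
    return n_chunks * timing.chunk_period_s


def _balanced_draw(labels: Sequence[str], n: int, rng: np.random.Generator) -> list[str]:
    """Draw ``n`` labels keeping per-label counts within +/-1 of each other.

    Concatenates independently shuffled full cycles of ``labels`` and takes a
    prefix, so any prefix covers whole cycles plus at most one partial cycle.
    """
    out: list[str] = []
    while len(out) < n:
        cycle = list(labels)
        rng.shuffle(cycle)
        out.extend(cycle)
    return out[:n]


def _chunk_onset_ms(chunk: int, timing: TimingSpec) -> int:
    period_ms = timing.chunk_size * timing.syllable_dur_ms + timing.boundary_silence_ms
    return chunk * period_ms


def _event_row(
    chunk: int,
    position: int,
    syllable: str,
    role: str,
    condition: str,
    phase: str,
    trial_index: int,
    timing: TimingSpec,
) -> dict:
    onset_ms = _chunk_onset_ms(chunk, timing) + (position - 1) * timing.syllable_dur_ms
    return {
        "onset_s": onset_ms / 1000.0,
        "duration_s": timing.syllable_dur_s,
        "syllable": syllable,
        "chunk_index": chunk,
        "position": position,
        "condition": condition,
        "phase": phase,
        "role": role,
        "trial_index": trial_index,
    }


def make_within_stream(
    pair: Sequence[str],
    n_target_chunks: int,
    inventory: SyllableInventory | None = None,
    timing: TimingSpec | None = None,
    seed: int | np.random.SeedSequence = 0,
    phase: str = "learning",
    trial_index: int = 0,
) -> pd.DataFrame:
    """Alternating target/filler chunk stream with the pair at positions 2 and 5.

    Every odd-indexed chunk is a filler chunk; every even-indexed chunk is a
    target chunk carrying ``pair`` at within-chunk positions 2 (``dep_first``)
    and 5 (``dep_second``). Free positions are filled from the inventory with
    per-syllable usage balanced to within one occurrence.
    """
    inventory = inventory or default_inventory()
    timing = timing or TimingSpec()
    inventory.pair_index(pair)
    if n_target_chunks < 1:
        raise DesignError("n_target_chunks must be >= 1")
    rng = np.random.default_rng(seed)
    first, second = pair

    free_positions = [p for p in range(1, timing.chunk_size + 1) if p not in (2, 5)]
    target_fill = _balanced_draw(
        inventory.target_syllables, len(free_positions) * n_target_chunks, rng
    )
    filler_fill = _balanced_draw(
        inventory.filler_syllables, timing.chunk_size * n_target_chunks, rng
    )

    rows: list[dict] = []
    ti, fi = 0, 0
    for chunk in range(2 * n_target_chunks):
        if chunk % 2 == 0:  # target chunk
            for pos in range(1, timing.chunk_size + 1):
                if pos == 2:
                    syl, role = first, "dep_first"
                elif pos == 5:
                    syl, role = second, "dep_second"
                else:
                    syl, role = target_fill[ti], "other_target"
                    ti += 1
                rows.append(
                    _event_row(chunk, pos, syl, role, "within", phase, trial_index, timing)
                )
        else:  # filler chunk
            for pos in range(1, timing.chunk_size + 1):
                rows.append(
                    _event_row(
                        chunk, pos, filler_fill[fi], "filler", "within", phase,
                        trial_index, timing,
                    )
                )
                fi += 1
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def make_across_stream(
    pair: Sequence[str],
    n_chunks: int,
    inventory: SyllableInventory | None = None,
    timing: TimingSpec | None = None,
    seed: int | np.random.SeedSequence = 0,
    phase: str = "learning",
    trial_index: int = 0,
) -> pd.DataFrame:
    """Target-chunk stream with the pair spanning each consecutive chunk pair.

    In every chunk pair (2i, 2i+1), ``dep_first`` sits at position 5 of the
    first chunk and ``dep_second`` at position 2 of the second, so the
    dependency crosses the chunk boundary. All chunks draw from the target
    syllables, balanced to within one occurrence.
    """
    inventory = inventory or default_inventory()
    timing = timing or TimingSpec()
    inventory.pair_index(pair)
    if n_chunks < 2 or n_chunks % 2 != 0:
        raise DesignError("n_chunks must be even and >= 2")
    rng = np.random.default_rng(seed)
    first, second = pair

    n_free = n_chunks * timing.chunk_size - n_chunks  # one dep slot per chunk
    fill = _balanced_draw(inventory.target_syllables, n_free, rng)

    rows: list[dict] = []
    fi = 0
    for chunk in range(n_chunks):
        dep_pos = 5 if chunk % 2 == 0 else 2
        dep_syl = first if chunk % 2 == 0 else second
        dep_role = "dep_first" if chunk % 2 == 0 else "dep_second"
        for pos in range(1, timing.chunk_size + 1):
            if pos == dep_pos:
                syl, role = dep_syl, dep_role
            else:
                syl, role = fill[fi], "other_target"
                fi += 1
            rows.append(
                _event_row(chunk, pos, syl, role, "across", phase, trial_index, timing)
            )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def make_test_trials(
    pairs: Sequence[Sequence[str]] | None = None,
    inventory: SyllableInventory | None = None,
    timing: TimingSpec | None = None,
    seed: int | np.random.SeedSequence = 0,
    n_per_cell: int = 36,
    n_target_chunks: int = 4,
    violation_syllables: dict[str, str] | None = None,
) -> list[pd.DataFrame]:
    """Balanced 2x2 (within/across x NAD/violation) test-phase trials.

    Parameters
    ----------
    pairs
        ``(within_pair, across_pair)``; defaults to the first two inventory
        pairs. A participant learns one pair per condition.
    n_per_cell
        Trials per design cell (default 36, i.e. 144 trials in total).
    n_target_chunks
        Target chunks per trial. Within-condition trials interleave an equal
        number of filler chunks.
    violation_syllables
        Per-condition replacement for the correct second element. Defaults to
        the second element of the *other* learned pair.

    Returns
    -------
    list of event tables, one per trial, in randomized presentation order;
    ``trial_index`` records that order.
    """
    inventory = inventory or default_inventory()
    timing = timing or TimingSpec()
    if pairs is None:
        pairs = inventory.dependency_pairs[:2]
    if len(pairs) != 2:
        raise DesignError("pairs must be (within_pair, across_pair)")
    within_pair, across_pair = (tuple(p) for p in pairs)
    inventory.pair_index(within_pair)
    inventory.pair_index(across_pair)
    if violation_syllables is None:
        violation_syllables = {
            "within": across_pair[1],
            "across": within_pair[1],
        }

    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    order_rng = np.random.default_rng(ss.spawn(1)[0])
    cells = [
        ("within", True), ("within", False), ("across", True), ("across", False),
    ]
    slots = [cell for cell in cells for _ in range(n_per_cell)]
    order_rng.shuffle(slots)

    child_seeds = ss.spawn(len(slots))
    trials: list[pd.DataFrame] = []
    for trial_index, ((condition, grammatical), child) in enumerate(
        zip(slots, child_seeds)
    ):
        if condition == "within":
            table = make_within_stream(
                within_pair, n_target_chunks, inventory, timing, child,
                phase="test", trial_index=trial_index,
            )
        else:
            table = make_across_stream(
                across_pair, 2 * (n_target_chunks // 2), inventory, timing, child,
                phase="test", trial_index=trial_index,
            )
        if not grammatical:
            mask = table["role"] == "dep_second"
            table.loc[mask, "syllable"] = violation_syllables[condition]
            table.loc[mask, "role"] = "dep_second_violation"
        trials.append(table)
    return trials


def validate_events(table: pd.DataFrame, timing: TimingSpec | None = None) -> None:
    """Check event-table invariants; raise :class:`DesignError` on violation.

    Verifies strictly increasing onsets and, when ``timing`` is given, the
    within-chunk / boundary onset deltas and dependency pairing.
    """
    timing = timing or TimingSpec()
    if list(table.columns) != EVENT_COLUMNS:
        raise DesignError(f"expected columns {EVENT_COLUMNS}, got {list(table.columns)}")
    onsets = table["onset_s"].to_numpy()
    if not np.all(np.diff(onsets) > 0):
        raise DesignError("onsets must be strictly increasing")
    deltas = np.diff(onsets)
    same_chunk = np.diff(table["chunk_index"].to_numpy()) == 0
    within_ok = np.allclose(deltas[same_chunk], timing.syllable_dur_s, atol=1e-9)
    boundary_ok = np.allclose(
        deltas[~same_chunk],
        timing.syllable_dur_s + timing.boundary_silence_s,
        atol=1e-9,
    )
    if not (within_ok and boundary_ok):
        raise DesignError("onset deltas do not match the timing spec")
    n_first = int((table["role"] == "dep_first").sum())
    n_second = int(table["role"].isin(["dep_second", "dep_second_violation"]).sum())
    if n_first != n_second:
        raise DesignError(
            f"unbalanced dependency roles: {n_first} first vs {n_second} second"
        )
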