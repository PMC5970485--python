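"""Fundamental value types: gene sets and binary expression states.

A :class:`BinaryState` is represented as a plain tuple of 0/1 ints, one bit
per gene in :class:`GeneSet` order.  Tuples are hashable and compare
lexicographically, which is the total order used everywhere downstream
(BFS tie-breaking, stable-state output order).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import UnknownGeneError

BinaryState = tuple  # tuple[int, ...] with entries in {0, 1}


@dataclass(frozen=True)
class GeneSet:
    """Ordered collection of unique gene names; index i <-> bit position i."""

    names: tuple[str, ...]
    _index: dict = field(init=False, repr=False, compare=False, hash=False)

    def __init__(self, names: Iterable[str]):
        names = tuple(names)
        if len(names) < 2:
            raise ValueError("a gene set needs at least 2 genes")
        if len(set(names)) != len(names):
            raise ValueError("gene names must be unique")
        if any(not n for n in names):
            raise ValueError("gene names must be non-empty")
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "_index", {g: i for i, g in enumerate(names)})

    @property
    def n(self) -> int:
        return len(self.names)

    def index(self, gene: str) -> int:
        try:
            return self._index[gene]
        except KeyError:
            raise UnknownGeneError(f"unknown gene {gene!r}") from None

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def __iter__(self):
        return iter(self.names)

    def __len__(self) -> int:
        return len(self.names)


def make_state(bits: Sequence[int]) -> BinaryState:
    state = tuple(int(b) for b in bits)
    if any(b not in (0, 1) for b in state):
        raise ValueError("state bits must be 0 or 1")
    return state


def state_from_string(s: str) -> BinaryState:
    """Parse a bit string like '100' into a state tuple."""
    return tuple(1 if c == "1" else 0 for c in s)


def state_to_string(state: BinaryState) -> str:
    return "".join("1" if b else "0" for b in state)


def flip_bit(state: BinaryState, i: int) -> BinaryState:
    return state[:i] + (1 - state[i],) + state[i + 1 :]


def hamming(s1: BinaryState, s2: BinaryState) -> int:
    return sum(a != b for a, b in zip(s1, s2))


def all_states(n: int):
    """Yield all 2**n states of width n in lexicographic order."""
    for k in range(1 << n):
        yield tuple((k >> (n - 1 - i)) & 1 for i in range(n))
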