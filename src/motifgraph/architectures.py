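"""Motif-architecture enumeration.

A motif-architecture (MA) is the statistical frame of this pipeline: a
chain of exactly four motif occurrences inside one TM segment in which
each motif starts on the residue immediately after the previous one ends
— no residue gaps, no overlaps between chain members. Every (start,
length-composition) pair that fits the segment yields one architecture;
overlapping architectures all count.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

from .motifs import DEFAULT_N_RANGE, MotifLabel, MotifOccurrence
from .sequence_io import TMSegment

#: Number of chained motifs per architecture.
DEFAULT_ARCHITECTURE_SIZE = 4


@dataclass(frozen=True)
class MotifArchitecture:
    """An ordered, gap-free chain of motif occurrences in one segment."""

    motifs: tuple[MotifOccurrence, ...]

    def __post_init__(self) -> None:
        if len(self.motifs) < 1:
            raise ValueError("architecture needs at least one motif")
        seg = self.motifs[0].segment
        pos = self.motifs[0].offset
        for occ in self.motifs:
            if occ.segment is not seg:
                raise ValueError("architecture spans multiple segments")
            if occ.offset != pos:
                raise ValueError(
                    f"residue gap in architecture: expected offset {pos}, "
                    f"got {occ.offset}"
                )
            pos = occ.offset + occ.label.n + 1
        if pos > len(seg):
            raise ValueError("architecture overruns its segment")

    @property
    def segment(self) -> TMSegment:
        return self.motifs[0].segment

    @property
    def start(self) -> int:
        return self.motifs[0].offset

    @property
    def span(self) -> int:
        return sum(m.label.n + 1 for m in self.motifs)

    @property
    def labels(self) -> tuple[MotifLabel, ...]:
        return tuple(m.label for m in self.motifs)

    @property
    def composition(self) -> tuple[int, ...]:
        return tuple(m.label.n for m in self.motifs)


def enumerate_architectures(
    occurrences: Sequence[MotifOccurrence],
    segment: TMSegment,
    size: int = DEFAULT_ARCHITECTURE_SIZE,
) -> list[MotifArchitecture]:
    """Every gap-free ``size``-chain of occurrences in the segment.

    Occurrences are indexed by start offset and chained depth-first: the
    successor of an occurrence at offset *i* with separation *n* starts
    at offset *i + n + 1*. Output order is deterministic — by start
    offset, then lexicographically by the (n_1, ..., n_size) length
    composition. Occurrences dropped upstream (e.g. windows containing
    'X') break the chains that would have used them.
    """
    if size < 1:
        raise ValueError("architecture size must be >= 1")
    by_offset: dict[int, list[MotifOccurrence]] = {}
    for occ in occurrences:
        if occ.segment is not segment:
            raise ValueError("occurrence does not belong to the segment")
        by_offset.setdefault(occ.offset, []).append(occ)
    for bucket in by_offset.values():
        bucket.sort(key=lambda o: o.label.n)

    out: list[MotifArchitecture] = []
    chain: list[MotifOccurrence] = []

    def extend(next_offset: int) -> None:
        if len(chain) == size:
            out.append(MotifArchitecture(tuple(chain)))
            return
        for occ in by_offset.get(next_offset, ()):
            chain.append(occ)
            extend(next_offset + occ.label.n + 1)
            chain.pop()

    for start in sorted(by_offset):
        extend(start)
    return out


def count_architectures(
    L: int,
    n_range: Iterable[int] = DEFAULT_N_RANGE,
    size: int = DEFAULT_ARCHITECTURE_SIZE,
) -> int:
    """Analytic architecture count for a homogeneous 'X'-free segment.

    Sums, over every length composition (n_1, ..., n_size), the number of
    start offsets at which the chain fits: ``max(0, L - span + 1)`` with
    ``span = sum(n_k + 1)``.
    """
    if L < 0:
        raise ValueError("segment length must be >= 0")
    ns = sorted(set(n_range))
    total = 0
    for comp in product(ns, repeat=size):
        span = sum(comp) + size
        total += max(0, L - span + 1)
    return total
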