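"""XYn motif extraction by naive window scan.

An XYn motif is a pair of anchor residues — X at position *i* and Y at
position *i + n* — with ``n - 1`` unconstrained "variable" residues in
between, written e.g. ``LG5`` (leucine and glycine separated by four
residues). Every window position of every span in the configured range
yields one occurrence; overlaps are all kept.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

from .sequence_io import TMSegment

logger = logging.getLogger(__name__)

#: Default X->Y separation parameters.
DEFAULT_N_RANGE = (4, 5, 6, 7)

_LABEL_RE = re.compile(r"^([A-Z])([A-Z])(\d+)$")


@dataclass(frozen=True)
class MotifLabel:
    """Canonical XYn motif label; ``n`` is the X->Y index difference."""

    x: str
    y: str
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("motif separation n must be >= 2")

    @property
    def text(self) -> str:
        return f"{self.x}{self.y}{self.n}"

    @classmethod
    def parse(cls, text: str) -> "MotifLabel":
        m = _LABEL_RE.match(text)
        if m is None:
            raise ValueError(f"not a valid XYn motif label: {text!r}")
        return make_label(m.group(1), m.group(2), int(m.group(3)))

    def __str__(self) -> str:
        return self.text


@lru_cache(maxsize=None)
def make_label(x: str, y: str, n: int) -> MotifLabel:
    """Interned label constructor (extraction creates millions of these)."""
    return MotifLabel(x, y, n)


def format_label(label: MotifLabel, convention: str = "span") -> str:
    """Render a label under a numbering convention.

    ``span`` (default) writes n = the X->Y index difference (LG5 = four
    variable residues); ``gap`` writes the variable-position count n - 1
    (the same motif prints as LG4), for comparison with outputs numbered
    that way.
    """
    if convention == "span":
        return label.text
    if convention == "gap":
        return f"{label.x}{label.y}{label.n - 1}"
    raise ValueError(f"unknown label convention {convention!r}")


@dataclass(frozen=True)
class MotifOccurrence:
    """A located XYn match inside one segment."""

    segment: TMSegment
    offset: int  # 0-based start within the segment
    label: MotifLabel

    @property
    def span(self) -> int:
        """Residues covered: the two anchors plus n - 1 variable ones."""
        return self.label.n + 1

    @property
    def residues(self) -> str:
        return self.segment.subsequence[self.offset:self.offset + self.span]

    @property
    def variable_residues(self) -> str:
        return self.segment.subsequence[self.offset + 1:
                                        self.offset + self.label.n]


def extract_occurrences(
    segment: TMSegment,
    n_range: Iterable[int] = DEFAULT_N_RANGE,
) -> list[MotifOccurrence]:
    """All XYn occurrences in a segment, ordered by offset then n.

    For every start offset *i* and every n in ``n_range`` with
    ``i + n < len(segment)`` there is exactly one occurrence, so for an
    'X'-free segment the count equals
    ``sum(max(0, L - n) for n in n_range)``. Windows containing the
    unknown residue 'X' anywhere (anchor or variable position) are
    discarded with a log message.
    """
    ns = sorted(set(n_range))
    if not ns:
        raise ValueError("n_range must be non-empty")
    if ns[0] < 2:
        raise ValueError("all n in n_range must be >= 2")
    sub = segment.subsequence
    L = len(sub)
    out: list[MotifOccurrence] = []
    has_x = "X" in sub
    for i in range(L):
        for n in ns:
            j = i + n
            if j >= L:
                break
            if has_x and "X" in sub[i:j + 1]:
                logger.debug(
                    "segment %s[%d:%d]: dropped occurrence with 'X' at "
                    "offset %d (n=%d)",
                    segment.protein_id, segment.start, segment.end, i, n,
                )
                continue
            out.append(
                MotifOccurrence(segment, i, make_label(sub[i], sub[j], n))
            )
    return out


def unique_labels(occurrences: Sequence[MotifOccurrence]) -> list[MotifLabel]:
    """Duplicate-free label list in first-seen order."""
    return list(dict.fromkeys(occ.label for occ in occurrences))


def expected_occurrence_count(L: int, n_range: Iterable[int]) -> int:
    """Analytic occurrence count for an 'X'-free segment of length L."""
    if L < 0:
        raise ValueError("segment length must be >= 0")
    return sum(max(0, L - n) for n in set(n_range))
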