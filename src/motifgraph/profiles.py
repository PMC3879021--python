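"""Log-odds topology profiles (LOPs) and per-motif state prediction.

For every motif label, the residues at its variable positions are tallied
separately for occurrences found in membrane (TM) segments and in
non-membrane (nTM) runs. Each per-position relative frequency is set
against a background ("nature") amino-acid frequency and log-transformed,
giving one log-odds profile per (motif, state). A motif's topology state
is then predicted by comparing the strength of its two profiles.

With pseudocount :math:`c` and background :math:`q`, the score of amino
acid *a* at variable position *p* is

.. math::

    \\mathrm{LOP}[p][a] = \\log_2 \\frac{(k_{pa} + c\\,q_a) / (N + c)}{q_a}

where :math:`k_{pa}` is the observed count and :math:`N` the number of
contributing occurrences. A profile's strength is the observed-frequency-
weighted mean of its log-odds values; the predicted state is the argmax
over the two strengths.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .graph import MotifGraph, UNCLASSIFIED
from .motifs import MotifLabel, MotifOccurrence
from .sequence_io import AMINO_ACIDS, NTM, TM, ProteinRecord

logger = logging.getLogger(__name__)

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class BackgroundFrequencies:
    """Background ("nature") amino-acid frequencies, one per canonical residue."""

    q: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.q) != set(AMINO_ACIDS):
            raise ValueError("background must cover exactly the 20 amino acids")
        if any(v <= 0 for v in self.q.values()):
            raise ValueError("background frequencies must all be positive")
        total = sum(self.q.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"background frequencies sum to {total}, not 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.q[aa] for aa in AMINO_ACIDS])


def _normalise(counts: Mapping[str, float]) -> BackgroundFrequencies:
    total = sum(counts.values())
    return BackgroundFrequencies({aa: counts[aa] / total for aa in AMINO_ACIDS})


def builtin_background() -> BackgroundFrequencies:
    """The packaged Swiss-Prot average composition table."""
    text = (resources.files("motifgraph") / "data" /
            "background_frequencies.tsv").read_text()
    freqs: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, value = line.split("\t")
        freqs[aa] = float(value)
    return _normalise(freqs)


def read_background_tsv(path: str | Path) -> BackgroundFrequencies:
    """Read a two-column (amino acid, frequency) TSV background table."""
    freqs: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, value = line.split("\t")
        freqs[aa] = float(value)
    return _normalise(freqs)


def dataset_background(records: Iterable[ProteinRecord]) -> BackgroundFrequencies:
    """Empirical residue frequencies over a whole dataset.

    Counts every canonical residue (TM and nTM alike, 'X' skipped) with a
    +1 pseudocount per amino acid so rare residues never hit zero.
    """
    counts = {aa: 1.0 for aa in AMINO_ACIDS}
    seen = 0
    for rec in records:
        for ch in rec.sequence:
            if ch in AA_INDEX:
                counts[ch] += 1.0
                seen += 1
    if seen == 0:
        raise ValueError("dataset background requires at least one residue")
    return _normalise(counts)


def natural_background(
    source: str = "builtin",
    records: Iterable[ProteinRecord] | None = None,
    path: str | Path | None = None,
) -> BackgroundFrequencies:
    """Background table from the packaged file, the dataset, or a TSV."""
    if source == "builtin":
        return builtin_background()
    if source == "dataset":
        if records is None:
            raise ValueError("dataset background requires records")
        return dataset_background(records)
    if source == "file":
        if path is None:
            raise ValueError("file background requires a path")
        return read_background_tsv(path)
    raise ValueError(f"unknown background source {source!r}")


@dataclass
class PositionCounts:
    """Variable-position residue counts for one (motif, state) pair.

    ``counts`` has shape (n - 1, 20): rows are variable positions 1..n-1,
    columns follow :data:`AMINO_ACIDS`. Every row sums to
    ``total_occurrences`` because occurrences containing 'X' are excluded
    upstream.
    """

    label: MotifLabel
    state: str
    counts: np.ndarray
    total_occurrences: int

    def frequencies(self) -> np.ndarray:
        if self.total_occurrences < 1:
            raise ValueError("no occurrences to normalise")
        return self.counts / self.total_occurrences


def collect_position_counts(
    occurrences_by_state: Mapping[str, Sequence[MotifOccurrence]],
) -> dict[tuple[str, str], PositionCounts]:
    """Tally variable-position residues per (label, state).

    ``occurrences_by_state`` maps a topology state (TM or nTM) to the
    occurrences harvested from that state's maximal runs, so every residue
    of an occurrence carries the state of its run. Occurrences whose
    variable positions contain 'X' are skipped with a log message (the
    extractor already drops them; this is a second guard for hand-built
    inputs).
    """
    out: dict[tuple[str, str], PositionCounts] = {}
    for state, occurrences in occurrences_by_state.items():
        if state not in (TM, NTM):
            raise ValueError(f"unknown topology state {state!r}")
        for occ in occurrences:
            variable = occ.variable_residues
            if "X" in variable:
                logger.warning(
                    "skipping %s occurrence with 'X' at a variable position "
                    "in %s", occ.label.text, occ.segment.protein_id,
                )
                continue
            key = (occ.label.text, state)
            pc = out.get(key)
            if pc is None:
                pc = PositionCounts(
                    label=occ.label, state=state,
                    counts=np.zeros((occ.label.n - 1, len(AMINO_ACIDS)),
                                    dtype=np.int64),
                    total_occurrences=0,
                )
                out[key] = pc
            for p, aa in enumerate(variable):
                pc.counts[p, AA_INDEX[aa]] += 1
            pc.total_occurrences += 1
    return out


@dataclass
class LogOddProfile:
    """Per-position log-odds matrix of one (motif, state) pair."""

    label: MotifLabel
    state: str
    values: np.ndarray  # (n - 1, 20)
    pseudocount: float
    total_occurrences: int
    counts: np.ndarray  # retained for the frequency weights of scoring

    def strength(self) -> float:
        """Observed-frequency-weighted mean log-odds of the profile."""
        f = self.counts / self.total_occurrences
        return float(np.sum(f * self.values))


def build_lop(
    counts: PositionCounts,
    background: BackgroundFrequencies,
    pseudocount: float = 1.0,
    log_base: float = 2.0,
) -> LogOddProfile:
    """Smoothed log-odds of per-position frequencies against background."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if counts.total_occurrences < 1:
        raise ValueError("profile requires at least one occurrence")
    if (counts.counts < 0).any():
        raise ValueError("position counts must be non-negative")
    if pseudocount == 0 and (counts.counts == 0).any():
        raise ValueError(
            "zero counts with pseudocount 0 give infinite log-odds; "
            "use a positive pseudocount"
        )
    q = background.as_array()
    smoothed = (counts.counts + pseudocount * q) / (
        counts.total_occurrences + pseudocount)
    values = np.log(smoothed / q) / math.log(log_base)
    return LogOddProfile(
        label=counts.label, state=counts.state, values=values,
        pseudocount=pseudocount,
        total_occurrences=counts.total_occurrences,
        counts=counts.counts.astype(float),
    )


@dataclass(frozen=True)
class MotifClassification:
    """Predicted topology state of one motif with its evidence."""

    label: str
    state: str  # TM, nTM, or unclassified
    score_tm: float
    score_ntm: float
    n_tm: int
    n_ntm: int


def classify_motif(
    label: MotifLabel,
    lop_tm: LogOddProfile | None = None,
    lop_ntm: LogOddProfile | None = None,
    min_occurrences: int = 5,
) -> MotifClassification:
    """Predict a motif's topology state from its profiles.

    With both profiles present, the state with the larger strength wins;
    an exact tie is left unclassified. With a single profile, that state
    wins only when it is backed by at least ``min_occurrences``
    occurrences — a guard against calls from a handful of chance matches.
    """
    if lop_tm is None and lop_ntm is None:
        raise ValueError(f"motif {label.text}: no profile for either state")
    s_tm = lop_tm.strength() if lop_tm is not None else math.nan
    s_ntm = lop_ntm.strength() if lop_ntm is not None else math.nan
    n_tm = lop_tm.total_occurrences if lop_tm is not None else 0
    n_ntm = lop_ntm.total_occurrences if lop_ntm is not None else 0
    if lop_tm is not None and lop_ntm is not None:
        if s_tm > s_ntm:
            state = TM
        elif s_ntm > s_tm:
            state = NTM
        else:
            state = UNCLASSIFIED
    elif lop_tm is not None:
        state = TM if n_tm >= min_occurrences else UNCLASSIFIED
    else:
        state = NTM if n_ntm >= min_occurrences else UNCLASSIFIED
    return MotifClassification(label.text, state, s_tm, s_ntm, n_tm, n_ntm)


def classify_all(
    counts: Mapping[tuple[str, str], PositionCounts],
    background: BackgroundFrequencies,
    pseudocount: float = 1.0,
    log_base: float = 2.0,
    min_occurrences: int = 5,
) -> dict[str, MotifClassification]:
    """Classify every motif present in a position-count collection."""
    labels: dict[str, MotifLabel] = {}
    for (text, _), pc in counts.items():
        labels[text] = pc.label
    out: dict[str, MotifClassification] = {}
    for text in sorted(labels):
        lop_tm = lop_ntm = None
        if (text, TM) in counts:
            lop_tm = build_lop(counts[(text, TM)], background,
                               pseudocount, log_base)
        if (text, NTM) in counts:
            lop_ntm = build_lop(counts[(text, NTM)], background,
                                pseudocount, log_base)
        out[text] = classify_motif(labels[text], lop_tm, lop_ntm,
                                   min_occurrences)
    return out


def annotate_graph(
    graph: MotifGraph,
    classifications: Mapping[str, MotifClassification | str],
) -> MotifGraph:
    """Set every node's topology state from the classification table.

    Nodes without a classification become ``unclassified``. Edges are
    untouched; returns a new graph.
    """
    out = graph.copy()
    for node in out.nx.nodes:
        cls = classifications.get(node)
        if cls is None:
            out.nx.nodes[node]["topology_state"] = UNCLASSIFIED
        else:
            out.nx.nodes[node]["topology_state"] = (
                cls if isinstance(cls, str) else cls.state
            )
    return out


def write_classification_tsv(
    classifications: Mapping[str, MotifClassification], path: str | Path
) -> None:
    """Export the classification table (label, state, scores, counts)."""
    with open(path, "w") as fh:
        fh.write("label\tstate\tscore_tm\tscore_ntm\tn_tm\tn_ntm\n")
        for text in sorted(classifications):
            c = classifications[text]
            fh.write(
                f"{c.label}\t{c.state}\t{c.score_tm:.6f}\t"
                f"{c.score_ntm:.6f}\t{c.n_tm}\t{c.n_ntm}\n"
            )
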