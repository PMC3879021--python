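"""Sequence and per-residue topology I/O.

Reads protein sequences (FASTA), per-residue membrane-topology information
(either a TMHMM-style posterior-probability table or a simple state TSV),
assigns each residue a topology state (``TM`` / ``nTM`` / ``ambiguous``)
from the posteriors, and slices out maximal runs of membrane-spanning
residues.

Coordinate conventions: all file dialects are 1-based inclusive; everything
in memory is 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 canonical one-letter amino-acid codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Canonical residues plus 'X' for unknown.
ALPHABET = frozenset(AMINO_ACIDS) | {"X"}

TM = "TM"
NTM = "nTM"
AMBIGUOUS = "ambiguous"
STATES = (TM, NTM, AMBIGUOUS)

#: Kyte-Doolittle hydropathy scale (kcal/mol-free units, positive =
#: hydrophobic). 'X' is treated as neutral (0.0).
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence: the unit all motif extraction runs over."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r} contains characters outside the "
                f"21-letter alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ResidueTopologyTrack:
    """Per-residue topology posteriors and/or assigned states.

    ``posteriors`` holds one ``(p_inside, p_membrane, p_outside)`` triple
    per residue when the track came from a posterior table; ``states``
    holds one label from :data:`STATES` per residue once assigned.
    """

    protein_id: str
    posteriors: list[tuple[float, float, float]] | None = None
    states: list[str] | None = None

    def __len__(self) -> int:
        if self.states is not None:
            return len(self.states)
        if self.posteriors is not None:
            return len(self.posteriors)
        return 0


@dataclass(frozen=True)
class TMSegment:
    """A maximal run of same-state residues within one protein.

    Segments are produced for the membrane (``TM``) state when slicing
    helices, and for the ``nTM`` state when harvesting the non-membrane
    background for topology profiles; ``state`` records which.
    """

    protein_id: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    subsequence: str
    state: str = TM

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError("segment must contain at least one residue")
        if len(self.subsequence) != self.end - self.start:
            raise ValueError("subsequence length does not match [start, end)")

    def __len__(self) -> int:
        return self.end - self.start


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased; characters outside the 21-letter alphabet are
    replaced by ``'X'`` with a logged warning. A record with an empty
    sequence is a hard error naming the record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"FASTA record {rec.id!r} has an empty sequence")
        cleaned = []
        replaced: set[str] = set()
        for ch in seq:
            if ch in ALPHABET:
                cleaned.append(ch)
            else:
                cleaned.append("X")
                replaced.add(ch)
        if replaced:
            logger.warning(
                "record %s: replaced non-standard residues %s with 'X'",
                rec.id, sorted(replaced),
            )
        records.append(
            ProteinRecord(id=rec.id, sequence="".join(cleaned),
                          description=rec.description)
        )
    if not records:
        raise ValueError(f"FASTA file {path} contains no records")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records to FASTA (60-column wrapping via Biopython)."""
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id,
                  description=r.description or "")
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def _check_probability(value: float, where: str) -> float:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"probability {value} outside [0, 1] at {where}")
    return value


def parse_tmhmm_posteriors(
    path: str | Path, *, sum_tolerance: float = 0.02
) -> dict[str, ResidueTopologyTrack]:
    """Parse a TMHMM-style per-residue posterior table.

    Whitespace-separated rows ``index residue p_inside p_membrane
    p_outside`` with 1-based consecutive indices. A comment line whose sole
    token after ``#`` names a protein starts a new block (``# <id>``);
    other ``#`` lines are ignored. A file with no header lines is a single
    protein named after the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    tracks: dict[str, ResidueTopologyTrack] = {}
    current_id = path.stem
    current: list[tuple[float, float, float]] = []

    def flush() -> None:
        if current:
            if current_id in tracks:
                raise ValueError(f"duplicate protein block {current_id!r}")
            tracks[current_id] = ResidueTopologyTrack(
                protein_id=current_id, posteriors=list(current)
            )
            current.clear()

    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            tokens = line[1:].split()
            if len(tokens) == 1:  # "# <protein_id>" header
                flush()
                current_id = tokens[0]
            continue
        fields = line.split()
        if len(fields) != 5:
            raise ValueError(
                f"{path}:{lineno}: expected 5 columns, got {len(fields)}"
            )
        idx = int(fields[0])
        if idx != len(current) + 1:
            raise ValueError(
                f"{path}:{lineno}: non-consecutive residue index {idx} "
                f"(expected {len(current) + 1}) for {current_id!r}"
            )
        where = f"{path}:{lineno}"
        triple = tuple(
            _check_probability(float(v), where) for v in fields[2:5]
        )
        total = sum(triple)
        if abs(total - 1.0) > sum_tolerance:
            raise ValueError(
                f"{where}: posteriors sum to {total:.4f}, not 1 "
                f"within ±{sum_tolerance}"
            )
        current.append(triple)  # type: ignore[arg-type]
    flush()
    if not tracks:
        raise ValueError(f"posterior table {path} contains no rows")
    return tracks


def parse_topology_tsv(path: str | Path) -> dict[str, ResidueTopologyTrack]:
    """Parse the simple per-residue state TSV.

    Columns ``protein_id``, ``position`` (1-based), ``state`` in
    {TM, nTM, ambiguous} (case-insensitive). Positions must be contiguous
    from 1 per protein; a duplicate (protein, position) is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    state_map = {s.lower(): s for s in STATES}
    per_protein: dict[str, dict[int, str]] = {}
    lines = path.read_text().splitlines()
    start = 0
    if lines and lines[0].lower().startswith("protein_id"):
        start = 1
    for lineno, raw in enumerate(lines[start:], start=start + 1):
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 columns")
        pid, pos_s, state_s = fields
        state = state_map.get(state_s.strip().lower())
        if state is None:
            raise ValueError(
                f"{path}:{lineno}: unknown state token {state_s!r}"
            )
        pos = int(pos_s)
        if pos < 1:
            raise ValueError(f"{path}:{lineno}: position must be >= 1")
        bucket = per_protein.setdefault(pid, {})
        if pos in bucket:
            raise ValueError(
                f"{path}:{lineno}: duplicate position {pos} for {pid!r}"
            )
        bucket[pos] = state
    tracks: dict[str, ResidueTopologyTrack] = {}
    for pid, bucket in per_protein.items():
        n = max(bucket)
        if set(bucket) != set(range(1, n + 1)):
            missing = sorted(set(range(1, n + 1)) - set(bucket))[:5]
            raise ValueError(
                f"{path}: protein {pid!r} is missing positions {missing}"
            )
        tracks[pid] = ResidueTopologyTrack(
            protein_id=pid, states=[bucket[i] for i in range(1, n + 1)]
        )
    return tracks


def write_topology_tsv(
    tracks: Mapping[str, ResidueTopologyTrack], path: str | Path
) -> None:
    """Write assigned states in the topology TSV dialect (1-based)."""
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\tstate\n")
        for pid, track in tracks.items():
            if track.states is None:
                raise ValueError(f"track {pid!r} has no assigned states")
            for i, state in enumerate(track.states, start=1):
                fh.write(f"{pid}\t{i}\t{state}\n")


def assign_states(
    track: ResidueTopologyTrack,
    threshold: float = 0.9,
    *,
    ntm_rule: str = "max",
) -> ResidueTopologyTrack:
    """Assign TM / nTM / ambiguous states from posteriors.

    A residue is ``TM`` when its membrane posterior strictly exceeds
    ``threshold``; it is ``nTM`` when the extra/intra-cellular evidence
    exceeds the threshold, judged either by the larger of the inside and
    outside posteriors (``ntm_rule='max'``, the default, since the two are
    competing states) or by their sum (``ntm_rule='sum'``). Everything
    else is ``ambiguous``. Returns a new track; the input is unmodified.
    """
    if track.posteriors is None:
        raise ValueError(
            f"track {track.protein_id!r} has no posteriors; parse states "
            "directly with parse_topology_tsv instead"
        )
    if ntm_rule not in ("max", "sum"):
        raise ValueError(f"unknown ntm_rule {ntm_rule!r}")
    states = []
    for p_in, p_mem, p_out in track.posteriors:
        if p_mem > threshold:
            states.append(TM)
        else:
            evidence = (p_in + p_out) if ntm_rule == "sum" else max(p_in, p_out)
            states.append(NTM if evidence > threshold else AMBIGUOUS)
    return replace(track, states=states)


def extract_state_runs(
    record: ProteinRecord, track: ResidueTopologyTrack, state: str
) -> list[TMSegment]:
    """All maximal runs of ``state`` residues, disjoint and in order."""
    if track.states is None:
        raise ValueError(f"track {track.protein_id!r} has no assigned states")
    if len(track.states) != len(record.sequence):
        raise ValueError(
            f"track length {len(track.states)} does not match sequence "
            f"length {len(record.sequence)} for {record.id!r}"
        )
    runs: list[TMSegment] = []
    start = None
    for i, s in enumerate(track.states):
        if s == state and start is None:
            start = i
        elif s != state and start is not None:
            runs.append(TMSegment(record.id, start, i,
                                  record.sequence[start:i], state))
            start = None
    if start is not None:
        n = len(record.sequence)
        runs.append(TMSegment(record.id, start, n,
                              record.sequence[start:n], state))
    return runs


def extract_tm_segments(
    record: ProteinRecord, track: ResidueTopologyTrack
) -> list[TMSegment]:
    """All maximal transmembrane segments of a protein.

    Ambiguous residues break runs exactly as nTM residues do: only
    residues firmly assigned ``TM`` enter a segment.
    """
    return extract_state_runs(record, track, TM)


def hydropathy_fallback(
    record: ProteinRecord, window: int = 19, cutoff: float = 1.6
) -> ResidueTopologyTrack:
    """Sliding-window mean-hydropathy topology stand-in.

    Kyte-Doolittle windowed mean; a residue whose centred window mean
    strictly exceeds ``cutoff`` is TM, otherwise nTM. Termini where the
    window does not fit are ambiguous. Deterministic; useful when no
    posterior table is available.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if window > len(record.sequence):
        raise ValueError(
            f"window {window} larger than sequence ({len(record.sequence)})"
        )
    half = window // 2
    scores = [KYTE_DOOLITTLE[ch] for ch in record.sequence]
    states = [AMBIGUOUS] * len(scores)
    running = sum(scores[:window])
    for i in range(half, len(scores) - half):
        mean = running / window
        states[i] = TM if mean > cutoff else NTM
        if i + half + 1 < len(scores):
            running += scores[i + half + 1] - scores[i - half]
    return ResidueTopologyTrack(protein_id=record.id, states=states)
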