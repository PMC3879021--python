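"""Deterministic synthetic membrane-protein data.

Generates protein-like sequences with a known alternation of
non-membrane (nTM) loops and membrane-spanning (TM) helices, residues
drawn i.i.d. from state-specific composition tables (hydrophobic-enriched
inside the membrane, polar-enriched outside), and optionally "plants"
chosen motif-architectures at recorded positions so the whole pipeline
can be validated against ground truth. A single integer seed fixes every
byte of the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from .motifs import MotifLabel
from .sequence_io import (AMINO_ACIDS, NTM, TM, ProteinRecord,
                          ResidueTopologyTrack, write_fasta,
                          write_topology_tsv)


def _composition(elevated: dict[str, float]) -> dict[str, float]:
    rest = (1.0 - sum(elevated.values())) / (len(AMINO_ACIDS) - len(elevated))
    return {aa: elevated.get(aa, rest) for aa in AMINO_ACIDS}


#: Hydrophobic-enriched membrane-helix composition (elevated A, L, V, I, G, F).
DEFAULT_TM_COMPOSITION = _composition(
    {"A": 0.11, "L": 0.15, "V": 0.11, "I": 0.10, "G": 0.08, "F": 0.07}
)
#: Polar-enriched loop composition (elevated S, N, P, Y, D, K).
DEFAULT_NTM_COMPOSITION = _composition(
    {"S": 0.10, "N": 0.08, "P": 0.08, "Y": 0.06, "D": 0.08, "K": 0.08}
)


def _as_labels(labels: Sequence[MotifLabel | str]) -> tuple[MotifLabel, ...]:
    return tuple(
        lab if isinstance(lab, MotifLabel) else MotifLabel.parse(lab)
        for lab in labels
    )


@dataclass
class SynthesisConfig:
    """Study conditions for one synthetic dataset.

    Defaults: helices of 18-28 residues, loops of 5-40, one to seven
    helices per protein (seven-helix bundles being the classic
    polytopic example), with the hydrophobic/polar composition split
    above. ``planted`` lists (4-label architecture, copies) pairs to
    embed in randomly chosen helices.
    """

    n_proteins: int = 10
    tm_length_range: tuple[int, int] = (18, 28)
    ntm_length_range: tuple[int, int] = (5, 40)
    helices_per_protein_range: tuple[int, int] = (1, 7)
    tm_composition: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TM_COMPOSITION))
    ntm_composition: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NTM_COMPOSITION))
    planted: list[tuple[tuple[MotifLabel, ...], int]] = field(
        default_factory=list)
    emit_posteriors: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name, comp in (("tm_composition", self.tm_composition),
                           ("ntm_composition", self.ntm_composition)):
            if set(comp) != set(AMINO_ACIDS):
                raise ValueError(f"{name} must cover the 20 amino acids")
            if abs(sum(comp.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        for name, (lo, hi) in (
                ("tm_length_range", self.tm_length_range),
                ("ntm_length_range", self.ntm_length_range),
                ("helices_per_protein_range", self.helices_per_protein_range)):
            if lo > hi or lo < 0:
                raise ValueError(f"{name} is empty or negative: ({lo}, {hi})")
        if self.n_proteins < 0:
            raise ValueError("n_proteins must be >= 0")
        self.planted = [(_as_labels(labels), count)
                        for labels, count in self.planted]


class TruthEntry(NamedTuple):
    """Ground-truth location of one planted architecture."""

    protein_id: str
    segment_start: int  # 0-based start of the helix in the protein
    arch_start: int     # 0-based offset of the architecture in the helix
    labels: tuple[MotifLabel, ...]


class SyntheticDataset(NamedTuple):
    records: list[ProteinRecord]
    tracks: dict[str, ResidueTopologyTrack]
    truth: list[TruthEntry]


def plant_architecture(
    buffer: list[str],
    labels: Sequence[MotifLabel | str],
    offset: int,
    rng: np.random.Generator,
    composition: dict[str, float] | None = None,
) -> list[str]:
    """Write a chained architecture's anchors into a residue buffer.

    Anchor residues X/Y land at the chained offsets (each motif starts on
    the residue after the previous one ends); variable positions are
    redrawn from ``composition`` (default: the hydrophobic helix table).
    Modifies and returns ``buffer``.
    """
    labels = _as_labels(labels)
    comp = composition if composition is not None else DEFAULT_TM_COMPOSITION
    aa = list(AMINO_ACIDS)
    probs = np.array([comp[a] for a in aa])
    span = sum(lab.n + 1 for lab in labels)
    if offset < 0 or offset + span > len(buffer):
        raise ValueError(
            f"architecture span {span} at offset {offset} overflows "
            f"buffer of length {len(buffer)}"
        )
    pos = offset
    for lab in labels:
        buffer[pos] = lab.x
        for k in range(1, lab.n):
            buffer[pos + k] = str(rng.choice(aa, p=probs))
        buffer[pos + lab.n] = lab.y
        pos += lab.n + 1
    return buffer


def _sample_run(rng: np.random.Generator, length: int,
                comp: dict[str, float]) -> list[str]:
    aa = list(AMINO_ACIDS)
    probs = np.array([comp[a] for a in aa])
    return list(rng.choice(aa, size=length, p=probs))


def sample_dataset(config: SynthesisConfig) -> SyntheticDataset:
    """Generate sequences, exact topology tracks, and the truth table.

    Each protein alternates loop / helix / loop / ... starting and ending
    with a loop. Posterior triples, when enabled, put probability 1 on
    the true channel (helices on the membrane channel; loops alternate
    inside / outside). Identical config and seed give byte-identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    records: list[ProteinRecord] = []
    tracks: dict[str, ResidueTopologyTrack] = {}
    # (protein index, helix start, buffer, occupied intervals)
    helix_slots: list[dict] = []
    layouts: list[list[tuple[str, list[str]]]] = []

    tm_lo, tm_hi = config.tm_length_range
    nt_lo, nt_hi = config.ntm_length_range
    h_lo, h_hi = config.helices_per_protein_range
    for i in range(config.n_proteins):
        pid = f"syn{i:04d}"
        n_helices = int(rng.integers(h_lo, h_hi + 1))
        runs: list[tuple[str, list[str]]] = []
        runs.append((NTM, _sample_run(
            rng, int(rng.integers(nt_lo, nt_hi + 1)), config.ntm_composition)))
        for _ in range(n_helices):
            runs.append((TM, _sample_run(
                rng, int(rng.integers(tm_lo, tm_hi + 1)),
                config.tm_composition)))
            runs.append((NTM, _sample_run(
                rng, int(rng.integers(nt_lo, nt_hi + 1)),
                config.ntm_composition)))
        layouts.append(runs)
        pos = 0
        for state, buf in runs:
            if state == TM:
                helix_slots.append({"protein": i, "start": pos,
                                    "buffer": buf, "occupied": []})
            pos += len(buf)

    truth: list[TruthEntry] = []
    for labels, count in config.planted:
        span = sum(lab.n + 1 for lab in labels)
        if span > tm_hi:
            raise ValueError(
                f"architecture {'-'.join(l.text for l in labels)} spans "
                f"{span} residues but helices are at most {tm_hi} long"
            )
        for _ in range(count):
            placed = False
            for slot_idx in rng.permutation(len(helix_slots)):
                slot = helix_slots[int(slot_idx)]
                free = [
                    o for o in range(len(slot["buffer"]) - span + 1)
                    if all(o + span <= s or o >= e
                           for s, e in slot["occupied"])
                ]
                if not free:
                    continue
                offset = int(rng.choice(free))
                plant_architecture(slot["buffer"], labels, offset, rng,
                                   config.tm_composition)
                slot["occupied"].append((offset, offset + span))
                truth.append(TruthEntry(
                    protein_id=f"syn{slot['protein']:04d}",
                    segment_start=slot["start"], arch_start=offset,
                    labels=tuple(labels),
                ))
                placed = True
                break
            if not placed:
                raise ValueError(
                    "no helix has room left for another planted architecture"
                )

    for i, runs in enumerate(layouts):
        pid = f"syn{i:04d}"
        sequence = "".join("".join(buf) for _, buf in runs)
        states: list[str] = []
        posteriors: list[tuple[float, float, float]] | None = (
            [] if config.emit_posteriors else None)
        loop_parity = 0
        for state, buf in runs:
            states.extend([state] * len(buf))
            if posteriors is not None:
                if state == TM:
                    triple = (0.0, 1.0, 0.0)
                else:
                    triple = (1.0, 0.0, 0.0) if loop_parity == 0 \
                        else (0.0, 0.0, 1.0)
                    loop_parity ^= 1
                posteriors.extend([triple] * len(buf))
        records.append(ProteinRecord(id=pid, sequence=sequence,
                                     description="synthetic"))
        tracks[pid] = ResidueTopologyTrack(
            protein_id=pid, posteriors=posteriors, states=states)
    truth.sort(key=lambda t: (t.protein_id, t.segment_start, t.arch_start))
    return SyntheticDataset(records=records, tracks=tracks, truth=truth)


def sample_position_counts(
    label: MotifLabel,
    state: str,
    n_occurrences: int,
    composition: dict[str, float],
    rng: np.random.Generator,
):
    """Variable-position counts for a motif generated under one state.

    Emulates ``n_occurrences`` motif occurrences whose variable positions
    are i.i.d. draws from ``composition`` — the same residue model the
    sequence generator uses — without materialising sequences. Used by
    the profile parameter-recovery experiments.
    """
    from .profiles import PositionCounts

    probs = np.array([composition[a] for a in AMINO_ACIDS])
    counts = np.vstack([rng.multinomial(n_occurrences, probs)
                        for _ in range(label.n - 1)])
    return PositionCounts(label=label, state=state, counts=counts,
                          total_occurrences=n_occurrences)


def write_truth_tsv(truth: Sequence[TruthEntry], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tsegment_start\tarch_start\t"
                 "label1\tlabel2\tlabel3\tlabel4\n")
        for t in truth:
            labels = "\t".join(lab.text for lab in t.labels)
            fh.write(f"{t.protein_id}\t{t.segment_start}\t"
                     f"{t.arch_start}\t{labels}\n")


def read_truth_tsv(path: str | Path) -> list[TruthEntry]:
    lines = Path(path).read_text().splitlines()
    out: list[TruthEntry] = []
    for raw in lines[1:]:
        if not raw.strip():
            continue
        pid, seg, arch, *labels = raw.split("\t")
        out.append(TruthEntry(
            protein_id=pid, segment_start=int(seg), arch_start=int(arch),
            labels=tuple(MotifLabel.parse(t) for t in labels),
        ))
    return out


def write_posterior_table(
    tracks: dict[str, ResidueTopologyTrack], sequences: dict[str, str],
    path: str | Path,
) -> None:
    """Write a concatenated TMHMM-style posterior table (``# <id>`` blocks)."""
    with open(path, "w") as fh:
        for pid, track in tracks.items():
            if track.posteriors is None:
                raise ValueError(f"track {pid!r} has no posteriors")
            fh.write(f"# {pid}\n")
            seq = sequences[pid]
            for i, (p_in, p_mem, p_out) in enumerate(track.posteriors):
                fh.write(f"{i + 1} {seq[i]} {p_in:.3f} {p_mem:.3f} "
                         f"{p_out:.3f}\n")


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA, topology TSV, truth TSV (and posteriors if present).

    Everything round-trips losslessly through the ``sequence_io``
    parsers. Returns the paths written, keyed by role.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "sequences.fasta",
        "topology": outdir / "topology.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(dataset.records, paths["fasta"])
    write_topology_tsv(dataset.tracks, paths["topology"])
    write_truth_tsv(dataset.truth, paths["truth"])
    if any(t.posteriors is not None for t in dataset.tracks.values()):
        paths["posteriors"] = outdir / "posteriors.txt"
        write_posterior_table(
            dataset.tracks, {r.id: r.sequence for r in dataset.records},
            paths["posteriors"])
    return paths
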