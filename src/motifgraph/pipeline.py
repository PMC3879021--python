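"""End-to-end workflow: sequences + topology in, annotated graphs out.

Stages: parse inputs -> assign per-residue states -> slice maximal TM
segments (and nTM runs for the profile background) -> extract XYn motif
occurrences -> enumerate four-motif architectures -> build per-segment
graphs -> merge into the main graph -> build log-odds profiles and
classify motif topology -> annotate nodes -> optionally reduce by edge
weight -> export tables, graphs, and a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

from . import architectures as arch_mod
from . import graph as graph_mod
from . import motifs as motif_mod
from . import profiles as prof_mod
from . import sequence_io as seqio
from .config import RunConfig

logger = logging.getLogger(__name__)

_FORMAT_EXT = {"graphml": "graphml", "dot": "dot", "edge_tsv": "tsv"}


class StageError(RuntimeError):
    """An error attributed to a named pipeline stage."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_tracks(config: RunConfig) -> dict[str, seqio.ResidueTopologyTrack]:
    path = Path(config.topology)
    fmt = config.topology_format
    if fmt == "auto":
        fmt = "tsv" if path.suffix.lower() == ".tsv" else "tmhmm"
    if fmt == "tsv":
        return seqio.parse_topology_tsv(path)
    tracks = seqio.parse_tmhmm_posteriors(path)
    return {
        pid: seqio.assign_states(track, config.state_threshold,
                                 ntm_rule=config.ntm_rule)
        for pid, track in tracks.items()
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the whole workflow; returns the manifest dictionary.

    Writes, under ``config.outdir``: the occurrence and architecture
    tables, the classification table, the annotated main graph (and the
    reduced graph when an edge threshold is configured, otherwise a
    weight histogram to guide choosing one), and ``manifest.json``. Any
    stage failure removes the partial outputs and raises
    :class:`StageError`.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(config, outdir, written)
    except StageError:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    except Exception as exc:  # attribute unexpected failures to a stage too
        for p in written:
            p.unlink(missing_ok=True)
        raise StageError("internal", str(exc)) from exc


def _run(config: RunConfig, outdir: Path, written: list[Path]) -> dict:
    fmt_label = lambda lab: motif_mod.format_label(  # noqa: E731
        lab, config.label_convention)

    # -- inputs -----------------------------------------------------------
    if config.fasta is None or config.topology is None:
        raise StageError("inputs", "fasta and topology paths are required")
    try:
        records = seqio.read_fasta(config.fasta)
    except (OSError, ValueError) as exc:
        raise StageError("read_fasta", str(exc)) from exc
    try:
        tracks = _load_tracks(config)
    except (OSError, ValueError) as exc:
        raise StageError("read_topology", str(exc)) from exc

    # -- states and segments ----------------------------------------------
    tm_segments: dict[str, list[seqio.TMSegment]] = {}
    ntm_runs: dict[str, list[seqio.TMSegment]] = {}
    for rec in records:
        track = tracks.get(rec.id)
        if track is None:
            raise StageError("segments",
                             f"no topology track for protein {rec.id!r}")
        try:
            tm_segments[rec.id] = seqio.extract_tm_segments(rec, track)
            ntm_runs[rec.id] = seqio.extract_state_runs(rec, track, seqio.NTM)
        except ValueError as exc:
            raise StageError("segments", str(exc)) from exc

    # -- motif occurrences --------------------------------------------------
    n_range = tuple(config.n_range)
    tm_occurrences: list[motif_mod.MotifOccurrence] = []
    per_segment: list[tuple[seqio.TMSegment,
                            list[motif_mod.MotifOccurrence]]] = []
    for rec in records:
        for seg in tm_segments[rec.id]:
            occs = motif_mod.extract_occurrences(seg, n_range)
            per_segment.append((seg, occs))
            tm_occurrences.extend(occs)
    ntm_occurrences: list[motif_mod.MotifOccurrence] = []
    for rec in records:
        for run in ntm_runs[rec.id]:
            ntm_occurrences.extend(motif_mod.extract_occurrences(run, n_range))
    labels = motif_mod.unique_labels(tm_occurrences)

    occ_path = outdir / "occurrences.tsv"
    written.append(occ_path)
    with open(occ_path, "w") as fh:
        fh.write("protein_id\tsegment_start\toffset_in_segment\tlabel\tn\n")
        for seg, occs in per_segment:
            for occ in occs:
                fh.write(f"{seg.protein_id}\t{seg.start}\t{occ.offset}\t"
                         f"{fmt_label(occ.label)}\t{occ.label.n}\n")

    # -- architectures ------------------------------------------------------
    all_archs: list[arch_mod.MotifArchitecture] = []
    segment_graphs: list[graph_mod.MotifGraph] = []
    arch_path = outdir / "architectures.tsv"
    written.append(arch_path)
    size = config.architecture_size
    with open(arch_path, "w") as fh:
        header_labels = "\t".join(f"label{i + 1}" for i in range(size))
        fh.write(f"protein_id\tsegment_start\tarch_start\t{header_labels}\n")
        for seg, occs in per_segment:
            archs = arch_mod.enumerate_architectures(occs, seg, size)
            all_archs.extend(archs)
            segment_graphs.append(graph_mod.build_segment_graph(archs))
            for a in archs:
                row_labels = "\t".join(fmt_label(lab) for lab in a.labels)
                fh.write(f"{seg.protein_id}\t{seg.start}\t{a.start}\t"
                         f"{row_labels}\n")

    # -- main graph ---------------------------------------------------------
    main_graph = graph_mod.build_main_graph(segment_graphs, config.merge_mode)

    # -- topology profiles and classification -------------------------------
    try:
        if config.background_source == "file":
            background = prof_mod.natural_background(
                "file", path=config.background)
        elif config.background_source == "builtin":
            background = prof_mod.natural_background("builtin")
        else:
            background = prof_mod.natural_background(
                "dataset", records=records)
        counts = prof_mod.collect_position_counts(
            {seqio.TM: tm_occurrences, seqio.NTM: ntm_occurrences})
        classifications = prof_mod.classify_all(
            counts, background, config.pseudocount, config.log_base,
            config.min_occurrences)
    except ValueError as exc:
        raise StageError("classify", str(exc)) from exc
    cls_path = outdir / "classifications.tsv"
    written.append(cls_path)
    prof_mod.write_classification_tsv(classifications, cls_path)

    annotated = prof_mod.annotate_graph(main_graph, classifications)

    # -- reduction and export -----------------------------------------------
    ext = _FORMAT_EXT[config.export_format]
    main_path = outdir / f"main_graph.{ext}"
    written.append(main_path)
    graph_mod.export_graph(annotated, main_path, config.export_format,
                           config.n_bins, config.bin_mode)
    reduced = None
    if config.edge_threshold is not None:
        reduced = graph_mod.filter_edges(annotated, config.edge_threshold)
        reduced_path = outdir / f"reduced_graph.{ext}"
        written.append(reduced_path)
        graph_mod.export_graph(reduced, reduced_path, config.export_format,
                               config.n_bins, config.bin_mode)
    else:
        hist_path = outdir / "weight_histogram.tsv"
        written.append(hist_path)
        hist: dict[int, int] = {}
        for _, _, w in annotated.edges():
            hist[w] = hist.get(w, 0) + 1
        with open(hist_path, "w") as fh:
            fh.write("weight\tn_edges\n")
            for w in sorted(hist):
                fh.write(f"{w}\t{hist[w]}\n")

    # -- manifest -----------------------------------------------------------
    digests = {"fasta": _sha256(Path(config.fasta)),
               "topology": _sha256(Path(config.topology))}
    if config.background_source == "file" and config.background:
        digests["background"] = _sha256(Path(config.background))
    by_state = {"TM": 0, "nTM": 0, "unclassified": 0}
    for c in classifications.values():
        by_state[c.state] += 1
    manifest = {
        "config": config.to_dict(),
        "input_digests": digests,
        "counts": {
            "proteins": len(records),
            "residues": sum(len(r) for r in records),
            "tm_segments": sum(len(v) for v in tm_segments.values()),
            "ntm_runs": sum(len(v) for v in ntm_runs.values()),
            "tm_occurrences": len(tm_occurrences),
            "ntm_occurrences": len(ntm_occurrences),
            "unique_labels": len(labels),
            "architectures": len(all_archs),
            "classified": by_state,
        },
        "main_graph": {
            "nodes": annotated.node_count,
            "edges": annotated.edge_count,
            "total_weight": annotated.total_weight,
        },
    }
    if reduced is not None:
        manifest["reduced_graph"] = {
            "nodes": reduced.node_count,
            "edges": reduced.edge_count,
            "total_weight": reduced.total_weight,
        }
    manifest_path = outdir / "manifest.json"
    written.append(manifest_path)
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True)
                             + "\n")
    logger.info(
        "pipeline finished: %d proteins, %d TM segments, %d occurrences, "
        "%d architectures, main graph %d/%d nodes/edges",
        len(records), manifest["counts"]["tm_segments"],
        len(tm_occurrences), len(all_archs),
        annotated.node_count, annotated.edge_count,
    )
    return manifest
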