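"""Weighted directed motif co-occurrence graphs.

Each motif-architecture contributes a tiny graph — its four motifs as
nodes, its three consecutive pairs as weight-1 edge increments. Per-
segment graphs merge those; the main graph merges all segment graphs,
accumulating edge weights. The main graph is then reduced by an edge-
weight threshold, hub motifs are scored by weighted degree, and edge
weights are binned onto a colour scale for export.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx

from .architectures import MotifArchitecture

UNCLASSIFIED = "unclassified"

MERGE_MODES = ("sum", "presence")
EXPORT_FORMATS = ("graphml", "dot", "edge_tsv")


class MotifGraph:
    """Directed graph of motif labels with integer edge weights.

    Node attributes: ``topology_state`` (TM / nTM / unclassified) and
    ``occurrence_count`` (how many architecture slots the motif filled).
    Edge attribute: ``weight`` (positive integer). Backed by a
    :class:`networkx.DiGraph`; the raw graph is reachable as ``.nx``.
    """

    __slots__ = ("nx",)

    def __init__(self, graph: nx.DiGraph | None = None) -> None:
        self.nx = graph if graph is not None else nx.DiGraph()

    # -- construction -----------------------------------------------------
    def add_motif(self, label: str, count: int = 0,
                  state: str = UNCLASSIFIED) -> None:
        g = self.nx
        if label in g:
            g.nodes[label]["occurrence_count"] += count
            if state != UNCLASSIFIED:
                g.nodes[label]["topology_state"] = state
        else:
            g.add_node(label, topology_state=state, occurrence_count=count)

    def add_edge_weight(self, source: str, target: str, weight: int = 1) -> None:
        if source not in self.nx or target not in self.nx:
            raise KeyError("edge endpoints must be existing motif nodes")
        if weight < 1:
            raise ValueError("edge weight increments must be >= 1")
        data = self.nx.get_edge_data(source, target)
        if data is None:
            self.nx.add_edge(source, target, weight=weight)
        else:
            data["weight"] += weight

    # -- views ------------------------------------------------------------
    @property
    def node_count(self) -> int:
        return self.nx.number_of_nodes()

    @property
    def edge_count(self) -> int:
        return self.nx.number_of_edges()

    @property
    def total_weight(self) -> int:
        return sum(w for _, _, w in self.edges())

    def nodes(self) -> list[str]:
        return list(self.nx.nodes)

    def node_attrs(self, label: str) -> dict:
        return dict(self.nx.nodes[label])

    def edges(self) -> list[tuple[str, str, int]]:
        return [(u, v, d["weight"]) for u, v, d in self.nx.edges(data=True)]

    def weight(self, source: str, target: str) -> int:
        return self.nx[source][target]["weight"]

    def has_edge(self, source: str, target: str) -> bool:
        return self.nx.has_edge(source, target)

    def copy(self) -> "MotifGraph":
        return MotifGraph(self.nx.copy())

    def __contains__(self, label: str) -> bool:
        return label in self.nx

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MotifGraph):
            return NotImplemented
        a, b = self.nx, other.nx
        if set(a.nodes) != set(b.nodes):
            return False
        for n in a.nodes:
            if (a.nodes[n].get("topology_state"),
                    a.nodes[n].get("occurrence_count")) != (
                    b.nodes[n].get("topology_state"),
                    b.nodes[n].get("occurrence_count")):
                return False
        if set(a.edges) != set(b.edges):
            return False
        return all(a[u][v]["weight"] == b[u][v]["weight"] for u, v in a.edges)

    def __repr__(self) -> str:
        return (f"MotifGraph(nodes={self.node_count}, "
                f"edges={self.edge_count}, total_weight={self.total_weight})")


def graph_from_architecture(arch: MotifArchitecture) -> MotifGraph:
    """One architecture as a graph: <=4 nodes, 3 edge-increment events.

    Consecutive pairs with identical (source, target) labels accumulate
    onto the same edge (self-chains produce self-loops).
    """
    g = MotifGraph()
    labels = [m.label.text for m in arch.motifs]
    for lab in labels:
        g.add_motif(lab, count=1)
    for src, dst in zip(labels, labels[1:]):
        g.add_edge_weight(src, dst, 1)
    return g


def merge_graphs(graphs: Sequence[MotifGraph], mode: str = "sum") -> MotifGraph:
    """Union of nodes and edges with accumulated attributes.

    ``occurrence_count`` sums; a non-unclassified topology state wins over
    unclassified. Edge weights either sum across inputs (``mode='sum'``)
    or count the number of input graphs containing the edge
    (``mode='presence'``).
    """
    if mode not in MERGE_MODES:
        raise ValueError(f"unknown merge mode {mode!r}")
    out = MotifGraph()
    for g in graphs:
        for label in g.nx.nodes:
            attrs = g.nx.nodes[label]
            out.add_motif(label, count=attrs.get("occurrence_count", 0),
                          state=attrs.get("topology_state", UNCLASSIFIED))
        for u, v, w in g.edges():
            out.add_edge_weight(u, v, w if mode == "sum" else 1)
    return out


def build_segment_graph(archs: Sequence[MotifArchitecture]) -> MotifGraph:
    """Merge (sum mode) of the per-architecture graphs of one segment.

    Accumulates directly instead of materialising one graph per
    architecture; total edge weight is 3 x len(archs) for size-4 frames.
    """
    g = MotifGraph()
    for arch in archs:
        labels = [m.label.text for m in arch.motifs]
        for lab in labels:
            g.add_motif(lab, count=1)
        for src, dst in zip(labels, labels[1:]):
            g.add_edge_weight(src, dst, 1)
    return g


def build_main_graph(segment_graphs: Sequence[MotifGraph],
                     mode: str = "sum") -> MotifGraph:
    """Merge all per-segment graphs into the dataset's main graph."""
    return merge_graphs(segment_graphs, mode=mode)


def filter_edges(graph: MotifGraph, min_weight: int) -> MotifGraph:
    """Reduce a graph by keeping edges with weight >= ``min_weight``.

    Nodes that lose their last incident edge are removed; nodes that were
    isolated before the call are kept, so ``min_weight=0`` is the
    identity. The input graph is unmodified.
    """
    if min_weight < 0:
        raise ValueError("min_weight must be >= 0")
    out = graph.copy()
    g = out.nx
    doomed_edges = [(u, v) for u, v, d in g.edges(data=True)
                    if d["weight"] < min_weight]
    had_edges = {n for n in g.nodes
                 if g.in_degree(n) > 0 or g.out_degree(n) > 0}
    g.remove_edges_from(doomed_edges)
    doomed_nodes = [n for n in had_edges
                    if g.in_degree(n) == 0 and g.out_degree(n) == 0]
    g.remove_nodes_from(doomed_nodes)
    return out


def hub_scores(graph: MotifGraph) -> dict[str, int]:
    """Weighted total degree per motif (self-loops counted twice).

    Hubs are motifs that participate in many architectures with many
    partners; in-strength plus out-strength captures exactly that.
    """
    g = graph.nx
    return {
        n: g.in_degree(n, weight="weight") + g.out_degree(n, weight="weight")
        for n in g.nodes
    }


def top_hubs(graph: MotifGraph, k: int) -> list[tuple[str, int]]:
    """The k highest-scoring motifs; ties broken alphabetically."""
    if k < 0:
        raise ValueError("k must be >= 0")
    scores = hub_scores(graph)
    ranked = sorted(scores.items(), key=lambda item: (-item[1], item[0]))
    return ranked[:k]


def edge_color_bins(graph: MotifGraph, n_bins: int = 5,
                    bin_mode: str = "width") -> dict[tuple[str, str], int]:
    """Assign each edge a colour-scale bin index in [0, n_bins).

    ``width`` mode partitions [min_weight, max_weight] into equal-width
    intervals; ``frequency`` mode uses equal-count quantile boundaries.
    Bin ``n_bins - 1`` is the heaviest ("red") bin; a graph whose edges
    all share one weight maps everything to the top bin.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if bin_mode not in ("width", "frequency"):
        raise ValueError(f"unknown bin_mode {bin_mode!r}")
    edges = graph.edges()
    if not edges:
        return {}
    weights = [w for _, _, w in edges]
    lo, hi = min(weights), max(weights)
    if lo == hi:
        return {(u, v): n_bins - 1 for u, v, _ in edges}
    if bin_mode == "width":
        scale = n_bins / (hi - lo)
        return {(u, v): min(n_bins - 1, int((w - lo) * scale))
                for u, v, w in edges}
    ordered = sorted(weights)
    bounds = [ordered[min(len(ordered) - 1, (len(ordered) * (i + 1)) // n_bins - 1)]
              for i in range(n_bins - 1)]
    out = {}
    for u, v, w in edges:
        b = 0
        while b < n_bins - 1 and w > bounds[b]:
            b += 1
        out[(u, v)] = b
    return out


def _dot_escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


def export_graph(graph: MotifGraph, path: str | Path, format: str,
                 n_bins: int = 5, bin_mode: str = "width") -> None:
    """Write a graph to GraphML, DOT, or an edge TSV.

    All formats carry the node attributes ``topology_state`` and
    ``occurrence_count`` (where the format has nodes) and the edge
    attributes ``weight`` and ``color_bin``. GraphML re-imports exactly
    via :func:`read_graphml`.
    """
    if format not in EXPORT_FORMATS:
        raise ValueError(f"unknown export format {format!r}")
    path = Path(path)
    bins = edge_color_bins(graph, n_bins=n_bins, bin_mode=bin_mode)
    if format == "graphml":
        g = graph.nx.copy()
        for (u, v), b in bins.items():
            g[u][v]["color_bin"] = b
        nx.write_graphml(g, str(path), infer_numeric_types=False)
        return
    if format == "edge_tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\tcolor_bin\n")
            for u, v, w in graph.edges():
                fh.write(f"{u}\t{v}\t{w}\t{bins[(u, v)]}\n")
        return
    lines = ["digraph motifs {"]
    for n in graph.nodes():
        attrs = graph.node_attrs(n)
        lines.append(
            f'  "{_dot_escape(n)}" '
            f'[topology_state="{attrs["topology_state"]}", '
            f'occurrence_count={attrs["occurrence_count"]}];'
        )
    for u, v, w in graph.edges():
        lines.append(
            f'  "{_dot_escape(u)}" -> "{_dot_escape(v)}" '
            f'[weight={w}, color_bin={bins[(u, v)]}];'
        )
    lines.append("}")
    path.write_text("\n".join(lines) + "\n")


def read_graphml(path: str | Path) -> MotifGraph:
    """Read a GraphML file written by :func:`export_graph`."""
    g = nx.read_graphml(str(path))
    out = nx.DiGraph()
    for n, attrs in g.nodes(data=True):
        out.add_node(
            n,
            topology_state=str(attrs.get("topology_state", UNCLASSIFIED)),
            occurrence_count=int(attrs.get("occurrence_count", 0)),
        )
    for u, v, attrs in g.edges(data=True):
        out.add_edge(u, v, weight=int(attrs["weight"]))
        if "color_bin" in attrs:
            out[u][v]["color_bin"] = int(attrs["color_bin"])
    return MotifGraph(out)
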