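"""Declarative run configuration.

One YAML file drives the whole workflow; every tunable constant of the
library modules appears here with the module's own default. Unknown keys
are rejected so typos never silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml


@dataclass
class RunConfig:
    fasta: str | None = None
    topology: str | None = None
    topology_format: str = "auto"        # auto | tsv | tmhmm
    background_source: str = "dataset"   # dataset | builtin | file
    background: str | None = None
    n_range: list[int] = field(default_factory=lambda: [4, 5, 6, 7])
    architecture_size: int = 4
    state_threshold: float = 0.9
    ntm_rule: str = "max"                # max | sum
    merge_mode: str = "sum"              # sum | presence
    edge_threshold: int | None = None
    pseudocount: float = 1.0
    log_base: float = 2.0
    min_occurrences: int = 5
    n_bins: int = 5
    bin_mode: str = "width"              # width | frequency
    label_convention: str = "span"       # span | gap
    export_format: str = "graphml"       # graphml | dot | edge_tsv
    outdir: str = "motifgraph_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_range or any(n < 2 for n in self.n_range):
            raise ValueError("n_range must be non-empty with all n >= 2")
        if self.architecture_size < 1:
            raise ValueError("architecture_size must be >= 1")
        if not 0.0 <= self.state_threshold <= 1.0:
            raise ValueError("state_threshold must be in [0, 1]")
        if self.ntm_rule not in ("max", "sum"):
            raise ValueError(f"unknown ntm_rule {self.ntm_rule!r}")
        if self.merge_mode not in ("sum", "presence"):
            raise ValueError(f"unknown merge_mode {self.merge_mode!r}")
        if self.edge_threshold is not None and self.edge_threshold < 0:
            raise ValueError("edge_threshold must be >= 0")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.log_base <= 1.0:
            raise ValueError("log_base must be > 1")
        if self.topology_format not in ("auto", "tsv", "tmhmm"):
            raise ValueError(
                f"unknown topology_format {self.topology_format!r}")
        if self.background_source not in ("dataset", "builtin", "file"):
            raise ValueError(
                f"unknown background_source {self.background_source!r}")
        if self.bin_mode not in ("width", "frequency"):
            raise ValueError(f"unknown bin_mode {self.bin_mode!r}")
        if self.label_convention not in ("span", "gap"):
            raise ValueError(
                f"unknown label_convention {self.label_convention!r}")
        if self.export_format not in ("graphml", "dot", "edge_tsv"):
            raise ValueError(
                f"unknown export_format {self.export_format!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(
                f"unknown config keys in {path}: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return {f.name: getattr(self, f.name) for f in fields(self)}
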