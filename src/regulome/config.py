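"""Run-wide configuration.

All thresholds used across the pipeline live in one dataclass so that a
single YAML file can reproduce an analysis end to end.  Defaults are the
cut-offs used throughout the study design this package implements:
Pearson-|r| and Bonferroni limits for target classification, the log2
fold-change shift bound, coverage and delta-beta limits for methylation
calls, and the motif-scanning significance levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # target classification
    r_thresh: float = 0.15
    bonferroni_alpha: float = 1e-4
    # knockdown fold-change shift
    fc_shift: float = 0.25
    padj: float = 0.05
    # motif scanning / enrichment
    fimo_p: float = 1e-3
    motif_q: float = 0.05
    enrich_p: float = 1e-3
    evalue_max: float = 10.0
    n_draws: int = 10
    # methylation
    min_cov_cell: int = 7
    min_cov_tumor: int = 10
    delta_beta: float = 0.15
    # bootstraps
    n_boot_concordance: int = 10000
    n_boot_overlap: int = 1000
    # misc
    seed: int = 1
    promoter_window: tuple[int, int] = (2000, 500)  # (upstream, downstream)

    def __post_init__(self) -> None:
        for name in (
            "r_thresh", "bonferroni_alpha", "fc_shift", "padj", "fimo_p",
            "motif_q", "enrich_p", "evalue_max", "min_cov_cell",
            "min_cov_tumor", "delta_beta", "n_boot_concordance",
            "n_boot_overlap", "n_draws",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name!r} must be positive")
        for name in ("bonferroni_alpha", "padj", "fimo_p", "motif_q", "enrich_p"):
            if not (0.0 < getattr(self, name) <= 1.0):
                raise ValueError(f"probability threshold {name!r} must be in (0, 1]")
        self.promoter_window = tuple(self.promoter_window)  # type: ignore[assignment]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["promoter_window"] = list(self.promoter_window)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
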