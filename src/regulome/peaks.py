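"""Consensus ChIP-seq peaks and genotype categorization.

Replicate peak calls for one condition are intersected pairwise; each
intersection is re-centered on its summit (the interval midpoint,
floored for even lengths) and limited to a fixed-width window, 100 bp
either side by default, clipped at the chromosome start.  Consensus
sets from two conditions are then intersected/subtracted to label each
peak ``common``, ``A_specific`` or ``B_specific``, and peaks are
annotated to genes through promoter windows around the TSS
(-2000/+500 bp by default, strand-aware).

All coordinates are 0-based half-open throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from collections import defaultdict

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "consensus_from_replicates",
    "categorize_peaks",
    "annotate_to_promoters",
]

COMMON = "common"
A_SPECIFIC = "A_specific"
B_SPECIFIC = "B_specific"


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must be > start ({self.start})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """A peak interval with its summit and provenance label."""

    interval: GenomicInterval
    summit: int
    source: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside interval "
                f"[{self.interval.start}, {self.interval.end})"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    tss: int


def midpoint_summit(start: int, end: int) -> int:
    """Summit of an interval: floor of the midpoint."""
    return (start + end) // 2


def _by_chrom(peaks) -> dict[str, list[Peak]]:
    d: dict[str, list[Peak]] = defaultdict(list)
    for p in peaks:
        d[p.chrom].append(p)
    for chrom in d:
        d[chrom].sort(key=lambda p: (p.start, p.end))
    return d


def consensus_from_replicates(rep1, rep2, half_window: int = 100,
                              source: str = "") -> list[Peak]:
    """Consensus peaks from two replicate peak sets.

    Every pair of replicate peaks overlapping by >= 1 bp yields one
    consensus peak: the intersection interval's midpoint becomes the
    summit, and the peak is re-emitted as ``[summit - half_window,
    summit + half_window)`` clipped at position 0.
    """
    if half_window < 1:
        raise ValueError("half_window must be >= 1")
    out: list[Peak] = []
    r2 = _by_chrom(rep2)
    for chrom, peaks1 in sorted(_by_chrom(rep1).items()):
        others = r2.get(chrom, [])
        starts2 = np.array([p.start for p in others])
        ends2 = np.array([p.end for p in others])
        for p in peaks1:
            if len(others) == 0:
                continue
            hits = np.nonzero((starts2 < p.end) & (ends2 > p.start))[0]
            for j in hits:
                s = max(p.start, int(starts2[j]))
                e = min(p.end, int(ends2[j]))
                summit = midpoint_summit(s, e)
                lo = max(0, summit - half_window)
                hi = summit + half_window
                out.append(
                    Peak(
                        interval=GenomicInterval(chrom, lo, hi),
                        summit=summit,
                        source=source,
                        name=f"{chrom}:{lo}-{hi}",
                    )
                )
    return out


def categorize_peaks(set_a, set_b) -> list[Peak]:
    """Label two consensus peak sets as common / A- / B-specific.

    A peak in A overlapping any peak in B by >= 1 bp becomes a
    ``common`` record (reported once, with A's coordinates); A peaks
    without any B overlap are ``A_specific`` and symmetrically for B.
    The labels partition all reported peaks.
    """
    out: list[Peak] = []
    b_by_chrom = _by_chrom(set_b)
    a_by_chrom = _by_chrom(set_a)

    def _overlap_mask(peaks, other_by_chrom):
        mask = []
        for p in peaks:
            others = other_by_chrom.get(p.chrom, [])
            mask.append(
                any(o.start < p.end and o.end > p.start for o in others)
            )
        return mask

    a_list = list(set_a)
    b_list = list(set_b)
    a_hit = _overlap_mask(a_list, b_by_chrom)
    b_hit = _overlap_mask(b_list, a_by_chrom)
    for p, hit in zip(a_list, a_hit):
        out.append(replace(p, source=COMMON if hit else A_SPECIFIC))
    for p, hit in zip(b_list, b_hit):
        if not hit:
            out.append(replace(p, source=B_SPECIFIC))
    return out


def promoter_window(gene: GeneModel, upstream: int = 2000,
                    downstream: int = 500) -> GenomicInterval:
    """Strand-aware promoter window around a gene's TSS."""
    if gene.strand == "-":
        lo, hi = gene.tss - downstream, gene.tss + upstream
    else:
        lo, hi = gene.tss - upstream, gene.tss + downstream
    return GenomicInterval(gene.chrom, max(0, lo), hi, gene.strand)


def annotate_to_promoters(peaks, genes, upstream: int = 2000,
                          downstream: int = 500) -> pd.DataFrame:
    """Assign peaks to genes whose promoter window they overlap.

    A peak is assigned to *every* gene whose promoter it overlaps by
    >= 1 bp; peaks without any assignment are reported once with
    gene_id NA and category ``distal``.  ``distance_to_tss`` is the
    signed summit-to-TSS offset in the gene's reading direction.
    """
    windows = defaultdict(list)
    for g in genes:
        windows[g.chrom].append((g, promoter_window(g, upstream, downstream)))
    rows = []
    for p in peaks:
        assigned = False
        for g, w in windows.get(p.chrom, []):
            if w.start < p.end and w.end > p.start:
                dist = p.summit - g.tss
                if g.strand == "-":
                    dist = -dist
                rows.append(
                    {
                        "peak_id": p.name or f"{p.chrom}:{p.start}-{p.end}",
                        "gene_id": g.gene_id,
                        "category": p.source or "promoter",
                        "distance_to_tss": dist,
                    }
                )
                assigned = True
        if not assigned:
            rows.append(
                {
                    "peak_id": p.name or f"{p.chrom}:{p.start}-{p.end}",
                    "gene_id": pd.NA,
                    "category": "distal",
                    "distance_to_tss": pd.NA,
                }
            )
    return pd.DataFrame(
        rows, columns=["peak_id", "gene_id", "category", "distance_to_tss"]
    )
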