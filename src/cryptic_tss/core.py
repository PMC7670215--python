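"""Core domain containers shared across the pipeline.

Coordinate conventions, used consistently everywhere:

* interval-valued entities (peaks, clusters, exons, promoter windows) are
  0-based half-open ``[start, end)`` — the BED convention;
* single-base TSS positions (CTSS positions, dominant positions, annotated
  TSSs) are 1-based — the CTSS convention.

Conversion between the two happens only at well-marked points
(``pos - 1`` when a 1-based base enters an interval computation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand: {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """≥1 bp intersection, strand-agnostic."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class CtssProfile:
    """Per-sample 5'-end tag counts at single-base resolution.

    ``records`` is a DataFrame with columns (chrom, pos, strand, count);
    ``pos`` is 1-based; at most one row per (chrom, pos, strand).
    """

    sample_id: str
    condition: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        req = ["chrom", "pos", "strand", "count"]
        missing = [c for c in req if c not in self.records.columns]
        if missing:
            raise ValueError(f"CtssProfile records missing columns: {missing}")
        if len(self.records) and (self.records["count"] < 0).any():
            raise ValueError("negative tag count")
        if len(self.records) and (self.records["pos"] < 1).any():
            raise ValueError("CTSS positions are 1-based; found pos < 1")

    @property
    def library_size(self) -> int:
        return int(self.records["count"].sum())


@dataclass
class GeneModel:
    """A gene with its transcript exon structures and annotated 5' ends."""

    gene_id: str
    interval: GenomicInterval
    transcripts: list[list[GenomicInterval]]
    annotated_tss: list[int]  # 1-based
    expression: float = 0.0
    occupancy_label: str | None = None  # {"high", "low", None}

    def exon_union(self) -> list[tuple[int, int]]:
        """Merged union of all exons across transcripts (0-based half-open)."""
        spans = sorted(
            (e.start, e.end) for tx in self.transcripts for e in tx
        )
        merged: list[tuple[int, int]] = []
        for s, e in spans:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return merged

    def introns(self) -> list[tuple[int, int]]:
        """Gene-body bases not covered by any exon."""
        out: list[tuple[int, int]] = []
        prev = self.interval.start
        for s, e in self.exon_union():
            if s > prev:
                out.append((prev, s))
            prev = max(prev, e)
        if prev < self.interval.end:
            out.append((prev, self.interval.end))
        return out


@dataclass
class PeakSet:
    """A named collection of intervals (ATAC, H3K27ac, CpG islands, ...)."""

    name: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))

    def __len__(self) -> int:
        return len(self.intervals)

    def by_chrom(self) -> dict[str, np.ndarray]:
        """chrom → (n, 2) array of [start, end), sorted."""
        out: dict[str, list[tuple[int, int]]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append((iv.start, iv.end))
        return {c: np.asarray(v, dtype=np.int64) for c, v in out.items()}


class SignalTrack:
    """Dense per-base coverage, one float array per chromosome."""

    def __init__(self, name: str, data: Mapping[str, np.ndarray]):
        self.name = name
        self.data: dict[str, np.ndarray] = {}
        for chrom, arr in data.items():
            arr = np.asarray(arr, dtype=np.float64)
            if arr.ndim != 1:
                raise ValueError("per-chromosome coverage must be 1-D")
            if np.any(arr < 0):
                raise ValueError(f"negative coverage on {chrom}")
            self.data[chrom] = arr

    def value(self, chrom: str, pos0: int) -> float:
        """Coverage at a 0-based position (0.0 outside known chromosomes)."""
        arr = self.data.get(chrom)
        if arr is None or not (0 <= pos0 < arr.size):
            return 0.0
        return float(arr[pos0])

    def chrom_length(self, chrom: str) -> int:
        return int(self.data[chrom].size)


def merge_intervals(spans: Iterable[tuple[int, int]], gap: int = 0) -> list[tuple[int, int]]:
    """Merge sorted-or-unsorted (start, end) spans whose gap is ≤ ``gap``."""
    spans = sorted(spans)
    out: list[tuple[int, int]] = []
    for s, e in spans:
        if out and s - out[-1][1] <= gap:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out
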