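"""Genomic categorization and sequence characterization of TSS clusters.

Each consensus cluster is assigned exactly one of four categories by its
dominant position, with priority annotated_promoter > exonic > intronic >
intergenic. Gene-linked categories require a sense-strand match (CAGE is
stranded; an antisense hit falls through to the next category). Clusters
are additionally flagged when they intersect ATAC or H3K27ac peaks (the
enhancer/eRNA filter), and characterized by GC fraction and CpG-island
overlap.
"""

from __future__ import annotations

import numpy as np

from .annotation import AnnotationIndex
from .clustering import ConsensusCluster
from .core import GenomicInterval, PeakSet

CATEGORIES = ("annotated_promoter", "exonic", "intronic", "intergenic")
_FEATURE_TO_CATEGORY = {"promoter": "annotated_promoter", "exon": "exonic", "intron": "intronic"}
INTRAGENIC = ("exonic", "intronic")


def categorize(cluster: ConsensusCluster, index: AnnotationIndex) -> tuple[str, str]:
    """(category, host_gene_id) decided by the cluster's dominant position."""
    pos0 = cluster.dominant_pos - 1
    hits = index.query_point(cluster.interval.chrom, pos0, strand=cluster.strand)
    by_feature: dict[str, list[str]] = {}
    for h in hits:
        by_feature.setdefault(h.feature, []).append(h.gene_id)
    for feature in ("promoter", "exon", "intron"):
        if feature in by_feature:
            return _FEATURE_TO_CATEGORY[feature], sorted(by_feature[feature])[0]
    return "intergenic", ""


def categorize_all(clusters: list[ConsensusCluster], index: AnnotationIndex) -> None:
    """Assign category and host gene to every cluster in place."""
    for c in clusters:
        c.category, c.host_gene_id = categorize(c, index)


def flag_enhancer_overlap(clusters: list[ConsensusCluster], *peak_sets: PeakSet) -> None:
    """Set enhancer_overlap = True iff the cluster interval intersects ≥1 bp
    of any peak in any of the given sets (strand-agnostic, union rule)."""
    by_chrom = [ps.by_chrom() for ps in peak_sets]
    for c in clusters:
        c.enhancer_overlap = any(
            _interval_hits(arrs.get(c.interval.chrom), c.interval.start, c.interval.end)
            for arrs in by_chrom
        )


def _interval_hits(spans: np.ndarray | None, start: int, end: int) -> bool:
    if spans is None or spans.size == 0:
        return False
    # spans sorted by start; candidate = last span starting before `end`
    i = int(np.searchsorted(spans[:, 0], end, side="left"))
    return bool((spans[:i, 1] > start).any())


def peak_overlap_fraction(clusters: list[ConsensusCluster], peaks: PeakSet) -> dict[str, float]:
    """Per-category fraction of clusters intersecting the peak set."""
    arrs = peaks.by_chrom()
    totals: dict[str, int] = {}
    hits: dict[str, int] = {}
    for c in clusters:
        cat = c.category or "unassigned"
        totals[cat] = totals.get(cat, 0) + 1
        if _interval_hits(arrs.get(c.interval.chrom), c.interval.start, c.interval.end):
            hits[cat] = hits.get(cat, 0) + 1
    return {cat: hits.get(cat, 0) / n for cat, n in sorted(totals.items())}


def gc_fraction(cluster_or_interval, genome) -> float | None:
    """(#G + #C) / (#A + #C + #G + #T) over the interval; ambiguous bases
    are excluded from the denominator. None when no unambiguous base."""
    iv = getattr(cluster_or_interval, "interval", cluster_or_interval)
    seq = str(genome[iv.chrom][iv.start : iv.end]).upper()
    return gc_fraction_seq(seq)


def gc_fraction_seq(seq: str) -> float | None:
    gc = sum(seq.count(b) for b in "GC")
    at = sum(seq.count(b) for b in "AT")
    denom = gc + at
    if denom == 0:
        return None
    return gc / denom


def width_filter(clusters: list[ConsensusCluster], min_width_nt: int) -> list[ConsensusCluster]:
    """Retain clusters strictly wider than ``min_width_nt`` ("longer than")."""
    return [c for c in clusters if c.interval.width > min_width_nt]


def flag_cpg_overlap(clusters: list[ConsensusCluster], islands: PeakSet) -> None:
    arrs = islands.by_chrom()
    for c in clusters:
        c.cpg_island_overlap = _interval_hits(
            arrs.get(c.interval.chrom), c.interval.start, c.interval.end
        )


# ---------------------------------------------------------------------------
# CpG islands (Gardiner-Garden & Frommer criteria)

def _cpg_metrics(seq: str) -> tuple[float, float]:
    """(GC fraction, observed/expected CpG) of a sequence."""
    L = len(seq)
    c = seq.count("C")
    g = seq.count("G")
    cg = seq.count("CG")
    gcf = (c + g) / L if L else 0.0
    oe = (cg * L) / (c * g) if c and g else 0.0
    return gcf, oe


def call_cpg_islands(
    genome,
    min_len: int = 200,
    min_gc: float = 0.5,
    min_oe: float = 0.6,
    window: int = 200,
    name: str = "CpG_island",
) -> PeakSet:
    """Sliding-window CpG-island caller.

    Scans each chromosome with a ``window``-bp window at step 1; windows
    with GC ≥ min_gc and obs/exp CpG ≥ min_oe are merged when overlapping,
    and each merged interval is re-measured — intervals failing any
    criterion are trimmed back to a qualifying core so that every reported
    island satisfies all three criteria.
    """
    intervals: list[GenomicInterval] = []
    chroms = sorted(genome.keys()) if hasattr(genome, "keys") else sorted(genome)
    for chrom in chroms:
        seq = str(genome[chrom][:]).upper()
        L = len(seq)
        if L < window:
            continue
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        is_c = (arr == ord("C")).astype(np.int32)
        is_g = (arr == ord("G")).astype(np.int32)
        is_cg = np.zeros(L, dtype=np.int32)
        is_cg[:-1] = is_c[:-1] & is_g[1:]
        cum_c = np.concatenate(([0], np.cumsum(is_c)))
        cum_g = np.concatenate(([0], np.cumsum(is_g)))
        cum_cg = np.concatenate(([0], np.cumsum(is_cg)))
        n_win = L - window + 1
        wc = cum_c[window:window + n_win] - cum_c[:n_win]
        wg = cum_g[window:window + n_win] - cum_g[:n_win]
        # CG dinucleotides fully inside the window: starts in [i, i+window-1)
        wcg = cum_cg[window - 1 : window - 1 + n_win] - cum_cg[:n_win]
        gcf = (wc + wg) / window
        with np.errstate(divide="ignore", invalid="ignore"):
            oe = np.where((wc > 0) & (wg > 0), wcg * window / np.maximum(wc * wg, 1), 0.0)
        ok = (gcf >= min_gc) & (oe >= min_oe)
        starts = np.flatnonzero(ok)
        if starts.size == 0:
            continue
        # merge overlapping qualifying windows (runs of starts within `window`)
        run_start = starts[0]
        prev = starts[0]
        runs: list[tuple[int, int]] = []
        for s in starts[1:]:
            if s - prev >= window:  # windows no longer overlap
                runs.append((run_start, prev + window))
                run_start = s
            prev = s
        runs.append((run_start, prev + window))
        for s, e in runs:
            s2, e2 = _trim_island(seq, s, e, min_len, min_gc, min_oe, window)
            if e2 - s2 < min_len:
                # fall back to the first qualifying window of the run,
                # which satisfies all criteria by construction
                s2, e2 = s, s + window
            if e2 - s2 >= min_len:
                intervals.append(GenomicInterval(chrom, s2, e2))
    return PeakSet(name, intervals)


def _trim_island(seq, s, e, min_len, min_gc, min_oe, window):
    """Shrink [s, e) until it satisfies all criteria (a qualifying window
    exists inside, so termination at length `window` is guaranteed)."""
    while e - s >= min_len:
        gcf, oe = _cpg_metrics(seq[s:e])
        if gcf >= min_gc and oe >= min_oe:
            return s, e
        # trim the end whose flanking base contributes least GC
        left_gc = seq[s] in "GC"
        right_gc = seq[e - 1] in "GC"
        if not left_gc and right_gc:
            s += 1
        elif left_gc and not right_gc:
            e -= 1
        else:
            e -= 1
        if e - s < window:
            break
    return s, s  # no qualifying merged interval; drop (windows still covered)
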