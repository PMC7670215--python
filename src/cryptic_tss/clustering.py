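"""TP10M normalization and CTSS clustering.

Single-base CTSS counts are normalized to tags per 10 million (TP10M),
thresholded, and clustered per sample by greedy single-linkage over sorted
positions (CAGEr distclu-style): two surviving CTSSs join the same tag
cluster iff the distance between consecutive positions is ≤ ``max_gap``.
Per-sample tag clusters are then merged across samples into strand-specific
consensus clusters carrying a per-sample TP10M expression vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CtssProfile, GenomicInterval

TP10M_SCALE = 1e7


def normalize_tp10m(profile: CtssProfile) -> pd.DataFrame:
    """Per-position TP10M values: count / library_size × 10^7.

    Returns the records frame with an extra ``tp10m`` column; the values
    sum to exactly 10^7 (up to float rounding).
    """
    lib = profile.library_size
    if lib == 0:
        raise ValueError(f"empty library: {profile.sample_id}")
    df = profile.records.copy()
    df["tp10m"] = df["count"].to_numpy(dtype=np.float64) / lib * TP10M_SCALE
    return df


@dataclass
class TagCluster:
    interval: GenomicInterval
    positions: np.ndarray  # 1-based, sorted ascending
    counts: np.ndarray
    tp10ms: np.ndarray
    dominant_pos: int
    total_count: int
    tp10m: float

    @property
    def iq_width(self) -> int:
        return interquantile_width(self)


def _dominant(positions: np.ndarray, counts: np.ndarray, strand: str) -> int:
    """Position of the maximal count; 5'-most on ties (strand-aware)."""
    best = counts.max()
    cand = positions[counts == best]
    return int(cand.max() if strand == "-" else cand.min())


def cluster_ctss(
    profile: CtssProfile,
    max_gap: int = 20,
    min_tp10m: float = 0.5,
) -> dict[tuple[str, str], list[TagCluster]]:
    """Strand-separated single-linkage clustering of thresholded CTSSs.

    Returns {(chrom, strand): [TagCluster, ...]} with clusters sorted by
    coordinate. Positions with tp10m < min_tp10m are dropped before
    clustering.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be ≥ 0")
    df = normalize_tp10m(profile)
    df = df[df["tp10m"] >= min_tp10m]
    out: dict[tuple[str, str], list[TagCluster]] = {}
    for (chrom, strand), grp in df.groupby(["chrom", "strand"], sort=True):
        grp = grp.sort_values("pos", kind="mergesort")
        pos = grp["pos"].to_numpy(dtype=np.int64)
        cnt = grp["count"].to_numpy(dtype=np.int64)
        tpm = grp["tp10m"].to_numpy(dtype=np.float64)
        if pos.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > max_gap) + 1
        clusters = []
        for seg_pos, seg_cnt, seg_tpm in zip(
            np.split(pos, breaks), np.split(cnt, breaks), np.split(tpm, breaks)
        ):
            clusters.append(
                TagCluster(
                    interval=GenomicInterval(chrom, int(seg_pos[0]) - 1, int(seg_pos[-1]), strand),
                    positions=seg_pos,
                    counts=seg_cnt,
                    tp10ms=seg_tpm,
                    dominant_pos=_dominant(seg_pos, seg_cnt, strand),
                    total_count=int(seg_cnt.sum()),
                    tp10m=float(seg_tpm.sum()),
                )
            )
        out[(chrom, strand)] = clusters
    return out


def interquantile_width(cluster: TagCluster, q_low: float = 0.1, q_up: float = 0.9) -> int:
    """Width in bp between the positions holding the q_low and q_up
    quantiles of the cluster's tag mass, ordered 5'→3'."""
    if not (0 <= q_low < q_up <= 1):
        raise ValueError("need 0 ≤ q_low < q_up ≤ 1")
    if cluster.positions.size == 0:
        raise ValueError("empty cluster")
    if cluster.interval.strand == "-":
        pos = cluster.positions[::-1]
        cnt = cluster.counts[::-1]
    else:
        pos, cnt = cluster.positions, cluster.counts
    total = cnt.sum()
    cum = np.cumsum(cnt)
    i_low = int(np.searchsorted(cum, q_low * total, side="left"))
    i_up = int(np.searchsorted(cum, q_up * total, side="left"))
    i_low = min(i_low, pos.size - 1)
    i_up = min(i_up, pos.size - 1)
    return int(abs(int(pos[i_up]) - int(pos[i_low]))) + 1


@dataclass
class ConsensusCluster:
    id: str
    interval: GenomicInterval
    expression: dict[str, float]  # sample_id → tp10m (0 if absent)
    dominant_pos: int  # from the highest-expression sample
    category: str | None = None
    enhancer_overlap: bool = False
    host_gene_id: str = ""
    gc_fraction: float | None = None
    cpg_island_overlap: bool = False
    iq_width: int | None = None

    @property
    def strand(self) -> str:
        return self.interval.strand


def build_consensus(
    cluster_sets: dict[str, dict[tuple[str, str], list[TagCluster]]],
    merge_gap: int = 0,
) -> list[ConsensusCluster]:
    """Merge per-sample tag clusters into consensus clusters.

    Tag clusters from all samples on the same (chrom, strand) are merged
    when the gap between their intervals is ≤ merge_gap (overlap included).
    Each consensus carries one tp10m entry per input sample (0 when the
    sample has no overlapping tag cluster), and the dominant position of
    the overlapping tag cluster from the highest-expression sample.
    """
    if not cluster_sets:
        raise ValueError("need ≥1 sample")
    samples = sorted(cluster_sets)
    keys = sorted({k for cs in cluster_sets.values() for k in cs})
    out: list[ConsensusCluster] = []
    for chrom, strand in keys:
        entries = []  # (start, end, sample, cluster)
        for sample in samples:
            for tc in cluster_sets[sample].get((chrom, strand), []):
                entries.append((tc.interval.start, tc.interval.end, sample, tc))
        entries.sort(key=lambda e: (e[0], e[1]))
        block: list[tuple[int, int, str, TagCluster]] = []
        block_end = None
        for e in entries:
            if block and e[0] - block_end > merge_gap:
                out.append(_finish_block(chrom, strand, block, samples))
                block = []
            block.append(e)
            block_end = e[1] if block_end is None or len(block) == 1 else max(block_end, e[1])
        if block:
            out.append(_finish_block(chrom, strand, block, samples))
    out.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end, c.strand))
    for i, c in enumerate(out):
        c.id = f"C{i:06d}"
    return out


def _finish_block(chrom, strand, block, samples) -> ConsensusCluster:
    start = min(e[0] for e in block)
    end = max(e[1] for e in block)
    expr = {s: 0.0 for s in samples}
    best: tuple[float, TagCluster] | None = None
    width = None
    for _, _, sample, tc in block:
        expr[sample] += tc.tp10m
        if best is None or tc.tp10m > best[0]:
            best = (tc.tp10m, tc)
    # width statistic from the highest-expression member
    width = best[1].iq_width if best else None
    return ConsensusCluster(
        id="",
        interval=GenomicInterval(chrom, start, end, strand),
        expression=expr,
        dominant_pos=best[1].dominant_pos,
        iq_width=width,
    )


def expression_matrix(clusters: list[ConsensusCluster]) -> pd.DataFrame:
    """Clusters × samples TP10M matrix (index = consensus cluster id)."""
    rows = {c.id: c.expression for c in clusters}
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    return df[sorted(df.columns)]


def read_clusters_bed(path) -> list[ConsensusCluster]:
    """Read back a BED6+ file written by write_clusters_bed."""
    clusters: list[ConsensusCluster] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").lstrip("#").split("\t")
        samples = header[13:]
        for line in fh:
            f = line.rstrip("\n").split("\t")
            clusters.append(
                ConsensusCluster(
                    id=f[3],
                    interval=GenomicInterval(f[0], int(f[1]), int(f[2]), f[5]),
                    expression={s: float(v) for s, v in zip(samples, f[13:])},
                    dominant_pos=int(f[6]),
                    iq_width=int(f[7]) or None,
                    category=None if f[8] == "." else f[8],
                    enhancer_overlap=bool(int(f[9])),
                    host_gene_id="" if f[10] == "." else f[10],
                    gc_fraction=None if f[11] == "." else float(f[11]),
                    cpg_island_overlap=bool(int(f[12])),
                )
            )
    return clusters


def write_clusters_bed(clusters: list[ConsensusCluster], path) -> None:
    """BED6+ : name=id, score=round(total tp10m), then dominant_pos,
    iq_width, category, enhancer flag, host gene, gc fraction, CpG flag
    and per-sample tp10m columns."""
    samples = sorted(clusters[0].expression) if clusters else []
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\tdominant_pos\tiq_width\tcategory\t"
                 "enhancer_overlap\thost_gene\tgc_fraction\tcpg_overlap\t"
                 + "\t".join(samples) + "\n")
        for c in clusters:
            score = int(round(sum(c.expression.values())))
            gc = "." if c.gc_fraction is None else f"{c.gc_fraction:.4f}"
            fields = [
                c.interval.chrom, str(c.interval.start), str(c.interval.end), c.id,
                str(score), c.strand, str(c.dominant_pos), str(c.iq_width or 0),
                c.category or ".", str(int(c.enhancer_overlap)),
                c.host_gene_id or ".", gc, str(int(c.cpg_island_overlap)),
            ] + [f"{c.expression[s]:.4f}" for s in samples]
            fh.write("\t".join(fields) + "\n")
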