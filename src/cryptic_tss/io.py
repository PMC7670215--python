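"""Readers and writers for the text formats the pipeline touches.

Formats: 4-column CTSS text (chrom, 1-based pos, strand, count), BED3/6/12,
bedGraph, GTF, FASTA. All writers emit sorted, tab-separated, LF-terminated
output so that identical inputs always produce byte-identical files.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import gffutils
import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .core import CtssProfile, GeneModel, GenomicInterval, PeakSet, SignalTrack

log = logging.getLogger(__name__)


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# CTSS

def read_ctss(path: str | Path, sample_id: str | None = None, condition: str = "") -> CtssProfile:
    """Read a 4-column CTSS file; duplicate (chrom, pos, strand) lines are summed."""
    path = Path(path)
    rows: list[tuple[str, int, str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: expected ≥4 tab-separated fields")
            chrom, pos_s, strand, count_s = parts[0], parts[1], parts[2], parts[3]
            try:
                pos, count = int(pos_s), int(count_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer pos/count") from exc
            if count < 0:
                raise ParseError(f"{path}:{lineno}: negative count {count}")
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: invalid strand {strand!r}")
            rows.append((chrom, pos, strand, count))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "count"])
    if len(df):
        df = (
            df.groupby(["chrom", "pos", "strand"], as_index=False, sort=True)["count"]
            .sum()
        )
        df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)
    return CtssProfile(sample_id or path.stem, condition, df)


def write_ctss(profile: CtssProfile, path: str | Path) -> None:
    df = profile.records.sort_values(["chrom", "pos", "strand"], kind="mergesort")
    with open(path, "w") as fh:
        for chrom, pos, strand, count in df.itertuples(index=False):
            fh.write(f"{chrom}\t{pos}\t{strand}\t{count}\n")


# ---------------------------------------------------------------------------
# BED / bedGraph

def read_bed(path: str | Path, name: str | None = None) -> PeakSet:
    """Read BED3+ intervals (strand taken from column 6 when present)."""
    path = Path(path)
    ivs: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs ≥3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "."
            ivs.append(GenomicInterval(parts[0], start, end, strand))
    return PeakSet(name or path.stem, ivs)


def write_bed(peaks: PeakSet, path: str | Path, extra: dict[int, list] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(peaks.intervals):
            fields = [iv.chrom, str(iv.start), str(iv.end), f"{peaks.name}_{i}", "0", iv.strand]
            fh.write("\t".join(fields) + "\n")


def read_bedgraph(path: str | Path, name: str | None = None) -> SignalTrack:
    """Read a bedGraph into dense per-chromosome coverage.

    Overlapping intervals are rejected (the coverage would be ambiguous).
    Chromosome length is inferred from the right-most interval end.
    """
    path = Path(path)
    spans: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: bedGraph needs 4 fields")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if value < 0:
                raise ParseError(f"{path}:{lineno}: negative coverage")
            spans.setdefault(chrom, []).append((start, end, value))
    data: dict[str, np.ndarray] = {}
    for chrom, lst in spans.items():
        lst.sort()
        length = lst[-1][1]
        arr = np.zeros(length, dtype=np.float64)
        prev_end = -1
        for start, end, value in lst:
            if start < prev_end:
                raise ParseError(f"{path}: overlapping bedGraph intervals on {chrom} at {start}")
            arr[start:end] = value
            prev_end = end
        data[chrom] = arr
    return SignalTrack(name or path.stem, data)


def write_bedgraph(track: SignalTrack, path: str | Path, bin_size: int = 1) -> None:
    """Write coverage as a bedGraph, averaging within ``bin_size`` windows
    and run-length-merging equal adjacent values."""
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            arr = track.data[chrom]
            n = arr.size
            nbins = (n + bin_size - 1) // bin_size
            padded = np.full(nbins * bin_size, np.nan)
            padded[:n] = arr
            binned = np.nanmean(padded.reshape(nbins, bin_size), axis=1)
            binned = np.round(binned, 6)
            run_start = 0
            for b in range(1, nbins + 1):
                if b == nbins or binned[b] != binned[run_start]:
                    v = binned[run_start]
                    if v != 0.0:
                        s = run_start * bin_size
                        e = min(b * bin_size, n)
                        fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")
                    run_start = b


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> Fasta:
    """Random-access genome sequence (pyfaidx); lookup is 0-based slicing."""
    return Fasta(str(path), as_raw=True, sequence_always_upper=True)


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Annotation (GTF / BED12)

def read_annotation(path: str | Path, format: str = "gtf") -> list[GeneModel]:
    """Read a gene annotation into GeneModels.

    Annotated TSSs are the strand-aware 5' ends of each transcript
    (1-based): ``start + 1`` on the plus strand, ``end`` on the minus strand.
    """
    if format == "gtf":
        return _read_gtf(path)
    if format == "bed12":
        return _read_bed12(path)
    raise ValueError(f"unknown annotation format: {format!r}")


def _read_gtf(path: str | Path) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("gene", "transcript", "exon"):
            log.warning("skipping unknown feature type %r", feat.featuretype)
            continue
        gid = feat.attributes.get("gene_id", [None])[0]
        if gid is None:
            continue
        g = genes.setdefault(
            gid,
            {"chrom": feat.seqid, "strand": feat.strand, "min": feat.start - 1,
             "max": feat.end, "tx": {}},
        )
        g["min"] = min(g["min"], feat.start - 1)
        g["max"] = max(g["max"], feat.end)
        if feat.featuretype == "exon":
            tid = feat.attributes.get("transcript_id", ["tx"])[0]
            g["tx"].setdefault(tid, []).append(
                GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
            )
    out: list[GeneModel] = []
    for gid in sorted(genes):
        g = genes[gid]
        transcripts, tss = [], []
        for tid in sorted(g["tx"]):
            exons = sorted(g["tx"][tid], key=lambda e: e.start)
            transcripts.append(exons)
            if g["strand"] == "-":
                tss.append(exons[-1].end)  # 1-based 5' end on minus strand
            else:
                tss.append(exons[0].start + 1)
        out.append(
            GeneModel(
                gene_id=gid,
                interval=GenomicInterval(g["chrom"], g["min"], g["max"], g["strand"]),
                transcripts=transcripts,
                annotated_tss=sorted(set(tss)),
            )
        )
    return out


def _read_bed12(path: str | Path) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ParseError(f"{path}:{lineno}: BED12 needs 12 fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name, strand = parts[3], parts[5]
            block_sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            block_starts = [int(x) for x in parts[11].rstrip(",").split(",")]
            exons = [
                GenomicInterval(chrom, start + bs, start + bs + sz, strand)
                for bs, sz in zip(block_starts, block_sizes)
            ]
            gid = name.split(".")[0]  # transcripts named <gene>.<n> share a gene
            g = genes.setdefault(gid, {"chrom": chrom, "strand": strand,
                                       "min": start, "max": end, "tx": [], "tss": []})
            g["min"] = min(g["min"], start)
            g["max"] = max(g["max"], end)
            g["tx"].append(exons)
            g["tss"].append(end if strand == "-" else start + 1)
    out = []
    for gid in sorted(genes):
        g = genes[gid]
        out.append(
            GeneModel(
                gene_id=gid,
                interval=GenomicInterval(g["chrom"], g["min"], g["max"], g["strand"]),
                transcripts=g["tx"],
                annotated_tss=sorted(set(g["tss"])),
            )
        )
    return out


def write_gtf(genes: Iterable[GeneModel], path: str | Path, source: str = "cryptic_tss") -> None:
    with open(path, "w") as fh:
        for gene in genes:
            iv = gene.interval
            attrs = f'gene_id "{gene.gene_id}";'
            fh.write(
                f"{iv.chrom}\t{source}\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
            )
            for ti, exons in enumerate(gene.transcripts):
                tid = f"{gene.gene_id}.{ti + 1}"
                tattrs = f'gene_id "{gene.gene_id}"; transcript_id "{tid}";'
                ts = min(e.start for e in exons)
                te = max(e.end for e in exons)
                fh.write(
                    f"{iv.chrom}\t{source}\ttranscript\t{ts + 1}\t{te}\t.\t{iv.strand}\t.\t{tattrs}\n"
                )
                for e in sorted(exons, key=lambda x: x.start):
                    fh.write(
                        f"{iv.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t{iv.strand}\t.\t{tattrs}\n"
                    )


def write_bed12(genes: Iterable[GeneModel], path: str | Path) -> None:
    rows = []
    for gene in genes:
        for ti, exons in enumerate(gene.transcripts):
            exons = sorted(exons, key=lambda e: e.start)
            ts = exons[0].start
            te = exons[-1].end
            sizes = ",".join(str(e.width) for e in exons) + ","
            starts = ",".join(str(e.start - ts) for e in exons) + ","
            rows.append(
                (gene.interval.chrom, ts, te, f"{gene.gene_id}.{ti + 1}", 0,
                 gene.interval.strand, ts, te, "0,0,0", len(exons), sizes, starts)
            )
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")
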