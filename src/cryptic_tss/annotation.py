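"""Interval-queryable genome annotation index.

Builds promoter windows (annotated TSS ± halfwidth), exon, intron and
gene-body lookup trees from a list of GeneModels. Lookups are
deterministic: results are sorted by (feature, gene_id).
"""

from __future__ import annotations

from dataclasses import dataclass

from intervaltree import IntervalTree

from .core import GeneModel

FEATURES = ("promoter", "exon", "intron", "gene_body")


@dataclass
class Hit:
    feature: str
    gene_id: str
    strand: str


class AnnotationIndex:
    def __init__(self, genes: list[GeneModel], promoter_halfwidth: int = 500):
        if promoter_halfwidth <= 0:
            raise ValueError("promoter_halfwidth must be > 0")
        self.promoter_halfwidth = promoter_halfwidth
        self.genes = {g.gene_id: g for g in genes}
        self._trees: dict[str, dict[str, IntervalTree]] = {f: {} for f in FEATURES}
        for g in genes:
            chrom, strand = g.interval.chrom, g.interval.strand
            for tss in g.annotated_tss:
                lo = max(0, tss - 1 - promoter_halfwidth)
                hi = tss + promoter_halfwidth  # 0-based half-open [tss-1-hw, tss+hw)
                self._add("promoter", chrom, lo, hi, g.gene_id, strand)
            for s, e in g.exon_union():
                self._add("exon", chrom, s, e, g.gene_id, strand)
            for s, e in g.introns():
                self._add("intron", chrom, s, e, g.gene_id, strand)
            self._add("gene_body", chrom, g.interval.start, g.interval.end, g.gene_id, strand)

    def _add(self, feature: str, chrom: str, start: int, end: int, gene_id: str, strand: str) -> None:
        if end <= start:
            return
        tree = self._trees[feature].setdefault(chrom, IntervalTree())
        tree.addi(start, end, (gene_id, strand))

    def query_point(self, chrom: str, pos0: int, strand: str | None = None) -> list[Hit]:
        """All features overlapping a 0-based position.

        If ``strand`` is given, only sense-strand (matching) gene features
        are returned — CAGE is stranded, so antisense hits must not assign
        a cluster to a gene.
        """
        hits: list[Hit] = []
        for feature in FEATURES:
            tree = self._trees[feature].get(chrom)
            if tree is None:
                continue
            for iv in tree.at(pos0):
                gid, gstrand = iv.data
                if strand is not None and strand != gstrand:
                    continue
                hits.append(Hit(feature, gid, gstrand))
        hits.sort(key=lambda h: (FEATURES.index(h.feature), h.gene_id))
        return hits

    def query_interval(self, chrom: str, start: int, end: int, strand: str | None = None) -> list[Hit]:
        hits: list[Hit] = []
        seen: set[tuple[str, str]] = set()
        for feature in FEATURES:
            tree = self._trees[feature].get(chrom)
            if tree is None:
                continue
            for iv in tree.overlap(start, end):
                gid, gstrand = iv.data
                if strand is not None and strand != gstrand:
                    continue
                key = (feature, gid)
                if key not in seen:
                    seen.add(key)
                    hits.append(Hit(feature, gid, gstrand))
        hits.sort(key=lambda h: (FEATURES.index(h.feature), h.gene_id))
        return hits


def build_annotation_index(genes: list[GeneModel], promoter_halfwidth: int = 500) -> AnnotationIndex:
    return AnnotationIndex(genes, promoter_halfwidth)
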