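"""Synthetic genome, CAGE-like CTSS libraries, peak sets and signal tracks.

The generator emulates the statistical structure the analysis assumes:

* GC- and CpG-rich, broad annotated promoters in non-overlapping
  multi-exon genes on both strands, over ~40% GC background sequence;
* narrow (1–5 bp) GC-poor cryptic intragenic initiation sites,
  concentrated in highly expressed genes, with a multiplicative knockout
  effect (most Up, a minority Down) in a two-clone KO experiment;
* a second, position-disjoint pathway of cryptic sites (On + Up) measured
  in a separate single-KO experiment, so cross-pathway overlap and
  nearest-distance analyses can run;
* bidirectional intergenic enhancer sites co-located with ATAC and
  H3K27ac peaks;
* negative-binomial replicate noise (variance = μ + dispersion·μ²) on top
  of a uniform low-rate background tag process;
* ChIP-like coverage tracks with acetylation-style bumps at the ±1
  nucleosome positions flanking each active site.

All randomness flows from ``config.seed`` through independent
``numpy.random.SeedSequence`` streams, so every artifact is a pure
function of the config.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import call_cpg_islands
from .core import CtssProfile, GeneModel, GenomicInterval, PeakSet, SignalTrack
from . import io as tio

TRACK_NAMES = ("PolII_Ser5P", "FourSU", "H3K9ac", "H3K27ac")
_TRACK_SCALE = {"PolII_Ser5P": 1.0, "FourSU": 0.8, "H3K9ac": 1.2, "H3K27ac": 1.1}

PWWP2_EXPERIMENT = "pwwp2"
DNMT3B_EXPERIMENT = "dnmt3b"


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_chroms: int = 2
    genes_per_chrom: int = 100
    # quartile mean expected WT tags per replicate at the promoter
    quartile_mean_tags: dict = field(
        default_factory=lambda: {"High": 2000.0, "Intermediate": 400.0, "Low": 50.0, "No": 0.0}
    )
    expression_sigma: float = 0.3  # lognormal spread within quartile (natural log)
    # primary (HDAC-pathway) cryptic sites
    cryptic_count: int = 150
    cryptic_host_mix: dict = field(
        default_factory=lambda: {"High": 0.85, "Intermediate": 0.10, "Low": 0.05}
    )
    cryptic_mean_tags: float = 30.0
    cryptic_effect: float = 4.0
    cryptic_down_fraction: float = 0.10
    # second (DNA-methylation-pathway) cryptic sites, separate KO experiment
    dnmt3b_count: int = 80
    dnmt3b_host_mix: dict = field(
        default_factory=lambda: {"High": 0.70, "Intermediate": 0.20, "Low": 0.10}
    )
    dnmt3b_on_fraction: float = 0.6
    # enhancers
    enhancer_count: int = 30
    enhancer_mean_tags: float = 60.0
    # replicates
    wt_replicates: int = 3
    ko_replicates: tuple = (2, 3)  # KO clones A and B
    dnmt3b_wt_replicates: int = 2
    dnmt3b_ko_replicates: int = 2
    # noise
    dispersion: float = 0.1
    background_rate_per_kb: float = 0.05
    # site shapes
    promoter_spread_sd: float = 12.0
    promoter_spread_halfwidth: int = 40
    cryptic_max_width: int = 5
    # placement
    site_spacing: int = 2800
    site_jitter: int = 300
    tss_margin: int = 800  # cryptic sites at least this far from the annotated TSS
    gene_gap_range: tuple = (2500, 5500)
    exon_count_range: tuple = (4, 7)
    exon_len_range: tuple = (200, 400)
    intron_len_range: tuple = (1500, 3200)
    # sequence composition
    background_gc: float = 0.40
    promoter_gc: float = 0.60
    promoter_cpg_rate: float = 0.12
    promoter_seq_halfwidth: int = 300
    # peaks
    peak_halfwidth: int = 300
    # tracks
    track_bump_offset: int = 150
    track_bump_sd: float = 75.0
    ko_track_factor: float = 1.5
    track_height_sigma: float = 0.2
    occupancy_high_fraction: float = 0.1

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["ko_replicates"] = list(self.ko_replicates)
        for k in ("gene_gap_range", "exon_count_range", "exon_len_range", "intron_len_range"):
            d[k] = list(d[k])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = sorted(set(d) - known)
        if bad:
            raise ValueError(f"unknown config keys: {bad}")
        for k in ("ko_replicates", "gene_gap_range", "exon_count_range",
                  "exon_len_range", "intron_len_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class PlantedSite:
    site_id: str
    kind: str  # annotated_promoter | cryptic_exonic | cryptic_intronic | enhancer
    pathway: str  # "" | "pwwp2" | "dnmt3b"
    chrom: str
    pos: int  # 1-based mode position (the planted TSS)
    strand: str
    host_gene: str
    wt_mean: float
    ko_mean: float
    effect: float
    direction: str  # up | down | on | none
    offsets: np.ndarray = field(default_factory=lambda: np.zeros(1, dtype=np.int64))
    pmf: np.ndarray = field(default_factory=lambda: np.ones(1))


class SyntheticDataset:
    """Genome + annotation + planted truth, with CTSS/track simulators."""

    def __init__(self, config: SyntheticConfig):
        self.config = config
        self.genome: dict[str, str] = {}
        self.genes: list[GeneModel] = []
        self.sites: list[PlantedSite] = []
        self.atac: PeakSet = PeakSet("ATAC", [])
        self.h3k27ac: PeakSet = PeakSet("H3K27ac", [])
        self.cpg: PeakSet = PeakSet("CpG_island", [])

    # -- generation ---------------------------------------------------------

    @classmethod
    def generate(cls, config: SyntheticConfig) -> "SyntheticDataset":
        ds = cls(config)
        rng = np.random.default_rng([int(config.seed), 0])
        ds._place_genes(rng)
        ds._assign_expression(rng)
        ds._plant_sites(rng)
        ds._build_genome(rng)
        ds._build_peaks()
        ds.cpg = call_cpg_islands(ds.genome)
        return ds

    def _place_genes(self, rng) -> None:
        cfg = self.config
        self._chrom_lengths: dict[str, int] = {}
        self._gaps: list[tuple[str, int, int]] = []
        for ci in range(cfg.n_chroms):
            chrom = f"chr{ci + 1}"
            cursor = int(rng.integers(*cfg.gene_gap_range))
            for gi in range(cfg.genes_per_chrom):
                strand = "+" if rng.random() < 0.5 else "-"
                n_ex = int(rng.integers(cfg.exon_count_range[0], cfg.exon_count_range[1] + 1))
                ex_lens = rng.integers(cfg.exon_len_range[0], cfg.exon_len_range[1] + 1, n_ex)
                in_lens = rng.integers(cfg.intron_len_range[0], cfg.intron_len_range[1] + 1, n_ex - 1)
                start = cursor
                exons = []
                p = start
                for k in range(n_ex):
                    exons.append(GenomicInterval(chrom, p, p + int(ex_lens[k]), strand))
                    p += int(ex_lens[k])
                    if k < n_ex - 1:
                        p += int(in_lens[k])
                end = p
                tss = end if strand == "-" else start + 1
                gid = f"gene_{chrom}_{gi:03d}"
                self.genes.append(
                    GeneModel(gid, GenomicInterval(chrom, start, end, strand), [exons], [tss])
                )
                gap = int(rng.integers(*cfg.gene_gap_range))
                self._gaps.append((chrom, end, end + gap))
                cursor = end + gap
            self._chrom_lengths[chrom] = cursor + 2000

    def _assign_expression(self, rng) -> None:
        cfg = self.config
        genes = list(self.genes)
        order = rng.permutation(len(genes))
        groups = np.array_split(order, 4)
        self.gene_quartile: dict[str, str] = {}
        for grp_name, idxs in zip(("High", "Intermediate", "Low", "No"), groups):
            mean = cfg.quartile_mean_tags[grp_name]
            for i in idxs:
                g = genes[int(i)]
                self.gene_quartile[g.gene_id] = grp_name
                g.expression = float(mean * np.exp(rng.normal(0, cfg.expression_sigma))) if mean > 0 else 0.0
        # externally-supplied-style occupancy labels: top ~10% by expression
        ranked = sorted(genes, key=lambda g: (-g.expression, g.gene_id))
        n_high = max(1, int(round(cfg.occupancy_high_fraction * len(ranked)))) if ranked else 0
        for j, g in enumerate(ranked):
            g.occupancy_label = "high" if j < n_high else ("low" if g.expression > 0 else "none")

    # -- site planting ------------------------------------------------------

    def _gene_slots(self, rng) -> dict[str, list[tuple[GeneModel, int]]]:
        """Candidate cryptic positions (1-based) per quartile, ≥ site_spacing
        − jitter apart within and across genes."""
        cfg = self.config
        slots: dict[str, list[tuple[GeneModel, int]]] = {"High": [], "Intermediate": [], "Low": []}
        for g in self.genes:
            q = self.gene_quartile[g.gene_id]
            if q not in slots:
                continue
            iv = g.interval
            if iv.strand == "+":
                lo = iv.start + 1 + cfg.tss_margin
                hi = iv.end - 150
            else:
                lo = iv.start + 150
                hi = iv.end - cfg.tss_margin
            p = lo
            while p <= hi:
                slot = int(p + rng.integers(0, cfg.site_jitter))
                if slot <= hi:
                    slots[q].append((g, slot))
                p += cfg.site_spacing
        for q in slots:
            rng.shuffle(slots[q])
        return slots

    @staticmethod
    def _alloc(total: int, mix: dict) -> dict[str, int]:
        """Largest-remainder allocation of `total` over the mix fractions."""
        keys = sorted(mix)
        raw = {k: total * mix[k] for k in keys}
        base = {k: int(np.floor(raw[k])) for k in keys}
        rem = total - sum(base.values())
        for k in sorted(keys, key=lambda k: (-(raw[k] - base[k]), k))[:rem]:
            base[k] += 1
        return base

    def _site_kind(self, gene: GeneModel, pos: int) -> str:
        pos0 = pos - 1
        for s, e in gene.exon_union():
            if s <= pos0 < e:
                return "cryptic_exonic"
        return "cryptic_intronic"

    def _plant_sites(self, rng) -> None:
        cfg = self.config
        # promoters
        for g in self.genes:
            self.sites.append(
                PlantedSite(
                    site_id=f"prom_{g.gene_id}",
                    kind="annotated_promoter",
                    pathway="",
                    chrom=g.interval.chrom,
                    pos=g.annotated_tss[0],
                    strand=g.interval.strand,
                    host_gene=g.gene_id,
                    wt_mean=g.expression,
                    ko_mean=g.expression,
                    effect=1.0,
                    direction="none",
                    offsets=self._promoter_offsets(),
                    pmf=self._promoter_pmf(),
                )
            )
        # cryptic sites, two disjoint pathways drawn from one slot pool
        slots = self._gene_slots(rng)
        for pathway, count, mix in (
            (PWWP2_EXPERIMENT, cfg.cryptic_count, cfg.cryptic_host_mix),
            (DNMT3B_EXPERIMENT, cfg.dnmt3b_count, cfg.dnmt3b_host_mix),
        ):
            alloc = self._alloc(count, mix)
            chosen: list[tuple[GeneModel, int]] = []
            for q, n in alloc.items():
                if n > len(slots[q]):
                    raise ValueError(
                        f"cannot place {n} {pathway} cryptic sites in quartile {q} "
                        f"({len(slots[q])} slots available): use a larger genome"
                    )
                chosen.extend(slots[q][:n])
                slots[q] = slots[q][n:]
            if pathway == PWWP2_EXPERIMENT:
                n_down = int(round(cfg.cryptic_down_fraction * count))
                directions = ["down"] * n_down + ["up"] * (count - n_down)
            else:
                n_on = int(round(cfg.dnmt3b_on_fraction * count))
                directions = ["on"] * n_on + ["up"] * (count - n_on)
            rng.shuffle(directions)
            for k, ((gene, pos), direction) in enumerate(zip(chosen, directions)):
                base = cfg.cryptic_mean_tags
                if direction == "up":
                    wt, ko, eff = base, base * cfg.cryptic_effect, cfg.cryptic_effect
                elif direction == "down":
                    wt, ko, eff = base, base / cfg.cryptic_effect, 1.0 / cfg.cryptic_effect
                else:  # on
                    wt, ko, eff = 0.0, base * cfg.cryptic_effect, float("inf")
                width = int(rng.integers(1, cfg.cryptic_max_width + 1))
                pmf = 0.5 ** np.arange(width)
                self.sites.append(
                    PlantedSite(
                        site_id=f"{pathway}_{k:04d}",
                        kind=self._site_kind(gene, pos),
                        pathway=pathway,
                        chrom=gene.interval.chrom,
                        pos=pos,
                        strand=gene.interval.strand,
                        host_gene=gene.gene_id,
                        wt_mean=wt,
                        ko_mean=ko,
                        effect=eff,
                        direction=direction,
                        offsets=np.arange(width, dtype=np.int64),
                        pmf=pmf / pmf.sum(),
                    )
                )
        # enhancers in wide intergenic gaps
        wide = [(c, s, e) for c, s, e in self._gaps if e - s >= 4000]
        rng.shuffle(wide)
        if cfg.enhancer_count > len(wide):
            raise ValueError(
                f"cannot place {cfg.enhancer_count} enhancers in {len(wide)} wide "
                "intergenic gaps: use a larger genome"
            )
        for k in range(cfg.enhancer_count):
            chrom, s, e = wide[k]
            pos = (s + e) // 2
            self.sites.append(
                PlantedSite(
                    site_id=f"enh_{k:03d}",
                    kind="enhancer",
                    pathway="",
                    chrom=chrom,
                    pos=pos,
                    strand=".",
                    host_gene="",
                    wt_mean=cfg.enhancer_mean_tags,
                    ko_mean=cfg.enhancer_mean_tags,
                    effect=1.0,
                    direction="none",
                    offsets=np.arange(3, dtype=np.int64),
                    pmf=np.array([0.5, 0.3, 0.2]),
                )
            )

    def _promoter_offsets(self) -> np.ndarray:
        hw = self.config.promoter_spread_halfwidth
        return np.arange(-hw, hw + 1, dtype=np.int64)

    def _promoter_pmf(self) -> np.ndarray:
        off = self._promoter_offsets().astype(float)
        pmf = np.exp(-0.5 * (off / self.config.promoter_spread_sd) ** 2)
        return pmf / pmf.sum()

    # -- sequence -----------------------------------------------------------

    def _build_genome(self, rng) -> None:
        cfg = self.config
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        gc = cfg.background_gc
        p_bg = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        arrays: dict[str, np.ndarray] = {
            chrom: rng.choice(bases, size=L, p=p_bg)
            for chrom, L in self._chrom_lengths.items()
        }
        # CpG-enrich promoter neighborhoods so the island caller fires there
        for s in self.sites:
            if s.kind != "annotated_promoter":
                continue
            arr = arrays[s.chrom]
            lo = max(0, s.pos - 1 - cfg.promoter_seq_halfwidth)
            hi = min(arr.size, s.pos - 1 + cfg.promoter_seq_halfwidth)
            patch = np.frombuffer(self._cpg_rich(rng, hi - lo).encode(), dtype=np.uint8)
            arr[lo:hi] = patch
        self.genome = {c: a.tobytes().decode() for c, a in arrays.items()}

    def _cpg_rich(self, rng, length: int) -> str:
        cfg = self.config
        gc = cfg.promoter_gc
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        out: list[str] = []
        n = 0
        while n < length:
            if n + 1 < length and rng.random() < cfg.promoter_cpg_rate:
                out.append("CG")
                n += 2
            else:
                out.append("ACGT"[int(rng.choice(4, p=p))])
                n += 1
        return "".join(out)[:length]

    # -- peaks --------------------------------------------------------------

    def _build_peaks(self) -> None:
        hw = self.config.peak_halfwidth
        atac, k27 = [], []
        for s in self.sites:
            if s.kind == "annotated_promoter" and s.wt_mean > 0:
                iv = GenomicInterval(s.chrom, max(0, s.pos - 1 - hw), s.pos + hw)
                atac.append(iv)
                k27.append(iv)
            elif s.kind == "enhancer":
                iv = GenomicInterval(s.chrom, max(0, s.pos - 1 - hw), s.pos + hw)
                atac.append(iv)
                k27.append(iv)
        self.atac = PeakSet("ATAC", atac)
        self.h3k27ac = PeakSet("H3K27ac", k27)

    # -- experiments --------------------------------------------------------

    def samples(self, experiment: str) -> list[tuple[str, str]]:
        """[(sample_id, condition), ...] for an experiment."""
        cfg = self.config
        if experiment == PWWP2_EXPERIMENT:
            out = [(f"WT_rep{i + 1}", "WT") for i in range(cfg.wt_replicates)]
            for clone, n in zip(("KO_A", "KO_B"), cfg.ko_replicates):
                out += [(f"{clone}_rep{i + 1}", clone) for i in range(n)]
            return out
        if experiment == DNMT3B_EXPERIMENT:
            out = [(f"dWT_rep{i + 1}", "WT") for i in range(cfg.dnmt3b_wt_replicates)]
            out += [(f"dKO_rep{i + 1}", "KO_D") for i in range(cfg.dnmt3b_ko_replicates)]
            return out
        raise ValueError(f"unknown experiment {experiment!r}")

    def design(self, experiment: str) -> dict[str, list[str]]:
        d: dict[str, list[str]] = {}
        for sid, cond in self.samples(experiment):
            d.setdefault(cond, []).append(sid)
        return d

    def _site_mean(self, site: PlantedSite, experiment: str, condition: str) -> float:
        ko = condition != "WT"
        if ko and site.pathway == experiment:
            return site.ko_mean
        return site.wt_mean

    def simulate_ctss(self, experiment: str = PWWP2_EXPERIMENT) -> dict[str, CtssProfile]:
        """Negative-binomial CTSS libraries for every replicate of one
        experiment, with tag mass spread over each site's shape and a
        uniform background tag process added genome-wide."""
        cfg = self.config
        exp_idx = (PWWP2_EXPERIMENT, DNMT3B_EXPERIMENT).index(experiment)
        profiles: dict[str, CtssProfile] = {}
        for si, (sample_id, condition) in enumerate(self.samples(experiment)):
            rng = np.random.default_rng([int(cfg.seed), 1, exp_idx, si])
            chroms, poss, strands, counts = [], [], [], []

            def _emit(chrom, pos, strand, n):
                chroms.append(chrom)
                poss.append(pos)
                strands.append(strand)
                counts.append(n)

            for site in self.sites:
                mean = self._site_mean(site, experiment, condition)
                if mean <= 0:
                    continue
                if site.kind == "enhancer":
                    subsites = [(site.pos + 75, "+", mean / 2), (site.pos - 75, "-", mean / 2)]
                else:
                    subsites = [(site.pos, site.strand, mean)]
                for pos, strand, m in subsites:
                    total = self._nb(rng, m)
                    if total == 0:
                        continue
                    spread = rng.multinomial(total, site.pmf)
                    sign = -1 if strand == "-" else 1
                    for off, n in zip(site.offsets, spread):
                        if n > 0:
                            p = pos + sign * int(off)
                            if p >= 1:
                                _emit(site.chrom, p, strand, int(n))
            # background
            for chrom, L in sorted(self._chrom_lengths.items()):
                n_bg = rng.poisson(cfg.background_rate_per_kb * L / 1000.0)
                if n_bg:
                    bg_pos = rng.integers(1, L + 1, size=n_bg)
                    bg_str = rng.choice(np.array(["+", "-"]), size=n_bg)
                    for p, st in zip(bg_pos, bg_str):
                        _emit(chrom, int(p), str(st), 1)
            df = pd.DataFrame(
                {"chrom": chroms, "pos": poss, "strand": strands, "count": counts}
            )
            if len(df):
                df = df.groupby(["chrom", "pos", "strand"], as_index=False, sort=True)["count"].sum()
                df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)
            profiles[sample_id] = CtssProfile(sample_id, condition, df)
        return profiles

    def _nb(self, rng, mean: float) -> int:
        d = self.config.dispersion
        if mean <= 0:
            return 0
        if d <= 0:
            return int(rng.poisson(mean))
        r = 1.0 / d
        p = r / (r + mean)
        return int(rng.negative_binomial(r, p))

    # -- tracks -------------------------------------------------------------

    def simulate_tracks(
        self,
        conditions: tuple[str, str] = ("WT", "KO"),
        boost_positions: dict[str, list[int]] | None = None,
        ko_factor: float | None = None,
    ) -> dict[tuple[str, str], SignalTrack]:
        """ChIP-like coverage tracks for the two-condition comparison.

        Each active site contributes Gaussian bumps at ±track_bump_offset
        scaled by site expression (the ±1 nucleosome acetylation pattern,
        with a trough at the site itself). In the KO condition, bump
        heights at KO-sensitive sites — by default the up-directed
        primary-pathway sites, or the explicit ``boost_positions``
        ({chrom: [1-based positions]}) — are multiplied by ``ko_factor``.
        """
        cfg = self.config
        factor = cfg.ko_track_factor if ko_factor is None else ko_factor
        if boost_positions is not None:
            boosted = {(c, int(p)) for c, ps in boost_positions.items() for p in ps}
        else:
            boosted = {
                (s.chrom, s.pos)
                for s in self.sites
                if s.pathway == PWWP2_EXPERIMENT and s.direction == "up"
            }
        out: dict[tuple[str, str], SignalTrack] = {}
        for ti, track in enumerate(TRACK_NAMES):
            rng = np.random.default_rng([int(cfg.seed), 2, ti])
            heights = {
                s.site_id: _TRACK_SCALE[track]
                * s.wt_mean
                / 10.0
                * float(np.exp(rng.normal(0, cfg.track_height_sigma)))
                for s in self.sites
            }
            for cond in conditions:
                data = {c: np.zeros(L) for c, L in self._chrom_lengths.items()}
                for s in self.sites:
                    h = heights[s.site_id]
                    if h <= 0:
                        continue
                    if cond != conditions[0] and (s.chrom, s.pos) in boosted:
                        h *= factor
                    _add_bumps(
                        data[s.chrom], s.pos - 1, h, cfg.track_bump_offset, cfg.track_bump_sd
                    )
                out[(track, cond)] = SignalTrack(track, data)
        return out

    # -- truth + emission ---------------------------------------------------

    def truth_frame(self) -> pd.DataFrame:
        rows = [
            {
                "site_id": s.site_id,
                "kind": s.kind,
                "pathway": s.pathway or ".",
                "chrom": s.chrom,
                "pos": s.pos,
                "strand": s.strand,
                "host_gene": s.host_gene or ".",
                "wt_mean": s.wt_mean,
                "ko_mean": s.ko_mean,
                "effect": s.effect,
                "direction": s.direction,
            }
            for s in self.sites
        ]
        df = pd.DataFrame(rows, columns=["site_id", "kind", "pathway", "chrom", "pos",
                                         "strand", "host_gene", "wt_mean", "ko_mean",
                                         "effect", "direction"])
        return df.sort_values(["chrom", "pos", "site_id"], kind="mergesort").reset_index(drop=True)

    def write_all(self, outdir, track_bin: int = 10) -> dict[str, str]:
        """Emit every artifact as text files; returns {artifact: path}."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, str] = {}
        tio.write_fasta(self.genome, outdir / "genome.fa")
        paths["genome"] = str(outdir / "genome.fa")
        tio.write_gtf(self.genes, outdir / "genes.gtf")
        tio.write_bed12(self.genes, outdir / "genes.bed12")
        paths["annotation"] = str(outdir / "genes.gtf")
        for name, ps in (("cpg", self.cpg), ("atac", self.atac), ("h3k27ac", self.h3k27ac)):
            tio.write_bed(ps, outdir / f"{name}.bed")
            paths[name] = str(outdir / f"{name}.bed")
        (outdir / "ctss").mkdir(exist_ok=True)
        manifest_rows = []
        for experiment in (PWWP2_EXPERIMENT, DNMT3B_EXPERIMENT):
            for sample_id, profile in self.simulate_ctss(experiment).items():
                p = outdir / "ctss" / f"{sample_id}.ctss.tsv"
                tio.write_ctss(profile, p)
                manifest_rows.append(
                    (sample_id, experiment, profile.condition, str(p.relative_to(outdir)))
                )
        pd.DataFrame(manifest_rows, columns=["sample_id", "experiment", "condition", "path"]).to_csv(
            outdir / "samples.tsv", sep="\t", index=False
        )
        paths["samples"] = str(outdir / "samples.tsv")
        (outdir / "tracks").mkdir(exist_ok=True)
        for (track, cond), sig in self.simulate_tracks().items():
            p = outdir / "tracks" / f"{track}.{cond}.bedgraph"
            tio.write_bedgraph(sig, p, bin_size=track_bin)
        paths["tracks"] = str(outdir / "tracks")
        self.truth_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)
        paths["truth"] = str(outdir / "truth.tsv")
        with open(outdir / "occupancy.tsv", "w") as fh:
            fh.write("gene_id\toccupancy\n")
            for g in sorted(self.genes, key=lambda g: g.gene_id):
                fh.write(f"{g.gene_id}\t{g.occupancy_label}\n")
        paths["occupancy"] = str(outdir / "occupancy.tsv")
        self.config.to_yaml(outdir / "config.yaml")
        paths["config"] = str(outdir / "config.yaml")
        return paths


def _add_bumps(arr: np.ndarray, center0: int, height: float, offset: int, sd: float) -> None:
    span = int(offset + 4 * sd)
    lo = max(0, center0 - span)
    hi = min(arr.size, center0 + span + 1)
    if hi <= lo:
        return
    x = np.arange(lo, hi)
    arr[lo:hi] += height * (
        np.exp(-0.5 * ((x - (center0 - offset)) / sd) ** 2)
        + np.exp(-0.5 * ((x - (center0 + offset)) / sd) ** 2)
    )


# -- module-level convenience wrappers (the operation surface) --------------

def generate_genome_and_annotation(config: SyntheticConfig) -> SyntheticDataset:
    return SyntheticDataset.generate(config)


def simulate_ctss(dataset: SyntheticDataset, experiment: str = PWWP2_EXPERIMENT):
    return dataset.simulate_ctss(experiment)


def simulate_tracks(dataset: SyntheticDataset, **kw):
    return dataset.simulate_tracks(**kw)


def emit_truth(dataset: SyntheticDataset) -> pd.DataFrame:
    return dataset.truth_frame()
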