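"""Stage orchestration: simulate → cluster → classify → diff → metagene.

Each stage reads conventional file names from a working directory, writes
its outputs there, and appends its parameters and input/output counts to
``manifest.json``. Outputs are sorted and formatted deterministically, so
identical config + seed reproduce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import clustering, differential, io as tio, metagene as mg
from .annotation import build_annotation_index
from .classify import (
    INTRAGENIC,
    categorize_all,
    flag_cpg_overlap,
    flag_enhancer_overlap,
    gc_fraction,
    peak_overlap_fraction,
    width_filter,
)
from .clustering import ConsensusCluster, build_consensus, cluster_ctss, expression_matrix
from .simulate import DNMT3B_EXPERIMENT, PWWP2_EXPERIMENT, TRACK_NAMES, SyntheticConfig, SyntheticDataset

log = logging.getLogger(__name__)


class MissingInputError(FileNotFoundError):
    pass


@dataclass
class AnalysisParams:
    promoter_halfwidth: int = 500
    max_gap: int = 20
    min_tp10m: float = 0.5
    consensus_merge_gap: int = 0
    presence_min: float = 1.0
    fc_min: float = 2.0
    pseudocount: float = 0.1
    min_width_nt: int = 10
    overlap_slack_bp: int = 0
    nearest_within_bp: int = 100
    isolation_bp: int = 2000
    metagene_halfwidth: int = 1000
    metagene_bin: int = 25
    center_halfwidth: int = 250
    rel_pseudocount: float = 1.0
    top_fraction: float = 0.175
    rank_score: str = "diff"

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisParams":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = sorted(set(d) - known)
        if bad:
            raise ValueError(f"unknown analysis parameter keys: {bad}")
        return cls(**d)


def load_config(path) -> tuple[SyntheticConfig, AnalysisParams]:
    """YAML with optional top-level sections ``generator:`` and ``analysis:``."""
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    bad = sorted(set(d) - {"generator", "analysis"})
    if bad:
        raise ValueError(f"unknown config sections: {bad} (expected 'generator'/'analysis')")
    gen = d.get("generator", {})
    known = {f.name for f in dataclasses.fields(SyntheticConfig)}
    bad = sorted(set(gen) - known)
    if bad:
        raise ValueError(f"unknown generator keys: {bad}")
    for k in ("ko_replicates", "gene_gap_range", "exon_count_range",
              "exon_len_range", "intron_len_range"):
        if k in gen:
            gen[k] = tuple(gen[k])
    return SyntheticConfig(**gen), AnalysisParams.from_dict(d.get("analysis", {}))


# ---------------------------------------------------------------------------
# manifest

def _update_manifest(outdir: Path, stage: str, params: dict, counts: dict) -> None:
    path = outdir / "manifest.json"
    manifest = {"tool": "cryptic-tss", "version": __version__, "stages": {}}
    if path.exists():
        manifest = json.loads(path.read_text())
    manifest["stages"][stage] = {"params": params, "counts": counts}
    blob = json.dumps(
        {k: v for k, v in manifest.items() if k != "config_hash"}, sort_keys=True
    ).encode()
    manifest["config_hash"] = hashlib.sha256(blob).hexdigest()[:16]
    path.write_text(json.dumps(manifest, sort_keys=True, indent=1) + "\n")


def _require(outdir: Path, *names: str) -> None:
    for name in names:
        if not (outdir / name).exists():
            raise MissingInputError(f"missing required input: {outdir / name}")


# ---------------------------------------------------------------------------
# stages

def run_simulate(config: SyntheticConfig, outdir) -> SyntheticDataset:
    outdir = Path(outdir)
    ds = SyntheticDataset.generate(config)
    ds.write_all(outdir)
    _update_manifest(
        outdir,
        "simulate",
        dataclasses.asdict(config)
        | {"ko_replicates": list(config.ko_replicates),
           "gene_gap_range": list(config.gene_gap_range),
           "exon_count_range": list(config.exon_count_range),
           "exon_len_range": list(config.exon_len_range),
           "intron_len_range": list(config.intron_len_range)},
        {
            "genes": len(ds.genes),
            "planted_sites": len(ds.sites),
            "atac_peaks": len(ds.atac),
            "h3k27ac_peaks": len(ds.h3k27ac),
            "cpg_islands": len(ds.cpg),
        },
    )
    return ds


def _read_samples(outdir: Path) -> pd.DataFrame:
    _require(outdir, "samples.tsv")
    return pd.read_csv(outdir / "samples.tsv", sep="\t")


def run_cluster(outdir, params: AnalysisParams) -> dict[str, list[ConsensusCluster]]:
    """Per-experiment tag clustering + consensus construction."""
    outdir = Path(outdir)
    samples = _read_samples(outdir)
    counts: dict[str, int] = {}
    result: dict[str, list[ConsensusCluster]] = {}
    for experiment, grp in samples.groupby("experiment", sort=True):
        cluster_sets = {}
        n_tag = 0
        for row in grp.itertuples(index=False):
            ctss_path = Path(row.path)
            if not ctss_path.is_absolute():
                ctss_path = outdir / ctss_path
            profile = tio.read_ctss(ctss_path, sample_id=row.sample_id, condition=row.condition)
            cs = cluster_ctss(profile, max_gap=params.max_gap, min_tp10m=params.min_tp10m)
            n_tag += sum(len(v) for v in cs.values())
            cluster_sets[row.sample_id] = cs
        consensus = build_consensus(cluster_sets, merge_gap=params.consensus_merge_gap)
        clustering.write_clusters_bed(consensus, outdir / f"consensus_{experiment}.bed")
        expression_matrix(consensus).to_csv(
            outdir / f"expression_{experiment}.tsv", sep="\t", float_format="%.6f"
        )
        counts[f"{experiment}_tag_clusters"] = n_tag
        counts[f"{experiment}_consensus_clusters"] = len(consensus)
        result[experiment] = consensus
    _update_manifest(
        outdir,
        "cluster",
        {"max_gap": params.max_gap, "min_tp10m": params.min_tp10m,
         "consensus_merge_gap": params.consensus_merge_gap},
        counts,
    )
    return result


def run_classify(outdir, params: AnalysisParams) -> dict[str, list[ConsensusCluster]]:
    outdir = Path(outdir)
    _require(outdir, "genes.gtf", "genome.fa", "atac.bed", "h3k27ac.bed", "cpg.bed")
    genes = tio.read_annotation(outdir / "genes.gtf", format="gtf")
    index = build_annotation_index(genes, promoter_halfwidth=params.promoter_halfwidth)
    genome = tio.read_fasta(outdir / "genome.fa")
    atac = tio.read_bed(outdir / "atac.bed", name="ATAC")
    k27 = tio.read_bed(outdir / "h3k27ac.bed", name="H3K27ac")
    cpg = tio.read_bed(outdir / "cpg.bed", name="CpG_island")
    counts: dict[str, int | float] = {}
    result: dict[str, list[ConsensusCluster]] = {}
    for experiment in _experiments(outdir):
        bed = outdir / f"consensus_{experiment}.bed"
        _require(outdir, bed.name)
        clusters = clustering.read_clusters_bed(bed)
        categorize_all(clusters, index)
        flag_enhancer_overlap(clusters, atac, k27)
        flag_cpg_overlap(clusters, cpg)
        for c in clusters:
            c.gc_fraction = gc_fraction(c, genome)
        clustering.write_clusters_bed(clusters, bed)
        cat_counts = {cat: 0 for cat in ("annotated_promoter", "exonic", "intronic", "intergenic")}
        for c in clusters:
            cat_counts[c.category] += 1
        total = len(clusters)
        summary = pd.DataFrame(
            {
                "category": list(cat_counts),
                "count": list(cat_counts.values()),
                "percent": [100.0 * v / total if total else 0.0 for v in cat_counts.values()],
            }
        )
        summary.to_csv(outdir / f"category_summary_{experiment}.tsv", sep="\t",
                       index=False, float_format="%.3f")
        ov = {
            "ATAC": peak_overlap_fraction(clusters, atac),
            "H3K27ac": peak_overlap_fraction(clusters, k27),
        }
        rows = [
            {"peak_set": ps, "category": cat, "fraction": frac}
            for ps, d in ov.items()
            for cat, frac in d.items()
        ]
        pd.DataFrame(rows).to_csv(outdir / f"peak_overlap_{experiment}.tsv", sep="\t",
                                  index=False, float_format="%.4f")
        for cat, v in cat_counts.items():
            counts[f"{experiment}_{cat}"] = v
        result[experiment] = clusters
    _update_manifest(outdir, "classify", {"promoter_halfwidth": params.promoter_halfwidth}, counts)
    return result


def _experiments(outdir: Path) -> list[str]:
    samples = _read_samples(outdir)
    return sorted(samples["experiment"].unique())


def _design(outdir: Path, experiment: str) -> dict[str, list[str]]:
    samples = _read_samples(outdir)
    grp = samples[samples["experiment"] == experiment]
    d: dict[str, list[str]] = {}
    for row in grp.itertuples(index=False):
        d.setdefault(row.condition, []).append(row.sample_id)
    return d


def gene_expression_from_promoters(
    genes, clusters: list[ConsensusCluster], wt_samples: list[str]
) -> None:
    """Set each gene's expression to the summed mean-WT TP10M of its
    annotated-promoter clusters (0 when none)."""
    expr: dict[str, float] = {}
    for c in clusters:
        if c.category == "annotated_promoter" and c.host_gene_id:
            wt = float(np.mean([c.expression[s] for s in wt_samples]))
            expr[c.host_gene_id] = expr.get(c.host_gene_id, 0.0) + wt
    for g in genes:
        g.expression = expr.get(g.gene_id, 0.0)


def run_diff(outdir, params: AnalysisParams) -> dict:
    outdir = Path(outdir)
    _require(outdir, "genes.gtf")
    genes = tio.read_annotation(outdir / "genes.gtf", format="gtf")
    occupancy = None
    if (outdir / "occupancy.tsv").exists():
        occ_df = pd.read_csv(outdir / "occupancy.tsv", sep="\t")
        occupancy = dict(zip(occ_df["gene_id"], occ_df["occupancy"]))
    result: dict = {}
    counts: dict[str, int | float] = {}
    sets: dict[str, differential.SpuriousSet] = {}
    calls_by_exp: dict[str, pd.DataFrame] = {}
    clusters_by_exp: dict[str, list[ConsensusCluster]] = {}
    summary: dict = {}
    for experiment in _experiments(outdir):
        _require(outdir, f"consensus_{experiment}.bed", f"expression_{experiment}.tsv")
        clusters = clustering.read_clusters_bed(outdir / f"consensus_{experiment}.bed")
        if any(c.category is None for c in clusters):
            raise MissingInputError(
                f"consensus_{experiment}.bed has no categories; run 'classify' first"
            )
        expr = pd.read_csv(outdir / f"expression_{experiment}.tsv", sep="\t", index_col=0)
        design = _design(outdir, experiment)
        calls = differential.call_differential(
            expr, design, wt_condition="WT",
            presence_min=params.presence_min, fc_min=params.fc_min,
            pseudocount=params.pseudocount,
        )
        calls.to_csv(outdir / f"calls_{experiment}.tsv", sep="\t", float_format="%.6f")
        calls_by_exp[experiment] = calls
        clusters_by_exp[experiment] = clusters
        ko_conditions = sorted(k for k in design if k != "WT")
        if experiment == PWWP2_EXPERIMENT and len(ko_conditions) >= 2:
            ss = differential.define_pwwp2_sensitive(calls, clusters, tuple(ko_conditions[:2]))
        else:
            ss = differential.define_dnmt3b_sensitive(calls, clusters, ko_conditions[0])
        sets[experiment] = ss
        _write_set_bed(ss, outdir / f"sensitive_{experiment}.bed")
        counts[f"{experiment}_sensitive"] = len(ss)
        ratios = {}
        for cond in ko_conditions:
            for cat in ("exonic", "intronic"):
                r, inf = differential.updown_ratio(calls, clusters, cat, cond)
                ratios[f"{cond}_{cat}"] = None if inf else round(r, 4)
            r, inf = differential.updown_ratio(calls, clusters, INTRAGENIC, cond)
            ratios[f"{cond}_intragenic"] = None if inf else round(r, 4)
        summary[f"{experiment}_updown_ratios"] = ratios
        summary[f"{experiment}_provenance"] = [[n, c] for n, c in ss.provenance]
    # quartiles from the primary experiment's WT samples
    primary = PWWP2_EXPERIMENT if PWWP2_EXPERIMENT in clusters_by_exp else _experiments(outdir)[0]
    wt_samples = _design(outdir, primary)["WT"]
    gene_expression_from_promoters(genes, clusters_by_exp[primary], wt_samples)
    quartiles = differential.expression_quartiles(genes)
    qdf = pd.DataFrame(
        {"gene_id": quartiles.index, "group": quartiles.values,
         "expression": [g.expression for g in sorted(genes, key=lambda g: g.gene_id)]}
    )
    qdf = qdf.sort_values("gene_id", kind="mergesort")
    qdf.to_csv(outdir / "gene_quartiles.tsv", sep="\t", index=False, float_format="%.4f")
    for experiment, ss in sets.items():
        attr = differential.attribute_to_genes(ss, quartiles, occupancy)
        summary[f"{experiment}_attribution"] = attr
    # CpG-island contingency: sensitive set vs annotated promoters (primary)
    prom = [c for c in clusters_by_exp[primary] if c.category == "annotated_promoter"]
    ss = sets[primary]
    if prom and len(ss):
        table = [
            [sum(c.cpg_island_overlap for c in prom), sum(not c.cpg_island_overlap for c in prom)],
            [sum(c.cpg_island_overlap for c in ss.members), sum(not c.cpg_island_overlap for c in ss.members)],
        ]
        try:
            res = differential.chi_square_test(table)
            summary["cpg_chi_square"] = {
                "observed": table, "statistic": round(res.statistic, 4),
                "dof": res.dof, "p_value": float(f"{res.p_value:.6g}"),
            }
        except ValueError:
            summary["cpg_chi_square"] = {"observed": table, "note": "degenerate margin"}
        wide = width_filter(ss.members, params.min_width_nt)
        summary["gc_comparison"] = _gc_comparison(prom, wide, ss.members)
    # cross-pathway comparisons
    if len(sets) == 2 and all(len(s) for s in sets.values()):
        a, b = sets[PWWP2_EXPERIMENT], sets[DNMT3B_EXPERIMENT]
        ov = differential.overlap_sets(a, b, slack_bp=params.overlap_slack_bp)
        dists, frac = differential.nearest_distance(b, a, within_bp=params.nearest_within_bp)
        summary["cross_pathway"] = {
            "a_only": ov.a_only, "b_only": ov.b_only, "shared": ov.shared,
            "fraction_within_bp": round(frac, 4),
            "within_bp": params.nearest_within_bp,
            "n_query": int(dists.notna().sum()),
        }
        dists.rename("distance_bp").to_csv(outdir / "cross_pathway_distances.tsv", sep="\t")
    (outdir / "diff_summary.json").write_text(json.dumps(summary, sort_keys=True, indent=1) + "\n")
    _update_manifest(
        outdir, "diff",
        {"presence_min": params.presence_min, "fc_min": params.fc_min,
         "pseudocount": params.pseudocount, "overlap_slack_bp": params.overlap_slack_bp},
        counts,
    )
    result.update({"sets": sets, "calls": calls_by_exp, "clusters": clusters_by_exp,
                   "quartiles": quartiles, "summary": summary, "genes": genes})
    return result


def _gc_comparison(prom, spurious_wide, spurious_all) -> dict:
    """%GC of annotated-promoter clusters vs sensitive spurious clusters;
    the width-filtered comparison plus an unfiltered fallback (narrow
    spurious clusters can leave the filtered set empty)."""
    gp = [c.gc_fraction for c in prom if c.gc_fraction is not None]
    gw = [c.gc_fraction for c in spurious_wide if c.gc_fraction is not None]
    ga = [c.gc_fraction for c in spurious_all if c.gc_fraction is not None]
    out = {
        "promoter_median_gc": round(float(np.median(gp)), 4) if gp else None,
        "spurious_median_gc": round(float(np.median(gw)), 4) if gw else None,
        "spurious_median_gc_all": round(float(np.median(ga)), 4) if ga else None,
        "n_promoter": len(gp), "n_spurious": len(gw), "n_spurious_all": len(ga),
    }
    gs = gw if gw else ga
    if len(gp) >= 1 and len(gs) >= 1:
        cmp = mg.rank_sum_test(gp, gs, labels=("promoter", "spurious"))
        out["mann_whitney_p"] = float(f"{cmp.p_value:.6g}")
    return out


def _write_set_bed(ss: differential.SpuriousSet, path) -> None:
    with open(path, "w") as fh:
        for c in sorted(ss.members, key=lambda c: (c.interval.chrom, c.interval.start, c.id)):
            fh.write(
                f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}\t{c.id}\t0\t{c.strand}"
                f"\t{c.dominant_pos}\t{c.category}\t{c.host_gene_id}\n"
            )


def run_metagene(outdir, params: AnalysisParams) -> dict:
    outdir = Path(outdir)
    _require(outdir, f"sensitive_{PWWP2_EXPERIMENT}.bed", f"calls_{PWWP2_EXPERIMENT}.tsv")
    clusters = clustering.read_clusters_bed(outdir / f"consensus_{PWWP2_EXPERIMENT}.bed")
    by_id = {c.id: c for c in clusters}
    member_ids = []
    with open(outdir / f"sensitive_{PWWP2_EXPERIMENT}.bed") as fh:
        for line in fh:
            member_ids.append(line.split("\t")[3])
    members = [by_id[i] for i in member_ids if i in by_id]
    calls = pd.read_csv(outdir / f"calls_{PWWP2_EXPERIMENT}.tsv", sep="\t", index_col=0)
    ko_conditions = sorted(
        {c.rsplit("_status", 1)[0] for c in calls.columns if c.endswith("_status")}
    )
    isolated = mg.isolation_filter(members, params.isolation_bp)
    top, bottom = mg.rank_top_bottom(
        isolated, calls, ko_conditions, fraction=params.top_fraction, score=params.rank_score
    )
    summary: dict = {
        "n_members": len(members),
        "n_isolated": len(isolated),
        "n_top": len(top),
        "n_bottom": len(bottom),
        "tracks": {},
    }
    track_dir = outdir / "tracks"
    for track in TRACK_NAMES:
        wt_path = track_dir / f"{track}.WT.bedgraph"
        ko_path = track_dir / f"{track}.KO.bedgraph"
        if not wt_path.exists() or not ko_path.exists():
            raise MissingInputError(f"missing track files: {wt_path} / {ko_path}")
        wt = tio.read_bedgraph(wt_path, name=track)
        ko = tio.read_bedgraph(ko_path, name=track)
        mat_wt = mg.compute_metagene(wt, isolated, params.metagene_halfwidth,
                                     params.metagene_bin, condition="WT")
        mat_ko = mg.compute_metagene(ko, isolated, params.metagene_halfwidth,
                                     params.metagene_bin, condition="KO")
        prof = pd.DataFrame(
            {"offset": mat_wt.bin_offsets(), "WT": mat_wt.column_profile(),
             "KO": mat_ko.column_profile()}
        )
        prof.to_csv(outdir / f"metagene_{track}.tsv", sep="\t", index=False,
                    float_format="%.6f")
        rel = mg.relative_difference(mat_ko, mat_wt, params.center_halfwidth,
                                     params.rel_pseudocount)
        rel.rename("relative_difference").to_csv(
            outdir / f"reldiff_{track}.tsv", sep="\t", float_format="%.6f"
        )
        top_vals = rel[[c.id for c in top]].to_numpy()
        bot_vals = rel[[c.id for c in bottom]].to_numpy()
        if len(top_vals) and len(bot_vals):
            cmp = mg.rank_sum_test(top_vals, bot_vals, labels=("Top", "Bottom"))
            summary["tracks"][track] = {
                "top_median": round(float(np.median(top_vals)), 4),
                "bottom_median": round(float(np.median(bot_vals)), 4),
                "U": cmp.statistic,
                "p_value": float(f"{cmp.p_value:.6g}"),
                "method": cmp.method,
            }
    (outdir / "metagene_summary.json").write_text(
        json.dumps(summary, sort_keys=True, indent=1) + "\n"
    )
    _update_manifest(
        outdir, "metagene",
        {"isolation_bp": params.isolation_bp, "halfwidth": params.metagene_halfwidth,
         "bin_size": params.metagene_bin, "center_halfwidth": params.center_halfwidth,
         "rel_pseudocount": params.rel_pseudocount, "top_fraction": params.top_fraction,
         "rank_score": params.rank_score},
        {"isolated_sites": len(isolated), "top": len(top), "bottom": len(bottom)},
    )
    return {"isolated": isolated, "top": top, "bottom": bottom, "summary": summary}


def run_all(config: SyntheticConfig, params: AnalysisParams, outdir) -> dict:
    outdir = Path(outdir)
    run_simulate(config, outdir)
    run_cluster(outdir, params)
    run_classify(outdir, params)
    diff = run_diff(outdir, params)
    meta = run_metagene(outdir, params)
    return {"diff": diff, "metagene": meta}
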