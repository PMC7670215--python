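"""Synthetic-data generator: determinism, self-consistency, noise model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cryptic_tss import io as tio
from cryptic_tss.classify import gc_fraction_seq
from cryptic_tss.clustering import normalize_tp10m
from cryptic_tss.simulate import (
    DNMT3B_EXPERIMENT,
    PWWP2_EXPERIMENT,
    SyntheticConfig,
    SyntheticDataset,
)

from conftest import small_config


@pytest.fixture(scope="module")
def ds():
    return SyntheticDataset.generate(small_config(seed=21))


class TestGenomeAndAnnotation:
    def test_zero_genes_gives_fasta_only(self):
        cfg = small_config(seed=1, genes_per_chrom=0, cryptic_count=0,
                           dnmt3b_count=0, enhancer_count=0)
        empty = SyntheticDataset.generate(cfg)
        assert empty.genes == []
        assert len(empty.genome) == 1 and len(empty.genome["chr1"]) > 0

    def test_exons_within_bounds_and_roundtrip(self, ds, tmp_path):
        L = {c: len(s) for c, s in ds.genome.items()}
        for g in ds.genes:
            assert 0 <= g.interval.start < g.interval.end <= L[g.interval.chrom]
            for tx in g.transcripts:
                for e in tx:
                    assert g.interval.start <= e.start < e.end <= g.interval.end
        tio.write_gtf(ds.genes, tmp_path / "genes.gtf")
        back = tio.read_annotation(tmp_path / "genes.gtf", format="gtf")
        assert len(back) == len(ds.genes)
        assert [g.annotated_tss for g in back] == [
            g.annotated_tss for g in sorted(ds.genes, key=lambda g: g.gene_id)
        ]

    def test_promoter_gc_exceeds_background(self, ds):
        rng = np.random.default_rng(0)
        prom_gc, rand_gc = [], []
        for g in ds.genes:
            tss0 = g.annotated_tss[0] - 1
            seq = ds.genome[g.interval.chrom]
            prom_gc.append(gc_fraction_seq(seq[max(0, tss0 - 250): tss0 + 250]))
            r = int(rng.integers(0, len(seq) - 500))
            rand_gc.append(gc_fraction_seq(seq[r: r + 500]))
        assert np.mean(prom_gc) > np.mean(rand_gc) + 0.1

    def test_most_promoters_have_cpg_island(self, ds):
        islands = ds.cpg.by_chrom()
        n_hit = 0
        for g in ds.genes:
            tss0 = g.annotated_tss[0] - 1
            spans = islands.get(g.interval.chrom, np.empty((0, 2), dtype=int))
            if ((spans[:, 0] <= tss0 + 250) & (spans[:, 1] >= tss0 - 250)).any():
                n_hit += 1
        assert n_hit / len(ds.genes) > 0.8

    def test_cryptic_sites_inside_host_gene_bodies(self, ds):
        genes = {g.gene_id: g for g in ds.genes}
        truth = ds.truth_frame()
        cryptic = truth[truth.kind.str.startswith("cryptic")]
        assert len(cryptic) == 60  # 40 primary + 20 second-pathway
        for r in cryptic.itertuples():
            g = genes[r.host_gene]
            assert g.interval.start < r.pos - 1 < g.interval.end
            assert r.strand == g.interval.strand

    def test_enhancers_intergenic_and_peaked(self, ds):
        truth = ds.truth_frame()
        enh = truth[truth.kind == "enhancer"]
        atac = ds.atac.by_chrom()
        for r in enh.itertuples():
            for g in ds.genes:
                if g.interval.chrom == r.chrom:
                    assert not (g.interval.start < r.pos - 1 < g.interval.end)
            spans = atac[r.chrom]
            assert ((spans[:, 0] <= r.pos - 1) & (spans[:, 1] > r.pos - 1)).any()

    def test_peaks_exclude_cryptic_sites(self, ds):
        """The enhancer filter cannot remove planted cryptic sites."""
        truth = ds.truth_frame()
        cryptic = truth[truth.kind.str.startswith("cryptic")]
        for peaks in (ds.atac, ds.h3k27ac):
            spans = peaks.by_chrom()
            for r in cryptic.itertuples():
                s = spans.get(r.chrom, np.empty((0, 2), dtype=int))
                assert not ((s[:, 0] <= r.pos - 1) & (s[:, 1] > r.pos - 1)).any()

    def test_infeasible_density_raises(self):
        with pytest.raises(ValueError, match="larger genome"):
            SyntheticDataset.generate(small_config(seed=2, cryptic_count=5000))


class TestTruth:
    def test_row_count(self, ds):
        truth = ds.truth_frame()
        cfg = ds.config
        expected = (cfg.n_chroms * cfg.genes_per_chrom + cfg.cryptic_count
                    + cfg.dnmt3b_count + cfg.enhancer_count)
        assert len(truth) == expected

    def test_host_quartile_mix(self):
        cfg = small_config(seed=3, genes_per_chrom=80, cryptic_count=60, dnmt3b_count=0)
        d = SyntheticDataset.generate(cfg)
        truth = d.truth_frame()
        cryptic = truth[truth.pathway == PWWP2_EXPERIMENT]
        q = {g.gene_id: d.gene_quartile[g.gene_id] for g in d.genes}
        frac_high = np.mean([q[h] == "High" for h in cryptic.host_gene])
        assert abs(frac_high - 0.85) <= 0.05

    def test_same_seed_identical_artifacts(self, tmp_path):
        cfg = small_config(seed=4, genes_per_chrom=20, cryptic_count=10,
                           dnmt3b_count=4, enhancer_count=2)
        f1, f2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        for f in (f1, f2):
            d = SyntheticDataset.generate(cfg)
            d.truth_frame().to_csv(f, sep="\t", index=False)
        assert f1.read_bytes() == f2.read_bytes()


class TestCtssSimulation:
    def test_same_seed_byte_identical_ctss(self, tmp_path):
        cfg = small_config(seed=5, genes_per_chrom=20, cryptic_count=10,
                           dnmt3b_count=4, enhancer_count=2)
        outs = []
        for name in ("x", "y"):
            d = SyntheticDataset.generate(cfg)
            prof = d.simulate_ctss(PWWP2_EXPERIMENT)["WT_rep1"]
            p = tmp_path / f"{name}.ctss.tsv"
            tio.write_ctss(prof, p)
            outs.append(p.read_bytes())
        assert outs[0] == outs[1]

    def test_no_effect_means_no_systematic_shift(self):
        """With effect size 1, per-site WT/KO rank-sum p-values are ~uniform."""
        cfg = small_config(seed=6, cryptic_effect=1.0, cryptic_down_fraction=0.0,
                           dnmt3b_count=0, wt_replicates=3, ko_replicates=(3, 3))
        d = SyntheticDataset.generate(cfg)
        profiles = d.simulate_ctss(PWWP2_EXPERIMENT)
        truth = d.truth_frame()
        cryptic = truth[truth.pathway == PWWP2_EXPERIMENT]
        by_cond: dict[str, list] = {}
        for sid, prof in profiles.items():
            df = normalize_tp10m(prof).set_index(["chrom", "pos", "strand"])["tp10m"]
            by_cond.setdefault(prof.condition, []).append(df)
        pvals = []
        for r in cryptic.itertuples():
            key = (r.chrom, r.pos, r.strand)
            wt = [df.get(key, 0.0) for df in by_cond["WT"]]
            ko = [df.get(key, 0.0) for df in by_cond["KO_A"] + by_cond["KO_B"]]
            res = stats.mannwhitneyu(wt, ko, alternative="two-sided")
            pvals.append(res.pvalue)
        # no enrichment of small p-values beyond chance
        assert np.mean(np.asarray(pvals) < 0.05) < 0.2

    def test_poisson_limit_variance(self):
        """dispersion → 0 gives replicate variance ≈ mean (moment check)."""
        cfg = SyntheticConfig(seed=7, dispersion=0.0)
        ds0 = SyntheticDataset(cfg)
        rng = np.random.default_rng(0)
        draws = np.array([ds0._nb(rng, 50.0) for _ in range(10_000)])
        assert draws.mean() == pytest.approx(50.0, rel=0.05)
        assert draws.var() == pytest.approx(draws.mean(), rel=0.1)

    def test_nb_variance_matches_dispersion(self):
        cfg = SyntheticConfig(seed=8, dispersion=0.1)
        ds0 = SyntheticDataset(cfg)
        rng = np.random.default_rng(1)
        mean = 100.0
        draws = np.array([ds0._nb(rng, mean) for _ in range(10_000)])
        expected_var = mean + 0.1 * mean**2
        assert draws.var() == pytest.approx(expected_var, rel=0.1)

    def test_enhancers_emit_both_strands(self, ds):
        prof = ds.simulate_ctss(PWWP2_EXPERIMENT)["WT_rep1"]
        truth = ds.truth_frame()
        enh = truth[truth.kind == "enhancer"].iloc[0]
        rec = prof.records
        near = rec[(rec.chrom == enh.chrom) & (rec.pos - enh.pos).abs().le(100)]
        assert set(near.strand) == {"+", "-"}


class TestTracks:
    def test_ko_factor_one_identical(self, ds):
        tracks = ds.simulate_tracks(ko_factor=1.0)
        for name in ("H3K9ac", "PolII_Ser5P"):
            wt = tracks[(name, "WT")].data["chr1"]
            ko = tracks[(name, "KO")].data["chr1"]
            assert np.array_equal(wt, ko)

    def test_flanking_peaks_with_central_trough(self, ds):
        """±1-nucleosome bumps: maxima flank the site, local dip at it."""
        from cryptic_tss.metagene import compute_metagene
        from cryptic_tss.clustering import ConsensusCluster
        from cryptic_tss.core import GenomicInterval

        truth = ds.truth_frame()
        prom = truth[(truth.kind == "annotated_promoter") & (truth.wt_mean > 0)].iloc[0]
        tracks = ds.simulate_tracks()
        c = ConsensusCluster(
            id="p", interval=GenomicInterval(prom.chrom, prom.pos - 1, prom.pos),
            expression={}, dominant_pos=int(prom.pos),
        )
        mat = compute_metagene(tracks[("H3K27ac", "WT")], [c], 500, 25)
        prof = mat.matrix[0]
        center = len(prof) // 2
        peak_bins = np.argsort(prof)[-4:]
        assert prof[center] < prof.max()
        assert any(b < center for b in peak_bins) and any(b >= center for b in peak_bins)
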