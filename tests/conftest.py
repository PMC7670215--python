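import numpy as np
import pytest

from cryptic_tss.annotation import build_annotation_index
from cryptic_tss.classify import categorize_all, flag_enhancer_overlap
from cryptic_tss.clustering import build_consensus, cluster_ctss, expression_matrix
from cryptic_tss.differential import call_differential
from cryptic_tss.pipeline import AnalysisParams, run_all
from cryptic_tss.simulate import PWWP2_EXPERIMENT, SyntheticConfig, SyntheticDataset


def small_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A scaled-down study layout for fast repeated simulation."""
    base = dict(
        seed=seed,
        n_chroms=1,
        genes_per_chrom=60,
        cryptic_count=40,
        dnmt3b_count=20,
        enhancer_count=5,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


def run_core(ds: SyntheticDataset, params: AnalysisParams | None = None,
             experiment: str = PWWP2_EXPERIMENT):
    """In-memory cluster → categorize → differential for one experiment."""
    params = params or AnalysisParams()
    profiles = ds.simulate_ctss(experiment)
    cluster_sets = {
        sid: cluster_ctss(p, max_gap=params.max_gap, min_tp10m=params.min_tp10m)
        for sid, p in profiles.items()
    }
    consensus = build_consensus(cluster_sets, merge_gap=params.consensus_merge_gap)
    index = build_annotation_index(ds.genes, promoter_halfwidth=params.promoter_halfwidth)
    categorize_all(consensus, index)
    flag_enhancer_overlap(consensus, ds.atac, ds.h3k27ac)
    expr = expression_matrix(consensus)
    design = ds.design(experiment)
    calls = call_differential(
        expr, design, wt_condition="WT",
        presence_min=params.presence_min, fc_min=params.fc_min,
        pseudocount=params.pseudocount,
    )
    return consensus, calls, design


def cluster_for_truth_site(clusters, row, pad: int = 10):
    """The consensus cluster covering a planted site's mode position."""
    for c in clusters:
        if (
            c.interval.chrom == row.chrom
            and c.strand == row.strand
            and c.interval.start - pad <= row.pos - 1 <= c.interval.end + pad
        ):
            return c
    return None


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full default-scale pipeline run, shared across tests."""
    outdir = tmp_path_factory.mktemp("default_run")
    config = SyntheticConfig(seed=11)
    result = run_all(config, AnalysisParams(), outdir)
    return {"outdir": outdir, "config": config, "result": result}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
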