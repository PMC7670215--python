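"""Differential TSS usage between wild-type and knockout conditions.

Each consensus cluster is classified per KO comparison as On (absent in
WT, present in KO), Off (present in WT, absent in KO), Up / Down
(fold-change beyond a threshold, with pseudocount), Unchanged, or Absent.
Sensitive spurious-TSS sets are then built:

* the HDAC-pathway set ("pwwp2-sensitive"): intragenic, non-enhancer
  clusters called Up in BOTH KO clones;
* the DNA-methylation-pathway set ("dnmt3b-sensitive"): intragenic,
  non-enhancer clusters called On or Up in a single KO comparison.

Downstream statistics: Up:Down ratios per category, set overlap,
nearest-distance between pathway sets, expression quartiles and
quartile/occupancy attribution, chi-square contingency tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classify import INTRAGENIC
from .clustering import ConsensusCluster

STATUSES = ("Up", "Down", "Unchanged", "On", "Off", "Absent")


def call_differential(
    expr: pd.DataFrame,
    design: dict[str, list[str]],
    wt_condition: str = "WT",
    presence_min: float = 1.0,
    fc_min: float = 2.0,
    pseudocount: float = 0.1,
) -> pd.DataFrame:
    """Per-cluster, per-KO-condition differential calls.

    Parameters
    ----------
    expr : DataFrame, clusters × samples (TP10M).
    design : condition → list of sample columns; must contain
        ``wt_condition`` plus ≥1 KO condition.

    Returns a DataFrame indexed like ``expr`` with ``wt_mean`` and, per KO
    condition ``k``: ``{k}_mean``, ``{k}_lfc``, ``{k}_status``.
    """
    if fc_min <= 1:
        raise ValueError("fc_min must be > 1")
    for cond, samples in design.items():
        missing = [s for s in samples if s not in expr.columns]
        if missing:
            raise ValueError(f"design condition {cond!r} references unknown samples {missing}")
    if wt_condition not in design:
        raise ValueError(f"design lacks WT condition {wt_condition!r}")
    wt_mean = expr[design[wt_condition]].mean(axis=1)
    out = pd.DataFrame({"wt_mean": wt_mean})
    lfc_thr = np.log2(fc_min)
    for cond in sorted(design):
        if cond == wt_condition:
            continue
        ko_mean = expr[design[cond]].mean(axis=1)
        lfc = np.log2((ko_mean + pseudocount) / (wt_mean + pseudocount))
        present_wt = wt_mean >= presence_min
        present_ko = ko_mean >= presence_min
        status = np.full(len(expr), "Unchanged", dtype=object)
        status[(lfc >= lfc_thr).to_numpy()] = "Up"
        status[(lfc <= -lfc_thr).to_numpy()] = "Down"
        status[(~present_wt & present_ko).to_numpy()] = "On"
        status[(present_wt & ~present_ko).to_numpy()] = "Off"
        status[(~present_wt & ~present_ko).to_numpy()] = "Absent"
        out[f"{cond}_mean"] = ko_mean
        out[f"{cond}_lfc"] = lfc
        out[f"{cond}_status"] = status
    return out


@dataclass
class SpuriousSet:
    label: str
    members: list[ConsensusCluster]
    provenance: list[tuple[str, int]] = field(default_factory=list)

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.members]

    def __len__(self) -> int:
        return len(self.members)


def define_pwwp2_sensitive(
    calls: pd.DataFrame,
    clusters: list[ConsensusCluster],
    clone_conditions: tuple[str, str],
    label: str = "PWWP2_sensitive",
) -> SpuriousSet:
    """Intragenic, non-enhancer clusters Up in BOTH KO clones."""
    by_id = {c.id: c for c in clusters}
    prov: list[tuple[str, int]] = [("all_clusters", len(calls))]
    ids = [i for i in calls.index if i in by_id]
    ids = [i for i in ids if by_id[i].category in INTRAGENIC]
    prov.append(("intragenic", len(ids)))
    ids = [i for i in ids if not by_id[i].enhancer_overlap]
    prov.append(("no_enhancer_overlap", len(ids)))
    for clone in clone_conditions:
        ids = [i for i in ids if calls.at[i, f"{clone}_status"] == "Up"]
        prov.append((f"up_in_{clone}", len(ids)))
    return SpuriousSet(label, [by_id[i] for i in ids], prov)


def define_dnmt3b_sensitive(
    calls: pd.DataFrame,
    clusters: list[ConsensusCluster],
    ko_condition: str,
    label: str = "DNMT3B_sensitive",
) -> SpuriousSet:
    """Intragenic, non-enhancer clusters On or Up in a single KO comparison."""
    by_id = {c.id: c for c in clusters}
    prov: list[tuple[str, int]] = [("all_clusters", len(calls))]
    ids = [i for i in calls.index if i in by_id and by_id[i].category in INTRAGENIC]
    prov.append(("intragenic", len(ids)))
    ids = [i for i in ids if not by_id[i].enhancer_overlap]
    prov.append(("no_enhancer_overlap", len(ids)))
    ids = [i for i in ids if calls.at[i, f"{ko_condition}_status"] in ("On", "Up")]
    prov.append((f"on_or_up_in_{ko_condition}", len(ids)))
    return SpuriousSet(label, [by_id[i] for i in ids], prov)


def updown_ratio(
    calls: pd.DataFrame,
    clusters: list[ConsensusCluster],
    category: str | tuple[str, ...],
    condition: str,
) -> tuple[float, bool]:
    """(#Up / #Down) among clusters of the given category for one KO
    comparison. Returns (ratio, is_infinite); with no Down site the ratio
    is inf and flagged."""
    cats = (category,) if isinstance(category, str) else tuple(category)
    ids = {c.id for c in clusters if c.category in cats}
    sub = calls.loc[calls.index.isin(ids), f"{condition}_status"]
    n_up = int((sub == "Up").sum())
    n_down = int((sub == "Down").sum())
    if n_down == 0:
        return float("inf"), True
    return n_up / n_down, False


@dataclass
class OverlapResult:
    a_only: int
    b_only: int
    shared: int


def overlap_sets(set_a: SpuriousSet, set_b: SpuriousSet, slack_bp: int = 0) -> OverlapResult:
    """Venn-style counts between two cluster sets.

    Intervals are extended by ``slack_bp`` on both sides; connected
    components of the resulting overlap graph that contain members from
    both sets count as shared (symmetric by construction), components
    containing only one set count toward that set's exclusive total.
    """
    if slack_bp < 0:
        raise ValueError("slack_bp must be ≥ 0")
    entries = []  # (chrom, start, end, which)
    for which, ss in (("A", set_a), ("B", set_b)):
        for c in ss.members:
            entries.append(
                (c.interval.chrom, c.interval.start - slack_bp, c.interval.end + slack_bp, which)
            )
    entries.sort(key=lambda e: (e[0], e[1], e[2]))
    a_only = b_only = shared = 0
    comp: set[str] | None = None
    comp_end = -1
    comp_chrom = None

    def _flush():
        nonlocal a_only, b_only, shared
        if comp is None:
            return
        if comp == {"A", "B"}:
            shared += 1
        elif comp == {"A"}:
            a_only += comp_n["A"]
        else:
            b_only += comp_n["B"]

    comp_n = {"A": 0, "B": 0}
    for chrom, s, e, which in entries:
        if comp is None or chrom != comp_chrom or s >= comp_end:
            _flush()
            comp, comp_n = set(), {"A": 0, "B": 0}
            comp_chrom, comp_end = chrom, e
        comp.add(which)
        comp_n[which] += 1
        comp_end = max(comp_end, e)
    _flush()
    return OverlapResult(a_only=a_only, b_only=b_only, shared=shared)


def nearest_distance(
    query: SpuriousSet | list[ConsensusCluster],
    reference: SpuriousSet | list[ConsensusCluster],
    within_bp: int = 100,
) -> tuple[pd.Series, float]:
    """Per-query distance (bp) between dominant positions to the closest
    same-chromosome reference, and the fraction of non-missing queries
    within ``within_bp``."""
    qm = query.members if isinstance(query, SpuriousSet) else query
    rm = reference.members if isinstance(reference, SpuriousSet) else reference
    if not rm:
        raise ValueError("empty reference set")
    ref_by_chrom: dict[str, np.ndarray] = {}
    for c in rm:
        ref_by_chrom.setdefault(c.interval.chrom, []).append(c.dominant_pos)
    ref_by_chrom = {k: np.sort(np.asarray(v, dtype=np.int64)) for k, v in ref_by_chrom.items()}
    dists: dict[str, float] = {}
    for c in qm:
        refs = ref_by_chrom.get(c.interval.chrom)
        if refs is None:
            dists[c.id] = np.nan
            continue
        i = int(np.searchsorted(refs, c.dominant_pos))
        best = np.inf
        if i < refs.size:
            best = min(best, abs(int(refs[i]) - c.dominant_pos))
        if i > 0:
            best = min(best, abs(int(refs[i - 1]) - c.dominant_pos))
        dists[c.id] = float(best)
    ser = pd.Series(dists, dtype=float)
    valid = ser.dropna()
    frac = float((valid <= within_bp).mean()) if len(valid) else float("nan")
    return ser, frac


QUARTILE_GROUPS = ("High", "Intermediate", "Low", "No")


def expression_quartiles(genes) -> pd.Series:
    """gene_id → expression group, splitting genes sorted by descending
    WT expression into four equal groups (np.array_split sizes); ties are
    broken by gene_id for determinism."""
    items = sorted(genes, key=lambda g: (-g.expression, g.gene_id))
    ids = [g.gene_id for g in items]
    out: dict[str, str] = {}
    for group, chunk in zip(QUARTILE_GROUPS, np.array_split(np.arange(len(ids)), 4)):
        for i in chunk:
            out[ids[int(i)]] = group
    return pd.Series(out, dtype=object)


def attribute_to_genes(
    spurious: SpuriousSet,
    quartiles: pd.Series,
    occupancy_labels: dict[str, str] | None = None,
) -> dict[str, dict[str, float]]:
    """Fraction of set members per expression quartile (and per occupancy
    class when labels are supplied); fractions sum to 1 over non-empty
    groups."""
    counts: dict[str, int] = {}
    occ_counts: dict[str, int] = {}
    for c in spurious.members:
        if not c.host_gene_id:
            raise ValueError(f"spurious member {c.id} has no host gene")
        if c.host_gene_id not in quartiles.index:
            raise ValueError(f"host gene {c.host_gene_id} missing from quartile table")
        grp = quartiles[c.host_gene_id]
        counts[grp] = counts.get(grp, 0) + 1
        if occupancy_labels is not None:
            occ = occupancy_labels.get(c.host_gene_id, "none")
            occ_counts[occ] = occ_counts.get(occ, 0) + 1
    n = len(spurious.members)
    out = {"quartile": {g: counts.get(g, 0) / n for g in QUARTILE_GROUPS if n}}
    if occupancy_labels is not None and n:
        out["occupancy"] = {k: v / n for k, v in sorted(occ_counts.items())}
    return out


@dataclass
class ContingencyResult:
    observed: np.ndarray
    expected: np.ndarray
    statistic: float
    dof: int
    p_value: float


def chi_square_test(observed) -> ContingencyResult:
    """Pearson chi-square test of independence, no continuity correction.

    Expected counts come from the table margins; df = (r−1)(c−1).
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need a table with ≥2 rows and ≥2 columns")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    res = stats.chi2_contingency(obs, correction=False)
    return ContingencyResult(
        observed=obs,
        expected=np.asarray(res.expected_freq),
        statistic=float(res.statistic),
        dof=int(res.dof),
        p_value=float(res.pvalue),
    )
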