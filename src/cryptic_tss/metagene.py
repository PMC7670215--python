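"""Strand-oriented metagene signal profiles around TSSs.

A MetageneMatrix holds, per site, mean coverage in fixed-size bins over a
window centered on the site's dominant position, oriented 5'→3' by site
strand (minus-strand rows are computed over the mirrored window and
reversed, so that mirroring the genome leaves column profiles invariant).
Sites are isolation-filtered before profiling to avoid signal bleed from
neighbors; Top/Bottom sensitivity groups are compared by per-site relative
difference with a two-sided Mann-Whitney rank-sum test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import ConsensusCluster
from .core import SignalTrack

log = logging.getLogger(__name__)


def isolation_filter(
    sites: list[ConsensusCluster],
    min_separation_bp: int,
    exclusion_sets: list[tuple[list[int] | dict[str, list[int]], int]] | None = None,
    positions_by_chrom: dict[str, dict[str, int]] | None = None,
) -> list[ConsensusCluster]:
    """Keep sites whose dominant position is ≥ min_separation_bp from every
    OTHER input site (both members of a close pair are dropped) and ≥ the
    stated distance from every member of each exclusion set.

    ``exclusion_sets`` items are (positions, min_distance) where positions
    is {chrom: [1-based positions]}.
    """
    if min_separation_bp < 0:
        raise ValueError("min_separation_bp must be ≥ 0")
    by_chrom: dict[str, list[tuple[int, ConsensusCluster]]] = {}
    for c in sites:
        by_chrom.setdefault(c.interval.chrom, []).append((c.dominant_pos, c))
    kept: list[ConsensusCluster] = []
    excl = []
    for positions, dist in exclusion_sets or []:
        excl.append(({k: np.sort(np.asarray(v, dtype=np.int64)) for k, v in positions.items()}, dist))
    for chrom, items in by_chrom.items():
        items.sort(key=lambda t: t[0])
        pos = np.asarray([p for p, _ in items], dtype=np.int64)
        for i, (p, c) in enumerate(items):
            near = False
            if i > 0 and p - pos[i - 1] < min_separation_bp:
                near = True
            if i + 1 < pos.size and pos[i + 1] - p < min_separation_bp:
                near = True
            if near:
                continue
            drop = False
            for exc_pos, dist in excl:
                refs = exc_pos.get(chrom)
                if refs is None or refs.size == 0:
                    continue
                j = int(np.searchsorted(refs, p))
                d = min(
                    abs(int(refs[j]) - p) if j < refs.size else np.inf,
                    abs(int(refs[j - 1]) - p) if j > 0 else np.inf,
                )
                if d < dist:
                    drop = True
                    break
            if not drop:
                kept.append(c)
    kept.sort(key=lambda c: (c.interval.chrom, c.dominant_pos))
    return kept


@dataclass
class MetageneMatrix:
    site_ids: list[str]
    halfwidth: int
    bin_size: int
    matrix: np.ndarray  # sites × bins, oriented 5'→3'; NaN = out of bounds
    track_name: str
    condition: str = ""

    @property
    def n_bins(self) -> int:
        return 2 * self.halfwidth // self.bin_size

    def column_profile(self) -> np.ndarray:
        """Mean signal per bin over sites (NaN bins excluded)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.matrix, axis=0)

    def bin_offsets(self) -> np.ndarray:
        """5' offset of each bin relative to the site, in bp."""
        return np.arange(-self.halfwidth, self.halfwidth, self.bin_size)

    def central_means(self, center_halfwidth: int) -> np.ndarray:
        """Per-site mean over the central ± center_halfwidth bins."""
        off = self.bin_offsets()
        sel = (off >= -center_halfwidth) & (off < center_halfwidth)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.matrix[:, sel], axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.site_ids, columns=self.bin_offsets())


def compute_metagene(
    track: SignalTrack,
    sites: list[ConsensusCluster],
    halfwidth: int = 1000,
    bin_size: int = 25,
    condition: str = "",
) -> MetageneMatrix:
    """Per-site binned coverage around the dominant position.

    Oriented offset o ∈ [−halfwidth, halfwidth) maps to genomic position
    ``dom0 + o`` on plus-strand sites and ``dom0 − o`` on minus-strand
    sites (dom0 = 0-based dominant position). Out-of-bounds positions are
    NaN and excluded from column means; sites on unknown chromosomes are
    skipped with a logged warning.
    """
    if halfwidth % bin_size != 0:
        raise ValueError("halfwidth must be divisible by bin_size")
    n_bins = 2 * halfwidth // bin_size
    rows: list[np.ndarray] = []
    ids: list[str] = []
    n_skipped = 0
    for c in sites:
        arr = track.data.get(c.interval.chrom)
        if arr is None:
            n_skipped += 1
            continue
        dom0 = c.dominant_pos - 1
        if c.strand == "-":
            lo, hi = dom0 - halfwidth + 1, dom0 + halfwidth + 1
        else:
            lo, hi = dom0 - halfwidth, dom0 + halfwidth
        vals = np.full(2 * halfwidth, np.nan)
        s, e = max(lo, 0), min(hi, arr.size)
        if e > s:
            vals[s - lo : e - lo] = arr[s:e]
        if c.strand == "-":
            vals = vals[::-1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            row = np.nanmean(vals.reshape(n_bins, bin_size), axis=1)
        rows.append(row)
        ids.append(c.id)
    if n_skipped:
        log.warning("compute_metagene: skipped %d sites on unknown chromosomes", n_skipped)
    matrix = np.vstack(rows) if rows else np.empty((0, n_bins))
    return MetageneMatrix(ids, halfwidth, bin_size, matrix, track.name, condition)


def relative_difference(
    mat_ko: MetageneMatrix,
    mat_wt: MetageneMatrix,
    center_halfwidth: int = 250,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-site (m_KO − m_WT) / (m_WT + ψ) over the central window."""
    if mat_ko.site_ids != mat_wt.site_ids or mat_ko.matrix.shape != mat_wt.matrix.shape:
        raise ValueError("matrices must share sites and bins")
    m_ko = mat_ko.central_means(center_halfwidth)
    m_wt = mat_wt.central_means(center_halfwidth)
    return pd.Series((m_ko - m_wt) / (m_wt + pseudocount), index=mat_ko.site_ids)


def rank_top_bottom(
    members: list[ConsensusCluster],
    calls: pd.DataFrame,
    ko_conditions: list[str],
    fraction: float = 0.175,
    score: str = "diff",
) -> tuple[list[ConsensusCluster], list[ConsensusCluster]]:
    """Split sites into Top/Bottom groups by upregulation score.

    score="diff": mean KO TP10M − mean WT TP10M (averaged over KO
    conditions); score="lfc": mean log2 fold change. Top = first
    ⌊fraction·n⌋ after descending sort, Bottom = last ⌊fraction·n⌋; ties
    broken by cluster id.
    """
    if not (0 < fraction <= 0.5):
        raise ValueError("fraction must be in (0, 0.5]")
    if score not in ("diff", "lfc"):
        raise ValueError("score must be 'diff' or 'lfc'")

    def _score(c: ConsensusCluster) -> float:
        if score == "lfc":
            return float(np.mean([calls.at[c.id, f"{k}_lfc"] for k in ko_conditions]))
        ko = float(np.mean([calls.at[c.id, f"{k}_mean"] for k in ko_conditions]))
        return ko - float(calls.at[c.id, "wt_mean"])

    ranked = sorted(members, key=lambda c: (-_score(c), c.id))
    k = int(np.floor(fraction * len(ranked)))
    return ranked[:k], ranked[len(ranked) - k :]


@dataclass
class GroupComparison:
    labels: tuple[str, str]
    sizes: tuple[int, int]
    values_a: np.ndarray
    values_b: np.ndarray
    statistic: float
    p_value: float
    method: str


def rank_sum_test(values_a, values_b, labels: tuple[str, str] = ("A", "B")) -> GroupComparison:
    """Two-sided Mann-Whitney U test.

    Exact null distribution when both groups have ≤ 20 observations and
    there are no ties; tie-corrected normal approximation otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if a.size <= 20 and b.size <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        labels=labels,
        sizes=(a.size, b.size),
        values_a=a,
        values_b=b,
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=method,
    )


def plot_profiles(matrices: list[MetageneMatrix], path) -> None:
    """Column metagene profiles, one line per track/condition."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for m in matrices:
        label = f"{m.track_name} {m.condition}".strip()
        ax.plot(m.bin_offsets() + m.bin_size / 2, m.column_profile(), label=label)
    ax.set_xlabel("distance from TSS (bp)")
    ax.set_ylabel("mean signal")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
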