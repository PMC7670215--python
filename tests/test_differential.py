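"""Up/Down/On/Off calls, sensitive sets, set statistics and tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cryptic_tss.clustering import ConsensusCluster
from cryptic_tss.core import GeneModel, GenomicInterval
from cryptic_tss.differential import (
    SpuriousSet,
    attribute_to_genes,
    call_differential,
    chi_square_test,
    define_dnmt3b_sensitive,
    define_pwwp2_sensitive,
    expression_quartiles,
    nearest_distance,
    overlap_sets,
    updown_ratio,
)

DESIGN = {"WT": ["w1", "w2"], "KO_A": ["a1", "a2"], "KO_B": ["b1", "b2"]}


def make_calls(rows):
    """rows: cluster_id → (wt, ko_a, ko_b) mean TP10M (replicates equal)."""
    expr = pd.DataFrame(
        {c: {"w1": v[0], "w2": v[0], "a1": v[1], "a2": v[1], "b1": v[2], "b2": v[2]}
         for c, v in rows.items()}
    ).T
    return call_differential(expr, DESIGN)


def make_cluster(cid, category, enhancer=False, chrom="chr1", start=None, host="gH",
                 strand="+", cpg=False):
    start = start if start is not None else 100
    return ConsensusCluster(
        id=cid,
        interval=GenomicInterval(chrom, start, start + 10, strand),
        expression={},
        dominant_pos=start + 5,
        category=category,
        enhancer_overlap=enhancer,
        host_gene_id=host if category != "intergenic" else "",
        cpg_island_overlap=cpg,
    )


class TestCallDifferential:
    def test_on_definition(self):
        calls = make_calls({"c": (0.0, 8.0, 8.0)})
        assert calls.loc["c", "KO_A_status"] == "On"

    def test_equal_means_unchanged(self):
        calls = make_calls({"c": (4.0, 4.0, 4.0)})
        assert calls.loc["c", "KO_A_status"] == "Unchanged"
        assert calls.loc["c", "KO_A_lfc"] == pytest.approx(0.0)

    def test_fold_change_arithmetic(self):
        # log2((8 + 0.1)/(2 + 0.1)) = 1.9475 ≥ 1 → Up
        calls = make_calls({"c": (2.0, 8.0, 2.0)})
        assert calls.loc["c", "KO_A_lfc"] == pytest.approx(np.log2(8.1 / 2.1))
        assert calls.loc["c", "KO_A_status"] == "Up"

    def test_off_and_absent(self):
        calls = make_calls({"off": (5.0, 0.0, 5.0), "abs": (0.0, 0.0, 0.0)})
        assert calls.loc["off", "KO_A_status"] == "Off"
        assert calls.loc["abs", "KO_A_status"] == "Absent"

    def test_status_exclusivity(self):
        rng = np.random.default_rng(1)
        rows = {f"c{i}": tuple(rng.uniform(0, 10, 3)) for i in range(100)}
        calls = make_calls(rows)
        for col in ("KO_A_status", "KO_B_status"):
            assert calls[col].isin(["Up", "Down", "Unchanged", "On", "Off", "Absent"]).all()

    def test_unknown_sample_errors(self):
        expr = pd.DataFrame({"w1": [1.0]}, index=["c"])
        with pytest.raises(ValueError, match="unknown samples"):
            call_differential(expr, {"WT": ["w1"], "KO": ["nope"]})


class TestSensitiveSets:
    def _clusters(self):
        return [
            make_cluster("both_up", "intronic"),
            make_cluster("one_clone", "intronic", start=300),
            make_cluster("enh", "exonic", enhancer=True, start=600),
            make_cluster("intergenic_up", "intergenic", start=900),
        ]

    def _calls(self):
        return make_calls(
            {
                "both_up": (2.0, 9.0, 9.0),
                "one_clone": (2.0, 9.0, 2.0),
                "enh": (2.0, 9.0, 9.0),
                "intergenic_up": (2.0, 9.0, 9.0),
            }
        )

    def test_pwwp2_rules(self):
        ss = define_pwwp2_sensitive(self._calls(), self._clusters(), ("KO_A", "KO_B"))
        assert ss.ids == ["both_up"]

    def test_provenance_counts_non_increasing(self):
        ss = define_pwwp2_sensitive(self._calls(), self._clusters(), ("KO_A", "KO_B"))
        counts = [c for _, c in ss.provenance]
        assert counts == sorted(counts, reverse=True)
        assert counts[-1] == len(ss)

    def test_dnmt3b_rules(self):
        clusters = [
            make_cluster("on_intronic", "intronic"),
            make_cluster("off_exonic", "exonic", start=300),
            make_cluster("up_atac", "exonic", enhancer=True, start=600),
        ]
        calls = make_calls(
            {"on_intronic": (0.0, 8.0, 0), "off_exonic": (5.0, 0.0, 0), "up_atac": (2.0, 9.0, 0)}
        )
        ss = define_dnmt3b_sensitive(calls, clusters, "KO_A")
        assert ss.ids == ["on_intronic"]


class TestUpdownRatio:
    def test_simple_ratio(self):
        clusters = [make_cluster(f"c{i}", "exonic", start=i * 50) for i in range(21)]
        rows = {f"c{i}": (2.0, 9.0, 2.0) for i in range(14)}
        rows.update({f"c{i}": (9.0, 2.0, 2.0) for i in range(14, 21)})
        ratio, inf = updown_ratio(make_calls(rows), clusters, "exonic", "KO_A")
        assert not inf and ratio == pytest.approx(2.0)

    def test_no_down_flagged_infinite(self):
        clusters = [make_cluster(f"c{i}", "exonic", start=i * 50) for i in range(5)]
        rows = {f"c{i}": (2.0, 9.0, 2.0) for i in range(5)}
        ratio, inf = updown_ratio(make_calls(rows), clusters, "exonic", "KO_A")
        assert inf and ratio == float("inf")


class TestOverlapSets:
    def _set(self, label, spans, chrom="chr1"):
        members = [
            make_cluster(f"{label}{i}", "intronic", chrom=chrom, start=s)
            for i, s in enumerate(spans)
        ]
        for m, s in zip(members, spans):
            m.interval = GenomicInterval(chrom, s, s + 10, "+")
        return SpuriousSet(label, members)

    def test_identical_singletons_shared(self):
        a, b = self._set("a", [100]), self._set("b", [100])
        r = overlap_sets(a, b)
        assert (r.a_only, r.b_only, r.shared) == (0, 0, 1)

    def test_disjoint_far_apart(self):
        r = overlap_sets(self._set("a", [100]), self._set("b", [10100]))
        assert (r.a_only, r.b_only, r.shared) == (1, 1, 0)

    def test_slack_arithmetic(self):
        # A = [100,110), B = [150,160): extended by 25 → [75,135) vs [125,185)
        r = overlap_sets(self._set("a", [100]), self._set("b", [150]), slack_bp=25)
        assert r.shared == 1

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        a = self._set("a", sorted(rng.integers(0, 5000, 30).tolist()))
        b = self._set("b", sorted(rng.integers(0, 5000, 20).tolist()))
        r1, r2 = overlap_sets(a, b, 10), overlap_sets(b, a, 10)
        assert r1.shared == r2.shared
        assert (r1.a_only, r1.b_only) == (r2.b_only, r2.a_only)


class TestNearestDistance:
    def _set(self, label, positions, chrom="chr1"):
        members = []
        for i, p in enumerate(positions):
            c = make_cluster(f"{label}{i}", "intronic", chrom=chrom, start=max(0, p - 5))
            c.dominant_pos = p
            members.append(c)
        return SpuriousSet(label, members)

    def test_simple_minimum(self):
        d, _ = nearest_distance(self._set("q", [1000]), self._set("r", [900, 1950]))
        assert d.iloc[0] == 100

    def test_coincident_is_zero(self):
        d, frac = nearest_distance(self._set("q", [500]), self._set("r", [500]))
        assert d.iloc[0] == 0 and frac == 1.0

    def test_empty_reference_errors(self):
        with pytest.raises(ValueError, match="empty reference"):
            nearest_distance(self._set("q", [1]), self._set("r", []))

    def test_matches_allpairs_bruteforce(self):
        rng = np.random.default_rng(9)
        q = self._set("q", rng.integers(1, 10**6, 500).tolist())
        r = self._set("r", rng.integers(1, 10**6, 500).tolist())
        d, _ = nearest_distance(q, r)
        rpos = np.array([c.dominant_pos for c in r.members])
        for c in q.members:
            assert d[c.id] == np.abs(rpos - c.dominant_pos).min()

    def test_other_chromosome_is_missing(self):
        d, _ = nearest_distance(self._set("q", [100], chrom="chr2"), self._set("r", [100]))
        assert np.isnan(d.iloc[0])


def make_genes(expressions):
    return [
        GeneModel(f"g{i:02d}", GenomicInterval("chr1", 10 + 100 * i, 100 + 100 * i, "+"), [[]], [])
        for i in range(len(expressions))
    ]


class TestQuartiles:
    def test_eight_genes(self):
        genes = make_genes(range(8))
        for g, e in zip(genes, [8, 7, 6, 5, 4, 3, 2, 1]):
            g.expression = e
        q = expression_quartiles(genes)
        assert (q[["g00", "g01"]] == "High").all()
        assert (q[["g06", "g07"]] == "No").all()

    def test_ties_broken_by_gene_id(self):
        genes = make_genes([0] * 4)
        for g in genes:
            g.expression = 5.0
        q = expression_quartiles(genes)
        assert list(q[["g00", "g01", "g02", "g03"]]) == ["High", "Intermediate", "Low", "No"]

    def test_remainder_rule_sizes(self):
        genes = make_genes(range(10))
        for i, g in enumerate(genes):
            g.expression = 10 - i
        q = expression_quartiles(genes)
        sizes = q.value_counts()
        assert sizes["High"] == 3 and sizes["Intermediate"] == 3
        assert sizes["Low"] == 2 and sizes["No"] == 2


class TestAttribution:
    def _quartiles(self):
        return pd.Series({"gHigh": "High", "gLow": "Low"})

    def test_fraction(self):
        members = [make_cluster(f"c{i}", "intronic", host="gHigh", start=i * 50) for i in range(9)]
        members.append(make_cluster("c9", "intronic", host="gLow", start=900))
        out = attribute_to_genes(SpuriousSet("s", members), self._quartiles())
        assert out["quartile"]["High"] == pytest.approx(0.9)
        assert sum(out["quartile"].values()) == pytest.approx(1.0)

    def test_single_gene_gets_all(self):
        members = [make_cluster(f"c{i}", "exonic", host="gLow", start=i * 50) for i in range(4)]
        out = attribute_to_genes(SpuriousSet("s", members), self._quartiles())
        assert out["quartile"]["Low"] == 1.0

    def test_missing_host_errors(self):
        c = make_cluster("c", "intergenic")
        with pytest.raises(ValueError, match="no host gene"):
            attribute_to_genes(SpuriousSet("s", [c]), self._quartiles())


class TestChiSquare:
    def test_homogeneous_table(self):
        res = chi_square_test([[10, 10], [10, 10]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.dof == 1

    def test_hand_evaluated_2x2(self):
        # margins 30/30; expected 15 everywhere; Σ(O−E)²/E = 4·(25/15) = 6.667
        res = chi_square_test([[20, 10], [10, 20]])
        assert res.statistic == pytest.approx(20 * 25 / 75, rel=1e-12)
        assert res.statistic == pytest.approx(6.6667, abs=1e-4)
        assert res.p_value == pytest.approx(stats.chi2.sf(res.statistic, 1))

    def test_2x4_dof(self):
        res = chi_square_test([[5, 6, 7, 8], [8, 7, 6, 5]])
        assert res.dof == 3

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError, match="zero margin"):
            chi_square_test([[0, 0], [5, 5]])

    def test_expected_from_margins(self):
        res = chi_square_test([[20, 10], [10, 20]])
        assert res.expected == pytest.approx(np.full((2, 2), 15.0))
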