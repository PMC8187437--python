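"""Gene-level association: overlap counting, permutation p, max(T), ORs."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import cnvcohort as cc
from cnvcohort.core import CNVCall, CohortCallSet, GeneRegion


def call(sample, start, end, state=2, chrom="chr1", n_markers=10):
    return CNVCall(sample_id=sample, chrom=chrom, start=start, end=end,
                   state=state, n_markers=n_markers)


def counts_frame(per_sample, genes=("G",)):
    """Build the per-sample event-count matrix directly (all 'del')."""
    cols = pd.MultiIndex.from_product([genes, ["del", "dup"]])
    df = pd.DataFrame(0, index=list(per_sample), columns=cols, dtype=int)
    for sid, vals in per_sample.items():
        for g, v in zip(genes, np.atleast_1d(vals)):
            df.loc[sid, (g, "del")] = v
    return df


class TestGeneOverlapCounts:
    def test_call_spanning_two_genes(self):
        genes = [GeneRegion("A", "chr1", 1000, 2000),
                 GeneRegion("B", "chr1", 2500, 3500)]
        cs = CohortCallSet(calls=[call("S0", 1500, 3000)],
                           labels={"S0": "case"})
        m = cc.gene_overlap_counts(cs, genes)
        assert m.loc["S0", ("A", "del")] == 1
        assert m.loc["S0", ("B", "del")] == 1

    def test_case_enriched_fixture_counts(self):
        """Event counts split del/dup per group, e.g. 2 case deletions +
        6 case duplications vs 1 control duplication -> (2, 6, 0, 1)."""
        labels = {f"C{i}": "case" for i in range(8)}
        labels.update({f"H{i}": "control" for i in range(2)})
        gene = [GeneRegion("CNTN6like", "chr3", 1_134_619, 1_445_278)]
        calls = ([call(f"C{i}", 1_200_000, 1_300_000, state=2, chrom="chr3")
                  for i in range(2)]
                 + [call(f"C{i}", 1_200_000, 1_300_000, state=5, chrom="chr3")
                    for i in range(2, 8)]
                 + [call("H0", 1_200_000, 1_300_000, state=5, chrom="chr3")])
        cs = CohortCallSet(calls=calls, labels=labels)
        g = cc.group_counts(cc.gene_overlap_counts(cs, gene), labels)
        row = g.loc["CNTN6like"]
        assert (row["case_del"], row["case_dup"], row["ctrl_del"],
                row["ctrl_dup"]) == (2, 6, 0, 1)

    def test_empty_callset_zero(self):
        genes = [GeneRegion("A", "chr1", 1000, 2000)]
        cs = CohortCallSet(calls=[], labels={"S0": "case", "S1": "control"})
        assert cc.gene_overlap_counts(cs, genes).to_numpy().sum() == 0

    def test_duplicate_symbols_rejected(self):
        genes = [GeneRegion("A", "chr1", 1, 10), GeneRegion("A", "chr1", 20, 30)]
        cs = CohortCallSet(calls=[], labels={"S0": "case"})
        with pytest.raises(ValueError, match="duplicate"):
            cc.gene_overlap_counts(cs, genes)


class TestOddsRatioCI:
    @pytest.mark.parametrize("a,n1,b,n0,expected", [
        (8, 1031, 1, 1830, (14.30, 1.79, 114.52)),
        (5, 1031, 1, 1830, (8.91, 1.04, 76.40)),
        (46, 1031, 56, 1830, (1.48, 0.99, 2.20)),
    ])
    def test_woolf_reference_values(self, a, n1, b, n0, expected):
        or_v, lo, hi = cc.odds_ratio_ci(a, n1, b, n0)
        assert round(or_v, 2) == expected[0]
        assert round(lo, 2) == expected[1]
        assert round(hi, 2) == expected[2]

    def test_zero_cell_undefined(self):
        or_v, lo, hi = cc.odds_ratio_ci(4, 1031, 0, 1830)
        assert np.isnan(or_v) and np.isnan(lo) and np.isnan(hi)

    def test_equal_rates_or_one(self):
        or_v, _, _ = cc.odds_ratio_ci(10, 100, 10, 100)
        assert or_v == pytest.approx(1.0)

    def test_label_swap_inverts(self):
        or_ab, lo_ab, hi_ab = cc.odds_ratio_ci(8, 100, 3, 200)
        or_ba, lo_ba, hi_ba = cc.odds_ratio_ci(3, 200, 8, 100)
        assert or_ba == pytest.approx(1 / or_ab)
        assert lo_ba == pytest.approx(1 / hi_ab)
        assert hi_ba == pytest.approx(1 / lo_ab)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            cc.odds_ratio_ci(11, 10, 0, 10)


class TestAssocTest:
    def test_matches_exhaustive_enumeration(self):
        # 4 cases / 4 controls, 3 carriers all in cases
        labels = {f"S{i}": ("case" if i < 4 else "control")
                  for i in range(8)}
        counts = counts_frame({f"S{i}": (1 if i < 3 else 0)
                               for i in range(8)})
        # oracle: exhaustive 70-relabel enumeration with >= exceedance
        carriers = np.array([1, 1, 1, 0, 0, 0, 0, 0])
        obs = 3
        exceed = sum(carriers[list(idx)].sum() >= obs
                     for idx in combinations(range(8), 4))
        p_exact = exceed / 70  # = 5/70
        engine = cc.PermutationEngine(n_perm=10_000, seed=2)
        out = cc.assoc_test(counts, labels, engine)
        se = np.sqrt(p_exact * (1 - p_exact) / 10_000)
        assert abs(out.loc["G", "p_raw"] - p_exact) < 3 * se + 1e-4

    def test_single_gene_adjusted_equals_raw(self):
        labels = {f"S{i}": ("case" if i < 4 else "control")
                  for i in range(8)}
        counts = counts_frame({f"S{i}": (1 if i < 2 else 0)
                               for i in range(8)})
        out = cc.assoc_test(counts, labels,
                            cc.PermutationEngine(n_perm=999, seed=0))
        assert out.loc["G", "p_adj"] == pytest.approx(out.loc["G", "p_raw"])

    def test_maxt_dominance(self):
        rng = np.random.default_rng(3)
        labels = {f"S{i}": ("case" if i < 20 else "control")
                  for i in range(40)}
        genes = [f"G{j}" for j in range(15)]
        per = {f"S{i}": rng.binomial(1, 0.2, size=15) for i in range(40)}
        counts = counts_frame(per, genes=genes)
        out = cc.assoc_test(counts, labels,
                            cc.PermutationEngine(n_perm=499, seed=4))
        assert (out["p_adj"] >= out["p_raw"] - 1e-12).all()

    def test_zero_carrier_gene_flagged(self):
        labels = {"A": "case", "B": "control"}
        counts = counts_frame({"A": 0, "B": 0})
        out = cc.assoc_test(counts, labels,
                            cc.PermutationEngine(n_perm=99, seed=0))
        assert out.loc["G", "p_raw"] == 1.0
        assert bool(out.loc["G", "no_carriers"])

    def test_planted_signal_gene_wins(self):
        # one all-case-carrier gene among 30 null genes tops the ranking
        rng = np.random.default_rng(5)
        labels = {f"S{i}": ("case" if i < 25 else "control")
                  for i in range(50)}
        genes = ["HIT"] + [f"N{j}" for j in range(30)]
        per = {}
        for i in range(50):
            row = np.concatenate([
                [1 if i < 10 else 0],  # HIT: 10 case-only carriers
                rng.binomial(1, 0.05, size=30)])
            per[f"S{i}"] = row
        counts = counts_frame(per, genes=genes)
        out = cc.assoc_test(counts, labels,
                            cc.PermutationEngine(n_perm=999, seed=6))
        assert out["p_adj"].idxmin() == "HIT"

    def test_gene_and_sample_order_invariance(self):
        rng = np.random.default_rng(6)
        labels = {f"S{i}": ("case" if i < 5 else "control")
                  for i in range(10)}
        genes = [f"G{j}" for j in range(4)]
        per = {f"S{i}": rng.binomial(1, 0.3, size=4) for i in range(10)}
        counts = counts_frame(per, genes=genes)
        engine = cc.PermutationEngine(n_perm=199, seed=7)
        a = cc.assoc_test(counts, labels, engine)
        shuffled = counts.iloc[::-1]
        b = cc.assoc_test(shuffled, labels, engine)
        # same per-gene observed statistics and counts regardless of order
        assert (a["stat"] == b["stat"]).all()
        assert (a[["case_del", "case_dup"]] ==
                b[["case_del", "case_dup"]]).all().all()

    def test_literal_marker_denominator_variant(self):
        labels = {f"S{i}": ("case" if i < 4 else "control")
                  for i in range(8)}
        counts = counts_frame({f"S{i}": (1 if i < 3 else 0)
                               for i in range(8)})
        out = cc.assoc_test(counts, labels,
                            cc.PermutationEngine(n_perm=99, seed=0,
                                                 maxt_denominator="n_genes"))
        assert 0 < out.loc["G", "p_adj"] <= 1


class TestSubgroupCompare:
    def _callset(self):
        labels, subgroups, calls = {}, {}, []
        for i in range(12):
            sid = f"P{i}"
            labels[sid] = "case"
            subgroups[sid] = ["HCC", "LC", "ASC_CH"][i % 3]
        for i in range(12):
            sid = f"H{i}"
            labels[sid] = "control"
            subgroups[sid] = "NA"
        # LC-only duplication locus
        for i in range(12):
            if subgroups[f"P{i}"] == "LC":
                calls.append(call(f"P{i}", 10_000, 20_000, state=5))
        return CohortCallSet(calls=calls, labels=labels, subgroups=subgroups)

    def test_contrasts_emitted(self):
        cs = self._callset()
        genes = [GeneRegion("G1", "chr1", 5_000, 25_000)]
        out = cc.subgroup_compare(cs, genes,
                                  cc.PermutationEngine(n_perm=99, seed=0))
        assert "HCC_vs_control" in out and "HCC_vs_LC" in out

    def test_lc_only_locus_tops_lc_contrast(self):
        cs = self._callset()
        genes = [GeneRegion("G1", "chr1", 5_000, 25_000),
                 GeneRegion("G2", "chr1", 500_000, 600_000)]
        out = cc.subgroup_compare(cs, genes,
                                  cc.PermutationEngine(n_perm=999, seed=1))
        lc = out["LC_vs_control"]
        assert lc["p_raw"].idxmin() == "G1"

    def test_full_case_set_equals_all_case_analysis(self):
        cs = self._callset()
        genes = [GeneRegion("G1", "chr1", 5_000, 25_000)]
        engine = cc.PermutationEngine(n_perm=199, seed=2)
        out = cc.subgroup_compare(cs, genes, engine,
                                  contrasts=[("case", "control")])
        counts = cc.gene_overlap_counts(cs, genes)
        direct = cc.assoc_test(counts, dict(cs.labels), engine)
        pd.testing.assert_frame_equal(out["case_vs_control"], direct)

    def test_empty_subgroup_skipped(self, caplog):
        cs = self._callset()
        genes = [GeneRegion("G1", "chr1", 5_000, 25_000)]
        with caplog.at_level("WARNING"):
            out = cc.subgroup_compare(
                cs, genes, cc.PermutationEngine(n_perm=99, seed=0),
                contrasts=[("NOSUCH", "control")])
        assert out == {}
        assert "skipped" in caplog.text


def test_filter_by_age():
    df = pd.DataFrame({
        "sample_id": ["A", "B", "C"],
        "phenotype": ["control", "control", "case"],
        "subgroup": ["NA", "NA", "HCC"],
        "age": [45.0, 62.0, 30.0]})
    out = cc.filter_by_age(df, 50)
    assert list(out["sample_id"]) == ["B", "C"]
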