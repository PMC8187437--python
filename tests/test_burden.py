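"""Burden summaries, permutation p-values, and regulatory coverage."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import cnvcohort as cc
from cnvcohort.core import CNVCall, CohortCallSet, Interval, RegionSet


def call(sample, start, end, state=2, n_markers=10, chrom="chr1"):
    return CNVCall(sample_id=sample, chrom=chrom, start=start, end=end,
                   state=state, n_markers=n_markers)


def toy_callset(calls, labels):
    return CohortCallSet(calls=calls, labels=labels)


class TestPerSampleBurden:
    def test_zero_call_sample_all_zeros(self):
        cs = toy_callset([], {"A": "case"})
        genes = RegionSet("g", [])
        (b,) = cc.per_sample_burden(cs, genes)
        assert b.n_calls == 0 and b.total_kb == 0
        assert np.isnan(b.genes_per_100kb)

    def test_genes_per_100kb(self):
        # one 200 kb call hitting 3 genes -> 3 / (200/100) = 1.5
        genes = RegionSet("g", [Interval("chr1", 10_000, 11_000, "g1"),
                                Interval("chr1", 50_000, 51_000, "g2"),
                                Interval("chr1", 90_000, 91_000, "g3")])
        cs = toy_callset([call("A", 1, 200_000)], {"A": "case"})
        (b,) = cc.per_sample_burden(cs, genes)
        assert b.n_genic_calls == 1
        assert b.genes_hit == 3
        assert b.genes_per_100kb == pytest.approx(1.5)

    def test_call_count_conservation(self):
        rng = np.random.default_rng(0)
        labels = {f"S{i}": ("case" if i % 2 else "control")
                  for i in range(20)}
        calls = []
        for i in range(200):
            sid = f"S{rng.integers(20)}"
            s = int(rng.integers(1, 900_000))
            calls.append(call(sid, s, s + 1000,
                              state=int(rng.choice([1, 2, 5, 6]))))
        cs = toy_callset(calls, labels)
        burdens = cc.per_sample_burden(cs, RegionSet("g", []))
        assert sum(b.n_calls for b in burdens) == 200
        for b in burdens:
            assert b.n_calls == b.n_del + b.n_dup


class TestEmpiricalP:
    def test_formula(self):
        perm = np.zeros(9999)
        assert cc.empirical_p(1.0, perm) == pytest.approx(1e-4)

    def test_all_exceed(self):
        assert cc.empirical_p(0.0, np.ones(100)) == 1.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            cc.empirical_p(1.0, np.array([]))

    def test_tie_rules(self):
        perm = np.array([1.0, 1.0, 2.0, 0.0])
        assert cc.empirical_p(1.0, perm, "ge") == pytest.approx(4 / 5)
        assert cc.empirical_p(1.0, perm, "gt") == pytest.approx(2 / 5)

    def test_matches_exhaustive_enumeration(self):
        # 4 cases / 4 controls, statistic = case carrier count
        carriers = np.array([1, 1, 1, 0, 0, 0, 0, 0], dtype=float)
        obs = carriers[:4].sum()  # 3 carriers in cases
        exhaustive = [carriers[list(idx)].sum()
                      for idx in combinations(range(8), 4)]
        assert len(exhaustive) == 70
        p_exact = cc.empirical_p(obs, np.array(exhaustive))
        # closed form: relabelings with >= 3 case carriers =
        # C(3,3)*C(5,1) + 0 = 5 of 70 (only k=3 possible)
        assert p_exact == pytest.approx((5 + 1) / (70 + 1))
        # Monte-Carlo agrees within 3 binomial SE
        rng = np.random.default_rng(1)
        mc = np.array([carriers[rng.permutation(8)[:4]].sum()
                       for _ in range(10_000)])
        p_mc = cc.empirical_p(obs, mc)
        se = np.sqrt(p_exact * (1 - p_exact) / 10_000)
        assert abs(p_mc - 5 / 70) < 3 * se + 1e-4


class TestPermuteBurden:
    def _burdens(self, values, labels):
        burdens = []
        for (sid, _), v in zip(labels.items(), values):
            n = 1 if v > 0 else 0
            burdens.append(cc.SampleBurden(
                sample_id=sid, n_calls=n, n_del_cn1=n, total_kb=float(v)))
        return burdens

    def test_extreme_separation(self):
        labels = {f"S{i}": ("case" if i < 4 else "control")
                  for i in range(8)}
        burdens = self._burdens([100, 90, 80, 70, 1, 1, 1, 1], labels)
        out = cc.permute_burden(burdens, labels, n_perm=999, seed=0,
                                statistics=("avg_kb",))
        # all case burdens > all controls: only the identity-like
        # assignments reach the observed mean -> p = C(4,4)... near 1/70
        assert out["p_raw"].iloc[0] <= (1 + np.ceil(999 / 70) * 3) / 1000

    def test_type_i_error_calibration(self):
        # null labels: rejection rate at alpha=0.05 within binomial 3 SE
        rng = np.random.default_rng(7)
        n_reps, alpha = 400, 0.05
        rejections = 0
        labels = {f"S{i}": ("case" if i < 25 else "control")
                  for i in range(50)}
        for rep in range(n_reps):
            values = rng.exponential(50, size=50)
            burdens = self._burdens(values, labels)
            out = cc.permute_burden(burdens, labels, n_perm=199,
                                    seed=int(rng.integers(2**31)),
                                    statistics=("avg_kb",))
            if out["p_raw"].iloc[0] <= alpha:
                rejections += 1
        rate = rejections / n_reps
        se = np.sqrt(alpha * (1 - alpha) / n_reps)
        assert abs(rate - alpha) < 3 * se

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(8)
        labels = {f"S{i}": ("case" if i < 10 else "control")
                  for i in range(20)}
        ps = []
        for rep in range(200):
            burdens = self._burdens(rng.exponential(50, size=20), labels)
            out = cc.permute_burden(burdens, labels, n_perm=99,
                                    seed=int(rng.integers(2**31)),
                                    statistics=("avg_kb",))
            ps.append(out["p_raw"].iloc[0])
        assert 0.3 <= np.median(ps) <= 0.7

    def test_bonferroni_monotone(self):
        labels = {f"S{i}": ("case" if i < 5 else "control")
                  for i in range(10)}
        rng = np.random.default_rng(9)
        burdens = self._burdens(rng.exponential(50, size=10), labels)
        out = cc.permute_burden(burdens, labels, n_perm=199, seed=3)
        assert (out["p_bonf"] >= out["p_raw"] - 1e-12).all()
        assert (out["p_bonf"] <= 1.0).all()


class TestGroupBurdenTable:
    def test_proportion_formatting(self):
        assert cc.proportion_with_cnv(769, 1031) == 74.6
        assert cc.proportion_with_cnv(1253, 1830) == 68.5

    def test_uniform_cohort_means(self):
        labels = {f"S{i}": ("case" if i < 3 else "control")
                  for i in range(6)}
        calls = [call(f"S{i}", 1, 100_000) for i in range(6)]  # 100 kb each
        cs = toy_callset(calls, labels)
        burdens = cc.per_sample_burden(cs, RegionSet("g", []))
        table = cc.group_burden_table(burdens, labels, n_perm=99, seed=0)
        row = table.set_index("statistic")
        assert row.loc["avg_kb", "case"] == pytest.approx(100.0, rel=1e-3)
        assert row.loc["proportion_with_cnv", "case"] == 100.0

    def test_empty_group_raises(self):
        labels = {"A": "case"}
        burdens = [cc.SampleBurden(sample_id="A")]
        with pytest.raises(ValueError, match="empty group"):
            cc.group_burden_table(burdens, labels, n_perm=9)


def promoter_model():
    segs = [Interval("chr1", i * 25_000 + 1, i * 25_000 + 20_000,
                     "TssA" if i % 2 else "PromU") for i in range(40)]
    return cc.ChromatinModel(tissue="T1", segments=RegionSet("c", segs))


class TestRegulatoryCoverage:
    def test_single_call_counts_segments(self):
        # 100 kb call crossing 4 segments of one subgroup
        segs = [Interval("chr1", i * 25_000 + 1, i * 25_000 + 20_000,
                         "PromU") for i in range(8)]
        model = cc.ChromatinModel(tissue="T", segments=RegionSet("c", segs))
        labels = {"A": "case", "B": "control"}
        cs = toy_callset([call("A", 1, 100_000), call("B", 500_000, 600_000)],
                         labels)
        out = cc.regulatory_coverage(cs, model, n_perm=9, seed=0)
        prom = out.set_index("subgroup").loc["promoter"]
        assert prom["case_mean"] == pytest.approx(4.0)

    def test_identical_groups_ratio_one(self):
        model = promoter_model()
        labels = {"A": "case", "B": "control"}
        calls = [call("A", 1, 100_000), call("B", 1, 100_000)]
        out = cc.regulatory_coverage(toy_callset(calls, labels), model,
                                     n_perm=9, seed=0)
        ratios = out["ratio"].dropna()
        assert np.allclose(ratios, 1.0)

    def test_planted_case_enrichment_detected(self):
        model = promoter_model()
        labels = {f"C{i}": "case" for i in range(20)}
        labels.update({f"H{i}": "control" for i in range(20)})
        calls = []
        for i in range(20):
            # cases hit the promoter-dense region; controls a desert
            calls.append(call(f"C{i}", 1, 100_000))
            calls.append(call(f"H{i}", 2_000_000, 2_100_000))
        out = cc.regulatory_coverage(toy_callset(calls, labels), model,
                                     n_perm=999, seed=1)
        prom = out.set_index("subgroup").loc["promoter"]
        assert prom["ratio"] > 1 or np.isnan(prom["ratio"])
        assert prom["p_raw"] < 0.05

    def test_segment_order_invariance(self):
        segs = [Interval("chr1", i * 25_000 + 1, i * 25_000 + 20_000,
                         "PromU") for i in range(8)]
        m1 = cc.ChromatinModel(tissue="T", segments=RegionSet("c", segs))
        m2 = cc.ChromatinModel(tissue="T",
                               segments=RegionSet("c", segs[::-1]))
        labels = {"A": "case", "B": "control"}
        cs = toy_callset([call("A", 1, 100_000), call("B", 1, 50_000)],
                         labels)
        a = cc.regulatory_coverage(cs, m1, n_perm=9, seed=0)
        b = cc.regulatory_coverage(cs, m2, n_perm=9, seed=0)
        pd.testing.assert_frame_equal(a, b)

    def test_subgroup_map_covers_25_states(self):
        mapping = cc.load_subgroup_map()
        assert len(mapping) == 25
        subgroups = {v for v in mapping.values() if v != "none"}
        assert len(subgroups) == 12
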