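"""Global CNV burden statistics and permutation tests.

Per-sample burden summaries (call counts by copy number, total/average size,
genic content), group-level burden tables with label-permutation p-values
and Bonferroni adjustment, and chromatin-state regulatory-region coverage
per 100 kb of CNV with case/control ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .core import CNVCall, CohortCallSet, Interval, RegionSet

#: The burden statistics tested jointly (Bonferroni family).
BURDEN_STATISTICS = ("proportion_with_cnv", "avg_kb", "n_genic_calls",
                     "genes_per_100kb")


@dataclass(frozen=True)
class SampleBurden:
    sample_id: str
    n_calls: int = 0
    n_del_cn0: int = 0
    n_del_cn1: int = 0
    n_dup_cn3: int = 0
    n_dup_cn4: int = 0
    total_kb: float = 0.0
    n_genic_calls: int = 0
    genes_hit: int = 0

    @property
    def n_del(self) -> int:
        return self.n_del_cn0 + self.n_del_cn1

    @property
    def n_dup(self) -> int:
        return self.n_dup_cn3 + self.n_dup_cn4

    @property
    def avg_kb(self) -> float:
        return self.total_kb / self.n_calls if self.n_calls else float("nan")

    @property
    def genes_per_100kb(self) -> float:
        if self.total_kb <= 0:
            return float("nan")
        return self.genes_hit / (self.total_kb / 100.0)


def per_sample_burden(callset: CohortCallSet,
                      genes: RegionSet) -> list[SampleBurden]:
    """One burden record per labeled sample (zero records included).

    A call is genic when it overlaps at least one gene span by >= 1 bp;
    ``genes_hit`` counts distinct genes overlapped by any of the sample's
    calls.
    """
    by_sample: dict[str, list[CNVCall]] = {s: [] for s in callset.labels}
    for c in callset.calls:
        by_sample[c.sample_id].append(c)
    out = []
    for sid, calls in by_sample.items():
        if not calls:
            out.append(SampleBurden(sample_id=sid))
            continue
        cn = [c.copy_number for c in calls]
        hit_genes: set[str] = set()
        n_genic = 0
        for c in calls:
            overlapped = genes.overlapping(c.chrom, c.start, c.end)
            if overlapped:
                n_genic += 1
                hit_genes.update(iv.label for iv in overlapped)
        out.append(SampleBurden(
            sample_id=sid,
            n_calls=len(calls),
            n_del_cn0=sum(1 for x in cn if x == 0),
            n_del_cn1=sum(1 for x in cn if x == 1),
            n_dup_cn3=sum(1 for x in cn if x == 3),
            n_dup_cn4=sum(1 for x in cn if x == 4),
            total_kb=sum(c.length for c in calls) / 1000.0,
            n_genic_calls=n_genic,
            genes_hit=len(hit_genes)))
    return out


def empirical_p(observed: float, permuted: np.ndarray,
                tie_rule: str = "ge") -> float:
    """Permutation p-value (R + 1) / (N + 1).

    R counts permuted statistics that exceed the observed one; the default
    tie rule ">=" counts ties as exceedances (the conservative convention),
    "gt" uses a strict comparison.
    """
    permuted = np.asarray(permuted, dtype=float)
    if permuted.size == 0:
        raise ValueError("empty permutation vector")
    if tie_rule == "ge":
        r = int(np.sum(permuted >= observed))
    elif tie_rule == "gt":
        r = int(np.sum(permuted > observed))
    else:
        raise ValueError(f"unknown tie_rule {tie_rule!r}")
    return (r + 1) / (permuted.size + 1)


def bonferroni(p: float, k: int) -> float:
    return min(1.0, k * p)


def _group_stats(values: np.ndarray, valid: np.ndarray,
                 member: np.ndarray) -> float:
    """Mean of ``values`` over group members with a valid denominator."""
    mask = member & valid
    if not mask.any():
        return float("nan")
    return float(values[mask].mean())


def _burden_vectors(burdens: list[SampleBurden]):
    has_cnv = np.array([b.n_calls > 0 for b in burdens], dtype=float)
    avg_kb = np.array([b.avg_kb if b.n_calls else np.nan for b in burdens])
    n_genic = np.array([float(b.n_genic_calls) for b in burdens])
    g100 = np.array([b.genes_per_100kb for b in burdens])
    valid = {
        "proportion_with_cnv": np.ones(len(burdens), dtype=bool),
        "avg_kb": ~np.isnan(avg_kb),
        "n_genic_calls": np.ones(len(burdens), dtype=bool),
        "genes_per_100kb": ~np.isnan(g100),
    }
    values = {"proportion_with_cnv": has_cnv, "avg_kb": avg_kb,
              "n_genic_calls": n_genic, "genes_per_100kb": g100}
    return values, valid


def permute_burden(burdens: list[SampleBurden], labels: dict[str, str],
                   n_perm: int = 50_000, seed: int = 0,
                   statistics: tuple[str, ...] = BURDEN_STATISTICS,
                   sided: str = "greater",
                   tie_rule: str = "ge") -> pd.DataFrame:
    """Label-permutation test of case-vs-control burden means.

    The test statistic for each burden summary is the case-group mean
    (one-sided, case > control, by default; "two" doubles the smaller
    tail via the absolute case-control difference).  All statistics share
    one permutation stream so joint comparisons are coherent.  Returns a
    DataFrame with observed case/control means, raw p and Bonferroni p
    (family size = number of statistics tested).
    """
    import warnings
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives very coarse p-values")
    lab = np.array([labels[b.sample_id] for b in burdens])
    is_case = lab == "case"
    n_case = int(is_case.sum())
    if n_case == 0 or n_case == len(lab):
        raise ValueError("both groups must be present")
    values, valid = _burden_vectors(burdens)
    rng = np.random.default_rng(seed)
    n = len(burdens)
    perm_members = np.zeros((n_perm, n), dtype=bool)
    for i in range(n_perm):
        idx = rng.permutation(n)[:n_case]
        perm_members[i, idx] = True
    rows = []
    for stat in statistics:
        v, ok = values[stat], valid[stat]
        obs_case = _group_stats(v, ok, is_case)
        obs_ctrl = _group_stats(v, ok, ~is_case)
        vv = np.where(ok, v, 0.0)
        num = perm_members @ (vv * ok)
        den = perm_members @ ok.astype(float)
        with np.errstate(invalid="ignore"):
            perm_case_means = num / den
        if sided == "greater":
            obs_stat, perm_stat = obs_case, perm_case_means
        elif sided == "two":
            num_c = (~perm_members) @ (vv * ok)
            den_c = (~perm_members) @ ok.astype(float)
            with np.errstate(invalid="ignore"):
                perm_ctrl_means = num_c / den_c
            obs_stat = abs(obs_case - obs_ctrl)
            perm_stat = np.abs(perm_case_means - perm_ctrl_means)
        else:
            raise ValueError(f"unknown sidedness {sided!r}")
        p = empirical_p(obs_stat, perm_stat[~np.isnan(perm_stat)], tie_rule)
        rows.append((stat, obs_case, obs_ctrl, p,
                     bonferroni(p, len(statistics))))
    return pd.DataFrame(rows, columns=["statistic", "case_mean",
                                       "control_mean", "p_raw", "p_bonf"])


def group_burden_table(burdens: list[SampleBurden], labels: dict[str, str],
                       n_perm: int = 50_000, seed: int = 0) -> pd.DataFrame:
    """Group-level burden table for one cutoff.

    Rows mirror the conventional burden report: samples with >= 1 CNV,
    deletion/duplication counts split by copy number, proportion of
    samples with CNV, mean CNV size, mean genic-call count and genes per
    100 kb, with permutation p-values on the mean statistics.
    """
    lab = np.array([labels[b.sample_id] for b in burdens])
    groups = {"case": lab == "case", "control": lab == "control"}
    for g, mask in groups.items():
        if not mask.any():
            raise ValueError(f"empty group: {g}")
    values, valid = _burden_vectors(burdens)
    perm = permute_burden(burdens, labels, n_perm=n_perm, seed=seed)
    pmap = dict(zip(perm["statistic"], perm["p_bonf"]))

    def agg(mask) -> dict[str, float]:
        sel = [b for b, m in zip(burdens, mask) if m]
        return {
            "n_samples": len(sel),
            "samples_with_cnv": sum(1 for b in sel if b.n_calls > 0),
            "del_cn0": sum(b.n_del_cn0 for b in sel),
            "del_cn1": sum(b.n_del_cn1 for b in sel),
            "dup_cn3": sum(b.n_dup_cn3 for b in sel),
            "dup_cn4": sum(b.n_dup_cn4 for b in sel),
            "proportion_with_cnv": proportion_with_cnv(
                sum(1 for b in sel if b.n_calls > 0), len(sel)),
            "avg_kb": _group_stats(values["avg_kb"], valid["avg_kb"],
                                   np.asarray(mask)),
            "n_genic_calls": _group_stats(values["n_genic_calls"],
                                          valid["n_genic_calls"],
                                          np.asarray(mask)),
            "genes_per_100kb": _group_stats(values["genes_per_100kb"],
                                            valid["genes_per_100kb"],
                                            np.asarray(mask)),
        }

    case = agg(groups["case"])
    ctrl = agg(groups["control"])
    rows = []
    for key in case:
        p = pmap.get(key, float("nan"))
        rows.append((key, case[key], ctrl[key], p))
    return pd.DataFrame(rows, columns=["statistic", "case", "control",
                                       "p_bonf"])


def proportion_with_cnv(n_with: int, n_total: int) -> float:
    """Proportion of samples with >= 1 CNV, as a percentage to 0.1%."""
    if n_total == 0:
        raise ValueError("empty group")
    return round(100.0 * n_with / n_total, 1)


# ---------------------------------------------------------------------------
# chromatin-state regulatory coverage

def load_subgroup_map() -> dict[str, str]:
    """Packaged 25-state -> 12-subgroup mapping (quiescent maps to none)."""
    ref = resources.files("cnvcohort.data") / "chromatin_subgroups.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    return dict(zip(df["state"], df["subgroup"]))


@dataclass
class ChromatinModel:
    """A 25-state chromatin segmentation for one tissue/cell type."""

    tissue: str
    segments: RegionSet
    subgroup_map: dict[str, str] = field(default_factory=load_subgroup_map)

    def subgroups(self) -> list[str]:
        seen = []
        for sg in self.subgroup_map.values():
            if sg != "none" and sg not in seen:
                seen.append(sg)
        return seen

    def segments_for(self, subgroup: str) -> RegionSet:
        ivs = [iv for iv in self.segments
               if self.subgroup_map.get(iv.label) == subgroup]
        return RegionSet(f"{self.tissue}:{subgroup}", ivs)


def _coverage_vectors(callset: CohortCallSet, model: ChromatinModel
                      ) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-sample regulatory segments intersected per 100 kb of CNV.

    A segment counts once per sample per subgroup if any of the sample's
    calls intersects it by >= 1 bp.  Samples without calls get NaN (their
    per-100kb denominator is undefined).
    """
    samples = callset.sample_ids
    subgroups = model.subgroups()
    seg_sets = {sg: model.segments_for(sg) for sg in subgroups}
    by_sample: dict[str, list[CNVCall]] = {s: [] for s in samples}
    for c in callset.calls:
        by_sample[c.sample_id].append(c)
    mat = np.full((len(samples), len(subgroups)), np.nan)
    total_kb = np.zeros(len(samples))
    for i, sid in enumerate(samples):
        calls = by_sample[sid]
        if not calls:
            continue
        kb = sum(c.length for c in calls) / 1000.0
        total_kb[i] = kb
        for j, sg in enumerate(subgroups):
            hit: set[tuple] = set()
            for c in calls:
                for iv in seg_sets[sg].overlapping(c.chrom, c.start, c.end):
                    hit.add((iv.chrom, iv.start, iv.end))
            mat[i, j] = len(hit) / (kb / 100.0)
    return pd.DataFrame(mat, index=samples, columns=subgroups), total_kb


def regulatory_coverage(callset: CohortCallSet, model: ChromatinModel,
                        n_perm: int = 1000, seed: int = 0,
                        tie_rule: str = "ge") -> pd.DataFrame:
    """Case/control ratio of regulatory segments per 100 kb CNV.

    For each chromatin subgroup: group value = mean per-100kb segment count
    over samples with >= 1 call; ratio = case / control; permutation p from
    label shuffles of the case mean (one-sided, case > control).  Subgroups
    with zero control mean report a missing ratio.
    """
    cov, _ = _coverage_vectors(callset, model)
    lab = np.array([callset.labels[s] for s in cov.index])
    is_case = lab == "case"
    valid = ~cov.isna().to_numpy()
    v = np.nan_to_num(cov.to_numpy())
    rng = np.random.default_rng(seed)
    n = len(cov)
    n_case = int(is_case.sum())
    perm_members = np.zeros((n_perm, n), dtype=bool)
    for i in range(n_perm):
        perm_members[i, rng.permutation(n)[:n_case]] = True
    rows = []
    for j, sg in enumerate(cov.columns):
        ok = valid[:, j]
        case_mean = _group_stats(v[:, j], ok, is_case)
        ctrl_mean = _group_stats(v[:, j], ok, ~is_case)
        num = perm_members @ (v[:, j] * ok)
        den = perm_members @ ok.astype(float)
        with np.errstate(invalid="ignore"):
            perm_means = num / den
        p = empirical_p(case_mean, perm_means[~np.isnan(perm_means)],
                        tie_rule)
        ratio = (case_mean / ctrl_mean
                 if ctrl_mean and not np.isnan(ctrl_mean) and ctrl_mean > 0
                 else float("nan"))
        rows.append((model.tissue, sg, case_mean, ctrl_mean, ratio, p))
    return pd.DataFrame(rows, columns=["tissue", "subgroup", "case_mean",
                                       "control_mean", "ratio", "p_raw"])
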