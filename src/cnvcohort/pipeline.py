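"""End-to-end orchestration: signals on disk -> reports on disk.

Stage order mirrors the analysis workflow: sample QC -> PFB -> GC
adjustment -> Viterbi segmentation -> gap merging -> marker-count cutoffs
-> exclusion regions -> burden statistics (with permutations) ->
regulatory coverage -> gene-level association for every contrast.  One
global seed expands into per-stage child seeds via ``numpy.SeedSequence``
so stages can be rerun in isolation, and every report path is hashed into
the run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .assoc import PermutationEngine, assoc_test, gene_overlap_counts, subgroup_compare
from .burden import (ChromatinModel, group_burden_table, per_sample_burden,
                     regulatory_coverage)
from .core import CohortCallSet
from .hmm import HMMParams, segment_cohort
from .postprocess import (STANDARD_CUTOFFS, exclude_regions,
                          filter_min_markers, merge_cohort)
from .qc import QCThresholds, compute_pfb, gc_adjust, qc_report, sample_qc

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    signal_dir: str
    sample_sheet: str
    genes_bed: str
    exclusions_bed: str
    chromatin_bed: str | None
    marker_table: str | None
    out_dir: str
    cutoffs: tuple[int, ...] = STANDARD_CUTOFFS
    qc_thresholds: QCThresholds = field(default_factory=QCThresholds)
    hmm: HMMParams = field(default_factory=HMMParams)
    n_perm_burden: int = 50_000
    n_perm_assoc: int = 10_000
    n_perm_coverage: int = 1_000
    seed: int = 0
    run_subgroups: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "cutoffs" in raw:
            raw["cutoffs"] = tuple(raw["cutoffs"])
        return cls(**raw)


def stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Deterministic per-stage child seeds (< 2**31) from one global seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in
            ss.generate_state(n, dtype=np.uint32)]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    seed: int
    stages: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def record(self, stage: str, **info) -> None:
        self.stages[stage] = info
        logger.info("stage %s: %s", stage, info)

    def add_output(self, name: str, path: Path) -> None:
        self.outputs[name] = {"path": str(path), "sha256": _sha256(path)}

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, "stages": self.stages,
                       "outputs": self.outputs}, fh, indent=2, default=str)


def run_all(config: RunConfig, marker_map=None) -> RunManifest:
    """Execute the full pipeline and emit all report TSVs plus a manifest.

    ``marker_map`` may be passed directly (e.g. from the simulator);
    otherwise it is rebuilt from the first signal file (positions/GC from
    ``marker_table`` if given).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.seed)
    seeds = stage_seeds(config.seed)
    try:
        sheet = cio.read_sample_sheet(config.sample_sheet)
        labels = dict(zip(sheet["sample_id"], sheet["phenotype"]))
        subgroups = (dict(zip(sheet["sample_id"], sheet["subgroup"]))
                     if "subgroup" in sheet.columns else {})
        if marker_map is None:
            if config.marker_table:
                table = pd.read_csv(config.marker_table, sep="\t")
                from .core import MarkerMap
                marker_map = MarkerMap(table)
            else:
                raise ValueError("marker_table required when no MarkerMap given")
        signals = [cio.read_signal_file(
                       Path(config.signal_dir) / f"{sid}.signal.txt",
                       marker_map)
                   for sid in sheet["sample_id"]]
        manifest.record("load", n_samples=len(signals),
                        n_markers=len(marker_map))

        # --- sample QC (on GC-adjusted LRR) ---
        metrics = [sample_qc(s, marker_map, config.qc_thresholds)
                   for s in signals]
        rep = qc_report(metrics)
        rep.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        manifest.add_output("qc_report", out / "qc_report.tsv")
        passed = set(rep.loc[rep["pass"], "sample_id"])
        signals = [s for s in signals if s.sample_id in passed]
        labels = {s: g for s, g in labels.items() if s in passed}
        subgroups = {s: g for s, g in subgroups.items() if s in passed}
        manifest.record("sample_qc", n_pass=len(passed),
                        n_fail=len(rep) - len(passed))

        # --- PFB from control BAF ---
        if not marker_map.has_pfb:
            controls = [s for s in signals if labels.get(s.sample_id) == "control"]
            baf_matrix = np.stack([s.baf for s in controls], axis=1)
            marker_map = compute_pfb(None, marker_map, baf_matrix=baf_matrix)
        cio.write_pfb(out / "markers.pfb", marker_map)
        manifest.add_output("pfb", out / "markers.pfb")

        # --- GC adjustment + segmentation ---
        adjusted = [gc_adjust(s, marker_map) for s in signals]
        calls_by_sample = segment_cohort(adjusted, marker_map, config.hmm)
        raw_calls = [c for calls in calls_by_sample.values() for c in calls]
        cio.write_calls(out / "calls_raw.tsv", raw_calls)
        manifest.add_output("calls_raw", out / "calls_raw.tsv")
        manifest.record("viterbi", n_raw_calls=len(raw_calls))

        # --- postprocess ---
        exclusions = cio.read_bed(config.exclusions_bed, name="exclusions")
        merged = merge_cohort(raw_calls, marker_map=marker_map)
        genes_rs = cio.read_bed(config.genes_bed, name="genes")
        gene_regions = cio.gene_regions_from_bed(genes_rs)
        chromatin = None
        if config.chromatin_bed:
            chromatin = ChromatinModel(
                tissue="synthetic",
                segments=cio.read_bed(config.chromatin_bed, name="chromatin"))

        for i, cutoff in enumerate(config.cutoffs):
            filtered = filter_min_markers(merged, cutoff)
            cleaned = exclude_regions(
                filtered, [exclusions],
                known_chroms=set(marker_map.chroms))
            callset = CohortCallSet(calls=cleaned, labels=labels,
                                    subgroups=subgroups, cutoff=cutoff)
            tag = f"gt{cutoff}"
            cio.write_calls(out / f"calls_{tag}.tsv", cleaned)
            manifest.add_output(f"calls_{tag}", out / f"calls_{tag}.tsv")
            manifest.record(f"postprocess_{tag}", n_merged=len(merged),
                            n_filtered=len(filtered), n_final=len(cleaned))

            burdens = per_sample_burden(callset, genes_rs)
            table = group_burden_table(burdens, labels,
                                       n_perm=config.n_perm_burden,
                                       seed=seeds[0])
            table.to_csv(out / f"burden_{tag}.tsv", sep="\t", index=False)
            manifest.add_output(f"burden_{tag}", out / f"burden_{tag}.tsv")

            if chromatin is not None:
                cov = regulatory_coverage(callset, chromatin,
                                          n_perm=config.n_perm_coverage,
                                          seed=seeds[1])
                cov.to_csv(out / f"regulatory_{tag}.tsv", sep="\t",
                           index=False)
                manifest.add_output(f"regulatory_{tag}",
                                    out / f"regulatory_{tag}.tsv")

            engine = PermutationEngine(n_perm=config.n_perm_assoc,
                                       seed=seeds[2])
            counts = gene_overlap_counts(callset, gene_regions)
            res = assoc_test(counts, labels, engine)
            res.to_csv(out / f"assoc_{tag}.tsv", sep="\t")
            manifest.add_output(f"assoc_{tag}", out / f"assoc_{tag}.tsv")

            if config.run_subgroups and subgroups:
                for name, tbl in subgroup_compare(callset, gene_regions,
                                                  engine).items():
                    path = out / f"assoc_{tag}_{name}.tsv"
                    tbl.to_csv(path, sep="\t")
                    manifest.add_output(f"assoc_{tag}_{name}", path)
    except Exception as exc:
        manifest.record("FAILED", error=str(exc))
        manifest.write(out / "manifest.json")
        raise
    manifest.write(out / "manifest.json")
    return manifest
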