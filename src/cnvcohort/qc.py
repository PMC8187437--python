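"""Sample- and marker-level quality control for SNP-array signals.

Covers population B-allele frequency (PFB) estimation from control samples,
GC-wave adjustment of LRR, the three per-sample QC metrics used to gate
samples before CNV calling (LRR SD, BAF drift, wave factor), and control-based
marker filters (MAF, missingness, Hardy-Weinberg exact test).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MarkerMap, SampleSignal

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCThresholds:
    """Per-sample pass criteria (defaults are the conventional array-QC
    gates: LRR SD < 0.35, BAF drift < 0.01, |wave factor| < 0.05)."""

    max_lrr_sd: float = 0.35
    max_baf_drift: float = 0.01
    max_abs_wave_factor: float = 0.05


@dataclass(frozen=True)
class QCMetrics:
    sample_id: str
    lrr_sd: float
    baf_drift: float
    wave_factor: float
    passed: bool


def compute_pfb(genotypes: pd.DataFrame | None, marker_map: MarkerMap,
                baf_matrix: np.ndarray | None = None) -> MarkerMap:
    """Fill per-marker population frequency of the B allele from controls.

    From genotype calls when available: B-allele count / (2 x non-missing).
    Markers with no informative genotype fall back to 0.5 with a warning.
    Without genotypes, PFB is the mean control BAF per marker.
    """
    if genotypes is not None:
        if genotypes.shape[1] < 1:
            raise ValueError("need at least one control sample")
        g = genotypes.to_numpy()
        n_b = (g == "AB").sum(axis=1) + 2 * (g == "BB").sum(axis=1)
        n_called = (g != "NC").sum(axis=1)
        pfb = np.full(len(marker_map), 0.5)
        ok = n_called > 0
        pfb[ok] = n_b[ok] / (2 * n_called[ok])
        if (~ok).any():
            logger.warning("%d markers with all-missing genotypes; PFB set "
                           "to 0.5", int((~ok).sum()))
    elif baf_matrix is not None:
        baf = np.asarray(baf_matrix, dtype=float)
        if baf.ndim != 2 or baf.shape[0] != len(marker_map):
            raise ValueError("BAF matrix must be (markers x controls)")
        if baf.shape[1] < 1:
            raise ValueError("need at least one control sample")
        pfb = np.nanmean(baf, axis=1)
    else:
        raise ValueError("provide genotypes or a control BAF matrix")
    return marker_map.with_pfb(np.clip(pfb, 0.0, 1.0))


def gc_adjust(signal: SampleSignal, marker_map: MarkerMap) -> SampleSignal:
    """Remove the linear GC wave from LRR by OLS regression on GC content.

    The adjusted LRR is the regression residual plus the original LRR mean,
    so the genome-wide level is preserved.  A constant GC track makes the
    slope undefined; the adjustment is then the identity.
    """
    gc = marker_map.gc
    lrr = signal.lrr
    if len(gc) != len(lrr):
        raise ValueError("signal not aligned to marker map")
    var = np.var(gc)
    if var == 0:
        return SampleSignal(signal.sample_id, lrr.copy(), signal.baf.copy(),
                            signal.genotypes)
    slope = np.cov(gc, lrr, bias=True)[0, 1] / var
    fitted = lrr.mean() + slope * (gc - gc.mean())
    adjusted = lrr - fitted + lrr.mean()
    return SampleSignal(signal.sample_id, adjusted, signal.baf.copy(),
                        signal.genotypes)


def wave_factor(lrr: np.ndarray, marker_map: MarkerMap,
                window_bp: int = 1_000_000) -> float:
    """Signed GC-wave magnitude.

    Defined as the Pearson correlation between per-window median LRR and
    per-window mean GC, scaled by the SD of the window medians.  The sign
    tracks the wave phase relative to GC; near-flat tracks give ~0.
    """
    med_lrr, mean_gc = [], []
    for chrom, sl in marker_map.chrom_slices():
        pos = marker_map.positions[sl]
        sub_lrr = lrr[sl]
        sub_gc = marker_map.gc[sl]
        bins = (pos - 1) // window_bp
        for b in np.unique(bins):
            mask = bins == b
            if mask.sum() >= 3:
                med_lrr.append(np.median(sub_lrr[mask]))
                mean_gc.append(sub_gc[mask].mean())
    if len(med_lrr) < 2:
        return 0.0
    med_lrr = np.asarray(med_lrr)
    mean_gc = np.asarray(mean_gc)
    if np.std(med_lrr) == 0 or np.std(mean_gc) == 0:
        return 0.0
    r = np.corrcoef(med_lrr, mean_gc)[0, 1]
    return float(r * np.std(med_lrr))


def baf_drift(baf: np.ndarray) -> float:
    """Fraction of markers with BAF in the drift bands
    [0.2, 0.25] u [0.75, 0.8] — clean arrays keep BAF out of these bands."""
    b = np.asarray(baf)
    in_band = ((b >= 0.2) & (b <= 0.25)) | ((b >= 0.75) & (b <= 0.8))
    return float(in_band.mean())


def sample_qc(signal: SampleSignal, marker_map: MarkerMap,
              thresholds: QCThresholds = QCThresholds()) -> QCMetrics:
    """Compute the three gate metrics on the GC-adjusted autosomal LRR."""
    if len(signal) < 100:
        raise ValueError("insufficient markers for QC (need >= 100)")
    adj = gc_adjust(signal, marker_map)
    lrr_sd = float(np.std(adj.lrr, ddof=1))
    drift = baf_drift(adj.baf)
    wf = wave_factor(adj.lrr, marker_map)
    passed = (lrr_sd < thresholds.max_lrr_sd
              and drift < thresholds.max_baf_drift
              and -thresholds.max_abs_wave_factor < wf
              < thresholds.max_abs_wave_factor)
    return QCMetrics(signal.sample_id, lrr_sd, drift, wf, passed)


def qc_report(metrics: list[QCMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        [(m.sample_id, m.lrr_sd, m.baf_drift, m.wave_factor, m.passed)
         for m in metrics],
        columns=["sample_id", "lrr_sd", "baf_drift", "wave_factor", "pass"])


def hwe_exact_p(n_ab: int, n_aa: int, n_bb: int) -> float:
    """Two-sided Hardy-Weinberg exact test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more likely than the observed one (the
    standard exact formulation for biallelic markers).
    """
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    # rare allele count (conditioning statistic)
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    n_rare = min(n_a, n_b)
    # heterozygote count must match the parity of the rare allele count
    het_values = range(n_rare % 2, n_rare + 1, 2)
    logs = []
    for het in het_values:
        rare_hom = (n_rare - het) // 2
        common_hom = n - het - rare_hom
        if common_hom < 0:
            continue
        lp = (math.lgamma(n + 1)
              - math.lgamma(rare_hom + 1) - math.lgamma(het + 1)
              - math.lgamma(common_hom + 1)
              + het * math.log(2)
              + math.lgamma(n_rare + 1) + math.lgamma(2 * n - n_rare + 1)
              - math.lgamma(2 * n + 1))
        logs.append((het, lp))
    mx = max(lp for _, lp in logs)
    probs = {het: math.exp(lp - mx) for het, lp in logs}
    total = sum(probs.values())
    obs = probs.get(n_ab, 0.0)
    p = sum(v for v in probs.values() if v <= obs * (1 + 1e-12)) / total
    return min(1.0, p)


def marker_qc(genotypes: pd.DataFrame, marker_map: MarkerMap,
              min_maf: float = 0.10, max_missing: float = 0.01,
              min_hwe_p: float = 1e-6) -> list[str]:
    """Retain markers passing MAF, missingness and HWE filters in controls.

    Returns the ordered list of retained marker names.
    """
    if genotypes.shape[1] == 0:
        raise ValueError("empty genotype matrix")
    g = genotypes.to_numpy()
    n_samples = g.shape[1]
    n_aa = (g == "AA").sum(axis=1)
    n_ab = (g == "AB").sum(axis=1)
    n_bb = (g == "BB").sum(axis=1)
    n_called = n_aa + n_ab + n_bb
    missing = 1 - n_called / n_samples
    with np.errstate(invalid="ignore", divide="ignore"):
        p_b = (n_ab + 2 * n_bb) / (2 * n_called)
    maf = np.minimum(p_b, 1 - p_b)
    keep = (maf > min_maf) & (missing < max_missing) & (n_called > 0)
    idx = np.nonzero(keep)[0]
    retained = []
    names = genotypes.index.to_numpy()
    for i in idx:
        if hwe_exact_p(int(n_ab[i]), int(n_aa[i]), int(n_bb[i])) > min_hwe_p:
            retained.append(str(names[i]))
    return retained
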