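"""Post-calling filters: gap merging, marker-count cutoffs, region exclusion.

The pipeline order is fixed: merge adjacent calls, then apply the
marker-count cutoff, then drop calls overlapping exclusion regions
(V-(D)-J-recombining immunoglobulin/TCR loci, centromeres, telomeres, ...).
"""

from __future__ import annotations

import logging
from dataclasses import replace
from importlib import resources
from itertools import groupby

from .core import CNVCall, CohortCallSet, MarkerMap, RegionSet

logger = logging.getLogger(__name__)

#: Marker-count cutoffs conventionally examined side by side.
STANDARD_CUTOFFS = (5, 10, 15, 20)


def merge_adjacent(calls: list[CNVCall], fraction: float = 0.2,
                   marker_map: MarkerMap | None = None,
                   gap_denominator: str = "combined") -> list[CNVCall]:
    """Iteratively merge same-chromosome, same-state adjacent calls.

    A pair merges when the gap between them is smaller than ``fraction``
    times the combined length of the two calls.  ``gap_denominator``
    selects the denominator: "combined" (len1 + len2, the default reading)
    or "span" (end-to-end span including the gap).  Merging restarts from
    the left after every merge until no pair qualifies.  The merged call's
    marker count is the sum of the pair's counts plus any map markers that
    fall inside the gap (requires ``marker_map``; otherwise the gap
    contributes zero markers).

    Calls must belong to one sample and be pairwise disjoint.
    """
    if not calls:
        return []
    if len({c.sample_id for c in calls}) > 1:
        raise ValueError("merge_adjacent operates on a single sample")
    calls = sorted(calls, key=lambda c: (c.chrom, c.start))
    for a, b in zip(calls, calls[1:]):
        if a.chrom == b.chrom and b.start <= a.end:
            raise ValueError("calls must be disjoint")

    def gap_markers(chrom: str, gap_start: int, gap_end: int) -> int:
        if marker_map is None or gap_start > gap_end:
            return 0
        return marker_map.markers_in(chrom, gap_start, gap_end)

    merged = True
    while merged:
        merged = False
        for i in range(len(calls) - 1):
            a, b = calls[i], calls[i + 1]
            if a.chrom != b.chrom or a.state != b.state:
                continue
            gap = b.start - a.end - 1
            denom = (a.length + b.length if gap_denominator == "combined"
                     else b.end - a.start + 1)
            if gap < fraction * denom:
                n = a.n_markers + b.n_markers + gap_markers(
                    a.chrom, a.end + 1, b.start - 1)
                calls[i:i + 2] = [replace(
                    a, end=b.end, n_markers=n, end_marker=b.end_marker)]
                merged = True
                break
    return calls


def merge_cohort(calls: list[CNVCall], **kwargs) -> list[CNVCall]:
    """Apply :func:`merge_adjacent` per sample across a cohort."""
    out: list[CNVCall] = []
    key = lambda c: c.sample_id
    for _, grp in groupby(sorted(calls, key=key), key=key):
        out.extend(merge_adjacent(list(grp), **kwargs))
    return out


def filter_min_markers(calls: list[CNVCall], cutoff: int,
                       strict: bool = True) -> list[CNVCall]:
    """Retain calls supported by more than ``cutoff`` markers.

    The default comparison is strict (> cutoff), matching the ">5 markers"
    convention; ``strict=False`` keeps calls with at least ``cutoff``.
    """
    if strict:
        return [c for c in calls if c.n_markers > cutoff]
    return [c for c in calls if c.n_markers >= cutoff]


def exclude_regions(calls: list[CNVCall], region_sets: list[RegionSet],
                    min_overlap_fraction: float = 0.0,
                    known_chroms: set[str] | None = None) -> list[CNVCall]:
    """Drop calls overlapping any exclusion region.

    The default rule removes a call on >= 1 bp overlap;
    ``min_overlap_fraction`` > 0 instead requires that at least that
    fraction of the call be covered.  Regions on chromosomes absent from
    ``known_chroms`` (when given) are ignored with a warning.
    """
    if known_chroms is not None:
        for rs in region_sets:
            bad = rs.chroms() - known_chroms
            for chrom in sorted(bad):
                logger.warning("exclusion region on unknown chromosome %s "
                               "ignored", chrom)
    kept = []
    for call in calls:
        removed = False
        for rs in region_sets:
            if known_chroms is not None and call.chrom not in known_chroms:
                continue
            if min_overlap_fraction <= 0.0:
                if rs.any_overlap(call.chrom, call.start, call.end):
                    removed = True
                    break
            else:
                ov = rs.overlap_bp(call.chrom, call.start, call.end)
                if ov / call.length >= min_overlap_fraction:
                    removed = True
                    break
        if not removed:
            kept.append(call)
    return kept


def default_exclusion_regions() -> RegionSet:
    """Packaged hg19 immunoglobulin/TCR exclusion regions.

    These loci undergo V-(D)-J recombination in lymphocytes, so apparent
    copy-number changes there in blood-derived DNA are somatic rather than
    germline.
    """
    from .io import read_bed
    ref = resources.files("cnvcohort.data") / "ig_tcr_exclusions_hg19.bed"
    with resources.as_file(ref) as path:
        return read_bed(path, name="ig_tcr")


def postprocess_calls(calls: list[CNVCall], cutoff: int,
                      region_sets: list[RegionSet],
                      labels, subgroups=None,
                      marker_map: MarkerMap | None = None,
                      merge_fraction: float = 0.2,
                      min_overlap_fraction: float = 0.0) -> CohortCallSet:
    """Full postprocessing chain: merge -> marker cutoff -> exclusions."""
    merged = merge_cohort(calls, fraction=merge_fraction,
                          marker_map=marker_map)
    filtered = filter_min_markers(merged, cutoff)
    cleaned = exclude_regions(filtered, region_sets,
                              min_overlap_fraction=min_overlap_fraction)
    return CohortCallSet(calls=cleaned, labels=dict(labels),
                         subgroups=dict(subgroups or {}), cutoff=cutoff)
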