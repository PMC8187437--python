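"""Core domain containers shared across the pipeline.

Coordinates are 1-based inclusive everywhere inside the package; BED files
(0-based half-open) are converted at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: HMM state -> copy number for the six-state model used in SNP-array CNV
#: calling (states 3 and 4 are diploid; state 4 is copy-neutral LOH).
STATE_COPY_NUMBER: dict[int, int] = {1: 0, 2: 1, 3: 2, 4: 2, 5: 3, 6: 4}

#: States that are emitted as CNV calls (copy number differs from 2).
CNV_STATES: frozenset[int] = frozenset({1, 2, 5, 6})


class MarkerMap:
    """Ordered autosomal marker panel with GC context and PFB.

    Parameters
    ----------
    table:
        DataFrame with columns ``name``, ``chrom``, ``pos`` (1-based bp),
        ``gc`` (fraction), and optionally ``pfb`` (population B-allele
        frequency, filled by :func:`cnvcohort.qc.compute_pfb`).
    """

    REQUIRED = ("name", "chrom", "pos", "gc")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValueError(f"marker table missing columns: {missing}")
        table = table.reset_index(drop=True)
        if table["name"].duplicated().any():
            dup = table.loc[table["name"].duplicated(), "name"].iloc[0]
            raise ValueError(f"duplicate marker name: {dup!r}")
        for _, sub in table.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError("markers must be strictly sorted by position "
                                 "within each chromosome")
        self.table = table
        self._index = {n: i for i, n in enumerate(table["name"])}

    def __len__(self) -> int:
        return len(self.table)

    @property
    def names(self) -> np.ndarray:
        return self.table["name"].to_numpy()

    @property
    def chroms(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.table["pos"].to_numpy()

    @property
    def gc(self) -> np.ndarray:
        return self.table["gc"].to_numpy(dtype=float)

    @property
    def pfb(self) -> np.ndarray:
        if "pfb" not in self.table.columns:
            raise AttributeError("PFB not computed yet; run compute_pfb first")
        return self.table["pfb"].to_numpy(dtype=float)

    @property
    def has_pfb(self) -> bool:
        return "pfb" in self.table.columns

    def with_pfb(self, pfb: np.ndarray) -> "MarkerMap":
        pfb = np.asarray(pfb, dtype=float)
        if pfb.shape != (len(self),):
            raise ValueError("pfb length must equal marker count")
        if np.any((pfb < 0) | (pfb > 1)):
            raise ValueError("pfb must lie in [0, 1]")
        table = self.table.copy()
        table["pfb"] = pfb
        return MarkerMap(table)

    def index_of(self, name: str) -> int:
        return self._index[name]

    def chrom_slices(self) -> list[tuple[str, slice]]:
        """Contiguous (chromosome, row-slice) blocks in map order."""
        out = []
        chroms = self.chroms
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out.append((chroms[start], slice(start, i)))
                start = i
        return out

    def markers_in(self, chrom: str, start: int, end: int) -> int:
        """Number of markers with position in [start, end] on chrom."""
        sub = self.table[self.table["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        return int(np.searchsorted(pos, end, "right")
                   - np.searchsorted(pos, start, "left"))


@dataclass
class SampleSignal:
    """Per-sample LRR/BAF vectors aligned to a :class:`MarkerMap`."""

    sample_id: str
    lrr: np.ndarray
    baf: np.ndarray
    genotypes: np.ndarray | None = None  # values in {"AA","AB","BB","NC"}

    def __post_init__(self):
        self.lrr = np.asarray(self.lrr, dtype=float)
        self.baf = np.asarray(self.baf, dtype=float)
        if self.lrr.shape != self.baf.shape:
            raise ValueError("lrr and baf must have equal length")
        if self.genotypes is not None:
            self.genotypes = np.asarray(self.genotypes)
            if self.genotypes.shape != self.lrr.shape:
                raise ValueError("genotypes must align with signal vectors")

    def __len__(self) -> int:
        return len(self.lrr)


@dataclass(frozen=True)
class CNVCall:
    """One called CNV segment (1-based inclusive span)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    state: int
    n_markers: int
    start_marker: str = ""
    end_marker: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("call start must be <= end")
        if self.state not in CNV_STATES:
            raise ValueError(f"state {self.state} is not a CNV state")
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")

    @property
    def copy_number(self) -> int:
        return STATE_COPY_NUMBER[self.state]

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_deletion(self) -> bool:
        return self.copy_number < 2

    @property
    def is_duplication(self) -> bool:
        return self.copy_number > 2

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return (self.chrom == chrom and self.start <= end
                and start <= self.end)


@dataclass(frozen=True)
class Interval:
    """A labeled genomic interval, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("interval start must be <= end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class RegionSet:
    """A named collection of genomic intervals with fast overlap queries."""

    def __init__(self, name: str, intervals: Iterable[Interval]):
        self.name = name
        self.intervals = sorted(intervals, key=lambda r: (r.chrom, r.start, r.end))
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[Interval]]] = {}
        for iv in self.intervals:
            self._by_chrom.setdefault(iv.chrom, ([], [], []))  # type: ignore
        tmp: dict[str, list[Interval]] = {}
        for iv in self.intervals:
            tmp.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in tmp.items():
            starts = np.array([iv.start for iv in ivs])
            ends = np.array([iv.end for iv in ivs])
            self._by_chrom[chrom] = (starts, ends, ivs)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def chroms(self) -> set[str]:
        return set(self._by_chrom)

    def overlapping(self, chrom: str, start: int, end: int) -> list[Interval]:
        """Intervals overlapping [start, end] by >= 1 bp."""
        if chrom not in self._by_chrom:
            return []
        starts, ends, ivs = self._by_chrom[chrom]
        hit = (starts <= end) & (ends >= start)
        return [ivs[i] for i in np.nonzero(hit)[0]]

    def overlap_bp(self, chrom: str, start: int, end: int) -> int:
        """Total overlapped bp (intervals assumed non-self-overlapping)."""
        total = 0
        for iv in self.overlapping(chrom, start, end):
            total += min(end, iv.end) - max(start, iv.start) + 1
        return total

    def any_overlap(self, chrom: str, start: int, end: int) -> bool:
        if chrom not in self._by_chrom:
            return False
        starts, ends, _ = self._by_chrom[chrom]
        return bool(np.any((starts <= end) & (ends >= start)))


@dataclass(frozen=True)
class GeneRegion:
    """A gene span used for gene-level association (1-based inclusive)."""

    symbol: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.symbol}: start > end")


@dataclass
class CohortCallSet:
    """Post-filter calls for a cohort plus phenotype labels.

    ``labels`` maps sample_id -> phenotype ("case" or "control");
    ``subgroups`` optionally maps sample_id -> disease subgroup.
    """

    calls: list[CNVCall]
    labels: Mapping[str, str]
    subgroups: Mapping[str, str] = field(default_factory=dict)
    cutoff: int | None = None

    def __post_init__(self):
        unknown = {c.sample_id for c in self.calls} - set(self.labels)
        if unknown:
            raise ValueError(f"calls reference unlabeled samples: {sorted(unknown)[:3]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s, g in self.labels.items() if g == group]

    def calls_for(self, sample_id: str) -> list[CNVCall]:
        return [c for c in self.calls if c.sample_id == sample_id]

    def restrict(self, sample_ids: Sequence[str]) -> "CohortCallSet":
        keep = set(sample_ids)
        return CohortCallSet(
            calls=[c for c in self.calls if c.sample_id in keep],
            labels={s: g for s, g in self.labels.items() if s in keep},
            subgroups={s: g for s, g in self.subgroups.items() if s in keep},
            cutoff=self.cutoff,
        )

    def relabel(self, labels: Mapping[str, str]) -> "CohortCallSet":
        return replace(self, labels=dict(labels))
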