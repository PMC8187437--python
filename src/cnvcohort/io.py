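"""Readers and writers for the on-disk formats.

Signal files use the tab-delimited array-export dialect
(``Name  Chr  Position  <sample>.Log R Ratio  <sample>.B Allele Freq``);
BED files are 0-based half-open on disk and converted to the package's
1-based inclusive convention on read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import CNVCall, Interval, MarkerMap, RegionSet, SampleSignal


def write_signal_file(path: str | Path, signal: SampleSignal,
                      marker_map: MarkerMap) -> None:
    sid = signal.sample_id
    df = pd.DataFrame({
        "Name": marker_map.names,
        "Chr": marker_map.chroms,
        "Position": marker_map.positions,
        f"{sid}.Log R Ratio": np.round(signal.lrr, 4),
        f"{sid}.B Allele Freq": np.round(signal.baf, 4),
    })
    df.to_csv(path, sep="\t", index=False)


def read_signal_file(path: str | Path,
                     marker_map: MarkerMap | None = None) -> SampleSignal:
    """Parse a signal file; validate/reorder markers against the map.

    The sample name is taken from the LRR column header.  Rows are
    reordered to map order when a map is supplied; a marker absent from
    the file raises with the first divergent name.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed signal file: {exc}") from exc
    lrr_cols = [c for c in df.columns if c.endswith(".Log R Ratio")]
    baf_cols = [c for c in df.columns if c.endswith(".B Allele Freq")]
    if not lrr_cols or not baf_cols:
        raise ValueError(f"{path}: missing LRR/BAF columns")
    sid = lrr_cols[0].rsplit(".", 2)[0]
    for col in (lrr_cols[0], baf_cols[0]):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # 1-based + header
            raise ValueError(f"{path}: malformed numeric at line {line}")
    if marker_map is not None:
        df = df.set_index("Name")
        missing = [n for n in marker_map.names if n not in df.index]
        if missing:
            raise ValueError(f"{path}: marker mismatch; first divergent "
                             f"marker: {missing[0]}")
        df = df.loc[marker_map.names]
    lrr = pd.to_numeric(df[lrr_cols[0]], errors="coerce").to_numpy()
    baf = pd.to_numeric(df[baf_cols[0]], errors="coerce").to_numpy()
    return SampleSignal(sample_id=sid, lrr=lrr, baf=baf)


def write_bed(path: str | Path, intervals: list[Interval]) -> None:
    """Write 1-based inclusive intervals as 0-based half-open BED."""
    with open(path, "w") as fh:
        for iv in intervals:
            label = iv.label or "."
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{label}\n")


def read_bed(path: str | Path, name: str = "") -> RegionSet:
    """Read a BED file into a RegionSet (internal 1-based inclusive)."""
    path = Path(path)
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: need >= 3 BED columns")
            chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            if start0 >= end0:
                raise ValueError(f"{path}:{lineno}: start >= end")
            label = parts[3] if len(parts) > 3 else ""
            intervals.append(Interval(chrom, start0 + 1, end0, label))
    return RegionSet(name or path.stem, intervals)


def write_calls(path: str | Path, calls: list[CNVCall]) -> None:
    """Strict TSV call-set dialect, one column per field."""
    rows = [(c.sample_id, c.chrom, c.start, c.end, c.state, c.copy_number,
             c.n_markers, c.length, c.start_marker, c.end_marker)
            for c in calls]
    pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end",
                                "state", "cn", "numsnp", "length",
                                "startsnp", "endsnp"]).to_csv(
        path, sep="\t", index=False)


def write_calls_penncnv(path: str | Path, calls: list[CNVCall]) -> None:
    """PennCNV-style rawcnv dialect: chr:start-end numsnp=.. length=..
    state,cn= sample startsnp= endsnp=."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(f"{c.chrom}:{c.start}-{c.end}\tnumsnp={c.n_markers}\t"
                     f"length={c.length}\tstate{c.state},cn={c.copy_number}\t"
                     f"{c.sample_id}\tstartsnp={c.start_marker}\t"
                     f"endsnp={c.end_marker}\n")


def read_calls(path: str | Path) -> list[CNVCall]:
    df = pd.read_csv(path, sep="\t")
    return [CNVCall(sample_id=str(r.sample_id), chrom=str(r.chrom),
                    start=int(r.start), end=int(r.end), state=int(r.state),
                    n_markers=int(r.numsnp), start_marker=str(r.startsnp),
                    end_marker=str(r.endsnp))
            for r in df.itertuples()]


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    # keep_default_na: "NA" is a meaningful subgroup value, not missing data
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    if "age" in df.columns:
        df["age"] = pd.to_numeric(df["age"], errors="coerce")
    required = {"sample_id", "phenotype"}
    if not required <= set(df.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    return df


def write_pfb(path: str | Path, marker_map: MarkerMap) -> None:
    pd.DataFrame({"Name": marker_map.names, "Chr": marker_map.chroms,
                  "Position": marker_map.positions,
                  "PFB": np.round(marker_map.pfb, 4)}).to_csv(
        path, sep="\t", index=False)


def gene_regions_from_bed(regions: RegionSet):
    """Convert a labeled RegionSet into GeneRegion records."""
    from .core import GeneRegion
    return [GeneRegion(symbol=iv.label or f"g{i}", chrom=iv.chrom,
                       start=iv.start, end=iv.end)
            for i, iv in enumerate(regions)]
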