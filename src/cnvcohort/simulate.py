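"""Synthetic SNP-array cohort generator.

Emulates the statistical structure of Axiom-style genotyping-array data as
consumed by LRR/BAF CNV callers: an ordered marker panel with a smooth GC
track, Hardy-Weinberg genotypes, per-sample LRR/BAF signal vectors with
GC waves and Gaussian noise, and copy-number events planted at configurable
case/control carrier frequencies.  The generator is deterministic given a
seed and doubles as the fixture factory for the whole test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CNVCall, Interval, MarkerMap, SampleSignal, STATE_COPY_NUMBER

# Default LRR cluster geometry per HMM state (PennCNV-convention values;
# vendor HMM files are proprietary so these are package defaults).
DEFAULT_LRR_MEANS = {1: -3.5, 2: -0.66, 3: 0.0, 4: 0.0, 5: 0.40, 6: 0.68}
DEFAULT_LRR_SDS = {1: 1.0, 2: 0.2, 3: 0.2, 4: 0.2, 5: 0.2, 6: 0.2}

#: Fraction of homozygous BAF draws pinned exactly at 0/1 (array truncation).
DEFAULT_BOUNDARY_MASS = 0.3

#: Roadmap-style 25-state chromatin labels used for fixture BED files.
CHROMATIN_STATES_25 = [
    "TssA", "PromU", "PromD1", "PromD2", "Tx5", "Tx", "Tx3", "TxWk",
    "TxReg", "TxEnh5", "TxEnh3", "TxEnhW", "EnhA1", "EnhA2", "EnhAF",
    "EnhW1", "EnhW2", "EnhAc", "DNase", "ZNF/Rpts", "Het", "PromP",
    "PromBiv", "ReprPC", "Quies",
]


@dataclass(frozen=True)
class PlantedLocus:
    """A copy-number event planted at a locus with group-specific frequency."""

    chrom: str
    start: int
    end: int
    state: int  # 1, 2, 5 or 6 — planted events change copy number
    carrier_freq_case: float
    carrier_freq_control: float

    def __post_init__(self):
        if self.state in (3, 4):
            raise ValueError("planted events must change copy number "
                             "(state 3/4 not allowed)")
        if self.state not in STATE_COPY_NUMBER:
            raise ValueError(f"unknown state {self.state}")
        for f in (self.carrier_freq_case, self.carrier_freq_control):
            if not 0.0 <= f <= 1.0:
                raise ValueError("carrier frequencies must lie in [0, 1]")
        if self.start > self.end:
            raise ValueError("locus start must be <= end")


@dataclass
class SimConfig:
    """Study-design parameters of a synthetic cohort.

    ``lrr_sd``/``baf_sd`` are per-marker noise SDs; ``gc_wave_amplitude`` is
    the LRR shift per unit GC deviation from the panel mean (0 disables the
    wave); ``marker_spacing`` is the mean inter-marker gap in bp.
    """

    n_cases: int = 50
    n_controls: int = 50
    chromosomes: list[tuple[str, int]] = field(
        default_factory=lambda: [("chr1", 2_000_000)])
    marker_spacing: float = 1000.0
    planted_loci: list[PlantedLocus] = field(default_factory=list)
    lrr_sd: float = 0.2
    baf_sd: float = 0.03
    gc_wave_amplitude: float = 0.0
    gc_wave_period: float = 2_000_000.0
    allele_freq_range: tuple[float, float] = (0.05, 0.95)
    missing_rate: float = 0.0
    lrr_means: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_LRR_MEANS))
    boundary_mass: float = DEFAULT_BOUNDARY_MASS
    subgroup_fracs: dict[str, float] = field(
        default_factory=lambda: {"HCC": 0.46, "LC": 0.05, "ASC_CH": 0.49})
    seed: int = 0

    def __post_init__(self):
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be >= 1")
        if self.lrr_sd <= 0 or self.baf_sd <= 0:
            raise ValueError("lrr_sd and baf_sd must be > 0")
        declared = {name: length for name, length in self.chromosomes}
        for locus in self.planted_loci:
            if locus.chrom not in declared:
                raise ValueError(f"planted locus on undeclared chromosome {locus.chrom}")
            if locus.end > declared[locus.chrom]:
                raise ValueError("planted locus extends past chromosome end")

    @property
    def n_samples(self) -> int:
        return self.n_cases + self.n_controls


@dataclass
class TruthEvent:
    sample_id: str
    locus: PlantedLocus


@dataclass
class TruthSet:
    """Realized planted events, keyed by sample."""

    events: list[TruthEvent]

    def for_sample(self, sample_id: str) -> list[PlantedLocus]:
        return [e.locus for e in self.events if e.sample_id == sample_id]

    def carriers_of(self, locus: PlantedLocus) -> list[str]:
        return [e.sample_id for e in self.events if e.locus == locus]


def _rng(seed, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def build_marker_map(config: SimConfig) -> MarkerMap:
    """Lay down jittered markers along each chromosome with a smooth GC track.

    Inter-marker gaps are uniform on [0.5, 1.5] x ``marker_spacing``; the GC
    fraction follows a sinusoid in [0.3, 0.7] with period ``gc_wave_period``.
    """
    rng = _rng(config.seed, 1)
    rows = []
    for chrom, length in config.chromosomes:
        if length < 2 * config.marker_spacing:
            raise ValueError(f"chromosome too short: {chrom}")
        # oversample gaps, then trim to the chromosome
        n_guess = int(length / config.marker_spacing * 2) + 10
        gaps = rng.uniform(0.5, 1.5, size=n_guess) * config.marker_spacing
        pos = np.cumsum(gaps).astype(np.int64)
        pos = pos[pos <= length]
        pos = np.unique(pos)
        gc = 0.5 + 0.2 * np.sin(2 * np.pi * pos / config.gc_wave_period)
        for i, (p, g) in enumerate(zip(pos, gc)):
            rows.append((f"{chrom}_m{i:06d}", chrom, int(p), float(g)))
    table = pd.DataFrame(rows, columns=["name", "chrom", "pos", "gc"])
    return MarkerMap(table)


def simulate_genotypes(marker_map: MarkerMap, n_samples: int, seed: int,
                       allele_freq_range: tuple[float, float] = (0.05, 0.95),
                       missing_rate: float = 0.0,
                       baf_freqs: np.ndarray | None = None) -> pd.DataFrame:
    """Draw Hardy-Weinberg genotypes at each marker.

    Returns a (marker x sample) DataFrame of strings in {AA, AB, BB, NC}
    (NC = no-call).  Per-marker B-allele frequencies are uniform on
    ``allele_freq_range`` unless ``baf_freqs`` supplies them.
    """
    if len(marker_map) == 0:
        raise ValueError("marker map is empty")
    rng = _rng(seed, 2)
    m = len(marker_map)
    if baf_freqs is None:
        baf_freqs = rng.uniform(*allele_freq_range, size=m)
    baf_freqs = np.asarray(baf_freqs, dtype=float)
    u = rng.random((m, n_samples))
    p_aa = (1 - baf_freqs) ** 2
    p_ab = 2 * baf_freqs * (1 - baf_freqs)
    geno = np.full((m, n_samples), "BB", dtype="U2")
    geno[u < (p_aa + p_ab)[:, None]] = "AB"
    geno[u < p_aa[:, None]] = "AA"
    if missing_rate > 0:
        geno[rng.random((m, n_samples)) < missing_rate] = "NC"
    cols = [f"S{j:04d}" for j in range(n_samples)]
    out = pd.DataFrame(geno, index=marker_map.names, columns=cols)
    out.attrs["baf_freqs"] = baf_freqs
    return out


def assign_labels(config: SimConfig) -> pd.DataFrame:
    """Sample sheet: cases first, then controls; case subgroups drawn from
    ``subgroup_fracs``; ages drawn around cohort-typical means."""
    rng = _rng(config.seed, 3)
    rows = []
    subs = list(config.subgroup_fracs)
    probs = np.array([config.subgroup_fracs[s] for s in subs], dtype=float)
    probs = probs / probs.sum()
    for j in range(config.n_samples):
        sid = f"S{j:04d}"
        if j < config.n_cases:
            sub = subs[rng.choice(len(subs), p=probs)]
            age = float(np.clip(rng.normal(57.8, 12.8), 18, 95))
            rows.append((sid, "case", sub, round(age, 1)))
        else:
            age = float(np.clip(rng.normal(31.0, 12.2), 18, 95))
            rows.append((sid, "control", "NA", round(age, 1)))
    return pd.DataFrame(rows, columns=["sample_id", "phenotype", "subgroup", "age"])


def plant_events(config: SimConfig, labels: pd.DataFrame, seed: int) -> TruthSet:
    """Independently realize each planted locus per sample at the
    group-appropriate carrier frequency."""
    if len(labels) != config.n_samples:
        raise ValueError("labels length must equal n_cases + n_controls")
    rng = _rng(seed, 4)
    events: list[TruthEvent] = []
    for _, row in labels.iterrows():
        carried: list[PlantedLocus] = []
        for locus in config.planted_loci:
            freq = (locus.carrier_freq_case if row["phenotype"] == "case"
                    else locus.carrier_freq_control)
            if rng.random() < freq:
                for other in carried:
                    if (other.chrom == locus.chrom and other.start <= locus.end
                            and locus.start <= other.end):
                        raise ValueError("conflicting planted states: "
                                         f"{other} vs {locus}")
                carried.append(locus)
                events.append(TruthEvent(row["sample_id"], locus))
    return TruthSet(events)


def _state_track(marker_map: MarkerMap, loci: list[PlantedLocus]) -> np.ndarray:
    states = np.full(len(marker_map), 3, dtype=np.int8)
    chroms = marker_map.chroms
    pos = marker_map.positions
    for locus in loci:
        inside = (chroms == locus.chrom) & (pos >= locus.start) & (pos <= locus.end)
        states[inside] = locus.state
    return states


def _draw_baf(states: np.ndarray, b_alleles_cn2: np.ndarray,
              pfreq: np.ndarray, baf_sd: float, boundary_mass: float,
              rng: np.random.Generator) -> np.ndarray:
    """BAF per marker from the copy-number cluster model.

    CN2 uses the sample's actual genotype; abnormal states redraw the
    allelic composition binomially at the marker's population frequency.
    CN0 has no allelic signal: BAF is uniform.
    """
    m = len(states)
    cn = np.array([STATE_COPY_NUMBER[s] for s in range(1, 7)])[states - 1]
    nb = np.where(states == 3, b_alleles_cn2,
                  rng.binomial(np.maximum(cn, 1), pfreq))
    # state 4 (copy-neutral LOH): homozygous only
    loh = states == 4
    nb[loh] = np.where(rng.random(loh.sum()) < pfreq[loh], 2, 0)
    with np.errstate(invalid="ignore"):
        mean = np.where(cn > 0, nb / np.maximum(cn, 1), 0.5)
    baf = np.clip(mean + rng.normal(0, baf_sd, m), 0.0, 1.0)
    # homozygous clusters: extra point mass exactly at the rail
    homo = (cn > 0) & ((nb == 0) | (nb == cn))
    pin = homo & (rng.random(m) < boundary_mass)
    baf[pin] = mean[pin]
    baf[cn == 0] = rng.random((cn == 0).sum())
    return baf


def render_signal(sample_id: str, genotypes: pd.Series | np.ndarray,
                  truth_loci: list[PlantedLocus], marker_map: MarkerMap,
                  config: SimConfig, rng: np.random.Generator) -> SampleSignal:
    """Render LRR/BAF for one sample given its genotypes and planted events."""
    geno = np.asarray(genotypes)
    if geno.shape != (len(marker_map),):
        raise ValueError("genotypes must align to the marker map")
    states = _state_track(marker_map, truth_loci)
    means = np.array([config.lrr_means[s] for s in range(1, 7)])
    gc = marker_map.gc
    lrr = (means[states - 1]
           + config.gc_wave_amplitude * (gc - gc.mean())
           + rng.normal(0, config.lrr_sd, len(marker_map)))
    pfreq = np.asarray(
        marker_map.table.get("pfb",
                             pd.Series(0.5, index=marker_map.table.index)),
        dtype=float)
    nb_cn2 = np.select([geno == "AA", geno == "AB", geno == "BB"], [0, 1, 2], 1)
    baf = _draw_baf(states, nb_cn2, pfreq, config.baf_sd,
                    config.boundary_mass, rng)
    return SampleSignal(sample_id=sample_id, lrr=lrr, baf=baf, genotypes=geno)


@dataclass
class Cohort:
    """A fully rendered synthetic cohort."""

    config: SimConfig
    marker_map: MarkerMap
    genotypes: pd.DataFrame
    labels: pd.DataFrame
    truth: TruthSet
    signals: list[SampleSignal]

    def signal_for(self, sample_id: str) -> SampleSignal:
        for s in self.signals:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)


def simulate_cohort(config: SimConfig) -> Cohort:
    """End-to-end generation: markers -> genotypes -> events -> signals."""
    marker_map = build_marker_map(config)
    genotypes = simulate_genotypes(
        marker_map, config.n_samples, config.seed,
        allele_freq_range=config.allele_freq_range,
        missing_rate=config.missing_rate)
    # carry the generating allele frequencies as PFB so signal rendering and
    # downstream calling see consistent population frequencies
    marker_map = marker_map.with_pfb(genotypes.attrs["baf_freqs"])
    labels = assign_labels(config)
    truth = plant_events(config, labels, config.seed)
    signals = []
    for j, sid in enumerate(labels["sample_id"]):
        rng = _rng(config.seed, 1000 + j)
        signals.append(render_signal(sid, genotypes[sid], truth.for_sample(sid),
                                     marker_map, config, rng))
    return Cohort(config, marker_map, genotypes, labels, truth, signals)


# ---------------------------------------------------------------------------
# fixture BED generation + on-disk cohort layout

def make_gene_bed(config: SimConfig, n_genes_per_mb: float = 10.0,
                  seed: int = 0) -> list[Interval]:
    """Evenly spaced synthetic gene spans covering ~30% of each chromosome."""
    rng = _rng(seed, 5)
    genes: list[Interval] = []
    k = 0
    for chrom, length in config.chromosomes:
        n = max(1, int(length / 1e6 * n_genes_per_mb))
        pitch = length // (n + 1)
        for i in range(n):
            start = (i + 1) * pitch
            span = int(rng.uniform(0.1, 0.5) * pitch)
            genes.append(Interval(chrom, start, min(start + span, length),
                                  label=f"GENE{k:04d}"))
            k += 1
    return genes


def make_chromatin_bed(config: SimConfig, mean_segment: float = 20_000.0,
                       seed: int = 0) -> list[Interval]:
    """Random 25-state segmentation; every label occurs at least once."""
    rng = _rng(seed, 6)
    segs: list[Interval] = []
    state_cycle = list(CHROMATIN_STATES_25)
    i = 0
    for chrom, length in config.chromosomes:
        pos = 1
        while pos <= length:
            span = max(200, int(rng.exponential(mean_segment)))
            # cycle through all labels first so each appears, then random
            if i < len(state_cycle):
                label = state_cycle[i]
            else:
                label = state_cycle[rng.integers(len(state_cycle))]
            segs.append(Interval(chrom, pos, min(pos + span - 1, length), label))
            pos += span
            i += 1
    return segs


def make_exclusion_bed(config: SimConfig, fraction: float = 0.02,
                       seed: int = 0) -> list[Interval]:
    """A few telomere/centromere-like exclusion zones per chromosome."""
    out: list[Interval] = []
    for chrom, length in config.chromosomes:
        tel = max(1, int(length * fraction))
        out.append(Interval(chrom, 1, tel, label="telomere"))
        out.append(Interval(chrom, length - tel + 1, length, label="telomere"))
        mid = length // 2
        out.append(Interval(chrom, mid - tel // 2, mid + tel // 2,
                            label="centromere"))
    return out


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, object]:
    """Write the cohort in the on-disk layout the pipeline reads back.

    Emits one tab-delimited signal file per sample (marker name, chromosome,
    position, "<sample>.Log R Ratio", "<sample>.B Allele Freq"), a sample
    sheet, gene/exclusion/chromatin BED fixtures and the truth table, and
    returns a manifest of all paths.
    """
    from .io import write_bed, write_signal_file  # local import to avoid cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = {"signals": []}
    for sig in cohort.signals:
        path = out / f"{sig.sample_id}.signal.txt"
        write_signal_file(path, sig, cohort.marker_map)
        manifest["signals"].append(str(path))

    sheet = out / "samples.tsv"
    cohort.labels.to_csv(sheet, sep="\t", index=False)
    manifest["sample_sheet"] = str(sheet)

    genes = make_gene_bed(cohort.config, seed=cohort.config.seed)
    gene_bed = out / "genes.bed"
    write_bed(gene_bed, genes)
    manifest["genes"] = str(gene_bed)

    excl = make_exclusion_bed(cohort.config, seed=cohort.config.seed)
    excl_bed = out / "exclusions.bed"
    write_bed(excl_bed, excl)
    manifest["exclusions"] = str(excl_bed)

    chrom_segs = make_chromatin_bed(cohort.config, seed=cohort.config.seed)
    chrom_bed = out / "chromatin_states.bed"
    write_bed(chrom_bed, chrom_segs)
    manifest["chromatin"] = str(chrom_bed)

    truth_path = out / "truth.tsv"
    rows = [(e.sample_id, e.locus.chrom, e.locus.start, e.locus.end,
             e.locus.state) for e in cohort.truth.events]
    pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end",
                                "state"]).to_csv(truth_path, sep="\t",
                                                 index=False)
    manifest["truth"] = str(truth_path)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    manifest["manifest"] = str(out / "manifest.json")
    return manifest
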