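# Methods

This note documents the models, parameter choices and numerical
conventions behind `cnvcohort`, and what the synthetic-data studies do
and do not demonstrate.

## Signal model and HMM

Per marker, a sample is observed through LRR (log total intensity,
centered at 0 for two copies) and BAF (relative B-allele intensity in
[0,1]). The caller models six hidden states with copy numbers
(0, 1, 2, 2, 3, 4); state 4 is copy-neutral LOH and, like state 3, is
never emitted as a CNV call.

**LRR emissions** are Gaussian per state. Vendor HMM parameter files
for commercial arrays are proprietary, so the package ships defaults
with PennCNV-convention cluster geometry: means (−3.5, −0.66, 0, 0,
+0.40, +0.68), SD 0.2 (1.0 for CN 0, whose intensity is dominated by
background). All values are fields of `HMMParams` and overridable,
including from a key:value parameter file of the caller's dialect.

**BAF emissions** are genotype-class mixtures. For copy number k the
cluster means are j/k for j = 0..k B alleles, weighted Binomial(k, p)
at the marker's PFB p; state 4 uses the two homozygous classes with
weights (1−p, p); CN 0 has no allelic signal and is modeled uniform.
Cluster SD defaults to 0.05. Real arrays truncate BAF to [0,1], piling
homozygous draws exactly on the rails; we model this with a discrete
point mass (`boundary_mass`, default 0.3) carved out of each rail
cluster, which avoids density singularities at 0/1 and matches the
generator's rail artifact. A likelihood floor of 1e−9 guards against
−inf under impossible observations.

**Transitions** use a baseline matrix whose off-diagonal mass is scaled
by 1 − exp(−d/D) for inter-marker gap d (D = 100 kb) and renormalized
into the diagonal. The diploid state is sticky (leave probability 1e−4
at saturation); abnormal states revert mostly to diploid (leave 1e−2,
88% toward state 3). These values make a ~4-marker aberration the
smallest signal that can overcome the switching penalty at default
noise, which is deliberate: single-marker outliers should not call.

**Decoding** is exact Viterbi in log space, vectorized across samples
sharing a marker grid; ties resolve toward the lower state index so
decoding is deterministic. Maximal runs of CNV states become calls with
1-based inclusive spans anchored on the first/last marker of the run.
Correctness is checked against exhaustive enumeration of all 6^m paths
on small instances.

## QC definitions

- **LRR SD**: sample SD of GC-adjusted autosomal LRR; gate < 0.35.
- **BAF drift**: fraction of markers with BAF in [0.2, 0.25] ∪
  [0.75, 0.8]; gate < 0.01. The drift bands are the conventional
  "between-cluster" windows where a clean array has essentially no mass.
- **Wave factor**: Pearson correlation between per-1-Mb-window median
  LRR and window mean GC, multiplied by the SD of the window medians;
  gate |wf| < 0.05. The published QC names this metric without a
  formula; this definition captures the GC-wave artifact the gate
  targets and carries the wave's sign. We compute it on adjusted LRR
  (the gate then measures *residual* waviness); computing it
  pre-adjustment is a one-line variant.
- **GC adjustment**: OLS of LRR on GC fraction; the adjusted signal is
  the residual plus the original mean. A constant GC track leaves the
  signal untouched.
- **Marker QC** (control genotypes): MAF > 0.10, missingness < 1%, and
  Hardy–Weinberg exact p > 1e−6. The HWE test conditions on allele
  counts and enumerates heterozygote counts exactly (log-gamma
  arithmetic), which is affordable at any realistic n; a chi-square
  approximation was considered unnecessary.

## Postprocessing conventions

- **Merging**: adjacent same-chromosome, same-state calls merge when
  gap < 0.2 × (len1 + len2). "Combined length" is read literally as the
  sum of the two call lengths, excluding the gap; the span-including-gap
  denominator is available via `gap_denominator="span"`. Iteration
  restarts from the left after each merge until a fixed point; the
  result is idempotent and leaves no mergeable pair (both are asserted
  property-style in the tests). Same-state-only merging follows caller
  convention. Markers falling in a closed gap are added to the merged
  call's marker count when a marker map is supplied.
- **Marker cutoffs** are strict (> 5, > 10, > 15, > 20), matching the
  ">k markers" table convention; `strict=False` selects ≥.
- **Exclusion** removes (never trims) any call overlapping an excluded
  region by ≥ 1 bp; this rule is conservative and makes the cutoff and
  exclusion stages commute. A fractional-overlap threshold is available.
  Packaged defaults cover the hg19 immunoglobulin and T-cell-receptor
  loci, which rearrange somatically in blood-derived DNA.

## Permutation statistics

All tests shuffle case/control labels. The empirical p-value is
(R + 1)/(N + 1) with R the number of permuted statistics exceeding the
observed one; ties count as exceedances by default (the conservative
convention; strict `>` is selectable). Burden tests use the case-group
mean of each per-sample statistic, one-sided (case > control) because
the substantive claims are directional; per-100 kb statistics average
only over samples with ≥ 1 call, whose denominators are defined.
Bonferroni multiplies by the number of statistics tested jointly.

Gene association uses the case carrier-event count per gene. Each CNV
event overlapping a gene counts once (so one sample can contribute
multiple events across calls); event counting reproduces the reference
odds ratio of 14.30 from 8 vs 1 events, which fixes the interpretation.
max(T) follows the standard Westfall–Young form: per permutation, the
maximum over genes of the statistic standardized by its gene-wise
permutation mean/SD; adjusted p = (exceedances + 1)/(n_perm + 1). A
published variant divides by the number of tested regions instead of
the permutation count; that reading breaks the guarantee p_adj ≥ p_raw
and is implemented only as an audit option
(`maxt_denominator="n_genes"`). With the standard form, dominance
p_adj ≥ p_raw holds by construction and is asserted on every run.

Woolf CIs use the log-normal approximation with variance
1/a + 1/b + 1/c + 1/d and no continuity correction; any zero cell
yields NA, matching how such rows are conventionally reported.

Disease-subgroup contrasts (e.g. HCC vs LC) rerun the same machinery on
relabeled sample subsets with one shared seed policy. Age-restricted
reruns are a plain sample-sheet filter (age > threshold); no matching
algorithm is attempted.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not raw probe chemistry: jittered marker spacing (uniform 0.5–1.5× the
mean), a sinusoidal GC track in [0.3, 0.7] with 2 Mb period (so the
wave-factor gate has something real to detect), Hardy–Weinberg
genotypes at uniform allele frequencies, planted loci realized
independently per sample at group-specific carrier frequencies, and
signals drawn from the same cluster geometry the caller assumes, with
Gaussian noise (`lrr_sd`, `baf_sd`) and the 0/1 rail artifact. Default
noise (lrr_sd 0.2, baf_sd 0.03) is a stand-in for a well-behaved array;
no published values exist for the emulated platform, so both remain
configurable. Overlapping planted events in one sample are rejected
rather than composed.

Because generator and caller share the cluster-geometry family,
recovery studies here measure segmentation correctness under the model,
not robustness to model misfit (probe-specific biases, mosaicism,
batch structure, X/Y chromosomes are all out of scope). That is the
right instrument for validating the statistics downstream, which only
consume calls; it overstates what the caller would achieve on real
intensities.

## Problem sizes and determinism

Study sizes used by the shipped analyses: recovery over 200 planted
segments (≥ 20 markers each, ~1000-marker chromosomes); null
familywise-error calibration over 150–200 replicates of 50 genes × 100
samples at 199 permutations; end-to-end power over 6–10 replicates of
1000 + 1800 samples with 2000 permutations. These sizes give 3-SE
binomial resolution around the quantities being checked while keeping
a laptop-scale run. Every stochastic stage takes an explicit seed; one
global seed expands into per-stage child seeds via `SeedSequence`, and
identical configuration + seed reproduces every output byte-for-byte.

## Known limitations

- The HMM defaults are package conventions, not fitted to any platform;
  on real data they should be replaced by platform-trained values.
- PFB from control BAF means is biased toward 0.5 relative to
  genotype-derived PFB at intermediate frequencies; genotype-based
  estimation is preferred when calls are available.
- Chromatin-segment counting is intentionally not invariant to
  splitting a segment in two (each intersected segment counts once);
  ratios are comparable only within one segmentation.
- The quiescent 25th chromatin state belongs to no regulatory subgroup
  and is excluded from coverage counting.
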