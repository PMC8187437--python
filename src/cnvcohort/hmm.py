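"""Six-state LRR/BAF hidden Markov model and Viterbi segmentation.

States follow the SNP-array convention: 1 = homozygous deletion (CN 0),
2 = hemizygous deletion (CN 1), 3 = diploid (CN 2), 4 = copy-neutral LOH
(CN 2, homozygous BAF only), 5 = single duplication (CN 3), 6 = double
duplication (CN 4).  Emissions combine a Gaussian LRR term with a BAF
mixture whose genotype-class weights come from the marker's population
B-allele frequency; transitions decay with inter-marker distance.  Only
states with copy number != 2 are emitted as CNV calls.

Numeric parameter values are package defaults (vendor HMM files for
commercial arrays are not public); every value is overridable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import comb

from .core import CNVCall, CNV_STATES, MarkerMap, SampleSignal

logger = logging.getLogger(__name__)

N_STATES = 6
_SQRT2PI = np.sqrt(2 * np.pi)


def _default_lrr_means() -> np.ndarray:
    return np.array([-3.5, -0.66, 0.0, 0.0, 0.40, 0.68])


def _default_lrr_sds() -> np.ndarray:
    return np.array([1.0, 0.2, 0.2, 0.2, 0.2, 0.2])


def _default_initial() -> np.ndarray:
    p = np.full(N_STATES, 2.5e-4)
    p[2] = 1 - p.sum() + p[2]
    return p


def _default_base_transitions() -> np.ndarray:
    """Baseline (distance-saturated) transition matrix.

    Diploid state 3 is sticky (leave probability 1e-4); abnormal states
    revert mostly to diploid (leave probability 1e-2, 88% of it toward
    state 3).  Rows sum to 1.
    """
    t = np.zeros((N_STATES, N_STATES))
    for i in range(N_STATES):
        if i == 2:
            leave = 1e-4
            off = np.full(N_STATES, leave / (N_STATES - 1))
        else:
            leave = 1e-2
            off = np.full(N_STATES, leave * 0.12 / (N_STATES - 2))
            off[2] = leave * 0.88
        off[i] = 0.0
        t[i] = off
        t[i, i] = 1 - off.sum()
    return t


@dataclass
class HMMParams:
    """All tunable parameters of the six-state model."""

    lrr_means: np.ndarray = field(default_factory=_default_lrr_means)
    lrr_sds: np.ndarray = field(default_factory=_default_lrr_sds)
    baf_sd: float = 0.05
    boundary_mass: float = 0.3  # discrete BAF mass pinned at 0/1 rails
    initial: np.ndarray = field(default_factory=_default_initial)
    base_transitions: np.ndarray = field(default_factory=_default_base_transitions)
    distance_scale: float = 100_000.0  # bp; D in the (1 - exp(-d/D)) decay
    likelihood_floor: float = 1e-9

    def __post_init__(self):
        self.lrr_means = np.asarray(self.lrr_means, dtype=float)
        self.lrr_sds = np.asarray(self.lrr_sds, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        self.base_transitions = np.asarray(self.base_transitions, dtype=float)
        if np.any(self.lrr_sds <= 0):
            raise ValueError("lrr_sds must be positive")
        if self.distance_scale <= 0:
            raise ValueError("distance_scale must be positive")
        if not np.allclose(self.base_transitions.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")

    def copy_numbers(self) -> np.ndarray:
        return np.array([0, 1, 2, 2, 3, 4])


def _baf_clusters(state: int, pfb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(means, weights) of the BAF mixture for one state.

    Weights are per-marker arrays shaped (K, m): binomial genotype-class
    probabilities at the marker's PFB for the state's copy number; state 4
    uses the homozygous classes only.
    """
    p = np.asarray(pfb, dtype=float)
    if state == 1:  # CN0: no allelic signal — handled as uniform elsewhere
        return np.array([]), np.empty((0, len(p)))
    if state == 4:  # copy-neutral LOH
        means = np.array([0.0, 1.0])
        weights = np.vstack([1 - p, p])
        return means, weights
    cn = {2: 1, 3: 2, 5: 3, 6: 4}[state]
    k = np.arange(cn + 1)
    means = k / cn
    weights = np.stack([comb(cn, kk) * p**kk * (1 - p)**(cn - kk) for kk in k])
    return means, weights


def baf_log_likelihood(baf: np.ndarray, pfb: np.ndarray,
                       params: HMMParams) -> np.ndarray:
    """Per-state BAF log-likelihood matrix, shape (6, m).

    Interior observations use Gaussian cluster densities; observations at
    exactly 0 or 1 use the discrete rail mass (``boundary_mass`` of the
    homozygous cluster weight), which avoids density singularities at the
    truncation rails of real arrays.
    """
    baf = np.asarray(baf, dtype=float)
    m = len(baf)
    at0 = baf <= 0.0
    at1 = baf >= 1.0
    interior = ~(at0 | at1)
    out = np.empty((N_STATES, m))
    sd = params.baf_sd
    bm = params.boundary_mass
    for s in range(1, N_STATES + 1):
        if s == 1:
            lik = np.where(interior, 1.0, bm)  # uniform + rail allowance
        else:
            means, weights = _baf_clusters(s, pfb)
            is_rail = (means == 0.0) | (means == 1.0)
            cont_scale = np.where(is_rail, 1 - bm, 1.0)
            z = (baf[None, :] - means[:, None]) / sd
            dens = np.exp(-0.5 * z**2) / (sd * _SQRT2PI)
            lik = (weights * cont_scale[:, None] * dens).sum(axis=0)
            # rails: discrete mass from the matching homozygous cluster
            if at0.any() or at1.any():
                w0 = (weights[means == 0.0].sum(axis=0)
                      if (means == 0.0).any() else np.zeros(m))
                w1 = (weights[means == 1.0].sum(axis=0)
                      if (means == 1.0).any() else np.zeros(m))
                lik = np.where(at0, bm * w0, lik)
                lik = np.where(at1, bm * w1, lik)
        out[s - 1] = np.log(lik + params.likelihood_floor)
    return out


def lrr_log_likelihood(lrr: np.ndarray, params: HMMParams) -> np.ndarray:
    """Per-state Gaussian LRR log-likelihood matrix, shape (6, m)."""
    lrr = np.asarray(lrr, dtype=float)
    z = (lrr[None, :] - params.lrr_means[:, None]) / params.lrr_sds[:, None]
    return -0.5 * z**2 - np.log(params.lrr_sds[:, None] * _SQRT2PI)


def emission_log_likelihood(signal: SampleSignal, pfb: np.ndarray,
                            params: HMMParams) -> np.ndarray:
    return lrr_log_likelihood(signal.lrr, params) + baf_log_likelihood(
        signal.baf, pfb, params)


def transition_log_matrices(positions: np.ndarray,
                            params: HMMParams) -> np.ndarray:
    """Distance-dependent log transition matrices for consecutive markers.

    Off-diagonal mass of the baseline matrix is scaled by
    ``1 - exp(-d/D)`` (d = gap in bp) and the diagonal absorbs the rest,
    so closely spaced markers rarely switch state.
    Returns shape (m-1, 6, 6).
    """
    d = np.diff(np.asarray(positions, dtype=float))
    f = 1 - np.exp(-d / params.distance_scale)
    base_off = params.base_transitions.copy()
    np.fill_diagonal(base_off, 0.0)
    t = base_off[None, :, :] * f[:, None, None]
    diag = 1 - t.sum(axis=2)
    idx = np.arange(N_STATES)
    t[:, idx, idx] = diag
    return np.log(np.maximum(t, 1e-300))


def viterbi_path(log_emis: np.ndarray, log_trans: np.ndarray,
                 log_init: np.ndarray) -> np.ndarray:
    """Most probable state path (0-based state indices).

    Ties resolve toward the lower state index (argmax first-occurrence).
    """
    paths = viterbi_paths(log_emis[None, :, :], log_trans, log_init)
    return paths[0]


def viterbi_paths(log_emis: np.ndarray, log_trans: np.ndarray,
                  log_init: np.ndarray) -> np.ndarray:
    """Batched Viterbi over samples sharing one marker grid.

    log_emis: (n_samples, 6, m); log_trans: (m-1, 6, 6); returns
    (n_samples, m) int8 state-index paths.
    """
    n, k, m = log_emis.shape
    dp = log_init[None, :] + log_emis[:, :, 0]
    ptr = np.empty((m - 1, n, k), dtype=np.int8)
    for t in range(1, m):
        scores = dp[:, :, None] + log_trans[t - 1][None, :, :]
        ptr[t - 1] = scores.argmax(axis=1)
        dp = scores.max(axis=1) + log_emis[:, :, t]
    states = np.empty((n, m), dtype=np.int8)
    states[:, -1] = dp.argmax(axis=1)
    rows = np.arange(n)
    for t in range(m - 2, -1, -1):
        states[:, t] = ptr[t][rows, states[:, t + 1]]
    return states


def _calls_from_path(states: np.ndarray, sample_id: str, chrom: str,
                     pos: np.ndarray, names: np.ndarray) -> list[CNVCall]:
    calls: list[CNVCall] = []
    m = len(states)
    i = 0
    while i < m:
        s = int(states[i]) + 1
        j = i
        while j + 1 < m and states[j + 1] == states[i]:
            j += 1
        if s in CNV_STATES:
            calls.append(CNVCall(
                sample_id=sample_id, chrom=chrom,
                start=int(pos[i]), end=int(pos[j]), state=s,
                n_markers=j - i + 1,
                start_marker=str(names[i]), end_marker=str(names[j])))
        i = j + 1
    return calls


def viterbi_segment(signal: SampleSignal, marker_map: MarkerMap,
                    params: HMMParams | None = None) -> list[CNVCall]:
    """Segment one sample's LRR/BAF into CNV calls.

    Chromosomes are decoded independently; chromosomes with fewer than two
    markers are skipped with a warning.
    """
    return segment_cohort([signal], marker_map, params)[signal.sample_id]


def segment_cohort(signals: list[SampleSignal], marker_map: MarkerMap,
                   params: HMMParams | None = None
                   ) -> dict[str, list[CNVCall]]:
    """Batched segmentation of many samples on a shared marker grid."""
    if params is None:
        params = HMMParams()
    pfb = marker_map.pfb if marker_map.has_pfb else np.full(len(marker_map), 0.5)
    log_init = np.log(params.initial)
    out: dict[str, list[CNVCall]] = {s.sample_id: [] for s in signals}
    for chrom, sl in marker_map.chrom_slices():
        m = sl.stop - sl.start
        if m < 2:
            logger.warning("chromosome %s has <2 markers; skipped", chrom)
            continue
        pos = marker_map.positions[sl]
        names = marker_map.names[sl]
        log_trans = transition_log_matrices(pos, params)
        emis = np.stack([
            emission_log_likelihood(
                SampleSignal(s.sample_id, s.lrr[sl], s.baf[sl]),
                pfb[sl], params)
            for s in signals])
        paths = viterbi_paths(emis, log_trans, log_init)
        for s, path in zip(signals, paths):
            out[s.sample_id].extend(
                _calls_from_path(path, s.sample_id, chrom, pos, names))
    return out
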