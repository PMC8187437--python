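import numpy as np
import pandas as pd
import pytest

import cnvcohort as cc


@pytest.fixture(scope="session")
def small_config():
    return cc.SimConfig(
        n_cases=5, n_controls=5,
        chromosomes=[("chr1", 2_000_000)],
        marker_spacing=1000,
        planted_loci=[
            cc.PlantedLocus("chr1", 500_000, 560_000, 2, 1.0, 0.0),
            cc.PlantedLocus("chr1", 1_200_000, 1_260_000, 5, 0.0, 1.0),
        ],
        lrr_sd=0.2, baf_sd=0.03, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return cc.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_calls(small_cohort):
    by_sample = cc.segment_cohort(small_cohort.signals,
                                  small_cohort.marker_map)
    return [c for calls in by_sample.values() for c in calls]


@pytest.fixture
def make_call():
    def _make(sample="S0", chrom="chr1", start=1000, end=2000, state=2,
              n_markers=10):
        return cc.CNVCall(sample_id=sample, chrom=chrom, start=start,
                          end=end, state=state, n_markers=n_markers)
    return _make


@pytest.fixture
def labels_10():
    """5 cases + 5 controls for exhaustive-enumeration tests."""
    ids = [f"S{i}" for i in range(10)]
    return {s: ("case" if i < 5 else "control") for i, s in enumerate(ids)}
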