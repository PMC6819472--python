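"""Shared fixtures: synthetic studies at two scales.

``small_study`` is a quick bundle for unit-level checks; ``default_study``
is the full desk-scale study (1,000 peaks, 2 ChIP + 3 RNA replicates per
cross) used by the end-to-end recovery tests.  Both are session-scoped —
the generators are deterministic, so sharing them is safe.
"""

import pytest

from imprintseq import pipeline
from imprintseq.simdata import SimConfig


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=5, n_chrom=2, chrom_length=4_000_000, n_peaks=120,
                     n_background_ltrs=40, n_decoys_per_type=2)


@pytest.fixture(scope="session")
def small_study(small_config):
    return pipeline.simulate_study(small_config)


@pytest.fixture(scope="session")
def default_config():
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def default_study(default_config):
    return pipeline.simulate_study(default_config)


@pytest.fixture(scope="session")
def default_bundle(default_study, default_config):
    data, _truth = default_study
    return pipeline.run_pipeline(
        data, pipeline.PipelineConfig(seed=default_config.seed))
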