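"""Shared fixtures: deterministic simulated datasets at desk scale."""

from __future__ import annotations

import numpy as np
import pytest

from circsat.pipeline import (PipelineParams, SimulationConfig, analyze_reads,
                              simulate_dataset)


@pytest.fixture(scope="session")
def frt_dataset():
    """Error-free single-domain circles sealed through the 48-bp FRT pair."""
    cfg = SimulationConfig(seed=7, n_circles=3, reads_per_circle=4,
                           n_domains=1)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def frt_analysis(frt_dataset):
    b = frt_dataset
    return analyze_reads(b.reads, b.reference, b.fwd, b.rev,
                         PipelineParams(), site_table=b.site_table)


@pytest.fixture(scope="session")
def multi_dataset():
    """Error-free three-domain circles with donor switches."""
    cfg = SimulationConfig(seed=3, n_circles=8, reads_per_circle=2,
                           n_domains=3, donor_fraction=0.3)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def multi_analysis(multi_dataset):
    b = multi_dataset
    return analyze_reads(b.reads, b.reference, b.fwd, b.rev,
                         PipelineParams(), site_table=b.site_table)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240608)
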