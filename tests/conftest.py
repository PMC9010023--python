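"""Shared fixtures: one strong-signal synthetic study reused across modules."""

import numpy as np
import pytest

from cismr import PipelineConfig, SimTruth, simulate_mr_study
from cismr.instruments import build_candidates, clump


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def strong_study():
    """Two-sample study with a clear causal signal (theta = 0.3, h2 = 0.3)."""
    truth = SimTruth.default(m=50, n_causal=5, seed=7, theta=0.3)
    return simulate_mr_study(truth)


@pytest.fixture(scope="session")
def strong_candidates(strong_study, config):
    s = strong_study
    return build_candidates(s.exposure, s.outcome, s.gene, s.reference, config)


@pytest.fixture(scope="session")
def primary_instruments(strong_candidates, config):
    return clump(strong_candidates, config.primary_r2, config.primary_pval)
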