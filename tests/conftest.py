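"""Shared fixtures.

The transfer benchmark (8 healthy-like sources, DOC-like targets with
manifest-known shift, 5 master seeds) is expensive, so it runs once per
session and is shared by every test that interrogates it.
"""

from __future__ import annotations

import numpy as np
import pytest

from p300adapt.adda import AdaptConfig, PipelineConfig
from p300adapt.evaluation import TransferBenchmarkConfig, run_transfer_benchmark
from p300adapt.stcnn import TrainConfig
from p300adapt.synthetic import CohortConfig, make_cohort


@pytest.fixture(scope="session")
def benchmark_df():
    """Default synthetic transfer benchmark (direct vs adapted vs oracle)."""
    config = TransferBenchmarkConfig(n_targets_per_cohort=1,
                                     include_no_selection=True)
    return run_transfer_benchmark(config)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small cohort for plumbing tests (3 healthy + 1 DOC-like)."""
    cohort, manifest, profiles = make_cohort(
        CohortConfig(n_healthy=3, n_doc=1, n_targets=40, n_nontargets=40,
                     master_seed=7))
    return cohort, manifest, profiles


@pytest.fixture()
def fast_pipeline_config():
    """Pipeline config small enough for seconds-scale end-to-end runs."""
    return PipelineConfig(
        train=TrainConfig(max_epochs=5, seed=0),
        adapt=AdaptConfig(n_adversarial_steps=20),
        seed=0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
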