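"""Shared fixtures: small synthetic cohorts generated at test time."""

import numpy as np
import pytest

from semgcobb import SimParams, simulate_cohort


@pytest.fixture(scope="session")
def tiny_params() -> SimParams:
    """Three patients, 2 s holds: enough structure for format/feature tests."""
    return SimParams(n_patients=3, duration_s=2.0, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_params):
    cohort, gt = simulate_cohort(tiny_params)
    return cohort, gt


@pytest.fixture(scope="session")
def micro_bench_cohort():
    """Six patients, 2 s holds, for protocol/benchmark structure tests."""
    cohort, _ = simulate_cohort(SimParams(n_patients=6, duration_s=2.0, seed=13))
    return cohort


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
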