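"""Shared fixtures: small synthetic cohorts and toy count vectors."""

import numpy as np
import pytest

from epijsd import filter_coverage
from epijsd.simulate import SimConfig, simulate_cohort


def counts(**patterns: int) -> np.ndarray:
    """Build a 16-vector from pattern-string keyword counts, e.g. counts(p0000=5)."""
    vec = np.zeros(16, dtype=np.int64)
    for key, n in patterns.items():
        vec[int(key.lstrip("p"), 2)] = n
    return vec


@pytest.fixture(scope="session")
def default_cohort():
    """1 core + 4 peripheries, 500 null + 20 differential loci, depth 30."""
    config = SimConfig(n_null=500, n_differential=20, depth=30, seed=1)
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def default_cohort_filtered(default_cohort):
    return filter_coverage(default_cohort.tables, 10)


@pytest.fixture(scope="session")
def null_cohort():
    """5 samples drawing from identical per-locus mixtures (no signal)."""
    config = SimConfig(n_null=500, n_differential=0, depth=30, seed=7)
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def null_cohort_filtered(null_cohort):
    return filter_coverage(null_cohort.tables, 10)
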