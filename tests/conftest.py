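import numpy as np
import pytest

from strokeclust import (
    CohortConfig,
    assign_reference_fma,
    generate_cohort,
    subject_trunk_displacement,
    to_frequency_features,
)

TINY = CohortConfig(
    n_subjects_per_group=4,
    n_tasks=2,
    n_repetitions=2,
    duration_s=2.0,
    seed=7,
)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small 3-group cohort (12 subjects) reused across test modules."""
    trials, groups = generate_cohort(TINY)
    trials = assign_reference_fma(trials, TINY)
    return TINY, trials, groups


@pytest.fixture(scope="session")
def tiny_features(tiny_cohort):
    config, trials, groups = tiny_cohort
    fm = to_frequency_features(trials)
    td = subject_trunk_displacement(trials, config.trunk_channel)
    return fm, td, groups


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_partition(rng, n, k):
    """Random labels over n points with every cluster in [0, k) non-empty."""
    k = min(k, n)
    labels = rng.integers(0, k, size=n)
    labels[rng.permutation(n)[:k]] = np.arange(k)
    return labels
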