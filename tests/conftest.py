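import numpy as np
import pandas as pd
import pytest

from nspnet import CohortSpec, compute_fc, generate_cohort


def random_fc(rng, n, t=60):
    """A valid FC matrix from a random Gaussian series with block hints."""
    cov = np.full((n, n), 0.2)
    half = n // 2
    cov[:half, :half] = 0.5
    cov[half:, half:] = 0.5
    np.fill_diagonal(cov, 1.0)
    w, v = np.linalg.eigh(cov)
    root = (v * np.sqrt(np.clip(w, 0, None))) @ v.T
    x = rng.standard_normal((t, n)) @ root
    return compute_fc(x).to_numpy()


@pytest.fixture(scope="session")
def two_block_fc():
    a, b = 0.8, 0.2
    return np.array(
        [[1, a, b, b], [a, 1, b, b], [b, b, 1, a], [b, b, a, 1]], dtype=float
    )


@pytest.fixture(scope="session")
def small_spec():
    return CohortSpec(
        n_regions=14,
        system_sizes=(2, 2, 2, 2, 2, 2, 2),
        n_per_group=8,
        t_len=80,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def default_spec():
    return CohortSpec(seed=11)
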