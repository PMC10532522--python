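import numpy as np
import pytest

from cardioseg import (
    PhantomDatasetSpec,
    PhantomSpec,
    generate_dataset,
    generate_phantom,
    make_filter_bank,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230930)


@pytest.fixture(scope="session")
def bank():
    return make_filter_bank("seeded_random", seed=42)


@pytest.fixture(scope="session")
def clean_phantom():
    """One noise-free enlarged phantom with its exact mask."""
    return generate_phantom(PhantomSpec(seed=7, ctr=0.6, noise_sd=0.0))


@pytest.fixture(scope="session")
def small_cohort():
    """Six noisy subjects (3 enlarged) for fast pipeline tests."""
    return generate_dataset(
        PhantomDatasetSpec(
            n_subjects=6, n_enlarged=3, master_seed=11, noise_sd=0.02
        )
    )


@pytest.fixture(scope="session")
def blob_frame(rng):
    """Well-separated 3-class Gaussian blobs in 5 features (200 rows)."""
    means = np.array(
        [[0.0] * 5, [8.0] * 5, [0.0, 8.0, 0.0, 8.0, 0.0]]
    )
    rows, labels = [], []
    for c, mu in enumerate(means):
        rows.append(rng.normal(mu, 1.0, size=(70, 5)))
        labels.append(np.full(70, c))
    return np.vstack(rows), np.concatenate(labels)
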