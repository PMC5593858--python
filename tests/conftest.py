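import numpy as np
import pytest

import aquaspec as aq


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded 90-sample synthetic campaign shared across tests."""
    ds, w, truth = aq.generate_dataset(aq.SpectralSimConfig(), seed=7)
    return ds, w, truth


@pytest.fixture(scope="session")
def transformed(default_dataset):
    ds, w, _ = default_dataset
    masked, mask = aq.remove_noise_bands(ds)
    smoothed = aq.smooth_dataset(masked, mask)
    return aq.transform_spectra(smoothed, mask), w
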