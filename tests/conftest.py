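import numpy as np
import pytest

from leafspec import SpectraSet, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 40-sample synthetic campaign shared by read-only tests."""
    return generate_dataset(40, seed=11)


@pytest.fixture()
def tiny_spectra():
    """A handmade 3-sample, 5-band spectra set on a unit grid."""
    rng = np.random.default_rng(5)
    return SpectraSet(
        sample_ids=["a", "b", "c"],
        wavelengths=np.arange(500, 505),
        reflectance=rng.uniform(0.1, 0.6, size=(3, 5)),
    )
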