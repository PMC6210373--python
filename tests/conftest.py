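import numpy as np
import pytest

from nirselect import SpectraSet, generate, preset


@pytest.fixture(scope="session")
def small_dataset():
    """Small synthetic draw (N=60, P=300) shared by fast tests."""
    ds, truth = generate(preset("tobacco-small", seed=7, effect_size=4.0))
    return ds, truth


@pytest.fixture()
def toy_spectra():
    """Tiny handmade spectra set with known values."""
    wn = np.array([5000.0, 4900.0, 4800.0, 4700.0, 4600.0])
    absorb = np.array(
        [
            [0.1, 0.2, 0.3, 0.4, 0.5],
            [0.5, 0.4, 0.3, 0.2, 0.1],
            [0.2, 0.2, 0.2, 0.2, 0.2],
        ]
    )
    return SpectraSet(
        wavenumbers=wn,
        absorbance=absorb,
        labels=np.array(["A", "A", "B"]),
        sample_ids=np.array(["s1", "s2", "s3"]),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
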