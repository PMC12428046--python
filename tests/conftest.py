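"""Shared fixtures: small synthetic study designs reused across test modules."""

import numpy as np
import pytest

from seedspectra.synth import SynthSpec, make_spectrum_table


@pytest.fixture(scope="session")
def small_spec() -> SynthSpec:
    """Modest 5-variety design with the default noise model."""
    return SynthSpec(n_varieties=5, seeds_per_variety=20, n_bands=96, rng_seed=11)


@pytest.fixture(scope="session")
def small_table(small_spec):
    return make_spectrum_table(small_spec)


@pytest.fixture(scope="session")
def separable_spec() -> SynthSpec:
    """Noise-free, widely separated classes: classifiers should be perfect."""
    return SynthSpec(
        n_varieties=4, seeds_per_variety=10, n_bands=64, separability=2.0,
        scatter_sd=0.0, offset_sd=0.0, noise_sd=0.0, rng_seed=2,
    )


@pytest.fixture(scope="session")
def separable_table(separable_spec):
    return make_spectrum_table(separable_spec)


@pytest.fixture(scope="session")
def nosignal_spec() -> SynthSpec:
    """separability = 0: labels carry no information about the spectra."""
    return SynthSpec(
        n_varieties=6, seeds_per_variety=40, n_bands=32, separability=0.0, rng_seed=4
    )


@pytest.fixture(scope="session")
def nosignal_table(nosignal_spec):
    return make_spectrum_table(nosignal_spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
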