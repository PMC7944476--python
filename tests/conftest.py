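import numpy as np
import pytest

from neuroraman import (
    BandSpec,
    default_cohort_config,
    default_library,
    generate_cohort,
    generate_component_library,
)


@pytest.fixture(scope="session")
def axis():
    return np.arange(600.0, 1801.0)


@pytest.fixture(scope="session")
def library(axis):
    return default_library(axis)


@pytest.fixture(scope="session")
def two_band_library(axis):
    """Two nearly separable components for small unmixing problems."""
    return generate_component_library([
        ("A", [BandSpec(800.0, 20.0, 1.0)]),
        ("B", [BandSpec(1500.0, 20.0, 1.0)]),
    ], axis)


@pytest.fixture(scope="session")
def noisy_cohort(library):
    """Small default-condition cohort shared across tests (seeded)."""
    cfg = default_cohort_config(n_per_class=5, seed=42)
    return generate_cohort(cfg, library)


@pytest.fixture(scope="session")
def clean_cohort(library):
    """Noise-free, spike-free cohort with zero composition spread."""
    cfg = default_cohort_config(n_per_class=3, seed=7, noise_sd=0.0,
                                spike_rate=0.0, coefficient_cv=0.0)
    return generate_cohort(cfg, library)
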