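"""Shared fixtures: small random spectra and a desk-scale distorted pair."""

import numpy as np
import pytest

from plsct import SpectraSet, SimulationConfig, InstrumentDistortion, generate_paired_spectra


def random_spectra(seed: int, n: int = 12, p: int = 9, with_y: bool = True) -> SpectraSet:
    rng = np.random.default_rng(seed)
    return SpectraSet(
        X=rng.normal(size=(n, p)),
        wavelengths=np.arange(p, dtype=float),
        y=rng.normal(size=n) if with_y else None,
    )


@pytest.fixture
def small_random():
    return random_spectra(7)


@pytest.fixture
def noiseless_config():
    """Small noise-free paired dataset with identity distortion."""
    return SimulationConfig(
        n_samples=40, n_channels=120, n_components=3, seed=11,
        y_noise_sigma=0.0, master_noise_sigma=0.0,
        distortion=InstrumentDistortion(),
    )


@pytest.fixture
def distorted_config():
    """Small noise-free pair with an affine inter-instrument difference."""
    return SimulationConfig(
        n_samples=40, n_channels=120, n_components=3, seed=11,
        y_noise_sigma=0.0, master_noise_sigma=0.0,
        distortion=InstrumentDistortion(
            wavelength_shift=0.8, gain=1.04, baseline_offset=0.015,
        ),
    )


@pytest.fixture
def noiseless_pair(noiseless_config):
    return generate_paired_spectra(noiseless_config)


@pytest.fixture
def distorted_pair(distorted_config):
    return generate_paired_spectra(distorted_config)
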