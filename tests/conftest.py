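import dataclasses

import numpy as np
import pytest

import muacsim as m


@pytest.fixture(scope="session")
def small_geometry() -> m.ProjectionGeometry:
    """Desk-scale geometry: 128 grid, 42 angles (divisible by 21, 6, 3)."""
    return m.ProjectionGeometry(n_angles=42, n_bins=128, bin_width_mm=2.6,
                                image_size=128, spacing_mm=2.6)


@pytest.fixture(scope="session")
def small_phantom_config() -> m.PhantomConfig:
    """Half-scale anatomy on a 128 grid, noise-free."""
    return dataclasses.replace(m.PhantomConfig(hu_noise_sd=0.0).scaled(0.5),
                               grid_size=128)


@pytest.fixture(scope="session")
def small_phantom(small_phantom_config) -> m.DigitalPhantom:
    return m.generate_thorax_phantom(small_phantom_config)


@pytest.fixture(scope="session")
def small_experiment_config(small_phantom_config) -> m.ExperimentConfig:
    return m.ExperimentConfig(
        phantom=dataclasses.replace(small_phantom_config, hu_noise_sd=20.0),
        n_angles=42, n_subjects=1, total_counts=2e6,
        recon=m.ReconConfig(iterations=2, subsets=21, matrix=128), seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
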