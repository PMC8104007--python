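"""Shared fixtures: small, seeded synthetic configurations.

EEG-bearing fixtures run at 500 Hz with a handful of channels so the whole
suite stays desk-scale; BOLD-only fixtures use the full 185-volume default.
"""

from __future__ import annotations

import numpy as np
import pytest

from oscoupler.simulate import ArtifactConfig, SimConfig, cohort_truth


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Reduced-rate cohort with artifacts enabled (EEG cleaning tests)."""
    return SimConfig(
        seed=11,
        n_per_group=2,
        n_volumes=60,
        session_duration=140.0,
        eeg_rate_raw=500.0,
        n_channels=8,
    )


@pytest.fixture(scope="session")
def small_eeg(small_cfg):
    from oscoupler.simulate import simulate_eeg

    return simulate_eeg(small_cfg, 0)


@pytest.fixture(scope="session")
def clean_cfg() -> SimConfig:
    """Artifact-free reduced cohort (spectral / regressor tests)."""
    return SimConfig(
        seed=13,
        n_per_group=2,
        n_volumes=60,
        session_duration=140.0,
        eeg_rate_raw=500.0,
        n_channels=8,
        artifact=ArtifactConfig(gradient_amplitude=0.0, bcg_amplitude=0.0),
    )


@pytest.fixture(scope="session")
def default_cfg() -> SimConfig:
    """Full-length (185 volumes) default cohort; BOLD-side tests only."""
    return SimConfig(seed=5, n_per_group=10)


@pytest.fixture(scope="session")
def default_truth(default_cfg):
    return cohort_truth(default_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
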