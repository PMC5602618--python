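"""Shared fixtures: phantom images and the standard 20-phantom suite.

The suite run is session-scoped because segmentation of 20 phantoms is the
single most expensive computation in the test run and several tests consume
different columns of the same result table.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from fundus_cdr.experiments import phantom_suite
from fundus_cdr.synthetic import generate_phantom, profile_spec

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, vessel-free phantom: pure geometry checks."""
    spec = profile_spec("small", seed=0, noise_sigma=0.0, n_vessels=0, blur_sigma=0.0)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Standard test-profile phantom with vessels, blur and noise."""
    spec = profile_spec("small", seed=0, noise_sigma=8.0)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def suite_results():
    """The standard 20-phantom recovery suite (seeds 0-19, noise sigma 8)."""
    return phantom_suite(n_images=20, base_seed=0, noise_sigma=8.0, pipeline_seed=0)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    return 2 * inter / max(a.sum() + b.sum(), 1)
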