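"""Shared fixtures and generators for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from retdens import DensityFunction, SRTFunction, srt, trapezoid_weights, unit_grid


def make_random_density(
    rng: np.random.Generator, m: int = 512, roughness: int = 4, amplitude: float = 1.0
) -> DensityFunction:
    """A smooth, strictly positive random density on the shared grid."""
    x = unit_grid(m)
    logf = np.zeros(m)
    for k in range(1, roughness + 1):
        logf += rng.normal(0, 1.0 / k) * np.cos(np.pi * k * x)
        logf += rng.normal(0, 1.0 / k) * np.sin(np.pi * k * x)
    f = np.exp(amplitude * logf)
    f /= np.sum(trapezoid_weights(m) * f)
    return DensityFunction(x, f)


def make_random_srt(
    rng: np.random.Generator, m: int = 512, roughness: int = 4, amplitude: float = 1.0
) -> SRTFunction:
    return srt(make_random_density(rng, m, roughness, amplitude))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)


@pytest.fixture
def grid512() -> np.ndarray:
    return unit_grid(512)
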