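"""Shared fixtures: small synthetic systems reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from awv.matching import MetricFamily, MetricSpec
from awv.oracle import (
    HarmonicModel,
    generate_harmonic_trajectory,
    random_harmonic_model,
)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def model3() -> HarmonicModel:
    """A 4-atom, 3-mode harmonic model with assigned tensors (seeded)."""
    return random_harmonic_model(4, [800.0, 1200.0, 1600.0], seed=7, temperature=300.0)


@pytest.fixture(scope="session")
def all_pairs_metric():
    def make(n_atoms: int, sigma: float = 0.5) -> MetricSpec:
        return MetricSpec(
            [
                MetricFamily(
                    type="interatomic_distance",
                    atoms=[(i, j) for i in range(n_atoms) for j in range(i + 1, n_atoms)],
                    sigma=sigma,
                )
            ]
        )

    return make


@pytest.fixture(scope="session")
def short_harmonic_traj(model3):
    """20k-step harmonic trajectory with exact velocities (shared, read-only)."""
    return generate_harmonic_trajectory(model3, 20_000, 0.5, seed=11)
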