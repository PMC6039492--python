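"""Shared fixtures: calibration, simulated stacks, and histogram helpers."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from snb import compute_nb_maps
from snb.simulate import SimulationConfig, SpeciesSpec, simulate_frame_counts
from snb.stoichiometry import CalibrationReference

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def calibration() -> CalibrationReference:
    return CalibrationReference()


def make_stack(
    subunits: int = 2,
    nbar: float = 10.0,
    frames: int = 100,
    size: int = 64,
    seed: int = 0,
    **kwargs,
):
    """One-species fast-tier stack with study-default geometry."""
    cfg = SimulationConfig(
        species=[SpeciesSpec(subunits, nbar)],
        frames=frames,
        height=size,
        width=size,
        seed=seed,
        **kwargs,
    )
    return simulate_frame_counts(cfg)


@pytest.fixture(scope="session")
def dimer_stack():
    """Pure-dimer stack at study geometry (s=2, n-bar=10, T=100, 64x64)."""
    return make_stack(subunits=2, nbar=10.0, seed=42)


@pytest.fixture(scope="session")
def dimer_maps(dimer_stack):
    return compute_nb_maps(dimer_stack)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
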