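"""Shared fixtures: toy study conditions used across the suite.

The moving-trap toy: a = k = 1 kT per unit² at 300 K, trap dragged from
s = 0 to 1 over 5 time units (ten relaxation times of the combined trap,
τ = 1/(βD(a+k)) = 0.5 with D = 1), dt = 0.005. The analytic free-energy
difference of this protocol is a·k/(2(a+k)) = 0.25 kT.
"""

from __future__ import annotations

import numpy as np
import pytest

from neqbind import (
    RestraintParams,
    SteeringSchedule,
    ThermoState,
    ToyPotential,
    generate_bidirectional_works,
)

SEED = 11


@pytest.fixture(scope="session")
def thermo() -> ThermoState:
    return ThermoState(temperature=300.0, diffusion=1.0, dt=0.005, seed=SEED)


@pytest.fixture(scope="session")
def trap_setup(thermo):
    """(potential, schedule, restraints) of the standard moving-trap toy."""
    kt = thermo.kt
    pot = ToyPotential("harmonic", {"a": kt})
    sch = SteeringSchedule(0.0, 1.0, 5.0)
    rp = RestraintParams(k_spring=kt)
    return pot, sch, rp


@pytest.fixture(scope="session")
def node_grid() -> np.ndarray:
    return np.linspace(0.0, 1.0, 11)


@pytest.fixture(scope="session")
def slow_workset(thermo, trap_setup, node_grid):
    """200+200 slow bidirectional pulls with 10-segment work matrices."""
    pot, sch, rp = trap_setup
    return generate_bidirectional_works(
        pot, sch, rp, thermo, n_fwd=200, n_bwd=200, node_s=node_grid
    )


def gaussian_works(mean, sigma, n, seed):
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
    return rng.normal(mean, sigma, n)
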