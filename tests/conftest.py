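"""Shared fixtures.

The Monte Carlo traces used by several statistical tests are expensive, so
they are produced once per session at desk-scale sampling (1e7-1.2e8 trial
moves, far below the reference schedule of 1e10-1e12) and shared.
"""

from __future__ import annotations

import numpy as np
import pytest

from nanosorb.mc_engine import run_simulation
from nanosorb.system_builder import spec_for_series


@pytest.fixture(scope="session")
def trace_r1_n1():
    """R1 smallest system (one adsorbate, one site, V = 125 nm^3)."""
    spec = spec_for_series(
        "R1", 1, 1, seed=1001,
        n_equilibration=2_000_000, n_production=120_000_000, sample_interval=50,
    )
    return run_simulation(spec, collect_gsa=True, gsa_bin_width=0.003, gsa_rmax=1.5)


@pytest.fixture(scope="session")
def trace_r1_n2():
    spec = spec_for_series(
        "R1", 2, 2, seed=1002,
        n_equilibration=2_000_000, n_production=80_000_000, sample_interval=50,
    )
    return run_simulation(spec)


@pytest.fixture(scope="session")
def trace_r1_n4():
    spec = spec_for_series(
        "R1", 4, 4, seed=1004,
        n_equilibration=2_000_000, n_production=60_000_000, sample_interval=50,
    )
    return run_simulation(spec)


@pytest.fixture(scope="session")
def trace_r2_na1():
    """R2 with a single adsorbate and four sites (acceptance-ratio anchor)."""
    spec = spec_for_series(
        "R2", 1, 4, seed=1010,
        n_equilibration=2_000_000, n_production=30_000_000, sample_interval=50,
    )
    return run_simulation(spec)


@pytest.fixture(scope="session")
def trace_r4_eps15():
    """R4 weakest adsorption energy (eps_SA = 15 kJ/mol)."""
    spec = spec_for_series(
        "R4", 2, 2, seed=1015, epsilon_sa=15.0,
        n_equilibration=1_000_000, n_production=60_000_000, sample_interval=20,
    )
    return run_simulation(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
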