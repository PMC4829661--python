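"""Shared fixtures: small deterministic genomes and desk-scale simulations."""

from __future__ import annotations

import numpy as np
import pytest

from replisim.engine import ReplicationParams, run_simulation
from replisim.genome import (
    ChromatinClass,
    GenomeLayout,
    SyntheticGenomeParams,
    generate_synthetic_genome,
)


@pytest.fixture(scope="session")
def toy_layout() -> GenomeLayout:
    """Three hand-built chromosomes with known zone structure (12 Mbp)."""
    return GenomeLayout(
        ["tA", "tB", "tC"],
        [5e6, 4e6, 3e6],
        [
            [0.0, 2e6, 3e6, 5e6],
            [0.0, 1.5e6, 4e6],
            [0.0, 1e6, 2e6, 3e6],
        ],
        [
            [ChromatinClass.EU, ChromatinClass.FAC, ChromatinClass.CON],
            [ChromatinClass.EU, ChromatinClass.CON],
            [ChromatinClass.FAC, ChromatinClass.EU, ChromatinClass.CON],
        ],
    )


@pytest.fixture(scope="session")
def toy_params() -> ReplicationParams:
    """Parameters scaled to the 12 Mbp toy genome (density-preserving)."""
    return ReplicationParams(
        n_potential_origins=600,
        limiting_factor_max=16,
        seed=101,
        recording_interval=600.0,
    )


@pytest.fixture(scope="session")
def toy_result(toy_layout, toy_params):
    return run_simulation(toy_layout, toy_params, snapshot_times=(10_080.0,))


@pytest.fixture(scope="session")
def desk_layout() -> GenomeLayout:
    """Desk-scale HeLa-like synthetic genome (~1 Gbp, 8 chromosomes)."""
    return generate_synthetic_genome(
        SyntheticGenomeParams(n_chromosomes=8, target_total_length=1.0e9, seed=5)
    )


@pytest.fixture(scope="session")
def desk_params() -> ReplicationParams:
    """Density-preserving desk-scale parameters (~1/10 of the full genome)."""
    return ReplicationParams(
        n_potential_origins=48_000,
        limiting_factor_max=1_200,
        seed=9,
    )


@pytest.fixture(scope="session")
def desk_result(desk_layout, desk_params):
    snaps = (10_080.0,) + tuple(np.arange(900.0, 11.0 * 3600.0, 900.0))
    return run_simulation(desk_layout, desk_params, snapshot_times=snaps)
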