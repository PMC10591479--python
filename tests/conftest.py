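"""Shared fixtures: small geometries and a scaled assembly trajectory."""

from __future__ import annotations

import numpy as np
import pytest

from excitube import (
    AssemblySimParams,
    ExcitonParams,
    LatticeSpec,
    MoleculeFrame,
    TubeSpec,
    rolled_wall,
    simulate_assembly,
)
from excitube.dichroism import BandWindow, timeseries


@pytest.fixture(scope="session")
def lattice() -> LatticeSpec:
    return LatticeSpec.brickwork()


@pytest.fixture(scope="session")
def small_tube() -> TubeSpec:
    return TubeSpec(length=6.0)


@pytest.fixture(scope="session")
def iw_frame(lattice, small_tube) -> MoleculeFrame:
    return rolled_wall(
        lattice, small_tube.radius_iw, small_tube.length, small_tube.axis, "IW"
    )


@pytest.fixture
def monomer_frame() -> MoleculeFrame:
    return MoleculeFrame([[0.0, 0.0, 0.0]], [[0.0, 0.0, 1.0]],
                         [0.0, 0.0, 1.0], 1.0, ["OW"])


@pytest.fixture(scope="session")
def fast_params() -> ExcitonParams:
    """Reduced realization count for band-level (not peak-level) checks."""
    return ExcitonParams(n_realizations=40, seed=7)


@pytest.fixture(scope="session")
def slow_reorientation_trajectory(iw_frame, small_tube, lattice):
    """Recovery trajectory with slow patch reorientation (disordered regime)."""
    params = AssemblySimParams(
        adsorption_rate=0.08,
        nucleation_orientation_spread=np.pi,
        patch_reorientation_rate=0.3,
        n_steps=40,
        seed=11,
    )
    return simulate_assembly(iw_frame, small_tube, lattice, params)


@pytest.fixture(scope="session")
def trajectory_series(slow_reorientation_trajectory, fast_params):
    """Band-averaged OD/LD/LD_r series of the slow-reorientation run."""
    window = BandWindow(15324.0, 18550.0)
    grid = np.arange(14000.0, 21000.0, 4.0)
    return timeseries(
        slow_reorientation_trajectory, fast_params, window, grid=grid, seed=5
    )
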