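"""Shared fixtures: structures, plasma histories and one melt trajectory.

Expensive objects are session-scoped; the melt uses a 192-molecule cell
(desk-scale stand-in for the full 768-molecule reference cell) so the
whole suite stays fast on one CPU.
"""

import numpy as np
import pytest

from plasmice import crystal, ionization, md, pipeline


@pytest.fixture(scope="session")
def ice_mini():
    return crystal.build_ice_ih((2, 2, 3), proton_seed=11)


@pytest.fixture(scope="session")
def melt_cell():
    return crystal.build_ice_ih((4, 2, 3), proton_seed=11)


@pytest.fixture(scope="session")
def ice768():
    return crystal.build_ice_ih((8, 3, 4), proton_seed=1)


@pytest.fixture(scope="session")
def plasma18():
    pulse = ionization.PulseSpec(8000.0, 1e18, 50.0)
    return ionization.evolve_plasma(pulse, timestep=0.5)


@pytest.fixture(scope="session")
def plasma19():
    pulse = ionization.PulseSpec(8000.0, 1e19, 50.0)
    return ionization.evolve_plasma(pulse, timestep=0.5)


@pytest.fixture(scope="session")
def melt_traj(melt_cell, plasma18):
    """50 fs screened melt at 10^18 W/cm^2, thermal start."""
    return md.integrate(
        melt_cell, plasma18, dt=0.5, n_steps=100, seed=7, stride=10,
        temperature_k=265.0,
    )


@pytest.fixture(scope="session")
def melt_intensity(melt_traj, plasma18):
    """Damage-weighted I(q, t) of the melt trajectory."""
    grid, rdfs = pipeline.intensity_vs_time(melt_traj, plasma18)
    return grid


@pytest.fixture(scope="session")
def melt_padf_volumes(melt_traj):
    from plasmice import padf

    io = np.flatnonzero(melt_traj.species == "O")
    vols = []
    for t in (0.0, 20.0, 40.0):
        fr = melt_traj.frame_nearest(t)
        vols.append(
            padf.compute_padf(
                fr.positions[io], melt_traj.box, seed=3, time_fs=fr.time_fs
            )
        )
    return vols
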