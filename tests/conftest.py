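"""Shared fixtures: small deterministic trajectories and cached bath runs."""

from __future__ import annotations

import numpy as np
import pytest

import ionflow
from ionflow.simulate import FieldProtocol, SimConfig, preset_config


@pytest.fixture(scope="session")
def na_bath_all():
    """40 ps zero-field bath of the intermediate preset, all atoms stored.

    Shared by structure/equipartition/tilt tests; first 4 ps discarded.
    """
    cfg = preset_config("na", seed=9, sample_every=5)
    traj = ionflow.simulate(cfg, FieldProtocol.zero_field(40_000.0, 4_000.0), store="all")
    sub = traj.slice_frames(traj.times >= traj.times[0] + 4_000.0)
    return cfg, sub


@pytest.fixture(scope="session")
def na_ion_long():
    """100 ps zero-field run storing only the ion at 2 fs sampling."""
    cfg = preset_config("na", seed=9, sample_every=2)
    traj = ionflow.simulate(cfg, FieldProtocol.zero_field(100_000.0, 8_000.0), store="ion")
    sub = traj.slice_frames(traj.times >= traj.times[0] + 8_000.0)
    return cfg, sub


@pytest.fixture(scope="session")
def free_particle_long():
    """10^6 steps of a single free Langevin particle (Ornstein-Uhlenbeck oracle)."""
    cfg = SimConfig(
        n_solvent=0, box_length=50.0, ion_mass=22.99, trans_friction=0.01,
        dipole_moment=0.0, seed=7, sample_every=1,
    )
    traj = ionflow.simulate(cfg, FieldProtocol.zero_field(1_000_000.0, 0.0), store="ion")
    return cfg, traj


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def small_trajectory(n_frames=3, n_atoms=4, with_velocities=True, with_dipoles=False,
                     box=10.0, dt=5.0, seed=0):
    """Small random (but valid) trajectory for I/O and plumbing tests."""
    r = np.random.default_rng(seed)
    dip = None
    if with_dipoles:
        dip = r.standard_normal((n_frames, n_atoms, 3))
        dip /= np.linalg.norm(dip, axis=2, keepdims=True)
    return ionflow.Trajectory(
        times=dt * (1 + np.arange(n_frames)),
        box_length=box,
        species=["ION"] + ["SOL"] * (n_atoms - 1),
        positions=r.uniform(0, box, (n_frames, n_atoms, 3)),
        velocities=r.standard_normal((n_frames, n_atoms, 3)) * 1e-3 if with_velocities else None,
        dipoles=dip,
        fields=np.tile([0.0, 0.0, 0.01], (n_frames, 1)),
    )
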