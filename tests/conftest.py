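"""Shared fixtures: small synthetic systems generated at test time."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from leapkit.synthetic import LatticeSpec, make_vibrating_lattice

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")
from leapkit.trajectory_io import ParticleTrajectory


@pytest.fixture(scope="session")
def frozen_lattice():
    """6x6x3 simple-cubic lattice, zero vibration, 5 frames."""
    spec = LatticeSpec(shape=(6, 6, 3), spacing=1.0, vibration=0.0)
    return make_vibrating_lattice(spec, n_frames=5, seed=0)


@pytest.fixture(scope="session")
def vibrating_lattice():
    spec = LatticeSpec(shape=(6, 6, 3), spacing=1.0, vibration=0.05)
    return make_vibrating_lattice(spec, n_frames=10, seed=1)


@pytest.fixture()
def random_gas():
    """Factory for uniform random periodic gases."""

    def _make(n=300, n_frames=2, box=10.0, dim=3, seed=0, periodic=True):
        rng = np.random.default_rng(seed)
        pos = rng.uniform(0, box, size=(n_frames, n, dim))
        return ParticleTrajectory(
            positions=pos,
            ids=np.arange(n),
            box=np.full(dim, box) if periodic else None,
            periodic=np.full(dim, periodic),
        )

    return _make


def brute_force_neighbors(traj, rcut, frame):
    """O(N^2) minimum-image neighbor oracle: list of sorted id arrays."""
    pos = traj.positions[frame]
    out = []
    for i in range(traj.n_units):
        delta = pos - pos[i]
        if traj.box is not None:
            for ax in np.nonzero(traj.periodic)[0]:
                L = traj.box[frame, ax]
                delta[:, ax] -= L * np.round(delta[:, ax] / L)
        d = np.linalg.norm(delta, axis=1)
        mask = (d <= rcut)
        mask[i] = False
        out.append(np.sort(traj.ids[mask]))
    return out
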