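"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from dpdmix.engine import SimulationState, maxwell_velocities
from dpdmix.model import (
    BondedParams,
    SystemComposition,
    build_topology,
    default_bonded_params,
    default_interaction_matrix,
)

NO_BONDS = np.empty((0, 2), dtype=np.int64)
NO_ANGLES = np.empty((0, 3), dtype=np.int64)


@pytest.fixture(scope="session")
def interaction():
    return default_interaction_matrix()


@pytest.fixture(scope="session")
def bonded():
    return default_bonded_params()


def make_water_state(
    n: int, box, seed: int = 0, kBT: float = 1.0
) -> SimulationState:
    """Random water box at the given count (no bonds)."""
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    return SimulationState(
        positions=rng.uniform(0.0, 1.0, (n, 3)) * box,
        velocities=maxwell_velocities(n, kBT, rng),
        forces=np.zeros((n, 3)),
        species=np.full(n, 4, dtype=np.int8),
        molecule_id=np.full(n, -1, dtype=np.int32),
        bonds=NO_BONDS,
        angles=NO_ANGLES,
        box_lengths=box,
    )


def make_mixed_state(n: int, box, seed: int = 0) -> SimulationState:
    """Random box with random species and a few bonds/angles (force oracles)."""
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    n_chain = min(12, n)
    bonds = np.array([[i, i + 1] for i in range(n_chain - 1)], dtype=np.int64)
    angles = np.array(
        [[i, i + 1, i + 2] for i in range(n_chain - 2)], dtype=np.int64
    )
    molid = np.full(n, -1, dtype=np.int32)
    molid[:n_chain] = 0
    return SimulationState(
        positions=rng.uniform(0.0, 1.0, (n, 3)) * box,
        velocities=rng.normal(size=(n, 3)),
        forces=np.zeros((n, 3)),
        species=rng.integers(0, 5, n).astype(np.int8),
        molecule_id=molid,
        bonds=bonds,
        angles=angles,
        box_lengths=box,
    )


def small_composition(
    n1: int = 40, n2: int = 40, n_tail1: int = 4, n_tail2: int = 4,
    box=(8.0, 8.0, 16.0),
) -> SystemComposition:
    return SystemComposition.from_box(
        n1,
        n2,
        build_topology("type-I", 3, n_tail1),
        build_topology("type-II", 3, n_tail2),
        tuple(box),
    )


def numpy_pair_oracle(
    state: SimulationState, a_matrix: np.ndarray, gamma: float, rc: float = 1.0
) -> np.ndarray:
    """Brute-force O(N^2) conservative + dissipative forces in plain numpy.

    Independent of the engine's kernels: broadcasting over all pairs with
    minimum-image displacements.
    """
    pos = state.positions
    vel = state.velocities
    box = state.box_lengths
    d = pos[:, None, :] - pos[None, :, :]
    d -= box[None, None, :] * np.round(d / box[None, None, :])
    r = np.linalg.norm(d, axis=-1)
    np.fill_diagonal(r, np.inf)
    w = np.clip(1.0 - r / rc, 0.0, None)
    a = a_matrix[state.species[:, None], state.species[None, :]]
    rhat = d / r[:, :, None]
    dv = vel[:, None, :] - vel[None, :, :]
    rv = np.einsum("ijk,ijk->ij", rhat, dv)
    fmag = a * w - gamma * w * w * rv
    return np.sum(fmag[:, :, None] * rhat, axis=1)


def bonded_energy(
    positions: np.ndarray, bonds, angles, bonded: BondedParams, box
) -> float:
    """Scalar bond + angle potential evaluated directly (for grad checks)."""
    box = np.asarray(box, dtype=float)
    e = 0.0
    for i, j in bonds:
        d = positions[i] - positions[j]
        d -= box * np.round(d / box)
        r = np.linalg.norm(d)
        e += 0.5 * bonded.ks * bonded.rs * (1.0 - r / bonded.rs) ** 2
    for i, j, k in angles:
        u = positions[i] - positions[j]
        u -= box * np.round(u / box)
        v = positions[k] - positions[j]
        v -= box * np.round(v / box)
        c = np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)
        e += bonded.k_theta * (np.arccos(c) - bonded.theta0) ** 2
    return e


def pair_energy(positions, species, a_matrix, box, rc: float = 1.0) -> float:
    """Scalar conservative pair potential (for grad checks)."""
    box = np.asarray(box, dtype=float)
    d = positions[:, None, :] - positions[None, :, :]
    d -= box[None, None, :] * np.round(d / box[None, None, :])
    r = np.linalg.norm(d, axis=-1)
    iu = np.triu_indices(len(positions), k=1)
    w = np.clip(1.0 - r[iu] / rc, 0.0, None)
    a = a_matrix[species[:, None], species[None, :]][iu]
    return float(np.sum(0.5 * a * rc * w * w))
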