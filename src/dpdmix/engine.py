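"""DPD engine: state container, force field, and the modified velocity-Verlet
integrator with the pairwise Groot-Warren thermostat.

Forces on a bead are the sum over neighbours within the cutoff rc of a soft
conservative repulsion a_ij (1 - r/rc) r_hat, a dissipative drag
-gamma w^2 (r_hat . v_ij) r_hat and a random kick sigma w zeta dt^(-1/2) r_hat,
plus harmonic bond and angle-bending forces along each lipid chain.  All
pairwise forces (including the random one) are applied with equal and
opposite sign, so total momentum is conserved to machine precision and the
thermostat is momentum-preserving.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .model import BondedParams, InteractionModel

__all__ = [
    "SimulationState",
    "IntegratorSettings",
    "EnergyBreakdown",
    "pair_weight",
    "conservative_force",
    "dissipative_force",
    "random_force",
    "bond_force",
    "angle_force",
    "total_pair_force",
    "vv_step",
    "run",
    "temperature",
    "energy_breakdown",
    "maxwell_velocities",
]

logger = logging.getLogger(__name__)


@dataclass
class SimulationState:
    """Positions/velocities/forces of every bead in a periodic box.

    Positions are kept wrapped into [0, L) per axis.  ``species`` holds the
    :class:`~dpdmix.model.BeadSpecies` integer per bead and ``molecule_id``
    the owning chain (-1 for water).
    """

    positions: np.ndarray
    velocities: np.ndarray
    forces: np.ndarray
    species: np.ndarray
    molecule_id: np.ndarray
    bonds: np.ndarray
    angles: np.ndarray
    box_lengths: np.ndarray
    time: float = 0.0
    step: int = 0

    def __post_init__(self) -> None:
        n = self.positions.shape[0]
        for name in ("velocities", "forces"):
            if getattr(self, name).shape != (n, 3):
                raise ValueError(f"{name} shape incongruent with positions")
        if self.species.shape[0] != n or self.molecule_id.shape[0] != n:
            raise ValueError("per-bead arrays incongruent with positions")
        self.box_lengths = np.asarray(self.box_lengths, dtype=float)

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "SimulationState":
        return SimulationState(
            self.positions.copy(),
            self.velocities.copy(),
            self.forces.copy(),
            self.species.copy(),
            self.molecule_id.copy(),
            self.bonds,
            self.angles,
            self.box_lengths.copy(),
            self.time,
            self.step,
        )

    def wrap(self) -> None:
        np.mod(self.positions, self.box_lengths[None, :], out=self.positions)


@dataclass(frozen=True)
class IntegratorSettings:
    """Time step, velocity-prediction factor and RNG seed of the integrator."""

    dt: float = 0.01
    lambda_vv: float = 0.5
    seed: int = 0
    #: Verlet-list safety skin in rc; the list is rebuilt whenever a bead has
    #: moved more than skin/2 since the last build (sufficient for validity)
    skin: float = 0.5

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (0.0 <= self.lambda_vv <= 1.0):
            raise ValueError("lambda_vv must lie in [0, 1]")
        if self.skin < 0:
            raise ValueError("skin must be non-negative")


@dataclass(frozen=True)
class EnergyBreakdown:
    """Per-bead energies in kBT; total = kinetic + pair + bond + angle."""

    kinetic: float
    pair_conservative: float
    bond: float
    angle: float

    @property
    def total(self) -> float:
        return self.kinetic + self.pair_conservative + self.bond + self.angle


# ----------------------------------------------------------------------------
# Elementary force formulas (reference implementations, used directly for
# single pairs/triples and as the documented definition of the force field)


def pair_weight(r: float, rc: float = 1.0) -> float:
    """DPD weight w(r) = 1 - r/rc inside the cutoff, 0 outside."""
    return 1.0 - r / rc if r < rc else 0.0


def conservative_force(a: float, r_vec: np.ndarray, rc: float = 1.0) -> np.ndarray:
    """Soft repulsion a w(r) r_hat on bead i for separation r_vec = ri - rj."""
    r = float(np.linalg.norm(r_vec))
    if r >= rc:
        return np.zeros(3)
    if r < 1e-12:
        logger.warning("conservative_force: zero separation, magnitude capped at a")
        return np.array([a, 0.0, 0.0])
    return a * pair_weight(r, rc) * (np.asarray(r_vec) / r)


def dissipative_force(
    gamma: float, w: float, r_hat: np.ndarray, v_rel: np.ndarray
) -> np.ndarray:
    """Viscous drag -gamma w^2 (r_hat . v_rel) r_hat."""
    r_hat = np.asarray(r_hat, dtype=float)
    return -gamma * w * w * float(r_hat @ np.asarray(v_rel)) * r_hat


def random_force(
    sigma: float, w: float, zeta: float, dt: float, r_hat: np.ndarray
) -> np.ndarray:
    """Thermal kick sigma w zeta dt^(-1/2) r_hat (zeta: unit-variance Gaussian)."""
    return sigma * w * zeta / math.sqrt(dt) * np.asarray(r_hat, dtype=float)


def bond_force(ks: float, rs: float, r_vec: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Forces on the two beads of a bond with separation r_vec = ri - rj."""
    r = float(np.linalg.norm(r_vec))
    if r < 1e-12:
        logger.warning("bond_force: zero-length bond, force capped at zero")
        return np.zeros(3), np.zeros(3)
    f_i = ks * (1.0 - r / rs) * (np.asarray(r_vec) / r)
    return f_i, -f_i


def angle_force(
    k_theta: float,
    theta0: float,
    r_i: np.ndarray,
    r_j: np.ndarray,
    r_k: np.ndarray,
    box: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bending forces on the (i, j, k) triple; j is the middle bead."""
    if box is None:
        box = np.array([1e12, 1e12, 1e12])
    pos = np.array([r_i, r_j, r_k], dtype=float)
    fix, fiy, fiz, fkx, fky, fkz, _ = K._angle_triple(
        pos, 0, 1, 2, k_theta, theta0, np.asarray(box, dtype=float)
    )
    f_i = np.array([fix, fiy, fiz])
    f_k = np.array([fkx, fky, fkz])
    return f_i, -(f_i + f_k), f_k


# ----------------------------------------------------------------------------
# Whole-system force evaluation and integration


def _use_cells(box: np.ndarray, r_search: float) -> bool:
    """Cell-based search needs >= 3 cells per axis to avoid duplicate images."""
    return bool(np.all(np.floor(np.asarray(box) / r_search) >= 3))


def total_pair_force(
    state: SimulationState,
    interaction: InteractionModel,
    bonded: BondedParams,
    settings: IntegratorSettings | None = None,
    velocities: np.ndarray | None = None,
    thermostat: bool = True,
    step: int | None = None,
) -> tuple[np.ndarray, EnergyBreakdown]:
    """Evaluate all forces (C + D + R + bond + angle) for the current state.

    With ``thermostat=False`` only the deterministic conservative + bonded
    part is returned (useful for oracles and stress).  Random draws are keyed
    on (seed, step) so a force evaluation is reproducible.
    """
    settings = settings or IntegratorSettings()
    vel = state.velocities if velocities is None else velocities
    stp = state.step if step is None else step
    forces, e_pair, e_bond, e_angle, n_ov = K.compute_forces(
        state.positions,
        vel,
        state.species.astype(np.int8),
        state.bonds,
        state.angles,
        interaction.a,
        interaction.gamma,
        interaction.sigma,
        settings.dt,
        bonded.ks,
        bonded.rs,
        bonded.k_theta,
        bonded.theta0,
        state.box_lengths,
        interaction.rc,
        np.uint64(settings.seed & 0x7FFFFFFFFFFFFFFF),
        np.uint64(stp),
        thermostat,
        _use_cells(state.box_lengths, interaction.rc),
    )
    if n_ov > 0:
        logger.warning("zero-separation pairs encountered: %d", n_ov)
    n = state.n_beads
    kin = 0.5 * float(np.sum(vel * vel))
    eb = EnergyBreakdown(kin / n, e_pair / n, e_bond / n, e_angle / n)
    return forces, eb


def vv_step(
    state: SimulationState,
    settings: IntegratorSettings,
    interaction: InteractionModel,
    bonded: BondedParams,
) -> SimulationState:
    """One step of the modified velocity-Verlet scheme (in place; returns state).

    Sequence: positions drift with the old forces; velocities are predicted
    with factor lambda; forces are recomputed at the new positions (fresh
    random draws, dissipative term on the predicted velocities); velocities
    are corrected with the mean of old and new forces.
    """
    run(state, settings, interaction, bonded, n_steps=1, energy_stride=1)
    return state


def run(
    state: SimulationState,
    settings: IntegratorSettings,
    interaction: InteractionModel,
    bonded: BondedParams,
    n_steps: int,
    energy_stride: int = 100,
) -> np.ndarray:
    """Advance ``n_steps`` in place; returns the energy log.

    The log is a float array of shape (n_records, 7): columns are
    (time, kinetic, pair, bond, angle, total, temperature), energies per bead
    in kBT.  Forces must be valid on entry for states already stepped; a
    freshly built state (step 0, zero forces) gets an initial evaluation.
    """
    if state.step == 0 and not state.forces.any():
        f, _ = total_pair_force(state, interaction, bonded, settings, step=0)
        state.forces[:] = f
    n_rec_max = n_steps // energy_stride + 1
    e_step = np.zeros(n_rec_max, dtype=np.int64)
    e_kin = np.zeros(n_rec_max)
    e_pair = np.zeros(n_rec_max)
    e_bond = np.zeros(n_rec_max)
    e_angle = np.zeros(n_rec_max)
    n_rec, n_ov = K.run_chunk(
        state.positions,
        state.velocities,
        state.forces,
        state.species.astype(np.int8),
        state.bonds,
        state.angles,
        interaction.a,
        interaction.gamma,
        interaction.sigma,
        settings.dt,
        settings.lambda_vv,
        bonded.ks,
        bonded.rs,
        bonded.k_theta,
        bonded.theta0,
        state.box_lengths,
        interaction.rc,
        settings.skin,
        np.uint64(settings.seed & 0x7FFFFFFFFFFFFFFF),
        state.step,
        n_steps,
        energy_stride,
        e_step,
        e_kin,
        e_pair,
        e_bond,
        e_angle,
        _use_cells(state.box_lengths, interaction.rc + settings.skin),
    )
    if n_ov:
        logger.warning("zero-separation pairs during run: %d", n_ov)
    state.step += n_steps
    state.time = state.step * settings.dt
    if not np.all(np.isfinite(state.positions)):
        raise FloatingPointError(
            f"non-finite coordinates at step {state.step}; "
            "the configuration has blown up"
        )
    n = state.n_beads
    log = np.empty((n_rec, 7))
    log[:, 0] = e_step[:n_rec] * settings.dt
    log[:, 1] = e_kin[:n_rec] / n
    log[:, 2] = e_pair[:n_rec] / n
    log[:, 3] = e_bond[:n_rec] / n
    log[:, 4] = e_angle[:n_rec] / n
    log[:, 5] = log[:, 1] + log[:, 2] + log[:, 3] + log[:, 4]
    log[:, 6] = e_kin[:n_rec] * 2.0 / (3.0 * n)
    return log


def temperature(state: SimulationState) -> float:
    """Kinetic temperature kBT from the drift-corrected velocities."""
    v = state.velocities
    n = v.shape[0]
    if n < 2:
        raise ValueError("temperature needs at least 2 beads")
    vc = v - v.mean(axis=0, keepdims=True)
    return float(np.sum(vc * vc)) / (3.0 * (n - 1))


def energy_breakdown(
    state: SimulationState,
    interaction: InteractionModel,
    bonded: BondedParams,
) -> EnergyBreakdown:
    """Per-bead kinetic, pair, bond and angle energies of a configuration."""
    _, eb = total_pair_force(
        state, interaction, bonded, thermostat=False
    )
    return eb


def maxwell_velocities(
    n: int, kBT: float, rng: np.random.Generator
) -> np.ndarray:
    """Maxwellian velocities at temperature kBT with zero total momentum."""
    v = rng.normal(0.0, math.sqrt(kBT), size=(n, 3))
    v -= v.mean(axis=0, keepdims=True)
    return v
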