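"""Irving-Kirkwood pressure tensor and interfacial tension profiles.

The diagonal pressure components are kinetic plus virial terms,
p_aa = (sum_i m v_ia v_ia + sum_{i<j} F_ij^a r_ij^a) / V, with the pairwise
virial localized along the straight inter-bead contour: each interaction leg
deposits its contribution into z-slabs in proportion to the segment length
inside each slab, so the slab decomposition sums to the whole-box tensor
exactly.  Only conservative pair, bond and angle forces enter the reported
stress; the thermostat's dissipative and random forces average to zero
momentum flux at equilibrium and would only add noise (they can be assessed
separately through the kinetic temperature).  The interfacial tension is
sigma_z = p_zz - (p_xx + p_yy)/2, the normal-minus-tangential convention, so
a stretched water/lipid interface yields negative values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import _kernels as K
from .engine import SimulationState, _use_cells
from .model import BondedParams, InteractionModel

__all__ = [
    "StressRecord",
    "pressure_tensor",
    "tension_z",
    "tension_profile",
    "tension_near_pore",
    "tension_timeseries",
]


@dataclass(frozen=True)
class StressRecord:
    """Region-resolved diagonal pressure components and derived tension.

    ``region`` describes the averaging domain ("box", a z-slab index, or a
    y-window x z-slab); pressures are in kBT/rc^3.
    """

    region: str
    pxx: float
    pyy: float
    pzz: float
    time: float = 0.0

    @property
    def sigma_z(self) -> float:
        return self.pzz - 0.5 * (self.pxx + self.pyy)


def _slab_stress(
    state: SimulationState,
    interaction: InteractionModel,
    bonded: BondedParams,
    n_slabs: int,
    y_window: tuple[float, float] | None = None,
) -> np.ndarray:
    """(n_slabs, 3) diagonal pressure per z-slab for one frame."""
    y_lo, y_hi = (-1.0, -1.0) if y_window is None else y_window
    kin, vir = K.stress_slabs(
        state.positions,
        state.velocities,
        state.species.astype(np.int8),
        state.bonds,
        state.angles,
        interaction.a,
        bonded.ks,
        bonded.rs,
        bonded.k_theta,
        bonded.theta0,
        state.box_lengths,
        interaction.rc,
        n_slabs,
        y_lo,
        y_hi,
        _use_cells(state.box_lengths, interaction.rc),
    )
    lx, ly, lz = state.box_lengths
    dy = ly if y_window is None else (y_hi - y_lo)
    if dy <= 0:
        raise ValueError("empty y-window")
    slab_vol = lx * dy * (lz / n_slabs)
    return (kin + vir) / slab_vol


def pressure_tensor(
    state: SimulationState,
    interaction: InteractionModel,
    bonded: BondedParams,
    region: str = "box",
) -> StressRecord:
    """Whole-box diagonal pressure tensor of one frame."""
    p = _slab_stress(state, interaction, bonded, n_slabs=1)
    return StressRecord(
        region=region,
        pxx=float(p[0, 0]),
        pyy=float(p[0, 1]),
        pzz=float(p[0, 2]),
        time=state.time,
    )


def tension_z(record: StressRecord) -> float:
    """sigma_z = p_zz - (p_xx + p_yy)/2 of one stress record."""
    return record.sigma_z


def tension_profile(
    frames: Iterable[SimulationState],
    interaction: InteractionModel,
    bonded: BondedParams,
    n_slabs: int = 60,
    y_window: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Frame-averaged sigma_z(z) profile over z-slabs.

    Returns (z_centers, sigma_z, pressures) with pressures of shape
    (n_slabs, 3) = time-averaged (pxx, pyy, pzz) per slab.
    """
    acc = None
    n = 0
    box = None
    for state in frames:
        p = _slab_stress(state, interaction, bonded, n_slabs, y_window)
        acc = p if acc is None else acc + p
        n += 1
        box = state.box_lengths
    if n == 0:
        raise ValueError("need at least one frame")
    p = acc / n
    z = (np.arange(n_slabs) + 0.5) * (box[2] / n_slabs)
    sigma = p[:, 2] - 0.5 * (p[:, 0] + p[:, 1])
    return z, sigma, p


def tension_near_pore(
    frames: Iterable[SimulationState],
    interaction: InteractionModel,
    bonded: BondedParams,
    y_window: tuple[float, float] = (7.0, 17.0),
    n_slabs: int = 60,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """sigma_z(z) restricted to a y-window around the pore (x-averaged)."""
    return tension_profile(frames, interaction, bonded, n_slabs, y_window)


def _membrane_slab_mask(
    state: SimulationState, n_slabs: int, plateau_fraction: float = 0.5
) -> np.ndarray:
    """Slabs belonging to the membrane domain: lipid density above the given
    fraction of its plateau (the median over occupied slabs)."""
    lz = float(state.box_lengths[2])
    lipid = state.molecule_id >= 0
    z = np.mod(state.positions[lipid, 2], lz)
    counts, _ = np.histogram(z, bins=np.linspace(0.0, lz, n_slabs + 1))
    if not counts.any():
        return np.zeros(n_slabs, dtype=bool)
    plateau = np.median(counts[counts > 0])
    return counts > plateau_fraction * plateau


def tension_timeseries(
    frames: Sequence[SimulationState],
    interaction: InteractionModel,
    bonded: BondedParams,
    stages=None,
    n_slabs: int = 60,
) -> dict:
    """Per-frame and per-stage mean sigma_z over the membrane-domain slabs.

    ``stages`` is a :class:`~dpdmix.analysis.StageSegmentation` (or None for
    no stage averaging).  Returns {"times", "sigma_z", "stage_means"}.
    """
    times = []
    sigmas = []
    for state in frames:
        p = _slab_stress(state, interaction, bonded, n_slabs)
        sigma = p[:, 2] - 0.5 * (p[:, 0] + p[:, 1])
        mask = _membrane_slab_mask(state, n_slabs)
        val = float(sigma[mask].mean()) if mask.any() else float(sigma.mean())
        times.append(state.time)
        sigmas.append(val)
    times_arr = np.asarray(times)
    sig_arr = np.asarray(sigmas)
    out = {"times": times_arr, "sigma_z": sig_arr, "stage_means": None}
    if stages is not None and len(times_arr):
        idx = stages.stage_of(times_arr)
        out["stage_means"] = tuple(
            float(sig_arr[idx == s].mean()) if (idx == s).any() else float("nan")
            for s in range(3)
        )
    return out
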