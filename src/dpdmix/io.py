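"""Trajectory and log I/O: LAMMPS-style text dumps, XYZ export, energy CSV,
and checkpoint/restart containers."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import SimulationState
from .model import BeadSpecies

__all__ = [
    "write_dump_frame",
    "read_dump",
    "write_xyz_frame",
    "energy_log_frame",
    "write_checkpoint",
    "read_checkpoint",
    "config_hash",
]

ENERGY_COLUMNS = ["time", "kinetic", "pair", "bond", "angle", "total", "temperature"]


def write_dump_frame(
    path: str | Path,
    state: SimulationState,
    append: bool = True,
    velocities: bool = False,
) -> None:
    """Append one frame in LAMMPS text dump format (id type x y z [vx vy vz])."""
    lx, ly, lz = state.box_lengths
    cols = "id type x y z" + (" vx vy vz" if velocities else "")
    lines = [
        "ITEM: TIMESTEP",
        str(state.step),
        "ITEM: NUMBER OF ATOMS",
        str(state.n_beads),
        "ITEM: BOX BOUNDS pp pp pp",
        f"0.0 {lx:.10g}",
        f"0.0 {ly:.10g}",
        f"0.0 {lz:.10g}",
        f"ITEM: ATOMS {cols}",
    ]
    pos = state.positions
    vel = state.velocities
    for i in range(state.n_beads):
        row = f"{i + 1} {int(state.species[i]) + 1} {pos[i, 0]:.8g} {pos[i, 1]:.8g} {pos[i, 2]:.8g}"
        if velocities:
            row += f" {vel[i, 0]:.8g} {vel[i, 1]:.8g} {vel[i, 2]:.8g}"
        lines.append(row)
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write("\n".join(lines) + "\n")


def read_dump(path: str | Path) -> list[dict]:
    """Read all frames of a LAMMPS text dump written by write_dump_frame.

    Returns a list of dicts with keys step, box, species (0-based), positions
    and (when present) velocities.
    """
    frames = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        assert lines[i].startswith("ITEM: TIMESTEP")
        step = int(lines[i + 1])
        n = int(lines[i + 3])
        box = np.array(
            [float(lines[i + 5 + k].split()[1]) for k in range(3)]
        )
        header = lines[i + 8].split()[2:]
        has_vel = "vx" in header
        data = np.array(
            [[float(x) for x in lines[i + 9 + k].split()] for k in range(n)]
        )
        order = np.argsort(data[:, 0])
        data = data[order]
        frame = {
            "step": step,
            "box": box,
            "species": data[:, 1].astype(int) - 1,
            "positions": data[:, 2:5].copy(),
        }
        if has_vel:
            frame["velocities"] = data[:, 5:8].copy()
        frames.append(frame)
        i += 9 + n
    return frames


def write_xyz_frame(path: str | Path, state: SimulationState, append: bool = True) -> None:
    """Append one frame in XYZ format for quick viewing."""
    lines = [str(state.n_beads), f"step={state.step} time={state.time:.6g}"]
    for i in range(state.n_beads):
        name = BeadSpecies(int(state.species[i])).name
        p = state.positions[i]
        lines.append(f"{name} {p[0]:.6g} {p[1]:.6g} {p[2]:.6g}")
    with open(path, "a" if append else "w") as fh:
        fh.write("\n".join(lines) + "\n")


def energy_log_frame(log: np.ndarray) -> pd.DataFrame:
    """Wrap the engine's (n, 7) energy log into a tidy DataFrame."""
    return pd.DataFrame(log, columns=ENERGY_COLUMNS)


def write_checkpoint(path: str | Path, state: SimulationState, manifest: dict) -> None:
    """Serialize the full state (npz container) plus a JSON manifest string."""
    np.savez_compressed(
        path,
        positions=state.positions,
        velocities=state.velocities,
        forces=state.forces,
        species=state.species,
        molecule_id=state.molecule_id,
        bonds=state.bonds,
        angles=state.angles,
        box_lengths=state.box_lengths,
        time=np.array([state.time]),
        step=np.array([state.step]),
        manifest=np.array([json.dumps(manifest)]),
    )


def read_checkpoint(path: str | Path) -> tuple[SimulationState, dict]:
    d = np.load(path, allow_pickle=False)
    state = SimulationState(
        positions=d["positions"],
        velocities=d["velocities"],
        forces=d["forces"],
        species=d["species"],
        molecule_id=d["molecule_id"],
        bonds=d["bonds"],
        angles=d["angles"],
        box_lengths=d["box_lengths"],
        time=float(d["time"][0]),
        step=int(d["step"][0]),
    )
    manifest = json.loads(str(d["manifest"][0]))
    return state, manifest


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration dict (manifest traceability)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
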