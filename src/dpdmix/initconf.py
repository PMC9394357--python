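"""Seeded builders for initial configurations.

These generators are the simulations' input data: an unmixed layered
bilayer (type-I lipids in the upper leaflet, type-II in the lower), a fully
random dispersion, and two pre-assembled geometric fixtures (a perforated
bilayer and a closed vesicle) used to exercise the structure analytics.
Water fills the remaining volume so the global bead density hits its target
(3 beads per rc^3 by default); velocities are Maxwellian at kBT = 1 with the
centre-of-mass drift removed.
"""

from __future__ import annotations

import math

import numpy as np

from .engine import SimulationState, maxwell_velocities
from .model import SystemComposition

__all__ = [
    "layered_bilayer_init",
    "random_init",
    "perforated_fixture",
    "vesicle_fixture",
]


def _assemble_state(
    composition: SystemComposition,
    lipid_positions: np.ndarray,
    water_positions: np.ndarray,
    rng: np.random.Generator,
    kBT: float = 1.0,
) -> SimulationState:
    species, molid, bonds, angles = composition.bead_arrays()
    pos = np.vstack([lipid_positions, water_positions])
    if pos.shape[0] != composition.n_total:
        raise ValueError("bead bookkeeping mismatch in builder")
    box = np.asarray(composition.box_lengths, dtype=float)
    pos = np.mod(pos, box[None, :])
    vel = maxwell_velocities(composition.n_total, kBT, rng)
    state = SimulationState(
        positions=pos,
        velocities=vel,
        forces=np.zeros_like(pos),
        species=species,
        molecule_id=molid,
        bonds=bonds,
        angles=angles,
        box_lengths=box,
    )
    return state


def _leaflet_sites(
    n_chains: int, lx: float, ly: float, rng: np.random.Generator,
    exclude_radius: float = 0.0,
) -> np.ndarray:
    """Jittered square-lattice (x, y) sites for one leaflet.

    Spacing is sqrt(Lx*Ly / n_chains); jitter is uniform within 0.2 spacing,
    which keeps the packing layer-like while breaking lattice symmetry.  With
    ``exclude_radius > 0`` sites inside the centred disc are discarded first
    (pore carving), so enough lattice sites must remain.  Packings tighter
    than 0.4 rc^2 per chain are rejected: below that the "layer" degenerates
    into a dense overlap pile.
    """
    avail = lx * ly
    if exclude_radius > 0.0:
        avail = max(lx * ly - math.pi * exclude_radius**2, 0.05 * lx * ly)
    if n_chains > avail / 0.4:
        raise ValueError(
            f"leaflet area insufficient: {n_chains} chains on {avail:.1f} rc^2"
        )
    spacing = math.sqrt(avail / n_chains)
    nx = max(int(round(lx / spacing)), 1)
    ny = max(int(math.ceil(lx * ly / (spacing * spacing) / nx)), 1)
    xs = (np.arange(nx) + 0.5) * (lx / nx)
    ys = (np.arange(ny) + 0.5) * (ly / ny)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    sites = np.column_stack([gx.ravel(), gy.ravel()])
    if exclude_radius > 0.0:
        d = sites - np.array([lx / 2.0, ly / 2.0])
        sites = sites[np.hypot(d[:, 0], d[:, 1]) > exclude_radius]
    if sites.shape[0] < n_chains:
        raise ValueError(
            f"leaflet area insufficient: {sites.shape[0]} sites for "
            f"{n_chains} chains"
        )
    order = rng.permutation(sites.shape[0])[:n_chains]
    sites = sites[order]
    sites += rng.uniform(-0.2 * spacing, 0.2 * spacing, size=sites.shape)
    return sites


def _straight_chain_z(
    site_xy: np.ndarray, n_beads: int, rs: float, z_head: float, down: bool
) -> np.ndarray:
    """A straight chain along z: head bead at z_head, tail toward the midplane."""
    sign = -1.0 if down else 1.0
    z = z_head + sign * rs * np.arange(n_beads)
    out = np.empty((n_beads, 3))
    out[:, 0] = site_xy[0]
    out[:, 1] = site_xy[1]
    out[:, 2] = z
    return out


def _water_fill(
    n_water: int,
    box: np.ndarray,
    rng: np.random.Generator,
    z_exclude: tuple[float, float] | None = None,
    keep_fn=None,
) -> np.ndarray:
    """Uniform water positions, optionally excluding a z-slab (pore-pierced
    via ``keep_fn(xyz) -> bool array`` which can re-admit excluded points)."""
    out = np.empty((n_water, 3))
    filled = 0
    while filled < n_water:
        m = max(2 * (n_water - filled), 1000)
        cand = rng.uniform(0.0, 1.0, size=(m, 3)) * box[None, :]
        ok = np.ones(m, dtype=bool)
        if z_exclude is not None:
            inside = (cand[:, 2] > z_exclude[0]) & (cand[:, 2] < z_exclude[1])
            if keep_fn is not None:
                inside &= ~keep_fn(cand)
            ok &= ~inside
        cand = cand[ok]
        take = min(cand.shape[0], n_water - filled)
        out[filled : filled + take] = cand[:take]
        filled += take
    return out


def layered_bilayer_init(
    composition: SystemComposition,
    seed: int = 0,
    rs: float = 0.7,
    leaflet_gap: float = 0.3,
) -> SimulationState:
    """Unmixed layered bilayer: all type-I chains up, all type-II chains down.

    Chains start straight (bonds at rs, angles at theta0) and normal to the
    membrane plane, heads outward and tails meeting at the box midplane.
    Water fills everything outside the initial tail slab.
    """
    rng = np.random.default_rng(seed)
    box = np.asarray(composition.box_lengths, dtype=float)
    z_mid = box[2] / 2.0
    topo1, topo2 = composition.topology1, composition.topology2
    sites1 = _leaflet_sites(composition.n1, box[0], box[1], rng)
    sites2 = _leaflet_sites(composition.n2, box[0], box[1], rng)
    chains = []
    # upper leaflet (type-I): head outermost, beads descending toward midplane
    z_head1 = z_mid + leaflet_gap / 2.0 + (topo1.n_beads - 1) * rs
    for s in sites1:
        chains.append(_straight_chain_z(s, topo1.n_beads, rs, z_head1, down=True))
    # lower leaflet (type-II): mirrored
    z_head2 = z_mid - leaflet_gap / 2.0 - (topo2.n_beads - 1) * rs
    for s in sites2:
        chains.append(_straight_chain_z(s, topo2.n_beads, rs, z_head2, down=False))
    lipid_pos = np.vstack(chains)
    half_tail = max(topo1.n_tail, topo2.n_tail) * rs + leaflet_gap / 2.0
    water = _water_fill(
        composition.n_water, box, rng, z_exclude=(z_mid - half_tail, z_mid + half_tail)
    )
    return _assemble_state(composition, lipid_pos, water, rng)


def random_init(
    composition: SystemComposition,
    seed: int = 0,
    rs: float = 0.7,
) -> SimulationState:
    """Random dispersion: chains as freely jointed walks with bond length rs."""
    rng = np.random.default_rng(seed)
    box = np.asarray(composition.box_lengths, dtype=float)
    chains = []
    for n_chains, topo in (
        (composition.n1, composition.topology1),
        (composition.n2, composition.topology2),
    ):
        for _ in range(n_chains):
            start = rng.uniform(0.0, 1.0, 3) * box
            steps = rng.normal(size=(topo.n_beads - 1, 3))
            steps /= np.linalg.norm(steps, axis=1, keepdims=True)
            pos = np.vstack([start, start + np.cumsum(rs * steps, axis=0)])
            chains.append(pos)
    lipid_pos = (
        np.vstack(chains) if chains else np.empty((0, 3))
    )
    water = _water_fill(composition.n_water, box, rng)
    return _assemble_state(composition, lipid_pos, water, rng)


def perforated_fixture(
    composition: SystemComposition,
    pore_radius: float,
    seed: int = 0,
    rs: float = 0.7,
) -> SimulationState:
    """Layered bilayer pierced by a centred cylindrical solvent pore.

    Lipid lattice sites inside the pore disc are discarded and the displaced
    chains re-packed on the remaining sites; water fills the outside slabs
    and the pore channel, keeping exact species counts.
    """
    box = np.asarray(composition.box_lengths, dtype=float)
    if pore_radius >= min(box[0], box[1]) / 2.0:
        raise ValueError("pore radius must be smaller than half the box side")
    if pore_radius <= 0.0:
        return layered_bilayer_init(composition, seed=seed, rs=rs)
    rng = np.random.default_rng(seed)
    z_mid = box[2] / 2.0
    topo1, topo2 = composition.topology1, composition.topology2
    # jitter can push a site into the disc by up to 0.2 spacing; carve a
    # slightly larger disc so the carved geometry stays clean
    margin = 0.25 * math.sqrt(box[0] * box[1] / max(composition.n1, 1))
    sites1 = _leaflet_sites(
        composition.n1, box[0], box[1], rng, exclude_radius=pore_radius + margin
    )
    sites2 = _leaflet_sites(
        composition.n2, box[0], box[1], rng, exclude_radius=pore_radius + margin
    )
    chains = []
    z_head1 = z_mid + 0.15 + (topo1.n_beads - 1) * rs
    for s in sites1:
        chains.append(_straight_chain_z(s, topo1.n_beads, rs, z_head1, down=True))
    z_head2 = z_mid - 0.15 - (topo2.n_beads - 1) * rs
    for s in sites2:
        chains.append(_straight_chain_z(s, topo2.n_beads, rs, z_head2, down=False))
    lipid_pos = np.vstack(chains)
    half_tail = max(topo1.n_tail, topo2.n_tail) * rs + 0.15
    cx, cy = box[0] / 2.0, box[1] / 2.0

    def in_pore(xyz: np.ndarray) -> np.ndarray:
        return np.hypot(xyz[:, 0] - cx, xyz[:, 1] - cy) < pore_radius

    water = _water_fill(
        composition.n_water,
        box,
        rng,
        z_exclude=(z_mid - half_tail, z_mid + half_tail),
        keep_fn=in_pore,
    )
    return _assemble_state(composition, lipid_pos, water, rng)


def _fibonacci_sphere(n: int, rng: np.random.Generator) -> np.ndarray:
    """n approximately equidistributed unit vectors (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i + rng.uniform(0, 2 * math.pi)
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def vesicle_fixture(
    composition: SystemComposition,
    radius: float,
    seed: int = 0,
    rs: float = 0.7,
) -> SimulationState:
    """Closed spherical bilayer of the given mid-surface radius at box centre.

    Chains point radially: the outer leaflet has heads outermost, the inner
    leaflet heads innermost, tails meeting at the mid-surface.  Chains of
    both types are interleaved over both leaflets, split by leaflet area.
    Water occupies the core and the exterior.
    """
    rng = np.random.default_rng(seed)
    box = np.asarray(composition.box_lengths, dtype=float)
    centre = box / 2.0
    topo1, topo2 = composition.topology1, composition.topology2
    max_len = max(topo1.n_beads, topo2.n_beads) * rs
    if radius + max_len >= min(box) / 2.0:
        raise ValueError("vesicle radius plus chain length must fit in half box")
    chains: list[np.ndarray] = []
    order: list[int] = []  # chain index in canonical (type-I first) ordering
    # split each type across leaflets in proportion to leaflet area
    r_out, r_in = radius + 0.3, radius - 0.3
    f_out = r_out**2 / (r_out**2 + r_in**2)
    specs = []
    for type_idx, (n_chains, topo) in enumerate(
        ((composition.n1, topo1), (composition.n2, topo2))
    ):
        n_out = int(round(f_out * n_chains))
        specs.append((type_idx, topo, n_out, n_chains - n_out))
    for leaflet in ("outer", "inner"):
        members = []
        for type_idx, topo, n_out, n_in in specs:
            members += [(type_idx, topo)] * (n_out if leaflet == "outer" else n_in)
        if not members:
            continue
        rng.shuffle(members)
        dirs = _fibonacci_sphere(len(members), rng)
        for (type_idx, topo), u in zip(members, dirs):
            nb = topo.n_beads
            if leaflet == "outer":
                # head outermost, beads descending toward the mid-surface
                radii = r_out + rs * (nb - 1) - rs * np.arange(nb)
            else:
                radii = r_in - rs * (nb - 1) + rs * np.arange(nb)
            pos = centre[None, :] + radii[:, None] * u[None, :]
            chains.append(pos)
            order.append(type_idx)
    # canonical bead ordering: all type-I chains first, then type-II
    order_arr = np.argsort(np.asarray(order), kind="stable")
    lipid_pos = np.vstack([chains[i] for i in order_arr])

    def in_shell(xyz: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(xyz - centre[None, :], axis=1)
        return (d > r_in - max_len) & (d < r_out + max_len)

    # water everywhere except the bilayer shell
    n_water = composition.n_water
    out = np.empty((n_water, 3))
    filled = 0
    while filled < n_water:
        m = max(2 * (n_water - filled), 1000)
        cand = rng.uniform(0.0, 1.0, size=(m, 3)) * box[None, :]
        cand = cand[~in_shell(cand)]
        take = min(cand.shape[0], n_water - filled)
        out[filled : filled + take] = cand[:take]
        filled += take
    return _assemble_state(composition, lipid_pos, out, rng)
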