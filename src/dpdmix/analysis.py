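"""Structural observables for lipid-mixture configurations.

Covers binned density profiles (axial and radial), the P2 orientational
order parameter of chain segments against the membrane normal, per-chain
gyration tensors and the derived shape factor, leaflet mixing counts,
bilayer thickness from the head-bead density profile, grid-based pore
detection, structure classification (membrane / perforated membrane /
vesicle) and the three-stage segmentation of observable time series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .engine import SimulationState
from .model import BeadSpecies

__all__ = [
    "DensityProfile",
    "GyrationRecord",
    "MixingRecord",
    "StageSegmentation",
    "density_profile",
    "radial_density_profile",
    "order_parameter",
    "unwrap_chain",
    "iter_chains",
    "gyration_tensor",
    "shape_factor",
    "chain_shape_stats",
    "leaflet_mixing_counts",
    "lipid_midplane",
    "membrane_normal",
    "membrane_normal_axis",
    "membrane_normal_vector",
    "membrane_thickness",
    "order_parameter_normal",
    "projected_head_profile",
    "pore_detect",
    "classify_structure",
    "stage_segmentation",
    "phase_point",
]

_HEAD_SPECIES = (int(BeadSpecies.H1), int(BeadSpecies.H2))
_TAIL_SPECIES = (int(BeadSpecies.T1), int(BeadSpecies.T2))


# ----------------------------------------------------------------------------
# Density profiles


@dataclass(frozen=True)
class DensityProfile:
    """Per-species binned bead density (beads/rc^3).

    ``kind`` is "axis" (slab bins along one box axis) or "radial" (spherical
    shells about a centre).  Multiplying each density by its bin volume and
    summing recovers the species bead count exactly.
    """

    kind: str
    bin_edges: np.ndarray
    densities: dict[str, np.ndarray]
    bin_volumes: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def total(self, labels: tuple[str, ...] | None = None) -> np.ndarray:
        labels = labels or tuple(self.densities)
        return np.sum([self.densities[k] for k in labels], axis=0)


def density_profile(
    state: SimulationState,
    axis: int = 2,
    n_bins: int = 60,
    species_filter: tuple[BeadSpecies, ...] | None = None,
    origin: float = 0.0,
) -> DensityProfile:
    """Slab-binned per-species density along a box axis (periodic wrapping).

    ``origin`` shifts the coordinate frame (periodically) before binning;
    recentering each frame on the bilayer midplane before averaging removes
    the broadening caused by slow drift of the membrane along its normal.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    L = float(state.box_lengths[axis])
    edges = np.linspace(0.0, L, n_bins + 1)
    area = float(np.prod(state.box_lengths)) / L
    bin_vol = np.full(n_bins, area * (L / n_bins))
    coords = np.mod(state.positions[:, axis] - origin, L)
    species = species_filter or tuple(BeadSpecies)
    densities = {}
    for sp in species:
        mask = state.species == int(sp)
        counts, _ = np.histogram(coords[mask], bins=edges)
        densities[sp.name] = counts / bin_vol
    return DensityProfile("axis", edges, densities, bin_vol)


def radial_density_profile(
    state: SimulationState,
    center: np.ndarray,
    n_bins: int = 30,
    r_max: float | None = None,
    species_filter: tuple[BeadSpecies, ...] | None = None,
) -> DensityProfile:
    """Spherical-shell per-species density about a centre inside the box."""
    center = np.asarray(center, dtype=float)
    box = state.box_lengths
    if np.any(center < 0) or np.any(center > box):
        raise ValueError("centre must lie inside the box")
    if r_max is None:
        r_max = float(np.min(box)) / 2.0
    d = state.positions - center[None, :]
    d -= box[None, :] * np.round(d / box[None, :])
    r = np.linalg.norm(d, axis=1)
    edges = np.linspace(0.0, r_max, n_bins + 1)
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    species = species_filter or tuple(BeadSpecies)
    densities = {}
    for sp in species:
        mask = state.species == int(sp)
        counts, _ = np.histogram(r[mask], bins=edges)
        densities[sp.name] = counts / shell_vol
    return DensityProfile("radial", edges, densities, shell_vol)


# ----------------------------------------------------------------------------
# Chains: unwrapping, gyration, shape, order


def unwrap_chain(pos: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Unwrap a bonded chain across periodic images by walking consecutive
    beads with minimum-image displacements (first bead is the anchor)."""
    d = np.diff(pos, axis=0)
    d -= box[None, :] * np.round(d / box[None, :])
    out = np.empty_like(pos)
    out[0] = pos[0]
    out[1:] = pos[0] + np.cumsum(d, axis=0)
    return out


def iter_chains(state: SimulationState):
    """Yield (chain_type, bead_indices) for every lipid chain.

    Chains are contiguous index ranges sharing a molecule id; the type is
    read off the head-bead species.
    """
    molid = state.molecule_id
    lipid = molid >= 0
    if not lipid.any():
        return
    ids = molid[lipid]
    starts = np.flatnonzero(np.diff(ids, prepend=ids[0] - 1) != 0)
    bead_idx = np.flatnonzero(lipid)
    bounds = list(starts) + [len(ids)]
    for a, b in zip(bounds[:-1], bounds[1:]):
        idx = bead_idx[a:b]
        head_sp = int(state.species[idx[0]])
        ctype = "type-I" if head_sp in (int(BeadSpecies.H1), int(BeadSpecies.T1)) else "type-II"
        yield ctype, idx


@dataclass(frozen=True)
class GyrationRecord:
    """Gyration tensor of one chain with its sorted eigenvalues.

    ``tensor`` is the 3x3 second-moment tensor about the chain centre of
    mass; eigenvalues are sorted L1^2 >= L2^2 >= L3^2; the trace equals the
    mean-square radius of gyration.
    """

    tensor: np.ndarray
    eigenvalues: np.ndarray

    @property
    def rg_squared(self) -> float:
        return float(np.trace(self.tensor))

    @property
    def components(self) -> np.ndarray:
        """(Rgxx, Rgyy, Rgzz) — square roots of the diagonal elements."""
        return np.sqrt(np.diag(self.tensor))

    @property
    def delta(self) -> float:
        return shape_factor(self.eigenvalues)


def gyration_tensor(chain_positions: np.ndarray) -> GyrationRecord:
    """Gyration tensor of a chain given its (unwrapped) bead positions."""
    pos = np.asarray(chain_positions, dtype=float)
    if pos.ndim != 2 or pos.shape[0] < 1:
        raise ValueError("need an (n_beads, 3) position array")
    rel = pos - pos.mean(axis=0, keepdims=True)
    tensor = rel.T @ rel / pos.shape[0]
    eig = np.sort(np.linalg.eigvalsh(tensor))[::-1]
    return GyrationRecord(tensor=tensor, eigenvalues=np.clip(eig, 0.0, None))


def shape_factor(eigenvalues: np.ndarray) -> float:
    """Shape factor delta in [0, 1]: 0 for a sphere, 1 for a rod.

    delta = 1 - 3 (L1^2 L2^2 + L2^2 L3^2 + L1^2 L3^2) / (L1^2+L2^2+L3^2)^2
    from the three gyration-tensor eigenvalues.
    """
    l1, l2, l3 = (float(x) for x in eigenvalues)
    s = l1 + l2 + l3
    if s <= 0.0:
        return float("nan")
    return 1.0 - 3.0 * (l1 * l2 + l2 * l3 + l1 * l3) / (s * s)


def chain_shape_stats(state: SimulationState) -> dict[str, dict[str, float]]:
    """Per-type ensemble means of Rg^2, the Rg components and delta."""
    acc: dict[str, list[GyrationRecord]] = {"type-I": [], "type-II": []}
    for ctype, idx in iter_chains(state):
        pos = unwrap_chain(state.positions[idx], state.box_lengths)
        acc[ctype].append(gyration_tensor(pos))
    out = {}
    for ctype, recs in acc.items():
        if not recs:
            continue
        comps = np.array([r.components for r in recs])
        out[ctype] = {
            "rg_squared": float(np.mean([r.rg_squared for r in recs])),
            "rg_xx": float(comps[:, 0].mean()),
            "rg_yy": float(comps[:, 1].mean()),
            "rg_zz": float(comps[:, 2].mean()),
            "delta": float(np.nanmean([r.delta for r in recs])),
            "n_chains": float(len(recs)),
        }
    return out


def order_parameter(
    state: SimulationState,
    sub_chain: str = "head",
    axis: int = 2,
    bin_width: float = 1.0,
    origin: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """P2 = (3 cos^2 theta - 1)/2 of chain segments against a box axis.

    theta is the angle between the end-to-end vector of the selected
    sub-chain ("head", "tail" or "whole") and the axis.  Values are averaged
    per spatial bin of the segment's first bead; returns
    (bin_centers, mean_p2, counts).  Degenerate zero-length vectors are
    skipped but counted in ``counts``'s complement.
    """
    if sub_chain not in ("head", "tail", "whole"):
        raise ValueError("sub_chain must be head, tail or whole")
    L = float(state.box_lengths[axis])
    n_bins = max(int(round(L / bin_width)), 1)
    edges = np.linspace(0.0, L, n_bins + 1)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for _, idx in iter_chains(state):
        sp = state.species[idx]
        if sub_chain == "head":
            sel = idx[np.isin(sp, _HEAD_SPECIES)]
        elif sub_chain == "tail":
            sel = idx[np.isin(sp, _TAIL_SPECIES)]
        else:
            sel = idx
        if len(sel) < 2:
            continue
        pos = unwrap_chain(state.positions[sel], state.box_lengths)
        vec = pos[-1] - pos[0]
        norm = np.linalg.norm(vec)
        if norm < 1e-12:
            continue
        cos = vec[axis] / norm
        p2 = 1.5 * cos * cos - 0.5
        z0 = (state.positions[sel[0], axis] - origin) % L
        b = min(int(z0 / L * n_bins), n_bins - 1)
        sums[b] += p2
        counts[b] += 1
    means = np.divide(sums, counts, out=np.full(n_bins, np.nan), where=counts > 0)
    return 0.5 * (edges[:-1] + edges[1:]), means, counts


# ----------------------------------------------------------------------------
# Leaflets, thickness, pores, classification


@dataclass(frozen=True)
class MixingRecord:
    """Leaflet occupancy of the two lipid types at one time point."""

    time: float
    n_type1_upper: int
    n_type1_lower: int
    n_type2_upper: int
    n_type2_lower: int
    n_unassigned: int = 0


def leaflet_mixing_counts(
    state: SimulationState,
    min_tilt: float = 0.0,
    structure: str | None = None,
) -> MixingRecord:
    """Count chains of each type per leaflet of a (possibly perforated) bilayer.

    A chain is assigned to the upper leaflet when its head beads sit above
    its tail beads (mean head z minus mean tail z of the unwrapped chain
    positive), and to the lower leaflet otherwise; chains lying flatter than
    ``min_tilt`` (e.g. pore-rim chains) are reported as unassigned rather
    than forced into a leaflet.
    """
    if structure == "vesicle":
        raise ValueError(
            "leaflet assignment by z-orientation is undefined for vesicles; "
            "use the radial density profile instead"
        )
    counts = {("type-I", "up"): 0, ("type-I", "dn"): 0,
              ("type-II", "up"): 0, ("type-II", "dn"): 0}
    unassigned = 0
    for ctype, idx in iter_chains(state):
        sp = state.species[idx]
        pos = unwrap_chain(state.positions[idx], state.box_lengths)
        zh = pos[np.isin(sp, _HEAD_SPECIES), 2].mean()
        zt = pos[np.isin(sp, _TAIL_SPECIES), 2].mean()
        dz = zh - zt
        if abs(dz) <= min_tilt:
            unassigned += 1
        elif dz > 0:
            counts[(ctype, "up")] += 1
        else:
            counts[(ctype, "dn")] += 1
    return MixingRecord(
        time=state.time,
        n_type1_upper=counts[("type-I", "up")],
        n_type1_lower=counts[("type-I", "dn")],
        n_type2_upper=counts[("type-II", "up")],
        n_type2_lower=counts[("type-II", "dn")],
        n_unassigned=unassigned,
    )


def membrane_thickness(
    head_profile: DensityProfile | tuple[np.ndarray, np.ndarray],
) -> float:
    """Bilayer thickness: distance between the outermost half-maximum
    crossings of the total head-bead density along the profile axis.

    Accepts a :class:`DensityProfile` (head species are summed) or a raw
    (bin_centers, density) pair.  Returns NaN when no two crossings exist.
    """
    if isinstance(head_profile, DensityProfile):
        z = head_profile.bin_centers
        rho = head_profile.total(
            tuple(k for k in ("H1", "H2") if k in head_profile.densities)
        )
    else:
        z, rho = head_profile
        rho = np.asarray(rho, dtype=float)
    if rho.size < 3 or not np.any(rho > 0):
        return float("nan")
    half = rho.max() / 2.0
    above = rho >= half
    if not above.any():
        return float("nan")
    lo = int(np.argmax(above))
    hi = len(rho) - 1 - int(np.argmax(above[::-1]))
    if hi <= lo:
        return float("nan")
    # sub-bin interpolation of the two outermost crossings
    if lo > 0:
        z_lo = np.interp(half, [rho[lo - 1], rho[lo]], [z[lo - 1], z[lo]])
    else:
        z_lo = z[0]
    if hi < len(rho) - 1:
        z_hi = np.interp(half, [rho[hi + 1], rho[hi]], [z[hi + 1], z[hi]])
    else:
        z_hi = z[-1]
    return float(z_hi - z_lo)


def lipid_midplane(state: SimulationState, axis: int = 2) -> float:
    """Circular mean coordinate of all lipid beads along an axis."""
    lipid = state.molecule_id >= 0
    if not lipid.any():
        return float(state.box_lengths[axis]) / 2.0
    return _circular_mean(state.positions[lipid, axis], float(state.box_lengths[axis]))


def membrane_normal_vector(state: SimulationState) -> np.ndarray:
    """Unit normal of a (possibly tilted) bilayer slab.

    The lipid cloud is centred by the circular mean per axis, displacements
    are taken with the minimum-image convention, and the normal is the
    eigenvector of the smallest eigenvalue of the displacement covariance —
    the direction of tightest confinement.  For a flat membrane this is a
    box axis; an edge-bounded ribbon may assemble tilted, and the
    axis-aligned profile would then overestimate its thickness by the
    secant of the tilt angle.
    """
    lipid = state.molecule_id >= 0
    if not lipid.any():
        return np.array([0.0, 0.0, 1.0])
    box = np.asarray(state.box_lengths, dtype=float)
    center = np.array(
        [_circular_mean(state.positions[lipid, d], box[d]) for d in range(3)]
    )
    d = state.positions[lipid] - center[None, :]
    d -= box[None, :] * np.round(d / box[None, :])
    cov = d.T @ d / d.shape[0]
    w, v = np.linalg.eigh(cov)
    normal = v[:, 0]  # eigh sorts ascending
    # deterministic sign: largest-magnitude component positive
    k = int(np.argmax(np.abs(normal)))
    return normal * np.sign(normal[k])


def membrane_normal(state: SimulationState, grid_spacing: float = 1.0) -> np.ndarray:
    """Unit membrane normal, combining topology and shape information.

    If the tail beads percolate one box plane under periodic connectivity
    (a spanning membrane, pored or not), its normal is topologically pinned
    to the remaining box axis — undulations cannot tilt it — so that axis is
    returned exactly.  Otherwise (edge-bounded ribbons, which are free to
    assemble tilted) the covariance-based normal of
    :func:`membrane_normal_vector` is used.
    """
    box = np.asarray(state.box_lengths, dtype=float)
    tails = np.isin(state.species, _TAIL_SPECIES)
    if not tails.any():
        return np.array([0.0, 0.0, 1.0])
    pos = state.positions[tails]
    spanning = []
    for a in range(3):
        b, c = [d for d in range(3) if d != a]
        nb = max(int(round(box[b] / grid_spacing)), 1)
        nc = max(int(round(box[c] / grid_spacing)), 1)
        ib = (np.mod(pos[:, b], box[b]) / box[b] * nb).astype(int) % nb
        ic = (np.mod(pos[:, c], box[c]) / box[c] * nc).astype(int) % nc
        occ = np.zeros((nb, nc), dtype=bool)
        occ[ib, ic] = True
        wrap_b, wrap_c = _wraps_periodically(occ)
        if wrap_b and wrap_c:
            spanning.append(a)
    if len(spanning) == 1:
        e = np.zeros(3)
        e[spanning[0]] = 1.0
        return e
    if len(spanning) > 1:
        # degenerate (e.g. dense disordered lipid): fall back to the most
        # confined of the candidate axes
        lipid = state.molecule_id >= 0
        spreads = []
        for a in spanning:
            L = box[a]
            ang = state.positions[lipid, a] / L * 2.0 * np.pi
            r = abs(np.exp(1j * ang).mean())
            spreads.append(np.sqrt(-2.0 * np.log(max(r, 1e-12))) * L / (2 * np.pi))
        e = np.zeros(3)
        e[spanning[int(np.argmin(spreads))]] = 1.0
        return e
    return membrane_normal_vector(state)


def projected_head_profile(
    state: SimulationState,
    normal: np.ndarray | None = None,
    bin_width: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Head-bead count profile along the membrane normal direction.

    Beads are measured by the projection of their minimum-image displacement
    from the lipid centre onto ``normal``, so the profile is centred on the
    bilayer and insensitive to drift and tilt.  Returns (bin_centers,
    counts_per_rc); only the half-maximum geometry matters for thickness, so
    no volume normalisation is applied.
    """
    if normal is None:
        normal = membrane_normal_vector(state)
    box = np.asarray(state.box_lengths, dtype=float)
    lipid = state.molecule_id >= 0
    center = np.array(
        [_circular_mean(state.positions[lipid, d], box[d]) for d in range(3)]
    )
    heads = np.isin(state.species, _HEAD_SPECIES)
    d = state.positions[heads] - center[None, :]
    d -= box[None, :] * np.round(d / box[None, :])
    h = d @ np.asarray(normal, dtype=float)
    half = float(np.max(box)) / 2.0
    n_bins = max(int(round(2.0 * half / bin_width)), 2)
    counts, edges = np.histogram(h, bins=n_bins, range=(-half, half))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts / (edges[1] - edges[0])


def order_parameter_normal(
    state: SimulationState,
    normal: np.ndarray | None = None,
    sub_chain: str = "head",
    bin_width: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """P2 of sub-chain end-to-end vectors against the membrane normal vector.

    Like :func:`order_parameter` but with an arbitrary (unit) reference
    direction and bins along the normal projection of each segment's first
    bead relative to the lipid centre.  Returns (bin_centers, mean_p2,
    counts).
    """
    if sub_chain not in ("head", "tail", "whole"):
        raise ValueError("sub_chain must be head, tail or whole")
    if normal is None:
        normal = membrane_normal_vector(state)
    normal = np.asarray(normal, dtype=float)
    box = np.asarray(state.box_lengths, dtype=float)
    lipid = state.molecule_id >= 0
    center = np.array(
        [_circular_mean(state.positions[lipid, d], box[d]) for d in range(3)]
    )
    half = float(np.max(box)) / 2.0
    n_bins = max(int(round(2.0 * half / bin_width)), 1)
    edges = np.linspace(-half, half, n_bins + 1)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for _, idx in iter_chains(state):
        sp = state.species[idx]
        if sub_chain == "head":
            sel = idx[np.isin(sp, _HEAD_SPECIES)]
        elif sub_chain == "tail":
            sel = idx[np.isin(sp, _TAIL_SPECIES)]
        else:
            sel = idx
        if len(sel) < 2:
            continue
        pos = unwrap_chain(state.positions[sel], box)
        vec = pos[-1] - pos[0]
        norm = np.linalg.norm(vec)
        if norm < 1e-12:
            continue
        cos = float(vec @ normal) / norm
        p2 = 1.5 * cos * cos - 0.5
        d0 = state.positions[sel[0]] - center
        d0 -= box * np.round(d0 / box)
        b = min(int((float(d0 @ normal) + half) / (2 * half) * n_bins), n_bins - 1)
        b = max(b, 0)
        sums[b] += p2
        counts[b] += 1
    means = np.divide(sums, counts, out=np.full(n_bins, np.nan), where=counts > 0)
    return 0.5 * (edges[:-1] + edges[1:]), means, counts


def membrane_normal_axis(state: SimulationState) -> int:
    """Detect the membrane normal as the axis of tightest lipid confinement.

    A bilayer (flat sheet or edge-bounded ribbon) concentrates its lipids in
    a thin slab along its normal; the circular (periodic) standard deviation
    of the lipid coordinates is therefore smallest along that axis.  Returns
    0, 1 or 2.
    """
    lipid = state.molecule_id >= 0
    if not lipid.any():
        return 2
    spreads = []
    for d in range(3):
        L = float(state.box_lengths[d])
        ang = state.positions[lipid, d] / L * 2.0 * np.pi
        r = abs(np.exp(1j * ang).mean())
        spreads.append(
            np.sqrt(-2.0 * np.log(max(r, 1e-12))) * L / (2.0 * np.pi)
        )
    return int(np.argmin(spreads))


def _circular_mean(x: np.ndarray, L: float) -> float:
    ang = x / L * 2.0 * np.pi
    return float(np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()) % (2 * np.pi)) * L / (2 * np.pi)


def _periodic_label_2d(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Label a 2D boolean mask with 4-connectivity and periodic wrapping."""
    lab, n = ndimage.label(mask)
    if n == 0:
        return lab, 0
    parent = list(range(n + 1))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for a, b in zip(lab[0, :], lab[-1, :]):
        if a and b:
            union(int(a), int(b))
    for a, b in zip(lab[:, 0], lab[:, -1]):
        if a and b:
            union(int(a), int(b))
    remap = {}
    out = np.zeros_like(lab)
    nxt = 0
    for lbl in range(1, n + 1):
        r = find(lbl)
        if r not in remap:
            nxt += 1
            remap[r] = nxt
    for lbl in range(1, n + 1):
        out[lab == lbl] = remap[find(lbl)]
    return out, nxt


def pore_detect(
    state: SimulationState,
    grid_spacing: float = 1.0,
    slab_half_width: float = 2.5,
    noise_floor_cells: int = 4,
) -> dict:
    """Detect a solvent pore piercing the bilayer core.

    Tail beads within ``slab_half_width`` of the bilayer midplane are
    projected onto an x-y grid; the largest periodically connected empty
    region bigger than the noise floor is the pore.  Returns a dict with
    ``has_pore``, ``diameter`` (2 sqrt(area/pi)), ``area`` and ``centroid``.
    """
    box = state.box_lengths
    tails = np.isin(state.species, _TAIL_SPECIES)
    if not tails.any():
        return {"has_pore": False, "diameter": 0.0, "area": 0.0, "centroid": None}
    zt = state.positions[tails, 2] % box[2]
    z_mid = _circular_mean(zt, box[2])
    dz = zt - z_mid
    dz -= box[2] * np.round(dz / box[2])
    in_slab = np.abs(dz) <= slab_half_width
    xy = state.positions[tails][in_slab][:, :2]
    nx = max(int(round(box[0] / grid_spacing)), 1)
    ny = max(int(round(box[1] / grid_spacing)), 1)
    ix = (np.mod(xy[:, 0], box[0]) / box[0] * nx).astype(int) % nx
    iy = (np.mod(xy[:, 1], box[1]) / box[1] * ny).astype(int) % ny
    occ = np.zeros((nx, ny), dtype=bool)
    occ[ix, iy] = True
    # close single-cell sampling voids (thermal roughness / sparse columns)
    # with a periodic 3x3 morphological closing; a genuine pore is far wider
    padded = np.pad(occ, 1, mode="wrap")
    occ = ndimage.binary_closing(padded, structure=np.ones((3, 3)))[1:-1, 1:-1]
    lab, n = _periodic_label_2d(~occ)
    cell_area = (box[0] / nx) * (box[1] / ny)
    best = 0
    best_lbl = 0
    for lbl in range(1, n + 1):
        sz = int((lab == lbl).sum())
        if sz > best:
            best, best_lbl = sz, lbl
    if best < noise_floor_cells:
        return {"has_pore": False, "diameter": 0.0, "area": 0.0, "centroid": None}
    area = best * cell_area
    cells = np.argwhere(lab == best_lbl)
    cx = _circular_mean((cells[:, 0] + 0.5) * box[0] / nx, box[0])
    cy = _circular_mean((cells[:, 1] + 0.5) * box[1] / ny, box[1])
    return {
        "has_pore": True,
        "diameter": float(2.0 * math.sqrt(area / math.pi)),
        "area": float(area),
        "centroid": (float(cx), float(cy)),
    }


def _wraps_periodically(mask2d: np.ndarray) -> tuple[bool, bool]:
    """Does any connected component of the 2D mask wrap around x / y?"""
    nx, ny = mask2d.shape
    tiled = np.tile(mask2d, (2, 2))
    lab, n = ndimage.label(tiled)
    wrap_x = wrap_y = False
    for lbl in range(1, n + 1):
        xs, ys = np.nonzero(lab == lbl)
        if xs.max() - xs.min() + 1 > nx:
            wrap_x = True
        if ys.max() - ys.min() + 1 > ny:
            wrap_y = True
        if wrap_x and wrap_y:
            break
    return wrap_x, wrap_y


def classify_structure(
    state: SimulationState,
    grid_spacing: float = 1.0,
) -> str:
    """Classify a frame as membrane / perforated_membrane / vesicle / other.

    A lipid aggregate that percolates the x-y plane (periodic connectivity of
    tail-bead occupancy) is a membrane, perforated if the bilayer core holds
    a solvent pore.  A non-spanning aggregate enclosing an interior water
    pocket (disconnected from the exterior on a coarse grid) is a vesicle.
    """
    box = state.box_lengths
    lipid = state.molecule_id >= 0
    if not lipid.any():
        return "other"
    tails = np.isin(state.species, _TAIL_SPECIES)
    nx = max(int(round(box[0] / grid_spacing)), 1)
    ny = max(int(round(box[1] / grid_spacing)), 1)
    xy = state.positions[tails][:, :2]
    ix = (np.mod(xy[:, 0], box[0]) / box[0] * nx).astype(int) % nx
    iy = (np.mod(xy[:, 1], box[1]) / box[1] * ny).astype(int) % ny
    occ2d = np.zeros((nx, ny), dtype=bool)
    occ2d[ix, iy] = True
    wrap_x, wrap_y = _wraps_periodically(occ2d)
    if wrap_x and wrap_y:
        pore = pore_detect(state, grid_spacing=grid_spacing)
        return "perforated_membrane" if pore["has_pore"] else "membrane"
    # vesicle test: lipid-free 3D cells split into exterior + enclosed interior
    nz = max(int(round(box[2] / grid_spacing)), 1)
    p = state.positions[lipid]
    i3 = (np.mod(p, box[None, :]) / box[None, :] * [nx, ny, nz]).astype(int)
    i3 = np.minimum(i3, [nx - 1, ny - 1, nz - 1])
    occ3d = np.zeros((nx, ny, nz), dtype=bool)
    occ3d[i3[:, 0], i3[:, 1], i3[:, 2]] = True
    # beads interact over ~1 rc: close single-cell gaps in the shell so a
    # sparsely sampled but physically tight bilayer still encloses its cavity
    padded = np.pad(occ3d, 1, mode="wrap")
    occ3d = ndimage.binary_closing(padded, structure=np.ones((3, 3, 3)))[
        1:-1, 1:-1, 1:-1
    ]
    lab, n = ndimage.label(~occ3d)
    if n >= 2:
        water = state.species == int(BeadSpecies.W)
        pw = state.positions[water]
        iw = (np.mod(pw, box[None, :]) / box[None, :] * [nx, ny, nz]).astype(int)
        iw = np.minimum(iw, [nx - 1, ny - 1, nz - 1])
        for lbl in range(1, n + 1):
            comp = lab == lbl
            touches = (
                comp[0, :, :].any() or comp[-1, :, :].any()
                or comp[:, 0, :].any() or comp[:, -1, :].any()
                or comp[:, :, 0].any() or comp[:, :, -1].any()
            )
            if not touches and comp[iw[:, 0], iw[:, 1], iw[:, 2]].any():
                return "vesicle"
    return "other"


# ----------------------------------------------------------------------------
# Stage segmentation of observable time series


@dataclass(frozen=True)
class StageSegmentation:
    """Three-stage split of a run: initial / adjustment / stable.

    Boundaries are in the time units of the input series; ``stage_means``
    holds the mean of the raw observable within each stage.
    """

    t_initial_end: float
    t_adjust_end: float
    stage_means: tuple[float, float, float]
    degenerate: bool = False

    def stage_of(self, t: np.ndarray) -> np.ndarray:
        """0/1/2 stage index for each time in ``t``."""
        t = np.asarray(t, dtype=float)
        return np.where(t <= self.t_initial_end, 0, np.where(t <= self.t_adjust_end, 1, 2))


def stage_segmentation(
    times: np.ndarray,
    values: np.ndarray,
    smooth_window: int = 50,
    min_segment: int | None = None,
) -> StageSegmentation:
    """Two-change-point fit of an observable series into three stages.

    The series is smoothed with a moving average, then the pair of break
    positions minimising the within-segment sum of squares is found
    exhaustively (prefix sums, O(n^2)).  A series whose best split explains
    almost none of the variance is flagged degenerate and split at thirds.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 3 or len(t) != n:
        raise ValueError("need at least 3 samples with matching times")
    w = max(1, min(smooth_window, n // 6))
    sm = ndimage.uniform_filter1d(v, size=w, mode="nearest")
    if min_segment is None:
        # every stage covers at least a tenth of the run: keeps the stable
        # window long enough for ensemble averaging
        min_segment = max(2, n // 10)
    c1 = np.concatenate([[0.0], np.cumsum(sm)])
    c2 = np.concatenate([[0.0], np.cumsum(sm * sm)])

    def sse(a: int, b: int) -> float:
        # sum of squares of sm[a:b] about its mean
        m = b - a
        s = c1[b] - c1[a]
        return (c2[b] - c2[a]) - s * s / m

    best = math.inf
    bi = bj = -1
    for i in range(min_segment, n - 2 * min_segment + 1):
        left = sse(0, i)
        for j in range(i + min_segment, n - min_segment + 1):
            tot = left + sse(i, j) + sse(j, n)
            if tot < best:
                best = tot
                bi, bj = i, j
    total_var = sse(0, n)
    degenerate = bi < 0 or total_var < 1e-12 or (total_var - best) < 1e-3 * total_var
    if degenerate:
        bi, bj = n // 3, 2 * n // 3
    means = (
        float(v[:bi].mean()),
        float(v[bi:bj].mean()),
        float(v[bj:].mean()),
    )
    return StageSegmentation(
        t_initial_end=float(t[bi - 1]),
        t_adjust_end=float(t[bj - 1]),
        stage_means=means,
        degenerate=degenerate,
    )


def phase_point(
    final_state: SimulationState,
    energy_times: np.ndarray | None = None,
    energy_values: np.ndarray | None = None,
) -> dict:
    """Classify the final frame of a run and bundle its structure metrics.

    Returns a dict with the phase ``label`` plus thickness / pore metrics
    where applicable; an unclassifiable frame is labelled "other" with the
    diagnostics attached.
    """
    label = classify_structure(final_state)
    out: dict = {"label": label}
    if label in ("membrane", "perforated_membrane"):
        prof = density_profile(
            final_state, axis=2, n_bins=int(round(final_state.box_lengths[2] / 0.5)),
            species_filter=(BeadSpecies.H1, BeadSpecies.H2),
        )
        out["thickness"] = membrane_thickness(prof)
        pore = pore_detect(final_state)
        out["pore"] = pore
    if energy_times is not None and energy_values is not None and len(energy_values) >= 3:
        seg = stage_segmentation(energy_times, energy_values)
        out["stages"] = {
            "t_initial_end": seg.t_initial_end,
            "t_adjust_end": seg.t_adjust_end,
            "stage_means": list(seg.stage_means),
            "degenerate": seg.degenerate,
        }
    return out
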