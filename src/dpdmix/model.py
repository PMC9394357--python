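"""Species, lipid topologies, composition bookkeeping and interaction parameters.

The model describes a binary mixture of coarse-grained single-tail lipids in
water.  Each lipid is a linear chain of one hydrophilic head block (H beads)
followed by one hydrophobic tail block (T beads); water is a single W bead.
Five bead species exist: ``H1``/``T1`` for type-I lipids, ``H2``/``T2`` for
type-II, and ``W``.  All quantities are in reduced DPD units (bead mass m = 1,
cutoff rc = 1, thermal energy kBT = 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "BeadSpecies",
    "LipidTopology",
    "SystemComposition",
    "InteractionModel",
    "BondedParams",
    "build_topology",
    "water_bead_count",
    "lipid_bead_count",
    "flory_chi",
    "default_interaction_matrix",
    "default_bonded_params",
    "load_config",
    "save_config",
    "default_config_path",
    "RC_NANOMETERS",
    "TAU_NANOSECONDS",
]

# Physical-unit mapping, metadata only: all computation is in reduced units.
RC_NANOMETERS = 0.5
TAU_NANOSECONDS = 1.88


class BeadSpecies(IntEnum):
    """The five bead species of the binary lipid/water mixture."""

    H1 = 0
    T1 = 1
    H2 = 2
    T2 = 3
    W = 4


#: Flory-Huggins mapping slope for excess DPD repulsion at bead density 3.
CHI_PER_DELTA_A = 0.286


@dataclass(frozen=True)
class LipidTopology:
    """Bead/bond/angle graph of one linear lipid chain (head block then tail)."""

    lipid_type: str  # "type-I" | "type-II"
    n_head: int
    n_tail: int
    bead_species: tuple[BeadSpecies, ...]
    bonds: tuple[tuple[int, int], ...]
    angles: tuple[tuple[int, int, int], ...]

    @property
    def n_beads(self) -> int:
        return self.n_head + self.n_tail


def build_topology(lipid_type: str, n_head: int, n_tail: int) -> LipidTopology:
    """Build the linear-chain topology of a single-head/single-tail lipid.

    Head beads occupy indices ``0 .. n_head-1``, tail beads follow.  Bonds
    connect every consecutive bead pair (including the head-tail junction);
    angles cover every consecutive bead triple, so a chain of ``L`` beads has
    ``L-1`` bonds and ``L-2`` angles.
    """
    if n_head < 1 or n_tail < 1:
        raise ValueError(
            f"head and tail block need at least one bead each, "
            f"got n_head={n_head}, n_tail={n_tail}"
        )
    if lipid_type not in ("type-I", "type-II"):
        raise ValueError(f"unknown lipid type {lipid_type!r}")
    head = BeadSpecies.H1 if lipid_type == "type-I" else BeadSpecies.H2
    tail = BeadSpecies.T1 if lipid_type == "type-I" else BeadSpecies.T2
    species = (head,) * n_head + (tail,) * n_tail
    n = n_head + n_tail
    bonds = tuple((i, i + 1) for i in range(n - 1))
    angles = tuple((i, i + 1, i + 2) for i in range(n - 2))
    return LipidTopology(lipid_type, n_head, n_tail, species, bonds, angles)


def lipid_bead_count(n_chains: int, n_head: int, n_tail: int) -> int:
    """Total bead count contributed by ``n_chains`` identical lipid chains."""
    if min(n_chains, n_head, n_tail) < 0:
        raise ValueError("counts must be non-negative")
    return n_chains * (n_head + n_tail)


def water_bead_count(
    n_total: int,
    n1: int,
    n2: int,
    nh1: int,
    nt1: int,
    nh2: int,
    nt2: int,
) -> int:
    """Water beads needed to close the composition N = n1·L1 + n2·L2 + NW.

    The total bead count N is held fixed while the tail lengths vary, so the
    water count is the dependent variable of the composition.
    """
    nw = n_total - n1 * (nh1 + nt1) - n2 * (nh2 + nt2)
    if nw < 0:
        raise ValueError(
            f"composition infeasible: lipids need {n_total - nw} beads "
            f"but the system holds only {n_total}"
        )
    return nw


@dataclass(frozen=True)
class SystemComposition:
    """Bead bookkeeping for a two-lipid/water box.

    Invariant: ``n_total == n1*topology1.n_beads + n2*topology2.n_beads + n_water``
    and ``n_total ≈ density * box volume`` (sub-bead rounding absorbed into
    the water count).
    """

    n1: int
    n2: int
    topology1: LipidTopology
    topology2: LipidTopology
    n_water: int
    box_lengths: tuple[float, float, float]
    density: float = 3.0

    @property
    def n_total(self) -> int:
        return (
            self.n1 * self.topology1.n_beads
            + self.n2 * self.topology2.n_beads
            + self.n_water
        )

    @property
    def volume(self) -> float:
        lx, ly, lz = self.box_lengths
        return lx * ly * lz

    @classmethod
    def from_box(
        cls,
        n1: int,
        n2: int,
        topology1: LipidTopology,
        topology2: LipidTopology,
        box_lengths: tuple[float, float, float],
        density: float = 3.0,
    ) -> "SystemComposition":
        """Fill the box to the target bead density; water is the closure."""
        lx, ly, lz = box_lengths
        n_total = int(round(density * lx * ly * lz))
        nw = water_bead_count(
            n_total,
            n1,
            n2,
            topology1.n_head,
            topology1.n_tail,
            topology2.n_head,
            topology2.n_tail,
        )
        return cls(n1, n2, topology1, topology2, nw, (lx, ly, lz), density)

    def species_counts(self) -> dict[BeadSpecies, int]:
        return {
            BeadSpecies.H1: self.n1 * self.topology1.n_head,
            BeadSpecies.T1: self.n1 * self.topology1.n_tail,
            BeadSpecies.H2: self.n2 * self.topology2.n_head,
            BeadSpecies.T2: self.n2 * self.topology2.n_tail,
            BeadSpecies.W: self.n_water,
        }

    def chain_slices(self) -> list[tuple[str, slice]]:
        """Contiguous bead-index ranges of every chain, type-I first.

        The builders lay beads out in this canonical order: all type-I chains,
        then all type-II chains, then water.
        """
        out: list[tuple[str, slice]] = []
        off = 0
        for _ in range(self.n1):
            out.append(("type-I", slice(off, off + self.topology1.n_beads)))
            off += self.topology1.n_beads
        for _ in range(self.n2):
            out.append(("type-II", slice(off, off + self.topology2.n_beads)))
            off += self.topology2.n_beads
        return out

    def bead_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Per-bead species, molecule id, bond list and angle list.

        Water beads get molecule id -1.  Returns ``(species, molecule_id,
        bonds, angles)`` with bonds ``(nb, 2)`` and angles ``(na, 3)`` as
        global bead indices.
        """
        species = np.empty(self.n_total, dtype=np.int8)
        molid = np.full(self.n_total, -1, dtype=np.int32)
        bonds: list[tuple[int, int]] = []
        angles: list[tuple[int, int, int]] = []
        off = 0
        mol = 0
        for n_chains, topo in ((self.n1, self.topology1), (self.n2, self.topology2)):
            spec = np.array([int(s) for s in topo.bead_species], dtype=np.int8)
            for _ in range(n_chains):
                species[off : off + topo.n_beads] = spec
                molid[off : off + topo.n_beads] = mol
                bonds.extend((off + i, off + j) for i, j in topo.bonds)
                angles.extend((off + i, off + j, off + k) for i, j, k in topo.angles)
                off += topo.n_beads
                mol += 1
        species[off:] = int(BeadSpecies.W)
        bond_arr = np.array(bonds, dtype=np.int64).reshape(-1, 2)
        angle_arr = np.array(angles, dtype=np.int64).reshape(-1, 3)
        return species, molid, bond_arr, angle_arr


@dataclass(frozen=True)
class InteractionModel:
    """DPD pair-interaction parameters.

    ``a`` is the symmetric 5x5 maximum-repulsion matrix (kBT/rc) indexed by
    :class:`BeadSpecies`; ``gamma`` and ``sigma`` are the dissipative and
    random-force amplitudes tied by the fluctuation-dissipation relation
    sigma^2 = 2*gamma*kBT.
    """

    a: np.ndarray
    gamma: float = 4.5
    sigma: float = 3.0
    rc: float = 1.0
    kBT: float = 1.0

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        if a.shape != (5, 5):
            raise ValueError("repulsion matrix must be 5x5")
        if not np.allclose(a, a.T):
            raise ValueError("repulsion matrix must be symmetric")
        object.__setattr__(self, "a", a)

    def fluctuation_dissipation_residual(self) -> float:
        return self.sigma**2 - 2.0 * self.gamma * self.kBT


def default_interaction_matrix() -> InteractionModel:
    """Default interaction parameters of the binary lipid/water model.

    Like beads repel with a = 25; unlike beads with a = 100, except that
    heads of either lipid are compatible with water and with each other
    (a = 25), which is what makes the heads hydrophilic and the tails
    hydrophobic.
    """
    S = BeadSpecies
    a = np.full((5, 5), 100.0)
    np.fill_diagonal(a, 25.0)
    for x, y in ((S.H1, S.W), (S.H2, S.W), (S.H1, S.H2)):
        a[x, y] = a[y, x] = 25.0
    return InteractionModel(a=a, gamma=4.5, sigma=3.0, rc=1.0, kBT=1.0)


@dataclass(frozen=True)
class BondedParams:
    """Harmonic bond + angle-bending parameters of the lipid chains.

    The bond force is ks*(1 - r/rs) along the bond; the bending potential is
    k_theta*(theta - theta0)^2 with theta the angle between the two bond
    vectors seen from the middle bead, so a straight chain has theta = pi.
    """

    ks: float = 120.0
    rs: float = 0.7
    k_theta: float = 6.0
    theta0: float = np.pi

    def __post_init__(self) -> None:
        if self.ks <= 0 or not (0 < self.rs):
            raise ValueError("ks must be positive and rs in (0, rc scale)")
        if not (0 < self.theta0 <= np.pi):
            raise ValueError("theta0 must lie in (0, pi]")


def default_bonded_params() -> BondedParams:
    return BondedParams()


def flory_chi(a_ij: float, a_ii: float) -> float:
    """Flory-Huggins chi mapped linearly from the excess DPD repulsion.

    chi = 0.286 * (a_ij - a_ii) at bead density 3; with a_ij = 100 and
    a_ii = 25 this gives chi ≈ 21.45, deep in the strongly segregated regime.
    """
    return CHI_PER_DELTA_A * (a_ij - a_ii)


# ----------------------------------------------------------------------------
# Plain-text configuration (YAML key-value schema, see docs/methods.md)

def _interaction_to_dict(im: InteractionModel) -> dict:
    names = [s.name for s in BeadSpecies]
    return {
        "a": {
            f"{names[i]}-{names[j]}": float(im.a[i, j])
            for i in range(5)
            for j in range(i, 5)
        },
        "gamma": im.gamma,
        "sigma": im.sigma,
        "rc": im.rc,
        "kBT": im.kBT,
    }


def _interaction_from_dict(d: dict) -> InteractionModel:
    base = default_interaction_matrix()
    a = base.a.copy()
    idx = {s.name: int(s) for s in BeadSpecies}
    for key, val in d.get("a", {}).items():
        x, y = key.split("-")
        a[idx[x], idx[y]] = a[idx[y], idx[x]] = float(val)
    return InteractionModel(
        a=a,
        gamma=float(d.get("gamma", base.gamma)),
        sigma=float(d.get("sigma", base.sigma)),
        rc=float(d.get("rc", base.rc)),
        kBT=float(d.get("kBT", base.kBT)),
    )


def save_config(
    path: str | Path,
    composition: SystemComposition,
    interaction: InteractionModel | None = None,
    bonded: BondedParams | None = None,
    extra: dict | None = None,
) -> None:
    """Serialize composition + parameters to a plain-text YAML config."""
    interaction = interaction or default_interaction_matrix()
    bonded = bonded or default_bonded_params()
    doc = {
        "composition": {
            "n1": composition.n1,
            "n2": composition.n2,
            "n_head1": composition.topology1.n_head,
            "n_tail1": composition.topology1.n_tail,
            "n_head2": composition.topology2.n_head,
            "n_tail2": composition.topology2.n_tail,
            "n_water": composition.n_water,
            "box_lengths": list(composition.box_lengths),
            "density": composition.density,
        },
        "interaction": _interaction_to_dict(interaction),
        "bonded": {
            "ks": bonded.ks,
            "rs": bonded.rs,
            "k_theta": bonded.k_theta,
            "theta0": float(bonded.theta0),
        },
        "units": {"rc_nm": RC_NANOMETERS, "tau_ns": TAU_NANOSECONDS},
    }
    if extra:
        doc.update(extra)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def default_config_path() -> Path:
    """Path of the packaged default config (full-scale composition, default
    interaction matrix and bonded parameters)."""
    return Path(__file__).parent / "data" / "default_config.yaml"


def load_config(
    path: str | Path,
) -> tuple[SystemComposition, InteractionModel, BondedParams, dict]:
    """Read a config written by :func:`save_config`; returns leftovers too."""
    doc = yaml.safe_load(Path(path).read_text())
    c = doc["composition"]
    topo1 = build_topology("type-I", int(c["n_head1"]), int(c["n_tail1"]))
    topo2 = build_topology("type-II", int(c["n_head2"]), int(c["n_tail2"]))
    comp = SystemComposition(
        n1=int(c["n1"]),
        n2=int(c["n2"]),
        topology1=topo1,
        topology2=topo2,
        n_water=int(c["n_water"]),
        box_lengths=tuple(float(x) for x in c["box_lengths"]),
        density=float(c.get("density", 3.0)),
    )
    interaction = _interaction_from_dict(doc.get("interaction", {}))
    b = doc.get("bonded", {})
    bonded = BondedParams(
        ks=float(b.get("ks", 120.0)),
        rs=float(b.get("rs", 0.7)),
        k_theta=float(b.get("k_theta", 6.0)),
        theta0=float(b.get("theta0", np.pi)),
    )
    leftovers = {
        k: v
        for k, v in doc.items()
        if k not in ("composition", "interaction", "bonded", "units")
    }
    return comp, interaction, bonded, leftovers
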