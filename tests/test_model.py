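"""Model layer: topologies, composition bookkeeping, interactions, chi mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dpdmix.model import (
    BeadSpecies,
    BondedParams,
    SystemComposition,
    build_topology,
    default_config_path,
    default_interaction_matrix,
    flory_chi,
    lipid_bead_count,
    load_config,
    save_config,
    water_bead_count,
)


@pytest.mark.parametrize(
    "n_head, n_tail, n_beads, n_bonds, n_angles",
    [(3, 2, 5, 4, 3), (3, 9, 12, 11, 10), (1, 1, 2, 1, 0)],
)
def test_topology_is_a_linear_chain(n_head, n_tail, n_beads, n_bonds, n_angles):
    topo = build_topology("type-I", n_head, n_tail)
    assert topo.n_beads == n_beads
    assert len(topo.bonds) == n_bonds
    assert len(topo.angles) == n_angles
    assert topo.bonds == tuple((i, i + 1) for i in range(n_beads - 1))
    # head block first, then tail block
    assert all(s == BeadSpecies.H1 for s in topo.bead_species[:n_head])
    assert all(s == BeadSpecies.T1 for s in topo.bead_species[n_head:])


def test_topology_rejects_empty_blocks():
    with pytest.raises(ValueError):
        build_topology("type-I", 0, 5)
    with pytest.raises(ValueError):
        build_topology("type-II", 3, 0)


@pytest.mark.parametrize(
    "args, expected",
    [
        ((81000, 900, 900, 3, 2, 3, 2), 72000),
        ((81000, 900, 900, 3, 9, 3, 9), 59400),
        ((10, 1, 1, 3, 2, 3, 2), 0),
    ],
)
def test_water_bead_count_closes_composition(args, expected):
    assert water_bead_count(*args) == expected


def test_water_bead_count_rejects_infeasible():
    with pytest.raises(ValueError):
        water_bead_count(100, 900, 900, 3, 9, 3, 9)


@pytest.mark.parametrize(
    "args, expected",
    [((900, 3, 2), 4500), ((0, 3, 9), 0), ((900, 3, 9), 10800)],
)
def test_lipid_bead_count(args, expected):
    assert lipid_bead_count(*args) == expected


@pytest.mark.parametrize(
    "a_ij, a_ii, chi",
    [(100.0, 25.0, 21.45), (25.0, 25.0, 0.0), (50.0, 25.0, 7.15)],
)
def test_flory_chi_mapping(a_ij, a_ii, chi):
    assert flory_chi(a_ij, a_ii) == pytest.approx(chi, abs=1e-12)


def test_default_interaction_matrix_values():
    im = default_interaction_matrix()
    S = BeadSpecies
    assert np.allclose(np.diag(im.a), 25.0)
    assert np.allclose(im.a, im.a.T)
    # heads are water-compatible, tails are not
    assert im.a[S.H1, S.W] == 25.0
    assert im.a[S.H2, S.W] == 25.0
    assert im.a[S.H1, S.H2] == 25.0
    assert im.a[S.T1, S.W] == 100.0
    assert im.a[S.T2, S.W] == 100.0
    assert im.a[S.T2, S.T1] == 100.0
    for head in (S.H1, S.H2):
        for tail in (S.T1, S.T2):
            assert im.a[head, tail] == 100.0
    # fluctuation-dissipation contract sigma^2 = 2 gamma kBT
    assert im.fluctuation_dissipation_residual() == pytest.approx(0.0)
    assert im.sigma == 3.0 and im.gamma == 4.5


def test_bonded_defaults_and_validation():
    bp = BondedParams()
    assert (bp.ks, bp.rs, bp.k_theta) == (120.0, 0.7, 6.0)
    assert bp.theta0 == pytest.approx(np.pi)
    with pytest.raises(ValueError):
        BondedParams(ks=-1.0)
    with pytest.raises(ValueError):
        BondedParams(theta0=0.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    n1=st.integers(0, 50),
    n2=st.integers(0, 50),
    nt1=st.integers(1, 10),
    nt2=st.integers(1, 10),
    L=st.floats(6.0, 20.0),
)
def test_composition_closure(n1, n2, nt1, nt2, L):
    """Re-summing species counts always reproduces the total bead count."""
    topo1 = build_topology("type-I", 3, nt1)
    topo2 = build_topology("type-II", 3, nt2)
    n_total = int(round(3.0 * L * L * L))
    lipid = n1 * topo1.n_beads + n2 * topo2.n_beads
    if lipid > n_total:
        return
    comp = SystemComposition.from_box(n1, n2, topo1, topo2, (L, L, L))
    assert sum(comp.species_counts().values()) == comp.n_total
    assert comp.n_total == n_total
    species, molid, bonds, angles = comp.bead_arrays()
    counts = comp.species_counts()
    for sp in BeadSpecies:
        assert int(np.sum(species == int(sp))) == counts[sp]
    assert bonds.shape[0] == n1 * len(topo1.bonds) + n2 * len(topo2.bonds)
    assert angles.shape[0] == n1 * len(topo1.angles) + n2 * len(topo2.angles)
    assert int(np.sum(molid < 0)) == comp.n_water


def test_packaged_default_config_is_the_full_scale_box():
    comp, im, bp, _ = load_config(default_config_path())
    assert comp.n_total == 81_000
    assert (comp.n1, comp.n2) == (900, 900)
    assert comp.box_lengths == (30.0, 30.0, 30.0)
    assert np.allclose(im.a, default_interaction_matrix().a)
    assert (bp.ks, bp.rs, bp.k_theta) == (120.0, 0.7, 6.0)


def test_config_roundtrip(tmp_path):
    comp = SystemComposition.from_box(
        10, 12,
        build_topology("type-I", 3, 5),
        build_topology("type-II", 3, 6),
        (10.0, 10.0, 12.0),
    )
    path = tmp_path / "config.yaml"
    save_config(path, comp)
    comp2, im, bp, _ = load_config(path)
    assert comp2 == comp
    assert np.allclose(im.a, default_interaction_matrix().a)
    assert bp.rs == 0.7
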