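"""Structure analytics: profiles, order, gyration, leaflets, pores, stages."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from dpdmix import analysis
from dpdmix.analysis import (
    classify_structure,
    density_profile,
    gyration_tensor,
    leaflet_mixing_counts,
    membrane_thickness,
    order_parameter,
    radial_density_profile,
    shape_factor,
    stage_segmentation,
    unwrap_chain,
)
from dpdmix.engine import SimulationState
from dpdmix.initconf import layered_bilayer_init
from conftest import NO_ANGLES, NO_BONDS, make_water_state, small_composition


def _chain_state(chains, box, types=None):
    """Build a minimal state from a list of (n_beads, 3) chain positions.

    All chains get 3 head + rest tail beads of type-I unless ``types`` gives
    per-chain "type-I"/"type-II" labels.
    """
    box = np.asarray(box, dtype=float)
    pos, species, molid = [], [], []
    for m, chain in enumerate(chains):
        chain = np.asarray(chain, dtype=float)
        nh = min(3, len(chain) - 1) if len(chain) > 1 else 1
        t = (types or ["type-I"] * len(chains))[m]
        head, tail = (0, 1) if t == "type-I" else (2, 3)
        species.extend([head] * nh + [tail] * (len(chain) - nh))
        molid.extend([m] * len(chain))
        pos.append(chain)
    pos = np.vstack(pos)
    n = len(pos)
    return SimulationState(
        positions=np.mod(pos, box),
        velocities=np.zeros((n, 3)),
        forces=np.zeros((n, 3)),
        species=np.array(species, dtype=np.int8),
        molecule_id=np.array(molid, dtype=np.int32),
        bonds=NO_BONDS,
        angles=NO_ANGLES,
        box_lengths=box,
    )


# ----------------------------------------------------------------------------
# density profiles


def test_density_profile_conserves_and_is_flat_for_uniform_water():
    state = make_water_state(6000, (10.0, 10.0, 20.0), seed=1)
    prof = density_profile(state, axis=2, n_bins=40)
    total = prof.total()
    # conservation: densities integrate back to the bead count exactly
    assert np.sum(total * prof.bin_volumes) == pytest.approx(6000.0)
    # flat within Poisson noise (~sqrt(150)/150 per bin)
    assert total.std() / total.mean() < 0.2


def test_density_profile_of_layered_init_shows_head_peaks():
    comp = small_composition()
    state = layered_bilayer_init(comp, seed=0)
    prof = density_profile(state, axis=2, n_bins=32)
    heads = prof.total(("H1", "H2"))
    tails = prof.total(("T1", "T2"))
    z = prof.bin_centers
    mid = state.box_lengths[2] / 2
    # tail mass is centred on the midplane, heads on both sides of it
    z_tail = np.sum(z * tails) / tails.sum()
    assert abs(z_tail - mid) < 1.0
    head_peaks = z[heads > 0.5 * heads.max()]
    assert head_peaks.min() < mid - 1.0 and head_peaks.max() > mid + 1.0


def test_radial_profile_shells_partition_the_sphere():
    state = make_water_state(8000, (12.0, 12.0, 12.0), seed=2)
    prof = radial_density_profile(state, center=np.array([6.0, 6.0, 6.0]), n_bins=12)
    r_max = prof.bin_edges[-1]
    assert prof.bin_volumes.sum() == pytest.approx(4 / 3 * np.pi * r_max**3)
    rho = prof.total(("W",))
    assert rho[2:].std() / rho[2:].mean() < 0.25  # flat away from tiny shells


# ----------------------------------------------------------------------------
# order parameter


def test_order_parameter_limits():
    box = (10.0, 10.0, 10.0)
    along_z = [[(1.0, 1.0, 2.0 + 0.5 * k) for k in range(5)]]
    _, p2, _ = order_parameter(_chain_state(along_z, box), "whole")
    assert np.nanmax(p2) == pytest.approx(1.0)
    in_plane = [[(1.0 + 0.5 * k, 1.0, 2.0) for k in range(5)]]
    _, p2, _ = order_parameter(_chain_state(in_plane, box), "whole")
    assert np.nanmin(p2) == pytest.approx(-0.5)


def test_order_parameter_isotropic_mean_is_zero():
    """Monte-Carlo oracle: random orientations average to P2 = 0."""
    rng = np.random.default_rng(42)
    chains = []
    for _ in range(4000):
        start = rng.uniform(2, 8, 3)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        chains.append([start, start + u])
    state = _chain_state(chains, (10.0, 10.0, 10.0))
    _, p2, counts = order_parameter(state, "whole", bin_width=10.0)
    mean = np.nansum(p2 * counts) / counts.sum()
    assert mean == pytest.approx(0.0, abs=3.0 / np.sqrt(4000))


def test_order_parameter_selects_sub_chain():
    # head triple along z, tail segment in-plane
    chain = [
        (1, 1, 5.0), (1, 1, 4.5), (1, 1, 4.0),
        (1.5, 1, 4.0), (2.0, 1, 4.0),
    ]
    state = _chain_state([chain], (10.0, 10.0, 10.0))
    _, p2h, _ = order_parameter(state, "head")
    _, p2t, _ = order_parameter(state, "tail")
    assert np.nanmax(p2h) == pytest.approx(1.0)
    assert np.nanmin(p2t) == pytest.approx(-0.5)


# ----------------------------------------------------------------------------
# gyration and shape


def test_gyration_tensor_simple_cases():
    rec = gyration_tensor(np.array([[-0.5, 0, 0], [0.5, 0, 0]]))
    assert rec.tensor[0, 0] == pytest.approx(0.25)
    assert np.allclose(rec.tensor.flat[1:], 0.0)
    assert gyration_tensor(np.array([[1.0, 2.0, 3.0]])).rg_squared == 0.0


def test_gyration_tensor_matches_double_loop_oracle():
    """Trace equals the pair-sum form Rg^2 = (1/2N^2) sum_ij (ri - rj)^2."""
    rng = np.random.default_rng(3)
    for n in (2, 5, 12, 20):
        pos = rng.normal(size=(n, 3))
        rec = gyration_tensor(pos)
        acc = 0.0
        for i in range(n):
            for j in range(n):
                acc += np.sum((pos[i] - pos[j]) ** 2)
        assert rec.rg_squared == pytest.approx(acc / (2 * n * n))
        assert rec.eigenvalues[0] >= rec.eigenvalues[1] >= rec.eigenvalues[2] >= 0


@pytest.mark.parametrize(
    "eigs, delta",
    [((4.0, 0.0, 0.0), 1.0), ((2.0, 2.0, 2.0), 0.0), ((2.0, 1.0, 1.0), 1.0 / 16.0)],
)
def test_shape_factor_reference_values(eigs, delta):
    assert shape_factor(np.array(eigs)) == pytest.approx(delta)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.tuples(*[st.floats(0.0, 1e3)] * 3).filter(lambda e: sum(e) > 1e-9))
def test_shape_factor_bounds(eigs):
    d = shape_factor(np.array(sorted(eigs, reverse=True)))
    assert -1e-12 <= d <= 1.0 + 1e-12


def test_unwrap_chain_across_boundary():
    box = np.array([10.0, 10.0, 10.0])
    pos = np.array([[9.8, 5, 5], [0.2, 5, 5], [0.6, 5, 5]])
    un = unwrap_chain(pos, box)
    assert np.allclose(un[:, 0], [9.8, 10.2, 10.6])


# ----------------------------------------------------------------------------
# leaflets


def test_leaflet_counts_and_mirror_symmetry():
    comp = small_composition()
    state = layered_bilayer_init(comp, seed=0)
    rec = leaflet_mixing_counts(state)
    assert (rec.n_type1_upper, rec.n_type2_lower) == (40, 40)
    # mirror flip swaps leaflet labels
    flipped = state.copy()
    flipped.positions[:, 2] = state.box_lengths[2] - flipped.positions[:, 2]
    rec_f = leaflet_mixing_counts(flipped)
    assert rec_f.n_type1_lower == rec.n_type1_upper
    assert rec_f.n_type2_upper == rec.n_type2_lower


def test_leaflet_counts_detect_flipped_chains():
    comp = small_composition()
    state = layered_bilayer_init(comp, seed=0)
    # flip 10 type-I chains head-for-tail (they now point downward)
    mid = state.box_lengths[2] / 2
    for _, idx in list(analysis.iter_chains(state))[:10]:
        state.positions[idx, 2] = 2 * mid - state.positions[idx, 2] + 6.0
    rec = leaflet_mixing_counts(state)
    assert rec.n_type1_upper == 30
    assert rec.n_type1_lower == 10
    assert rec.n_type2_lower == 40


def test_leaflet_counts_refuse_vesicles():
    comp = small_composition()
    state = layered_bilayer_init(comp, seed=0)
    with pytest.raises(ValueError):
        leaflet_mixing_counts(state, structure="vesicle")


# ----------------------------------------------------------------------------
# thickness


def test_thickness_recovers_two_gaussian_oracle():
    """Closed-form oracle: outermost half-max crossings of a double Gaussian."""
    mu, sig, L = 5.0, 1.0, 30.0
    z = np.linspace(0.25, L - 0.25, 60)
    rho = np.exp(-((z - (15 - mu)) ** 2) / (2 * sig**2)) + np.exp(
        -((z - (15 + mu)) ** 2) / (2 * sig**2)
    )
    thick = membrane_thickness((z, rho))

    def f(x):
        val = np.exp(-((x - (15 - mu)) ** 2) / 2) + np.exp(-((x - (15 + mu)) ** 2) / 2)
        return val - rho.max() / 2

    lo = brentq(f, 0.5, 15 - mu)
    hi = brentq(f, 15 + mu, L - 0.5)
    assert thick == pytest.approx(hi - lo, abs=0.5)  # within one bin
    # symmetric under z-reflection
    assert membrane_thickness((z, rho[::-1])) == pytest.approx(thick, abs=1e-9)


def test_thickness_undefined_without_profile():
    z = np.linspace(0, 10, 20)
    assert np.isnan(membrane_thickness((z, np.zeros(20))))


def test_membrane_normal_on_flat_and_tilted_slabs():
    """Spanning membranes pin the normal to a box axis; a tilted non-spanning
    slab is measured along its covariance normal, recovering the true
    thickness regardless of tilt."""
    comp = small_composition()
    flat = layered_bilayer_init(comp, seed=0)
    n_flat = analysis.membrane_normal(flat)
    assert np.allclose(n_flat, [0.0, 0.0, 1.0])
    # synthetic tilted ribbon: two head sheets at +-5 along a normal rotated
    # 30 degrees from z in the x-z plane, spanning y only
    rng = np.random.default_rng(7)
    theta = np.deg2rad(30.0)
    n_true = np.array([np.sin(theta), 0.0, np.cos(theta)])
    e_u = np.array([np.cos(theta), 0.0, -np.sin(theta)])  # in-plane, finite
    box = np.array([30.0, 30.0, 30.0])
    chains = []
    for _ in range(1200):
        u = rng.uniform(-10.0, 10.0)
        y = rng.uniform(0.0, 30.0)
        sign = rng.choice([-1.0, 1.0])
        base = np.array([15.0, 0.0, 15.0]) + u * e_u + np.array([0.0, y, 0.0])
        # 3 head beads at the outer face, 3 tail beads toward the midplane
        offs = sign * (5.0 - 0.7 * np.arange(6))
        chains.append(base[None, :] + offs[:, None] * n_true[None, :])
    state = _chain_state(chains, box)
    n_est = analysis.membrane_normal(state)
    assert abs(float(n_est @ n_true)) > 0.99
    z, rho = analysis.projected_head_profile(state, n_est)
    thick = analysis.membrane_thickness((z, rho))
    # head beads sit at |h| in [3.6, 5.0]: outer half-max crossings ~ +-5
    assert thick == pytest.approx(10.0, abs=1.0)


# ----------------------------------------------------------------------------
# classification


def test_classifier_on_canonical_fixtures():
    comp = small_composition()
    assert classify_structure(layered_bilayer_init(comp, seed=0)) == "membrane"
    state = make_water_state(2000, (10.0, 10.0, 10.0), seed=0)
    assert classify_structure(state) == "other"
    # determinism on a frame
    s = layered_bilayer_init(comp, seed=5)
    assert classify_structure(s) == classify_structure(s)


# ----------------------------------------------------------------------------
# stage segmentation


def test_stage_segmentation_recovers_breakpoints():
    rng = np.random.default_rng(0)
    t = np.arange(300, dtype=float)
    v = np.where(t < 100, 6.12, np.where(t < 200, 6.08, 6.05))
    v = v + rng.normal(0, 0.004, size=len(t))
    seg = stage_segmentation(t, v, smooth_window=20)
    assert not seg.degenerate
    assert seg.t_initial_end == pytest.approx(100, abs=20)
    assert seg.t_adjust_end == pytest.approx(200, abs=20)
    m = seg.stage_means
    assert m[0] > m[1] > m[2]
    assert m[0] == pytest.approx(6.12, abs=0.01)
    assert m[2] == pytest.approx(6.05, abs=0.01)


def test_stage_segmentation_flags_flat_series():
    t = np.arange(100, dtype=float)
    seg = stage_segmentation(t, np.full(100, 2.5), smooth_window=10)
    assert seg.degenerate
    assert 0 < seg.t_initial_end < seg.t_adjust_end <= t[-1]
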