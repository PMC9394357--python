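"""Engine: force formulas, integrator, thermostat, conservation laws."""

import dataclasses

import numpy as np
import pytest

import dpdmix._kernels as K
from dpdmix.engine import (
    IntegratorSettings,
    angle_force,
    bond_force,
    conservative_force,
    dissipative_force,
    energy_breakdown,
    pair_weight,
    random_force,
    run,
    temperature,
    total_pair_force,
    vv_step,
)
from dpdmix.model import default_interaction_matrix

from conftest import (
    bonded_energy,
    make_mixed_state,
    make_water_state,
    numpy_pair_oracle,
    pair_energy,
)


# ----------------------------------------------------------------------------
# elementary formulas


@pytest.mark.parametrize("r, rc, w", [(0.0, 1.0, 1.0), (1.0, 1.0, 0.0), (0.3, 1.0, 0.7), (1.7, 1.0, 0.0)])
def test_pair_weight(r, rc, w):
    assert pair_weight(r, rc) == pytest.approx(w)


def test_conservative_force_magnitudes():
    f = conservative_force(100.0, np.array([0.5, 0.0, 0.0]))
    assert np.allclose(f, [50.0, 0.0, 0.0])
    assert np.allclose(conservative_force(25.0, np.array([1.2, 0.0, 0.0])), 0.0)
    f = conservative_force(100.0, np.array([0.0, 0.3, 0.0]))
    assert np.linalg.norm(f) == pytest.approx(70.0)


def test_dissipative_force_projects_on_separation():
    r_hat = np.array([1.0, 0.0, 0.0])
    assert np.allclose(dissipative_force(4.5, 1.0, r_hat, np.array([0, 2.0, 0])), 0.0)
    f = dissipative_force(4.5, 1.0, r_hat, np.array([1.0, 0, 0]))
    assert np.allclose(f, [-4.5, 0.0, 0.0])  # opposes separation velocity
    assert np.allclose(dissipative_force(4.5, 0.5, r_hat, np.zeros(3)), 0.0)


def test_random_force_scaling():
    r_hat = np.array([0.0, 0.0, 1.0])
    assert np.allclose(random_force(3.0, 1.0, 0.0, 0.01, r_hat), 0.0)
    f = random_force(3.0, 1.0, 1.0, 0.01, r_hat)
    assert np.linalg.norm(f) == pytest.approx(30.0)  # 3 * 1 * 0.01**-0.5


def test_pair_gauss_is_standard_normal():
    """The counter-based per-pair variates must be unit-variance Gaussians."""
    hstep = K._step_hash(np.uint64(3), np.uint64(11))
    draws = np.array(
        [K._pair_gauss(hstep, np.uint64(k)) for k in range(100_000)]
    )
    assert abs(draws.mean()) < 0.01
    assert draws.var() == pytest.approx(1.0, abs=0.02)
    assert np.mean(draws**4) == pytest.approx(3.0, abs=0.1)  # Gaussian kurtosis
    # symmetry: same key gives the same draw (zeta_ij == zeta_ji)
    assert K._pair_gauss(hstep, K._pair_key(3, 7)) == K._pair_gauss(
        hstep, K._pair_key(7, 3)
    )


def test_bond_force_values():
    f_i, f_j = bond_force(120.0, 0.7, np.array([0.7, 0.0, 0.0]))
    assert np.allclose(f_i, 0.0) and np.allclose(f_j, 0.0)
    f_i, _ = bond_force(120.0, 0.7, np.array([0.35, 0.0, 0.0]))
    assert np.linalg.norm(f_i) == pytest.approx(60.0)
    assert f_i[0] > 0  # repulsive when compressed
    f_i, f_j = bond_force(120.0, 0.7, np.array([1.4, 0.0, 0.0]))
    assert np.linalg.norm(f_i) == pytest.approx(120.0)
    assert f_i[0] < 0  # attractive when stretched
    assert np.allclose(f_i, -f_j)


def test_angle_force_at_minimum_and_translation_invariance():
    r_i = np.array([0.0, 0.0, 0.0])
    r_j = np.array([0.7, 0.0, 0.0])
    r_k = np.array([1.4, 0.0, 0.0])
    forces = angle_force(6.0, np.pi, r_i, r_j, r_k)
    assert all(np.allclose(f, 0.0) for f in forces)
    rng = np.random.default_rng(5)
    for _ in range(10):
        p = rng.normal(size=(3, 3))
        f_i, f_j, f_k = angle_force(6.0, np.pi, *p)
        assert np.allclose(f_i + f_j + f_k, 0.0, atol=1e-12)
        # zero net torque about the middle bead
        tau = np.cross(p[0] - p[1], f_i) + np.cross(p[2] - p[1], f_k)
        assert np.allclose(tau, 0.0, atol=1e-10)


def test_angle_force_matches_finite_difference():
    """Analytic bending force equals -grad of k_theta (theta - theta0)^2."""
    rng = np.random.default_rng(11)
    k_theta, theta0 = 6.0, np.pi
    box = np.array([100.0, 100.0, 100.0])

    def energy(p):
        u = p[0] - p[1]
        v = p[2] - p[1]
        c = np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)
        return k_theta * (np.arccos(c) - theta0) ** 2

    h = 1e-6
    for _ in range(5):
        p = rng.normal(size=(3, 3))
        forces = np.vstack(angle_force(k_theta, theta0, *p, box=box))
        for bead in range(3):
            for d in range(3):
                dp = p.copy()
                dp[bead, d] += h
                dm = p.copy()
                dm[bead, d] -= h
                grad = (energy(dp) - energy(dm)) / (2 * h)
                assert forces[bead, d] == pytest.approx(-grad, rel=1e-5, abs=1e-6)


# ----------------------------------------------------------------------------
# whole-system force evaluation


def test_isolated_beads_feel_nothing(interaction, bonded):
    state = make_water_state(2, (10.0, 10.0, 10.0), seed=0)
    state.positions[0] = [1.0, 1.0, 1.0]
    state.positions[1] = [5.0, 5.0, 5.0]
    f, _ = total_pair_force(state, interaction, bonded)
    assert np.allclose(f, 0.0)


def test_force_evaluation_conserves_momentum(interaction, bonded):
    state = make_mixed_state(300, (6.0, 6.0, 6.0), seed=3)
    f, _ = total_pair_force(state, interaction, bonded, step=9)
    assert np.allclose(f.sum(axis=0), 0.0, atol=1e-10)


def test_forces_match_numpy_all_pairs_oracle(interaction, bonded):
    """Conservative + dissipative forces equal a brute-force numpy evaluation."""
    det = dataclasses.replace(interaction, sigma=0.0)
    for n, L, seed in ((100, 5.0, 1), (200, 6.5, 2)):
        state = make_water_state(n, (L, L, L), seed=seed)
        f_engine, _ = total_pair_force(state, det, bonded, step=4)
        f_oracle = numpy_pair_oracle(state, det.a, det.gamma)
        assert np.abs(f_engine - f_oracle).max() < 1e-10


def test_cell_list_equals_all_pairs_including_random(interaction, bonded):
    """The sorted cell-list path and the O(N^2) path give identical forces."""
    for n, L, seed in ((100, 5.0, 7), (200, 6.0, 8)):
        state = make_mixed_state(n, (L, L, L), seed=seed)
        args = (
            state.positions, state.velocities, state.species.astype(np.int8),
            state.bonds, state.angles, interaction.a, interaction.gamma,
            interaction.sigma, 0.01, bonded.ks, bonded.rs, bonded.k_theta,
            bonded.theta0, state.box_lengths, 1.0, np.uint64(5), np.uint64(13),
            True,
        )
        f_cells = K.compute_forces(*args, True)[0]
        f_all = K.compute_forces(*args, False)[0]
        assert np.abs(f_cells - f_all).max() < 1e-10


def test_pair_and_bonded_forces_are_minus_energy_gradient(interaction, bonded):
    """Central-difference check of the conservative force field."""
    state = make_mixed_state(40, (4.0, 4.0, 4.0), seed=4)
    f, _ = total_pair_force(state, interaction, bonded, thermostat=False)
    h = 1e-6
    rng = np.random.default_rng(0)
    for bead in rng.integers(0, 40, size=8):
        for d in range(3):
            e = []
            for sign in (+1, -1):
                p = state.positions.copy()
                p[bead, d] += sign * h
                e.append(
                    pair_energy(p, state.species, interaction.a, state.box_lengths)
                    + bonded_energy(p, state.bonds, state.angles, bonded, state.box_lengths)
                )
            grad = (e[0] - e[1]) / (2 * h)
            assert f[bead, d] == pytest.approx(-grad, rel=1e-5, abs=1e-5)


# ----------------------------------------------------------------------------
# integration


def test_uniform_motion_without_forces(bonded):
    free = dataclasses.replace(
        default_interaction_matrix(), a=np.zeros((5, 5)), sigma=0.0, gamma=0.0
    )
    state = make_water_state(10, (8.0, 8.0, 8.0), seed=1)
    r0 = state.positions.copy()
    v0 = state.velocities.copy()
    settings = IntegratorSettings(dt=0.01)
    run(state, settings, free, bonded, n_steps=100)
    expected = np.mod(r0 + v0 * 1.0, 8.0)
    assert np.allclose(state.positions, expected, atol=1e-10)
    assert np.allclose(state.velocities, v0)


def test_ballistic_step_under_preset_force(bonded):
    """One velocity-Verlet step: position gains dt^2/2 * f from the old force."""
    free = dataclasses.replace(
        default_interaction_matrix(), a=np.zeros((5, 5)), sigma=0.0, gamma=0.0
    )
    state = make_water_state(1, (8.0, 8.0, 8.0), seed=2)
    state.velocities[:] = 0.0
    state.forces[:] = [[2.0, 0.0, -1.0]]
    state.step = 1  # pre-set forces are honoured mid-run
    r0 = state.positions.copy()
    settings = IntegratorSettings(dt=0.01)
    vv_step(state, settings, free, bonded)
    assert np.allclose(
        state.positions, r0 + 0.5 * 0.01**2 * np.array([2.0, 0.0, -1.0])
    )
    # force recompute found nothing, so velocity gains dt/2 * f_old
    assert np.allclose(state.velocities, 0.5 * 0.01 * np.array([[2.0, 0.0, -1.0]]))


def test_momentum_conserved_over_many_steps(interaction, bonded):
    state = make_mixed_state(200, (4.0, 4.0, 4.0), seed=6)
    p0 = state.velocities.sum(axis=0)
    run(state, IntegratorSettings(dt=0.01, seed=3), interaction, bonded, 2_000)
    p1 = state.velocities.sum(axis=0)
    assert np.abs(p1 - p0).max() < 1e-9


def test_thermostat_reaches_unit_temperature(interaction, bonded):
    """Fluctuation-dissipation self-consistency: sigma=3, gamma=4.5 -> kBT = 1."""
    state = make_water_state(500, (5.5, 5.5, 5.5), seed=9, kBT=0.5)
    settings = IntegratorSettings(dt=0.01, seed=10)
    run(state, settings, interaction, bonded, 1000)  # equilibrate
    log = run(state, settings, interaction, bonded, 1500, energy_stride=50)
    t_mean = log[:, 6].mean()
    assert 0.95 <= t_mean <= 1.05


def test_trajectory_is_deterministic(interaction, bonded):
    outs = []
    for _ in range(2):
        state = make_mixed_state(150, (5.0, 5.0, 5.0), seed=12)
        run(state, IntegratorSettings(dt=0.01, seed=42), interaction, bonded, 300)
        outs.append((state.positions.copy(), state.velocities.copy()))
    assert np.array_equal(outs[0][0], outs[1][0])
    assert np.array_equal(outs[0][1], outs[1][1])
    other = make_mixed_state(150, (5.0, 5.0, 5.0), seed=12)
    run(other, IntegratorSettings(dt=0.01, seed=43), interaction, bonded, 300)
    assert not np.array_equal(outs[0][0], other.positions)


def test_nonfinite_state_aborts(interaction, bonded):
    state = make_water_state(20, (5.0, 5.0, 5.0), seed=0)
    state.velocities[0] = np.nan
    with pytest.raises(FloatingPointError):
        run(state, IntegratorSettings(dt=0.01), interaction, bonded, 10)


# ----------------------------------------------------------------------------
# diagnostics


def test_temperature_estimates():
    state = make_water_state(4000, (11.0, 11.0, 11.0), seed=3)
    assert temperature(state) == pytest.approx(1.0, abs=0.05)
    state.velocities[:] = 0.0
    assert temperature(state) == 0.0
    # pure drift does not count as temperature
    state.velocities[:] = [1.0, 2.0, 3.0]
    assert temperature(state) == pytest.approx(0.0, abs=1e-12)


def test_energy_breakdown_values(interaction, bonded):
    state = make_water_state(2, (10.0, 10.0, 10.0), seed=0)
    state.velocities[:] = 0.0
    state.positions[0] = [1.0, 1.0, 1.0]
    state.positions[1] = [2.0, 1.0, 1.0]  # exactly at the cutoff
    eb = energy_breakdown(state, interaction, bonded)
    assert eb.pair_conservative == pytest.approx(0.0)
    state.positions[1] = [1.0, 1.0, 1.0]  # exact overlap: energy a/2 per pair
    eb = energy_breakdown(state, interaction, bonded)
    assert eb.pair_conservative * 2 == pytest.approx(12.5)
    assert eb.total == eb.kinetic + eb.pair_conservative + eb.bond + eb.angle
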