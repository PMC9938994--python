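"""Pair forces, thermostat terms, boundaries and observables."""

import numpy as np
import pytest

from mesodpd import engine, fixtures
from mesodpd.engine import (BoxSpec, BoxState, SimulationConfig,
                            apply_boundaries, conservative_forces,
                            observables, thermostat_pair_terms)


def test_soft_repulsion_magnitude_and_cutoff(two_bead_state):
    state, pset = two_bead_state(r=0.5, a=25.0)
    f, e_dpd, e_bond, _ = conservative_forces(state, pset)
    assert np.linalg.norm(f[0]) == pytest.approx(12.5)        # 25 * (1 - 0.5)
    np.testing.assert_allclose(f[0], -f[1])
    assert e_dpd == pytest.approx(0.5 * 25.0 * 0.25)
    assert e_bond == 0.0

    state, pset = two_bead_state(r=1.2)
    f, e_dpd, _, _ = conservative_forces(state, pset)
    assert np.all(f == 0.0) and e_dpd == 0.0


def test_bond_force_zero_at_rest_length(two_bead_state):
    state, pset = two_bead_state(r=1.0, a=0.0, bonded=True)
    f, _, e_bond, _ = conservative_forces(state, pset, k_bond=4.0, r_bond=1.0)
    assert np.all(f == 0.0) and e_bond == 0.0
    state, pset = two_bead_state(r=1.5, a=0.0, bonded=True)
    f, _, e_bond, _ = conservative_forces(state, pset)
    # stretched bond pulls bead 0 toward bead 1 (+x): |F| = k (r - r0)
    assert f[0][0] == pytest.approx(4.0 * 0.5)
    assert e_bond == pytest.approx(0.5 * 4.0 * 0.25)


def test_coincident_beads_use_deterministic_fallback(two_bead_state):
    state, pset = two_bead_state(r=0.0)
    with pytest.warns(UserWarning, match="coincident"):
        f, _, _, _ = conservative_forces(state, pset)
    assert np.linalg.norm(f[0]) == pytest.approx(25.0)  # full-overlap force
    np.testing.assert_allclose(f[0], -f[1])


@pytest.mark.parametrize("boundary", ["periodic_xyz",
                                      "periodic_xy_reflective_z"])
def test_cell_list_matches_all_pairs(demo_set, boundary):
    rng = np.random.default_rng(11)
    n = 50
    box = BoxSpec((4.0, 5.0, 6.0), boundary)
    pos = rng.random((n, 3)) * box.array
    tids = rng.integers(0, demo_set.n_types, n)
    bonds = np.array([[2 * i, 2 * i + 1] for i in range(10)])
    state = BoxState(pos, np.zeros((n, 3)), tids, np.zeros(n, int), bonds,
                     box, type_names=demo_set.names)
    f_cells, e1, eb1, v1 = conservative_forces(state, demo_set, method="cells")
    f_all, e2, eb2, v2 = conservative_forces(state, demo_set,
                                             method="all_pairs")
    assert np.abs(f_cells - f_all).max() <= 1e-12
    assert e1 == pytest.approx(e2, abs=1e-12)
    assert eb1 == pytest.approx(eb2, abs=1e-12)
    np.testing.assert_allclose(v1, v2, atol=1e-12)


def test_gamma_is_derived_from_sigma():
    cfg = SimulationConfig(temperature=300.0, sigma=3.0)
    assert cfg.gamma == pytest.approx(4.5)    # sigma^2 / (2 k_BT), k_BT = 1
    cfg = SimulationConfig(temperature=298.0, sigma=3.0)
    assert cfg.gamma == pytest.approx(9.0 / (2 * 298.0 / 300.0))


def test_thermostat_terms_conserve_momentum(demo_set):
    rng = np.random.default_rng(5)
    n = 120
    box = BoxSpec((4.0, 4.0, 4.0))
    state = BoxState(rng.random((n, 3)) * 4.0, rng.normal(size=(n, 3)),
                     rng.integers(0, 5, n), np.zeros(n, int),
                     np.empty((0, 2), int), box, type_names=demo_set.names)
    f_d, f_r = thermostat_pair_terms(state, sigma=3.0, dt=0.04, T=298.0,
                                     seed=9)
    assert np.abs(f_d.sum(axis=0)).max() < 1e-12 * n
    assert np.abs(f_r.sum(axis=0)).max() < 1e-12 * n


def test_random_force_magnitude_statistics(two_bead_state):
    """|F^R| at fixed r averages to sigma * w(r) / sqrt(dt) * E|zeta|."""
    r, sigma, dt = 0.4, 3.0, 0.04
    state, _ = two_bead_state(r=r)
    mags = []
    for step in range(4000):
        _, f_r = thermostat_pair_terms(state, sigma=sigma, dt=dt, T=298.0,
                                       seed=123, step=step)
        mags.append(np.linalg.norm(f_r[0]))
    expected = sigma * (1 - r) / np.sqrt(dt) * np.sqrt(2 / np.pi)
    assert np.mean(mags) == pytest.approx(expected, rel=0.05)


def test_boundary_wrap_and_reflection():
    box = BoxSpec((10.0, 10.0, 10.0), "periodic_xy_reflective_z")
    pos = np.array([[12.0, -0.5, -0.1], [1.0, 1.0, 10.4]])
    vel = np.array([[1.0, 1.0, -2.0], [0.0, 0.0, 3.0]])
    state = BoxState(pos, vel, np.zeros(2, int), np.zeros(2, int),
                     np.empty((0, 2), int), box, type_names=["W"])
    out = apply_boundaries(state)
    np.testing.assert_allclose(out.positions[0], [2.0, 9.5, 0.1])
    assert out.velocities[0, 2] == 2.0          # v_z flipped at the wall
    np.testing.assert_allclose(out.positions[1], [1.0, 1.0, 9.6])
    assert out.velocities[1, 2] == -3.0


def test_wrap_example_fractional():
    box = BoxSpec((5.0, 5.0, 5.0))
    state = BoxState(np.array([[1.2 * 5.0, 0.0, 0.0]]), np.zeros((1, 3)),
                     np.zeros(1, int), np.zeros(1, int),
                     np.empty((0, 2), int), box, type_names=["W"])
    out = apply_boundaries(state)
    assert out.positions[0, 0] == pytest.approx(0.2 * 5.0)


def test_observables_zero_velocity_zero_temperature(two_bead_state):
    state, pset = two_bead_state(r=1.5)
    rec = observables(state, pset, SimulationConfig(temperature=298.0))
    assert rec.t_dpd == 0.0 and rec.t_kelvin == 0.0
    assert rec.e_pot_dpd == 0.0


def test_ideal_fluid_pressure_is_rho_kbt():
    """With a = 0 and no bonds the virial vanishes: P = rho k_BT."""
    box = engine.BoxSpec((8.0, 8.0, 8.0))
    cfg, state, pset = fixtures.pure_fluid_box(1536, 0.0, 300.0, box, seed=21)
    from dataclasses import replace

    cfg = replace(cfg, dt=0.01, n_steps=2000, sample_interval=10)
    res = engine.run_simulation(cfg, state, pset, store_frames=False)
    p = np.array([[r.pxx, r.pyy, r.pzz] for r in res.records[50:]])
    g = np.array([r.surface_tension_z for r in res.records[50:]])
    se = p.std() / np.sqrt(p.shape[0] / 5)       # crude autocorr allowance
    assert abs(p.mean() - 3.0) < 3 * max(se, 1e-3)
    # isotropic fluid: z surface tension fluctuates around zero
    assert abs(g.mean()) < 4 * g.std() / np.sqrt(len(g) / 5)
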