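"""Integrator/thermostat schemes: reductions, momentum, determinism."""

from dataclasses import replace

import numpy as np
import pytest

from mesodpd import engine, fixtures
from mesodpd.engine import (BoxSpec, BoxState, SimulationConfig,
                            SimulationDiverged, run_simulation, step_gwmvv,
                            step_pnhln, step_s1mvv, step_scmvv)


def _free_gas(n=32, seed=0, boundary="periodic_xyz"):
    box = BoxSpec((4.0, 4.0, 4.0))
    rng = np.random.default_rng(seed)
    state = BoxState(rng.random((n, 3)) * 4.0, rng.normal(size=(n, 3)),
                     np.zeros(n, int), np.zeros(n, int),
                     np.empty((0, 2), int), BoxSpec((4.0, 4.0, 4.0), boundary),
                     type_names=["W"])
    return state, fixtures._UniformSet(0.0)


def _soft_gas(n=64, seed=3, a=25.0, boundary="periodic_xyz"):
    box = BoxSpec((4.0, 4.0, 4.0), boundary)
    rng = np.random.default_rng(seed)
    state = BoxState(rng.random((n, 3)) * 4.0, rng.normal(0, 1, (n, 3)),
                     np.zeros(n, int), np.zeros(n, int),
                     np.empty((0, 2), int), box, type_names=["W"])
    return state, fixtures._UniformSet(a)


@pytest.mark.parametrize("stepper, extra", [
    (step_gwmvv, (0.65,)), (step_scmvv, (3,)), (step_s1mvv, ()),
    (step_pnhln, (500.0,)),
])
def test_free_flight_advances_positions_only(stepper, extra):
    """With no forces and sigma = 0, every scheme is pure drift."""
    state, pset = _free_gas()
    cfg = SimulationConfig(temperature=300.0, sigma=0.0, dt=0.05)
    out = stepper(state, cfg, *extra, pset)
    expect = (state.positions + cfg.dt * state.velocities) % 4.0
    np.testing.assert_allclose(out.positions, expect, atol=1e-13)
    np.testing.assert_allclose(out.velocities, state.velocities)


def test_gwmvv_half_reduces_to_velocity_verlet_bitwise():
    """At lambda = 0.5 and sigma = 0 the GW scheme is plain velocity-Verlet,
    which is also what the S1 splitting degenerates to."""
    state, pset = _soft_gas()
    cfg = SimulationConfig(temperature=300.0, sigma=0.0, dt=0.02)
    a = step_gwmvv(state, cfg, 0.5, pset, n_steps=25)
    b = step_s1mvv(state, cfg, pset, n_steps=25)
    assert np.array_equal(a.positions, b.positions)
    assert np.array_equal(a.velocities, b.velocities)
    # with sigma = 0 the prediction weight is irrelevant
    c = step_gwmvv(state, cfg, 1.0, pset, n_steps=25)
    assert np.array_equal(a.positions, c.positions)


def test_scmvv_iterations_converge_to_fixed_point(two_bead_state):
    state, pset = two_bead_state(r=0.5, a=25.0,
                                 vel=[[0.3, -0.2, 0.1], [-0.1, 0.4, 0.0]])
    cfg = SimulationConfig(temperature=300.0, dt=0.02)
    v5 = step_scmvv(state, cfg, 5, pset).velocities
    v50 = step_scmvv(state, cfg, 50, pset).velocities
    assert np.abs(v5 - v50).max() < 1e-8
    # a single iteration (the DPDMVV alias) differs from the fixed point
    v1 = step_scmvv(state, cfg, 1, pset).velocities
    assert np.abs(v1 - v50).max() > 0


@pytest.mark.parametrize("integrator, param", [
    ("s1mvv", None), ("pnhln", 500.0), ("gwmvv", 0.65), ("scmvv", 2),
])
def test_momentum_conserved_every_step_periodic(integrator, param):
    state, pset = _soft_gas(n=96, seed=8)
    cfg = SimulationConfig(temperature=298.0, dt=0.04, integrator=integrator,
                           integrator_param=param, n_steps=20,
                           sample_interval=1, seed=4)
    res = run_simulation(cfg, state, pset, store_frames=False)
    p0 = state.velocities.sum(axis=0)
    for rec in res.records:
        assert abs(rec.px - p0[0]) < 1e-10
        assert abs(rec.py - p0[1]) < 1e-10
        assert abs(rec.pz - p0[2]) < 1e-10


def test_walls_break_only_z_momentum():
    state, pset = _soft_gas(n=96, seed=9, boundary="periodic_xy_reflective_z")
    cfg = SimulationConfig(temperature=298.0, dt=0.04, integrator="s1mvv",
                           n_steps=200, sample_interval=1, seed=4)
    res = run_simulation(cfg, state, pset, store_frames=False)
    p0 = state.velocities.sum(axis=0)
    px = np.array([r.px for r in res.records])
    pz = np.array([r.pz for r in res.records])
    assert np.abs(px - p0[0]).max() < 1e-10
    assert np.abs(pz - p0[2]).max() > 1e-6   # reflections exchange z momentum


def test_identical_seed_identical_run(demo_set):
    cfg, state = fixtures.small_lamellar_system(scale=0.001, seed=42)
    cfg = replace(cfg, n_steps=300, sample_interval=50, dt=0.04)
    r1 = run_simulation(cfg, state, demo_set)
    r2 = run_simulation(cfg, state, demo_set)
    assert np.array_equal(r1.final_state.positions, r2.final_state.positions)
    assert [a.t_dpd for a in r1.records] == [a.t_dpd for a in r2.records]
    assert len(r1.records) == 300 // 50


def test_record_count_matches_interval():
    state, pset = _soft_gas(n=48)
    cfg = SimulationConfig(dt=0.04, n_steps=1000, sample_interval=100, seed=1)
    res = run_simulation(cfg, state, pset, store_frames=False)
    assert len(res.records) == 10
    assert [r.step for r in res.records] == list(range(100, 1001, 100))


def test_divergence_raises():
    state, pset = _soft_gas(n=48)
    state.velocities[:] = 100.0     # one step flies across many box lengths
    cfg = SimulationConfig(dt=1.0, n_steps=5, sample_interval=1, seed=1)
    with pytest.raises(SimulationDiverged):
        run_simulation(cfg, state, pset, store_frames=False)


def test_pnhln_beats_s1_at_coarse_time_step():
    """Adaptive pairwise NHL friction cancels discretization heating that
    the plain DPD thermostat cannot, at dt = 0.04 on the same fluid."""
    box = BoxSpec((8.0, 8.0, 8.0))
    devs = {}
    for integ, par in [("pnhln", 500.0), ("s1mvv", None)]:
        cfg, state, pset = fixtures.pure_fluid_box(1536, 25.0, 300.0, box,
                                                   seed=2)
        cfg = replace(cfg, integrator=integ, integrator_param=par, dt=0.04,
                      n_steps=8000, sample_interval=10)
        res = run_simulation(cfg, state, pset, store_frames=False)
        tk = np.array([r.t_kelvin for r in res.records])
        devs[integ] = abs(tk[len(tk) // 2:].mean() - 300.0)
    assert devs["pnhln"] < devs["s1mvv"]
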