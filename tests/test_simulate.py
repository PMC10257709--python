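"""Integrator, initialization, recycling, event logging and determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from oscidisk import (Geometry, ParticleState, SimulationConfig,
                      initialize_particles, integrate_step, make_scenario,
                      net_forces, recycle_particles, run_simulation,
                      update_radii)
from oscidisk.errors import IntegrationBlowUpError


def _free_speed(t, v_f=3.3, tau=1.0):
    """Closed-form speed of a contact-free particle starting at rest."""
    return v_f * (1.0 - np.exp(-t / tau))


def test_free_particle_exponential_relaxation():
    sc = make_scenario("free_particle")
    cfg = sc.config.replace(T=1.0, dt_k=0.5)
    res = run_simulation(cfg, initial_state=sc.state)
    speed = float(np.linalg.norm(res.state.velocities[0]))
    assert speed == pytest.approx(_free_speed(1.0), abs=1e-3)
    # velocity is straight down; x never changes
    assert res.state.velocities[0, 0] == 0.0
    assert res.state.positions[0, 0] == sc.state.positions[0, 0]


def test_oscillating_singleton_radius_trace_is_kinematic():
    sc = make_scenario("oscillating_singleton")
    cfg = sc.config.replace(T=1.0)
    res = run_simulation(cfg, initial_state=sc.state)
    f = res.frames
    expected = cfg.r0 * (1.0 + cfg.A * np.sin(cfg.omega * f["t"].to_numpy()))
    np.testing.assert_allclose(f["r"].to_numpy(), expected, atol=1e-12)
    # bounds are exact
    assert f["r"].min() >= cfg.r0 * (1 - cfg.A) - 1e-12
    assert f["r"].max() <= cfg.r0 * (1 + cfg.A) + 1e-12


def test_head_on_pair_momentum_conserved():
    """Symmetric contact, negligible driving: total momentum stays zero."""
    sc = make_scenario("head_on_pair")
    geo = Geometry.from_config(sc.config)
    state, t, acc = sc.state, 0.0, None
    for _ in range(200):
        state, t, acc = integrate_step(state, t, geo, sc.config, acc)
    p_total = state.velocities.sum(axis=0)
    assert np.linalg.norm(p_total) < 1e-9
    # and the pair actually repelled
    assert state.velocities[0, 0] < 0 < state.velocities[1, 0]


def test_kernel_matches_reference_integrator():
    """The compiled kernel and the pure-numpy step agree step for step."""
    cfg = SimulationConfig(N=3, A=0.15, omega=25.0, T=0.5, dt_k=0.5, seed=2)
    state = initialize_particles(cfg)
    # place two particles in contact to exercise pair + wall paths
    state.positions[0] = (0.95, 50.0)   # pressing the left wall
    state.positions[1] = (2.6, 50.0)    # overlapping particle 0
    state.positions[2] = (10.0, 2.0)    # near the orifice
    state.velocities[:] = [[0.5, -1.0], [-0.3, 0.2], [0.0, -3.0]]

    res = run_simulation(cfg, initial_state=state)

    geo = Geometry.from_config(cfg)
    ref, t, acc = state.copy(), 0.0, None
    ref.radii = update_radii(0.0, ref.phases, cfg)
    for _ in range(cfg.n_steps):
        ref, t, acc = integrate_step(ref, t, geo, cfg, acc)
    np.testing.assert_allclose(res.state.positions, ref.positions, atol=1e-9)
    np.testing.assert_allclose(res.state.velocities, ref.velocities, atol=1e-8)


def test_initialization_no_overlaps_and_determinism(ref_config):
    state = initialize_particles(ref_config)
    assert state.n == ref_config.N
    pos, radii = state.positions, state.radii
    # all pairwise overlaps non-positive
    d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
    xi = radii[:, None] + radii[None, :] - d
    np.fill_diagonal(xi, -np.inf)
    assert xi.max() <= 0.0
    # at least one radius from every boundary
    assert np.all(pos[:, 0] >= radii) and np.all(pos[:, 1] >= radii)
    assert np.all(pos[:, 0] <= ref_config.box_width - radii)
    assert np.all(pos[:, 1] <= ref_config.box_height - radii)
    assert np.all(state.velocities == 0.0)
    # same seed -> identical state
    again = initialize_particles(ref_config)
    np.testing.assert_array_equal(state.positions, again.positions)
    np.testing.assert_array_equal(state.phases, again.phases)


def test_single_particle_initialization():
    cfg = SimulationConfig(N=1)
    st = initialize_particles(cfg)
    assert st.n == 1


def test_recycling_reinjects_into_window(tiny_config, rng):
    cfg = tiny_config
    st = initialize_particles(cfg)
    st.positions[0] = (10.0, cfg.removal_y - 0.01)
    st.velocities[0] = (0.3, -3.0)
    new = recycle_particles(st, rng, cfg)
    x, y = new.positions[0]
    assert cfg.reinjection_x_range[0] < x < cfg.reinjection_x_range[1]
    assert cfg.reinjection_y_range[0] < y < cfg.reinjection_y_range[1]
    assert np.all(new.velocities[0] == 0.0)
    assert new.n == st.n
    # nothing below the line: untouched
    unchanged = recycle_particles(new, rng, cfg)
    np.testing.assert_array_equal(unchanged.positions, new.positions)


def test_exit_event_at_analytic_fall_time():
    """One particle dropped over the orifice center crosses y=0 at the
    time predicted by integrating dy/dt = -v_f (1 - e^(-t/tau))."""
    cfg = SimulationConfig(N=1, box_height=60.0,
                           reinjection_y_range=(40.0, 60.0), T=15.0)
    y0 = 30.0
    st = ParticleState(np.array([[10.0, y0]]), np.zeros((1, 2)),
                       np.ones(1), np.zeros(1))
    res = run_simulation(cfg, initial_state=st)
    assert len(res.events) >= 1
    t_pred = brentq(
        lambda t: y0 - cfg.v_f * (t - (1 - np.exp(-t))) , 5.0, 15.0)
    assert res.events["t"].iloc[0] == pytest.approx(t_pred, abs=1e-2)
    # event times strictly increasing
    assert np.all(np.diff(res.events["t"].to_numpy()) > 0)


def test_zero_time_run_yields_single_frame_no_events(tiny_config):
    cfg = tiny_config.replace(T=0.0)
    res = run_simulation(cfg)
    assert len(res.events) == 0
    assert res.frames["t"].nunique() == 1
    assert (res.frames["t"] == 0.0).all()


def test_run_determinism_byte_identical(tmp_path):
    cfg = SimulationConfig(N=12, box_height=30.0,
                           reinjection_y_range=(20.0, 30.0),
                           A=0.15, omega=25.0, T=20.0, seed=11)
    a = run_simulation(cfg, out_dir=tmp_path / "a")
    b = run_simulation(cfg, out_dir=tmp_path / "b")
    assert (tmp_path / "a" / "events.csv").read_bytes() == \
        (tmp_path / "b" / "events.csv").read_bytes()
    pd.testing.assert_frame_equal(a.frames, b.frames)


def test_particle_count_conserved_with_recycling():
    cfg = SimulationConfig(N=12, box_height=30.0,
                           reinjection_y_range=(20.0, 30.0),
                           A=0.15, omega=25.0, T=30.0, seed=5)
    res = run_simulation(cfg)
    counts = res.frames.groupby("t")["id"].count()
    assert (counts == cfg.N).all()
    assert len(res.events) > 0  # particles did cycle through
    assert res.summary["recycle_failures"] == 0
    # frames spaced by dt_k
    times = np.sort(res.frames["t"].unique())
    np.testing.assert_allclose(np.diff(times), cfg.dt_k, atol=1e-9)


def test_blow_up_raises_with_particle_and_time():
    """A non-finite state is reported with the offending particle and time."""
    cfg = SimulationConfig(N=2, T=5.0, seed=1)
    st = ParticleState(np.array([[10.0, 50.0], [14.0, 50.0]]),
                       np.array([[0.0, 0.0], [np.nan, 0.0]]),
                       np.ones(2), np.zeros(2))
    with pytest.raises(IntegrationBlowUpError) as exc:
        run_simulation(cfg, initial_state=st)
    assert exc.value.particle == 1
    assert exc.value.time > 0
    # the pure-numpy reference step reports it too
    geo = Geometry.from_config(cfg)
    with pytest.raises(IntegrationBlowUpError):
        integrate_step(st, 0.0, geo, cfg)


def test_stability_guard_reference_run(ref_config):
    """Reference dt resolves the stiff-contact period; no blow-up in T=10."""
    cfg = ref_config.replace(T=10.0, A=0.15, omega=25.0, seed=4)
    res = run_simulation(cfg)
    assert res.summary["status"] == 0
    v = res.frames[["vx", "vy"]].to_numpy()
    assert np.all(np.isfinite(v))
    # speeds remain physically bounded (no numerical heating)
    assert np.abs(v).max() < 20 * cfg.v_f
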