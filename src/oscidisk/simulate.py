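"""Particle state, initialization, integration and the full simulation run.

The driver :func:`run_simulation` advances N self-propelled disks with
prescribed radius oscillation through the constriction geometry, recording
trajectory frames every ``dt_k`` and an event whenever a particle center
crosses the exit line moving downward. Particles reaching the removal depth
are recycled into the reinjection window by rejection sampling, conserving N.

:func:`integrate_step` is a slow, pure-numpy single step of the identical
velocity-Verlet scheme, kept as the oracle for the compiled kernel.
"""

from __future__ import annotations

import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from . import _kernel
from .config import Geometry, SimulationConfig
from .errors import (DegenerateGeometryError, InitializationDensityError,
                     IntegrationBlowUpError, OscidiskError)
from .forces import net_forces, update_radii

__all__ = [
    "ParticleState",
    "SimulationResult",
    "initialize_particles",
    "recycle_particles",
    "integrate_step",
    "run_simulation",
    "load_events",
    "load_trajectory",
]


@dataclass
class ParticleState:
    """Positions (N,2), velocities (N,2), radii (N) and fixed phases (N)."""

    positions: np.ndarray
    velocities: np.ndarray
    radii: np.ndarray
    phases: np.ndarray

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        self.velocities = np.atleast_2d(np.asarray(self.velocities, float))
        self.radii = np.atleast_1d(np.asarray(self.radii, float))
        self.phases = np.atleast_1d(np.asarray(self.phases, float))

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "ParticleState":
        return ParticleState(self.positions.copy(), self.velocities.copy(),
                             self.radii.copy(), self.phases.copy())


@dataclass
class SimulationResult:
    """Trajectory frames, exit-event log and run summary."""

    config: SimulationConfig
    frames: pd.DataFrame      # columns t, id, x, y, vx, vy, r
    events: pd.DataFrame      # columns t, id
    state: ParticleState
    summary: dict


def initialize_particles(config: SimulationConfig,
                         rng: Optional[np.random.Generator] = None
                         ) -> ParticleState:
    """Sequential rejection-sampling placement with no initial contacts.

    Each particle is placed uniformly at random at least one (current) radius
    from every boundary; candidates overlapping an already placed particle
    are discarded and redrawn. Phases are drawn uniformly from [0, 2*pi) and
    initial velocities are zero.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.N
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n)
    radii = update_radii(0.0, phases, config)
    W, H = config.box_width, config.box_height
    if 2 * radii.max() > min(W, H):
        raise InitializationDensityError("box smaller than one particle")
    positions = np.empty((n, 2))
    for i in range(n):
        r = radii[i]
        placed = False
        for _ in range(config.init_attempt_cap):
            x = rng.uniform(r, W - r)
            y = rng.uniform(r, H - r)
            if i > 0:
                d2 = ((positions[:i] - (x, y)) ** 2).sum(axis=1)
                if np.any(d2 < (radii[:i] + r) ** 2):
                    continue
            positions[i] = (x, y)
            placed = True
            break
        if not placed:
            raise InitializationDensityError(
                f"could not place particle {i} of {n} after "
                f"{config.init_attempt_cap} attempts")
    return ParticleState(positions, np.zeros((n, 2)), radii, phases)


def recycle_particles(state: ParticleState, rng: np.random.Generator,
                      config: SimulationConfig) -> ParticleState:
    """Re-place every particle at or below the removal depth.

    Rejection sampling inside the reinjection window avoiding overlap with
    all current particles; velocity is zeroed (or kept, per config). A
    particle whose placement exceeds the attempt cap is parked below the
    removal line and retried at the next step — never dropped.
    """
    state = state.copy()
    rx0, rx1 = config.reinjection_x_range
    ry0, ry1 = config.reinjection_y_range
    for i in np.flatnonzero(state.positions[:, 1] <= config.removal_y):
        placed = False
        for _ in range(config.recycle_attempt_cap):
            cand = np.array([rng.uniform(rx0, rx1), rng.uniform(ry0, ry1)])
            d2 = ((state.positions - cand) ** 2).sum(axis=1)
            d2[i] = np.inf
            if np.all(d2 >= (state.radii + state.radii[i]) ** 2):
                state.positions[i] = cand
                placed = True
                break
        if not placed:
            state.positions[i] = (0.5 * (rx0 + rx1),
                                  config.removal_y - 5.0 * config.r0)
        if config.recycle_velocity == "zero":
            state.velocities[i] = 0.0
    return state


def integrate_step(state: ParticleState, t: float, geometry: Geometry,
                   config: SimulationConfig,
                   acc: Optional[np.ndarray] = None
                   ) -> Tuple[ParticleState, float, np.ndarray]:
    """One velocity-Verlet step of the reference (pure-numpy) integrator.

    Forces are velocity dependent (driving + tangential friction); the new
    acceleration is evaluated at the predicted velocity v + a*dt, then the
    velocity is corrected with the average of old and new accelerations.

    Returns (new_state, t + dt, new_acceleration); pass the returned
    acceleration back in to avoid re-evaluating forces.
    """
    dt = config.dt
    st = state.copy()
    if acc is None:
        acc = net_forces(st.positions, st.velocities, st.radii, geometry,
                         config) / config.m
    st.positions += st.velocities * dt + 0.5 * acc * dt * dt
    t_new = t + dt
    st.radii = update_radii(t_new, st.phases, config)
    vel_pred = st.velocities + acc * dt
    acc_new = net_forces(st.positions, vel_pred, st.radii, geometry,
                         config) / config.m
    st.velocities += 0.5 * (acc + acc_new) * dt
    if not (np.all(np.isfinite(st.positions))
            and np.all(np.isfinite(st.velocities))):
        bad = np.flatnonzero(~(np.isfinite(st.positions).all(axis=1)
                               & np.isfinite(st.velocities).all(axis=1)))[0]
        raise IntegrationBlowUpError(bad, t_new)
    return st, t_new, acc_new


def run_simulation(config: SimulationConfig,
                   initial_state: Optional[ParticleState] = None,
                   out_dir=None, t0: float = 0.0) -> SimulationResult:
    """Run the full simulation defined by ``config``.

    Returns trajectory frames (every ``dt_k``), the exit-event log and a
    summary. Identical (config, seed) inputs produce identical outputs. When
    ``out_dir`` is given, writes ``trajectory.csv``, ``events.csv`` and
    ``manifest.json`` there (partial outputs are flushed on failure).
    """
    geometry = Geometry.from_config(config)
    if initial_state is None:
        state = initialize_particles(config)
    else:
        state = initial_state.copy()
        state.radii = update_radii(t0, state.phases, config)
    n = state.n
    if n != config.N:
        config = config.replace(N=n)

    n_steps = config.n_steps
    record_every = config.record_every
    n_frames = n_steps // record_every + 1
    # generous event buffer: bounded by recycling turnaround, not by N
    max_events = int(20.0 * max(config.T, 1.0) * max(config.v_f, 1.0)) + 1000

    frames = np.empty((n_frames, n, 5))
    frame_times = np.empty(n_frames)
    exit_times = np.empty(max_events)
    exit_ids = np.empty(max_events, dtype=np.int64)

    pos = np.ascontiguousarray(state.positions)
    vel = np.ascontiguousarray(state.velocities)
    ox0, ox1 = geometry.orifice_x
    wall_time = _time.perf_counter()
    (status, n_events, n_frames_written, bad_particle, bad_time,
     recycle_failures, recross) = _kernel.simulate_kernel(
        pos, vel, state.phases,
        config.r0, config.A, config.omega, config.m, config.tau,
        config.v_f, config.k_n, config.k_t,
        config.box_width, config.box_height, config.exit_y, ox0, ox1,
        config.removal_y,
        config.reinjection_x_range[0], config.reinjection_x_range[1],
        config.reinjection_y_range[0], config.reinjection_y_range[1],
        config.dt, n_steps, record_every, t0,
        config.seed, config.recycle_attempt_cap,
        config.recycle_velocity == "keep",
        0.4 * config.r0,
        frames, frame_times, exit_times, exit_ids)
    wall_time = _time.perf_counter() - wall_time

    frames_df = _frames_to_df(frames[:n_frames_written],
                              frame_times[:n_frames_written])
    events_df = pd.DataFrame({"t": exit_times[:n_events],
                              "id": exit_ids[:n_events]})
    final_state = ParticleState(pos, vel,
                                update_radii(bad_time, state.phases, config)
                                if status else
                                update_radii(t0 + n_steps * config.dt,
                                             state.phases, config),
                                state.phases)
    summary = _summary(config, events_df, n_frames_written, recycle_failures,
                       recross, wall_time, status)
    result = SimulationResult(config, frames_df, events_df, final_state,
                              summary)
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    if status == _kernel.STATUS_NONFINITE:
        raise IntegrationBlowUpError(bad_particle, bad_time)
    if status == _kernel.STATUS_DEGENERATE:
        raise DegenerateGeometryError(
            f"degenerate contact geometry near t={bad_time:g}")
    if status != _kernel.STATUS_OK:
        raise OscidiskError(f"simulation aborted with status {status}")
    return result


def _frames_to_df(frames: np.ndarray, times: np.ndarray) -> pd.DataFrame:
    n_frames, n, _ = frames.shape
    ids = np.tile(np.arange(n), n_frames)
    t = np.repeat(times, n)
    flat = frames.reshape(n_frames * n, 5)
    return pd.DataFrame({"t": t, "id": ids, "x": flat[:, 0], "y": flat[:, 1],
                         "vx": flat[:, 2], "vy": flat[:, 3], "r": flat[:, 4]})


def _summary(config, events_df, n_frames, recycle_failures, recross,
             wall_time, status) -> dict:
    n_exits = len(events_df)
    last_exit = float(events_df["t"].iloc[-1]) if n_exits else None
    arrested = (config.T > 0 and
                (n_exits == 0 or last_exit < 0.9 * config.T))
    return {
        "n_exits": n_exits,
        "T": config.T,
        "exits_per_time": n_exits / config.T if config.T > 0 else 0.0,
        "last_exit": last_exit,
        "arrested": bool(arrested),
        "n_frames": int(n_frames),
        "recycle_failures": int(recycle_failures),
        "re_crossings": int(recross),
        "wall_time_s": wall_time,
        "status": int(status),
    }


def _write_outputs(result: SimulationResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.frames.to_csv(out_dir / "trajectory.csv", index=False)
    result.events.to_csv(out_dir / "events.csv", index=False)
    from . import __version__
    manifest = {
        "config": result.config.to_dict(),
        "seed": result.config.seed,
        "version": __version__,
        "n_events": len(result.events),
        "n_frames": int(result.summary["n_frames"]),
        "summary": result.summary,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def load_events(path) -> pd.DataFrame:
    """Read an exit-event CSV (columns t, id)."""
    df = pd.read_csv(path)
    if "t" not in df.columns:
        raise OscidiskError(f"{path} is not an event log (no 't' column)")
    return df


def load_trajectory(path) -> pd.DataFrame:
    """Read a trajectory CSV (columns t, id, x, y, vx, vy, r)."""
    df = pd.read_csv(path)
    missing = {"t", "x", "y", "r"} - set(df.columns)
    if missing:
        raise OscidiskError(f"{path} is missing trajectory columns {missing}")
    return df
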