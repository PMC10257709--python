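"""Numba-compiled inner loop of the simulator.

Implements exactly the physics of :mod:`oscidisk.forces` (same formulas, same
velocity-Verlet scheme as :func:`oscidisk.simulate.integrate_step`) but runs
the whole time loop in compiled code with a Verlet neighbor list. The test
suite asserts step-level agreement with the pure-numpy reference path.

Status codes returned by :func:`simulate_kernel`:
0 ok; 1 non-finite state (blow-up); 2 event buffer overflow;
3 degenerate geometry; 4 neighbor-list overflow.
"""

import numpy as np
from numba import njit

MAX_NEIGH = 48

STATUS_OK = 0
STATUS_NONFINITE = 1
STATUS_EVENT_OVERFLOW = 2
STATUS_DEGENERATE = 3
STATUS_NEIGH_OVERFLOW = 4


@njit(cache=True)
def _build_neighbors(pos, rcut2, neigh, cnt, ref_pos):
    n = pos.shape[0]
    for i in range(n):
        cnt[i] = 0
    for i in range(n):
        xi = pos[i, 0]
        yi = pos[i, 1]
        for j in range(i + 1, n):
            dx = xi - pos[j, 0]
            dy = yi - pos[j, 1]
            if dx * dx + dy * dy < rcut2:
                if cnt[i] >= MAX_NEIGH:
                    return STATUS_NEIGH_OVERFLOW
                neigh[i, cnt[i]] = j
                cnt[i] += 1
    for i in range(n):
        ref_pos[i, 0] = pos[i, 0]
        ref_pos[i, 1] = pos[i, 1]
    return STATUS_OK


@njit(cache=True)
def _seg_contact(px, py, vx, vy, r, ax, ay, bx, by, kn, kt, out):
    """Add the contact force of one wall segment on one particle to out."""
    abx = bx - ax
    aby = by - ay
    denom = abx * abx + aby * aby
    if denom > 1e-14:
        s = ((px - ax) * abx + (py - ay) * aby) / denom
        if s < 0.0:
            s = 0.0
        elif s > 1.0:
            s = 1.0
    else:
        s = 0.0
    cx = ax + s * abx
    cy = ay + s * aby
    dx = px - cx
    dy = py - cy
    d = np.sqrt(dx * dx + dy * dy)
    if d >= r:
        return STATUS_OK
    if d < 1e-14:
        return STATUS_DEGENERATE
    xi = r - d
    enx = dx / d
    eny = dy / d
    etx = -eny
    ety = enx
    vt = vx * etx + vy * ety
    out[0] += xi * (kn * enx + kt * (-vt) * etx)
    out[1] += xi * (kn * eny + kt * (-vt) * ety)
    return STATUS_OK


@njit(cache=True)
def _compute_forces(pos, vel, radii, neigh, cnt,
                    m, tau, vf, kn, kt,
                    W, H, y0, ox0, ox1, wall_range,
                    acc_out):
    """Fill acc_out with force/m; returns a status code."""
    n = pos.shape[0]
    fb = np.zeros(2)
    for i in range(n):
        acc_out[i, 0] = (0.0 - vel[i, 0]) / tau
        acc_out[i, 1] = (-vf - vel[i, 1]) / tau
        px = pos[i, 0]
        py = pos[i, 1]
        # walls only when plausibly within reach
        if px < wall_range or px > W - wall_range or py < y0 + wall_range:
            fb[0] = 0.0
            fb[1] = 0.0
            r = radii[i]
            st = _seg_contact(px, py, vel[i, 0], vel[i, 1], r,
                              0.0, y0, 0.0, H, kn, kt, fb)
            if st != STATUS_OK:
                return st
            st = _seg_contact(px, py, vel[i, 0], vel[i, 1], r,
                              W, y0, W, H, kn, kt, fb)
            if st != STATUS_OK:
                return st
            st = _seg_contact(px, py, vel[i, 0], vel[i, 1], r,
                              0.0, y0, ox0, y0, kn, kt, fb)
            if st != STATUS_OK:
                return st
            st = _seg_contact(px, py, vel[i, 0], vel[i, 1], r,
                              ox1, y0, W, y0, kn, kt, fb)
            if st != STATUS_OK:
                return st
            acc_out[i, 0] += fb[0] / m
            acc_out[i, 1] += fb[1] / m
    for i in range(n):
        xi_pos = pos[i, 0]
        yi_pos = pos[i, 1]
        for k in range(cnt[i]):
            j = neigh[i, k]
            dx = xi_pos - pos[j, 0]
            dy = yi_pos - pos[j, 1]
            d2 = dx * dx + dy * dy
            rsum = radii[i] + radii[j]
            if d2 >= rsum * rsum:
                continue
            d = np.sqrt(d2)
            if d < 1e-14:
                return STATUS_DEGENERATE
            xi = rsum - d
            enx = dx / d
            eny = dy / d
            etx = -eny
            ety = enx
            vrt = (vel[j, 0] - vel[i, 0]) * etx + (vel[j, 1] - vel[i, 1]) * ety
            fx = xi * (kn * enx + kt * vrt * etx)
            fy = xi * (kn * eny + kt * vrt * ety)
            acc_out[i, 0] += fx / m
            acc_out[i, 1] += fy / m
            acc_out[j, 0] -= fx / m
            acc_out[j, 1] -= fy / m
    return STATUS_OK


@njit(cache=True)
def simulate_kernel(pos, vel, phases,
                    r0, A, omega, m, tau, vf, kn, kt,
                    W, H, y0, ox0, ox1,
                    removal_y, rx0, rx1, ry0, ry1,
                    dt, n_steps, record_every, t0,
                    seed, recycle_cap, keep_velocity,
                    skin,
                    frames, frame_times, exit_times, exit_ids):
    """Advance the system n_steps and record frames plus exit events.

    frames: (n_frames, N, 5) buffer [x, y, vx, vy, r]; frame 0 is the initial
    state. exit_times/exit_ids are preallocated event buffers.

    Returns (status, n_events, n_frames, bad_particle, bad_time,
    recycle_failures, recross_count).
    """
    n = pos.shape[0]
    np.random.seed(seed)

    radii = np.empty(n)
    for i in range(n):
        radii[i] = r0 * (1.0 + A * np.sin(omega * t0 + phases[i]))

    wall_range = r0 * (1.0 + A) + 1e-9

    neigh = np.empty((n, MAX_NEIGH), dtype=np.int32)
    cnt = np.zeros(n, dtype=np.int32)
    ref_pos = np.empty((n, 2))
    rcut = 2.0 * r0 * (1.0 + A) + skin
    rcut2 = rcut * rcut
    half_skin2 = (0.5 * skin) * (0.5 * skin)

    st = _build_neighbors(pos, rcut2, neigh, cnt, ref_pos)
    if st != STATUS_OK:
        return st, 0, 0, -1, t0, 0, 0

    acc = np.empty((n, 2))
    acc_new = np.empty((n, 2))
    vel_pred = np.empty((n, 2))
    st = _compute_forces(pos, vel, radii, neigh, cnt, m, tau, vf, kn, kt,
                         W, H, y0, ox0, ox1, wall_range, acc)
    if st != STATUS_OK:
        return st, 0, 0, -1, t0, 0, 0

    # initial frame
    n_frames = 0
    if frames.shape[0] > 0:
        for i in range(n):
            frames[0, i, 0] = pos[i, 0]
            frames[0, i, 1] = pos[i, 1]
            frames[0, i, 2] = vel[i, 0]
            frames[0, i, 3] = vel[i, 1]
            frames[0, i, 4] = radii[i]
        frame_times[0] = t0
        n_frames = 1

    max_events = exit_times.shape[0]
    n_events = 0
    recycle_failures = 0
    recross = 0
    crossings = np.zeros(n, dtype=np.int32)

    t = t0
    for step in range(n_steps):
        # drift
        rebuild = False
        for i in range(n):
            prev_y = pos[i, 1]
            pos[i, 0] += vel[i, 0] * dt + 0.5 * acc[i, 0] * dt * dt
            pos[i, 1] += vel[i, 1] * dt + 0.5 * acc[i, 1] * dt * dt
            # downward center-crossing of the exit line
            if prev_y > y0 and pos[i, 1] <= y0:
                if n_events >= max_events:
                    return (STATUS_EVENT_OVERFLOW, n_events, n_frames,
                            i, t, recycle_failures, recross)
                exit_times[n_events] = t + dt
                exit_ids[n_events] = i
                n_events += 1
                if crossings[i] > 0:
                    recross += 1
                crossings[i] += 1
        t = t0 + (step + 1) * dt

        # recycling: rejection-sample into the reinjection window
        for i in range(n):
            if pos[i, 1] <= removal_y:
                placed = False
                for _ in range(recycle_cap):
                    cx = rx0 + (rx1 - rx0) * np.random.random()
                    cy = ry0 + (ry1 - ry0) * np.random.random()
                    ok = True
                    for j in range(n):
                        if j == i:
                            continue
                        ddx = cx - pos[j, 0]
                        ddy = cy - pos[j, 1]
                        rs = radii[i] + radii[j]
                        if ddx * ddx + ddy * ddy < rs * rs:
                            ok = False
                            break
                    if ok:
                        pos[i, 0] = cx
                        pos[i, 1] = cy
                        placed = True
                        break
                if not placed:
                    # park below the removal line; retried next step
                    pos[i, 0] = 0.5 * (rx0 + rx1)
                    pos[i, 1] = removal_y - 5.0 * r0
                    recycle_failures += 1
                if not keep_velocity:
                    vel[i, 0] = 0.0
                    vel[i, 1] = 0.0
                # reinjection window is interior and overlap-free: only the
                # driving force acts right after placement
                acc[i, 0] = (0.0 - vel[i, 0]) / tau
                acc[i, 1] = (-vf - vel[i, 1]) / tau
                crossings[i] = 0
                rebuild = True

        # neighbor-list freshness
        if not rebuild:
            for i in range(n):
                ddx = pos[i, 0] - ref_pos[i, 0]
                ddy = pos[i, 1] - ref_pos[i, 1]
                if ddx * ddx + ddy * ddy > half_skin2:
                    rebuild = True
                    break
        if rebuild:
            st = _build_neighbors(pos, rcut2, neigh, cnt, ref_pos)
            if st != STATUS_OK:
                return st, n_events, n_frames, -1, t, recycle_failures, recross

        # radii at the new time
        for i in range(n):
            radii[i] = r0 * (1.0 + A * np.sin(omega * t + phases[i]))

        # velocity-Verlet: forces at predicted velocity
        for i in range(n):
            vel_pred[i, 0] = vel[i, 0] + acc[i, 0] * dt
            vel_pred[i, 1] = vel[i, 1] + acc[i, 1] * dt
        st = _compute_forces(pos, vel_pred, radii, neigh, cnt, m, tau, vf,
                             kn, kt, W, H, y0, ox0, ox1, wall_range, acc_new)
        if st != STATUS_OK:
            return st, n_events, n_frames, -1, t, recycle_failures, recross
        for i in range(n):
            vel[i, 0] += 0.5 * (acc[i, 0] + acc_new[i, 0]) * dt
            vel[i, 1] += 0.5 * (acc[i, 1] + acc_new[i, 1]) * dt
            acc[i, 0] = acc_new[i, 0]
            acc[i, 1] = acc_new[i, 1]

        # recording + blow-up guard
        if (step + 1) % record_every == 0 and n_frames < frames.shape[0]:
            for i in range(n):
                if not (np.isfinite(pos[i, 0]) and np.isfinite(pos[i, 1])
                        and np.isfinite(vel[i, 0]) and np.isfinite(vel[i, 1])):
                    return (STATUS_NONFINITE, n_events, n_frames, i, t,
                            recycle_failures, recross)
                frames[n_frames, i, 0] = pos[i, 0]
                frames[n_frames, i, 1] = pos[i, 1]
                frames[n_frames, i, 2] = vel[i, 0]
                frames[n_frames, i, 3] = vel[i, 1]
                frames[n_frames, i, 4] = radii[i]
            frame_times[n_frames] = t
            n_frames += 1

    return STATUS_OK, n_events, n_frames, -1, t, recycle_failures, recross
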