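"""Reference implementations of the model's forces.

These pure-numpy functions define the physics:

* driving force  F_d = m (v_f e_d - v) / tau  with fixed goal direction
  e_d = (0, -1);
* linear repulsive contact with velocity-proportional tangential friction,
  F_ij = g(xi_ij) { k_n e_n + k_t [(v_j - v_i) . e_t] e_t },
  where xi_ij = (r_i + r_j) - d_ij is the overlap, g(z) = z for z >= 0 and 0
  otherwise, e_n points from j toward i (repulsion) and e_t = rot90(e_n);
* the same law against walls with the particle's velocity alone entering the
  tangential term;
* the prescribed radius oscillation r_i(t) = r0 (1 + A sin(omega t + phi_i)).

The numba kernel in ``_kernel`` reimplements the same formulas for speed; the
test suite asserts both paths agree.
"""

from __future__ import annotations

import numpy as np

from .config import Geometry, SimulationConfig
from .errors import DegenerateGeometryError

__all__ = [
    "driving_force",
    "pair_overlap",
    "contact_force_pair",
    "contact_force_boundary",
    "update_radii",
    "net_forces",
]

_EPS = 1e-14


def driving_force(velocity, config: SimulationConfig) -> np.ndarray:
    """Self-propulsion force relaxing v toward v_f*(0,-1) over time tau."""
    v = np.asarray(velocity, dtype=float)
    target = np.array([0.0, -config.v_f])
    return config.m * (target - v) / config.tau


def pair_overlap(pos_i, pos_j, r_i: float, r_j: float) -> float:
    """Overlap xi = (r_i + r_j) - |x_i - x_j|; negative when not in contact."""
    d = float(np.hypot(*(np.asarray(pos_i, float) - np.asarray(pos_j, float))))
    if d < _EPS:
        raise DegenerateGeometryError("coincident particle centers")
    return (r_i + r_j) - d


def contact_force_pair(pos_i, pos_j, vel_i, vel_j, r_i, r_j,
                       config: SimulationConfig) -> np.ndarray:
    """Contact force exerted on particle i by particle j (zero if xi < 0)."""
    pos_i = np.asarray(pos_i, float)
    pos_j = np.asarray(pos_j, float)
    delta = pos_i - pos_j
    d = float(np.hypot(*delta))
    if d < _EPS:
        raise DegenerateGeometryError("coincident particle centers")
    xi = (r_i + r_j) - d
    if xi < 0:
        return np.zeros(2)
    e_n = delta / d
    e_t = np.array([-e_n[1], e_n[0]])
    v_rel_t = float(np.dot(np.asarray(vel_j, float) - np.asarray(vel_i, float), e_t))
    return xi * (config.k_n * e_n + config.k_t * v_rel_t * e_t)


def _segment_closest_point(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    denom = float(np.dot(ab, ab))
    if denom < _EPS:
        return a
    s = float(np.dot(p - a, ab)) / denom
    s = min(1.0, max(0.0, s))
    return a + s * ab


def contact_force_boundary(pos_i, vel_i, r_i, geometry: Geometry,
                           config: SimulationConfig) -> np.ndarray:
    """Sum of wall-contact forces on a particle.

    Each wall segment contributes when the center-to-segment distance is below
    the particle radius; an orifice lip is the segment-endpoint case, giving
    xi = r - |center - corner| with the normal along (center - corner).
    Simultaneous contact with several boundary elements is summed.
    """
    p = np.asarray(pos_i, float)
    v = np.asarray(vel_i, float)
    force = np.zeros(2)
    for ax, ay, bx, by in geometry.segments:
        c = _segment_closest_point(p, np.array([ax, ay]), np.array([bx, by]))
        delta = p - c
        d = float(np.hypot(*delta))
        if d >= r_i:
            continue
        if d < _EPS:
            raise DegenerateGeometryError(
                "particle center lies exactly on a wall line")
        xi = r_i - d
        e_n = delta / d
        e_t = np.array([-e_n[1], e_n[0]])
        v_t = float(np.dot(v, e_t))
        force += xi * (config.k_n * e_n + config.k_t * (-v_t) * e_t)
    return force


def update_radii(t: float, phases, config: SimulationConfig) -> np.ndarray:
    """Prescribed radii r_i(t) = r0 (1 + A sin(omega t + phi_i)).

    A = 0 gives a monodisperse system; omega = 0 freezes distinct radii set
    by the random phases (polydisperse).
    """
    phases = np.asarray(phases, dtype=float)
    return config.r0 * (1.0 + config.A * np.sin(config.omega * t + phases))


def net_forces(positions, velocities, radii, geometry: Geometry,
               config: SimulationConfig) -> np.ndarray:
    """Total force (driving + contacts) on every particle; O(N^2) reference.

    This is the all-pairs oracle the fast kernel is checked against.
    """
    pos = np.asarray(positions, float)
    vel = np.asarray(velocities, float)
    n = pos.shape[0]
    forces = np.empty((n, 2))
    for i in range(n):
        forces[i] = driving_force(vel[i], config)
        forces[i] += contact_force_boundary(pos[i], vel[i], radii[i], geometry, config)
    for i in range(n):
        for j in range(i + 1, n):
            f = contact_force_pair(pos[i], pos[j], vel[i], vel[j],
                                   radii[i], radii[j], config)
            forces[i] += f
            forces[j] -= f
    return forces
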