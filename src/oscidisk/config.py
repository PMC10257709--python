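"""Simulation configuration and box geometry.

All quantities are dimensionless: particle mass m, rest radius r0 and the
driving relaxation time tau define the units (m = r0 = tau = 1 by default).
The reference system is a 20 x 150 box with a bottom orifice of width
D = 2.8 centered on the box, N = 200 disks, normal stiffness k_n = 500,
tangential stiffness k_t = 1000 and free speed v_f = 3.3.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Tuple

import yaml

from .errors import ConfigError

__all__ = ["SimulationConfig", "Geometry"]


@dataclass
class SimulationConfig:
    """Full parameter set of the constriction-flow model.

    Defaults reproduce the reference system, so ``SimulationConfig()`` (or an
    empty YAML config file) is the reference simulation.

    Parameters
    ----------
    N : particle count.
    m, r0, tau : mass, rest radius and driving relaxation time (units).
    k_n, k_t : normal / tangential contact stiffness. The tangential term is
        a velocity-proportional friction active only during overlap.
    v_f : free speed; the driving force relaxes each particle's velocity
        toward ``v_f * (0, -1)`` over time ``tau``.
    A, omega : amplitude and angular frequency of the active radius
        oscillation ``r_i(t) = r0 * (1 + A sin(omega t + phi_i))``.
    box_width, box_height : box dimensions; walls at x=0, x=box_width and a
        bottom wall at ``exit_y`` interrupted by the orifice.
    D : orifice width. ``orifice_center`` defaults to ``box_width / 2``.
    removal_y : particles reaching this depth are recycled into the
        reinjection window with zero velocity (configurable).
    dt : integration time step; dt_k : recording interval; T : total time.
    seed : RNG seed controlling initial placement, phases and reinjection.
    """

    N: int = 200
    m: float = 1.0
    r0: float = 1.0
    tau: float = 1.0
    k_n: float = 500.0
    k_t: float = 1000.0
    v_f: float = 3.3
    A: float = 0.0
    omega: float = 0.0
    box_width: float = 20.0
    box_height: float = 150.0
    D: float = 2.8
    orifice_center: Optional[float] = None
    exit_y: float = 0.0
    removal_y: float = -15.0
    reinjection_x_range: Tuple[float, float] = (2.0, 18.0)
    reinjection_y_range: Tuple[float, float] = (100.0, 150.0)
    dt: float = 1e-4
    dt_k: float = 0.5
    T: float = 5000.0
    seed: int = 0
    recycle_velocity: str = "zero"  # "zero" or "keep"
    recycle_attempt_cap: int = 10_000
    init_attempt_cap: int = 100_000

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if not (self.D > 0 and self.D < self.box_width):
            raise ConfigError("orifice width D must satisfy 0 < D < box_width")
        if not (self.dt > 0 and self.dt < self.dt_k):
            raise ConfigError("time steps must satisfy 0 < dt < dt_k")
        if self.T > 0 and not self.dt_k <= self.T:
            raise ConfigError("recording interval dt_k must not exceed T")
        if self.T < 0:
            raise ConfigError("total time T must be >= 0")
        if not (0 <= self.A < 1):
            raise ConfigError("amplitude A must be in [0, 1) to keep radii positive")
        for name in ("k_n", "k_t", "m", "tau", "v_f", "r0"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.omega < 0:
            raise ConfigError("omega must be >= 0")
        if self.N < 1:
            raise ConfigError("N must be >= 1")
        if self.recycle_velocity not in ("zero", "keep"):
            raise ConfigError("recycle_velocity must be 'zero' or 'keep'")
        cx = self.orifice_x_center
        if not (cx - self.D / 2 >= 0 and cx + self.D / 2 <= self.box_width):
            raise ConfigError("orifice must lie within the bottom wall")

    # -- derived quantities ---------------------------------------------
    @property
    def orifice_x_center(self) -> float:
        return self.box_width / 2 if self.orifice_center is None else self.orifice_center

    @property
    def natural_frequency(self) -> float:
        """Contact natural frequency omega_0 = sqrt(k_n / m)."""
        return (self.k_n / self.m) ** 0.5

    @property
    def n_steps(self) -> int:
        return int(round(self.T / self.dt))

    @property
    def record_every(self) -> int:
        return max(1, int(round(self.dt_k / self.dt)))

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)

    @classmethod
    def scaled_down(cls, **overrides) -> "SimulationConfig":
        """Reduced-size system preserving the constriction physics.

        Same orifice, stiffness, speed and time step as the reference system
        but a shorter box with fewer particles, cutting cost roughly 20x.
        """
        base = dict(N=60, T=1000.0, box_height=60.0, reinjection_y_range=(40.0, 60.0))
        base.update(overrides)
        return cls(**base)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["reinjection_x_range"] = list(d["reinjection_x_range"])
        d["reinjection_y_range"] = list(d["reinjection_y_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("reinjection_x_range", "reinjection_y_range"):
            if key in d:
                d[key] = tuple(d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass(frozen=True)
class Geometry:
    """Wall segments and orifice lip corner points of the simulation box.

    Segments are (ax, ay, bx, by) tuples: the two side walls and the two
    bottom-wall pieces flanking the orifice. The orifice lips are the inner
    endpoints of the bottom segments; contact with a lip is the endpoint case
    of segment-closest-point contact.
    """

    segments: Tuple[Tuple[float, float, float, float], ...]
    corners: Tuple[Tuple[float, float], ...]
    orifice_x: Tuple[float, float]

    @classmethod
    def from_config(cls, config: SimulationConfig) -> "Geometry":
        W, H, y0 = config.box_width, config.box_height, config.exit_y
        cx = config.orifice_x_center
        ox0, ox1 = cx - config.D / 2, cx + config.D / 2
        segments = (
            (0.0, y0, 0.0, H),        # left wall
            (W, y0, W, H),            # right wall
            (0.0, y0, ox0, y0),       # bottom, left of orifice
            (ox1, y0, W, y0),         # bottom, right of orifice
        )
        return cls(segments=segments, corners=((ox0, y0), (ox1, y0)),
                   orifice_x=(ox0, ox1))

    @property
    def orifice_width(self) -> float:
        return self.orifice_x[1] - self.orifice_x[0]
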