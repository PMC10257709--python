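"""Deterministic micro-scenarios and synthetic statistical samples.

Scenarios are tiny, hand-built initial conditions that make every force and
integration path testable in milliseconds without running a full simulation.
The synthetic samplers generate power-law tails and intermittent event logs
with known ground truth for exercising the statistics stack end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .errors import InsufficientDataError, ScenarioError
from .simulate import ParticleState

__all__ = ["Scenario", "make_scenario", "SCENARIO_NAMES",
           "power_law_inverse_cdf", "sample_power_law",
           "sample_intermittent_log", "IntermittentTruth"]


@dataclass
class Scenario:
    """Named deterministic initial condition plus its config overrides."""

    name: str
    state: ParticleState
    config: SimulationConfig
    description: str = ""

    def to_frame(self, t: float = 0.0) -> pd.DataFrame:
        """Export the state as one trajectory frame in the simulator's CSV
        schema (t, id, x, y, vx, vy, r), so analysis readers apply."""
        s = self.state
        return pd.DataFrame({
            "t": np.full(s.n, t), "id": np.arange(s.n),
            "x": s.positions[:, 0], "y": s.positions[:, 1],
            "vx": s.velocities[:, 0], "vy": s.velocities[:, 1],
            "r": s.radii,
        })


def _single(x, y, phase=0.0):
    return ParticleState(np.array([[x, y]]), np.zeros((1, 2)),
                         np.ones(1), np.array([phase]))


def _make_free_particle(base: SimulationConfig) -> Scenario:
    cfg = base.replace(N=1, A=0.0, omega=0.0)
    mid = (cfg.box_width / 2, cfg.box_height / 2)
    return Scenario("free_particle", _single(*mid), cfg,
                    "one particle at rest mid-box; relaxes to v_f exponentially")


def _make_head_on_pair(base: SimulationConfig) -> Scenario:
    # overlap xi = 0.1 on a horizontal axis, no driving (v_f handled via tiny)
    cfg = base.replace(N=2, A=0.0, omega=0.0, v_f=1e-12)
    y = base.box_height / 2
    state = ParticleState(np.array([[9.05, y], [10.95, y]]),
                          np.zeros((2, 2)), np.ones(2), np.zeros(2))
    return Scenario("head_on_pair", state, cfg,
                    "two disks overlapping by xi=0.1; pair force k_n*0.1 each")


def _make_wall_press(base: SimulationConfig) -> Scenario:
    cfg = base.replace(N=1, A=0.0, omega=0.0)
    state = _single(0.9, base.box_height / 2)
    return Scenario("wall_press", state, cfg,
                    "disk overlapping the left wall by 0.1; normal force k_n*0.1")


def _make_corner_touch(base: SimulationConfig) -> Scenario:
    cfg = base.replace(N=1, A=0.0, omega=0.0)
    ox0 = cfg.orifice_x_center - cfg.D / 2
    # center 0.95 from the left orifice lip, up-right at 45 degrees so the
    # disk hangs over the gap and touches only the lip point
    c = (ox0 + 0.95 / np.sqrt(2), cfg.exit_y + 0.95 / np.sqrt(2))
    return Scenario("corner_touch", _single(*c), cfg,
                    "disk overlapping the left orifice lip by xi=0.05")


# Frozen arch coordinates: three rigid (A=0) unit disks spanning the D=2.8
# orifice, obtained once by relaxing dropped disks under the reference
# contact law until static equilibrium and rounding the result. Two lateral
# disks lean on the orifice lips; the middle disk rests on both.
ARCH_POSITIONS = np.array([
    [9.001243, 0.904134],
    [10.998757, 0.904134],
    [10.000000, 2.632502],
])


def _make_arch(base: SimulationConfig) -> Scenario:
    cfg = base.replace(N=3, A=0.0, omega=0.0)
    state = ParticleState(ARCH_POSITIONS.copy(), np.zeros((3, 2)),
                          np.ones(3), np.zeros(3))
    return Scenario("arch_at_orifice", state, cfg,
                    "three rigid disks arching over the orifice; stable clog")


def _make_oscillating_singleton(base: SimulationConfig) -> Scenario:
    cfg = base.replace(N=1, A=0.15, omega=25.0)
    mid = (cfg.box_width / 2, cfg.box_height / 2)
    return Scenario("oscillating_singleton", _single(*mid), cfg,
                    "isolated disk with A=0.15, omega=25, phi=0")


_REGISTRY = {
    "free_particle": _make_free_particle,
    "head_on_pair": _make_head_on_pair,
    "wall_press": _make_wall_press,
    "corner_touch": _make_corner_touch,
    "arch_at_orifice": _make_arch,
    "oscillating_singleton": _make_oscillating_singleton,
}

SCENARIO_NAMES = tuple(sorted(_REGISTRY))


def make_scenario(name: str,
                  base: Optional[SimulationConfig] = None) -> Scenario:
    """Build a registered deterministic scenario on top of ``base`` config."""
    if name not in _REGISTRY:
        raise ScenarioError(
            f"unknown scenario {name!r}; available: {SCENARIO_NAMES}")
    if base is None:
        base = SimulationConfig()
    return _REGISTRY[name](base)


# ---------------------------------------------------------------------------
# synthetic statistical samples
# ---------------------------------------------------------------------------

def power_law_inverse_cdf(u, alpha: float, x_min: float):
    """Map uniform u in (0,1) to a power-law variate x = x_min * u^(-1/(alpha-1))."""
    u = np.asarray(u, dtype=float)
    out = x_min * u ** (-1.0 / (alpha - 1.0))
    return out if out.ndim else float(out)


def sample_power_law(alpha: float, x_min: float, n: int,
                     seed: int = 0) -> np.ndarray:
    """n i.i.d. draws from the continuous power law p(x) ~ x^-alpha, x >= x_min."""
    if alpha <= 1:
        raise ValueError("alpha must exceed 1 (distribution not normalizable)")
    if n < 1:
        raise InsufficientDataError("need n >= 1 samples")
    if x_min <= 0:
        raise ValueError("x_min must be positive")
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    u = np.where(u == 0.0, np.nextafter(0.0, 1.0), u)
    return power_law_inverse_cdf(u, alpha, x_min)


@dataclass
class IntermittentTruth:
    """Generating parameters of a synthetic intermittent event log."""

    phi: float                 # analytic <dt_f> / (<dt_c> + <dt_f>); 0 if alpha<=2
    mean_burst: float
    mean_clog: float           # inf when alpha <= 2
    clog_alpha: float
    clog_x_min: float
    events_per_burst: int
    mean_gap: float


def sample_intermittent_log(mean_burst_gap: float, mean_clog: float,
                            clog_alpha: float, n_events: int, seed: int = 0,
                            events_per_burst: int = 20
                            ) -> tuple[pd.DataFrame, IntermittentTruth]:
    """Synthetic event log alternating exponential bursts and power-law clogs.

    Bursts are runs of ``events_per_burst`` gaps drawn Exp(mean_burst_gap);
    each burst is separated by one clog drawn from a power law with exponent
    ``clog_alpha``. For ``clog_alpha > 2`` the clog scale ``x_min`` is chosen
    so the clog mean equals ``mean_clog``; for ``clog_alpha <= 2`` the mean
    diverges and ``mean_clog`` is used directly as ``x_min``.

    Returns the event log and the analytic ground truth (burst mean
    ``events_per_burst * mean_burst_gap``, clog mean, Phi).
    """
    if min(mean_burst_gap, mean_clog, clog_alpha, n_events) <= 0:
        raise ValueError("all generator parameters must be positive")
    if clog_alpha > 2:
        x_min = mean_clog * (clog_alpha - 2.0) / (clog_alpha - 1.0)
        clog_mean = mean_clog
    else:
        x_min = mean_clog
        clog_mean = np.inf
    rng = np.random.default_rng(seed)
    intervals = []
    while len(intervals) < n_events - 1:
        gaps = rng.exponential(mean_burst_gap, size=events_per_burst)
        intervals.extend(gaps.tolist())
        u = max(rng.random(), np.nextafter(0.0, 1.0))
        intervals.append(float(power_law_inverse_cdf(u, clog_alpha, x_min)))
    intervals = np.asarray(intervals[: n_events - 1])
    times = np.concatenate([[0.0], np.cumsum(intervals)])
    events = pd.DataFrame({"t": times, "id": np.arange(len(times))})
    mean_burst = events_per_burst * mean_burst_gap
    phi = 0.0 if clog_alpha <= 2 else mean_burst / (clog_mean + mean_burst)
    truth = IntermittentTruth(phi=phi, mean_burst=mean_burst,
                              mean_clog=clog_mean, clog_alpha=clog_alpha,
                              clog_x_min=x_min,
                              events_per_burst=events_per_burst,
                              mean_gap=mean_burst_gap)
    return events, truth
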