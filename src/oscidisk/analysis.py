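"""Flow statistics for constriction-flow event logs and trajectories.

Covers everything the simulator's outputs are interrogated for:

* inter-exit intervals ``dt_out`` and the discharge curve;
* flow rate Q from a least-squares slope of the discharge curve (with 95% CI)
  and the identity estimator Q = 1 / <dt_out>;
* Clauset–Shalizi–Newman power-law fit of the ``dt_out`` tail: continuous MLE
  for the exponent alpha with the lower cutoff ``dt_out_min`` chosen by
  minimizing the Kolmogorov–Smirnov distance over candidate cutoffs;
* decomposition of the event log into bursts (runs of sub-cutoff intervals)
  and clogs (intervals >= cutoff), and the flowing parameter
  Phi = <dt_f> / (<dt_c> + <dt_f>), forced to 0 when alpha <= 2 because the
  mean clog duration then diverges;
* bulk observables in a measurement region: contactless probability P_free,
  density rho, number of contacting particles n_c and mean overlap xi_c;
* the driven-damped-oscillator resonance amplitude used to interpret the
  flow-rate resonance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .errors import DegenerateSampleError, InsufficientDataError

__all__ = [
    "DischargeCurve", "FlowRate", "PowerLawFit", "FlowClassification",
    "MeasurementRegion", "BulkObservables",
    "exit_intervals", "pooled_intervals", "flow_rate", "fit_power_law",
    "decompose_bursts_clogs", "flowing_parameter", "bulk_observables",
    "resonance_amplitude", "resonance_peak_frequency", "analyze_events",
]

DEFAULT_BURN_IN = 100.0


def _event_times(events) -> np.ndarray:
    if isinstance(events, pd.DataFrame):
        times = events["t"].to_numpy(dtype=float)
    else:
        times = np.asarray(events, dtype=float)
    return np.sort(times)


@dataclass
class DischargeCurve:
    """Cumulative exit count versus time."""

    times: np.ndarray
    counts: np.ndarray

    @classmethod
    def from_events(cls, events) -> "DischargeCurve":
        t = _event_times(events)
        return cls(times=t, counts=np.arange(1, len(t) + 1, dtype=float))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.times, "count": self.counts})


def exit_intervals(events) -> np.ndarray:
    """Successive differences dt_out of the exit-event times."""
    times = _event_times(events)
    if len(times) < 2:
        raise InsufficientDataError(
            f"need at least 2 exit events, got {len(times)}")
    return np.diff(times)


def pooled_intervals(event_logs: Iterable) -> np.ndarray:
    """Pool dt_out samples across replicate runs that clog early.

    Each log is differenced separately and the interval samples are
    concatenated — never the timelines, which would fabricate spurious
    inter-run intervals. Logs with fewer than two events contribute nothing.
    """
    chunks = []
    for log in event_logs:
        times = _event_times(log)
        if len(times) >= 2:
            chunks.append(np.diff(times))
    if not chunks:
        raise InsufficientDataError("no log contributed two or more events")
    return np.concatenate(chunks)


@dataclass
class FlowRate:
    """Flow rate from the discharge-curve slope plus the identity estimator."""

    Q: float
    ci95: Tuple[float, float]
    q_identity: float
    n_events: int
    window: Tuple[float, float]
    empty: bool = False


def flow_rate(events, t_start: Optional[float] = None,
              t_end: Optional[float] = None,
              burn_in: float = DEFAULT_BURN_IN) -> FlowRate:
    """Least-squares slope of the cumulative exit count over a time window.

    The default window starts at ``burn_in`` or the first exit, whichever is
    later, and ends at the last exit (pass ``t_end=T`` to include a trailing
    arrested period: the final count is anchored at ``t_end``). Also returns
    the identity estimator 1 / <dt_out> over the window. An empty window
    yields a flagged zero-flow result rather than an exception.
    """
    times = _event_times(events)
    if len(times) == 0:
        return FlowRate(0.0, (0.0, 0.0), 0.0, 0, (0.0, 0.0), empty=True)
    if t_start is None:
        t_start = max(burn_in, times[0])
    if t_end is None:
        t_end = times[-1]
    counts = np.arange(1, len(times) + 1, dtype=float)
    mask = (times >= t_start) & (times <= t_end)
    if mask.sum() < 2:
        return FlowRate(0.0, (0.0, 0.0), 0.0, int(mask.sum()),
                        (t_start, t_end), empty=True)
    tw = times[mask]
    cw = counts[mask]
    if t_end > tw[-1]:
        tw = np.append(tw, t_end)
        cw = np.append(cw, cw[-1])
    res = stats.linregress(tw, cw)
    dof = len(tw) - 2
    tcrit = stats.t.ppf(0.975, dof) if dof > 0 else np.inf
    half = tcrit * res.stderr if np.isfinite(res.stderr) else 0.0
    intervals = np.diff(times[mask])
    q_ident = 1.0 / intervals.mean() if len(intervals) else 0.0
    return FlowRate(float(res.slope), (res.slope - half, res.slope + half),
                    float(q_ident), int(mask.sum()), (t_start, t_end))


@dataclass
class PowerLawFit:
    """Continuous power-law tail fit p(x) ~ x^-alpha for x >= x_min."""

    alpha: float
    x_min: float
    n_tail: int
    ks_distance: float

    @property
    def dt_out_min(self) -> float:
        return self.x_min


def _alpha_mle(tail: np.ndarray, x_min: float) -> float:
    log_sum = np.log(tail / x_min).sum()
    if log_sum <= 0:
        raise DegenerateSampleError("zero log-spread in the fitted tail")
    return 1.0 + len(tail) / log_sum


def _ks_distance(tail_sorted: np.ndarray, x_min: float, alpha: float) -> float:
    n = len(tail_sorted)
    cdf = 1.0 - (tail_sorted / x_min) ** (1.0 - alpha)
    ecdf_lo = np.arange(n) / n
    ecdf_hi = np.arange(1, n + 1) / n
    return float(np.maximum(np.abs(cdf - ecdf_lo),
                            np.abs(cdf - ecdf_hi)).max())


def fit_power_law(samples: Sequence[float], x_min: Optional[float] = None,
                  min_tail: int = 10) -> PowerLawFit:
    """Clauset–Shalizi–Newman fit of a continuous power-law tail.

    With ``x_min`` fixed, uses the closed-form MLE
    ``alpha = 1 + n / sum(log(x_i / x_min))`` over the tail x_i >= x_min.
    Otherwise every unique sample value leaving at least ``min_tail`` tail
    samples is a candidate cutoff and the one minimizing the KS distance
    between the tail empirical CDF and the fitted power law wins; KS ties go
    to the smaller cutoff (larger tail).
    """
    x = np.sort(np.asarray(list(samples), dtype=float))
    if len(x) < 2:
        raise InsufficientDataError("need at least 2 samples")
    if np.any(x <= 0):
        raise ValueError("power-law samples must be positive")
    if x[0] == x[-1]:
        raise DegenerateSampleError("all samples identical")

    if x_min is not None:
        tail = x[x >= x_min]
        if len(tail) < 2:
            raise InsufficientDataError(
                f"tail above x_min={x_min:g} has {len(tail)} < 2 samples")
        alpha = _alpha_mle(tail, x_min)
        return PowerLawFit(alpha, float(x_min), len(tail),
                           _ks_distance(tail, x_min, alpha))

    candidates = np.unique(x)
    best = None
    for xm in candidates:
        tail = x[x >= xm]
        if len(tail) < max(min_tail, 2) or tail[0] == tail[-1]:
            continue
        alpha = _alpha_mle(tail, xm)
        ks = _ks_distance(tail, xm, alpha)
        if best is None or ks < best.ks_distance:
            best = PowerLawFit(alpha, float(xm), len(tail), ks)
    if best is None:
        raise InsufficientDataError(
            f"no cutoff candidate leaves a tail of >= {min_tail} samples")
    return best


def decompose_bursts_clogs(events, dt_out_min: float
                           ) -> Tuple[np.ndarray, np.ndarray]:
    """Split inter-exit intervals into burst and clog durations.

    Every interval >= ``dt_out_min`` is one clog; maximal runs of consecutive
    sub-cutoff intervals are merged into one burst whose duration is their
    sum. Burst and clog durations jointly partition the event-log span.
    Accepts an event-log DataFrame (differenced internally) or a plain array
    of precomputed intervals.
    """
    if isinstance(events, pd.DataFrame):
        intervals = exit_intervals(events)
    else:
        intervals = np.asarray(events, dtype=float)
    bursts, clogs = [], []
    acc = 0.0
    for dt in intervals:
        if dt >= dt_out_min:
            if acc > 0:
                bursts.append(acc)
                acc = 0.0
            clogs.append(dt)
        else:
            acc += dt
    if acc > 0:
        bursts.append(acc)
    return np.asarray(bursts), np.asarray(clogs)


@dataclass
class FlowClassification:
    """Flowing parameter Phi and the clogged/intermittent/flowing label."""

    phi: float
    mean_burst: float
    mean_clog: float
    label: str
    alpha: Optional[float] = None


def flowing_parameter(bursts: Sequence[float], clogs: Sequence[float],
                      alpha: Optional[float] = None) -> FlowClassification:
    """Phi = <dt_f> / (<dt_c> + <dt_f>), forced to 0 when alpha <= 2.

    An exponent alpha <= 2 means the power-law clog durations have a
    diverging mean, so in the long-run limit the system is clogged even if a
    finite simulation shows some flow.
    """
    bursts = np.asarray(bursts, dtype=float)
    clogs = np.asarray(clogs, dtype=float)
    mean_burst = float(bursts.mean()) if len(bursts) else 0.0
    mean_clog = float(clogs.mean()) if len(clogs) else 0.0
    if len(clogs) == 0:
        phi = 1.0 if len(bursts) else 0.0
    elif alpha is None:
        raise InsufficientDataError(
            "a power-law fit (alpha) is required when clogs are present")
    elif alpha <= 2.0 or len(bursts) == 0:
        phi = 0.0
    else:
        phi = mean_burst / (mean_clog + mean_burst)
    label = "clogged" if phi == 0.0 else ("flowing" if phi == 1.0
                                          else "intermittent")
    return FlowClassification(phi, mean_burst, mean_clog, label, alpha)


@dataclass(frozen=True)
class MeasurementRegion:
    """Axis-aligned bulk region; the reference region is [2,18] x [2,30]."""

    x_range: Tuple[float, float] = (2.0, 18.0)
    y_range: Tuple[float, float] = (2.0, 30.0)

    @property
    def area(self) -> float:
        return ((self.x_range[1] - self.x_range[0])
                * (self.y_range[1] - self.y_range[0]))

    def contains(self, x, y) -> np.ndarray:
        return ((x >= self.x_range[0]) & (x <= self.x_range[1])
                & (y >= self.y_range[0]) & (y <= self.y_range[1]))


@dataclass
class BulkObservables:
    """Time-averaged bulk quantities with their frame-to-frame dispersions."""

    p_free: float
    rho: float
    n_c: float
    xi_c: float
    p_free_std: float
    rho_std: float
    n_c_std: float
    xi_c_std: float
    frames_used: int
    frames_skipped: int


def bulk_observables(frames: pd.DataFrame,
                     region: Optional[MeasurementRegion] = None
                     ) -> BulkObservables:
    """Contactless probability, density, contact count and mean overlap.

    Region membership is by particle center. Contact status counts contacts
    with *any* particle, including partners outside the region. ``xi_c`` of a
    frame is the mean, over in-region contacting particles, of each
    particle's mean overlap with its contact partners. Frames with no
    in-region particle are skipped for P_free and xi_c (counted in
    ``frames_skipped``) but still contribute rho = 0 and n_c = 0.
    """
    if region is None:
        region = MeasurementRegion()
    if len(frames) == 0:
        raise InsufficientDataError("no trajectory frames")
    p_free_l, rho_l, n_c_l, xi_c_l = [], [], [], []
    skipped = 0
    for _, frame in frames.groupby("t", sort=True):
        pos = frame[["x", "y"]].to_numpy(dtype=float)
        radii = frame["r"].to_numpy(dtype=float)
        inside = region.contains(pos[:, 0], pos[:, 1])
        n_in = int(inside.sum())
        rho_l.append(n_in / region.area)
        if n_in == 0:
            n_c_l.append(0.0)
            skipped += 1
            continue
        if len(pos) > 1:
            d = squareform(pdist(pos))
            overlap = (radii[:, None] + radii[None, :]) - d
            np.fill_diagonal(overlap, -np.inf)
            contact = overlap > 0
        else:
            contact = np.zeros((1, 1), dtype=bool)
            overlap = np.full((1, 1), -np.inf)
        has_contact = contact.any(axis=1)
        n_free = int((inside & ~has_contact).sum())
        n_c = int((inside & has_contact).sum())
        p_free_l.append(n_free / n_in)
        n_c_l.append(float(n_c))
        if n_c > 0:
            idx = np.flatnonzero(inside & has_contact)
            per_particle = [overlap[i][contact[i]].mean() for i in idx]
            xi_c_l.append(float(np.mean(per_particle)))
    if not p_free_l:
        raise InsufficientDataError("no frame had an in-region particle")

    def _ms(vals):
        a = np.asarray(vals, dtype=float)
        return float(a.mean()), float(a.std())

    p_free, p_free_std = _ms(p_free_l)
    rho, rho_std = _ms(rho_l)
    n_c, n_c_std = _ms(n_c_l)
    xi_c, xi_c_std = _ms(xi_c_l) if xi_c_l else (0.0, 0.0)
    return BulkObservables(p_free, rho, n_c, xi_c,
                           p_free_std, rho_std, n_c_std, xi_c_std,
                           frames_used=len(p_free_l), frames_skipped=skipped)


def resonance_amplitude(omega, omega0: float, zeta: float):
    """Driven-damped-oscillator amplitude curve (relative units).

    ``1 / sqrt((2 omega omega0 zeta)^2 + (omega^2 - omega0^2)^2)``; returns
    inf at the undamped resonance (omega = omega0, zeta = 0), which is the
    divergence flag. The curve decays to zero as omega -> inf: very fast
    radius oscillation leaves the contact spring effectively unperturbed.
    """
    if omega0 <= 0:
        raise ValueError("omega0 must be > 0")
    if zeta < 0:
        raise ValueError("zeta must be >= 0")
    omega = np.asarray(omega, dtype=float)
    denom2 = (2.0 * omega * omega0 * zeta) ** 2 + (omega ** 2 - omega0 ** 2) ** 2
    with np.errstate(divide="ignore"):
        out = 1.0 / np.sqrt(denom2)
    return out if out.ndim else float(out)


def resonance_peak_frequency(omega0: float, zeta: float) -> float:
    """Argmax of the amplitude curve: omega0*sqrt(1-2 zeta^2) for zeta<1/sqrt(2)."""
    if zeta >= 1.0 / np.sqrt(2.0):
        return 0.0
    return omega0 * np.sqrt(1.0 - 2.0 * zeta ** 2)


def analyze_events(events, T: Optional[float] = None,
                   frames: Optional[pd.DataFrame] = None,
                   region: Optional[MeasurementRegion] = None,
                   burn_in: float = DEFAULT_BURN_IN,
                   min_tail: int = 10,
                   min_events_for_fit: int = 30) -> dict:
    """One-stop summary: Q, CI, alpha, dt_out_min, Phi, label, bulk stats."""
    times = _event_times(events)
    out: dict = {"n_events": int(len(times))}
    fr = flow_rate(times, t_end=T, burn_in=burn_in)
    out.update(Q=fr.Q, Q_ci95_lo=fr.ci95[0], Q_ci95_hi=fr.ci95[1],
               Q_identity=fr.q_identity)
    if T is not None:
        out["exits_per_time"] = len(times) / T if T > 0 else 0.0
        out["arrested"] = bool(len(times) == 0 or times[-1] < 0.9 * T)
    alpha = x_min = ks = np.nan
    phi = np.nan
    label = "unknown"
    if len(times) >= max(min_events_for_fit, 2):
        intervals = np.diff(times)
        try:
            fit = fit_power_law(intervals, min_tail=min_tail)
            alpha, x_min, ks = fit.alpha, fit.x_min, fit.ks_distance
            bursts, clogs = decompose_bursts_clogs(intervals, fit.x_min)
            cls = flowing_parameter(bursts, clogs, alpha)
            phi, label = cls.phi, cls.label
            out.update(mean_burst=cls.mean_burst, mean_clog=cls.mean_clog)
        except (InsufficientDataError, DegenerateSampleError):
            pass
    out.update(alpha=alpha, dt_out_min=x_min, ks_distance=ks,
               phi=phi, label=label)
    if frames is not None and len(frames):
        try:
            bulk = bulk_observables(frames, region)
            out.update(p_free=bulk.p_free, rho=bulk.rho, n_c=bulk.n_c,
                       xi_c=bulk.xi_c, p_free_std=bulk.p_free_std,
                       rho_std=bulk.rho_std, n_c_std=bulk.n_c_std,
                       xi_c_std=bulk.xi_c_std)
        except InsufficientDataError:
            pass
    return out
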