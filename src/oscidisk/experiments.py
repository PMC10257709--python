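"""Parameter sweeps, resonance location and the omega*-k_n scaling fit.

A sweep runs one simulation + analysis per (grid value, replicate seed) for a
single swept parameter (A, omega, v_f or k_n; sweeping k_n keeps k_t = 2 k_n
so the friction force stays comparable as overlaps shrink). The resonance
utilities find the oscillation frequency omega* maximizing the mean flow
rate and fit the power law omega* = k_n^gamma (plus the fixed-exponent form
omega* = c sqrt(k_n)).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .analysis import analyze_events
from .config import SimulationConfig
from .errors import ConfigError, InsufficientDataError, OscidiskError
from .simulate import run_simulation

__all__ = ["SweepSpec", "ResonanceResult", "ScalingFit",
           "run_sweep", "find_omega_star", "fit_scaling", "derive_seed",
           "omega_star_vs_kn"]

SWEEPABLE = ("A", "omega", "v_f", "k_n")


def derive_seed(master_seed: int, grid_index: int, replicate: int) -> int:
    """Deterministic per-run seed below 2**31."""
    return (master_seed * 1_000_003 + grid_index * 10_007 + replicate * 101
            + 17) % (2 ** 31)


@dataclass
class SweepSpec:
    """One-parameter sweep: base config, grid, replicate seeds per point."""

    base: SimulationConfig
    parameter: str
    values: Sequence[float]
    seeds: int = 3
    master_seed: int = 0
    couple_kt: bool = True  # keep k_t = 2 k_n when sweeping k_n
    burn_in: float = 100.0

    def __post_init__(self):
        if self.parameter not in SWEEPABLE:
            raise ConfigError(
                f"swept parameter must be one of {SWEEPABLE}")
        vals = np.asarray(list(self.values), dtype=float)
        if len(vals) == 0:
            raise ConfigError("sweep grid must be non-empty")
        if len(vals) > 1 and not np.all(np.diff(vals) > 0):
            raise ConfigError("sweep grid must be strictly increasing")
        self.values = vals
        if self.seeds < 1:
            raise ConfigError("need at least one replicate seed per point")

    def config_for(self, grid_index: int, replicate: int) -> SimulationConfig:
        value = float(self.values[grid_index])
        changes = {self.parameter: value,
                   "seed": derive_seed(self.master_seed, grid_index, replicate)}
        if self.parameter == "k_n" and self.couple_kt:
            changes["k_t"] = 2.0 * value
        return self.base.replace(**changes)

    def to_dict(self) -> dict:
        return {"base": self.base.to_dict(), "parameter": self.parameter,
                "values": list(map(float, self.values)), "seeds": self.seeds,
                "master_seed": self.master_seed, "couple_kt": self.couple_kt,
                "burn_in": self.burn_in}

    @classmethod
    def from_dict(cls, d: dict) -> "SweepSpec":
        d = dict(d)
        d["base"] = SimulationConfig.from_dict(d.get("base", {}))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SweepSpec":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _run_one(spec: SweepSpec, gi: int, rep: int) -> dict:
    cfg = spec.config_for(gi, rep)
    row = {"parameter": spec.parameter, "value": float(spec.values[gi]),
           "seed": cfg.seed, "replicate": rep}
    try:
        result = run_simulation(cfg)
    except OscidiskError as exc:  # record, keep sweeping
        row.update(failed=True, error=str(exc))
        return row
    summary = analyze_events(result.events, T=cfg.T, burn_in=spec.burn_in)
    row.update(failed=False, error="",
               n_exits=summary["n_events"],
               exits_per_time=summary["exits_per_time"],
               arrested=summary["arrested"],
               Q=summary["Q"], Q_identity=summary["Q_identity"],
               alpha=summary["alpha"], dt_out_min=summary["dt_out_min"],
               phi=summary["phi"], label=summary["label"])
    return row


def run_sweep(spec: SweepSpec, out_dir=None, progress: bool = False
              ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Execute the sweep; returns (per-run tidy table, per-point aggregate).

    With ``out_dir`` the sweep is resumable: completed runs are looked up in
    ``manifest.json`` and skipped; tables are rewritten after every run.
    """
    manifest_path = done = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest_path = out_dir / "manifest.json"
        if manifest_path.exists():
            done = json.loads(manifest_path.read_text())
            if done.get("spec") != spec.to_dict():
                done = {"spec": spec.to_dict(), "runs": {}}
        else:
            done = {"spec": spec.to_dict(), "runs": {}}

    rows = []
    for gi in range(len(spec.values)):
        for rep in range(spec.seeds):
            key = f"{gi}:{rep}"
            if done is not None and key in done["runs"]:
                rows.append(done["runs"][key])
                continue
            row = _run_one(spec, gi, rep)
            rows.append(row)
            if progress:
                print(f"[sweep] {spec.parameter}={row['value']:g} "
                      f"rep={rep} -> Q={row.get('Q', float('nan')):.3g}")
            if done is not None:
                done["runs"][key] = row
                manifest_path.write_text(json.dumps(done, indent=2))
                pd.DataFrame(rows).to_csv(out_dir / "runs.csv", index=False)
    runs = pd.DataFrame(rows)
    agg = aggregate_sweep(runs)
    if out_dir is not None:
        runs.to_csv(out_dir / "runs.csv", index=False)
        agg.to_csv(out_dir / "aggregate.csv", index=False)
    return runs, agg


def aggregate_sweep(runs: pd.DataFrame) -> pd.DataFrame:
    """Per-grid-point means and dispersions over replicate seeds."""
    ok = runs[~runs.get("failed", pd.Series(False, index=runs.index))]
    if len(ok) == 0:
        return pd.DataFrame()
    grouped = ok.groupby("value", sort=True)
    agg = grouped.agg(
        Q_mean=("Q", "mean"), Q_std=("Q", "std"),
        Q_sem=("Q", "sem"), n_runs=("Q", "size"),
        exits_per_time_mean=("exits_per_time", "mean"),
        phi_mean=("phi", "mean"), alpha_mean=("alpha", "mean"),
        arrested_frac=("arrested", "mean"),
    ).reset_index()
    return agg.fillna({"Q_std": 0.0, "Q_sem": 0.0})


@dataclass
class ResonanceResult:
    """Location of the flow-rate maximum over an omega grid."""

    omegas: np.ndarray
    q_mean: np.ndarray
    q_sem: np.ndarray
    omega_star: float
    omega_star_err: float
    q_max: float
    at_boundary: bool = False
    no_resonance: bool = False


def find_omega_star(runs: pd.DataFrame, n_boot: int = 200,
                    seed: int = 0) -> ResonanceResult:
    """Grid argmax of the mean flow rate over omega, with an uncertainty.

    The uncertainty combines, in quadrature, half the local grid spacing at
    the maximum with the standard deviation of the argmax over bootstrap
    resamples of the replicate seeds. Ties break toward lower omega; a flat
    response (max within the joint 95% CI of the min) raises the
    ``no_resonance`` flag.
    """
    col = "value" if "value" in runs.columns else "omega"
    if "failed" in runs.columns:
        runs = runs[~runs["failed"].astype(bool)]
    grid = np.unique(runs[col].to_numpy(dtype=float))
    if len(grid) < 3:
        raise InsufficientDataError("need at least 3 omega grid points")
    q_by = [runs.loc[runs[col] == w, "Q"].to_numpy(dtype=float) for w in grid]
    q_mean = np.array([q.mean() for q in q_by])
    q_sem = np.array([q.std(ddof=1) / np.sqrt(len(q)) if len(q) > 1 else 0.0
                      for q in q_by])
    k = int(np.argmax(q_mean))  # first max -> lowest omega on ties
    omega_star = float(grid[k])
    # half local grid spacing
    left = grid[k] - grid[k - 1] if k > 0 else grid[k + 1] - grid[k]
    right = grid[k + 1] - grid[k] if k < len(grid) - 1 else left
    grid_err = 0.5 * max(left, right)
    rng = np.random.default_rng(seed)
    boot_stars = np.empty(n_boot)
    for b in range(n_boot):
        means = np.array([rng.choice(q, size=len(q), replace=True).mean()
                          for q in q_by])
        boot_stars[b] = grid[int(np.argmax(means))]
    err = float(np.hypot(grid_err, boot_stars.std()))
    i_min = int(np.argmin(q_mean))
    flat = (q_mean[k] - q_mean[i_min]
            <= 1.96 * np.hypot(q_sem[k], q_sem[i_min]))
    return ResonanceResult(grid, q_mean, q_sem, omega_star, err,
                           q_max=float(q_mean[k]),
                           at_boundary=k in (0, len(grid) - 1),
                           no_resonance=bool(flat))


@dataclass
class ScalingFit:
    """Power-law fit of omega* against k_n on log-log axes."""

    gamma: float               # one-parameter form omega* = k_n^gamma
    gamma_se: float
    gamma_free: float          # two-parameter form omega* = c * k_n^gamma
    gamma_free_se: float
    prefactor_free: float
    c_sqrt: float              # fixed gamma = 0.5 prefactor
    c_sqrt_se: float
    n_points: int


def fit_scaling(pairs: Sequence[Tuple[float, float]]) -> ScalingFit:
    """Fit omega* = k_n^gamma from (k_n, omega*) pairs.

    Three fits on log-log data: the one-parameter form (zero intercept, the
    headline), the two-parameter form with a free prefactor, and the fixed
    exponent 1/2 with a free prefactor c (omega* = c sqrt(k_n)).
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise InsufficientDataError("need at least 3 (k_n, omega*) pairs")
    kn, ws = arr[:, 0], arr[:, 1]
    if np.any(kn <= 0) or np.any(ws <= 0):
        raise ValueError("k_n and omega* must be positive")
    if kn.max() / kn.min() < 3.0:
        raise InsufficientDataError("k_n values must span at least a factor 3")
    u = np.log(kn)
    v = np.log(ws)
    n = len(u)
    # one-parameter: v = gamma * u
    gamma = float((u * v).sum() / (u * u).sum())
    resid = v - gamma * u
    gamma_se = float(np.sqrt((resid ** 2).sum() / max(n - 1, 1)
                             / (u * u).sum()))
    # two-parameter
    res = stats.linregress(u, v)
    # fixed exponent 0.5
    logc = v - 0.5 * u
    c_sqrt = float(np.exp(logc.mean()))
    c_sqrt_se = float(c_sqrt * logc.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return ScalingFit(gamma=gamma, gamma_se=gamma_se,
                      gamma_free=float(res.slope),
                      gamma_free_se=float(res.stderr),
                      prefactor_free=float(np.exp(res.intercept)),
                      c_sqrt=c_sqrt, c_sqrt_se=c_sqrt_se, n_points=n)


def omega_star_vs_kn(base: SimulationConfig, kn_values: Sequence[float],
                     omega_grid: Sequence[float], seeds: int = 3,
                     master_seed: int = 0, out_dir=None, progress: bool = False
                     ) -> Tuple[pd.DataFrame, dict]:
    """Locate omega* for each k_n (with k_t = 2 k_n) on a shared omega grid.

    Returns a table of (k_n, omega_star, omega_star_err, q_max) and a dict of
    the per-k_n ResonanceResult objects. Feed the table to
    :func:`fit_scaling` for the omega* = k_n^gamma law.
    """
    rows = []
    details = {}
    for i, kn in enumerate(kn_values):
        cfg = base.replace(k_n=float(kn), k_t=2.0 * float(kn))
        spec = SweepSpec(base=cfg, parameter="omega",
                         values=sorted(omega_grid), seeds=seeds,
                         master_seed=derive_seed(master_seed, i, 0))
        sub_dir = None if out_dir is None else Path(out_dir) / f"kn_{kn:g}"
        runs, _ = run_sweep(spec, out_dir=sub_dir, progress=progress)
        res = find_omega_star(runs)
        details[float(kn)] = res
        rows.append({"k_n": float(kn), "omega_star": res.omega_star,
                     "omega_star_err": res.omega_star_err,
                     "q_max": res.q_max, "at_boundary": res.at_boundary})
    table = pd.DataFrame(rows)
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        table.to_csv(Path(out_dir) / "omega_star_vs_kn.csv", index=False)
    return table, details
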