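"""Parameter sweep and particle-swarm parameter estimation.

``run_sweep`` executes the 5x5 (P_SNC x T_SEN) sensitivity grid — one
simulation per grid point, sampled every 500 MCS — and classifies every end
state against a healthy baseline run.  ``pso_fit`` is a canonical
global-best particle swarm (inertia + cognitive + social velocity update,
positions clamped to box bounds) used to estimate the six behavioural
thresholds against calibration curves via ``objective_relative_error``.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ConfigError, SimulationParams
from .scenarios import (ClassifyParams, ScenarioConfig, classify_outcome,
                        run_replicate)

#: the six free thresholds of the parameter search
THRESHOLD_NAMES = ("pdgf_f", "snc_thr", "mmp_thr", "ecm_thr", "inf_thr",
                   "csf1_thr")

#: observables compared against calibration curves
OBSERVABLES = ("fibroblasts", "myofibroblasts", "senescent_myofibroblasts",
               "macrophages", "ecm", "closure_rate")

_COLUMN_OF = {
    "fibroblasts": "n_fibroblast",
    "myofibroblasts": "n_myofibroblast",
    "senescent_myofibroblasts": "n_senescent",
    "macrophages": "n_macrophage",
    "ecm": "n_ecm",
}


# --------------------------------------------------------------------------
# sensitivity sweep
# --------------------------------------------------------------------------

@dataclass
class SweepSpec:
    """The (P_SNC, T_SEN) sensitivity grid.

    Five evenly spread P_SNC levels including 0 and 0.75, and five T_SEN
    levels (units of 1000 MCS) spanning the inflammation -> remodelling
    phases.  ``include_preexisting`` adds the pre-existing-senescence
    pseudo-level as an extra column mapped to the chronic_preexisting
    scenario.
    """

    p_snc_values: tuple = (0.0, 0.075, 0.15, 0.45, 0.75)
    t_sen_values: tuple = (6.0, 12.0, 24.0, 36.0, 48.0)
    include_preexisting: bool = False
    lattice_size: int = 200
    duration_days: float = 18.0
    sample_period_mcs: int = 500
    seed: int = 0

    def validate(self) -> "SweepSpec":
        if len(self.p_snc_values) < 1 or len(self.t_sen_values) < 1:
            raise ConfigError("sweep: needs at least one level per axis")
        if any(not 0 <= p <= 1 for p in self.p_snc_values):
            raise ConfigError("sweep.p_snc_values: probabilities in [0, 1]")
        return self


@dataclass
class SweepResult:
    spec: SweepSpec
    timeseries: dict          # (p_snc, t_sen_or_'preexisting') -> DataFrame
    classification: dict      # same keys -> 'healthy' | 'chronic' | 'fibrotic'
    baseline: pd.DataFrame

    @property
    def n_runs(self) -> int:
        return len(self.timeseries)


def _cell_seed(master: int, i: int, j: int) -> int:
    return int((master * 1_000_003 + i * 1009 + j * 9176) % (2**31 - 1))


def run_sweep(params: SimulationParams, spec: SweepSpec,
              classify: ClassifyParams | None = None) -> SweepResult:
    """One simulation per (P_SNC, T_SEN) grid point; |P| x |T| runs total.

    Each grid cell uses a fixed seed derived from its coordinates and the
    master seed.  Only P_SNC, T_SEN (and pre-existing seeding for the
    pseudo-level) differ between cells.
    """
    spec.validate()
    if spec.lattice_size != params.grid.width:
        params = dataclasses.replace(
            params, grid=params.grid.scaled(spec.lattice_size))
    base_cfg = ScenarioConfig(
        name="healthy", duration_days=spec.duration_days, replicates=1,
        sample_period_mcs=spec.sample_period_mcs, seed=spec.seed)
    baseline = run_replicate(params, base_cfg, _cell_seed(spec.seed, 99, 99))

    columns: list = list(spec.t_sen_values)
    if spec.include_preexisting:
        columns = ["preexisting"] + columns
    ts_grid: dict = {}
    labels: dict = {}
    for i, p_snc in enumerate(spec.p_snc_values):
        for j, t_sen in enumerate(columns):
            if t_sen == "preexisting":
                cfg = dataclasses.replace(
                    base_cfg, name="chronic_preexisting",
                    overrides={"p_snc": float(p_snc)})
            else:
                cfg = dataclasses.replace(
                    base_cfg, overrides={"p_snc": float(p_snc),
                                         "t_sen": float(t_sen)})
            ts = run_replicate(params, cfg, _cell_seed(spec.seed, i, j))
            ts_grid[(p_snc, t_sen)] = ts
            labels[(p_snc, t_sen)] = classify_outcome(ts, baseline, classify)
    return SweepResult(spec=spec, timeseries=ts_grid, classification=labels,
                       baseline=baseline)


# --------------------------------------------------------------------------
# objective
# --------------------------------------------------------------------------

def closure_rate(ts: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Wound-closure rate (fraction/day) at sample midpoints."""
    day = ts["day"].to_numpy()
    clo = ts["closure"].to_numpy()
    dd = np.diff(day)
    mid = 0.5 * (day[1:] + day[:-1])
    rate = np.diff(clo) / np.where(dd > 0, dd, 1.0)
    return mid, rate


def objective_relative_error(ts: pd.DataFrame, targets: dict,
                             eps_fraction: float = 0.05) -> float:
    """Mean relative error between a simulated time series and calibration
    target curves.

    ``targets`` maps observable names (a subset of :data:`OBSERVABLES`) to
    ``(days, values)`` pairs.  Each target is linearly interpolated onto the
    simulation sample days; the per-observable error is
    ``mean_t |sim_t - target_t| / max(|target_t|, eps)`` with
    ``eps = eps_fraction * max|target| + 1e-12`` guarding near-zero target
    values.  The objective is the unweighted mean over observables.
    """
    if not targets:
        raise ConfigError("objective: no target curves given")
    errs = []
    for name, (t_days, t_vals) in targets.items():
        if name not in OBSERVABLES:
            raise ConfigError(f"objective: unknown observable '{name}'")
        t_days = np.asarray(t_days, float)
        t_vals = np.asarray(t_vals, float)
        if len(t_days) == 0:
            raise ConfigError(f"objective: empty target curve '{name}'")
        if name == "closure_rate":
            s_days, s_vals = closure_rate(ts)
        else:
            s_days = ts["day"].to_numpy()
            s_vals = ts[_COLUMN_OF[name]].to_numpy(dtype=float)
        lo, hi = t_days[0], t_days[-1]
        sel = (s_days >= lo) & (s_days <= hi)
        if not sel.any():
            sel = slice(None)
        tgt = np.interp(s_days[sel], t_days, t_vals)
        eps = eps_fraction * np.max(np.abs(t_vals)) + 1e-12
        denom = np.maximum(np.abs(tgt), eps)
        errs.append(float(np.mean(np.abs(s_vals[sel] - tgt) / denom)))
    return float(np.mean(errs))


def timeseries_targets(ts: pd.DataFrame,
                       observables=OBSERVABLES) -> dict:
    """Turn a simulated time series into target curves (used for synthetic
    parameter-recovery experiments)."""
    out = {}
    for name in observables:
        if name == "closure_rate":
            out[name] = closure_rate(ts)
        else:
            out[name] = (ts["day"].to_numpy(),
                         ts[_COLUMN_OF[name]].to_numpy(dtype=float))
    return out


# --------------------------------------------------------------------------
# particle swarm optimisation
# --------------------------------------------------------------------------

@dataclass
class PSOSpec:
    """Canonical global-best PSO hyper-parameters."""

    bounds: dict = field(default_factory=dict)  # name -> (low, high)
    swarm_size: int = 15
    omega: float = 0.7
    c_cognitive: float = 1.5
    c_social: float = 1.5
    iterations: int = 30

    def validate(self) -> "PSOSpec":
        if self.swarm_size < 2:
            raise ConfigError("pso.swarm_size: must be >= 2")
        if not self.bounds:
            raise ConfigError("pso.bounds: at least one free parameter")
        for k, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ConfigError(f"pso.bounds[{k}]: need finite low < high")
        return self


@dataclass
class PSOResult:
    best_position: dict       # name -> value
    best_value: float
    trace: np.ndarray         # per-iteration global best (non-increasing)
    n_evaluations: int


def pso_fit(objective, spec: PSOSpec, rng: np.random.Generator) -> PSOResult:
    """Minimise ``objective(dict of params) -> float`` over the box bounds.

    Velocity update v <- w v + c1 r1 (pbest - x) + c2 r2 (gbest - x);
    positions are clamped to the bounds after every move.  Reaching the
    iteration budget is normal termination.
    """
    spec.validate()
    names = list(spec.bounds)
    lo = np.array([spec.bounds[k][0] for k in names])
    hi = np.array([spec.bounds[k][1] for k in names])
    span = hi - lo
    n, d = spec.swarm_size, len(names)

    x = lo + rng.random((n, d)) * span
    v = (rng.random((n, d)) - 0.5) * span * 0.2
    f = np.array([objective(dict(zip(names, row))) for row in x])
    pbest_x = x.copy()
    pbest_f = f.copy()
    g = int(np.argmin(f))
    gbest_x = x[g].copy()
    gbest_f = float(f[g])
    trace = [gbest_f]
    evals = n

    for _ in range(spec.iterations):
        r1 = rng.random((n, d))
        r2 = rng.random((n, d))
        v = (spec.omega * v + spec.c_cognitive * r1 * (pbest_x - x)
             + spec.c_social * r2 * (gbest_x[None, :] - x))
        x = np.clip(x + v, lo, hi)
        f = np.array([objective(dict(zip(names, row))) for row in x])
        evals += n
        better = f < pbest_f
        pbest_x[better] = x[better]
        pbest_f[better] = f[better]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f:
            gbest_f = float(pbest_f[g])
            gbest_x = pbest_x[g].copy()
        trace.append(gbest_f)

    return PSOResult(best_position=dict(zip(names, gbest_x)),
                     best_value=gbest_f, trace=np.asarray(trace),
                     n_evaluations=evals)


def threshold_objective(params: SimulationParams, targets: dict,
                        duration_days: float = 6.0, lattice_size: int = 60,
                        sample_period_mcs: int = 500, seed: int = 1234):
    """Objective factory for threshold estimation: each evaluation runs one
    reduced-scale healthy simulation with the candidate thresholds (common
    random numbers across evaluations) and scores it against ``targets``."""
    if lattice_size != params.grid.width:
        params = dataclasses.replace(params,
                                     grid=params.grid.scaled(lattice_size))
    cfg = ScenarioConfig(name="healthy", duration_days=duration_days,
                         replicates=1, sample_period_mcs=sample_period_mcs,
                         seed=seed)

    def objective(candidate: dict) -> float:
        unknown = set(candidate) - set(THRESHOLD_NAMES)
        if unknown:
            raise ConfigError(f"objective: not threshold params: {unknown}")
        behavior = dataclasses.replace(params.behavior, **{
            k: float(v) for k, v in candidate.items()})
        p = dataclasses.replace(params, behavior=behavior)
        ts = run_replicate(p, cfg, seed)
        return objective_relative_error(ts, targets)

    return objective
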