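"""Scenario construction and orchestration.

Five repair-outcome scenarios are defined, differing only in senescent-cell
dynamics (the probability of myofibroblast senescence P_SNC, the senescence
induction gate time T_SEN, and pre-existing inflammatory senescent cells):

* ``healthy``             — calibrated baseline; transient senescence.
* ``chronic_high_psnc``   — P_SNC raised 0.15 -> 0.75; senescent-cell burden
                            overwhelms macrophage clearance (chronic wound).
* ``fibrotic_no_snc``     — P_SNC = 0; no senescent myofibroblasts, excess
                            ECM (fibrosis).
* ``fibrotic_delayed``    — T_SEN moved to 15 days; senescence arrives too
                            late to remodel the scar (fibrosis).
* ``chronic_preexisting`` — inflammatory senescent cells seeded at t = 0
                            (aged / inflamed tissue), chronic wound.

The initial condition is a dermal margin of fibroblasts checkerboarded with
one-pixel ECM cells around a central square wound populated by M2
macrophages.  The wound mask is frozen at t = 0 and defines both the
wound-closure fraction and the "wound region" gate for myofibroblast
differentiation.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import Lattice
from .fields import ChemFields
from .params import (ECM, FIBROBLAST, INF, MACROPHAGE, PRE_SENESCENT,
                     ConfigError, SimulationParams)
from .simulation import SAMPLE_COLUMNS, Simulation

log = logging.getLogger("woundcpm")

SCENARIO_NAMES = ("healthy", "chronic_high_psnc", "fibrotic_no_snc",
                  "fibrotic_delayed", "chronic_preexisting")

# per-scenario overrides; restricted to P_SNC, T_SEN and pre-existing seeding
_SCENARIO_OVERRIDES: dict[str, dict] = {
    "healthy": {},
    "chronic_high_psnc": {"p_snc": 0.75},
    "fibrotic_no_snc": {"p_snc": 0.0},
    "fibrotic_delayed": {"t_sen": 48.0},   # 48,000 MCS = 15 days
    "chronic_preexisting": {"preexisting": True},
}

_ALLOWED_OVERRIDES = {"p_snc", "t_sen", "preexisting", "preexisting_count"}

SNAPSHOT_DAYS = (0, 1, 3, 5, 7, 12, 18)


@dataclass
class ScenarioConfig:
    """One scenario run request."""

    name: str = "healthy"
    duration_days: float = 18.0
    replicates: int = 3
    sample_period_mcs: int = 500
    seed: int = 0
    overrides: dict = field(default_factory=dict)

    def validate(self) -> "ScenarioConfig":
        if self.name not in SCENARIO_NAMES:
            raise ConfigError(f"scenario.name: unknown scenario '{self.name}'")
        if self.duration_days < 0:
            raise ConfigError("scenario.duration_days: must be >= 0")
        if self.replicates < 1:
            raise ConfigError("scenario.replicates: must be >= 1")
        if self.sample_period_mcs < 1:
            raise ConfigError("scenario.sample_period_mcs: must be >= 1")
        unknown = set(self.overrides) - _ALLOWED_OVERRIDES
        if unknown:
            raise ConfigError(
                f"scenario.overrides: only {sorted(_ALLOWED_OVERRIDES)} may "
                f"be overridden, got {sorted(unknown)}")
        return self


def scenario_params(params: SimulationParams,
                    config: ScenarioConfig) -> tuple[SimulationParams, bool]:
    """Apply a scenario's overrides; returns (params, seed_preexisting)."""
    over = dict(_SCENARIO_OVERRIDES[config.name])
    over.update(config.overrides)
    behavior = dataclasses.replace(
        params.behavior,
        p_snc=float(over.get("p_snc", params.behavior.p_snc)),
        t_sen=float(over.get("t_sen", params.behavior.t_sen)))
    grid = params.grid
    if "preexisting_count" in over:
        grid = dataclasses.replace(grid,
                                   preexisting_count=int(over["preexisting_count"]))
    out = dataclasses.replace(params, behavior=behavior, grid=grid)
    return out.validate(), bool(over.get("preexisting", False))


def build_initial_state(params: SimulationParams, config: ScenarioConfig,
                        rng: np.random.Generator) -> Simulation:
    """Construct the t = 0 state for one replicate.

    The dermal margin is tiled with cell_size x cell_size blocks in a
    checkerboard of fibroblasts and one-pixel ECM cells; the central wound
    holds randomly placed M2 macrophages (and, for the pre-existing
    scenario, inflammatory senescent cells surrounded by an initial
    inflammation level).  All other fields start at zero.
    """
    config.validate()
    params, seed_pre = scenario_params(params, config)
    g = params.grid
    H, W, cs = g.height, g.width, g.cell_size
    lat = Lattice(W, H, params.energy)
    chem = ChemFields(H, W)

    r0 = (H - g.wound_size) // 2
    c0 = (W - g.wound_size) // 2
    wound = np.zeros((H, W), dtype=bool)
    wound[r0:r0 + g.wound_size, c0:c0 + g.wound_size] = True
    # CSF1 carry-over from the inflammatory phase keeps the seeded
    # macrophages alive until activated fibroblasts start supplying CSF1
    chem.csf1[wound] = g.wound_csf1_init

    # dermal margin: checkerboard of fibroblasts and ECM pixel blocks
    for bi, rb in enumerate(range(0, H, cs)):
        for bj, cb in enumerate(range(0, W, cs)):
            rows = np.arange(rb, min(rb + cs, H))
            cols = np.arange(cb, min(cb + cs, W))
            rr, cc = np.meshgrid(rows, cols, indexing="ij")
            block = np.stack([rr.ravel(), cc.ravel()], axis=1)
            outside = ~wound[block[:, 0], block[:, 1]]
            block = block[outside]
            if len(block) == 0:
                continue
            if (bi + bj) % 2 == 0:
                lat.new_cell(FIBROBLAST, block)
            else:
                # porous matrix: ECM pixels alternate with Medium gaps so
                # fibroblasts can migrate along (not through) the scaffold
                for px in block:
                    if (px[0] + px[1]) % 2 == 0:
                        lat.new_cell(ECM, [px])

    # wound: macrophages (M2) on random non-overlapping block slots
    slots = []
    for rb in range(r0, r0 + g.wound_size - cs + 1, cs):
        for cb in range(c0, c0 + g.wound_size - cs + 1, cs):
            slots.append((rb, cb))
    slots = np.asarray(slots)
    n_pre = g.preexisting_count if seed_pre else 0
    need = g.macrophage_count + n_pre
    if need > len(slots):
        raise ConfigError(
            f"grid: wound has {len(slots)} cell slots but {need} wound cells "
            "were requested")
    pick = rng.choice(len(slots), size=need, replace=False)
    blocks = []
    for rb, cb in slots[pick]:
        rr, cc = np.meshgrid(np.arange(rb, rb + cs), np.arange(cb, cb + cs),
                             indexing="ij")
        blocks.append(np.stack([rr.ravel(), cc.ravel()], axis=1))
    for k in range(g.macrophage_count):
        lat.new_cell(MACROPHAGE, blocks[k])
    for k in range(g.macrophage_count, need):
        cid = lat.new_cell(PRE_SENESCENT, blocks[k])
        lat.sen_clock[cid] = 0.0
        lat.sen_mech[cid] = 4  # MECH_PREEXISTING
        px = blocks[k]
        chem.inf[px[:, 0], px[:, 1]] = g.preexisting_inf_value

    lat.recount()
    seed = int(rng.integers(2**31 - 1))
    return Simulation(params, lat, chem, wound, seed, n_preexisting=n_pre)


def run_replicate(params: SimulationParams, config: ScenarioConfig,
                  seed: int, snapshot_hook=None) -> pd.DataFrame:
    """Run one replicate; returns its sampled TimeSeries.

    ``snapshot_hook(sim, day)`` is called at each of the standard snapshot
    days that fall inside the run (and at the final state).
    """
    rng = np.random.default_rng(seed)
    sim = build_initial_state(params, config, rng)
    total_mcs = params.units.days_to_mcs(config.duration_days)
    rows = [sim.sample()]
    snap_at = {params.units.days_to_mcs(d) for d in SNAPSHOT_DAYS
               if d <= config.duration_days}
    if snapshot_hook is not None and 0 in snap_at:
        snapshot_hook(sim, 0.0)
    next_sample = config.sample_period_mcs
    while sim.t_mcs < total_mcs:
        chunk = min(next_sample - sim.t_mcs, total_mcs - sim.t_mcs)
        sim.step(chunk)
        if sim.t_mcs >= next_sample:
            row = sim.sample()
            rows.append(row)
            next_sample += config.sample_period_mcs
            log.info(
                "%s seed=%d day %.2f: closure=%.2f senescent=%d "
                "inductions=%d cleared=%d",
                config.name, seed, row["day"], row["closure"],
                row["n_senescent"] + row["n_preexisting"],
                row["ind_primary"] + row["ind_juxtacrine"]
                + row["ind_paracrine"], row["cleared"])
        if snapshot_hook is not None:
            hits = [m for m in snap_at if sim.t_mcs - chunk < m <= sim.t_mcs]
            for m in hits:
                snapshot_hook(sim, params.units.mcs_to_days(m))
    if rows[-1]["mcs"] != sim.t_mcs:
        rows.append(sim.sample())
    df = pd.DataFrame(rows, columns=list(SAMPLE_COLUMNS))
    df.attrs["seed"] = seed
    df.attrs["scenario"] = config.name
    return df


def run_scenario(params: SimulationParams, config: ScenarioConfig,
                 snapshot_hook=None) -> list[pd.DataFrame]:
    """Run all replicates of a scenario (seeds seed, seed+1, ...)."""
    config.validate()
    return [run_replicate(params, config, config.seed + k,
                          snapshot_hook=snapshot_hook if k == 0 else None)
            for k in range(config.replicates)]


def wound_closure_fraction(lat: Lattice, wound_mask: np.ndarray) -> float:
    """Fraction of the t = 0 wound-mask pixels occupied by any cell.

    The wound-closure *rate* reported in time series is the per-sample
    difference of this fraction.
    """
    n = int(np.count_nonzero(wound_mask))
    if n == 0:
        raise ConfigError("wound mask is empty")
    return float(np.count_nonzero(lat.grid[wound_mask])) / n


@dataclass
class ClassifyParams:
    """End-state classification thresholds (calibrated so the five canonical
    scenarios map onto their labels; see docs/methods.md)."""

    fibrosis_factor: float = 1.25   # final ECM above baseline by this factor
    deficit_factor: float = 0.70    # final ECM below baseline by this factor
    inflammation_factor: float = 2.0  # final INF or macrophages above baseline
    inf_floor_fraction: float = 0.05  # floor for the INF baseline: fraction
                                      # of the baseline's peak INF


def classify_outcome(ts: pd.DataFrame, baseline_ts: pd.DataFrame,
                     thresholds: ClassifyParams | None = None) -> str:
    """Label an end state 'healthy', 'chronic' or 'fibrotic' by comparing
    day-18 (final) ECM, inflammation and macrophage levels to the healthy
    baseline run sampled on the same day grid."""
    th = thresholds or ClassifyParams()
    if len(ts) != len(baseline_ts) or not np.allclose(
            ts["day"].to_numpy(), baseline_ts["day"].to_numpy(), atol=1e-9):
        raise ConfigError("time series and baseline use different day grids")
    ecm_f = float(ts["n_ecm"].iloc[-1])
    ecm_b = float(baseline_ts["n_ecm"].iloc[-1])
    inf_f = float(ts["total_inf"].iloc[-1])
    inf_b = max(float(baseline_ts["total_inf"].iloc[-1]),
                th.inf_floor_fraction * float(baseline_ts["total_inf"].max()),
                1e-12)
    mac_f = float(ts["n_macrophage"].iloc[-1])
    mac_b = max(float(baseline_ts["n_macrophage"].iloc[-1]), 1.0)
    if ecm_f > th.fibrosis_factor * ecm_b:
        return "fibrotic"
    if (ecm_f < th.deficit_factor * ecm_b
            or inf_f > th.inflammation_factor * inf_b
            or mac_f > th.inflammation_factor * mac_b):
        return "chronic"
    return "healthy"
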