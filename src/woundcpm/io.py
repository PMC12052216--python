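"""File I/O: time-series tables, snapshot archives, rendered cell fields,
synthetic calibration curves and provenance records."""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import (CELL_TYPE_NAMES, ECM, FIBROBLAST, MACROPHAGE,
                     MYOFIBROBLAST, PRE_SENESCENT, SENESCENT, ConfigError,
                     SimulationParams)
from .simulation import SAMPLE_COLUMNS, Simulation


class TimeSeriesError(ValueError):
    pass


# --------------------------------------------------------------------------
# time series
# --------------------------------------------------------------------------

def write_timeseries(ts: pd.DataFrame, path) -> None:
    """Comma-delimited table, one row per sample; lossless float round-trip
    (shortest-repr formatting)."""
    missing = [c for c in SAMPLE_COLUMNS if c not in ts.columns]
    if missing:
        raise TimeSeriesError(f"time series is missing columns {missing}")
    ts.to_csv(path, index=False)


def read_timeseries(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise TimeSeriesError(f"{path}: cannot parse time series: {exc}") from exc
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise TimeSeriesError(
            f"{path}: malformed time series, missing columns {missing}")
    for i, col in enumerate(df.columns):
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col].map(lambda v: not isinstance(v, (int, float))).idxmax()
            raise TimeSeriesError(
                f"{path}: non-numeric value in column '{col}' "
                f"(data line {bad + 2})")
    return df


# --------------------------------------------------------------------------
# snapshots and rendering
# --------------------------------------------------------------------------

def params_hash(params: SimulationParams) -> str:
    blob = json.dumps(params.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def save_snapshot(sim: Simulation, path) -> None:
    """Compressed array archive (cell-id grid, per-cell table, four fields)
    plus a JSON metadata sidecar (seed, MCS, parameter hash)."""
    lat = sim.lattice
    n = lat.n_ids
    np.savez_compressed(
        path,
        grid=lat.grid,
        fields=sim.chem.data,
        wound_mask=sim.wound_mask,
        cell_type=lat.ctype[:n],
        volume=lat.volume[:n],
        target_volume=lat.tvol[:n],
        activated=lat.activated[:n],
        m1=lat.m1[:n],
        senescence_clock_mcs=lat.sen_clock[:n],
        senescence_mechanism=lat.sen_mech[:n],
    )
    meta = {"seed": sim.seed, "mcs": sim.t_mcs, "day": sim.day,
            "params_hash": params_hash(sim.params),
            "counters": sim.counters}
    sidecar = str(path)
    sidecar = sidecar[:-4] if sidecar.endswith(".npz") else sidecar
    with open(sidecar + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


#: cell-field palette: fibroblast blue, myofibroblast green, macrophage
#: brown, ECM yellow, senescent myofibroblast pink, pre-existing senescent
#: red; Medium white.
PALETTE = {
    0: (1.00, 1.00, 1.00),
    FIBROBLAST: (0.12, 0.30, 0.85),
    MYOFIBROBLAST: (0.15, 0.65, 0.25),
    MACROPHAGE: (0.55, 0.35, 0.15),
    SENESCENT: (0.95, 0.55, 0.75),
    PRE_SENESCENT: (0.85, 0.10, 0.10),
    ECM: (0.92, 0.85, 0.25),
}


def render_cell_field(sim: Simulation, path) -> None:
    """PNG of the cell field using the standard palette."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lat = sim.lattice
    img = np.zeros(lat.grid.shape + (3,))
    types = lat.ctype[lat.grid]
    for t, rgb in PALETTE.items():
        img[types == t] = rgb
    plt.imsave(path, img)


def write_provenance(path, params: SimulationParams, seeds, extra=None) -> None:
    """JSON provenance sidecar for a CLI run."""
    from . import __version__
    rec = {"package": "woundcpm", "version": __version__,
           "params_hash": params_hash(params),
           "seeds": list(np.atleast_1d(seeds).tolist())}
    if extra:
        rec.update(extra)
    with open(path, "w") as fh:
        json.dump(rec, fh, indent=1)


# --------------------------------------------------------------------------
# synthetic calibration curves
# --------------------------------------------------------------------------

@dataclass
class CurveSpec:
    """Shape specification for one synthetic calibration curve.

    ``kind`` is one of ``peak`` (log-normal-shaped pulse), ``logistic``
    (saturating rise from ``base`` to ``base + amplitude``) or
    ``double_plateau`` (fast rise to a first plateau, partial drop to a
    second).  Days and amplitudes are in simulation units (days, cells or
    field totals).
    """

    kind: str = "peak"
    peak_day: float = 4.0
    amplitude: float = 1.0
    base: float = 0.0
    width: float = 0.45        # log-sigma of the peak / logistic steepness
    drop_day: float = 7.0      # double_plateau: day of the partial drop
    drop_fraction: float = 0.5  # double_plateau: second/first plateau ratio


#: default landmark curves: myofibroblasts peak near day 4, senescent
#: myofibroblasts near day 7, macrophages plateau at ~2x initial near day
#: 3.5, ECM rises sharply then settles on a lower second plateau after ~day
#: 7, fibroblasts rise steadily over days 1-5.
DEFAULT_CURVE_SPECS = {
    "fibroblasts": CurveSpec(kind="logistic", peak_day=3.0, amplitude=140.0,
                             base=200.0, width=1.2),
    "myofibroblasts": CurveSpec(kind="peak", peak_day=4.0, amplitude=60.0,
                                width=0.45),
    "senescent_myofibroblasts": CurveSpec(kind="peak", peak_day=7.0,
                                          amplitude=25.0, width=0.40),
    "macrophages": CurveSpec(kind="logistic", peak_day=2.0, amplitude=30.0,
                             base=30.0, width=1.5),
    "ecm": CurveSpec(kind="double_plateau", peak_day=1.5, amplitude=9000.0,
                     width=1.8, drop_day=7.0, drop_fraction=0.5),
    "closure_rate": CurveSpec(kind="peak", peak_day=3.0, amplitude=0.35,
                              width=0.55),
}


def _eval_curve(spec: CurveSpec, days: np.ndarray) -> np.ndarray:
    d = np.asarray(days, float)
    if spec.kind == "peak":
        t = np.maximum(d, 1e-6)
        y = np.exp(-0.5 * (np.log(t / spec.peak_day) / spec.width) ** 2)
        vals = spec.base + spec.amplitude * y
    elif spec.kind == "logistic":
        vals = spec.base + spec.amplitude / (
            1.0 + np.exp(-spec.width * (d - spec.peak_day)))
    elif spec.kind == "double_plateau":
        rise = 1.0 / (1.0 + np.exp(-spec.width * (d - spec.peak_day)))
        drop = 1.0 / (1.0 + np.exp(-spec.width * (d - spec.drop_day)))
        vals = spec.base + spec.amplitude * rise * (
            1.0 - (1.0 - spec.drop_fraction) * drop)
    else:
        raise ConfigError(f"curve kind '{spec.kind}' unknown")
    return vals


def generate_calibration_curves(specs: dict | None = None,
                                days: np.ndarray | None = None,
                                ) -> pd.DataFrame:
    """Synthetic calibration curves emulating peaked/saturating literature
    time courses for the six calibration observables.

    These curves deliberately replace re-digitised literature data: they are
    parameterised stand-ins with the qualitative landmarks of healthy
    healing, not measurements.  Returns a wide table with a ``day`` column.
    """
    specs = dict(DEFAULT_CURVE_SPECS, **(specs or {}))
    if days is None:
        days = np.arange(0.0, 18.0 + 1e-9, 0.25)
    days = np.asarray(days, float)
    if np.any(np.diff(days) <= 0):
        raise ConfigError("calibration days must be strictly increasing")
    out = {"day": days}
    for name, spec in specs.items():
        vals = _eval_curve(spec, days)
        if np.any(vals < 0):
            raise ConfigError(f"curve '{name}' produced negative values")
        out[name] = vals
    return pd.DataFrame(out)


def write_calibration_curves(curves: pd.DataFrame, path) -> None:
    curves.to_csv(path, index=False)


def read_calibration_curves(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if "day" not in df.columns:
        raise ConfigError(f"{path}: calibration table needs a 'day' column")
    if np.any(np.diff(df["day"].to_numpy()) <= 0):
        raise ConfigError(f"{path}: days must be strictly increasing")
    if np.any(df.drop(columns="day").to_numpy() < 0):
        raise ConfigError(f"{path}: calibration values must be >= 0")
    return df


def curves_to_targets(curves: pd.DataFrame) -> dict:
    """Convert a calibration table to the target-dict form used by
    :func:`woundcpm.sweep.objective_relative_error`."""
    days = curves["day"].to_numpy()
    return {name: (days, curves[name].to_numpy(dtype=float))
            for name in curves.columns if name != "day"}
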