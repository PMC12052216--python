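"""Shared fixtures and lattice-building helpers for the test suite."""
from __future__ import annotations

import numpy as np
import pytest

from woundcpm.engine import Lattice
from woundcpm.params import (ECM, FIBROBLAST, MACROPHAGE, MYOFIBROBLAST,
                             SENESCENT, EnergyParams, SimulationParams,
                             baseline_params)


@pytest.fixture
def params() -> SimulationParams:
    return baseline_params()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def zero_energy() -> EnergyParams:
    """Energy parameters with every coefficient zero (dH == 0 for any copy)."""
    e = EnergyParams()
    e.contact = np.zeros_like(np.asarray(e.contact, float))
    e.lambda_volume = np.zeros(7)
    e.lambda_surface = np.zeros(7)
    e.chem_lambda = np.zeros(7)
    e.chem_lambda_ecm = np.zeros(7)
    return e


def lattice_from_grid(grid: np.ndarray, type_of_id: dict[int, int],
                      energy: EnergyParams | None = None) -> Lattice:
    """Build a lattice directly from an id grid (fast path for fixtures).

    ``type_of_id`` maps each nonzero id in ``grid`` to its cell type; energy
    defaults (target volume, lambdas) are taken from ``energy``.
    """
    grid = np.asarray(grid, dtype=np.int32)
    H, W = grid.shape
    energy = energy if energy is not None else EnergyParams()
    lat = Lattice(W, H, energy)
    max_id = int(grid.max())
    lat._ensure(max_id + 1)
    lat.n_ids = max_id + 1
    lat.grid[:] = grid
    for cid, ct in type_of_id.items():
        lat.ctype[cid] = ct
        lat.tvol[cid] = energy.target_volume[ct]
        lat.vt0[cid] = lat.tvol[cid]
        lat.lamv[cid] = energy.lambda_volume[ct]
        lat.tsurf[cid] = energy.target_surface[ct]
        lat.lams[cid] = energy.lambda_surface[ct]
    lat.recount()
    return lat


def random_lattice(rng: np.random.Generator, size: int = 6, n_cells: int = 3,
                   energy: EnergyParams | None = None,
                   with_ecm: bool = False) -> Lattice:
    """Random multi-cell lattice for oracle tests: blobs of a few cell types
    (optionally with scattered one-pixel ECM cells)."""
    grid = np.zeros((size, size), dtype=np.int32)
    types = {}
    cid = 1
    for _ in range(n_cells):
        r, c = rng.integers(size, size=2)
        for _ in range(rng.integers(2, 6)):
            rr = int(np.clip(r + rng.integers(-1, 2), 0, size - 1))
            cc = int(np.clip(c + rng.integers(-1, 2), 0, size - 1))
            grid[rr, cc] = cid
        if np.any(grid == cid):
            types[cid] = int(rng.choice(
                [FIBROBLAST, MYOFIBROBLAST, MACROPHAGE, SENESCENT]))
            cid += 1
    if with_ecm:
        for _ in range(rng.integers(1, 4)):
            r, c = rng.integers(size, size=2)
            if grid[r, c] == 0:
                grid[r, c] = cid
                types[cid] = ECM
                cid += 1
    # drop ids that were fully overwritten while blobs were painted
    types = {c: t for c, t in types.items() if np.any(grid == c)}
    return lattice_from_grid(grid, types, energy)
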