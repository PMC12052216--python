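"""Cellular Potts lattice mechanics.

A :class:`Lattice` holds the integer cell-id grid plus per-cell caches
(volume, surface, centre of mass, medium/ECM contact) and per-cell state
used by the behaviour rules.  Module-level functions implement the CPM
operations: effective-energy deltas, Metropolis pixel-copy attempts,
Monte-Carlo steps, contact surfaces and the medium-surface ratio Rs used
for contact inhibition.

The effective energy is

    H = sum_pairs J(tau, tau') (1 - delta(sigma, sigma'))
      + sum_cells lambda_vol (v - V_t)^2 + lambda_surf (s - S_t)^2

with a chemotaxis bias -lambda_chem * (c(target) - c(source)) added to dH
when a copy extends a chemotacting cell.  Copies are accepted with
probability min(1, exp(-dH / T_m)).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .params import (CELL_TYPE_NAMES, ECM, FIBROBLAST, MECH_NONE, MEDIUM,
                     N_TYPES, EnergyParams, SimulationParams)

_GROW_TYPES = (1, 2, 3)  # Fibroblast, Myofibroblast, Macrophage


class LatticeError(ValueError):
    pass


@dataclass
class CellRecord:
    """Read-only snapshot of one generalized cell (a view row of the
    lattice's per-cell arrays)."""

    id: int
    cell_type: int
    volume: int
    surface: int
    target_volume: float
    lambda_volume: float
    com: tuple[float, float]
    activated: bool
    m1: bool
    senescence_clock_mcs: float
    senescence_mechanism: int
    growth_frozen: bool

    @property
    def type_name(self) -> str:
        return CELL_TYPE_NAMES[self.cell_type]


class Lattice:
    """Cell-id grid with coherent per-cell caches.

    Caches are updated incrementally by the Metropolis kernel and may be
    rebuilt from scratch with :meth:`recount` (done at every behaviour
    sweep); coherence of the two paths is property-tested.
    """

    def __init__(self, width: int, height: int, energy: EnergyParams):
        self.width = int(width)
        self.height = int(height)
        self.energy = energy
        self.grid = np.zeros((self.height, self.width), dtype=np.int32)
        self._cap = 1024
        self.n_ids = 1  # id 0 is Medium
        self.free_ids: list[int] = []   # retired ids available for reuse
        self._alloc()
        self.ctype[0] = MEDIUM

    def _alloc(self):
        c = self._cap
        self.ctype = np.zeros(c, dtype=np.int8)
        self.volume = np.zeros(c, dtype=np.int64)
        self.surface = np.zeros(c, dtype=np.int64)
        self.tvol = np.zeros(c, dtype=np.float64)
        self.lamv = np.zeros(c, dtype=np.float64)
        self.tsurf = np.zeros(c, dtype=np.float64)
        self.lams = np.zeros(c, dtype=np.float64)
        self.sumr = np.zeros(c, dtype=np.float64)
        self.sumc = np.zeros(c, dtype=np.float64)
        self.med_contact = np.zeros(c, dtype=np.int64)
        self.ecm_contact = np.zeros(c, dtype=np.int64)
        # behavioural state
        self.vt0 = np.zeros(c, dtype=np.float64)       # original target volume
        self.activated = np.zeros(c, dtype=bool)
        self.m1 = np.zeros(c, dtype=bool)
        self.sen_clock = np.full(c, -1.0)              # MCS since induction
        self.sen_mech = np.zeros(c, dtype=np.int8)
        self.frozen = np.zeros(c, dtype=bool)

    _ARRAYS = ("ctype", "volume", "surface", "tvol", "lamv", "tsurf", "lams",
               "sumr", "sumc", "med_contact", "ecm_contact", "vt0",
               "activated", "m1", "sen_clock", "sen_mech", "frozen")

    def _ensure(self, n: int):
        if n <= self._cap:
            return
        new_cap = self._cap
        while new_cap < n:
            new_cap *= 2
        for name in self._ARRAYS:
            old = getattr(self, name)
            arr = np.zeros(new_cap, dtype=old.dtype)
            if name == "sen_clock":
                arr[:] = -1.0
            arr[:self._cap] = old
            setattr(self, name, arr)
        self._cap = new_cap

    # ---- cell management -------------------------------------------------

    def acquire_id(self) -> int:
        """Fresh cell id: recycles retired ids to keep the id space (and all
        per-id passes) bounded by the peak live-cell count."""
        if self.free_ids:
            cid = self.free_ids.pop()
        else:
            cid = self.n_ids
            self._ensure(cid + 1)
            self.n_ids += 1
        self._reset_id(cid)
        return cid

    def _reset_id(self, cid: int):
        for name in self._ARRAYS:
            getattr(self, name)[cid] = 0
        self.sen_clock[cid] = -1.0

    def release_id(self, cid: int):
        """Retire a cell record whose pixels have all been cleared."""
        if self.volume[cid] != 0:
            raise LatticeError(f"cannot release live cell {cid}")
        self.ctype[cid] = MEDIUM
        self.sen_clock[cid] = -1.0
        self.free_ids.append(int(cid))

    def new_cell(self, cell_type: int, pixels, target_volume=None) -> int:
        """Create a cell occupying ``pixels`` (iterable of (row, col)).

        Pixels must currently be Medium.  Energy defaults (target volume,
        lambdas) come from the lattice's :class:`EnergyParams`.
        """
        pixels = np.atleast_2d(np.asarray(pixels, dtype=np.int64))
        if pixels.shape[0] == 0:
            raise LatticeError("a cell needs at least one pixel")
        if np.any(self.grid[pixels[:, 0], pixels[:, 1]] != 0):
            raise LatticeError("new_cell: target pixels are not Medium")
        cid = self.acquire_id()
        e = self.energy
        self.ctype[cid] = cell_type
        self.tvol[cid] = (e.target_volume[cell_type]
                          if target_volume is None else target_volume)
        self.vt0[cid] = self.tvol[cid]
        self.lamv[cid] = e.lambda_volume[cell_type]
        self.tsurf[cid] = e.target_surface[cell_type]
        self.lams[cid] = e.lambda_surface[cell_type]
        self.grid[pixels[:, 0], pixels[:, 1]] = cid
        self._recount_cell_patch(pixels)
        return cid

    def remove_cell(self, cid: int):
        """Turn all pixels of ``cid`` into Medium and retire the record."""
        self._check_id(cid)
        pixels = np.argwhere(self.grid == cid)
        self.grid[pixels[:, 0], pixels[:, 1]] = 0
        self.volume[cid] = 0
        self.surface[cid] = 0
        self.release_id(cid)
        self._recount_cell_patch(pixels)

    def _recount_cell_patch(self, pixels):
        """Cheap local fix-up: full recount (vectorised kernel) — adding or
        removing cells happens only at behaviour sweeps / setup, where a full
        recount is performed anyway, so just do it."""
        self.recount()

    def recount(self):
        _kernels.recount_caches(self.grid, self.ctype, self.volume,
                                self.surface, self.sumr, self.sumc,
                                self.med_contact, self.ecm_contact)

    # ---- queries ---------------------------------------------------------

    def _check_id(self, cid: int):
        if not (0 < cid < self.n_ids) or self.volume[cid] <= 0:
            raise LatticeError(f"unknown or empty cell id {cid}")

    def alive_ids(self) -> np.ndarray:
        ids = np.arange(1, self.n_ids)
        return ids[self.volume[1:self.n_ids] > 0]

    def record(self, cid: int) -> CellRecord:
        self._check_id(cid)
        return CellRecord(
            id=cid, cell_type=int(self.ctype[cid]),
            volume=int(self.volume[cid]), surface=int(self.surface[cid]),
            target_volume=float(self.tvol[cid]),
            lambda_volume=float(self.lamv[cid]),
            com=com(self, cid),
            activated=bool(self.activated[cid]), m1=bool(self.m1[cid]),
            senescence_clock_mcs=float(self.sen_clock[cid]),
            senescence_mechanism=int(self.sen_mech[cid]),
            growth_frozen=bool(self.frozen[cid]))

    def type_counts(self) -> np.ndarray:
        """Number of live cells of each type (length N_TYPES; index 0 unused)."""
        counts = np.zeros(N_TYPES, dtype=np.int64)
        ids = self.alive_ids()
        if len(ids):
            counts += np.bincount(self.ctype[ids], minlength=N_TYPES)
        return counts

    def pixels_of(self, cid: int) -> np.ndarray:
        self._check_id(cid)
        return np.argwhere(self.grid == cid)


# --------------------------------------------------------------------------
# CPM operations
# --------------------------------------------------------------------------

def _kernel_args(lat: Lattice, fields: np.ndarray):
    e = lat.energy
    return (lat.grid, lat.ctype, lat.volume, lat.surface, lat.tvol, lat.lamv,
            lat.tsurf, lat.lams, lat.ecm_contact,
            np.ascontiguousarray(e.contact, dtype=np.float64),
            float(e.temperature),
            np.ascontiguousarray(e.chem_field, dtype=np.int64),
            np.ascontiguousarray(e.chem_lambda, dtype=np.float64),
            np.ascontiguousarray(e.chem_lambda_ecm, dtype=np.float64),
            fields)


def delta_energy(lat: Lattice, fields: np.ndarray,
                 source_pixel, target_pixel) -> float:
    """dH of copying the cell id at ``source_pixel`` onto ``target_pixel``.

    The two pixels must be lattice neighbours carrying different ids.
    ``fields`` is the (4, H, W) chemical-field array (zeros disable
    chemotaxis).
    """
    sr, sc = map(int, source_pixel)
    tr, tc = map(int, target_pixel)
    H, W = lat.grid.shape
    for (r, c) in ((sr, sc), (tr, tc)):
        if not (0 <= r < H and 0 <= c < W):
            raise LatticeError(f"pixel ({r}, {c}) outside the {H}x{W} lattice")
    if max(abs(sr - tr), abs(sc - tc)) != 1:
        raise LatticeError("source and target must be lattice neighbours")
    if lat.grid[sr, sc] == lat.grid[tr, tc]:
        raise LatticeError("source and target pixels carry the same cell id")
    args = _kernel_args(lat, fields)
    return float(_kernels.delta_h(*args, sr, sc, tr, tc))


def attempt_pixel_copy(lat: Lattice, fields: np.ndarray,
                       rng: np.random.Generator) -> bool:
    """One Metropolis pixel-copy attempt; returns True if a copy happened."""
    H, W = lat.grid.shape
    tr = int(rng.integers(H))
    tc = int(rng.integers(W))
    k = int(rng.integers(4))
    sr, sc = tr + int(_kernels._N4R[k]), tc + int(_kernels._N4C[k])
    if not (0 <= sr < H and 0 <= sc < W):
        return False
    s_id = int(lat.grid[sr, sc])
    if s_id == lat.grid[tr, tc]:
        return False
    dH = float(_kernels.delta_h(*_kernel_args(lat, fields), sr, sc, tr, tc))
    if dH <= 0.0 or rng.random() < np.exp(-dH / lat.energy.temperature):
        _kernels.apply_copy(lat.grid, lat.ctype, lat.volume, lat.surface,
                            lat.tvol, lat.sumr, lat.sumc, lat.med_contact,
                            lat.ecm_contact, tr, tc, s_id)
        return True
    return False


def run_mcs(lat: Lattice, fields: np.ndarray, rng: np.random.Generator,
            n_mcs: int = 1) -> int:
    """Run ``n_mcs`` Monte-Carlo steps (width x height attempts each).

    Returns the number of accepted copies.  Randomness is drawn from a
    kernel stream seeded per call from ``rng`` (deterministic for a given
    generator state).
    """
    accepted = 0
    args = _kernel_args(lat, fields)
    n_attempts = lat.width * lat.height
    for _ in range(int(n_mcs)):
        seed = int(rng.integers(2**31 - 1))
        accepted += _kernels.run_attempts(
            args[0], args[1], args[2], args[3], args[4], args[5], args[6],
            args[7], lat.sumr, lat.sumc, lat.med_contact, args[8],
            args[9], args[10], args[11], args[12], args[13], args[14],
            n_attempts, seed)
    return accepted


def contact_surface(lat: Lattice, cid: int, other: int) -> int:
    """Boundary pixel-pair count between cell ``cid`` and pixels of type
    ``other`` (a cell-type code; MEDIUM counts contact with Medium)."""
    lat._check_id(cid)
    mask = lat.grid == cid
    H, W = lat.grid.shape
    count = 0
    for dr, dc in zip(_kernels._M8R, _kernels._M8C):
        r0, r1 = max(0, dr), min(H, H + dr)
        c0, c1 = max(0, dc), min(W, W + dc)
        sub = mask[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
        nb = lat.grid[r0:r1, c0:c1]
        if other == MEDIUM:
            hit = nb == 0
        else:
            hit = (lat.ctype[nb] == other) & (nb != cid)
        count += int(np.count_nonzero(sub & hit))
    return count


def medium_surface_ratio(lat: Lattice, cid: int) -> float:
    """Rs = s(sigma)_medium / s(sigma): the fraction of a cell's boundary
    pairs that touch Medium.  1 for an isolated cell, 0 when fully
    enclosed by other cells."""
    lat._check_id(cid)
    s = int(lat.surface[cid])
    if s == 0:
        raise LatticeError(f"cell {cid} has zero surface (degenerate)")
    return float(lat.med_contact[cid]) / s


def com(lat: Lattice, cid: int) -> tuple[float, float]:
    """Centre of mass (row, col) of a cell: the mean of its pixel coords."""
    lat._check_id(cid)
    v = lat.volume[cid]
    return (float(lat.sumr[cid]) / v, float(lat.sumc[cid]) / v)


def free_cell_speed(params: SimulationParams, n_mcs: int = 10_000,
                    seeds=(0, 1, 2, 3, 4), lattice_size: int = 50,
                    burn_in: int = 500) -> float:
    """Mean per-MCS centre-of-mass displacement of one unconstrained cell.

    A single cell of baseline size is placed on an otherwise empty lattice
    with baseline energy parameters and no chemoattractant; the reported
    speed is |dCOM| per MCS averaged over ``n_mcs`` steps (after burn-in)
    and over seeds.  The baseline parameters are calibrated so this is
    ~0.1 pixel/MCS (0.3 um/MCS), the reference motility anchoring the
    27 s/MCS time conversion.
    """
    side = int(np.sqrt(params.energy.target_volume[FIBROBLAST]))
    speeds = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        lat = Lattice(lattice_size, lattice_size, params.energy)
        lo = (lattice_size - side) // 2
        px = [(r, c) for r in range(lo, lo + side)
              for c in range(lo, lo + side)]
        cid = lat.new_cell(FIBROBLAST, px)
        fields = np.zeros((4, lattice_size, lattice_size))
        run_mcs(lat, fields, rng, burn_in)
        prev = com(lat, cid)
        disp = np.empty(n_mcs)
        for k in range(n_mcs):
            run_mcs(lat, fields, rng)
            cur = com(lat, cid)
            disp[k] = np.hypot(cur[0] - prev[0], cur[1] - prev[1])
            prev = cur
        speeds.append(disp.mean())
    return float(np.mean(speeds))


# --------------------------------------------------------------------------
# brute-force oracles (used by tests; kept here so they share the type codes)
# --------------------------------------------------------------------------

def total_energy(lat: Lattice) -> float:
    """Brute-force effective energy of the whole lattice: all Moore contact
    pairs (each unordered pair once) plus the volume and surface constraints.
    Chemotaxis contributes no configurational energy."""
    grid = lat.grid
    H, W = grid.shape
    J = np.asarray(lat.energy.contact, float)
    E = 0.0
    for dr, dc in ((0, 1), (1, -1), (1, 0), (1, 1)):  # each pair once
        r0, r1 = max(0, dr), min(H, H + dr)
        c0, c1 = max(0, dc), min(W, W + dc)
        a = grid[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
        b = grid[r0:r1, c0:c1]
        diff = a != b
        E += float(np.sum(J[lat.ctype[a[diff]], lat.ctype[b[diff]]]))
    # constraint terms persist for cells driven to zero volume (the cell
    # record still exists until a behaviour sweep buries it), matching the
    # incremental formula
    for cid in range(1, lat.n_ids):
        if lat.ctype[cid] == 0:
            continue
        E += lat.lamv[cid] * (lat.volume[cid] - lat.tvol[cid]) ** 2
        if lat.lams[cid] != 0.0:
            s = contact_surface_total(lat, cid)
            E += lat.lams[cid] * (s - lat.tsurf[cid]) ** 2
    return E


def contact_surface_total(lat: Lattice, cid: int) -> int:
    """Brute-force recount of a cell's total boundary pair count."""
    mask = lat.grid == cid
    H, W = lat.grid.shape
    count = 0
    for dr, dc in zip(_kernels._M8R, _kernels._M8C):
        r0, r1 = max(0, dr), min(H, H + dr)
        c0, c1 = max(0, dc), min(W, W + dc)
        sub = mask[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
        nb = lat.grid[r0:r1, c0:c1] != cid
        count += int(np.count_nonzero(sub & nb))
    return count
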