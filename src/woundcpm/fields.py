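"""The four diffusible species: PDGF, CSF1, MMP and inflammatory SASP.

Each field obeys  dc/dt = D lap(c) - delta c + S  with no-flux borders,
integrated by forward Euler (5-point Laplacian, clamped-index boundaries)
with automatic sub-stepping to satisfy D*dt <= 1/4.  Fields ignore cell
boundaries entirely — species diffuse across cells — and secretion is
deposited uniformly over all pixels of the secreting cell, so the per-cell
rate does not scale with cell size.

Secretion rules (who secretes what):

* M2 macrophages secrete PDGF; M1 macrophages secrete MMP; any macrophage
  touching ECM additionally secretes MMP.
* Activated fibroblasts secrete CSF1 only while sharing surface with a
  macrophage; myofibroblasts secrete PDGF always and CSF1 under the same
  macrophage-contact gate.
* Senescent cells in the fibrogenic SASP phase secrete PDGF; in the
  fibrolytic phase (and pre-existing inflammatory senescent cells always)
  they secrete CSF1, inflammation and MMP.
"""
from __future__ import annotations

import numpy as np

from . import _kernels
from .engine import Lattice
from .params import (CSF1, ECM, FIBROBLAST, INF, MACROPHAGE, MEDIUM, MMP,
                     MYOFIBROBLAST, N_FIELDS, PDGF, PRE_SENESCENT, SENESCENT,
                     FieldParams, SimulationParams)


class ChemFields:
    """Non-negative scalar fields co-registered with the lattice."""

    def __init__(self, height: int, width: int, data: np.ndarray | None = None):
        if data is None:
            data = np.zeros((N_FIELDS, height, width))
        data = np.asarray(data, dtype=np.float64)
        if data.shape != (N_FIELDS, height, width):
            raise ValueError("field array must have shape (4, height, width)")
        if np.any(data < 0):
            raise ValueError("field values must be non-negative")
        self.data = data

    @property
    def pdgf(self): return self.data[PDGF]
    @property
    def csf1(self): return self.data[CSF1]
    @property
    def mmp(self): return self.data[MMP]
    @property
    def inf(self): return self.data[INF]


def step_fields(fields: ChemFields, secretion_map: np.ndarray,
                field_params: FieldParams) -> ChemFields:
    """Advance all four fields by one MCS (in place; also returned).

    ``secretion_map`` is a (4, H, W) array of non-negative per-pixel
    deposition rates for this MCS.
    """
    if np.any(secretion_map < 0):
        raise ValueError("secretion map must be non-negative")
    substeps = field_params.resolved_substeps()
    _kernels.step_fields(
        fields.data,
        np.ascontiguousarray(field_params.diffusion, dtype=np.float64),
        np.ascontiguousarray(field_params.decay, dtype=np.float64),
        np.ascontiguousarray(secretion_map, dtype=np.float64),
        substeps)
    return fields


def build_secretion_map(lat: Lattice, params: SimulationParams,
                        fibro_phase: np.ndarray | None = None) -> np.ndarray:
    """Per-pixel secretion rates for each field, (4, H, W).

    ``fibro_phase`` is the per-id boolean "senescent cell is in its
    fibrogenic SASP phase" (computed from the senescence clock by
    :func:`woundcpm.behaviors.sasp_phases`); if omitted it is derived here.
    Each cell's rate is split uniformly over its pixels.
    """
    from .behaviors import sasp_phases  # local import to avoid a cycle
    n = lat.n_ids
    s = params.fields.secretion
    if fibro_phase is None:
        fibro_phase = sasp_phases(lat, params)
    rate = np.zeros((n, N_FIELDS))
    ct = lat.ctype[:n]
    alive = lat.volume[:n] > 0

    mac = alive & (ct == MACROPHAGE)
    rate[mac & ~lat.m1[:n], PDGF] += s.mac_pdgf
    rate[mac & lat.m1[:n], MMP] += s.mac_mmp
    rate[mac & (lat.ecm_contact[:n] > 0), MMP] += s.mac_mmp

    mac_touch = _macrophage_contact(lat) > 0
    fib = alive & (ct == FIBROBLAST) & lat.activated[:n]
    rate[fib & mac_touch, CSF1] += s.fib_csf1
    myo = alive & (ct == MYOFIBROBLAST)
    rate[myo, PDGF] += s.myo_pdgf
    rate[myo & mac_touch, CSF1] += s.myo_csf1

    sen = alive & (ct == SENESCENT)
    pre = alive & (ct == PRE_SENESCENT)
    fibro = sen & fibro_phase[:n]
    lytic = (sen & ~fibro_phase[:n]) | pre
    rate[fibro, PDGF] += s.sen_pdgf
    rate[lytic, CSF1] += s.sen_csf1
    rate[lytic, INF] += s.sen_inf
    rate[lytic, MMP] += s.sen_mmp

    # per-pixel rate = per-cell rate / volume, scattered through the grid
    vol = np.maximum(lat.volume[:n], 1)
    per_pixel = np.ascontiguousarray(rate / vol[:, None])
    return _kernels.gather_secretion(lat.grid, per_pixel)


def _macrophage_contact(lat: Lattice) -> np.ndarray:
    """Per-id boundary-pair count with macrophage pixels (Moore pairs)."""
    n = lat.n_ids
    code = np.where(lat.ctype[:n] == MACROPHAGE, 1, 0).astype(np.int64)
    counts = _kernels.contact_counts(lat.grid, code, n, 2)
    return counts[:, 1]


def field_at_com(field: np.ndarray, com: tuple[float, float]) -> float:
    """Field value at the pixel containing a centre of mass.

    Nearest-pixel convention with round half up in both coordinates.
    """
    r = int(np.floor(com[0] + 0.5))
    c = int(np.floor(com[1] + 0.5))
    H, W = field.shape
    if not (0 <= r < H and 0 <= c < W):
        raise ValueError(f"COM {com} maps outside the {H}x{W} field")
    return float(field[r, c])


def total_field(field: np.ndarray) -> float:
    """Total amount of a field: the sum over all pixels."""
    return float(np.sum(field))
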