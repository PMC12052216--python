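"""Simulation driver: couples the CPM lattice, the diffusible fields and the
behaviour rules into one clocked replicate.

Per MCS: one Monte-Carlo step of pixel-copy attempts, then one field step
(secretion built from the current cell states and pixel occupancy), then the
per-MCS growth/mitosis pass; every ``sweep_period_mcs`` MCS the full
behaviour sweep runs.  Time-series rows are sampled every ``sample_period``
MCS.
"""
from __future__ import annotations

import numpy as np

from . import _kernels, behaviors, engine, fields
from .params import (ECM, FIBROBLAST, MACROPHAGE, MYOFIBROBLAST,
                     PRE_SENESCENT, SENESCENT, SimulationParams)

_GROW = (FIBROBLAST, MYOFIBROBLAST, MACROPHAGE)

SAMPLE_COLUMNS = (
    "day", "mcs", "n_fibroblast", "n_myofibroblast", "n_macrophage",
    "n_senescent", "n_preexisting", "n_ecm", "total_pdgf", "total_csf1",
    "total_mmp", "total_inf", "closure", "ind_primary", "ind_juxtacrine",
    "ind_paracrine", "ind_preexisting", "cleared")


class Simulation:
    """One seeded replicate of the wound-healing model."""

    def __init__(self, params: SimulationParams, lattice: engine.Lattice,
                 chem: fields.ChemFields, wound_mask: np.ndarray,
                 seed: int, n_preexisting: int = 0):
        self.params = params
        self.lattice = lattice
        self.chem = chem
        self.wound_mask = wound_mask
        self.rng = np.random.default_rng(seed)
        self.seed = seed
        self.t_mcs = 0
        self.counters = {"primary": 0, "juxtacrine": 0, "paracrine": 0,
                         "preexisting": n_preexisting, "cleared": 0}
        fp = params.fields
        self._substeps = fp.resolved_substeps()
        self._diffusion = np.ascontiguousarray(fp.diffusion, dtype=np.float64)
        self._decay = np.ascontiguousarray(fp.decay, dtype=np.float64)
        self._refresh_growth_ids()

    def _refresh_growth_ids(self):
        lat = self.lattice
        n = lat.n_ids
        mask = (lat.volume[:n] > 0) & np.isin(lat.ctype[:n], _GROW)
        self.growth_ids = np.flatnonzero(mask)

    def step(self, n_mcs: int = 1):
        """Advance the simulation by ``n_mcs`` Monte-Carlo steps."""
        lat, chem, p = self.lattice, self.chem, self.params
        period = p.behavior.sweep_period_mcs
        for _ in range(int(n_mcs)):
            engine.run_mcs(lat, chem.data, self.rng)
            sec = fields.build_secretion_map(lat, p)
            _kernels.step_fields(chem.data, self._diffusion, self._decay,
                                 sec, self._substeps)
            events = behaviors.growth_step(lat, chem, p, self.growth_ids,
                                           self.rng)
            if events:
                self._refresh_growth_ids()
            self.t_mcs += 1
            if self.t_mcs % period == 0:
                behaviors.behavior_sweep(lat, chem, p, self.rng, self.t_mcs,
                                         self.wound_mask, self.counters)
                self._refresh_growth_ids()

    @property
    def day(self) -> float:
        return self.params.units.mcs_to_days(self.t_mcs)

    def closure_fraction(self) -> float:
        from .scenarios import wound_closure_fraction
        return wound_closure_fraction(self.lattice, self.wound_mask)

    def sample(self) -> dict:
        """One time-series row: cell counts, total field amounts, cumulative
        senescence inductions by mechanism and wound-closure fraction."""
        lat, chem = self.lattice, self.chem
        counts = lat.type_counts()
        return {
            "day": self.day,
            "mcs": self.t_mcs,
            "n_fibroblast": int(counts[FIBROBLAST]),
            "n_myofibroblast": int(counts[MYOFIBROBLAST]),
            "n_macrophage": int(counts[MACROPHAGE]),
            "n_senescent": int(counts[SENESCENT]),
            "n_preexisting": int(counts[PRE_SENESCENT]),
            "n_ecm": int(counts[ECM]),
            "total_pdgf": fields.total_field(chem.pdgf),
            "total_csf1": fields.total_field(chem.csf1),
            "total_mmp": fields.total_field(chem.mmp),
            "total_inf": fields.total_field(chem.inf),
            "closure": self.closure_fraction(),
            "ind_primary": self.counters["primary"],
            "ind_juxtacrine": self.counters["juxtacrine"],
            "ind_paracrine": self.counters["paracrine"],
            "ind_preexisting": self.counters["preexisting"],
            "cleared": self.counters["cleared"],
        }
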