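"""Cell-state rule system: growth, mitosis, contact inhibition, activation,
myofibroblast differentiation and fate, senescence induction (primary /
juxtacrine / paracrine), SASP phase switching, ECM production/degradation,
TIMP-like protease inhibition, macrophage polarization and removal rules.

Growth and mitosis run every MCS; all threshold/probability rules run in a
behaviour sweep every ``sweep_period_mcs`` MCS.  The sweep evaluates every
rule against a snapshot of the lattice taken at sweep start (contact counts,
COM concentrations); removals and type changes are applied immediately to
the grid but do not refresh the snapshot mid-sweep.  Sweep rule order:

1. fragment culling (connected components below 2 pixels -> Medium),
2. macrophage polarization (M1 iff INF(COM) > INF_thr),
3. fibroblast activation (persistent once PDGF(COM) > PDGF_f),
4. myofibroblast differentiation (activated, in the t=0 wound region,
   PDGF gate + ECM-contact gate, probability P_MF),
5. TIMP inhibition (MMP at each myofibroblast COM reduced by MMP_thr),
6. ECM degradation (ECM cells with MMP(COM) > MMP_thr removed),
7. ECM production (gated fibroblasts/myofibroblasts and fibrogenic-phase
   senescent cells spawn one-pixel ECM cells on adjacent Medium),
8. secondary senescence (juxtacrine before paracrine; evaluated before
   apoptosis so inflammatory apoptosis cannot pre-empt paracrine induction),
9. myofibroblast fate (tension-release / inflammatory apoptosis, else the
   T_SEN-gated primary senescence draw with probability P_SNC),
10. senescence clock advance and SASP phase bookkeeping,
11. senescent-cell clearance (macrophage contact, or inflammation, each with
    probability p_clear — the "equal chance" rule),
12. background removal (rate mu for activated fibroblasts and macrophages;
    CSF1 withdrawal for macrophages).

All threshold comparisons are strict (>) except the contact-inhibition gate,
where growth proceeds when Rs >= T_CI.
"""
from __future__ import annotations

import numpy as np
from skimage.measure import label as _cc_label

from . import _kernels
from .engine import Lattice, com, medium_surface_ratio
from .fields import ChemFields, field_at_com
from .params import (CSF1, ECM, FIBROBLAST, INF, MACROPHAGE, MECH_JUXTACRINE,
                     MECH_PARACRINE, MECH_PRIMARY, MEDIUM, MMP, MYOFIBROBLAST,
                     PDGF, PRE_SENESCENT, SENESCENT, BehaviorParams,
                     SimulationParams)

_MOORE = tuple(zip(_kernels._M8R.tolist(), _kernels._M8C.tolist()))

# pixel classes used for per-cell contact counts (senescent split by phase)
CLS_MEDIUM, CLS_FIB, CLS_MYO, CLS_MAC, CLS_ECM, CLS_SEN_FIBRO, CLS_SEN_LYTIC = range(7)
_N_CLASSES = 7


# --------------------------------------------------------------------------
# elementary rules (pure, per cell)
# --------------------------------------------------------------------------

def monod_growth_increment(cell_type: int, concentration: float,
                           b: BehaviorParams) -> float:
    """Target-volume increment per MCS: Gmax * c / (c + c0).

    PDGF limits fibroblast/myofibroblast growth, CSF1 limits macrophage
    growth.  Monotone non-decreasing in concentration, saturating at Gmax.
    """
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    if cell_type == FIBROBLAST:
        gmax, c0 = b.gmax_f, b.pdgf0
    elif cell_type == MYOFIBROBLAST:
        gmax, c0 = b.gmax_mf, b.pdgf0
    elif cell_type == MACROPHAGE:
        gmax, c0 = b.gmax_m, b.csf0
    else:
        raise ValueError(f"cell type {cell_type} does not grow")
    if concentration == 0.0:
        return 0.0
    return gmax * concentration / (concentration + c0)


def contact_inhibition_gate(lat: Lattice, cid: int, b: BehaviorParams) -> bool:
    """True when the cell may grow: Rs >= T_CI.

    Growth is arrested when too little of the cell's surface faces Medium
    (crowding); arrest freezes the target volume at the current volume while
    retaining the original lambda.
    """
    return medium_surface_ratio(lat, cid) >= b.t_ci


def polarize_macrophage(inf_at_com: float, b: BehaviorParams) -> bool:
    """M1 (returns True) iff the inflammation level at the COM exceeds
    INF_thr (strict); otherwise M2."""
    return inf_at_com > b.inf_thr


def activate_fibroblast(activated: bool, pdgf_at_com: float,
                        b: BehaviorParams) -> bool:
    """Quiescent fibroblasts activate when PDGF(COM) > PDGF_f.

    Activation is persistent: an activated fibroblast stays activated even
    if PDGF later falls below the threshold.
    """
    return activated or pdgf_at_com > b.pdgf_f


def differentiation_gate(pdgf_at_com: float, ecm_contact: int,
                         b: BehaviorParams) -> bool:
    """Myofibroblast differentiation requires the PDGF gate plus mechanical
    stimulation (ECM contact above ECM_thr)."""
    return pdgf_at_com > b.pdgf_f and ecm_contact > b.ecm_thr


def timp_inhibition(lat: Lattice, chem: ChemFields, cid: int,
                    b: BehaviorParams) -> None:
    """Myofibroblast TIMP activity: MMP at the cell's COM pixel is reduced
    by MMP_thr, clamped at zero."""
    r, c = _com_pixel(lat, cid)
    chem.mmp[r, c] = max(0.0, chem.mmp[r, c] - b.mmp_thr)


def update_sasp_phase(clock_mcs: float, cell_type: int,
                      params: SimulationParams) -> str:
    """SASP phase of a senescent cell: fibrogenic while the senescence clock
    is below T_NIS, fibrolytic from T_NIS on.  Pre-existing inflammatory
    senescent cells are permanently fibrolytic."""
    if cell_type == PRE_SENESCENT:
        return "fibrolytic"
    if cell_type != SENESCENT:
        raise ValueError("not a senescent cell")
    t_nis_mcs = params.behavior.t_nis_days * params.units.mcs_per_day
    return "fibrogenic" if clock_mcs < t_nis_mcs else "fibrolytic"


def senescence_gate_open(t_mcs: float, b: BehaviorParams) -> bool:
    """Whether the primary (CCN1) senescence time gate permits induction.

    Default ("open_after"): induction permitted for t >= T_SEN.  The
    alternative "closed_before" reading permits induction only for
    t < T_SEN.
    """
    if b.t_sen_mode == "open_after":
        return t_mcs >= b.t_sen_mcs
    return t_mcs < b.t_sen_mcs


def myofibroblast_fate(ecm_contact: int, inf_at_com: float, t_mcs: float,
                       b: BehaviorParams, rng: np.random.Generator) -> str:
    """One of 'survive' / 'apoptosis' / 'senesce'.

    Apoptosis on loss of mechanical tension (ECM contact below ECM_thr) or
    inflammatory exposure (INF(COM) > INF_thr).  Otherwise, when the T_SEN
    gate is open and ECM contact exceeds ECM_thr, the cell senesces with
    probability P_SNC (CCN1-mediated primary senescence).
    """
    if ecm_contact < b.ecm_thr or inf_at_com > b.inf_thr:
        return "apoptosis"
    if (senescence_gate_open(t_mcs, b) and ecm_contact > b.ecm_thr
            and rng.random() < b.p_snc):
        return "senesce"
    return "survive"


def secondary_senescence(fibro_contact: int, lytic_contact: int,
                         pdgf_at_com: float, inf_at_com: float,
                         b: BehaviorParams) -> int | None:
    """Secondary senescence mechanism for a myofibroblast, or None.

    Juxtacrine: contact with a fibrogenic-phase senescent cell while
    PDGF(COM) > SNC_thr.  Paracrine: contact with a fibrolytic-phase (or
    pre-existing) senescent cell while INF(COM) > INF_thr.  Juxtacrine is
    checked first.
    """
    if fibro_contact > 0 and pdgf_at_com > b.snc_thr:
        return MECH_JUXTACRINE
    if lytic_contact > 0 and inf_at_com > b.inf_thr:
        return MECH_PARACRINE
    return None


def clear_senescent(mac_contact: int, inf_at_com: float, b: BehaviorParams,
                    rng: np.random.Generator) -> bool:
    """Senescent-cell removal: phagocytosis on macrophage contact, and an
    equal-probability inflammation-mediated route, each a Bernoulli draw
    with probability p_clear per sweep."""
    if mac_contact > 0 and rng.random() < b.p_clear:
        return True
    if inf_at_com > b.inf_thr and rng.random() < b.p_clear:
        return True
    return False


def removal_probability_per_sweep(b: BehaviorParams,
                                  mcs_per_day: float) -> float:
    """Per-sweep removal probability from the continuous rate mu (1/day):
    p = 1 - exp(-mu * dt_sweep)."""
    dt_days = b.sweep_period_mcs / mcs_per_day
    return 1.0 - np.exp(-b.mu_per_day * dt_days)


# --------------------------------------------------------------------------
# mitosis
# --------------------------------------------------------------------------

def maybe_divide(lat: Lattice, cid: int, rng: np.random.Generator,
                 max_tries: int = 10):
    """Divide a cell that has reached its doubling volume.

    Division occurs when the actual volume is at least twice the type's
    original target volume; the member pixels are split by a random line
    through the COM, both daughters receive the original target volume and
    inherit the parent's state flags.  Returns (cid, new_cid) or None.
    """
    lat._check_id(cid)
    if lat.volume[cid] < 2.0 * lat.vt0[cid]:
        return None
    pixels = lat.pixels_of(cid)
    cr, cc = com(lat, cid)
    for _ in range(max_tries):
        theta = rng.uniform(0.0, np.pi)
        n = np.array([np.cos(theta), np.sin(theta)])
        side = (pixels - np.array([cr, cc])) @ n >= 0.0
        if side.all() or not side.any():
            continue
        new_cid = _split_off(lat, cid, pixels[side])
        return (cid, new_cid)
    return None


def _split_off(lat: Lattice, cid: int, daughter_pixels: np.ndarray) -> int:
    """Move ``daughter_pixels`` of cell ``cid`` into a fresh cell inheriting
    the parent's type and state; reset both target volumes to the original."""
    new_cid = lat.acquire_id()
    ct = int(lat.ctype[cid])
    lat.ctype[new_cid] = ct
    lat.grid[daughter_pixels[:, 0], daughter_pixels[:, 1]] = new_cid
    for name in ("lamv", "tsurf", "lams", "vt0", "activated", "m1",
                 "sen_clock", "sen_mech"):
        getattr(lat, name)[new_cid] = getattr(lat, name)[cid]
    lat.tvol[cid] = lat.vt0[cid]
    lat.tvol[new_cid] = lat.vt0[cid]
    lat.frozen[cid] = False
    lat.frozen[new_cid] = False
    lat.recount()
    return new_cid


# --------------------------------------------------------------------------
# per-MCS growth pass
# --------------------------------------------------------------------------

def growth_step(lat: Lattice, chem: ChemFields, params: SimulationParams,
                growth_ids: np.ndarray, rng: np.random.Generator) -> list:
    """Monod growth + contact inhibition + mitosis for one MCS.

    ``growth_ids`` is the cached list of live fibroblast / myofibroblast /
    macrophage ids.  Returns the list of division events (parent, daughter).
    """
    b = params.behavior
    if len(growth_ids) == 0:
        return []
    vol = lat.volume[growth_ids]
    live = vol > 0
    ids = growth_ids[live]
    if len(ids) == 0:
        return []
    vol = vol[live].astype(np.float64)
    surf = lat.surface[ids]
    rs = np.where(surf > 0, lat.med_contact[ids] / np.maximum(surf, 1), 0.0)
    arrested = rs < b.t_ci
    newly_arrested = arrested & ~lat.frozen[ids]
    if newly_arrested.any():
        sel = ids[newly_arrested]
        lat.tvol[sel] = lat.volume[sel]
    lat.frozen[ids] = arrested

    growing = ~arrested
    if growing.any():
        gids = ids[growing]
        r = np.clip(np.floor(lat.sumr[gids] / vol[growing] + 0.5),
                    0, lat.height - 1).astype(np.int64)
        c = np.clip(np.floor(lat.sumc[gids] / vol[growing] + 0.5),
                    0, lat.width - 1).astype(np.int64)
        ct = lat.ctype[gids]
        is_mac = ct == MACROPHAGE
        conc = np.where(is_mac, chem.csf1[r, c], chem.pdgf[r, c])
        gmax = np.where(is_mac, b.gmax_m,
                        np.where(ct == MYOFIBROBLAST, b.gmax_mf, b.gmax_f))
        c0 = np.where(is_mac, b.csf0, b.pdgf0)
        lat.tvol[gids] += gmax * conc / (conc + c0 + 1e-300)

    events = []
    ready = ids[lat.volume[ids] >= 2.0 * lat.vt0[ids]]
    for cid in ready:
        ev = maybe_divide(lat, int(cid), rng)
        if ev is not None:
            events.append(ev)
    return events


# --------------------------------------------------------------------------
# sweep-level helpers
# --------------------------------------------------------------------------

def sasp_phases(lat: Lattice, params: SimulationParams) -> np.ndarray:
    """Boolean per-id array: True where a senescent myofibroblast is still
    in its fibrogenic SASP phase."""
    n = lat.n_ids
    t_nis_mcs = params.behavior.t_nis_days * params.units.mcs_per_day
    return ((lat.ctype[:n] == SENESCENT) & (lat.sen_clock[:n] >= 0)
            & (lat.sen_clock[:n] < t_nis_mcs))


def state_codes(lat: Lattice, params: SimulationParams) -> np.ndarray:
    """Pixel-class code per cell id (senescent cells split by SASP phase)."""
    n = lat.n_ids
    ct = lat.ctype[:n]
    code = np.zeros(n, dtype=np.int64)
    code[ct == FIBROBLAST] = CLS_FIB
    code[ct == MYOFIBROBLAST] = CLS_MYO
    code[ct == MACROPHAGE] = CLS_MAC
    code[ct == ECM] = CLS_ECM
    fibro = sasp_phases(lat, params)
    code[(ct == SENESCENT) & fibro] = CLS_SEN_FIBRO
    code[(ct == SENESCENT) & ~fibro] = CLS_SEN_LYTIC
    code[ct == PRE_SENESCENT] = CLS_SEN_LYTIC
    return code


def class_contact_counts(lat: Lattice, params: SimulationParams) -> np.ndarray:
    """(n_ids, 7) Moore boundary-pair counts between each cell and each
    pixel class."""
    return _kernels.contact_counts(lat.grid, state_codes(lat, params),
                                   lat.n_ids, _N_CLASSES)


def cull_fragments(lat: Lattice) -> int:
    """Remove connected fragments below 2 pixels (non-ECM ids) to Medium.

    Pixel copies can disconnect plain-CPM cells; isolated single pixels are
    not biologically meaningful and are culled.  One-pixel ECM cells are by
    construction whole cells and are kept.  Returns the number of pixels
    culled.
    """
    lab = _cc_label(lat.grid, background=0, connectivity=2)
    if lab.max() == 0:
        return 0
    sizes = np.bincount(lab.ravel())
    small = np.flatnonzero(sizes == 1)
    small = small[small > 0]
    removed = 0
    for l in small:
        r, c = np.argwhere(lab == l)[0]
        cid = lat.grid[r, c]
        if cid != 0 and lat.ctype[cid] != ECM:
            lat.grid[r, c] = 0
            removed += 1
    return removed


def _com_pixel(lat: Lattice, cid: int) -> tuple[int, int]:
    cr, cc = com(lat, cid)
    r = min(max(int(np.floor(cr + 0.5)), 0), lat.height - 1)
    c = min(max(int(np.floor(cc + 0.5)), 0), lat.width - 1)
    return r, c


def adjacent_medium_pixels(lat: Lattice, producer_ids: np.ndarray):
    """All (row, col, owner) triples where a Medium pixel touches (Moore) a
    pixel of one of the producer cells.  A pixel touching several producers
    appears once per producer."""
    grid = lat.grid
    H, W = grid.shape
    ok = np.zeros(lat.n_ids, dtype=bool)
    ok[np.asarray(producer_ids, dtype=np.int64)] = True
    rows, cols, owners = [], [], []
    med = grid == 0
    for dr, dc in _MOORE:
        r0, r1 = max(0, -dr), min(H, H - dr)
        c0, c1 = max(0, -dc), min(W, W - dc)
        centre = med[r0:r1, c0:c1]
        nb = grid[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        hit = centre & ok[nb]
        if hit.any():
            rr, cc = np.nonzero(hit)
            rows.append(rr + r0)
            cols.append(cc + c0)
            owners.append(nb[hit])
    if not rows:
        return (np.empty(0, np.int64),) * 3
    return (np.concatenate(rows), np.concatenate(cols),
            np.concatenate(owners).astype(np.int64))


def _spawn_ecm(lat: Lattice, pixels: np.ndarray) -> list[int]:
    """Create one-pixel immobile ECM cells at ``pixels`` (must be Medium);
    caches for the new cells are set directly (full recount happens at the
    end of the sweep)."""
    new_ids = []
    e = lat.energy
    for r, c in pixels:
        cid = lat.acquire_id()
        lat.ctype[cid] = ECM
        lat.grid[r, c] = cid
        lat.volume[cid] = 1
        lat.sumr[cid] = r
        lat.sumc[cid] = c
        lat.tvol[cid] = e.target_volume[ECM]
        lat.vt0[cid] = lat.tvol[cid]
        lat.lamv[cid] = e.lambda_volume[ECM]
        new_ids.append(cid)
    return new_ids


def produce_ecm(lat: Lattice, cid: int, pdgf_at_com: float,
                params: SimulationParams, rng: np.random.Generator) -> list[int]:
    """ECM production by one cell for one sweep.

    Activated fibroblasts produce ECM_Fib one-pixel ECM cells on adjacent
    Medium when PDGF(COM) > PDGF_f; myofibroblasts produce ECM_Myof = 2x
    that amount; fibrogenic-phase senescent cells produce ECM_Fib as part of
    their SASP (no PDGF gate).  With fewer free adjacent Medium pixels than
    the production amount, only the free ones are filled.
    """
    b = params.behavior
    ct = int(lat.ctype[cid])
    if ct == FIBROBLAST:
        if not (lat.activated[cid] and pdgf_at_com > b.pdgf_f):
            return []
        amount = b.ecm_fib
    elif ct == MYOFIBROBLAST:
        if not pdgf_at_com > b.pdgf_f:
            return []
        amount = b.ecm_myof
    elif ct == SENESCENT:
        if update_sasp_phase(lat.sen_clock[cid], ct, params) != "fibrogenic":
            return []
        amount = b.ecm_fib
    else:
        return []
    rows, cols, _ = adjacent_medium_pixels(lat, np.array([cid]))
    if len(rows) == 0 or amount == 0:
        return []
    uniq = np.unique(np.stack([rows, cols], axis=1), axis=0)
    take = min(amount, len(uniq))
    sel = uniq[rng.choice(len(uniq), size=take, replace=False)]
    ids = _spawn_ecm(lat, sel)
    lat.recount()
    return ids


def degrade_ecm(lat: Lattice, chem: ChemFields, b: BehaviorParams) -> int:
    """Remove every ECM cell whose MMP concentration at its pixel exceeds
    MMP_thr.  Returns the number of ECM cells removed."""
    n = lat.n_ids
    ids = np.flatnonzero((lat.ctype[:n] == ECM) & (lat.volume[:n] > 0))
    if len(ids) == 0:
        return 0
    r = lat.sumr[ids].astype(np.int64)
    c = lat.sumc[ids].astype(np.int64)
    doomed = ids[chem.mmp[r, c] > b.mmp_thr]
    for cid in doomed:
        lat.grid[int(lat.sumr[cid]), int(lat.sumc[cid])] = 0
        lat.volume[cid] = 0
        lat.release_id(int(cid))
    return len(doomed)


def _kill(lat: Lattice, cid: int):
    """Fast in-sweep removal: grid pixels to Medium; caches fixed by the
    end-of-sweep recount; the id returns to the recycling pool."""
    lat.grid[lat.grid == cid] = 0
    lat.volume[cid] = 0
    lat.release_id(cid)


# --------------------------------------------------------------------------
# the behaviour sweep
# --------------------------------------------------------------------------

def behavior_sweep(lat: Lattice, chem: ChemFields, params: SimulationParams,
                   rng: np.random.Generator, t_mcs: float,
                   wound_mask: np.ndarray, counters: dict) -> None:
    """Run all threshold/probability rules once (every sweep_period MCS)."""
    b = params.behavior
    lat.recount()
    cull_fragments(lat)
    lat.recount()
    _bury_dead(lat, counters)

    n = lat.n_ids
    ct = lat.ctype[:n]
    alive = lat.volume[:n] > 0
    counts = class_contact_counts(lat, params)
    vol = np.maximum(lat.volume[:n], 1).astype(np.float64)
    rr = np.clip(np.floor(lat.sumr[:n] / vol + 0.5), 0, lat.height - 1).astype(np.int64)
    cc = np.clip(np.floor(lat.sumc[:n] / vol + 0.5), 0, lat.width - 1).astype(np.int64)
    pdgf_com = chem.pdgf[rr, cc]
    csf1_com = chem.csf1[rr, cc]
    inf_com = chem.inf[rr, cc]
    in_wound = wound_mask[rr, cc]

    # 2. macrophage polarization
    for cid in np.flatnonzero(alive & (ct == MACROPHAGE)):
        lat.m1[cid] = polarize_macrophage(inf_com[cid], b)

    # 3. fibroblast activation (persistent)
    for cid in np.flatnonzero(alive & (ct == FIBROBLAST)):
        lat.activated[cid] = activate_fibroblast(
            bool(lat.activated[cid]), pdgf_com[cid], b)

    # 4. myofibroblast differentiation
    for cid in np.flatnonzero(alive & (ct == FIBROBLAST)):
        if not (lat.activated[cid] and in_wound[cid]):
            continue
        if differentiation_gate(pdgf_com[cid], counts[cid, CLS_ECM], b):
            if rng.random() < b.p_mf:
                lat.ctype[cid] = MYOFIBROBLAST
                lat.vt0[cid] = lat.energy.target_volume[MYOFIBROBLAST]
                lat.lamv[cid] = lat.energy.lambda_volume[MYOFIBROBLAST]
    ct = lat.ctype[:n]  # refresh after type changes

    # 5. TIMP inhibition
    for cid in np.flatnonzero(alive & (ct == MYOFIBROBLAST)):
        chem.mmp[rr[cid], cc[cid]] = max(
            0.0, chem.mmp[rr[cid], cc[cid]] - b.mmp_thr)

    # 6. ECM degradation
    degrade_ecm(lat, chem, b)

    # 7. ECM production (batch over all producers)
    producers, amounts = [], []
    fibro = sasp_phases(lat, params)
    for cid in np.flatnonzero(alive & (ct == FIBROBLAST)):
        if lat.activated[cid] and pdgf_com[cid] > b.pdgf_f and b.ecm_fib > 0:
            producers.append(cid)
            amounts.append(b.ecm_fib)
    for cid in np.flatnonzero(alive & (ct == MYOFIBROBLAST)):
        if pdgf_com[cid] > b.pdgf_f and b.ecm_myof > 0:
            producers.append(cid)
            amounts.append(b.ecm_myof)
    for cid in np.flatnonzero(alive & fibro[:n]):
        if b.ecm_fib > 0:
            producers.append(cid)
            amounts.append(b.ecm_fib)
    if producers:
        _batch_produce_ecm(lat, np.asarray(producers), np.asarray(amounts), rng)

    # 8+9. myofibroblast fate and secondary senescence run on their own,
    # slower cadence (fate_period_mcs): fate decisions are rarer events than
    # the signalling rules above.  Secondary senescence is evaluated before
    # fate, so paracrine induction precedes inflammatory apoptosis.
    if t_mcs % b.fate_period_mcs == 0:
        for cid in np.flatnonzero(alive & (ct == MYOFIBROBLAST)):
            mech = secondary_senescence(
                counts[cid, CLS_SEN_FIBRO], counts[cid, CLS_SEN_LYTIC],
                pdgf_com[cid], inf_com[cid], b)
            if mech is not None:
                _senesce(lat, cid, mech, counters)
        ct = lat.ctype[:n]
        for cid in np.flatnonzero(alive & (ct == MYOFIBROBLAST)):
            if lat.volume[cid] <= 0:
                continue
            fate = myofibroblast_fate(counts[cid, CLS_ECM], inf_com[cid],
                                      t_mcs, b, rng)
            if fate == "apoptosis":
                _kill(lat, cid)
            elif fate == "senesce":
                _senesce(lat, cid, MECH_PRIMARY, counters)

    # 10. senescence clocks
    ct = lat.ctype[:n]
    sen = np.flatnonzero(alive & (ct == SENESCENT) & (lat.volume[:n] > 0))
    lat.sen_clock[sen] += b.sweep_period_mcs

    # 11. senescent clearance
    for cid in np.flatnonzero(
            alive & ((ct == SENESCENT) | (ct == PRE_SENESCENT))):
        if lat.volume[cid] <= 0:
            continue
        if clear_senescent(counts[cid, CLS_MAC], inf_com[cid], b, rng):
            _kill(lat, cid)
            counters["cleared"] += 1

    # 12. background removal
    p_mu = removal_probability_per_sweep(b, params.units.mcs_per_day)
    for cid in np.flatnonzero(alive):
        if lat.volume[cid] <= 0:
            continue
        t = lat.ctype[cid]
        if t == MACROPHAGE:
            if csf1_com[cid] < b.csf1_thr or rng.random() < p_mu:
                _kill(lat, cid)
        elif t == FIBROBLAST and lat.activated[cid]:
            if rng.random() < p_mu:
                _kill(lat, cid)

    lat.recount()


def _bury_dead(lat: Lattice, counters: dict):
    """Retire records of cells that lost all pixels to CPM dynamics or
    fragment culling; senescent attrition counts as clearance so that the
    senescence ledger (inductions - clearances = live senescent cells)
    stays balanced."""
    n = lat.n_ids
    dead = np.flatnonzero((lat.volume[:n] == 0) & (lat.ctype[:n] != MEDIUM))
    for cid in dead:
        if lat.ctype[cid] in (SENESCENT, PRE_SENESCENT):
            counters["cleared"] += 1
        lat.release_id(int(cid))


def _senesce(lat: Lattice, cid: int, mech: int, counters: dict):
    lat.ctype[cid] = SENESCENT
    lat.sen_clock[cid] = 0.0
    lat.sen_mech[cid] = mech
    lat.tvol[cid] = lat.vt0[cid]
    lat.frozen[cid] = False
    key = {MECH_PRIMARY: "primary", MECH_JUXTACRINE: "juxtacrine",
           MECH_PARACRINE: "paracrine"}[mech]
    counters[key] += 1


def _batch_produce_ecm(lat: Lattice, producers: np.ndarray,
                       amounts: np.ndarray, rng: np.random.Generator):
    """Spawn ECM for many producers in one pass; colliding claims on the
    same Medium pixel are resolved in random producer order."""
    rows, cols, owners = adjacent_medium_pixels(lat, producers)
    if len(rows) == 0:
        return
    order = np.argsort(owners, kind="stable")
    rows, cols, owners = rows[order], cols[order], owners[order]
    starts = np.searchsorted(owners, producers)
    ends = np.searchsorted(owners, producers, side="right")
    taken = np.zeros(lat.grid.shape, dtype=bool)
    spawn = []
    perm = rng.permutation(len(producers))
    for i in perm:
        lo, hi = starts[i], ends[i]
        if lo >= hi:
            continue
        idx = np.arange(lo, hi)
        rng.shuffle(idx)
        need = int(amounts[i])
        for j in idx:
            if need == 0:
                break
            r, c = rows[j], cols[j]
            if not taken[r, c]:
                taken[r, c] = True
                spawn.append((r, c))
                need -= 1
    if spawn:
        _spawn_ecm(lat, np.asarray(spawn))


def background_removal(lat: Lattice, chem: ChemFields,
                       params: SimulationParams,
                       rng: np.random.Generator) -> list[int]:
    """Standalone background-removal pass (rate mu for activated fibroblasts
    and macrophages; CSF1-withdrawal apoptosis for macrophages).  Returns the
    removed cell ids.  The behaviour sweep applies the same rule inline."""
    b = params.behavior
    p_mu = removal_probability_per_sweep(b, params.units.mcs_per_day)
    removed = []
    for cid in lat.alive_ids():
        t = lat.ctype[cid]
        if t == MACROPHAGE:
            r, c = _com_pixel(lat, cid)
            if chem.csf1[r, c] < b.csf1_thr or rng.random() < p_mu:
                removed.append(int(cid))
        elif t == FIBROBLAST and lat.activated[cid]:
            if rng.random() < p_mu:
                removed.append(int(cid))
    for cid in removed:
        _kill(lat, cid)
    if removed:
        lat.recount()
    return removed
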