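"""Numba kernels for the Metropolis pixel-copy dynamics and the explicit
finite-difference field solver.

All kernels operate on flat per-cell arrays indexed by cell id (id 0 is
Medium) plus the integer cell-id grid.  The incremental energy formula and
the cache updates implemented here are cross-checked against brute-force
recomputation in the test suite.

Conventions: grids are indexed [row, col]; the contact energy, surface
counts and contact caches use the Moore (8-neighbour) neighbourhood; copy
attempts use the von Neumann (4-neighbour) neighbourhood.  Lattice borders
are fixed (no wraparound); pairs straddling the border do not exist.
"""
from __future__ import annotations

import numpy as np
from numba import njit

# Moore neighbourhood (contact energy / boundary pairs)
_M8R = np.array([-1, -1, -1, 0, 0, 1, 1, 1], dtype=np.int64)
_M8C = np.array([-1, 0, 1, -1, 1, -1, 0, 1], dtype=np.int64)
# von Neumann neighbourhood (copy-attempt adjacency)
_N4R = np.array([-1, 1, 0, 0], dtype=np.int64)
_N4C = np.array([0, 0, -1, 1], dtype=np.int64)

ECM_TYPE = 6  # must match params.ECM


@njit(cache=True)
def delta_h(grid, ctype, volume, surface, tvol, lamv, tsurf, lams,
            ecm_contact, J, temperature, chem_field, chem_lambda,
            chem_lambda_ecm, fields, sr, sc, tr, tc):
    """Energy change of copying the id at (sr, sc) onto pixel (tr, tc).

    Returns the sum of the contact, volume-constraint, surface-constraint
    and chemotaxis contributions.  The chemotaxis term applies only when the
    copy extends a chemotacting cell; it is -lambda * (c(target) - c(source))
    so that motion up-gradient is energetically favoured.
    """
    H, W = grid.shape
    s_id = grid[sr, sc]
    t_id = grid[tr, tc]
    st = ctype[s_id]
    tt = ctype[t_id]

    dH = 0.0
    ds_s = 0  # surface change of the gaining cell
    ds_t = 0  # surface change of the losing cell
    for k in range(8):
        nr = tr + _M8R[k]
        nc = tc + _M8C[k]
        if nr < 0 or nr >= H or nc < 0 or nc >= W:
            continue
        n_id = grid[nr, nc]
        nt = ctype[n_id]
        # contact energy of the pair (target, neighbour)
        if n_id != t_id:
            dH -= J[tt, nt]
        if n_id != s_id:
            dH += J[st, nt]
        # boundary-pair bookkeeping for the surface constraint
        if s_id != 0:
            if n_id != s_id:
                ds_s += 1
            else:
                ds_s -= 1
        if t_id != 0:
            if n_id == t_id:
                ds_t += 1
            else:
                ds_t -= 1

    # volume constraint: gaining cell goes v -> v+1, losing cell v -> v-1
    if s_id != 0:
        v = volume[s_id]
        vt = tvol[s_id]
        dH += lamv[s_id] * ((v + 1 - vt) ** 2 - (v - vt) ** 2)
        if lams[s_id] != 0.0:
            s = surface[s_id]
            st_ = tsurf[s_id]
            dH += lams[s_id] * ((s + ds_s - st_) ** 2 - (s - st_) ** 2)
    if t_id != 0:
        v = volume[t_id]
        vt = tvol[t_id]
        dH += lamv[t_id] * ((v - 1 - vt) ** 2 - (v - vt) ** 2)
        if lams[t_id] != 0.0:
            s = surface[t_id]
            st_ = tsurf[t_id]
            dH += lams[t_id] * ((s + ds_t - st_) ** 2 - (s - st_) ** 2)

    # chemotaxis on extension of a chemotacting cell
    if s_id != 0:
        fidx = chem_field[st]
        if fidx >= 0:
            if ecm_contact[s_id] > 0:
                lam = chem_lambda_ecm[st]
            else:
                lam = chem_lambda[st]
            dH -= lam * (fields[fidx, tr, tc] - fields[fidx, sr, sc])
    return dH


@njit(cache=True)
def apply_copy(grid, ctype, volume, surface, tvol, sumr, sumc,
               med_contact, ecm_contact, tr, tc, s_id):
    """Flip pixel (tr, tc) to ``s_id`` and update all per-cell caches."""
    H, W = grid.shape
    t_id = grid[tr, tc]
    st = ctype[s_id]
    tt = ctype[t_id]
    ds_s = 0
    ds_t = 0
    for k in range(8):
        nr = tr + _M8R[k]
        nc = tc + _M8C[k]
        if nr < 0 or nr >= H or nc < 0 or nc >= W:
            continue
        n_id = grid[nr, nc]
        nt = ctype[n_id]
        if s_id != 0:
            if n_id != s_id:
                ds_s += 1
            else:
                ds_s -= 1
        if t_id != 0:
            if n_id == t_id:
                ds_t += 1
            else:
                ds_t -= 1
        # medium-contact pairs (target, n)
        if n_id != t_id:
            if n_id == 0 and t_id != 0:
                med_contact[t_id] -= 1
            if t_id == 0 and n_id != 0:
                med_contact[n_id] -= 1
            if nt == ECM_TYPE and t_id != 0:
                ecm_contact[t_id] -= 1
            if tt == ECM_TYPE and n_id != 0:
                ecm_contact[n_id] -= 1
        if n_id != s_id:
            if n_id == 0 and s_id != 0:
                med_contact[s_id] += 1
            if s_id == 0 and n_id != 0:
                med_contact[n_id] += 1
            if nt == ECM_TYPE and s_id != 0:
                ecm_contact[s_id] += 1
            if st == ECM_TYPE and n_id != 0:
                ecm_contact[n_id] += 1

    grid[tr, tc] = s_id
    if s_id != 0:
        volume[s_id] += 1
        surface[s_id] += ds_s
        sumr[s_id] += tr
        sumc[s_id] += tc
    if t_id != 0:
        volume[t_id] -= 1
        surface[t_id] += ds_t
        sumr[t_id] -= tr
        sumc[t_id] -= tc


@njit(cache=True)
def run_attempts(grid, ctype, volume, surface, tvol, lamv, tsurf, lams,
                 sumr, sumc, med_contact, ecm_contact,
                 J, temperature, chem_field, chem_lambda, chem_lambda_ecm,
                 fields, n_attempts, seed):
    """One batch of Metropolis pixel-copy attempts (one MCS = H*W attempts).

    Picks a random target pixel and a random von Neumann neighbour as the
    source; accepts with probability 1 if dH <= 0, else exp(-dH/T).
    Returns the number of accepted copies.
    """
    np.random.seed(seed)
    H, W = grid.shape
    accepted = 0
    for _ in range(n_attempts):
        tr = np.random.randint(0, H)
        tc = np.random.randint(0, W)
        k = np.random.randint(0, 4)
        sr = tr + _N4R[k]
        sc = tc + _N4C[k]
        if sr < 0 or sr >= H or sc < 0 or sc >= W:
            continue
        s_id = grid[sr, sc]
        t_id = grid[tr, tc]
        if s_id == t_id:
            continue
        dH = delta_h(grid, ctype, volume, surface, tvol, lamv, tsurf, lams,
                     ecm_contact, J, temperature, chem_field, chem_lambda,
                     chem_lambda_ecm, fields, sr, sc, tr, tc)
        if dH <= 0.0 or np.random.random() < np.exp(-dH / temperature):
            apply_copy(grid, ctype, volume, surface, tvol, sumr, sumc,
                       med_contact, ecm_contact, tr, tc, s_id)
            accepted += 1
    return accepted


@njit(cache=True)
def step_fields(fields, diffusion, decay, secretion, substeps):
    """Advance all fields by one MCS of forward-Euler diffusion + secretion,
    with multiplicative decay per sub-step and reflecting (no-flux) borders.

    The Laplacian uses clamped indices at the borders, which conserves mass
    exactly under pure diffusion.  Values are clamped at zero (the scheme is
    already non-negative within the stability bound; the clamp guards
    round-off).
    """
    nf, H, W = fields.shape
    dt = 1.0 / substeps
    new = np.empty((H, W))
    for _ in range(substeps):
        for f in range(nf):
            D = diffusion[f]
            keep = 1.0 - decay[f] * dt
            for i in range(H):
                iu = i - 1 if i > 0 else 0
                idn = i + 1 if i < H - 1 else H - 1
                for j in range(W):
                    jl = j - 1 if j > 0 else 0
                    jr = j + 1 if j < W - 1 else W - 1
                    c = fields[f, i, j]
                    lap = (fields[f, iu, j] + fields[f, idn, j]
                           + fields[f, i, jl] + fields[f, i, jr] - 4.0 * c)
                    v = (c + dt * (D * lap + secretion[f, i, j])) * keep
                    new[i, j] = v if v > 0.0 else 0.0
            for i in range(H):
                for j in range(W):
                    fields[f, i, j] = new[i, j]


@njit(cache=True)
def gather_secretion(grid, per_pixel):
    """Scatter per-cell per-pixel secretion rates onto the field grids:
    out[f, i, j] = per_pixel[grid[i, j], f] (zero on Medium)."""
    H, W = grid.shape
    nf = per_pixel.shape[1]
    out = np.zeros((nf, H, W))
    for i in range(H):
        for j in range(W):
            cid = grid[i, j]
            if cid > 0:
                for f in range(nf):
                    out[f, i, j] = per_pixel[cid, f]
    return out


@njit(cache=True)
def recount_caches(grid, ctype, volume, surface, sumr, sumc,
                   med_contact, ecm_contact):
    """Recompute volume, surface, COM sums and contact caches from the grid."""
    H, W = grid.shape
    volume[:] = 0
    surface[:] = 0
    sumr[:] = 0.0
    sumc[:] = 0.0
    med_contact[:] = 0
    ecm_contact[:] = 0
    for i in range(H):
        for j in range(W):
            cid = grid[i, j]
            if cid == 0:
                continue
            volume[cid] += 1
            sumr[cid] += i
            sumc[cid] += j
            for k in range(8):
                nr = i + _M8R[k]
                nc = j + _M8C[k]
                if nr < 0 or nr >= H or nc < 0 or nc >= W:
                    continue
                n_id = grid[nr, nc]
                if n_id != cid:
                    surface[cid] += 1
                    if n_id == 0:
                        med_contact[cid] += 1
                    elif ctype[n_id] == ECM_TYPE:
                        ecm_contact[cid] += 1


@njit(cache=True)
def contact_counts(grid, state_code, n_ids, n_classes):
    """Boundary pixel-pair counts between each cell and each pixel class.

    ``state_code`` maps cell id -> pixel class (Medium, the cell types, with
    senescent cells split by SASP phase).  Returns an (n_ids, n_classes)
    matrix of Moore-pair counts.
    """
    H, W = grid.shape
    out = np.zeros((n_ids, n_classes), dtype=np.int64)
    for i in range(H):
        for j in range(W):
            cid = grid[i, j]
            if cid == 0:
                continue
            for k in range(8):
                nr = i + _M8R[k]
                nc = j + _M8C[k]
                if nr < 0 or nr >= H or nc < 0 or nc >= W:
                    continue
                n_id = grid[nr, nc]
                if n_id != cid:
                    out[cid, state_code[n_id]] += 1
    return out
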