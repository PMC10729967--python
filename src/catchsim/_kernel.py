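"""Event-driven core of the discontinuous molecular-dynamics engine.

Beads move ballistically between discrete events: hard-core collisions,
square-well captures/escapes/bounces, bond-wall reflections, hydrogen-bond
association/dissociation, Andersen ghost collisions and cell-list
bookkeeping.  Event times are exact quadratic roots; there is no time step.

Scheduling uses a per-bead event calendar: every bead stores only its
earliest pending event (over all candidate partners plus its next
cell-crossing/refresh), and an indexed binary heap of bead ids orders the
calendars.  Entries are revalidated lazily through per-bead epoch counters;
the globally earliest true event is always some bead's stored minimum, so
no event is ever missed.  Positions are synchronised lazily (each bead
carries its last-update time).

All functions here are numba-compiled and operate on flat arrays prepared
by :mod:`catchsim.dmd_engine`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# event kinds
K_NONE = -1
K_CORE = 0        # hard-core collision
K_CAPTURE = 1     # enter a square well from outside
K_ESCAPE = 2      # well boundary reached from inside (escape or bounce)
K_BONDIN = 3      # inner bond wall
K_BONDOUT = 4     # outer bond wall
K_HBMAKE = 5      # NH-CO association attempt at the H-bond range
K_HBESC = 6       # registered H-bond pair at the range (break or bounce)
K_CROSS = 8       # cell crossing / minimum-image refresh

# counter indices
C_CORE, C_CAPTURE, C_ESCAPE, C_BOUNCE, C_BONDWALL = 0, 1, 2, 3, 4
C_HBMAKE, C_HBBREAK, C_HBREJECT, C_HBBOUNCE = 5, 6, 7, 8
C_GHOST, C_CROSSINGS, C_STALE = 9, 10, 11
N_COUNTERS = 12

# error codes
E_OK = 0
E_OVERLAP = 1         # interacting pair closer than sigma
E_BOND_RANGE = 2      # bonded pair outside its wall window
E_REGISTRY = 3        # H-bond registry conflict
E_STALL = 9           # iteration guard tripped (engine defect)

_TOL = 1e-9           # relative tolerance for boundary classification

MASK64 = np.uint64(0xFFFFFFFFFFFFFFFF)


# ---------------------------------------------------------------------------
# deterministic RNG (splitmix64 + Box-Muller)
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _rng_next(state):
    s = (state[0] + np.uint64(0x9E3779B97F4A7C15)) & MASK64
    state[0] = s
    z = s
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & MASK64
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & MASK64
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _rng_uniform(state):
    return (np.float64(_rng_next(state)) + 1.0) / 18446744073709551617.0


@njit(cache=True)
def _rng_gauss(state):
    u1 = _rng_uniform(state)
    u2 = _rng_uniform(state)
    return np.sqrt(-2.0 * np.log(u1)) * np.cos(6.283185307179586 * u2)


# ---------------------------------------------------------------------------
# small utilities
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _mic(d, box):
    return d - box * np.round(d / box)


@njit(cache=True, inline="always")
def _in_sorted(arr, lo, hi, x):
    while lo < hi:
        mid = (lo + hi) >> 1
        v = arr[mid]
        if v == x:
            return mid
        if v < x:
            lo = mid + 1
        else:
            hi = mid
    return -1


# ---------------------------------------------------------------------------
# pair event prediction (pure kinematics)
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _predict_bond(d2, b, v2, lo2, hi2):
    """Next wall crossing for a bonded pair confined to [lo, hi]."""
    if v2 <= 0.0:
        return np.inf, K_BONDIN
    if b < 0.0 and lo2 > 0.0:
        if d2 <= lo2 * (1.0 + _TOL):
            return 0.0, K_BONDIN
        disc = b * b - v2 * (d2 - lo2)
        if disc > 0.0:
            return (-b - np.sqrt(disc)) / v2, K_BONDIN
    disc = b * b - v2 * (d2 - hi2)
    if disc < 0.0:
        # outside the window and receding (numerical drift): reflect now
        return 0.0, K_BONDOUT
    return (-b + np.sqrt(disc)) / v2, K_BONDOUT


@njit(cache=True, inline="always")
def _predict_nonbond(d2, b, v2, sig2, l2, hb_mode):
    """Next discontinuity for a non-bonded pair.

    ``l2`` is the squared well range (0 if hard-sphere only); ``hb_mode`` is
    0 for an ordinary pair, 1 for an unregistered NH-CO pair and 2 for a
    registered (hydrogen-bonded) pair.
    """
    if v2 <= 0.0:
        return np.inf, K_CORE
    if l2 > 0.0:
        at_boundary = d2 >= l2 * (1.0 - _TOL) and d2 <= l2 * (1.0 + _TOL)
        inside = d2 < l2 * (1.0 - _TOL) or (at_boundary and b < 0.0)
        if not inside:
            if b < 0.0 and not at_boundary:
                disc = b * b - v2 * (d2 - l2)
                if disc > 0.0:
                    dt = (-b - np.sqrt(disc)) / v2
                    if hb_mode == 1:
                        return dt, K_HBMAKE
                    if hb_mode == 2:
                        return dt, K_HBESC
                    return dt, K_CAPTURE
            return np.inf, K_NONE
        # inside the well: core contact or boundary exit
        if b < 0.0:
            if d2 <= sig2 * (1.0 + _TOL):
                return 0.0, K_CORE
            disc = b * b - v2 * (d2 - sig2)
            if disc > 0.0:
                return (-b - np.sqrt(disc)) / v2, K_CORE
        if hb_mode == 1:
            # unregistered NH-CO pair drifting out of range: no event occurs
            # at the boundary, and it cannot re-enter without a velocity
            # change that re-predicts the pair
            return np.inf, K_NONE
        dd = d2 - l2
        if dd > 0.0:
            dd = 0.0
        dt = (-b + np.sqrt(b * b - v2 * dd)) / v2
        if hb_mode == 2:
            return dt, K_HBESC
        return dt, K_ESCAPE
    # hard sphere only
    if b < 0.0:
        if d2 <= sig2 * (1.0 + _TOL):
            return 0.0, K_CORE
        disc = b * b - v2 * (d2 - sig2)
        if disc > 0.0:
            return (-b - np.sqrt(disc)) / v2, K_CORE
    return np.inf, K_NONE


@njit(cache=True, inline="always")
def _pair_channel(i, j, btype, role, pep, res,
                  bond_indptr, bond_j, bond_lo2, bond_hi2,
                  excl_indptr, excl_j, sig2, lam2, hb_range2, min_res_sep):
    """Classify the interaction channel of a pair.

    Returns (mode, p0, p1): mode 0 none, 1 bond (lo2, hi2),
    2 plain non-bonded (sig2, lam2), 3 H-bond eligible (sig2, range2).
    """
    bptr = _in_sorted(bond_j, bond_indptr[i], bond_indptr[i + 1], j)
    if bptr >= 0:
        return 1, bond_lo2[bptr], bond_hi2[bptr]
    if _in_sorted(excl_j, excl_indptr[i], excl_indptr[i + 1], j) >= 0:
        return 0, 0.0, 0.0
    ri = role[i]
    rj = role[j]
    if (ri == 0 and rj == 2) or (ri == 2 and rj == 0):
        ok = pep[i] != pep[j]
        if not ok:
            dr = res[i] - res[j]
            if dr < 0:
                dr = -dr
            ok = dr >= min_res_sep
        if ok:
            return 3, sig2[btype[i], btype[j]], hb_range2
    return 2, sig2[btype[i], btype[j]], lam2[btype[i], btype[j]]


@njit(cache=True, inline="always")
def _predict_pair(i, j, t, pos, vel, last_t, partner,
                  btype, role, pep, res,
                  bond_indptr, bond_j, bond_lo2, bond_hi2,
                  excl_indptr, excl_j, sig2, lam2, hb_range2, min_res_sep,
                  box):
    """Earliest discontinuity time offset and kind for the pair (i, j)."""
    mode, p0, p1 = _pair_channel(
        i, j, btype, role, pep, res, bond_indptr, bond_j, bond_lo2, bond_hi2,
        excl_indptr, excl_j, sig2, lam2, hb_range2, min_res_sep)
    if mode == 0:
        return np.inf, K_NONE
    dti = t - last_t[i]
    dtj = t - last_t[j]
    dx = _mic(pos[i, 0] + vel[i, 0] * dti - pos[j, 0] - vel[j, 0] * dtj, box)
    dy = _mic(pos[i, 1] + vel[i, 1] * dti - pos[j, 1] - vel[j, 1] * dtj, box)
    dz = _mic(pos[i, 2] + vel[i, 2] * dti - pos[j, 2] - vel[j, 2] * dtj, box)
    vx = vel[i, 0] - vel[j, 0]
    vy = vel[i, 1] - vel[j, 1]
    vz = vel[i, 2] - vel[j, 2]
    d2 = dx * dx + dy * dy + dz * dz
    b = dx * vx + dy * vy + dz * vz
    v2 = vx * vx + vy * vy + vz * vz
    if mode == 1:
        return _predict_bond(d2, b, v2, p0, p1)
    if mode == 3:
        hbm = 2 if partner[i] == j else 1
        return _predict_nonbond(d2, b, v2, p0, p1, hbm)
    return _predict_nonbond(d2, b, v2, p0, p1, 0)


@njit(cache=True)
def _cross_next(i, t, pos, vel, last_t, cell_w, ncell, use_cl, horizon,
                cell_of):
    """Next cell-boundary crossing (or refresh horizon, without cells).

    Wall positions are taken from the bead's *assigned* cell, not from the
    floor of its coordinate: at a wall the assignment may lead the position
    by a rounding error, and measuring from the assignment guarantees that
    every crossing makes progress.  Returns (dt, payload) where payload
    encodes the crossed axis and direction (axis * 2 + (direction > 0)),
    or payload -1 for a refresh event.
    """
    if not use_cl:
        speed = np.sqrt(vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2)
        if speed <= 0.0:
            return np.inf, -1
        return horizon / speed, -1
    c = cell_of[i]
    cz = c % ncell
    cy = (c // ncell) % ncell
    cx = c // (ncell * ncell)
    best = np.inf
    payload = -1
    for ax in range(3):
        v = vel[i, ax]
        if v == 0.0:
            continue
        x = pos[i, ax] + v * (t - last_t[i])
        cc = cx if ax == 0 else (cy if ax == 1 else cz)
        # unwrap the coordinate next to the assigned cell so that wall
        # distances stay local when the assignment leads across the box edge
        lo = cc * cell_w
        span = x - lo
        span -= ncell * cell_w * np.round(span / (ncell * cell_w))
        if v > 0.0:
            dt = (cell_w - span) / v
        else:
            dt = -span / v
        if dt < 0.0:
            dt = 0.0
        if dt < best:
            best = dt
            payload = ax * 2 + (1 if v > 0.0 else 0)
    return best, payload


# ---------------------------------------------------------------------------
# per-bead event calendar + indexed heap of bead ids
# ---------------------------------------------------------------------------

@njit(cache=True)
def _heap_fix(heap, hpos, ev_t, i):
    """Restore heap order after ev_t[i] changed (sift up then down)."""
    n = heap.shape[0]
    idx = hpos[i]
    # up
    while idx > 0:
        par = (idx - 1) >> 1
        if ev_t[heap[par]] <= ev_t[heap[idx]]:
            break
        a = heap[par]; b = heap[idx]
        heap[par] = b; heap[idx] = a
        hpos[b] = par; hpos[a] = idx
        idx = par
    # down
    while True:
        left = 2 * idx + 1
        if left >= n:
            break
        small = left
        right = left + 1
        if right < n and ev_t[heap[right]] < ev_t[heap[left]]:
            small = right
        if ev_t[heap[idx]] <= ev_t[heap[small]]:
            break
        a = heap[idx]; b = heap[small]
        heap[idx] = b; heap[small] = a
        hpos[b] = idx; hpos[a] = small
        idx = small


@njit(cache=True)
def _schedule_bead(i, t, pos, vel, last_t, partner, epoch,
                   btype, role, pep, res,
                   bond_indptr, bond_j, bond_lo2, bond_hi2,
                   excl_indptr, excl_j, sig2, lam2, hb_range2, min_res_sep,
                   box, cell_w, ncell, use_cl, horizon, horizon_t,
                   cell_of, head, nxt, radius,
                   ev_t, ev_j, ev_k, ev_pay, ev_jep, heap, hpos):
    """Recompute bead i's earliest event and reposition it in the heap.

    The stencil radius is per bead: a bead only needs to scan as far as its
    own largest interaction range, so compact backbone beads use a 27-cell
    stencil while long-range sidechain beads scan wider.
    """
    best_t = np.inf
    best_j = -1
    best_k = K_NONE
    if use_cl:
        c = cell_of[i]
        cz = c % ncell
        cy = (c // ncell) % ncell
        cx = c // (ncell * ncell)
        rad = radius[i]
        for ox in range(-rad, rad + 1):
            ax = (cx + ox) % ncell
            for oy in range(-rad, rad + 1):
                ay = (cy + oy) % ncell
                for oz in range(-rad, rad + 1):
                    az = (cz + oz) % ncell
                    jj = head[(ax * ncell + ay) * ncell + az]
                    while jj >= 0:
                        if jj != i:
                            dt, kind = _predict_pair(
                                i, jj, t, pos, vel, last_t, partner,
                                btype, role, pep, res,
                                bond_indptr, bond_j, bond_lo2, bond_hi2,
                                excl_indptr, excl_j, sig2, lam2,
                                hb_range2, min_res_sep, box)
                            if t + dt < best_t:
                                best_t = t + dt
                                best_j = jj
                                best_k = kind
                        jj = nxt[jj]
    else:
        for jj in range(pos.shape[0]):
            if jj != i:
                dt, kind = _predict_pair(
                    i, jj, t, pos, vel, last_t, partner,
                    btype, role, pep, res,
                    bond_indptr, bond_j, bond_lo2, bond_hi2,
                    excl_indptr, excl_j, sig2, lam2,
                    hb_range2, min_res_sep, box)
                if t + dt < best_t:
                    best_t = t + dt
                    best_j = jj
                    best_k = kind

    dtc, payload = _cross_next(i, t, pos, vel, last_t, cell_w, ncell,
                               use_cl, horizon, cell_of)
    if dtc > horizon_t:
        # guarantee one refresh per horizon so that pair events farther out
        # (whose partners may change course) are re-examined in time
        dtc = horizon_t
        payload = -1
    pay = -1
    if t + dtc < best_t:
        best_t = t + dtc
        best_j = -1
        best_k = K_CROSS
        pay = payload

    ev_t[i] = best_t
    ev_j[i] = best_j
    ev_k[i] = best_k
    ev_pay[i] = pay
    ev_jep[i] = epoch[best_j] if best_j >= 0 else -1
    _heap_fix(heap, hpos, ev_t, i)


# ---------------------------------------------------------------------------
# main kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def run_kernel(
    pos, vel, mass, btype, role, pep, res,
    bond_indptr, bond_j, bond_lo2, bond_hi2,
    excl_indptr, excl_j,
    sig2, lam2, eps,
    hb_aux1, hb_aux2, aux_min2,
    hb_range2, hb_eps, min_res_sep,
    partner,
    box, t0, t_star, ghost_rate,
    max_phys_events, max_time, sample_every,
    seed, use_cells,
    fr_time, fr_pos, fr_partner, fr_ke, fr_pe, counts,
):
    """Run the event loop.  Mutates pos/vel/partner in place and fills the
    frame buffers; returns
    (n_frames, t_final, pe_final, err_code, err_i, err_j, n_physical_events).
    """
    n = pos.shape[0]
    last_t = np.full(n, t0)
    epoch = np.zeros(n, dtype=np.int64)
    rng = np.empty(1, dtype=np.uint64)
    rng[0] = (np.uint64(seed) * np.uint64(2685821657736338717)
              + np.uint64(88172645463325252)) & MASK64

    # ---- per-bead interaction ranges & cell geometry ---------------------
    # each bead's own largest discontinuity distance (cores, wells, H-bond
    # range, bond walls) sets how far its stencil must reach
    ntypes = sig2.shape[0]
    type_range2 = np.zeros(ntypes)
    for a in range(ntypes):
        for b2 in range(ntypes):
            r2 = sig2[a, b2]
            if lam2[a, b2] > r2:
                r2 = lam2[a, b2]
            if r2 > type_range2[a]:
                type_range2[a] = r2
    bead_range = np.zeros(n)
    for i in range(n):
        r2 = type_range2[btype[i]]
        if role[i] == 0 or role[i] == 2:
            if hb_range2 > r2:
                r2 = hb_range2
        for p in range(bond_indptr[i], bond_indptr[i + 1]):
            if bond_hi2[p] > r2:
                r2 = bond_hi2[p]
        bead_range[i] = np.sqrt(r2) * 1.0000001

    # base cell width: the largest range among backbone beads (sidechain
    # beads with longer reach scan a proportionally wider stencil)
    base_range = 0.0
    max_range = 0.0
    for i in range(n):
        if role[i] != 3 and bead_range[i] > base_range:
            base_range = bead_range[i]
        if bead_range[i] > max_range:
            max_range = bead_range[i]
    if base_range <= 0.0:
        base_range = max_range

    ncell = int(box / base_range)
    max_rad = int(np.ceil(max_range / base_range))
    use_cl = bool(use_cells) and ncell >= 2 * max_rad + 1
    if not use_cl:
        ncell = 1
    cell_w = box / ncell
    radius = np.ones(n, dtype=np.int64)
    if use_cl:
        for i in range(n):
            radius[i] = int(np.ceil(bead_range[i] / cell_w))
            if radius[i] < 1:
                radius[i] = 1
    horizon = box / 8.0   # refresh travel distance in no-cell mode
    horizon_t = 10.0      # reduced-time scheduling horizon

    cell_of = np.zeros(n, dtype=np.int64)
    head = np.full(ncell * ncell * ncell, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    prv = np.full(n, -1, dtype=np.int64)
    if use_cl:
        for i in range(n):
            cx = int(pos[i, 0] / cell_w) % ncell
            cy = int(pos[i, 1] / cell_w) % ncell
            cz = int(pos[i, 2] / cell_w) % ncell
            c = (cx * ncell + cy) * ncell + cz
            cell_of[i] = c
            nxt[i] = head[c]
            if head[c] >= 0:
                prv[head[c]] = i
            prv[i] = -1
            head[c] = i

    # ---- initial validation & potential energy ---------------------------
    pe = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            mode, p0, p1 = _pair_channel(
                i, j, btype, role, pep, res,
                bond_indptr, bond_j, bond_lo2, bond_hi2,
                excl_indptr, excl_j, sig2, lam2, hb_range2, min_res_sep)
            if mode == 0:
                continue
            dx = _mic(pos[i, 0] - pos[j, 0], box)
            dy = _mic(pos[i, 1] - pos[j, 1], box)
            dz = _mic(pos[i, 2] - pos[j, 2], box)
            d2 = dx * dx + dy * dy + dz * dz
            if mode == 1:
                if d2 < p0 * (1.0 - 1e-7) or d2 > p1 * (1.0 + 1e-7):
                    return 0, t0, 0.0, E_BOND_RANGE, i, j, 0
            else:
                if d2 < p0 * (1.0 - 1e-7):
                    return 0, t0, 0.0, E_OVERLAP, i, j, 0
                if mode == 2:
                    l2 = lam2[btype[i], btype[j]]
                    if l2 > 0.0 and d2 < l2:
                        pe -= eps[btype[i], btype[j]]
    for i in range(n):
        if role[i] == 0 and partner[i] >= 0:
            if partner[partner[i]] != i:
                return 0, t0, 0.0, E_REGISTRY, i, partner[i], 0
            pe -= hb_eps

    # ---- per-bead calendars and the indexed heap --------------------------
    ev_t = np.full(n, np.inf)
    ev_j = np.full(n, -1, dtype=np.int64)
    ev_k = np.full(n, K_NONE, dtype=np.int8)
    ev_pay = np.full(n, -1, dtype=np.int64)
    ev_jep = np.full(n, -1, dtype=np.int64)
    heap = np.arange(n, dtype=np.int64)
    hpos = np.arange(n, dtype=np.int64)

    for i in range(n):
        _schedule_bead(
            i, t0, pos, vel, last_t, partner, epoch,
            btype, role, pep, res,
            bond_indptr, bond_j, bond_lo2, bond_hi2,
            excl_indptr, excl_j, sig2, lam2, hb_range2, min_res_sep,
            box, cell_w, ncell, use_cl, horizon, horizon_t,
            cell_of, head, nxt, radius,
            ev_t, ev_j, ev_k, ev_pay, ev_jep, heap, hpos)

    # ---- sampling ----------------------------------------------------------
    n_frames = 0
    frame_cap = fr_time.shape[0]
    next_sample = t0

    ghost_t = np.inf
    if ghost_rate > 0.0:
        ghost_t = t0 - np.log(_rng_uniform(rng)) / (ghost_rate * n)

    t = t0
    n_phys = 0
    err_code = E_OK
    err_i = -1
    err_j = -1
    n_iter = 0

    while n_phys < max_phys_events:
        n_iter += 1
        if n_iter > 2_000_000_000:
            return n_frames, t, pe, E_STALL, err_i, err_j, n_phys

        root = heap[0]
        t_ev = ev_t[root]
        is_ghost = ghost_t < t_ev
        if is_ghost:
            t_ev = ghost_t
        if t_ev > max_time:
            t_ev = max_time

        # emit samples at or before the event
        while next_sample <= t_ev and n_frames < frame_cap:
            ke = 0.0
            for i in range(n):
                dt_i = next_sample - last_t[i]
                fr_pos[n_frames, i, 0] = (pos[i, 0] + vel[i, 0] * dt_i) % box
                fr_pos[n_frames, i, 1] = (pos[i, 1] + vel[i, 1] * dt_i) % box
                fr_pos[n_frames, i, 2] = (pos[i, 2] + vel[i, 2] * dt_i) % box
                fr_partner[n_frames, i] = partner[i]
                ke += 0.5 * mass[i] * (vel[i, 0] ** 2 + vel[i, 1] ** 2
                                       + vel[i, 2] ** 2)
            fr_time[n_frames] = next_sample
            fr_ke[n_frames] = ke
            fr_pe[n_frames] = pe
            n_frames += 1
            next_sample += sample_every

        if t_ev >= max_time or not np.isfinite(t_ev):
            t = min(t_ev, max_time)
            break

        if is_ghost:
            t = ghost_t
            gi = int(_rng_next(rng) % np.uint64(n))
            dtg = t - last_t[gi]
            pos[gi, 0] += vel[gi, 0] * dtg
            pos[gi, 1] += vel[gi, 1] * dtg
            pos[gi, 2] += vel[gi, 2] * dtg
            last_t[gi] = t
            sd = np.sqrt(t_star / mass[gi])
            vel[gi, 0] = sd * _rng_gauss(rng)
            vel[gi, 1] = sd * _rng_gauss(rng)
            vel[gi, 2] = sd * _rng_gauss(rng)
            epoch[gi] += 1
            _schedule_bead(
                gi, t, pos, vel, last_t, partner, epoch,
                btype, role, pep, res,
                bond_indptr, bond_j, bond_lo2, bond_hi2,
                excl_indptr, excl_j, sig2, lam2, hb_range2, min_res_sep,
                box, cell_w, ncell, use_cl, horizon, horizon_t,
                cell_of, head, nxt, radius,
                ev_t, ev_j, ev_k, ev_pay, ev_jep, heap, hpos)
            counts[C_GHOST] += 1
            n_phys += 1
            ghost_t = t - np.log(_rng_uniform(rng)) / (ghost_rate * n)
            continue

        ei = root
        ej = ev_j[ei]
        ekind = ev_k[ei]
        epay = ev_pay[ei]

        # lazy revalidation: the partner may have changed since scheduling
        if ej >= 0 and epoch[ej] != ev_jep[ei]:
            counts[C_STALE] += 1
            _schedule_bead(
                ei, t, pos, vel, last_t, partner, epoch,
                btype, role, pep, res,
                bond_indptr, bond_j, bond_lo2, bond_hi2,
                excl_indptr, excl_j, sig2, lam2, hb_range2, min_res_sep,
                box, cell_w, ncell, use_cl, horizon, horizon_t,
                cell_of, head, nxt, radius,
                ev_t, ev_j, ev_k, ev_pay, ev_jep, heap, hpos)
            continue

        t = t_ev
        err_i = ei
        err_j = ej

        if ekind == K_CROSS:
            # advance, wrap, step the assigned cell, discover new neighbours
            dtc = t - last_t[ei]
            pos[ei, 0] += vel[ei, 0] * dtc
            pos[ei, 1] += vel[ei, 1] * dtc
            pos[ei, 2] += vel[ei, 2] * dtc
            last_t[ei] = t
            pos[ei, 0] %= box
            pos[ei, 1] %= box
            pos[ei, 2] %= box
            if use_cl and epay >= 0:
                cold = cell_of[ei]
                cz = cold % ncell
                cy = (cold // ncell) % ncell
                cx = cold // (ncell * ncell)
                ax = epay // 2
                step = 1 if (epay % 2) == 1 else -1
                if ax == 0:
                    cx = (cx + step) % ncell
                elif ax == 1:
                    cy = (cy + step) % ncell
                else:
                    cz = (cz + step) % ncell
                cnew = (cx * ncell + cy) * ncell + cz
                if cnew != cold:
                    # unlink
                    if prv[ei] >= 0:
                        nxt[prv[ei]] = nxt[ei]
                    else:
                        head[cold] = nxt[ei]
                    if nxt[ei] >= 0:
                        prv[nxt[ei]] = prv[ei]
                    # link
                    cell_of[ei] = cnew
                    nxt[ei] = head[cnew]
                    if head[cnew] >= 0:
                        prv[head[cnew]] = ei
                    prv[ei] = -1
                    head[cnew] = ei
            epoch[ei] += 1
            _schedule_bead(
                ei, t, pos, vel, last_t, partner, epoch,
                btype, role, pep, res,
                bond_indptr, bond_j, bond_lo2, bond_hi2,
                excl_indptr, excl_j, sig2, lam2, hb_range2, min_res_sep,
                box, cell_w, ncell, use_cl, horizon, horizon_t,
                cell_of, head, nxt, radius,
                ev_t, ev_j, ev_k, ev_pay, ev_jep, heap, hpos)
            counts[C_CROSSINGS] += 1
            continue

        # --- two-body event -------------------------------------------------
        i = ei
        j = ej
        dti = t - last_t[i]
        pos[i, 0] += vel[i, 0] * dti
        pos[i, 1] += vel[i, 1] * dti
        pos[i, 2] += vel[i, 2] * dti
        last_t[i] = t
        dtj = t - last_t[j]
        pos[j, 0] += vel[j, 0] * dtj
        pos[j, 1] += vel[j, 1] * dtj
        pos[j, 2] += vel[j, 2] * dtj
        last_t[j] = t

        dx = _mic(pos[i, 0] - pos[j, 0], box)
        dy = _mic(pos[i, 1] - pos[j, 1], box)
        dz = _mic(pos[i, 2] - pos[j, 2], box)
        d2 = dx * dx + dy * dy + dz * dz
        d = np.sqrt(d2)
        vx = vel[i, 0] - vel[j, 0]
        vy = vel[i, 1] - vel[j, 1]
        vz = vel[i, 2] - vel[j, 2]
        b = dx * vx + dy * vy + dz * vz
        mi = mass[i]
        mj = mass[j]
        mu = mi * mj / (mi + mj)
        vr = b / d  # signed radial closing speed

        reflect = False
        dvr = 0.0   # radial velocity change to apply along the pair axis

        if ekind == K_CORE or ekind == K_BONDIN or ekind == K_BONDOUT:
            reflect = True
            if ekind == K_CORE:
                counts[C_CORE] += 1
            else:
                counts[C_BONDWALL] += 1
        elif ekind == K_CAPTURE:
            epsv = eps[btype[i], btype[j]]
            vr_new = -np.sqrt(vr * vr + 2.0 * epsv / mu)
            dvr = vr_new - vr
            pe -= epsv
            counts[C_CAPTURE] += 1
        elif ekind == K_ESCAPE:
            epsv = eps[btype[i], btype[j]]
            if 0.5 * mu * vr * vr >= epsv and vr > 0.0:
                vr_new = np.sqrt(vr * vr - 2.0 * epsv / mu)
                dvr = vr_new - vr
                pe += epsv
                counts[C_ESCAPE] += 1
            else:
                reflect = True
                counts[C_BOUNCE] += 1
        elif ekind == K_HBMAKE:
            nh = i if role[i] == 0 else j
            co = j if role[i] == 0 else i
            ok = partner[nh] < 0 and partner[co] < 0
            if ok:
                # directional auxiliary criteria at the association instant
                for a_idx in range(4):
                    if a_idx == 0:
                        aa = hb_aux1[nh]
                        bb = co
                    elif a_idx == 1:
                        aa = hb_aux2[nh]
                        bb = co
                    elif a_idx == 2:
                        aa = hb_aux1[co]
                        bb = nh
                    else:
                        aa = hb_aux2[co]
                        bb = nh
                    if aa < 0:
                        continue
                    dta = t - last_t[aa]
                    ax2 = pos[aa, 0] + vel[aa, 0] * dta
                    ay2 = pos[aa, 1] + vel[aa, 1] * dta
                    az2 = pos[aa, 2] + vel[aa, 2] * dta
                    qx = _mic(ax2 - pos[bb, 0], box)
                    qy = _mic(ay2 - pos[bb, 1], box)
                    qz = _mic(az2 - pos[bb, 2], box)
                    if qx * qx + qy * qy + qz * qz < aux_min2[a_idx]:
                        ok = False
                        break
            if ok:
                vr_new = -np.sqrt(vr * vr + 2.0 * hb_eps / mu)
                dvr = vr_new - vr
                pe -= hb_eps
                partner[nh] = co
                partner[co] = nh
                counts[C_HBMAKE] += 1
            else:
                counts[C_HBREJECT] += 1
                # transparent crossing: no velocity change
        elif ekind == K_HBESC:
            if 0.5 * mu * vr * vr >= hb_eps and vr > 0.0:
                vr_new = np.sqrt(vr * vr - 2.0 * hb_eps / mu)
                dvr = vr_new - vr
                pe += hb_eps
                nh = i if role[i] == 0 else j
                co = j if role[i] == 0 else i
                partner[nh] = -1
                partner[co] = -1
                counts[C_HBBREAK] += 1
            else:
                reflect = True
                counts[C_HBBOUNCE] += 1

        if reflect:
            fac = -2.0 * mu * b / d2
            vel[i, 0] += fac / mi * dx
            vel[i, 1] += fac / mi * dy
            vel[i, 2] += fac / mi * dz
            vel[j, 0] -= fac / mj * dx
            vel[j, 1] -= fac / mj * dy
            vel[j, 2] -= fac / mj * dz
        elif dvr != 0.0:
            ux = dx / d
            uy = dy / d
            uz = dz / d
            vel[i, 0] += mu / mi * dvr * ux
            vel[i, 1] += mu / mi * dvr * uy
            vel[i, 2] += mu / mi * dvr * uz
            vel[j, 0] -= mu / mj * dvr * ux
            vel[j, 1] -= mu / mj * dvr * uy
            vel[j, 2] -= mu / mj * dvr * uz

        epoch[i] += 1
        epoch[j] += 1
        n_phys += 1
        _schedule_bead(
            i, t, pos, vel, last_t, partner, epoch,
            btype, role, pep, res,
            bond_indptr, bond_j, bond_lo2, bond_hi2,
            excl_indptr, excl_j, sig2, lam2, hb_range2, min_res_sep,
            box, cell_w, ncell, use_cl, horizon, horizon_t,
            cell_of, head, nxt, radius,
            ev_t, ev_j, ev_k, ev_pay, ev_jep, heap, hpos)
        _schedule_bead(
            j, t, pos, vel, last_t, partner, epoch,
            btype, role, pep, res,
            bond_indptr, bond_j, bond_lo2, bond_hi2,
            excl_indptr, excl_j, sig2, lam2, hb_range2, min_res_sep,
            box, cell_w, ncell, use_cl, horizon, horizon_t,
            cell_of, head, nxt, radius,
            ev_t, ev_j, ev_k, ev_pay, ev_jep, heap, hpos)

    # ---- finalize -----------------------------------------------------------
    if not np.isfinite(t):
        t = t0
    for i in range(n):
        dtf = t - last_t[i]
        pos[i, 0] = (pos[i, 0] + vel[i, 0] * dtf) % box
        pos[i, 1] = (pos[i, 1] + vel[i, 1] * dtf) % box
        pos[i, 2] = (pos[i, 2] + vel[i, 2] * dtf) % box
        last_t[i] = t

    return n_frames, t, pe, err_code, err_i, err_j, n_phys
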