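"""Event-driven (discontinuous) molecular dynamics over the four-bead model.

Between events every bead moves ballistically; the engine advances from one
exactly-solved discontinuity to the next: hard-core collisions, square-well
capture/escape/bounce, bond-wall reflections, directional hydrogen-bond
association and dissociation, and Andersen-thermostat ghost collisions.

Reduced units throughout: lengths in Angstrom, energies in units of the
hydrogen-bond well depth eps_HB, masses in amu; the derived time unit is
about 28 fs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from catchsim import _kernel
from catchsim.peptide_model import (
    EPS_HB_KJ,
    RESIDUES,
    BeadTopology,
    InteractionTable,
    PeptideSequence,
    SystemState,
    bead_type_token,
    build_topology,
    default_interaction_table,
)

__all__ = [
    "CGSystem",
    "compile_system",
    "Event",
    "EventLog",
    "Frame",
    "Trajectory",
    "pair_event_time",
    "resolve_event",
    "run_dmd",
    "total_energy",
    "instantaneous_temperature",
    "count_hbonds",
    "check_state",
    "maxwell_velocities",
]

_KIND_NAMES = {
    _kernel.K_CORE: "core",
    _kernel.K_CAPTURE: "capture",
    _kernel.K_ESCAPE: "escape",
    _kernel.K_BONDIN: "bond_wall",
    _kernel.K_BONDOUT: "bond_wall",
    _kernel.K_HBMAKE: "hbond_make",
    _kernel.K_HBESC: "hbond_break",
    _kernel.K_CROSS: "cell_cross",
}

_COUNTER_NAMES = [
    "core", "capture", "escape", "bounce", "bond_wall",
    "hbond_make", "hbond_break", "hbond_reject", "hbond_bounce",
    "ghost", "cell_cross", "stale",
]


# ---------------------------------------------------------------------------
# Compiled system
# ---------------------------------------------------------------------------

@dataclass
class CGSystem:
    """Flat-array view of a multi-peptide four-bead system.

    Couples the per-peptide :class:`BeadTopology` graphs with the interaction
    table, pre-computing everything the event kernel needs: bead types and
    roles, bond windows, short-range exclusions (beads within three bonds in
    the same peptide do not interact non-bondedly) and the square-well
    parameter matrices.
    """

    sequences: list[PeptideSequence]
    topologies: list[BeadTopology]
    table: InteractionTable
    type_tokens: list[str]
    btype: np.ndarray
    role: np.ndarray              # 0 NH, 1 CA, 2 CO, 3 R
    pep: np.ndarray
    res: np.ndarray
    mass: np.ndarray
    bond_indptr: np.ndarray
    bond_j: np.ndarray
    bond_lo2: np.ndarray
    bond_hi2: np.ndarray
    excl_indptr: np.ndarray
    excl_j: np.ndarray
    sig2: np.ndarray
    lam2: np.ndarray
    eps: np.ndarray
    hb_aux1: np.ndarray
    hb_aux2: np.ndarray
    aux_min2: np.ndarray
    hb_range2: float
    hb_eps: float
    min_res_sep: int
    hydrophobic: np.ndarray       # bool per bead: hydrophobic sidechain
    pep_offsets: np.ndarray       # bead offset of each peptide (n_pep+1)

    @property
    def n_beads(self) -> int:
        return len(self.btype)

    @property
    def n_peptides(self) -> int:
        return len(self.sequences)

    def bead_slice(self, pep_index: int) -> slice:
        return slice(int(self.pep_offsets[pep_index]),
                     int(self.pep_offsets[pep_index + 1]))

    def bead_index(self, pep_index: int, residue_index: int, role: str) -> int:
        r = {"NH": 0, "CA": 1, "CO": 2, "R": 3}[role]
        sl = self.bead_slice(pep_index)
        for i in range(sl.start, sl.stop):
            if self.res[i] == residue_index and self.role[i] == r:
                return i
        raise KeyError((pep_index, residue_index, role))

    def calpha_indices(self, pep_index: int) -> np.ndarray:
        sl = self.bead_slice(pep_index)
        idx = np.arange(sl.start, sl.stop)
        return idx[self.role[sl] == 1]


_ROLE_OF = {"NH": 0, "CA": 1, "CO": 2, "R": 3}


def compile_system(
    sequences: Sequence[PeptideSequence],
    table: InteractionTable | None = None,
) -> CGSystem:
    """Compile peptide topologies and an interaction table into kernel arrays."""
    if table is None:
        table = default_interaction_table()
    sequences = list(sequences)
    topologies = [build_topology(s) for s in sequences]

    tokens = ["NH", "CA", "CO"]
    for seq in sequences:
        for code in seq.residues:
            tok = bead_type_token("R", code)
            if tok not in tokens:
                tokens.append(tok)

    btype, role, pep, res, mass = [], [], [], [], []
    pep_offsets = [0]
    bonds_global: list[tuple[int, int, float, float]] = []
    for p, (seq, topo) in enumerate(zip(sequences, topologies)):
        off = pep_offsets[-1]
        for bead in topo.beads:
            tok = (bead.bead_type if bead.bead_type != "R"
                   else bead_type_token("R", seq.residues[bead.residue_index]))
            btype.append(tokens.index(tok))
            role.append(_ROLE_OF[bead.bead_type])
            pep.append(p)
            res.append(bead.residue_index)
            mass.append(bead.mass)
        for bond in topo.bonds:
            lo = bond.length * (1.0 - bond.tolerance)
            hi = bond.length * (1.0 + bond.tolerance)
            bonds_global.append((off + bond.a, off + bond.b, lo * lo, hi * hi))
        pep_offsets.append(off + topo.n_beads)

    n = pep_offsets[-1]
    btype = np.array(btype, dtype=np.int64)
    role = np.array(role, dtype=np.int8)
    pep = np.array(pep, dtype=np.int64)
    res = np.array(res, dtype=np.int64)
    mass = np.array(mass, dtype=np.float64)

    # bond CSR (both directions)
    adj: list[list[tuple[int, float, float]]] = [[] for _ in range(n)]
    graph: list[list[int]] = [[] for _ in range(n)]
    for a, b, lo2, hi2 in bonds_global:
        adj[a].append((b, lo2, hi2))
        adj[b].append((a, lo2, hi2))
        graph[a].append(b)
        graph[b].append(a)
    bond_indptr = np.zeros(n + 1, dtype=np.int64)
    bj, blo, bhi = [], [], []
    for i in range(n):
        entries = sorted(adj[i])
        bond_indptr[i + 1] = bond_indptr[i] + len(entries)
        for j, lo2, hi2 in entries:
            bj.append(j)
            blo.append(lo2)
            bhi.append(hi2)
    bond_j = np.array(bj, dtype=np.int64)
    bond_lo2 = np.array(blo)
    bond_hi2 = np.array(bhi)

    # exclusions: beads within 3 bonds (same peptide), including bonded pairs
    excl_indptr = np.zeros(n + 1, dtype=np.int64)
    ej: list[int] = []
    for i in range(n):
        seen = {i: 0}
        frontier = [i]
        for depth in range(1, 4):
            nxt = []
            for u in frontier:
                for v in graph[u]:
                    if v not in seen:
                        seen[v] = depth
                        nxt.append(v)
            frontier = nxt
        excl = sorted(v for v in seen if v != i)
        excl_indptr[i + 1] = excl_indptr[i] + len(excl)
        ej.extend(excl)
    excl_j = np.array(ej, dtype=np.int64)

    # interaction matrices
    T = len(tokens)
    sig2 = np.zeros((T, T))
    lam2 = np.zeros((T, T))
    eps = np.zeros((T, T))
    for a in range(T):
        for b in range(T):
            sig2[a, b] = table.sigma(tokens[a], tokens[b]) ** 2
            well = table.well(tokens[a], tokens[b])
            if well is not None and well[1] < 0:
                lam2[a, b] = well[0] ** 2
                eps[a, b] = -well[1]

    # hydrogen-bond auxiliaries
    hb_aux1 = np.full(n, -1, dtype=np.int64)
    hb_aux2 = np.full(n, -1, dtype=np.int64)
    index_of: dict[tuple[int, int, int], int] = {}
    for i in range(n):
        index_of[(int(pep[i]), int(res[i]), int(role[i]))] = i
    for i in range(n):
        p, r = int(pep[i]), int(res[i])
        if role[i] == 0:      # NH: CA of same residue, CO of previous
            hb_aux1[i] = index_of[(p, r, 1)]
            hb_aux2[i] = index_of.get((p, r - 1, 2), -1)
        elif role[i] == 2:    # CO: CA of same residue, NH of next
            hb_aux1[i] = index_of[(p, r, 1)]
            hb_aux2[i] = index_of.get((p, r + 1, 0), -1)

    rule = table.hbond
    aux_min2 = np.array([d * d for _, d in rule.aux_criteria])
    if aux_min2.shape != (4,):
        raise ValueError("the H-bond rule needs exactly 4 auxiliary criteria")

    hydrophobic = np.array(
        [role[i] == 3 and
         RESIDUES[sequences[pep[i]].residues[res[i]]].res_class == "hydrophobic"
         for i in range(n)], dtype=bool)

    return CGSystem(
        sequences=sequences, topologies=topologies, table=table,
        type_tokens=tokens, btype=btype, role=role, pep=pep, res=res,
        mass=mass,
        bond_indptr=bond_indptr, bond_j=bond_j,
        bond_lo2=bond_lo2, bond_hi2=bond_hi2,
        excl_indptr=excl_indptr, excl_j=excl_j,
        sig2=sig2, lam2=lam2, eps=eps,
        hb_aux1=hb_aux1, hb_aux2=hb_aux2, aux_min2=aux_min2,
        hb_range2=rule.range ** 2,
        hb_eps=rule.epsilon_hb / EPS_HB_KJ,
        min_res_sep=rule.min_residue_separation,
        hydrophobic=hydrophobic,
        pep_offsets=np.array(pep_offsets, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# Events, frames, logs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Event:
    """A predicted or executed discontinuity."""

    time: float
    kind: str
    members: tuple[int, ...]


@dataclass
class Frame:
    time: float
    positions: np.ndarray
    partner: np.ndarray           # per-bead H-bond partner (-1 free)
    kinetic_energy: float
    potential_energy: float

    def hbond_pairs(self, system: CGSystem) -> list[tuple[int, int]]:
        nh = np.nonzero((system.role == 0) & (self.partner >= 0))[0]
        return [(int(i), int(self.partner[i])) for i in nh]

    @property
    def energy(self) -> float:
        return self.kinetic_energy + self.potential_energy


@dataclass
class Trajectory:
    system: CGSystem
    box_length: float
    frames: list[Frame]
    final_state: SystemState

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])


@dataclass
class EventLog:
    """Counts per event kind plus sampled (time, energy, T*, H-bonds)."""

    counts: dict[str, int]
    samples: pd.DataFrame

    def total_events(self) -> int:
        return int(sum(self.counts.values()))


# ---------------------------------------------------------------------------
# Python-level single-pair prediction and resolution (reference path)
# ---------------------------------------------------------------------------

def _pair_channel_py(system: CGSystem, state: SystemState, i: int, j: int):
    return _kernel._pair_channel.py_func(
        i, j, system.btype, system.role, system.pep, system.res,
        system.bond_indptr, system.bond_j, system.bond_lo2, system.bond_hi2,
        system.excl_indptr, system.excl_j, system.sig2, system.lam2,
        system.hb_range2, system.min_res_sep)


def pair_event_time(
    state: SystemState, i: int, j: int, system: CGSystem
) -> Event | None:
    """Earliest future discontinuity for the pair (i, j), or None.

    Exact quadratic-root solution under the minimum-image convention; raises
    if an interacting pair already overlaps its hard core.
    """
    if i == j:
        raise ValueError("need two distinct beads")
    box = state.box_length
    mode, p0, p1 = _pair_channel_py(system, state, i, j)
    if mode == 0:
        return None
    d = state.positions[i] - state.positions[j]
    d -= box * np.round(d / box)
    v = state.velocities[i] - state.velocities[j]
    d2 = float(d @ d)
    b = float(d @ v)
    v2 = float(v @ v)
    if mode == 1:
        if d2 < p0 * (1 - 1e-7) or d2 > p1 * (1 + 1e-7):
            raise RuntimeError(f"bonded pair ({i},{j}) outside its bond window")
        dt, kind = _kernel._predict_bond.py_func(d2, b, v2, p0, p1)
    else:
        if d2 < p0 * (1 - 1e-7):
            raise RuntimeError(f"pair ({i},{j}) overlaps its hard core")
        if mode == 3:
            registered = state.hbond_registry.get(i) == j or \
                state.hbond_registry.get(j) == i
            dt, kind = _kernel._predict_nonbond.py_func(
                d2, b, v2, p0, p1, 2 if registered else 1)
        else:
            dt, kind = _kernel._predict_nonbond.py_func(d2, b, v2, p0, p1, 0)
    if not np.isfinite(dt):
        return None
    return Event(time=state.time + dt, kind=_KIND_NAMES[int(kind)],
                 members=(i, j))


def resolve_event(
    state: SystemState,
    event: Event,
    system: CGSystem,
    t_star: float = 0.18,
    rng: np.random.Generator | None = None,
) -> SystemState:
    """Apply a two-body (or ghost) event to a copy of the state.

    Reference implementation of the collision rules used by the compiled
    event loop; momentum is conserved exactly for all two-body events.
    """
    out = state.copy()
    out.time = event.time
    dt = event.time - state.time
    out.positions = state.positions + state.velocities * dt

    if event.kind == "ghost":
        (i,) = event.members
        rng = rng or np.random.default_rng(0)
        out.velocities[i] = rng.normal(
            0.0, math.sqrt(t_star / system.mass[i]), 3)
        return out
    if event.kind in ("well_exit", "cell_cross"):
        return out

    i, j = event.members
    box = state.box_length
    d = out.positions[i] - out.positions[j]
    d -= box * np.round(d / box)
    dist = float(np.linalg.norm(d))
    u = d / dist
    mi, mj = system.mass[i], system.mass[j]
    mu = mi * mj / (mi + mj)
    vrel = out.velocities[i] - out.velocities[j]
    b = float(d @ vrel)
    vr = b / dist

    def reflect():
        fac = -2.0 * mu * b / dist**2
        out.velocities[i] += fac / mi * d
        out.velocities[j] -= fac / mj * d

    def radial(dvr):
        out.velocities[i] += mu / mi * dvr * u
        out.velocities[j] -= mu / mj * dvr * u

    ti, tj = system.btype[i], system.btype[j]
    if event.kind in ("core", "bond_wall"):
        reflect()
    elif event.kind == "capture":
        epsv = system.eps[ti, tj]
        radial(-math.sqrt(vr * vr + 2 * epsv / mu) - vr)
    elif event.kind == "escape":
        epsv = system.eps[ti, tj]
        if vr > 0 and 0.5 * mu * vr * vr >= epsv:
            radial(math.sqrt(vr * vr - 2 * epsv / mu) - vr)
        else:
            reflect()
    elif event.kind == "hbond_make":
        nh, co = (i, j) if system.role[i] == 0 else (j, i)
        free = nh not in out.hbond_registry and \
            co not in set(out.hbond_registry.values())
        if free and _aux_criteria_ok(out, system, nh, co):
            radial(-math.sqrt(vr * vr + 2 * system.hb_eps / mu) - vr)
            out.hbond_registry[nh] = co
        # else: transparent crossing
    elif event.kind == "hbond_break":
        nh, co = (i, j) if system.role[i] == 0 else (j, i)
        if out.hbond_registry.get(nh) != co:
            raise RuntimeError("hbond_break on an unregistered pair")
        if vr > 0 and 0.5 * mu * vr * vr >= system.hb_eps:
            radial(math.sqrt(vr * vr - 2 * system.hb_eps / mu) - vr)
            del out.hbond_registry[nh]
        else:
            reflect()
    else:
        raise ValueError(f"unknown event kind {event.kind!r}")
    return out


def _aux_criteria_ok(state: SystemState, system: CGSystem,
                     nh: int, co: int) -> bool:
    box = state.box_length
    pairs = [
        (system.hb_aux1[nh], co), (system.hb_aux2[nh], co),
        (system.hb_aux1[co], nh), (system.hb_aux2[co], nh),
    ]
    for k, (a, b) in enumerate(pairs):
        if a < 0:
            continue
        d = state.positions[a] - state.positions[b]
        d -= box * np.round(d / box)
        if float(d @ d) < system.aux_min2[k]:
            return False
    return True


# ---------------------------------------------------------------------------
# Observables
# ---------------------------------------------------------------------------

def _interaction_masks(system: CGSystem):
    """Dense boolean masks of excluded/bonded pairs (small systems only)."""
    n = system.n_beads
    excl = np.zeros((n, n), dtype=bool)
    for i in range(n):
        sl = slice(system.excl_indptr[i], system.excl_indptr[i + 1])
        excl[i, system.excl_j[sl]] = True
    np.fill_diagonal(excl, True)
    return excl


def _min_image_dist2(positions: np.ndarray, box: float) -> np.ndarray:
    d2 = np.zeros((len(positions), len(positions)))
    for ax in range(3):
        d = positions[:, ax, None] - positions[None, :, ax]
        d -= box * np.round(d / box)
        d2 += d * d
    return d2


def total_energy(state: SystemState, system: CGSystem) -> float:
    """Kinetic energy plus engaged square-well depths, in eps_HB units.

    A sidechain well contributes -eps whenever the pair is inside its range;
    every registered hydrogen bond contributes -eps_HB (= -1 reduced).
    """
    ke = 0.5 * float(np.sum(system.mass * np.sum(state.velocities**2, axis=1)))
    d2 = _min_image_dist2(state.positions, state.box_length)
    lam2 = system.lam2[system.btype][:, system.btype]
    eps = system.eps[system.btype][:, system.btype]
    excl = _interaction_masks(system)
    engaged = (lam2 > 0) & (d2 < lam2) & ~excl
    pe = -0.5 * float(np.sum(eps[engaged]))
    pe -= system.hb_eps * len(state.hbond_registry)
    return ke + pe


def instantaneous_temperature(state: SystemState, system: CGSystem) -> float:
    """Reduced temperature from the mean kinetic energy per degree of freedom."""
    ke = 0.5 * float(np.sum(system.mass * np.sum(state.velocities**2, axis=1)))
    return 2.0 * ke / (3.0 * state.n_beads)


def count_hbonds(state: SystemState) -> int:
    return len(state.hbond_registry)


def check_state(state: SystemState, system: CGSystem,
                tol: float = 1e-6) -> list[str]:
    """Verify the hard constraints of a state; returns a list of violations."""
    problems: list[str] = []
    pos = state.positions
    box = state.box_length
    d2 = _min_image_dist2(pos, box)
    sig2 = system.sig2[system.btype][:, system.btype]
    excl = _interaction_masks(system)
    # NH-CO registered pairs may sit inside the (larger) H-bond range but
    # never inside the core
    core_bad = (d2 < sig2 * (1 - tol)) & ~excl
    for i, j in zip(*np.nonzero(np.triu(core_bad, 1))):
        problems.append(f"core overlap {i}-{j}: d={math.sqrt(d2[i, j]):.4f}")
    for i in range(system.n_beads):
        for p in range(system.bond_indptr[i], system.bond_indptr[i + 1]):
            j = system.bond_j[p]
            if j < i:
                continue
            if d2[i, j] < system.bond_lo2[p] * (1 - tol) or \
                    d2[i, j] > system.bond_hi2[p] * (1 + tol):
                problems.append(
                    f"bond window violation {i}-{j}: "
                    f"d={math.sqrt(d2[i, j]):.4f}")
    cos = list(state.hbond_registry.values())
    if len(set(cos)) != len(cos):
        problems.append("hbond registry is not injective")
    for nh, co in state.hbond_registry.items():
        if system.role[nh] != 0 or system.role[co] != 2:
            problems.append(f"registry pair {nh}-{co} has wrong bead roles")
        if d2[nh, co] > system.hb_range2 * (1 + 1e-6):
            problems.append(
                f"registered H-bond {nh}-{co} outside range: "
                f"d={math.sqrt(d2[nh, co]):.4f}")
    return problems


def maxwell_velocities(system: CGSystem, t_star: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Maxwell-Boltzmann velocities at reduced temperature t_star."""
    sd = np.sqrt(t_star / system.mass)[:, None]
    return rng.normal(size=(system.n_beads, 3)) * sd


# ---------------------------------------------------------------------------
# The event loop
# ---------------------------------------------------------------------------

def run_dmd(
    state: SystemState,
    system: CGSystem,
    t_star: float = 0.18,
    ghost_rate: float = 0.01,
    max_events: int = 100_000,
    max_time: float = math.inf,
    sample_every: float = 50.0,
    seed: int = 0,
    use_cells: bool = True,
    max_frames: int = 4096,
) -> tuple[Trajectory, EventLog]:
    """Run event-driven dynamics from ``state``.

    ``max_events`` counts physical events (collisions, wall hits, well and
    H-bond events, ghost collisions); cell-list bookkeeping is free.  The
    trajectory holds frames sampled every ``sample_every`` reduced time
    units, and the final state after the last event.  Deterministic for a
    fixed seed.
    """
    if t_star <= 0:
        raise ValueError("t_star must be positive")
    n = system.n_beads
    if state.n_beads != n:
        raise ValueError("state does not match system size")

    pos = np.mod(state.positions.astype(float).copy(), state.box_length)
    vel = state.velocities.astype(float).copy()
    partner = np.full(n, -1, dtype=np.int64)
    for nh, co in state.hbond_registry.items():
        partner[nh] = co
        partner[co] = nh

    if math.isfinite(max_time):
        cap = int((max_time - state.time) / sample_every) + 2
        cap = min(cap, max_frames)
    else:
        cap = max_frames
    fr_time = np.zeros(cap)
    fr_pos = np.zeros((cap, n, 3))
    fr_partner = np.zeros((cap, n), dtype=np.int64)
    fr_ke = np.zeros(cap)
    fr_pe = np.zeros(cap)
    counts = np.zeros(_kernel.N_COUNTERS, dtype=np.int64)

    (n_frames, t_final, pe_final, err, err_i, err_j, n_phys) = \
        _kernel.run_kernel(
            pos, vel, system.mass, system.btype, system.role,
            system.pep, system.res,
            system.bond_indptr, system.bond_j,
            system.bond_lo2, system.bond_hi2,
            system.excl_indptr, system.excl_j,
            system.sig2, system.lam2, system.eps,
            system.hb_aux1, system.hb_aux2, system.aux_min2,
            system.hb_range2, system.hb_eps, system.min_res_sep,
            partner,
            float(state.box_length), float(state.time),
            float(t_star), float(ghost_rate),
            int(max_events), float(max_time), float(sample_every),
            int(seed) & 0x7FFFFFFF, bool(use_cells),
            fr_time, fr_pos, fr_partner, fr_ke, fr_pe, counts,
        )

    if err != _kernel.E_OK:
        names = {_kernel.E_OVERLAP: "hard-core overlap",
                 _kernel.E_BOND_RANGE: "bond outside its wall window",
                 _kernel.E_REGISTRY: "H-bond registry conflict"}
        raise RuntimeError(
            f"invariant violation before/while running: "
            f"{names.get(err, err)} for beads ({err_i}, {err_j})")

    frames = [
        Frame(
            time=float(fr_time[k]),
            positions=fr_pos[k].copy(),
            partner=fr_partner[k].copy(),
            kinetic_energy=float(fr_ke[k]),
            potential_energy=float(fr_pe[k]),
        )
        for k in range(n_frames)
    ]
    registry = {int(i): int(partner[i])
                for i in np.nonzero((system.role == 0) & (partner >= 0))[0]}
    final_state = SystemState(
        positions=pos, velocities=vel, box_length=state.box_length,
        time=float(t_final), hbond_registry=registry, rng_seed=seed,
    )
    log = EventLog(
        counts={name: int(c) for name, c in zip(_COUNTER_NAMES, counts)},
        samples=pd.DataFrame({
            "time": fr_time[:n_frames],
            "energy": fr_ke[:n_frames] + fr_pe[:n_frames],
            "t_star": 2.0 * fr_ke[:n_frames] / (3.0 * n),
            "n_hbonds": [int(np.sum((system.role == 0) & (fr_partner[k] >= 0)))
                         for k in range(n_frames)],
        }),
    )
    traj = Trajectory(system=system, box_length=state.box_length,
                      frames=frames, final_state=final_state)
    return traj, log
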