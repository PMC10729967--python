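"""Event prediction, collision rules, conservation laws and determinism."""

import math

import numpy as np
import pytest

from catchsim import dmd_engine as de
from catchsim.dmd_engine import Event, pair_event_time, resolve_event
from catchsim.peptide_model import SystemState, catch_sequence
from catchsim.structure_builder import ideal_strand, random_coil_box

BOX = 200.0


def _dimer_state(system, i, j, ri, rj, vi, vj):
    """Both peptides parked far apart, beads i and j overridden."""
    n = system.n_beads
    pos = np.zeros((n, 3))
    half = system.bead_slice(0).stop
    coords0 = ideal_strand(system.sequences[0])
    coords1 = ideal_strand(system.sequences[1])
    pos[:half] = coords0 - coords0.mean(0) + 40.0
    pos[half:] = coords1 - coords1.mean(0) + 150.0
    vel = np.zeros((n, 3))
    pos[i] = ri
    pos[j] = rj
    vel[i] = vi
    vel[j] = vj
    return SystemState(pos, vel, BOX)


def _scan_oracle(state, i, j, threshold_sqs, t_max=20.0):
    """First threshold crossing of the pair distance by dense scan+bisection."""
    r0 = state.positions[i] - state.positions[j]
    r0 -= BOX * np.round(r0 / BOX)
    v = state.velocities[i] - state.velocities[j]

    def d2(t):
        r = r0 + v * t
        return float(r @ r)

    grid = np.linspace(0.0, t_max, 200001)
    best = math.inf
    for s2 in threshold_sqs:
        f0 = d2(0.0) - s2
        for k in range(1, len(grid)):
            f1 = d2(grid[k]) - s2
            if f0 == 0.0:
                f0 = f1
                continue
            if f0 * f1 < 0:
                lo, hi = grid[k - 1], grid[k]
                for _ in range(80):
                    mid = 0.5 * (lo + hi)
                    if (d2(mid) - s2) * f0 < 0:
                        hi = mid
                    else:
                        lo = mid
                best = min(best, 0.5 * (lo + hi))
                break
            f0 = f1
    return best


class TestPairEventTime:
    def test_head_on_core_contact(self, dimer_system):
        sys_ = dimer_system
        ca0 = sys_.bead_index(0, 5, "CA")
        ca1 = sys_.bead_index(1, 5, "CA")
        sigma = math.sqrt(sys_.sig2[sys_.btype[ca0], sys_.btype[ca1]])
        gap = 4.0
        state = _dimer_state(sys_, ca0, ca1,
                             [50.0, 50.0, 50.0],
                             [50.0 + sigma + gap, 50.0, 50.0],
                             [0.5, 0.0, 0.0], [-0.5, 0.0, 0.0])
        ev = pair_event_time(state, ca0, ca1, sys_)
        assert ev.kind == "core"
        assert ev.time == pytest.approx(gap / 1.0, rel=1e-12)

    def test_receding_pair_has_no_event(self, dimer_system):
        sys_ = dimer_system
        ca0 = sys_.bead_index(0, 5, "CA")
        ca1 = sys_.bead_index(1, 5, "CA")
        state = _dimer_state(sys_, ca0, ca1,
                             [50.0, 50.0, 50.0], [60.0, 50.0, 50.0],
                             [-0.3, 0.0, 0.0], [0.3, 0.0, 0.0])
        assert pair_event_time(state, ca0, ca1, sys_) is None

    def test_same_bead_rejected(self, dimer_system):
        state = _dimer_state(dimer_system, 0, 45, [50] * 3, [150] * 3,
                             [0] * 3, [0] * 3)
        with pytest.raises(ValueError):
            pair_event_time(state, 3, 3, dimer_system)

    @pytest.mark.parametrize("seed", range(12))
    def test_randomized_pairs_match_time_scan(self, dimer_system, seed):
        """Exact quadratic roots agree with a dense scan+bisection oracle."""
        sys_ = dimer_system
        rng = np.random.default_rng(seed)
        kind = seed % 3
        if kind == 0:      # bonded pair (NH-CA of residue 0)
            i = sys_.bead_index(0, 0, "NH")
            j = sys_.bead_index(0, 0, "CA")
            ptr = None
            for p in range(sys_.bond_indptr[i], sys_.bond_indptr[i + 1]):
                if sys_.bond_j[p] == j:
                    ptr = p
            lo = math.sqrt(sys_.bond_lo2[ptr])
            hi = math.sqrt(sys_.bond_hi2[ptr])
            d0 = rng.uniform(lo * 1.001, hi * 0.999)
            thresholds = [sys_.bond_lo2[ptr], sys_.bond_hi2[ptr]]
        elif kind == 1:    # F-F sidechain pair with a square well
            i = sys_.bead_index(0, 3, "R")
            j = sys_.bead_index(1, 3, "R")
            lam = math.sqrt(sys_.lam2[sys_.btype[i], sys_.btype[j]])
            d0 = rng.uniform(lam * 1.05, lam * 2.5)
            thresholds = [sys_.sig2[sys_.btype[i], sys_.btype[j]],
                          sys_.lam2[sys_.btype[i], sys_.btype[j]]]
        else:              # NH-CO hydrogen-bond channel
            i = sys_.bead_index(0, 2, "NH")
            j = sys_.bead_index(1, 6, "CO")
            d0 = rng.uniform(5.0, 12.0)
            thresholds = [sys_.sig2[sys_.btype[i], sys_.btype[j]],
                          sys_.hb_range2]
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        ri = np.array([70.0, 70.0, 70.0])
        rj = ri + d0 * u
        vi = rng.normal(scale=0.3, size=3)
        vj = rng.normal(scale=0.3, size=3)
        state = _dimer_state(dimer_system, i, j, ri, rj, vi, vj)
        t_max = 20.0
        ev = pair_event_time(state, i, j, sys_)
        oracle = _scan_oracle(state, i, j, thresholds, t_max)
        if ev is None or ev.time > t_max:
            assert oracle == math.inf or oracle > t_max * 0.999
        else:
            assert ev.time == pytest.approx(oracle, abs=1e-9)


class TestResolveEvent:
    def test_equal_mass_head_on_exchanges_velocities(self, dimer_system):
        sys_ = dimer_system
        i = sys_.bead_index(0, 5, "CA")
        j = sys_.bead_index(1, 5, "CA")
        sigma = math.sqrt(sys_.sig2[sys_.btype[i], sys_.btype[j]])
        state = _dimer_state(sys_, i, j,
                             [50.0, 50.0, 50.0],
                             [50.0 + sigma, 50.0, 50.0],
                             [0.4, 0.0, 0.0], [-0.1, 0.0, 0.0])
        out = resolve_event(state, Event(0.0, "core", (i, j)), sys_)
        assert out.velocities[i] == pytest.approx([-0.1, 0, 0])
        assert out.velocities[j] == pytest.approx([0.4, 0, 0])

    def test_capture_gains_exactly_the_well_depth(self, dimer_system):
        sys_ = dimer_system
        i = sys_.bead_index(0, 3, "R")
        j = sys_.bead_index(1, 3, "R")
        eps = sys_.eps[sys_.btype[i], sys_.btype[j]]
        lam = math.sqrt(sys_.lam2[sys_.btype[i], sys_.btype[j]])
        state = _dimer_state(sys_, i, j,
                             [60.0, 60.0, 60.0], [60.0 + lam, 60.0, 60.0],
                             [0.2, 0.05, 0.0], [-0.2, 0.0, 0.0])
        m = sys_.mass
        ke0 = 0.5 * float((m[:, None] * state.velocities ** 2).sum())
        out = resolve_event(state, Event(0.0, "capture", (i, j)), sys_)
        ke1 = 0.5 * float((m[:, None] * out.velocities ** 2).sum())
        assert ke1 - ke0 == pytest.approx(eps, rel=1e-12)

    def test_insufficient_escape_bounces_back(self, dimer_system):
        sys_ = dimer_system
        i = sys_.bead_index(0, 3, "R")
        j = sys_.bead_index(1, 3, "R")
        lam = math.sqrt(sys_.lam2[sys_.btype[i], sys_.btype[j]])
        # tiny outward radial speed: radial KE far below the well depth
        state = _dimer_state(sys_, i, j,
                             [60.0, 60.0, 60.0], [60.0 + lam, 60.0, 60.0],
                             [-0.01, 0.0, 0.0], [0.01, 0.0, 0.0])
        m = sys_.mass
        e0 = 0.5 * float((m[:, None] * state.velocities ** 2).sum())
        out = resolve_event(state, Event(0.0, "escape", (i, j)), sys_)
        e1 = 0.5 * float((m[:, None] * out.velocities ** 2).sum())
        assert e1 == pytest.approx(e0, rel=1e-12)          # no energy change
        r = out.positions[i] - out.positions[j]
        v = out.velocities[i] - out.velocities[j]
        assert float(r @ v) < 0                            # now approaching

    @pytest.mark.parametrize("kind", ["core", "capture", "escape"])
    def test_momentum_conserved_exactly(self, dimer_system, kind):
        sys_ = dimer_system
        i = sys_.bead_index(0, 3, "R")
        j = sys_.bead_index(1, 3, "R")
        lam = math.sqrt(sys_.lam2[sys_.btype[i], sys_.btype[j]])
        sigma = math.sqrt(sys_.sig2[sys_.btype[i], sys_.btype[j]])
        d = sigma if kind == "core" else lam
        rng = np.random.default_rng(hash(kind) % 2**31)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        ri = np.array([60.0, 60.0, 60.0])
        state = _dimer_state(sys_, i, j, ri, ri + d * u,
                             rng.normal(scale=0.3, size=3),
                             rng.normal(scale=0.3, size=3))
        m = sys_.mass
        p0 = (m[:, None] * state.velocities).sum(axis=0)
        out = resolve_event(state, Event(0.0, kind, (i, j)), sys_)
        p1 = (m[:, None] * out.velocities).sum(axis=0)
        assert p1 == pytest.approx(p0, abs=1e-12)


class TestObservables:
    def test_static_system_without_wells_has_zero_energy(self, dimer_system):
        state = _dimer_state(dimer_system, 0, 45, [40.0] * 3, [150.0] * 3,
                             [0.0] * 3, [0.0] * 3)
        assert de.total_energy(state, dimer_system) == pytest.approx(0.0)

    def test_one_registered_hbond_at_rest(self, dimer_system):
        sys_ = dimer_system
        nh = sys_.bead_index(0, 0, "NH")
        co = sys_.bead_index(1, 0, "CO")
        state = _dimer_state(sys_, nh, co, [40.0] * 3,
                             [44.0, 40.0, 40.0], [0.0] * 3, [0.0] * 3)
        state.hbond_registry = {nh: co}
        assert de.total_energy(state, sys_) == pytest.approx(-1.0)
        assert de.count_hbonds(state) == 1

    def test_instantaneous_temperature_matches_sampling(self):
        cb = random_coil_box(2, 2, 70.0, seed=21, t_star=0.25)
        # 528 degrees of freedom: sampling error of the mean is ~6%
        assert de.instantaneous_temperature(cb.state, cb.system) == \
            pytest.approx(0.25, rel=0.2)

    def test_kernel_potential_energy_matches_brute_force(self):
        cb = random_coil_box(2, 2, 55.0, seed=13)
        traj, _ = de.run_dmd(cb.state, cb.system, t_star=0.18,
                             ghost_rate=0.02, max_events=30000,
                             sample_every=25.0, seed=99)
        frame = traj.frames[-1]
        registry = {int(i): int(p) for i, p in enumerate(frame.partner)
                    if p >= 0 and cb.system.role[i] == 0}
        state = SystemState(frame.positions,
                            np.zeros_like(frame.positions),
                            cb.state.box_length, hbond_registry=registry)
        assert frame.potential_energy == pytest.approx(
            de.total_energy(state, cb.system), abs=1e-9)


class TestRunDMD:
    def test_deterministic_under_seed(self):
        cb = random_coil_box(1, 1, 45.0, seed=6)
        outs = []
        for _ in range(2):
            traj, _ = de.run_dmd(cb.state.copy(), cb.system, t_star=0.18,
                                 ghost_rate=0.05, max_events=20000,
                                 sample_every=20.0, seed=42)
            outs.append(traj.final_state)
        assert np.array_equal(outs[0].positions, outs[1].positions)
        assert np.array_equal(outs[0].velocities, outs[1].velocities)

    def test_energy_conserved_without_thermostat(self):
        cb = random_coil_box(1, 1, 45.0, seed=8)
        _, log = de.run_dmd(cb.state.copy(), cb.system, t_star=0.3,
                            ghost_rate=0.0, max_events=30000,
                            sample_every=20.0, seed=2)
        e = log.samples.energy.to_numpy()
        assert abs(e[-1] - e[0]) / abs(e[0]) < 1e-8

    def test_total_momentum_conserved_without_thermostat(self):
        cb = random_coil_box(1, 1, 45.0, seed=8)
        m = cb.system.mass[:, None]
        p0 = (m * cb.state.velocities).sum(axis=0)
        traj, _ = de.run_dmd(cb.state.copy(), cb.system, t_star=0.3,
                             ghost_rate=0.0, max_events=30000,
                             sample_every=20.0, seed=2)
        p1 = (m * traj.final_state.velocities).sum(axis=0)
        assert p1 == pytest.approx(p0, abs=1e-9)

    def test_cell_list_equivalence(self):
        cb = random_coil_box(2, 2, 60.0, seed=14)
        frames = []
        for cells in (True, False):
            traj, _ = de.run_dmd(cb.state.copy(), cb.system, t_star=0.18,
                                 ghost_rate=0.0, max_events=4000,
                                 sample_every=2.0, seed=3, use_cells=cells,
                                 max_frames=64)
            frames.append(traj.frames)
        assert len(frames[0]) == len(frames[1])
        for fa, fb in zip(frames[0], frames[1]):
            assert np.allclose(fa.positions, fb.positions, atol=1e-9)
            assert np.array_equal(fa.partner, fb.partner)

    def test_invariants_hold_after_run(self):
        cb = random_coil_box(2, 2, 55.0, seed=17)
        traj, _ = de.run_dmd(cb.state.copy(), cb.system, t_star=0.18,
                             ghost_rate=0.05, max_events=50000,
                             sample_every=50.0, seed=7)
        assert de.check_state(traj.final_state, cb.system) == []
        # registry on every sampled frame is a matching within range
        for frame in traj.frames:
            partner = frame.partner
            for i in np.nonzero(partner >= 0)[0]:
                assert partner[partner[i]] == i

    def test_overlapping_start_rejected(self, dimer_system):
        sys_ = dimer_system
        n = sys_.n_beads
        coords0 = ideal_strand(sys_.sequences[0])
        pos = np.zeros((n, 3))
        pos[:44] = coords0 - coords0.mean(0) + 40.0
        pos[44:] = coords0 - coords0.mean(0) + 40.3  # nearly superimposed
        state = SystemState(pos, np.zeros_like(pos), BOX)
        with pytest.raises(RuntimeError, match="overlap|invariant"):
            de.run_dmd(state, sys_, max_events=100, seed=0)


class TestChargeComplementarity:
    def test_complementary_peptides_hydrogen_bond_like_charges_do_not(self):
        """K/E dimers form backbone H-bonds; K/K dimers never connect."""
        ke_total = 0
        for seed in range(3):
            cb = random_coil_box(1, 1, 38.0, seed=seed)
            traj, _ = de.run_dmd(cb.state, cb.system, t_star=0.18,
                                 ghost_rate=0.05, max_events=600000,
                                 sample_every=500.0, seed=seed + 30)
            fs = traj.final_state
            ke_total += sum(
                1 for nh, co in fs.hbond_registry.items()
                if cb.system.pep[nh] != cb.system.pep[co])
        assert ke_total >= 1

        for seed in range(2):
            cb = random_coil_box(2, 0, 38.0, seed=seed)
            traj, _ = de.run_dmd(cb.state, cb.system, t_star=0.18,
                                 ghost_rate=0.05, max_events=300000,
                                 sample_every=500.0, seed=seed + 60)
            fs = traj.final_state
            inter = sum(
                1 for nh, co in fs.hbond_registry.items()
                if cb.system.pep[nh] != cb.system.pep[co])
            # like-charge pair: no 5-H-bond connection ever forms
            assert inter < 5
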