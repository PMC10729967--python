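"""Twist, plane fits, detectors, RMSD and secondary-structure aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from catchsim.structure_builder import build_sheet, salt_bridge_fixture
from catchsim.structure_metrics import (
    AtomisticStructure,
    SecondaryContentTable,
    aggregate_secondary,
    class_totals,
    contact_map,
    fit_plane,
    group_contacts,
    hydrogen_bonds,
    kabsch_rmsd,
    pair_twist,
    salt_bridges,
    sheet_separation,
    sheet_twist,
    strand_axis,
)

from conftest import (
    brute_force_contacts,
    brute_force_hbonds,
    random_hbond_geometry,
    random_salt_structure,
)


def _simple_structure(coords, codes=None, chains=None, resi=None):
    n = len(coords)
    return AtomisticStructure(
        chain_ids=np.array(chains if chains is not None else ["A"] * n),
        residue_indices=np.array(resi if resi is not None else range(n)),
        residue_codes=np.array(codes if codes is not None else ["G"] * n),
        atom_names=np.array([f"X{i}" for i in range(n)]),
        elements=np.array(["C"] * n),
        coords=np.asarray(coords, float),
    )


class TestStrandAxis:
    def test_points_on_x_axis(self):
        pts = np.array([[i, 0.0, 0.0] for i in range(5)])
        assert strand_axis(pts) == pytest.approx([1, 0, 0])

    def test_orientation_follows_terminal_order(self):
        pts = np.array([[i, 0.0, 0.0] for i in range(5)])[::-1]
        assert strand_axis(pts) == pytest.approx([-1, 0, 0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            strand_axis(np.zeros((2, 3)))

    def test_builder_closure(self, seq_6k, seq_6e):
        sheet = build_sheet(seq_6k, seq_6e, n_strands=2)
        axis = strand_axis(sheet.strand_calphas(0))
        assert abs(float(axis @ [0, 1, 0])) == pytest.approx(1.0, abs=1e-6)


class TestPairTwist:
    def test_identical_axes(self):
        assert pair_twist([0, 1, 0], [0, 1, 0], [1, 0, 0]) == 0.0

    def test_antiparallel_axes_are_aligned_first(self):
        assert pair_twist([0, 1, 0], [0, -1, 0], [1, 0, 0]) == \
            pytest.approx(0.0, abs=1e-12)

    def test_sign_flips_under_mirror(self):
        a = np.array([0.0, 1.0, 0.0])
        b = Rotation.from_euler("x", -3.0, degrees=True).apply(a)
        stack = np.array([1.0, 0.0, 0.0])
        t1 = pair_twist(a, b, stack)
        # mirror the geometry through the xy plane
        t2 = pair_twist(a * [1, 1, -1], b * [1, 1, -1], stack)
        assert t1 == pytest.approx(-t2, abs=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            pair_twist([0, 0, 0], [0, 1, 0], [1, 0, 0])

    def test_sheet_twist_recovers_construction(self, seq_6k, seq_6e):
        sheet = build_sheet(seq_6k, seq_6e, n_strands=12,
                            twist_per_strand=-2.22)
        assert sheet_twist(sheet.sheet_calphas(0)) == \
            pytest.approx(-2.22, abs=0.05)


class TestPlanes:
    def test_parallel_plane_distance(self):
        rng = np.random.default_rng(0)
        a = np.column_stack([rng.uniform(0, 10, 30), rng.uniform(0, 10, 30),
                             np.zeros(30)])
        b = a + [0.0, 0.0, 11.5]
        assert sheet_separation(a, b) == pytest.approx(11.5, abs=1e-9)

    def test_isometry_invariance(self):
        rng = np.random.default_rng(1)
        a = np.column_stack([rng.uniform(0, 10, 25), rng.uniform(0, 10, 25),
                             rng.normal(0, 0.1, 25)])
        b = a + [0.0, 0.0, 13.0]
        rot = Rotation.random(random_state=2).as_matrix()
        shift = np.array([5.0, -3.0, 2.0])
        d0 = sheet_separation(a, b)
        d1 = sheet_separation(a @ rot.T + shift, b @ rot.T + shift)
        assert d1 == pytest.approx(d0, abs=1e-9)

    def test_collinear_points_rejected(self):
        line = np.array([[i, 0.0, 0.0] for i in range(5)])
        with pytest.raises(ValueError):
            fit_plane(line)


class TestHydrogenBondDetector:
    def _fixture(self, dist, angle):
        d = np.array([0.0, 0.0, 0.0])
        h = np.array([1.0, 0.0, 0.0])
        rad = np.radians(angle)
        a = h + dist * np.array([-np.cos(rad), 0.0, np.sin(rad)])
        return _simple_structure([d, h, a]), [(0, 1)], [2]

    def test_inside_both_cutoffs(self):
        s, donors, acc = self._fixture(2.9, 170.0)
        assert len(hydrogen_bonds(s, donors, acc)) == 1

    def test_angle_failure(self):
        s, donors, acc = self._fixture(2.9, 130.0)
        assert len(hydrogen_bonds(s, donors, acc)) == 0

    def test_distance_failure(self):
        s, donors, acc = self._fixture(3.1, 170.0)
        assert len(hydrogen_bonds(s, donors, acc)) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        s, donors, acc = random_hbond_geometry(rng)
        found = sorted((b.hydrogen_index, b.acceptor_index)
                       for b in hydrogen_bonds(s, donors, acc))
        assert found == brute_force_hbonds(s, donors, acc)

    def test_missing_hydrogens_named(self):
        s = _simple_structure([[0, 0, 0], [3, 0, 0]], codes=["K", "E"],
                              resi=[1, 2])
        s.atom_names = np.array(["NZ", "OE1"])
        with pytest.raises(ValueError, match="K1"):
            salt_bridges(s)


class TestSaltBridges:
    def test_reported_geometry_matches_fixture(self):
        rep = salt_bridges(salt_bridge_fixture(2.8, 156.0))
        assert len(rep) == 1
        assert rep.mean_length == pytest.approx(2.8)
        assert rep.mean_angle == pytest.approx(156.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(100 + seed)
        s = random_salt_structure(rng)
        donors, acceptors = [], []
        names = s.atom_names
        for i in range(s.n_atoms):
            if names[i] == "NZ":
                for k in range(3):
                    donors.append((i, i + 1 + k))
            elif names[i].startswith(("OE", "OD")):
                acceptors.append(i)
        expected = brute_force_hbonds(s, donors, acceptors)
        found = sorted((b.hydrogen_index, b.acceptor_index)
                       for b in salt_bridges(s).bridges)
        assert found == expected


class TestContacts:
    def test_cutoff_boundary(self):
        s = _simple_structure([[0, 0, 0], [6.9, 0, 0]], codes=["K", "E"])
        assert contact_map(s).get("E", "K") == 1
        s2 = _simple_structure([[0, 0, 0], [7.1, 0, 0]], codes=["K", "E"])
        assert contact_map(s2).get("E", "K") == 0

    def test_intra_residue_pairs_excluded(self):
        s = _simple_structure([[0, 0, 0], [1, 0, 0]], codes=["K", "K"],
                              resi=[1, 1])
        assert contact_map(s).total() == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = 150
        codes = rng.choice(list("KEDFQ"), n)
        s = _simple_structure(rng.uniform(0, 25, (n, 3)), codes=codes,
                              resi=rng.integers(1, 40, n),
                              chains=rng.choice(["A", "B"], n))
        assert contact_map(s).counts == brute_force_contacts(s)

    def test_group_contacts_requires_disjoint_selections(self):
        s = _simple_structure(np.zeros((4, 3)))
        with pytest.raises(ValueError, match="disjoint"):
            group_contacts(s, [0, 1], [1, 2])
        with pytest.raises(ValueError, match="empty"):
            group_contacts(s, [], [1])

    def test_group_contacts_counts_cross_pairs_only(self):
        coords = [[0, 0, 0], [1, 0, 0], [2, 0, 0], [50, 0, 0]]
        s = _simple_structure(coords, resi=[1, 2, 3, 4])
        assert group_contacts(s, [0], [1, 2, 3]) == 2

    def test_isometry_invariance(self):
        rng = np.random.default_rng(7)
        n = 80
        coords = rng.uniform(0, 20, (n, 3))
        s = _simple_structure(coords, codes=rng.choice(list("KEF"), n),
                              resi=np.arange(n))
        rot = Rotation.random(random_state=3).as_matrix()
        s2 = s.transformed(rot, np.array([3.0, 4.0, 5.0]))
        assert contact_map(s).counts == contact_map(s2).counts


class TestKabschRMSD:
    def test_identical_sets(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        assert kabsch_rmsd(pts, pts) == pytest.approx(0.0, abs=1e-6)

    def test_rigid_motion_removed(self):
        pts = np.random.default_rng(1).normal(size=(12, 3))
        rot = Rotation.random(random_state=4).as_matrix()
        moved = pts @ rot.T + [1.0, -2.0, 3.0]
        assert kabsch_rmsd(pts, moved) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_svd_solution(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(15, 3))
        b = a + rng.normal(scale=0.3, size=(15, 3))
        # independent classic Kabsch: SVD of the covariance matrix
        a0 = a - a.mean(0)
        b0 = b - b.mean(0)
        u, s, vt = np.linalg.svd(a0.T @ b0)
        d = np.sign(np.linalg.det(u @ vt))
        r = u @ np.diag([1.0, 1.0, d]) @ vt
        expected = float(np.sqrt(((a0 - b0 @ r.T) ** 2).sum() / len(a)))
        assert kabsch_rmsd(a, b) == pytest.approx(expected, rel=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))


class TestSecondaryAggregation:
    def test_all_coil(self):
        frames = {f: {r: "coil" for r in range(11)} for f in range(20)}
        table = aggregate_secondary(frames)
        totals = class_totals(table)
        assert totals["coil"] == pytest.approx(11.0)
        assert (table.per_residue["coil"] == 1.0).all()

    def test_occupancy_conservation(self):
        rng = np.random.default_rng(3)
        classes = ["helix_alpha", "helix_310", "bend", "turn", "coil"]
        frames = {f: {r: rng.choice(classes) for r in range(7)}
                  for f in range(30)}
        table = aggregate_secondary(frames)
        row_sums = table.per_residue.sum(axis=1)
        assert np.allclose(row_sums, 1.0, atol=1e-12)
        totals = class_totals(table)
        assert sum(totals[c] for c in
                   ("helix_310", "helix_alpha", "helix_pi", "bend", "turn",
                    "coil", "strand")) == pytest.approx(7.0, abs=1e-12)

    def test_helix_total_combines_three_helix_classes(self):
        frames = {0: {0: "helix_alpha", 1: "helix_310", 2: "helix_pi"},
                  1: {0: "helix_alpha", 1: "coil", 2: "coil"}}
        totals = class_totals(aggregate_secondary(frames))
        assert totals["helix"] == pytest.approx(
            totals["helix_310"] + totals["helix_alpha"] + totals["helix_pi"])

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="spaghetti"):
            aggregate_secondary({0: {0: "spaghetti", 1: "coil"}})

    def test_incomplete_assignment_rejected(self):
        df = pd.DataFrame({0: ["coil", None], 1: ["coil", "coil"]})
        with pytest.raises(ValueError):
            aggregate_secondary(df)

    def test_occupancy_bounds_enforced(self):
        bad = pd.DataFrame({"coil": [0.5, 1.4]})
        with pytest.raises(ValueError):
            SecondaryContentTable.from_occupancies(bad)
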