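"""Synthetic-structure generators: ideal beta-sheet architectures, random
dispersions and scripted assembly trajectories with known ground truth.

The builders construct the idealised co-assembled geometries of binary
charge-complementary (CATCH-type) peptide systems: in-register antiparallel
beta-sheets with alternating cationic/anionic strands (~5 A strand spacing),
bilayers with the phenylalanine sidechains buried between two sheets
(~13 A sheet gap), and two-bilayer stacks whose facing charged sidechains
are either in contact (stacked) or separated.

Coordinate convention: sheet long axis (strand stacking) = x, strand axis
= y (alternating direction), bilayer stacking = z; a right-handed frame, so
a negative twist is left-handed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from catchsim import dmd_engine
from catchsim.dmd_engine import CGSystem, Frame, Trajectory, compile_system
from catchsim.peptide_model import (
    RESIDUES,
    RISE_PER_RESIDUE,
    InteractionTable,
    PeptideSequence,
    SystemState,
    catch_sequence,
    local_bead_offsets,
)
from catchsim.structure_metrics import AtomisticStructure

__all__ = [
    "Strand",
    "SheetModel",
    "GroundTruth",
    "ideal_strand",
    "build_sheet",
    "build_bilayer",
    "build_two_bilayers",
    "random_coil_box",
    "CoilBox",
    "salt_bridge_fixture",
    "ScriptedCluster",
    "FrameScript",
    "scripted_trajectory",
]

_BEAD_PDB_NAME = {"NH": "N", "CA": "CA", "CO": "C", "R": "R"}


# ---------------------------------------------------------------------------
# Ground truth / model containers
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Construction parameters recorded for test consumption only."""

    true_twist: float = 0.0
    true_strand_spacing: float = 0.0
    true_sheet_separations: list[float] = field(default_factory=list)
    true_cluster_labels: list[dict[int, int]] = field(default_factory=list)
    true_classes: list[dict[int, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "true_twist": self.true_twist,
            "true_strand_spacing": self.true_strand_spacing,
            "true_sheet_separations": list(self.true_sheet_separations),
            "true_cluster_labels": [
                {str(k): v for k, v in d.items()}
                for d in self.true_cluster_labels],
            "true_classes": [
                {str(k): v for k, v in d.items()} for d in self.true_classes],
        }


@dataclass
class Strand:
    sequence: PeptideSequence
    orientation: str              # '+' or '-'
    coords: np.ndarray            # (n_beads, 3) in topology bead order


@dataclass
class SheetModel:
    """Ordered strands grouped into sheets, with builder parameters."""

    strands: list[Strand]
    sheets: list[list[int]]
    strand_spacing: float
    sheet_gap: float
    twist_per_strand: float
    layer_gaps: list[float]
    ground_truth: GroundTruth

    @property
    def n_peptides(self) -> int:
        return len(self.strands)

    def _roles(self, strand: Strand) -> list[tuple[int, str]]:
        out = []
        for i, code in enumerate(strand.sequence.residues):
            out.append((i, "NH"))
            out.append((i, "CA"))
            out.append((i, "CO"))
            if RESIDUES[code].has_sidechain:
                out.append((i, "R"))
        return out

    def strand_calphas(self, strand_index: int) -> np.ndarray:
        strand = self.strands[strand_index]
        rows = [k for k, (_, r) in enumerate(self._roles(strand)) if r == "CA"]
        return strand.coords[rows]

    def sheet_calphas(self, sheet_index: int) -> list[np.ndarray]:
        return [self.strand_calphas(s) for s in self.sheets[sheet_index]]

    def sheet_backbone(self, sheet_index: int) -> np.ndarray:
        pts = []
        for s in self.sheets[sheet_index]:
            strand = self.strands[s]
            rows = [k for k, (_, r) in enumerate(self._roles(strand))
                    if r in ("NH", "CA", "CO")]
            pts.append(strand.coords[rows])
        return np.vstack(pts)

    def sidechain_offsets(self, sheet_index: int,
                          residue_class: str | None = None) -> np.ndarray:
        """Vectors from CA to R for (optionally class-filtered) residues."""
        out = []
        for s in self.sheets[sheet_index]:
            strand = self.strands[s]
            roles = self._roles(strand)
            ca_of = {res: k for k, (res, r) in enumerate(roles) if r == "CA"}
            for k, (res, r) in enumerate(roles):
                if r != "R":
                    continue
                code = strand.sequence.residues[res]
                if residue_class and RESIDUES[code].res_class != residue_class:
                    continue
                out.append(strand.coords[k] - strand.coords[ca_of[res]])
        return np.array(out)

    def positions(self) -> np.ndarray:
        return np.vstack([s.coords for s in self.strands])

    def sequences(self) -> list[PeptideSequence]:
        return [s.sequence for s in self.strands]

    def to_structure(self, box: float | None = None) -> AtomisticStructure:
        chains, resi, codes, names, elems, coords = [], [], [], [], [], []
        chain_alphabet = ("ABCDEFGHIJKLMNOPQRSTUVWXYZ"
                          "abcdefghijklmnopqrstuvwxyz0123456789")
        for si, strand in enumerate(self.strands):
            cid = chain_alphabet[si % len(chain_alphabet)]
            for k, (res, r) in enumerate(self._roles(strand)):
                chains.append(cid)
                resi.append(res + 1)
                codes.append(strand.sequence.residues[res])
                names.append(_BEAD_PDB_NAME[r])
                elems.append("N" if r == "NH" else "C")
                coords.append(strand.coords[k])
        return AtomisticStructure(
            np.array(chains), np.array(resi), np.array(codes),
            np.array(names), np.array(elems), np.array(coords), box)

    def to_state(self, box_length: float | None = None,
                 margin: float = 30.0) -> SystemState:
        pos = self.positions()
        span = pos.max(axis=0) - pos.min(axis=0)
        if box_length is None:
            box_length = float(span.max() + 2 * margin)
        center = pos.mean(axis=0)
        pos = pos - center + box_length / 2.0
        return SystemState(
            positions=pos, velocities=np.zeros_like(pos),
            box_length=box_length)

    def system(self, table: InteractionTable | None = None) -> CGSystem:
        return compile_system(self.sequences(), table)


# ---------------------------------------------------------------------------
# Ideal strands and sheets
# ---------------------------------------------------------------------------

def ideal_strand(
    seq: PeptideSequence,
    representation: str = "four_bead",
    pleat: int = 1,
    orientation: str = "+",
) -> np.ndarray:
    """Extended antiparallel-beta-strand geometry along a straight axis.

    The CA atoms lie on a line (rise 3.5 A per residue, strand axis y);
    sidechain beads alternate sides of the backbone plane (the beta pleat).
    ``representation`` is 'four_bead' (NH/CA/CO/R beads in topology order)
    or 'backbone_atomistic' (N/CA/C positions only).
    """
    if representation not in ("four_bead", "backbone_atomistic"):
        raise ValueError(f"unknown representation {representation!r}")
    if orientation not in ("+", "-"):
        raise ValueError(f"unknown orientation {orientation!r}")
    coords = []
    n = len(seq)
    for i, code in enumerate(seq.residues):
        offsets = local_bead_offsets(i, code, pleat=pleat)
        ca = np.array([0.0, RISE_PER_RESIDUE * i, 0.0])
        order = ["NH", "CA", "CO"]
        if representation == "four_bead" and "R" in offsets:
            order.append("R")
        for bt in order:
            coords.append(ca + offsets[bt])
    coords = np.array(coords)
    if orientation == "-":
        coords[:, 0] *= -1.0
        coords[:, 1] = RISE_PER_RESIDUE * (n - 1) - coords[:, 1]
    return coords


def _rot_x(deg: float) -> np.ndarray:
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[1.0, 0, 0], [0, c, -s], [0, s, c]])


def _make_sheet_strands(
    seq_plus: PeptideSequence,
    seq_minus: PeptideSequence,
    n_strands: int,
    strand_spacing: float,
    twist_per_strand: float,
    pleat: int,
    origin: np.ndarray,
) -> list[Strand]:
    n_res = len(seq_plus)
    y_center = RISE_PER_RESIDUE * (n_res - 1) / 2.0
    strands = []
    for k in range(n_strands):
        seq = seq_plus if k % 2 == 0 else seq_minus
        orientation = "+" if k % 2 == 0 else "-"
        coords = ideal_strand(seq, "four_bead", pleat=pleat,
                              orientation=orientation)
        coords = coords - np.array([0.0, y_center, 0.0])
        coords = coords @ _rot_x(k * twist_per_strand).T
        coords = coords + origin + np.array([k * strand_spacing, 0.0, 0.0])
        strands.append(Strand(seq, orientation, coords))
    return strands


def build_sheet(
    seq_plus: PeptideSequence,
    seq_minus: PeptideSequence,
    n_strands: int = 12,
    strand_spacing: float = 5.0,
    twist_per_strand: float = 0.0,
    pleat: int = 1,
) -> SheetModel:
    """One in-register antiparallel sheet of charge-alternating strands.

    Strand k is rotated by ``k * twist_per_strand`` degrees about the sheet
    long axis (x); a negative value builds a left-handed twist.
    """
    if n_strands < 2:
        raise ValueError("a sheet needs at least 2 strands")
    if strand_spacing <= 0:
        raise ValueError("strand spacing must be positive")
    if len(seq_plus) != len(seq_minus):
        raise ValueError("the two sequences must have equal length")
    strands = _make_sheet_strands(
        seq_plus, seq_minus, n_strands, strand_spacing, twist_per_strand,
        pleat, np.zeros(3))
    return SheetModel(
        strands=strands, sheets=[list(range(n_strands))],
        strand_spacing=strand_spacing, sheet_gap=0.0,
        twist_per_strand=twist_per_strand, layer_gaps=[],
        ground_truth=GroundTruth(true_twist=twist_per_strand,
                                 true_strand_spacing=strand_spacing))


def build_bilayer(
    seq_plus: PeptideSequence,
    seq_minus: PeptideSequence,
    n_strands: int = 12,
    strand_spacing: float = 5.0,
    sheet_gap: float = 13.0,
    twist_per_strand: float = 0.0,
) -> SheetModel:
    """Two sheets with hydrophobic (F) sidechains facing inward, backbone
    planes ``sheet_gap`` apart."""
    if sheet_gap <= 0:
        raise ValueError("sheet gap must be positive")
    s0 = _make_sheet_strands(seq_plus, seq_minus, n_strands, strand_spacing,
                             twist_per_strand, +1, np.zeros(3))
    s1 = _make_sheet_strands(seq_plus, seq_minus, n_strands, strand_spacing,
                             twist_per_strand, -1,
                             np.array([0.0, 0.0, sheet_gap]))
    strands = s0 + s1
    return SheetModel(
        strands=strands,
        sheets=[list(range(n_strands)), list(range(n_strands, 2 * n_strands))],
        strand_spacing=strand_spacing, sheet_gap=sheet_gap,
        twist_per_strand=twist_per_strand, layer_gaps=[sheet_gap],
        ground_truth=GroundTruth(true_twist=twist_per_strand,
                                 true_strand_spacing=strand_spacing,
                                 true_sheet_separations=[sheet_gap]))


def _surface_reach(seq_plus: PeptideSequence,
                   seq_minus: PeptideSequence) -> float:
    """Mean sidechain tip extent of the charged residue types on a sheet face."""
    charged = {c for c in (*seq_plus.residues, *seq_minus.residues)
               if RESIDUES[c].res_class in ("cationic", "anionic")}
    if not charged:
        raise ValueError("sequences contain no charged residues")
    return float(np.mean([RESIDUES[c].reach for c in sorted(charged)]))


def build_two_bilayers(
    seq_plus: PeptideSequence,
    seq_minus: PeptideSequence,
    mode: str = "stacked",
    n_strands: int = 12,
    strand_spacing: float = 5.0,
    sheet_gap: float = 13.0,
    twist_per_strand: float = 0.0,
    tip_gap_stacked: float = 3.0,
    tip_gap_separated: float = 13.0,
) -> SheetModel:
    """Two bilayers with the charged faces of sheets 2 and 3 toward each other.

    In ``stacked`` mode the inward-facing sidechain tips of sheets 2 and 3
    are ``tip_gap_stacked`` (default ~3 A) apart; in ``separated`` mode the
    bilayer surfaces are ``tip_gap_separated`` (default ~13 A) apart.  The
    resulting backbone-plane distance between sheets 2 and 3 is
    ``tip gap + the two facing sidechain tip extents``.
    """
    if mode not in ("stacked", "separated"):
        raise ValueError(f"unknown mode {mode!r}")
    tip_gap = tip_gap_stacked if mode == "stacked" else tip_gap_separated
    reach = _surface_reach(seq_plus, seq_minus)
    inner_gap = tip_gap + 2.0 * reach
    z3 = sheet_gap + inner_gap

    pleats = (+1, -1, +1, -1)
    z_offsets = (0.0, sheet_gap, z3, z3 + sheet_gap)
    strands: list[Strand] = []
    sheets: list[list[int]] = []
    for pleat, z in zip(pleats, z_offsets):
        start = len(strands)
        strands.extend(_make_sheet_strands(
            seq_plus, seq_minus, n_strands, strand_spacing,
            twist_per_strand, pleat, np.array([0.0, 0.0, z])))
        sheets.append(list(range(start, len(strands))))
    return SheetModel(
        strands=strands, sheets=sheets,
        strand_spacing=strand_spacing, sheet_gap=sheet_gap,
        twist_per_strand=twist_per_strand,
        layer_gaps=[sheet_gap, inner_gap, sheet_gap],
        ground_truth=GroundTruth(
            true_twist=twist_per_strand,
            true_strand_spacing=strand_spacing,
            true_sheet_separations=[sheet_gap, inner_gap, sheet_gap]))


# ---------------------------------------------------------------------------
# Random dispersions
# ---------------------------------------------------------------------------

@dataclass
class CoilBox:
    """A periodic box of randomly placed, randomised-conformation peptides."""

    state: SystemState
    system: CGSystem
    sequences: list[PeptideSequence]


def _randomized_conformers(
    seq: PeptideSequence,
    n_conformers: int,
    table: InteractionTable | None,
    seed: int,
    t_star_randomize: float,
) -> list[np.ndarray]:
    """Decorrelated single-chain conformations from a short high-temperature
    event-driven run of one peptide (all bond and excluded-volume
    constraints hold exactly by construction)."""
    system = compile_system([seq], table)
    coords = ideal_strand(seq, "four_bead")
    box = float(np.ptp(coords, axis=0).max() * 3 + 60.0)
    pos = coords - coords.mean(axis=0) + box / 2.0
    rng = np.random.default_rng(seed)
    state = SystemState(
        positions=pos,
        velocities=dmd_engine.maxwell_velocities(system, t_star_randomize, rng),
        box_length=box)
    interval = 40.0
    traj, _ = dmd_engine.run_dmd(
        state, system, t_star=t_star_randomize, ghost_rate=0.1,
        max_events=200_000_000, max_time=interval * (n_conformers + 2),
        sample_every=interval, seed=seed,
        max_frames=n_conformers + 4)
    frames = traj.frames[-n_conformers:]
    if len(frames) < n_conformers:
        raise RuntimeError("conformer generation produced too few frames")
    out = []
    for fr in frames:
        # unwrap the chain across the periodic boundary, then centre it
        p = fr.positions - box * np.round((fr.positions - fr.positions[0]) / box)
        out.append(p - p.mean(axis=0))
    return out


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def random_coil_box(
    n_plus: int,
    n_minus: int,
    box_length: float,
    min_separation: float = 5.5,
    seed: int = 0,
    t_star: float = 0.18,
    seq_plus: PeptideSequence | None = None,
    seq_minus: PeptideSequence | None = None,
    table: InteractionTable | None = None,
    t_star_randomize: float = 1.0,
    max_attempts: int = 5000,
) -> CoilBox:
    """Randomly place peptides with randomised conformations in a cubic box.

    Cationic peptides come first in the bead ordering.  No inter-peptide
    bead pair is closer than ``min_separation``; velocities are drawn from
    the Maxwell-Boltzmann distribution at ``t_star``.  Fully reproducible
    for a fixed seed.
    """
    from scipy.spatial import cKDTree

    seq_plus = seq_plus or catch_sequence("6K+")
    seq_minus = seq_minus or catch_sequence("6E-")
    conf_plus = _randomized_conformers(
        seq_plus, n_plus, table, seed * 7919 + 1, t_star_randomize) \
        if n_plus else []
    conf_minus = _randomized_conformers(
        seq_minus, n_minus, table, seed * 7919 + 2, t_star_randomize) \
        if n_minus else []

    rng = np.random.default_rng(seed)
    sequences = [seq_plus] * n_plus + [seq_minus] * n_minus
    conformers = conf_plus + conf_minus

    placed: list[np.ndarray] = []
    tree = None
    for p, conf in enumerate(conformers):
        ok = False
        for _ in range(max_attempts):
            rot = _random_rotation(rng)
            shift = rng.uniform(0.0, box_length, size=3)
            cand = np.mod(conf @ rot.T + shift, box_length)
            if tree is None:
                ok = True
            else:
                dist, _ = tree.query(cand, k=1)
                ok = bool(np.min(dist) >= min_separation)
            if ok:
                placed.append(cand)
                tree = cKDTree(np.vstack(placed), boxsize=box_length)
                break
        if not ok:
            raise RuntimeError(
                f"could not place peptide {p} at min_separation="
                f"{min_separation}; placed {len(placed)} of {len(conformers)}")

    system = compile_system(sequences, table)
    positions = np.vstack(placed)
    state = SystemState(
        positions=positions,
        velocities=dmd_engine.maxwell_velocities(system, t_star, rng),
        box_length=box_length,
        rng_seed=seed,
    )
    return CoilBox(state=state, system=system, sequences=sequences)


# ---------------------------------------------------------------------------
# Atomistic salt-bridge micro-fixture
# ---------------------------------------------------------------------------

def salt_bridge_fixture(
    distance: float,
    angle: float,
    acceptor_residue: str = "E",
) -> AtomisticStructure:
    """A lysine ammonium group and a carboxylate (or, for a like-charge
    control, a second ammonium) with exact H...O distance and N-H...O angle.

    The donor N-H lies on the x axis; the acceptor oxygen is placed so the
    angle at the hydrogen between H->N and H->O equals ``angle``.
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    if not 0 < angle <= 180:
        raise ValueError("angle must lie in (0, 180]")
    if acceptor_residue not in ("E", "D", "K"):
        raise ValueError("acceptor_residue must be 'E', 'D' or 'K'")

    nz = np.array([0.0, 0.0, 0.0])
    hz = np.array([1.0, 0.0, 0.0])
    a = math.radians(angle)
    u = np.array([-math.cos(a), 0.0, math.sin(a)])

    chains = ["A", "A", "A"]
    resi = [1, 1, 1]
    codes = ["K", "K", "K"]
    names = ["CE", "NZ", "HZ1"]
    elems = ["C", "N", "H"]
    coords = [nz - np.array([1.5, 0.0, 0.0]), nz, hz]

    if acceptor_residue in ("E", "D"):
        o1 = hz + distance * u
        cd = o1 + 1.25 * u
        o2 = cd + 1.25 * u
        onames = ("OE1", "CD", "OE2") if acceptor_residue == "E" \
            else ("OD1", "CG", "OD2")
        chains += ["B", "B", "B"]
        resi += [1, 1, 1]
        codes += [acceptor_residue] * 3
        names += list(onames)
        elems += ["O", "C", "O"]
        coords += [o1, cd, o2]
    else:
        nz2 = hz + distance * u
        chains += ["B", "B"]
        resi += [1, 1]
        codes += ["K", "K"]
        names += ["NZ", "HZ1"]
        elems += ["N", "H"]
        coords += [nz2, nz2 + np.array([0.0, 1.0, 0.0])]

    return AtomisticStructure(
        np.array(chains), np.array(resi), np.array(codes),
        np.array(names), np.array(elems), np.array(coords), None)


# ---------------------------------------------------------------------------
# Scripted assembly trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScriptedCluster:
    members: tuple[int, ...]
    shape: str                     # 'sheet' | 'barrel' | 'blob'

    def __post_init__(self) -> None:
        if self.shape not in ("sheet", "barrel", "blob"):
            raise ValueError(f"unknown cluster shape {self.shape!r}")
        if len(set(self.members)) != len(self.members):
            raise ValueError("duplicate members in cluster")


@dataclass(frozen=True)
class FrameScript:
    time: float
    clusters: tuple[ScriptedCluster, ...]


def _expected_class(shape: str, size: int, sheet_min: int) -> str:
    if size == 1:
        return "free"
    if shape == "barrel":
        return "beta_barrel" if size >= 3 else "oligomer"
    if shape == "sheet" and size >= sheet_min:
        return "beta_sheet"
    return "oligomer"


def scripted_trajectory(
    script: Sequence[FrameScript],
    n_peptides: int,
    sequences: Sequence[PeptideSequence] | None = None,
    table: InteractionTable | None = None,
    hbonds_per_interface: int = 6,
    strand_spacing: float = 5.0,
    sheet_min: int = 4,
    seed: int = 0,
) -> tuple[Trajectory, GroundTruth]:
    """Fabricate a trajectory whose connectivity analysis has known output.

    Each scripted frame lists clusters (member sets plus a geometric shape);
    unlisted peptides are free.  Sheet and barrel clusters receive
    ``hbonds_per_interface`` fabricated hydrogen bonds per adjacent strand
    pair (a barrel additionally closes the first-last pair into a cycle);
    'blob' clusters touch only through hydrophobic sidechain contacts.
    """
    if sequences is None:
        sequences = [catch_sequence("6K+") if p % 2 == 0
                     else catch_sequence("6E-") for p in range(n_peptides)]
    sequences = list(sequences)
    if len(sequences) != n_peptides:
        raise ValueError("sequence list does not match n_peptides")
    system = compile_system(sequences, table)
    n_res = len(sequences[0])
    h = hbonds_per_interface
    if h > n_res:
        raise ValueError("more H-bonds per interface than residues")

    # home grid (free-peptide slots), generous pitch to isolate clusters
    pitch = 80.0
    side = math.ceil(n_peptides ** (1.0 / 3.0))
    homes = []
    for p in range(n_peptides):
        ix, iy, iz = p % side, (p // side) % side, p // (side * side)
        homes.append(np.array([ix, iy, iz], dtype=float) * pitch + pitch / 2)
    box = side * pitch

    frames: list[Frame] = []
    labels_per_frame: list[dict[int, int]] = []
    classes_per_frame: list[dict[int, str]] = []

    for fs in script:
        seen: set[int] = set()
        for cl in fs.clusters:
            for m in cl.members:
                if m in seen:
                    raise ValueError(
                        f"peptide {m} appears in two clusters at t={fs.time}")
                if not 0 <= m < n_peptides:
                    raise ValueError(f"peptide index {m} out of range")
                seen.add(m)

        positions = np.zeros((system.n_beads, 3))
        partner = np.full(system.n_beads, -1, dtype=np.int64)

        def place(pep_idx: int, coords: np.ndarray) -> None:
            sl = system.bead_slice(pep_idx)
            positions[sl] = coords

        # free peptides at their home slots
        clustered = seen
        for p in range(n_peptides):
            if p not in clustered:
                coords = ideal_strand(sequences[p], "four_bead")
                place(p, coords - coords.mean(axis=0) + homes[p])

        labels: dict[int, int] = {}
        classes: dict[int, str] = {}
        next_cluster = 0
        for p in range(n_peptides):
            if p not in clustered:
                labels[p] = next_cluster
                classes[next_cluster] = "free"
                next_cluster += 1

        for cl in fs.clusters:
            origin = homes[min(cl.members)]
            members = list(cl.members)
            m = len(members)
            for k, p in enumerate(members):
                coords = ideal_strand(
                    sequences[p], "four_bead",
                    orientation="+" if k % 2 == 0 else "-")
                coords = coords - coords.mean(axis=0)
                if cl.shape == "barrel":
                    radius = m * strand_spacing / (2 * math.pi)
                    phi = 2 * math.pi * k / m
                    offset = np.array([radius * math.cos(phi), 0.0,
                                       radius * math.sin(phi)])
                else:
                    offset = np.array([k * strand_spacing, 0.0, 0.0])
                place(p, coords + origin + offset)

            if cl.shape in ("sheet", "barrel"):
                interfaces = [(members[k], members[k + 1])
                              for k in range(m - 1)]
                if cl.shape == "barrel":
                    interfaces.append((members[-1], members[0]))
                k1 = (h + 1) // 2
                k2 = h - k1
                for a, b in interfaces:
                    for r in range(k1):
                        nh = system.bead_index(b, r, "NH")
                        co = system.bead_index(a, r, "CO")
                        partner[nh] = co
                        partner[co] = nh
                    for r in range(k2):
                        nh = system.bead_index(a, n_res - 1 - r, "NH")
                        co = system.bead_index(b, n_res - 1 - r, "CO")
                        partner[nh] = co
                        partner[co] = nh

            for p in members:
                labels[p] = next_cluster
            classes[next_cluster] = _expected_class(cl.shape, m, sheet_min)
            next_cluster += 1

        frames.append(Frame(
            time=fs.time, positions=positions, partner=partner,
            kinetic_energy=0.0, potential_energy=0.0))
        labels_per_frame.append(labels)
        classes_per_frame.append(classes)

    last = frames[-1] if frames else None
    final_state = SystemState(
        positions=last.positions.copy() if last is not None
        else np.zeros((system.n_beads, 3)),
        velocities=np.zeros((system.n_beads, 3)),
        box_length=box,
        time=last.time if last is not None else 0.0,
    )
    traj = Trajectory(system=system, box_length=box, frames=frames,
                      final_state=final_state)
    gt = GroundTruth(true_cluster_labels=labels_per_frame,
                     true_classes=classes_per_frame)
    return traj, gt
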