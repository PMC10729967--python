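"""Geometric and structural analyses of peptide assemblies.

Implements the measurements used to characterise beta-sheet bilayers:
strand-axis twist between neighbouring peptides, total-least-squares plane
fits and inter-sheet centroid distances, geometric hydrogen-bond and
salt-bridge detection, residue-pair contact maps, group contact counts,
Kabsch RMSD, and aggregation of per-frame secondary-structure assignments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from catchsim.peptide_model import RESIDUES, THREE_TO_ONE

__all__ = [
    "AtomisticStructure",
    "ContactMap",
    "SecondaryContentTable",
    "strand_axis",
    "pair_twist",
    "sheet_twist",
    "strand_spacing",
    "fit_plane",
    "sheet_separation",
    "hydrogen_bonds",
    "salt_bridges",
    "contact_map",
    "group_contacts",
    "kabsch_rmsd",
    "aggregate_secondary",
    "class_totals",
    "SS_CLASSES",
    "HELIX_CLASSES",
]


# ---------------------------------------------------------------------------
# Structure container
# ---------------------------------------------------------------------------

@dataclass
class AtomisticStructure:
    """A flat atom table: chain, residue, atom name, element, coordinate."""

    chain_ids: np.ndarray      # str array
    residue_indices: np.ndarray
    residue_codes: np.ndarray  # one-letter codes
    atom_names: np.ndarray
    elements: np.ndarray
    coords: np.ndarray         # (N, 3) Angstrom
    box: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        n = len(self.coords)
        for arr in (self.chain_ids, self.residue_indices, self.residue_codes,
                    self.atom_names, self.elements):
            if len(arr) != n:
                raise ValueError("atom annotation length mismatch")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def select(self, mask: np.ndarray) -> "AtomisticStructure":
        return AtomisticStructure(
            self.chain_ids[mask], self.residue_indices[mask],
            self.residue_codes[mask], self.atom_names[mask],
            self.elements[mask], self.coords[mask], self.box,
        )

    def residue_keys(self) -> np.ndarray:
        """Integer id per atom, unique per (chain, residue)."""
        keys = [f"{c}|{r}" for c, r in zip(self.chain_ids, self.residue_indices)]
        _, inv = np.unique(keys, return_inverse=True)
        return inv

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "AtomisticStructure":
        out = self.select(np.ones(self.n_atoms, bool))
        out.coords = self.coords @ np.asarray(rotation).T + translation
        return out


def _pair_displacements(coords_a, coords_b, box):
    d = coords_a - coords_b
    if box is not None:
        d -= box * np.round(d / box)
    return d


# ---------------------------------------------------------------------------
# Strand axes and twist
# ---------------------------------------------------------------------------

def strand_axis(calpha_coords: np.ndarray) -> np.ndarray:
    """Oriented unit vector of the total-least-squares line through CA atoms.

    The sign is chosen so the axis points from the N-terminal toward the
    C-terminal CA.
    """
    pts = np.asarray(calpha_coords, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 CA positions")
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if np.dot(axis, pts[-1] - pts[0]) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def pair_twist(axis_i: np.ndarray, axis_j: np.ndarray,
               stacking_normal: np.ndarray) -> float:
    """Signed twist angle (degrees) between two neighbouring strand axes.

    Antiparallel neighbours are aligned by flipping ``axis_j`` when the axes
    oppose.  The magnitude is the angle between the aligned axes; the sign is
    that of ``(axis_i x axis_j) . stacking_normal`` where the reference
    direction points from strand i toward strand j.  Negative = left-handed.
    """
    a = np.asarray(axis_i, float)
    b = np.asarray(axis_j, float)
    n = np.asarray(stacking_normal, float)
    if np.linalg.norm(a) == 0 or np.linalg.norm(b) == 0:
        raise ValueError("zero axis vector")
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    if np.dot(a, b) < 0:
        b = -b
    cross = np.cross(a, b)
    angle = math.degrees(math.atan2(np.linalg.norm(cross),
                                    float(np.clip(np.dot(a, b), -1, 1))))
    sign = math.copysign(1.0, float(np.dot(cross, n))) if angle > 0 else 1.0
    return sign * angle


def strand_spacing(strand_calphas: Sequence[np.ndarray]) -> float:
    """Mean perpendicular distance between adjacent strand axes of a sheet."""
    if len(strand_calphas) < 2:
        raise ValueError("need at least 2 strands")
    axes = [strand_axis(c) for c in strand_calphas]
    centroids = [np.asarray(c, float).mean(axis=0) for c in strand_calphas]
    gaps = []
    for k in range(len(axes) - 1):
        d = centroids[k + 1] - centroids[k]
        a = axes[k] + (axes[k + 1] if np.dot(axes[k], axes[k + 1]) > 0
                       else -axes[k + 1])
        a = a / np.linalg.norm(a)
        gaps.append(np.linalg.norm(d - np.dot(d, a) * a))
    return float(np.mean(gaps))


def sheet_twist(strand_calphas: Sequence[np.ndarray]) -> float:
    """Mean signed twist over adjacent strand pairs of one beta-sheet.

    ``strand_calphas`` is an ordered list of per-strand CA coordinate arrays,
    ordered along the stacking direction of the sheet.
    """
    if len(strand_calphas) < 2:
        raise ValueError("need at least 2 strands")
    axes = [strand_axis(c) for c in strand_calphas]
    centroids = [np.asarray(c).mean(axis=0) for c in strand_calphas]
    twists = []
    for k in range(len(axes) - 1):
        stack = centroids[k + 1] - centroids[k]
        stack = stack / np.linalg.norm(stack)
        twists.append(pair_twist(axes[k], axes[k + 1], stack))
    return float(np.mean(twists))


# ---------------------------------------------------------------------------
# Plane fits and sheet separation
# ---------------------------------------------------------------------------

def fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares plane; returns (centroid, unit normal)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 points to fit a plane")
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    if s[1] < 1e-12:
        raise ValueError("degenerate (collinear) point set")
    return centroid, vt[2]


def sheet_separation(backbone_a: np.ndarray, backbone_b: np.ndarray) -> float:
    """Distance between centroids of plane fits to two backbone point sets."""
    ca, _ = fit_plane(backbone_a)
    cb, _ = fit_plane(backbone_b)
    return float(np.linalg.norm(ca - cb))


# ---------------------------------------------------------------------------
# Hydrogen bonds and salt bridges
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HydrogenBond:
    donor_index: int      # heavy donor atom
    hydrogen_index: int
    acceptor_index: int
    distance: float       # H...A, Angstrom
    angle: float          # donor-H...A, degrees


def hydrogen_bonds(
    structure: AtomisticStructure,
    donors: Sequence[tuple[int, int]],
    acceptors: Sequence[int],
    distance_cutoff: float = 3.0,
    angle_cutoff: float = 135.0,
) -> list[HydrogenBond]:
    """Geometric hydrogen-bond detection.

    ``donors`` are (heavy-atom, hydrogen) index pairs, ``acceptors`` acceptor
    atom indices.  A bond is reported for every (H, A) pair with H...A
    distance <= ``distance_cutoff`` and donor-H...A angle >= ``angle_cutoff``.
    """
    if len(donors) == 0 or len(acceptors) == 0:
        return []
    acceptors = np.asarray(acceptors, dtype=int)
    h_idx = np.array([h for _, h in donors], dtype=int)
    d_idx = np.array([d for d, _ in donors], dtype=int)
    box = structure.box
    coords = structure.coords
    if box is not None:
        hpos = np.mod(coords[h_idx], box)
        apos = np.mod(coords[acceptors], box)
        tree = cKDTree(apos, boxsize=box)
        pairs = tree.query_ball_point(hpos, distance_cutoff)
    else:
        tree = cKDTree(coords[acceptors])
        pairs = tree.query_ball_point(coords[h_idx], distance_cutoff)

    bonds = []
    for di, (ai_list, h, d) in enumerate(zip(pairs, h_idx, d_idx)):
        for aj in ai_list:
            a = acceptors[aj]
            if a == h or a == d:
                continue
            hd = _pair_displacements(coords[d], coords[h], box)
            ha = _pair_displacements(coords[a], coords[h], box)
            dist = float(np.linalg.norm(ha))
            if dist > distance_cutoff or dist == 0.0:
                continue
            cosang = float(np.dot(hd, ha) /
                           (np.linalg.norm(hd) * np.linalg.norm(ha)))
            angle = math.degrees(math.acos(np.clip(cosang, -1, 1)))
            if angle >= angle_cutoff:
                bonds.append(HydrogenBond(int(d), int(h), int(a), dist, angle))
    return bonds


@dataclass
class SaltBridgeReport:
    bridges: list[HydrogenBond]
    mean_length: float
    mean_angle: float

    def __len__(self) -> int:
        return len(self.bridges)


def salt_bridges(
    structure: AtomisticStructure,
    distance_cutoff: float = 3.0,
    angle_cutoff: float = 135.0,
) -> SaltBridgeReport:
    """Salt bridges between ammonium hydrogens (K/R/H) and carboxylate
    oxygens (D/E), using the hydrogen-bond geometric criteria.

    Raises if cationic residues are present without their polar hydrogens
    (no silent inference of hydrogen positions).
    """
    donors: list[tuple[int, int]] = []
    acceptors: list[int] = []
    missing = []
    rk = structure.residue_keys()
    for key in np.unique(rk):
        mask = rk == key
        idx = np.nonzero(mask)[0]
        code = str(structure.residue_codes[idx[0]])
        spec = RESIDUES.get(code)
        if spec is None:
            continue
        names = {str(structure.atom_names[i]): i for i in idx}
        if spec.res_class == "cationic" and spec.donor_atoms:
            found_any = False
            for heavy, hydrogens in spec.donor_atoms.items():
                if heavy not in names:
                    continue
                for h in hydrogens:
                    if h in names:
                        donors.append((names[heavy], names[h]))
                        found_any = True
            if not found_any:
                chain = structure.chain_ids[idx[0]]
                resi = structure.residue_indices[idx[0]]
                missing.append(f"{code}{resi}:{chain}")
        elif spec.res_class == "anionic":
            for o in spec.acceptor_atoms:
                if o in names:
                    acceptors.append(names[o])
    if missing:
        raise ValueError(
            "cationic residues missing explicit polar hydrogens: "
            + ", ".join(missing)
        )
    bridges = hydrogen_bonds(structure, donors, acceptors,
                             distance_cutoff, angle_cutoff)
    if bridges:
        mean_len = float(np.mean([b.distance for b in bridges]))
        mean_ang = float(np.mean([b.angle for b in bridges]))
    else:
        mean_len = math.nan
        mean_ang = math.nan
    return SaltBridgeReport(bridges, mean_len, mean_ang)


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------

@dataclass
class ContactMap:
    """Symmetric residue-code-pair contact counts at a distance cutoff."""

    counts: dict[tuple[str, str], int]
    cutoff: float

    def get(self, a: str, b: str) -> int:
        return self.counts.get((a, b) if a <= b else (b, a), 0)

    def total(self) -> int:
        return int(sum(self.counts.values()))

    def to_frame(self) -> pd.DataFrame:
        codes = sorted({c for pair in self.counts for c in pair})
        mat = pd.DataFrame(0, index=codes, columns=codes, dtype=int)
        for (a, b), n in self.counts.items():
            mat.loc[a, b] += n
            if a != b:
                mat.loc[b, a] += n
        return mat


def _contact_pairs(structure: AtomisticStructure, cutoff: float,
                   min_residue_separation: int):
    """Atom index pairs within cutoff, excluding close-in-sequence pairs.

    Pairs within the same residue are never counted; ``min_residue_separation``
    additionally excludes same-chain pairs with a smaller residue-index gap
    (1 keeps everything outside the residue itself).
    """
    coords = structure.coords
    box = structure.box
    if box is not None:
        tree = cKDTree(np.mod(coords, box), boxsize=box)
    else:
        tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return pairs
    same_chain = structure.chain_ids[pairs[:, 0]] == structure.chain_ids[pairs[:, 1]]
    gap = np.abs(structure.residue_indices[pairs[:, 0]].astype(int)
                 - structure.residue_indices[pairs[:, 1]].astype(int))
    keep = ~(same_chain & (gap < min_residue_separation))
    return pairs[keep]


def contact_map(structure: AtomisticStructure, cutoff: float = 7.0,
                min_residue_separation: int = 1) -> ContactMap:
    """Count atom pairs within ``cutoff``, grouped by residue-code pair."""
    pairs = _contact_pairs(structure, cutoff, min_residue_separation)
    counts: dict[tuple[str, str], int] = {}
    codes = structure.residue_codes
    for i, j in pairs:
        a, b = str(codes[i]), str(codes[j])
        key = (a, b) if a <= b else (b, a)
        counts[key] = counts.get(key, 0) + 1
    return ContactMap(counts, cutoff)


def group_contacts(structure: AtomisticStructure,
                   selection_a: np.ndarray, selection_b: np.ndarray,
                   cutoff: float = 7.0,
                   min_residue_separation: int = 1) -> int:
    """Number of atom pairs within cutoff between two disjoint selections."""
    sel_a = np.asarray(selection_a)
    sel_b = np.asarray(selection_b)
    if sel_a.dtype == bool:
        sel_a = np.nonzero(sel_a)[0]
    if sel_b.dtype == bool:
        sel_b = np.nonzero(sel_b)[0]
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise ValueError("empty selection")
    if np.intersect1d(sel_a, sel_b).size:
        raise ValueError("selections must be disjoint")
    in_a = np.zeros(structure.n_atoms, bool)
    in_a[sel_a] = True
    in_b = np.zeros(structure.n_atoms, bool)
    in_b[sel_b] = True
    pairs = _contact_pairs(structure, cutoff, min_residue_separation)
    if len(pairs) == 0:
        return 0
    hit = (in_a[pairs[:, 0]] & in_b[pairs[:, 1]]) | \
          (in_b[pairs[:, 0]] & in_a[pairs[:, 1]])
    return int(np.count_nonzero(hit))


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Minimal RMSD over proper rotations and translation (Kabsch)."""
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    if a.shape != b.shape:
        raise ValueError("coordinate sets must have equal shapes")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 points")
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    _, rssd = Rotation.align_vectors(a0, b0)
    return float(rssd / math.sqrt(a.shape[0]))


# ---------------------------------------------------------------------------
# Secondary-structure aggregation
# ---------------------------------------------------------------------------

SS_CLASSES = ("helix_310", "helix_alpha", "helix_pi",
              "bend", "turn", "coil", "strand")
HELIX_CLASSES = ("helix_310", "helix_alpha", "helix_pi")


@dataclass
class SecondaryContentTable:
    """Mean per-residue secondary-structure occupancies.

    ``per_residue`` is residues x classes with values in [0, 1]; helix is
    reported as the sum of the 3-10, alpha and pi helix occupancies.
    """

    per_residue: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.per_residue.to_numpy(float)
        if (vals < -1e-9).any() or (vals > 1 + 1e-9).any():
            raise ValueError("occupancies must lie in [0, 1]")

    @classmethod
    def from_occupancies(cls, table: pd.DataFrame) -> "SecondaryContentTable":
        """Wrap an existing residues x classes occupancy table."""
        return cls(per_residue=table.copy())

    @property
    def totals(self) -> dict[str, float]:
        out = {c: float(self.per_residue[c].sum())
               for c in self.per_residue.columns}
        helix_parts = [c for c in HELIX_CLASSES if c in self.per_residue]
        if helix_parts:
            out["helix"] = float(self.per_residue[helix_parts].sum().sum())
        return out


def aggregate_secondary(
    assignments: Mapping[int, Mapping[int, str]] | pd.DataFrame,
) -> SecondaryContentTable:
    """Average per-frame, per-residue class assignments into occupancies.

    ``assignments`` is frames x residues of class labels (a DataFrame or a
    nested mapping frame -> residue -> class).  Every residue must be
    assigned in every frame; unknown class labels are rejected.
    """
    if not isinstance(assignments, pd.DataFrame):
        assignments = pd.DataFrame.from_dict(assignments, orient="index")
    if assignments.isna().any().any():
        raise ValueError("assignments must cover all residues in all frames")
    labels = set(np.unique(assignments.to_numpy(str)))
    unknown = labels - set(SS_CLASSES)
    if unknown:
        raise ValueError(f"unknown secondary-structure classes: {sorted(unknown)}")
    residues = sorted(assignments.columns)
    table = pd.DataFrame(0.0, index=residues, columns=list(SS_CLASSES))
    n_frames = len(assignments)
    for res in residues:
        counts = assignments[res].value_counts()
        for cls_name, n in counts.items():
            table.loc[res, cls_name] = n / n_frames
    return SecondaryContentTable(per_residue=table)


def class_totals(table: SecondaryContentTable) -> dict[str, float]:
    """Per-class sums over residues, with the three helix classes combined."""
    return table.totals
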