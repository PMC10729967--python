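"""Domain types for the four-bead coarse-grained peptide model.

Each amino acid is represented by three backbone spheres (NH, CA, CO) and one
sidechain sphere (R).  Covalent structure is maintained by hard-wall bonds and
pseudobonds that keep the local backbone geometry near an ideal value; all
non-bonded interactions are hard spheres, optionally decorated with a single
square well (sidechain pairs) or with a directional hydrogen-bond well between
backbone NH and CO spheres.

Energies are expressed in reduced units of the hydrogen-bond well depth
``eps_HB`` (12.47 kJ/mol), lengths in Angstrom and masses in amu; the reduced
temperature is ``T* = k_B T / eps_HB``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "ResidueSpec",
    "RESIDUES",
    "PeptideSequence",
    "sequence_from_string",
    "Bead",
    "Bond",
    "BeadTopology",
    "build_topology",
    "HBondRule",
    "InteractionTable",
    "default_interaction_table",
    "SystemState",
    "ReducedUnits",
    "reduced_temperature",
    "kelvin_temperature",
    "K_BOLTZMANN_KJ",
    "EPS_HB_KJ",
]

#: Boltzmann constant, kJ/(mol K)
K_BOLTZMANN_KJ = 0.0083144621
#: Hydrogen-bond well depth, kJ/mol; the unit energy of the reduced system
EPS_HB_KJ = 12.47

# United-atom backbone bead masses (amu)
MASS_NH = 15.015
MASS_CA = 13.019  # CaH
MASS_CO = 28.010

# Canonical local strand geometry (Angstrom).  These constants define both the
# ideal extended-strand builder and the nominal bond/pseudobond lengths, so
# that built structures satisfy the topology constraints exactly.
RISE_PER_RESIDUE = 3.5     # Ca-Ca rise along the strand axis
BACKBONE_DX = 0.5          # lateral NH/CO offset from the Ca line
BACKBONE_DY = 1.25         # NH/CO offset along the strand axis

#: Default fractional half-width of every bond window (the customary DMD
#: pseudo-bond tolerance for this model family)
BOND_TOLERANCE = 0.02375

VALID_CAPS = ("acetyl", "amide", "free")


# ---------------------------------------------------------------------------
# Residue registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidueSpec:
    """Identity and coarse-grained geometry of one amino-acid type."""

    code: str
    name3: str
    res_class: str                 # hydrophobic | cationic | anionic | polar
    sidechain_mass: float          # amu
    sigma: float                   # R-bead hard-core diameter, Angstrom
    centroid: float                # nominal R-Ca distance, Angstrom
    reach: float                   # backbone plane to sidechain tip, Angstrom
    donor_atoms: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    acceptor_atoms: tuple[str, ...] = ()
    has_sidechain: bool = True

    @property
    def charge(self) -> int:
        if self.res_class == "cationic":
            return 1
        if self.res_class == "anionic":
            return -1
        return 0


def _load_registry() -> dict[str, ResidueSpec]:
    text = resources.files("catchsim.data").joinpath("residues.yaml").read_text()
    raw = yaml.safe_load(text)
    registry: dict[str, ResidueSpec] = {}
    for code, entry in raw.items():
        donors = {
            heavy: tuple(hs) for heavy, hs in entry.get("donor_atoms", {}).items()
        }
        registry[code] = ResidueSpec(
            code=code,
            name3=entry["name3"],
            res_class=entry["class"],
            sidechain_mass=float(entry["sidechain_mass"]),
            sigma=float(entry["sigma"]),
            centroid=float(entry["centroid"]),
            reach=float(entry["reach"]),
            donor_atoms=donors,
            acceptor_atoms=tuple(entry.get("acceptor_atoms", ())),
            has_sidechain=not entry.get("no_sidechain", False),
        )
    return registry


#: The 20 standard residues
RESIDUES: dict[str, ResidueSpec] = _load_registry()

THREE_TO_ONE = {spec.name3: code for code, spec in RESIDUES.items()}


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeptideSequence:
    """An ordered amino-acid sequence with terminal caps.

    ``net_charge`` is derived as (#cationic - #anionic) residues; terminal
    caps are charge-neutral and carry no extra beads.
    """

    residues: tuple[str, ...]
    n_term_cap: str = "acetyl"
    c_term_cap: str = "amide"
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.residues) < 2:
            raise ValueError("a peptide needs at least 2 residues")
        for cap in (self.n_term_cap, self.c_term_cap):
            if cap not in VALID_CAPS:
                raise ValueError(f"unknown terminal cap {cap!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return "".join(self.residues)

    @property
    def net_charge(self) -> int:
        return sum(RESIDUES[c].charge for c in self.residues)

    @property
    def specs(self) -> tuple[ResidueSpec, ...]:
        return tuple(RESIDUES[c] for c in self.residues)


def sequence_from_string(
    s: str,
    caps: tuple[str, str] = ("acetyl", "amide"),
    label: str = "",
) -> PeptideSequence:
    """Parse a one-letter amino-acid string into a :class:`PeptideSequence`."""
    if not s:
        raise ValueError("empty sequence")
    for ch in s:
        if ch not in RESIDUES:
            raise ValueError(f"invalid one-letter amino-acid code {ch!r} in {s!r}")
    return PeptideSequence(
        residues=tuple(s), n_term_cap=caps[0], c_term_cap=caps[1],
        label=label or s,
    )


# CATCH presets: palindromic 11-mers, pattern CQCFCFCFCQC
CATCH_SEQUENCES = {
    "6K+": "KQKFKFKFKQK",
    "6E-": "EQEFEFEFEQE",
    "6D-": "DQDFDFDFDQD",
}


def catch_sequence(name: str) -> PeptideSequence:
    """Return a CATCH preset sequence ('6K+', '6E-' or '6D-')."""
    try:
        return sequence_from_string(CATCH_SEQUENCES[name], label=f"CATCH({name})")
    except KeyError:
        raise ValueError(f"unknown CATCH preset {name!r}") from None


# ---------------------------------------------------------------------------
# Bead topology
# ---------------------------------------------------------------------------

BEAD_TYPES = ("NH", "CA", "CO", "R")


@dataclass(frozen=True)
class Bead:
    bead_type: str       # NH | CA | CO | R
    residue_index: int
    mass: float


@dataclass(frozen=True)
class Bond:
    a: int
    b: int
    length: float        # nominal length L, Angstrom
    tolerance: float     # fractional half-width delta; window [L(1-d), L(1+d)]
    kind: str            # "bond" | "pseudobond"


@dataclass
class BeadTopology:
    """Molecular graph of one coarse-grained peptide."""

    sequence: PeptideSequence
    beads: list[Bead]
    bonds: list[Bond]

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def masses(self) -> np.ndarray:
        return np.array([b.mass for b in self.beads])

    @property
    def total_mass(self) -> float:
        return float(sum(b.mass for b in self.beads))

    def bead_index(self, residue_index: int, bead_type: str) -> int:
        for i, b in enumerate(self.beads):
            if b.residue_index == residue_index and b.bead_type == bead_type:
                return i
        raise KeyError((residue_index, bead_type))

    def is_connected(self) -> bool:
        adj: dict[int, list[int]] = {i: [] for i in range(self.n_beads)}
        for bond in self.bonds:
            adj[bond.a].append(bond.b)
            adj[bond.b].append(bond.a)
        seen = {0}
        stack = [0]
        while stack:
            for j in adj[stack.pop()]:
                if j not in seen:
                    seen.add(j)
                    stack.append(j)
        return len(seen) == self.n_beads


def local_bead_offsets(i: int, code: str, pleat: int = 1) -> dict[str, np.ndarray]:
    """Canonical bead positions of residue *i* relative to its own CA.

    The strand axis is y; NH/CO alternate sides in x; the sidechain alternates
    sides in z (the beta-pleat).  ``pleat=+1`` puts odd-index sidechains at +z.
    """
    spec = RESIDUES[code]
    s = -1.0 if i % 2 == 0 else 1.0
    out = {
        "NH": np.array([s * BACKBONE_DX, -BACKBONE_DY, 0.0]),
        "CA": np.zeros(3),
        "CO": np.array([s * BACKBONE_DX, BACKBONE_DY, 0.0]),
    }
    if spec.has_sidechain:
        zsign = pleat * (1.0 if i % 2 else -1.0)
        out["R"] = np.array([0.0, 0.0, zsign * spec.centroid])
    return out


# Nominal bond lengths implied by the canonical geometry
L_NH_CA = math.hypot(BACKBONE_DX, BACKBONE_DY)
L_CO_NH_NEXT = math.hypot(2 * BACKBONE_DX, RISE_PER_RESIDUE - 2 * BACKBONE_DY)
L_NH_CO_INTRA = 2 * BACKBONE_DY
L_CA_CA = RISE_PER_RESIDUE


def build_topology(
    seq: PeptideSequence, tolerance: float = BOND_TOLERANCE
) -> BeadTopology:
    """Build the four-bead topology of a peptide.

    Backbone bonds NH-CA, CA-CO, CO-NH(next) and the sidechain bond R-CA are
    covalent; pseudobonds NH-CO (intra-residue), CA-CA (consecutive) and
    R-NH / R-CO maintain backbone geometry and sidechain orientation.
    """
    if not 0 < tolerance < 0.1:
        raise ValueError("bond tolerance must lie in (0, 0.1)")
    beads: list[Bead] = []
    index: dict[tuple[int, str], int] = {}
    for i, code in enumerate(seq.residues):
        spec = RESIDUES[code]
        for bt, m in (("NH", MASS_NH), ("CA", MASS_CA), ("CO", MASS_CO)):
            index[(i, bt)] = len(beads)
            beads.append(Bead(bt, i, m))
        if spec.has_sidechain:
            index[(i, "R")] = len(beads)
            beads.append(Bead("R", i, spec.sidechain_mass))

    bonds: list[Bond] = []

    def add(i_key, j_key, length, kind):
        bonds.append(Bond(index[i_key], index[j_key], length, tolerance, kind))

    for i, code in enumerate(seq.residues):
        spec = RESIDUES[code]
        add((i, "NH"), (i, "CA"), L_NH_CA, "bond")
        add((i, "CA"), (i, "CO"), L_NH_CA, "bond")
        add((i, "NH"), (i, "CO"), L_NH_CO_INTRA, "pseudobond")
        if spec.has_sidechain:
            l_r_backbone = math.sqrt(
                BACKBONE_DX**2 + BACKBONE_DY**2 + spec.centroid**2
            )
            add((i, "R"), (i, "CA"), spec.centroid, "bond")
            add((i, "R"), (i, "NH"), l_r_backbone, "pseudobond")
            add((i, "R"), (i, "CO"), l_r_backbone, "pseudobond")
        if i + 1 < len(seq):
            add((i, "CO"), (i + 1, "NH"), L_CO_NH_NEXT, "bond")
            add((i, "CA"), (i + 1, "CA"), L_CA_CA, "pseudobond")

    return BeadTopology(sequence=seq, beads=beads, bonds=bonds)


# ---------------------------------------------------------------------------
# Interaction table
# ---------------------------------------------------------------------------

@dataclass
class HBondRule:
    """Directional square-well hydrogen bond between backbone NH and CO.

    A bond may form when an unpartnered NH and CO pair reaches ``range``;
    directionality is enforced by minimum-distance criteria on the four
    flanking backbone beads, evaluated at the association instant.  Each NH
    and each CO holds at most one partner.
    """

    range: float = 4.2                      # association distance, Angstrom
    epsilon_hb: float = EPS_HB_KJ           # kJ/mol (== 1 in reduced units)
    # (description, minimum distance in Angstrom) for the four flanking pairs
    aux_criteria: tuple[tuple[str, float], ...] = (
        ("CA(donor)-CO(acceptor)", 4.2),
        ("CO(donor-1)-CO(acceptor)", 4.2),
        ("CA(acceptor)-NH(donor)", 4.2),
        ("NH(acceptor+1)-NH(donor)", 4.2),
    )
    max_partners: int = 1
    min_residue_separation: int = 4         # intra-chain eligibility

    def __post_init__(self) -> None:
        if self.range <= 0 or self.epsilon_hb <= 0:
            raise ValueError("hbond range and epsilon must be positive")
        if self.max_partners != 1:
            raise ValueError("the model allows exactly one partner per bead")


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def bead_type_token(bead_type: str, residue_code: str | None = None) -> str:
    """Canonical bead-type token: 'NH', 'CA', 'CO' or 'R:<code>'."""
    if bead_type == "R":
        if residue_code is None:
            raise ValueError("sidechain token needs a residue code")
        return f"R:{residue_code}"
    return bead_type


class InteractionTable:
    """Symmetric hard-core / square-well parameters per bead-type pair.

    ``sigma`` (hard-core diameter) is defined for every pair; a square well
    ``(well_width lambda, well_depth eps)`` exists only for selected sidechain
    pairs.  Depths are in units of eps_HB and negative where attractive.
    """

    def __init__(
        self,
        sigma: Mapping[tuple[str, str], float],
        well_width: Mapping[tuple[str, str], float],
        well_depth: Mapping[tuple[str, str], float],
        hbond: HBondRule,
    ):
        self._sigma = {_pair_key(*k): float(v) for k, v in sigma.items()}
        self._width = {_pair_key(*k): float(v) for k, v in well_width.items()}
        self._depth = {_pair_key(*k): float(v) for k, v in well_depth.items()}
        self.hbond = hbond
        self.validate()

    # -- lookups ----------------------------------------------------------
    def sigma(self, a: str, b: str) -> float:
        return self._sigma[_pair_key(a, b)]

    def well(self, a: str, b: str) -> tuple[float, float] | None:
        """Return (lambda, eps) for the pair, or None if hard-sphere only."""
        k = _pair_key(a, b)
        if k in self._width and self._depth.get(k, 0.0) != 0.0:
            return self._width[k], self._depth[k]
        return None

    @property
    def sigma_items(self) -> dict[tuple[str, str], float]:
        return dict(self._sigma)

    @property
    def well_items(self) -> dict[tuple[str, str], tuple[float, float]]:
        return {
            k: (self._width[k], self._depth[k])
            for k in self._width
            if self._depth.get(k, 0.0) != 0.0
        }

    def n_sidechain_pairs(self) -> int:
        return sum(
            1 for (a, b) in self._sigma if a.startswith("R:") and b.startswith("R:")
        )

    # -- validation & serialization ---------------------------------------
    def validate(self) -> None:
        bad = []
        for k, sig in self._sigma.items():
            if sig < 0:
                bad.append((k, "sigma < 0"))
        for k, lam in self._width.items():
            if k not in self._sigma:
                bad.append((k, "well without sigma"))
            elif self._depth.get(k, 0.0) != 0.0 and lam <= self._sigma[k]:
                bad.append((k, f"lambda {lam} <= sigma {self._sigma[k]}"))
        if bad:
            listing = "; ".join(f"{a}-{b}: {msg}" for (a, b), msg in bad)
            raise ValueError(f"invalid interaction table entries: {listing}")

    def to_dict(self) -> dict:
        fmt = lambda k: f"{k[0]}|{k[1]}"
        return {
            "sigma": {fmt(k): v for k, v in sorted(self._sigma.items())},
            "well_width": {fmt(k): v for k, v in sorted(self._width.items())},
            "well_depth": {fmt(k): v for k, v in sorted(self._depth.items())},
            "hbond": {
                "range": self.hbond.range,
                "epsilon_hb": self.hbond.epsilon_hb,
                "aux_criteria": [list(c) for c in self.hbond.aux_criteria],
                "max_partners": self.hbond.max_partners,
                "min_residue_separation": self.hbond.min_residue_separation,
            },
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "InteractionTable":
        def parse(section) -> dict[tuple[str, str], float]:
            out: dict[tuple[str, str], float] = {}
            clashes = []
            for key, v in data.get(section, {}).items():
                a, b = key.split("|")
                k = _pair_key(a, b)
                if k in out and out[k] != float(v):
                    clashes.append(key)
                out[k] = float(v)
            if clashes:
                raise ValueError(
                    f"asymmetric {section} entries for pairs: {clashes}"
                )
            return out

        hb = data.get("hbond", {})
        rule = HBondRule(
            range=float(hb.get("range", 4.2)),
            epsilon_hb=float(hb.get("epsilon_hb", EPS_HB_KJ)),
            aux_criteria=tuple(
                (str(n), float(d))
                for n, d in hb.get("aux_criteria", HBondRule().aux_criteria)
            ),
            max_partners=int(hb.get("max_partners", 1)),
            min_residue_separation=int(hb.get("min_residue_separation", 4)),
        )
        return cls(parse("sigma"), parse("well_width"), parse("well_depth"), rule)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "InteractionTable":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# Backbone bead hard-core diameters (Angstrom)
SIGMA_BACKBONE = {"NH": 3.30, "CA": 3.70, "CO": 3.50}

#: Square-well depths of the shipped default profile, in eps_HB units
DEPTH_HYDROPHOBIC_FF = -1.0
DEPTH_SALT = -0.5
#: F-F well width beyond sigma; salt-pair widths scale with sidechain reach
WIDTH_FF_PAD = 1.40
SALT_REACH_FACTOR = 0.30


def default_interaction_table(
    profile: str | Mapping | None = "catch",
    hydrophobic_scale: float = 1.0,
) -> InteractionTable:
    """Build the shipped stand-in interaction table, or load a user config.

    The default profile gives attractive square wells to F-F sidechain pairs
    and to every cation-anion sidechain pair; like-charge and all remaining
    pairs are hard-sphere only.  Salt-pair well widths grow with sidechain
    reach, so the K-E well is wider than the K-D well (a longer sidechain has
    a greater range of interaction).
    """
    if isinstance(profile, Mapping):
        return InteractionTable.from_dict(profile)
    if profile is not None and profile != "catch":
        return InteractionTable.load(profile)

    tokens = dict(SIGMA_BACKBONE)
    for code, spec in RESIDUES.items():
        tokens[bead_type_token("R", code)] = spec.sigma

    sigma: dict[tuple[str, str], float] = {}
    names = sorted(tokens)
    for i, a in enumerate(names):
        for b in names[i:]:
            sigma[_pair_key(a, b)] = 0.5 * (tokens[a] + tokens[b])

    width: dict[tuple[str, str], float] = {}
    depth: dict[tuple[str, str], float] = {}

    k_ff = _pair_key("R:F", "R:F")
    width[k_ff] = sigma[k_ff] + WIDTH_FF_PAD
    depth[k_ff] = DEPTH_HYDROPHOBIC_FF * hydrophobic_scale

    cations = [c for c, s in RESIDUES.items() if s.res_class == "cationic"]
    anions = [c for c, s in RESIDUES.items() if s.res_class == "anionic"]
    for cpos in cations:
        for cneg in anions:
            k = _pair_key(f"R:{cpos}", f"R:{cneg}")
            reach = RESIDUES[cpos].reach + RESIDUES[cneg].reach
            width[k] = sigma[k] + SALT_REACH_FACTOR * reach
            depth[k] = DEPTH_SALT

    return InteractionTable(sigma, width, depth, HBondRule())


# ---------------------------------------------------------------------------
# System state & reduced units
# ---------------------------------------------------------------------------

@dataclass
class SystemState:
    """Positions, velocities and bookkeeping of a periodic DMD system.

    Positions are in Angstrom, velocities in reduced units (Angstrom per
    reduced time), the box is cubic and periodic.  ``hbond_registry`` maps
    each bonded NH bead index to its CO partner (a partial matching).
    """

    positions: np.ndarray
    velocities: np.ndarray
    box_length: float
    time: float = 0.0
    hbond_registry: dict[int, int] = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=float)
        if self.positions.shape != self.velocities.shape:
            raise ValueError("positions/velocities shape mismatch")
        co_partners = list(self.hbond_registry.values())
        if len(set(co_partners)) != len(co_partners):
            raise ValueError("hbond registry is not a matching")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def wrapped(self) -> np.ndarray:
        return np.mod(self.positions, self.box_length)

    def copy(self) -> "SystemState":
        return SystemState(
            self.positions.copy(), self.velocities.copy(), self.box_length,
            self.time, dict(self.hbond_registry), self.rng_seed,
        )


@dataclass(frozen=True)
class ReducedUnits:
    """Unit system: lengths in Angstrom, energies in eps_HB, masses in amu."""

    epsilon_hb: float = EPS_HB_KJ          # kJ/mol
    k_b: float = K_BOLTZMANN_KJ            # kJ/(mol K)

    def t_star(self, t_kelvin: float) -> float:
        if t_kelvin <= 0:
            raise ValueError("temperature must be positive")
        return self.k_b * t_kelvin / self.epsilon_hb

    def kelvin(self, t_star: float) -> float:
        if t_star <= 0:
            raise ValueError("reduced temperature must be positive")
        return t_star * self.epsilon_hb / self.k_b

    @property
    def time_unit_fs(self) -> float:
        """The reduced time unit in femtoseconds (A * sqrt(amu/eps_HB))."""
        amu = 1.66053906660e-27
        joule_per_particle = self.epsilon_hb * 1e3 / 6.02214076e23
        return 1e-10 * math.sqrt(amu / joule_per_particle) * 1e15


_UNITS = ReducedUnits()


def reduced_temperature(t_kelvin: float) -> float:
    """T* = k_B T / eps_HB."""
    return _UNITS.t_star(t_kelvin)


def kelvin_temperature(t_star: float) -> float:
    """Inverse of :func:`reduced_temperature`."""
    return _UNITS.kelvin(t_star)
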