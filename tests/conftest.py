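"""Shared fixtures: sequences, compiled systems and random-structure factories."""

from __future__ import annotations

import numpy as np
import pytest

from catchsim.peptide_model import (
    catch_sequence,
    default_interaction_table,
    sequence_from_string,
)
from catchsim import dmd_engine as de
from catchsim.structure_metrics import AtomisticStructure


@pytest.fixture(scope="session")
def seq_6k():
    return catch_sequence("6K+")


@pytest.fixture(scope="session")
def seq_6e():
    return catch_sequence("6E-")


@pytest.fixture(scope="session")
def seq_6d():
    return catch_sequence("6D-")


@pytest.fixture(scope="session")
def table():
    return default_interaction_table()


@pytest.fixture(scope="session")
def dimer_system(seq_6k, seq_6e, table):
    """A compiled K-peptide + E-peptide two-chain system."""
    return de.compile_system([seq_6k, seq_6e], table)


def random_hbond_geometry(rng, n_donors=25, n_acceptors=25, box_side=18.0):
    """Random donor/hydrogen/acceptor point sets for detector oracles."""
    d_heavy = rng.uniform(0, box_side, (n_donors, 3))
    offsets = rng.normal(size=(n_donors, 3))
    offsets /= np.linalg.norm(offsets, axis=1)[:, None]
    hydrogens = d_heavy + offsets * 1.0
    acceptors = rng.uniform(0, box_side, (n_acceptors, 3))
    coords = np.vstack([d_heavy, hydrogens, acceptors])
    n = len(coords)
    structure = AtomisticStructure(
        chain_ids=np.array(["A"] * n),
        residue_indices=np.arange(n),
        residue_codes=np.array(["G"] * n),
        atom_names=np.array(
            [f"D{i}" for i in range(n_donors)]
            + [f"H{i}" for i in range(n_donors)]
            + [f"O{i}" for i in range(n_acceptors)]),
        elements=np.array(["N"] * n_donors + ["H"] * n_donors
                          + ["O"] * n_acceptors),
        coords=coords,
    )
    donors = [(i, n_donors + i) for i in range(n_donors)]
    acceptors_idx = list(range(2 * n_donors, n))
    return structure, donors, acceptors_idx


def random_salt_structure(rng, n_lys=8, n_acid=8, box_side=16.0):
    """Random lysine ammonium and carboxylate groups with proper atom names."""
    chains, resi, codes, names, elems, coords = [], [], [], [], [], []
    res = 1
    for _ in range(n_lys):
        nz = rng.uniform(0, box_side, 3)
        entries = [("NZ", "N", nz)]
        for k in range(3):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            entries.append((f"HZ{k + 1}", "H", nz + u))
        for nm, el, xyz in entries:
            chains.append("A")
            resi.append(res)
            codes.append("K")
            names.append(nm)
            elems.append(el)
            coords.append(xyz)
        res += 1
    for _ in range(n_acid):
        code = "E" if rng.random() < 0.5 else "D"
        cd = rng.uniform(0, box_side, 3)
        pre = "OE" if code == "E" else "OD"
        for k in range(2):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            chains.append("B")
            resi.append(res)
            codes.append(code)
            names.append(f"{pre}{k + 1}")
            elems.append("O")
            coords.append(cd + 1.25 * u)
        res += 1
    return AtomisticStructure(
        np.array(chains), np.array(resi), np.array(codes),
        np.array(names), np.array(elems), np.array(coords))


def brute_force_hbonds(structure, donors, acceptors,
                       distance_cutoff=3.0, angle_cutoff=135.0):
    """Exhaustive O(N^2) geometric hydrogen-bond scan (test oracle)."""
    out = []
    coords = structure.coords
    for d, h in donors:
        for a in acceptors:
            if a in (d, h):
                continue
            ha = coords[a] - coords[h]
            dist = float(np.linalg.norm(ha))
            if dist == 0.0 or dist > distance_cutoff:
                continue
            hd = coords[d] - coords[h]
            cosang = float(hd @ ha /
                           (np.linalg.norm(hd) * np.linalg.norm(ha)))
            ang = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
            if ang >= angle_cutoff:
                out.append((int(h), int(a)))
    return sorted(out)


def brute_force_contacts(structure, cutoff=7.0, min_residue_separation=1):
    """Exhaustive O(N^2) residue-pair contact count (test oracle)."""
    counts = {}
    n = structure.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            if structure.chain_ids[i] == structure.chain_ids[j] and \
                    abs(int(structure.residue_indices[i])
                        - int(structure.residue_indices[j])) \
                    < min_residue_separation:
                continue
            if np.linalg.norm(structure.coords[i]
                              - structure.coords[j]) <= cutoff:
                a, b = structure.residue_codes[i], structure.residue_codes[j]
                key = (a, b) if a <= b else (b, a)
                counts[key] = counts.get(key, 0) + 1
    return counts


class UnionFind:
    """Minimal union-find used as an independent clustering oracle."""

    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def components(self):
        groups = {}
        for x in range(len(self.parent)):
            groups.setdefault(self.find(x), set()).add(x)
        return sorted(map(frozenset, groups.values()), key=sorted)
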