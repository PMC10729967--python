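# Residue registry for the four-bead coarse-grained peptide model.
#
# Per residue:
#   name3          3-letter PDB residue name
#   class          hydrophobic | cationic | anionic | polar
#   sidechain_mass united-atom sidechain mass in amu (average residue mass
#                  minus the NH + CaH + CO backbone portion, 56.044 amu)
#   sigma          hard-core diameter of the sidechain R bead, Angstrom
#   centroid       nominal R-Ca distance (sidechain centroid), Angstrom
#   reach          distance from the backbone plane to the sidechain tip in an
#                  extended beta-strand, Angstrom; used for bilayer surface
#                  packing and interaction-range heuristics
#   donor_atoms / acceptor_atoms: atomistic polar-hydrogen donors and
#                  acceptor oxygens used by the salt-bridge detector
#
# sigma/centroid/reach are documented stand-in values for this model class
# (effective van-der-Waals bead sizes and extended sidechain dimensions);
# they are fully overridable through the interaction-table config.
A: {name3: ALA, class: hydrophobic, sidechain_mass: 15.03,  sigma: 2.70, centroid: 1.50, reach: 2.40}
R: {name3: ARG, class: cationic,    sidechain_mass: 100.14, sigma: 5.00, centroid: 4.10, reach: 7.30,
    donor_atoms: {NH1: [HH11, HH12], NH2: [HH21, HH22], NE: [HE]}}
N: {name3: ASN, class: polar,       sidechain_mass: 58.06,  sigma: 4.20, centroid: 2.50, reach: 3.70}
D: {name3: ASP, class: anionic,     sidechain_mass: 59.04,  sigma: 4.16, centroid: 2.46, reach: 3.55,
    acceptor_atoms: [OD1, OD2]}
C: {name3: CYS, class: hydrophobic, sidechain_mass: 47.10,  sigma: 3.60, centroid: 2.10, reach: 2.80}
Q: {name3: GLN, class: polar,       sidechain_mass: 72.09,  sigma: 4.44, centroid: 3.10, reach: 4.70}
E: {name3: GLU, class: anionic,     sidechain_mass: 73.07,  sigma: 4.48, centroid: 3.11, reach: 5.65,
    acceptor_atoms: [OE1, OE2]}
# G carries no sidechain bead in the topology; the nominal sigma only keeps
# the interaction table fully populated over all 210 sidechain pairs.
G: {name3: GLY, class: polar,       sidechain_mass: 0.0,    sigma: 2.20, centroid: 0.75, reach: 1.00,
    no_sidechain: true}
H: {name3: HIS, class: cationic,    sidechain_mass: 81.10,  sigma: 4.70, centroid: 3.10, reach: 4.70,
    donor_atoms: {NE2: [HE2], ND1: [HD1]}}
I: {name3: ILE, class: hydrophobic, sidechain_mass: 57.11,  sigma: 4.50, centroid: 2.30, reach: 3.90}
L: {name3: LEU, class: hydrophobic, sidechain_mass: 57.11,  sigma: 4.90, centroid: 2.60, reach: 3.90}
K: {name3: LYS, class: cationic,    sidechain_mass: 72.13,  sigma: 4.68, centroid: 3.51, reach: 6.15,
    donor_atoms: {NZ: [HZ1, HZ2, HZ3]}}
M: {name3: MET, class: hydrophobic, sidechain_mass: 75.15,  sigma: 4.60, centroid: 2.90, reach: 4.80}
F: {name3: PHE, class: hydrophobic, sidechain_mass: 91.13,  sigma: 5.08, centroid: 3.40, reach: 5.00}
P: {name3: PRO, class: hydrophobic, sidechain_mass: 41.07,  sigma: 4.30, centroid: 1.90, reach: 2.40}
S: {name3: SER, class: polar,       sidechain_mass: 31.03,  sigma: 3.30, centroid: 1.90, reach: 2.40}
T: {name3: THR, class: polar,       sidechain_mass: 45.06,  sigma: 3.90, centroid: 1.90, reach: 2.60}
W: {name3: TRP, class: hydrophobic, sidechain_mass: 130.17, sigma: 5.50, centroid: 3.90, reach: 5.90}
Y: {name3: TYR, class: polar,       sidechain_mass: 107.13, sigma: 5.20, centroid: 3.80, reach: 6.40}
V: {name3: VAL, class: hydrophobic, sidechain_mass: 43.09,  sigma: 4.00, centroid: 2.00, reach: 2.50}
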