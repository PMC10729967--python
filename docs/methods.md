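# Methods

## The coarse-grained model

Each amino acid is represented by four spheres: three backbone beads — NH
(15.015 amu), CαH (13.019 amu), CO (28.010 amu) — and one sidechain bead R
carrying the remaining residue mass.  Glycine has no sidechain bead.
Covalent structure is maintained by hard-wall bonds (NH–Cα, Cα–CO,
CO–NH(next), R–Cα) and pseudobonds (NH–CO within a residue, Cα–Cα between
consecutive residues, R–NH and R–CO) that confine each pair to
[L(1−δ), L(1+δ)] with δ = 0.02375, the customary tolerance for this model
family.  Nominal lengths L derive from one canonical local strand
geometry (rise 3.5 Å per residue, NH/CO offset ±0.5 Å laterally and
±1.25 Å axially from the Cα line, sidechain centroid perpendicular to the
backbone plane), so ideal built structures satisfy every bond window
exactly.  Beads within three bonds of each other in the same chain do not
interact non-bondedly; the pseudobond network holds their geometry.

Non-bonded interactions are hard-sphere cores, optionally decorated with
one square well:

* **Backbone cores**: NH 3.30 Å, Cα 3.70 Å, CO 3.50 Å diameter; sidechain
  cores are residue-specific (e.g. F 5.08 Å, K 4.68 Å, E 4.48 Å,
  D 4.16 Å); unlike pairs combine arithmetically.  These are documented
  effective van-der-Waals stand-ins; the exact published parameter tables
  of this model family live outside this package, so the interaction
  table is fully config-loadable (YAML with `sigma`, `well_width`,
  `well_depth`, `hbond` sections) and ships a default profile.
* **Default wells**: F–F at −1.0 ε_HB (width σ+1.4 Å) for the
  phenylalanine core, and every cation–anion sidechain pair at −0.5 ε_HB
  with width σ + 0.3·(reach_a + reach_b), where *reach* is the extended
  sidechain tip extent.  The longer glutamate sidechain therefore gives
  the K–E well (8.12 Å) a greater range than K–D (7.33 Å), the mechanism
  to which the bulk system's faster K/E kinetics is attributed (see the
  desk-scale discussion below).  Like-charge and all
  remaining pairs are hard-sphere only, so charge complementarity is
  built in: complementary peptides attract, like-charged ones do not.
* **Hydrogen bonds**: an unpartnered NH and CO associating at 4.2 Å form a
  bond of depth ε_HB (the unit energy, 12.47 kJ/mol) provided four
  directional criteria hold at the association instant: the donor's Cα
  and previous CO, and the acceptor's Cα and next NH, must each be at
  least 4.2 Å from the partner bead.  In the ideal antiparallel sheet
  geometry these flanking distances are 4.67 Å and 5.10 Å, so β-ladders
  are admitted while side-on approaches are vetoed.  Each NH and CO holds
  at most one partner; intra-chain bonds require a four-residue
  separation.  A bonded pair escapes only when its radial kinetic energy
  exceeds ε_HB, otherwise it bounces.

Reduced units: lengths in Å, energies in ε_HB, masses in amu.  The
derived time unit is √(amu·Å²/ε_HB) ≈ 28.3 fs.  Reduced temperature is
T\* = k_BT/ε_HB; the definition maps T\* = 0.18 to ≈ 270 K, while an
external calibration of this model family places it nearer 296 K — both
conversions are exposed and neither is asserted as canonical.

## The event-driven engine

Between events every bead moves ballistically; the engine advances from
one exactly-solved discontinuity to the next (hard-core collision, well
capture/escape/bounce, bond wall, hydrogen-bond association/dissociation,
thermostat ghost collision).  Collision rules conserve momentum exactly;
well crossings exchange exactly the well depth between radial kinetic and
potential energy, so with the thermostat off total energy is conserved to
round-off (measured drift ~1e-13 over 1e5 events).

Scheduling uses a per-bead event calendar: each bead stores only its
earliest pending event, ordered by an indexed binary heap, with per-bead
epoch counters for lazy revalidation.  Neighbour search uses a cell list
whose crossings are themselves events; stencil radii are per bead (a
backbone bead only needs 27 cells, a long-range charged sidechain scans
radius 2).  Cell walls are measured from the bead's *assigned* cell
rather than the floor of its coordinate, so a bead sitting numerically on
a wall cannot stall the event loop.  A 10-reduced-time-unit scheduling
horizon caps how far predictions look ahead; every bead is refreshed at
least once per horizon, which keeps the calendar exact.  Pair predictions
classify boundary states with a 1e-9 relative tolerance band so that
post-event round-off cannot generate phantom crossings.

With cells disabled the same trajectories are reproduced (the short-run
difference is at the 1e-13 level); over long runs the two modes drift
apart because piecewise ballistic updates accumulate different round-off,
which chaotic hard-sphere dynamics then amplifies — the equivalence test
therefore compares a few thousand events.

The Andersen thermostat redraws one uniformly chosen bead's velocity from
the Maxwell–Boltzmann distribution at T\* at Poisson-distributed times
(default rate 0.01 per bead per reduced time; assembly runs here use
0.05).  All randomness comes from a splitmix64 generator seeded
explicitly, so runs are bit-reproducible for a fixed seed.

## Builders and synthetic data

The ideal-structure builders use the coordinate convention sheet long
axis = x, strand axis = y, stacking = z (right-handed, so a negative
twist is left-handed).  Sheets alternate strand orientation and peptide
charge; strand k is rotated k·twist about the sheet long axis.  Bilayers
bury the phenylalanine faces (13 Å backbone-plane gap); two-bilayer
stacks face the charged surfaces of sheets 2 and 3 with a 3 Å tip gap
(stacked) or 13 Å surface gap (separated).  The facing-surface extent is
the mean extended tip reach of the charged residue types (K 6.15 Å,
E 5.65 Å, D 3.55 Å), chosen to reproduce the initial packing geometry of
the corresponding atomistic constructions: plane-fit layer distances of
14.8 Å (K/E) and 12.7 Å (K/D) in stacked mode.

Random dispersions are generated by randomising each chain's conformation
with a short high-temperature single-chain run of the engine itself (all
bond and excluded-volume constraints hold exactly by construction),
then placing rotated copies by rejection sampling at a minimum
inter-peptide separation, with Maxwell–Boltzmann velocities at the target
T\*.  Scripted trajectories fabricate frames with known cluster
composition — sheets as strand rows, barrels as strand cycles, "blob"
oligomers touching only hydrophobically — and a hydrogen-bond registry
wired so the connectivity analysis must reproduce the script; they are
the ground truth for the classifier and transition tests.

What the synthetic data do not emulate: solvent and counter-ions (the
model is implicit-solvent), relaxed thermal β-sheet geometry (builders
are ideal), and the multi-microsecond, 200-peptide scale of real
co-assembly runs.  Passing tests therefore demonstrate correct machinery
and qualitative physics, not quantitative bulk kinetics.

## Analyses

Strand axes are total-least-squares 3-D line fits through the Cα
positions, oriented N→C.  The twist between neighbouring strands aligns
antiparallel axes first (else every pair would read ≈180°) and signs the
angle by (axis_i × axis_j)·d̂ with d̂ pointing from strand i to strand j;
negative is left-handed.  Sheet separations are distances between the
centroids of total-least-squares planes through each sheet's backbone.
Hydrogen bonds and salt bridges use the geometric criteria H···A ≤ 3.0 Å
and donor–H···A ≥ 135°, with salt bridges restricted to ammonium
hydrogens (K/R/H) and carboxylate oxygens (D/E); missing polar hydrogens
are an explicit error, never silently inferred.  Contacts count atom
pairs within 7 Å, excluding intra-residue pairs (configurable) — a
self-contact carries no interaction meaning.  Structures are analysed
unwrapped; the minimum image is applied only when a periodic box is
present.

Secondary-structure aggregation averages per-frame DSSP class assignments
into per-residue occupancies; helix is reported as the sum of the 3-10,
α and π classes.  The packaged CATCH monomer table ships as the worked
example input; per-residue occupancies are stored to two decimals, so
only the columns whose printed totals equal their column sums are used as
exact references.

Assembly kinetics: peptides are connected at ≥ 5 shared hydrogen bonds or
≥ 2 hydrophobic sidechain contacts (hydrophobic-class R beads inside
their square-well range).  Within a connected component, the
strand-adjacency subgraph keeps only edges with ≥ 5 hydrogen bonds: a
single cycle through all members is a β-barrel, a single spanning path of
≥ 4 members a β-sheet, anything else an oligomer.  The fibrillar count
sums β-sheet and β-barrel peptides; cluster identity across frames uses
>50% member overlap, and class changes of persistent clusters are logged
as transitions (a retrospective final-frame fibril label is also
available from the last frame's census).

## Desk-scale study conditions

Bulk co-assembly operates at scales (hundreds of peptides, 1e11
collisions) far beyond a workstation test suite.  The comparative
kinetics experiment runs 10+10 peptides in a 60 Å box (≈ 77 mM) at
T\* = 0.18 with the default table over a common 1000-reduced-time window
(a matched clock: stopping at a fixed event budget instead would give
runs of different physical lengths and bias any time-based comparison),
ten seed-matched replicas per variant.  Charge complementarity behaves
as designed — complementary peptides aggregate and hydrogen-bond, the
K/K control never forms a 5-hydrogen-bond connection — but the finer
K/E-faster-than-K/D ordering does not emerge under these conditions:
halftime medians are statistically tied (with a slight reverse trend),
and aspartate's smaller sidechain, which shields the backbone less at
contact, offsets glutamate's wider capture well.  The greater-range
mechanism behind the faster K/E kinetics of the bulk system operates in
encounter-limited, dilute (≈ 20 mM) kinetics; since bond-wall events
cost a fixed ~4000 events per reduced time unit regardless of density,
reaching that regime needs runs one to two orders of magnitude longer
than a test suite can afford.  The comparative-kinetics acceptance test
asserts the bulk ordering and is expected to fail at desk scale; it is
kept as the faithful statement of the claim rather than weakened.

## Numerical and design choices

* Boundary classification tolerance 1e-9 (relative, squared distances);
  initial-state validation rejects core overlaps and broken bond windows
  rather than repairing them silently.
* Hydrogen-bond association that fails its directional criteria is a
  transparent crossing (no velocity change); an unregistered NH–CO pair
  inside range can only re-attempt after a velocity change, which is
  exact because re-entry requires one.
* Terminal caps are charge-neutral and folded into the terminal backbone
  beads; CATCH peptides are modelled acetyl/amide-capped.
* The +/− strand pattern within each sheet is strict alternation
  (charge-complementary contacts maximised); exposed as a builder option
  through the sequence arguments.
* Sidechain pleat parity is chosen per sheet so hydrophobic faces point
  inward in bilayers; chirality is not enforced by the distance network
  (a mirrored conformation satisfies the same constraints).
* The collision-count ↔ physical-time mapping of bulk studies is not
  derivable from stated quantities; all times here remain in reduced
  units.

## Known limitations

* The interaction table is a documented stand-in profile of the right
  model class, not the published parameter set; quantitative rates should
  not be compared against bulk experiments.
* Per-run time scales are ~1e3 reduced units, 5 orders of magnitude below
  bulk co-assembly studies; β-barrel intermediates large enough to close
  (6–8 strands) do not nucleate spontaneously at this scale and are
  exercised through scripted trajectories instead.
* DSSP assignment itself is consumed, not computed.
* Interaction energies (MM/GBSA- or LIE-style) are out of scope; group
  contact counts are the structural proxy.
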