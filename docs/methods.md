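# Methods

## The model system

A peptide-bond unit is the planar conjugated group linking residues *k*
and *k+1*: carbonyl C and O of residue *k*, amide N (and its polar H) of
residue *k+1*, with the two flanking Cα atoms. The N, C, O atoms span the
unit's π-plane. The unit is both an H-bond/Hp–π **donor** (through the
amide H) and an **acceptor** (through the plane). The minimal chemical
model of one unit is N-methyl-acetamide (NMA), CH₃–CO–NH–CH₃, and the
calibration energies used throughout are coupled-cluster interaction
energies of the NMA–NMA dimer.

## Contact geometry

For a donor H against an acceptor plane we record, per acceptor site
*s* ∈ {N, C, O, center}:

- `r_s` — 3D distance from H to the site point (nuclei, or the unweighted
  N/C/O centroid for "center"; the mass-weighted centroid differs by
  < 0.05 Å and the unweighted one is reproducible without mass tables);
- `theta` — angle of the donor N–H bond against the plane normal, folded
  to [0°, 90°] so the normal's sign never matters;
- `approach[s]` — elevation angle of H over the plane as seen from the
  site, `arccos(d_perp / r_s)`, also in [0°, 90°];
- `d_perp`, `(u, v)` — height over the plane and in-plane offsets of the
  projection;
- `angle_NHO` and the O-site elevation, the classical H-bond descriptors.

All distances are Å, all angles degrees. Descriptors are exactly
invariant under rigid motion.

## The anchored potential

Anchors (ε in kJ/mol, r in Å): vacuum N(−17.329, 2.310), C(−16.464,
2.514), O(−24.252, 2.368), center(−16.001, 2.550); water N(−12.207,
2.654), C(−8.276, 3.110), O(−15.759, 2.319); H-bond comparator
(−24.391, 2.019). The calibration set has no water "center" row; it is
synthesized as the vacuum center depth scaled by the mean water/vacuum
ratio over N, C, O (≈ 0.619, giving −9.90 kJ/mol at 2.550 Å) and flagged
as synthesized in the table metadata.

The radial profile is an (a, b) = (6, 10) n–m well in x = r/r_anchor,
`f(x) = (b·x⁻ᵃ − a·x⁻ᵇ)/(b − a)`: `f(1) = 1` makes every anchor exact by
construction, the x → ∞ tail vanishes, and x below ≈ 0.88 turns
repulsive, capped at `e_max = +50 kJ/mol` (a finite stand-in for the hard
wall at atomic collision; finite so grids stay plottable). Exponents are
exposed in `calibrate(a=..., b=...)`.

**Orientation law.** Site energies are weighted by cos²θ of an approach
angle, vanishing for in-plane approach — where the canonical hydrogen
bond takes over (its own weight is cos²(180° − angle_NHO) for angles
≥ 120°, zero below). For *which* angle to use the design was genuinely
open; the package uses the per-site **elevation angle of the hydrogen
over the plane** (`approach[s]`), not the N–H bond tilt, for these
reasons: (i) at every calibration pose the two coincide at 0°, so anchor
exactness is unaffected; (ii) the overlap of the H with the π cloud is a
function of where the H *is*, and bond lengths for these contacts are
conventionally measured from H to the plane; (iii) in rigid connected
peptides the N–H bond is geometrically forced tens of degrees off the
acceptor normal even in the canonical loop conformations — a bond-tilt
law scores precisely those conformations near zero and relocates the
torsion-map basins far from where they belong. The bond-tilt variant
remains available (`contact_energy(..., orientation="bond")`), and the
bond tilt itself is what the detector's `theta_max` gate tests.

A contact's energy is the minimum of the four site energies (the "best
site"). Negative energies are attractive (interaction energy relative to
separated monomers).

## In-plane scan

`plane_scan` holds a probe H at a fixed height (default 2.5 Å, the
typical Hp–π bond length) above the plane, perpendicular, and rasters a
4 × 8 Å rectangle in 0.1 Å steps, inclusive of both ends: 41 × 81 = 3321
nodes. The grid is centred on the site centroid with the long axis along
the in-plane N→O direction, so all three atom-site projections fall
inside. The three wells emerge at the site projections with the deepest
at O; at a fixed 2.5 Å height the N well is slightly shallower than the C
well because the N anchor distance (2.310 Å) is the furthest below the
probe height — per-site depth ordering at each site's *own* optimal
height follows the anchors (O < N < C).

## Hydrogen reconstruction and torsions

Amide hydrogens missing from the input are placed 1.010 Å from N in the
plane of (C_prev, N, CA), opposite the bisector of the C_prev→N and CA→N
directions — the standard planar sp² amide rule. Prolines and chain-start
residues get no H; file hydrogens win over reconstruction. Torsions
follow the IUPAC convention, degrees in (−180°, 180°], with chain
termini, chain breaks (C–N > 1.8 Å) and numerically collinear frames
flagged undefined rather than guessed.

## Detection gates

Defaults (all exposed in `DetectionParams`): Hp–π requires best-site
r ≤ 3.2 Å, N–H tilt θ ≤ 35°, height d_perp ≥ 1.5 Å, and the in-plane
projection within 1.2 Å of a site point or inside the N–C–O triangle.
H-bond requires r_HO ≤ 2.5 Å, N–H···O angle ≥ 120°, O-site elevation
≤ 30°, and takes precedence: the two regimes are geometrically
complementary (perpendicular vs in-plane), so an ambiguous pose is
recorded once, as an H-bond. The r/θ windows bracket the calibration
geometries (anchor distances 2.31–2.55 Å, bond lengths "around 2.5 Å");
they are exemplar-derived cutoffs, not fitted quantities. Adjacent units
are allowed (loop Hp–π bonds connect consecutive units; both pair orders
are evaluated, which also covers the four-atom-ring H→C contact of the
fourth loop conformation). Proline units can accept (the plane exists)
but never donate (no amide H).

## Dipeptide builder and torsion map

The blocked alanine dipeptide CH₃–CO–NH–CαH(CH₃)–CO–NH–CH₃ is built by
NeRF internal-coordinate placement from a fixed standard restraint set
(N–Cα 1.458, Cα–C 1.525, C–N 1.329, C=O 1.231, N–H 1.010, Cα–Cβ 1.521,
C–CH₃ 1.505 Å; N–Cα–C 111.0°, Cα–C–N 116.2°, C–N–Cα 121.7°, Cα–C–O
120.8°, C–N–H 119.2°, N–Cα–Cβ 110.4°; ω = 180°). Requested torsions are
reproduced exactly by construction. The Cβ branch offset (−122.6° off Φ)
gives the L configuration (validated against a reference L-alanine
template). The Cβ breaks the (Φ,Ψ) → (−Φ,−Ψ) symmetry of the map through
its clash contacts only, since the contact energy itself is
mirror-invariant.

The scan covers the inclusive grid (−180° … 180°, default 5° step, 73² =
5329 nodes; the ±180° seam is intentionally duplicated). Node energy =
the lower of the two directed unit-pair contact energies, with a
hard-sphere override: any non-bonded (graph distance ≥ 3 bonds)
heavy–heavy pair under 2.4 Å or H–heavy pair under 1.6 Å sets the node to
`e_max`. The map reproduces the *topology and geometry* of the torsion
landscape — collision ridge at the origin, attractive loop basins in all
four quadrants, H···site distances at the printed centers to ≤ 0.15 Å —
but **not** quantum-chemical ΔE values, which are differences against a
(Φ=90°, Ψ=180°) reference state this package does not compute.

**Known limitation — basin centres.** With the fixed restraint set the
rigid dipeptide cannot place the amide H perpendicular over the carbonyl
O at (−90°, 70°) the way QM-relaxed monomer geometries do (the H sits at
d_perp 1.68 Å with r_O 2.30 Å there). In consequence the continuous
surrogate landscape puts the first/third loop-conformation pits at about
(−91°, 40°)/(91°, −40°), i.e. 20–30° from the printed centres (nearest
grid pits (−95°, 50°)/(95°, −50°)), rather than on top of them. Both
basins classify to the correct region label. Treating this by softening
the restraint set or the angular law was rejected: every variant examined
(bond-tilt law: ≈ 56° off; no angular term: ≈ 47° off) is worse, and the
restraint values are part of the declared study conditions.

Region assignment is nearest-centre on the (Φ, Ψ) torus over the ten
named centres (α(−65,−40), β(−165,165), H–π–1(−90,70), H–π–2(60,40),
H–π–3(80,−65), H–π–4(−140,−70), three barriers, reference(90,180)), ties
broken by that fixed order; the second-nearest label is carried along
because the α and H–π–1 basins genuinely overlap.

## Synthetic fixtures

`make_ideal_segment` builds poly-alanine at exact per-residue (Φ, Ψ) —
ideal helices and strands for round-trip and parallel-plane tests.
`make_hp_pi_pair` / `make_hbond_pair` pose two NMA units at an exact
contact geometry (descriptors echo the request to ~1e−9), giving
constructed positives for both contact classes. `make_beta_pair` joins
two extended strands by one coplanar linear inter-strand H-bond — the
sheet-like geometry that must yield H-bonds and no Hp–π. `make_decoy`
grows a chain with uniform-torus torsions and heavy-atom clash rejection,
backtracking one residue when a clash is baked in upstream; fully seeded
and byte-reproducible. Decoys are the least-informative null for property
tests. What these fixtures do **not** emulate: side chains beyond
alanine, experimental coordinate noise, missing atoms/altloc pathologies
beyond what the parser tests construct, and realistic loop ensembles — so
passing tests certify the geometry and scoring machinery, not
detection-rate claims on real crystal structures.

## Problem sizes and determinism

The shared test torsion map uses the default 5° step (5329 dipeptide
builds, a few seconds); the plane scan is the full 3321-node
configuration; decoy property sweeps use 100 chains of 12 residues and
brute-force detector comparisons use chains of ≤ 6 residues where
exhaustive evaluation is trivial. Everything is seeded (NumPy PCG64);
identical inputs give byte-identical outputs, including contact ordering
(donor index, then acceptor index).

## Real-structure analysis

`analyze_loop` slices a chain range, reconstructs hydrogens, detects and
summarises contacts and reports backbone torsions; `hppi scan` is the CLI
wrapper. Structure files are never bundled — the α-amylase loop used in
the real-structure test (PDB 1BLI, chain A, Asp325–Phe343) must be
downloaded by the user, and the corresponding test states this explicitly
when the file is absent. Side-chain donors/acceptors (e.g. aspartate
carboxylate H-bonds) are out of scope and noted, not detected.
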