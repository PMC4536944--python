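# hppi — polar hydrogen–π bonds in protein backbones

`hppi` detects and scores **Hp–π bonds**: the attraction between a backbone
amide hydrogen (the polar H on nitrogen) and the π-electron plane of a
neighbouring peptide-bond unit. Every peptide bond C(=O)–N(H) is a small
conjugated plane spanned by its N, C and O atoms; in α-helices and
β-strands these planes stack so that classical N–H···O=C hydrogen bonds
form, but in loops the planes twist and the amide H often ends up
*perpendicular* over a neighbouring plane instead — a geometry where the
hydrogen bond vanishes and the Hp–π interaction takes over. These bonds
are a structural support of loop backbones, which is where much of a
protein's function (catalysis, recognition) lives.

The package is aimed at structural bioinformaticians who want to locate
and rank these contacts in PDB coordinates, and at modellers who want a
fast empirical stand-in for the underlying quantum-chemistry numbers.

## What it computes

**Anchored site potential.** Each acceptor site *s* ∈ {N, C, O, center}
carries a coupled-cluster calibration anchor (ε_s, r_s) — the well depth
(kJ/mol) at the anchor distance (Å) for perpendicular approach of the
N-methyl-acetamide dimer, in vacuum and in water. Around each anchor the
energy is

    E_s(r, θ) = ε_s · f(r / r_s) · cos²θ,
    f(x) = (b·x⁻ᵃ − a·x⁻ᵇ) / (b − a),   a = 6, b = 10,

so `f(1) = 1` reproduces every anchor exactly, the tail decays to zero,
and the short-range branch is repulsive (capped at E_max = +50 kJ/mol).
θ is the approach (elevation) angle of the hydrogen over the plane at the
site; a contact scores as the deepest of the four site energies. A
canonical H-bond comparator uses the same radial family around the
backbone H-bond anchor (−24.391 kJ/mol at 2.019 Å) for the complementary
in-plane, near-linear geometry.

**Detection.** Peptide units are assembled from consecutive residues,
amide hydrogens are reconstructed by the planar bisector rule (N–H
1.010 Å) when missing, and every ordered unit pair is classified by
geometric gates into `hp_pi`, `h_bond`, or neither (H-bond takes
precedence for ambiguous poses). Loop-level statistics report which
residues are "supported" by at least one Hp–π bond.

**Φ–Ψ torsion map.** A rigid blocked alanine dipeptide built from a
standard restraint set is scanned over the full (Φ, Ψ) torus; each node
gets the best directed unit-pair contact energy plus a hard-sphere clash
cap. Basins are located and every point is assigned to a named
conformational region (α, β, the four Hp–π loop conformations H–π–1…4,
barriers, reference).

**Synthetic fixtures.** Ideal helix/strand segments, exact-geometry
Hp–π and H-bond unit pairs, β-sheet-like strand pairs and seeded random
decoy chains — everything the test-suite needs is generated from internal
coordinates, no downloads.

## Worked example

```python
from hppi import calibrate, detect_hp_pi, summarize_contacts
from hppi.detect import contacts_to_dataframe
from hppi.fixtures import make_hp_pi_pair

model = calibrate()                       # anchor-exact site potential
s = make_hp_pi_pair("O", 2.368, 0.0)      # two NMA units at the O anchor pose
contacts = detect_hp_pi(s, model=model)
print(contacts_to_dataframe(contacts).to_string(index=False))
```

prints

```
donor_res acceptor_res class site     r  theta  d_perp   E_vac  E_water
     NME4         ACE1 hp_pi    O 2.368    0.0   2.368 -24.252  -15.574
```

one Hp–π contact: the donor's amide H sits 2.368 Å perpendicularly above
the acceptor's carbonyl O, scoring exactly the vacuum calibration depth
−24.252 kJ/mol (−15.574 kJ/mol with the water anchors — solvation roughly
halves the well, as the calibration table shows). `summarize_contacts`
reports 1 Hp–π bond supporting 2 residues.

On a real structure (download `1BLI.pdb` yourself; structures are never
bundled):

```bash
hppi scan 1BLI.pdb --chain A --range 325:343 --out loop.tsv
hppi map --step 5 --out map.csv
hppi classify --phi -90 --psi 70
# {"region": "hpi1", "center": [-90.0, 70.0], "distance_deg": 0.0, "second": "alpha"}
hppi fixtures --out fixtures/ --seed 17
```

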