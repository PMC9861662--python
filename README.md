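# glycotube

Modeling and trajectory analysis of glycosaminoglycan adsorption on
carboxylated carbon nanotubes.

Carboxyl-functionalized carbon nanotubes (fCNT) are a standard route to
biocompatible nanotube surfaces, and natural glycosaminoglycans —
hyaluronan (HA, repeating GlcA-β1,3-GlcNAc) and chondroitin (Ch, the
GalNAc epimer) — are candidate non-covalent coating agents. Studying how
these sugars adsorb requires three things this package provides as a
Python library:

1. **Structure builders with exact bookkeeping** — periodic zigzag
   (n,0) nanotubes grafted with carboxylate (COO⁻) or carboxylic-acid
   (COOH) motifs (anchor carbon rehybridized sp²→sp³ together with a
   hydrogen-capped neighbor), partial-charge assignment and uniform
   redistribution of the residual charge so the tube carries exactly
   −1 e per carboxylate; idealized ⁴C₁ glycan models with IUPAC atom
   names and exact glycosidic torsions φ = O5–C1–O1–C′ₙ,
   ψ = C1–O1–C′ₙ–C′ₙ₋₁ (n = 3 or 4); box assembly with Na⁺/Cl⁻ at a
   prescribed ionic strength and exact neutrality.
2. **A synthetic-trajectory generator** whose statistics are known by
   construction — two-state adsorption/desorption kinetics, monolayer
   radial placement, a scripted ring face (A = H1–H5, B = H2–H4/O4)
   toward the surface, and glycosidic torsions drawn from wrapped-normal
   basin mixtures — so every analysis can be validated against ground
   truth without running molecular dynamics.
3. **The analysis suite**: cylindrical radial density profiles and
   monolayer metrics, orientation-side classification from face-atom
   density peaks, detachment-event detection, Lennard-Jones/Coulomb pair
   energies `E_LJ = Σ 4ε_ij[(σ_ij/r)¹² − (σ_ij/r)⁶]`,
   `E_C = Σ f q_i q_j / r` (f = 138.935458 kJ·mol⁻¹·nm·e⁻², 1.2 nm
   cutoff, minimum image), strict geometric hydrogen-bond counting
   (d(A,D) < 3 Å and the acceptor–donor–H angle < 20°), free-energy maps
   by Boltzmann inversion `F = −k_BT ln(P/P_max)`, RMSF with optional
   least-squares superposition, and Cremer–Pople ring-pucker
   classification (⁴C₁/¹C₄ chair, boat, skew-boat).

The library is the interface; `examples/` holds one short narrative
script per capability, and a thin `glycotube` CLI wraps the builders and
analyses for shell use.

## Worked example

```python
from glycotube import fcnt, glycan, assemble as asm, adsorption as ads
from glycotube.trajectory import AdsorptionScenario, generate

tube = fcnt.functionalized_tube(seed=2024)       # (17,0), 14 cells, 2% COO-
print(tube.n_atoms, tube.n_groups, tube.net_charge)
# 1032 20 -20.0        <- 952 wall C + 20 four-atom motifs; exactly -1 e/group

system = asm.assemble(tube, [glycan.build_monosaccharide("GlcNAc")], 5,
                      asm.BoxSpec.for_tube(tube), asm.IonSpec(0.15), seed=1)
traj, truth = generate(system, AdsorptionScenario(facing="A"),
                       n_frames=500, seed=3)
profile = ads.radial_profile(traj, traj.indices(molclass="glycan"))
print(ads.layer_metrics(profile).fraction_within_15)
# 0.99...              <- monolayer: nearly all density within 15 A of the axis
print(ads.orientation(traj, "GlcNAc").preferred)
# 'A(H1-H5)'           <- the scripted ring face is recovered from the
#                         face-atom density peaks (side A peak at smaller r)
```

Running `python examples/build_functionalized_tube.py` prints the
structural bookkeeping of the production tube:

```
unfunctionalized tube: 952 carbons, period 5.9514 nm, radius 6.64 A
grafted 20 carboxylate motifs (ceil of 2% of 952 carbons)
net charge after redistribution: -20.000000000000 e (exactly -1 e per carboxylate group)
(10,0) QM reference clusters: 164 atoms (COO-), 165 atoms (COOH)
```

The 952/20/164/165 counts and the 5.95 nm box edge are the printed
characteristics of the simulated systems; the −20 e is the invariant the
charge-redistribution step enforces exactly.

## File formats

PDB (Å) and GRO (nm) coordinates are read and written through
MDAnalysis; extended XYZ carries the box in a `Lattice="..."` comment.
Glycan residues use the 3-letter codes GCA (GlcA), NAG (GlcNAc), NGA
(GalNAc). Tube topology (atoms/bonds/angles/dihedrals with
periodic-image flags) is written as a plain-text sectioned table, and
force-field parameters as a 4-column text table (type, σ nm, ε kJ/mol,
q e).

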