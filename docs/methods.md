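# Methods

This note records the models, conventions and numerical choices behind
`glycotube`, in the spirit of a simulation package's model
documentation: what is computed, under which assumptions, and what the
synthetic data do and do not establish about real systems.

## Nanotube construction and functionalization

A zigzag (n,0) tube is the rolled graphene sheet: circumference
n·√3·a_cc, hence radius r = √3·n·a_cc/(2π); the translational cell holds
4n carbons over a period of 3·a_cc. The default aromatic bond length is
a_cc = 0.1417 nm, which puts the 14-cell (17,0) production tube at 952
carbons over a 5.951 nm period — the box z edge, since the tube is
treated as an infinite molecule with bonds, angles and proper dihedrals
wrapping the z boundary (each bonded term carries a periodic-image
flag). All wall atoms lie exactly on the ideal cylinder; bonded topology
is generated by neighbor search at a 1.6 Å cutoff including periodic
images, giving exactly three carbon neighbors per wall carbon.

Carboxyl grafting follows the rehybridization motif: the anchor carbon
becomes sp³ and bonds the carboxyl carbon; one randomly chosen bonded
neighbor also becomes sp³ and is capped with hydrogen, conserving
valence. Anchors are drawn without replacement at a minimum bond-graph
separation of 3 (two motifs never share or fuse atoms); the draw is
deterministic per seed. Group count comes from ceiling rounding of the
coverage fraction — ceil(0.02·952) = 20 — which is what makes "2%"
consistent with 20 groups on 952 carbons.

Motif partial charges are a configuration block
(`MotifChargeSet`). The shipped defaults are synthetic placeholders:
they sum to a deliberately non-integral value per group so the
redistribution step is exercised, and they are not quantum-derived
values (those enter as configuration when available). Charge
redistribution divides the total residual over the non-motif wall
carbons uniformly and absorbs the final floating-point crumb, so the
net charge equals the formal charge (−1 e per carboxylate, 0 per acid)
to better than 1e-12 e. The finite hydrogen-capped (10,0) clusters
(2n·rings wall carbons + 2n axial caps at 1.09 Å + 4- or 5-atom motif)
reproduce the 164/165-atom reference models.

## Glycan models

Residues are β-D-pyranoses built on an ideal chair: ring atoms at
hexagonal positions (radius 1.442 Å) with alternating ±0.25 Å axial
displacement, phased so Cremer–Pople θ ≈ 0 (the ⁴C₁ convention for the
O5,C1..C5 ordering, verified against an embedded β-D-glucopyranose).
Every ring bond is 1.526 Å; this uniform "ideal" length (C–O ring bonds
are really ~1.43 Å) is the template's own reference value and is what
the geometry invariants check against. Substituents are placed by
tetrahedral completion at each ring carbon, which makes the face
structure emerge naturally: H1, H3, H5 axial on one face (side A), H2
and H4 on the other (side B), and the C4 epimerization that turns
GlcNAc into GalNAc swaps O4 into the axial side-B slot. GlcA carries a
deprotonated carboxylate (−0.5 e on each O6; formal charge −1),
matching physiological pH.

Chains grow residue by residue. Given the placed donor, the acceptor's
linkage carbon is positioned by internal coordinates (bond 1.43 Å,
C1–O1–C′ₙ angle 117°, dihedral φ), its neighbor by (template bond and
angle, dihedral ψ), and the acceptor template is rigidly mapped onto
the three anchor points (three-point Kabsch; the proper rotation is
unique, preserving chirality). The acceptor's linkage hydroxyl and the
donor's anomeric hydrogen are removed; the donor's O1 becomes the
glycosidic oxygen. Requested torsions are therefore reproduced exactly
(to 1e-7°), which the generator exploits to re-pose chains each frame.
The default build places every linkage at (φ, ψ) = (−70°, −110°), a
syn-region start; HA/Ch decamers alternate β1-3/β1-4 linkages with the
reducing end left free.

## Box assembly

The tube axis runs along z through the box center; the z edge equals
the periodic length. Glycan copies are placed at uniformly random
rigid poses, rejected until no interatomic distance between distinct
molecules falls below 2 Å (minimum image), with a bounded retry count.
Salt follows round(c·N_A·V) Na⁺/Cl⁻ pairs for the requested ionic
strength (0.15 mol/L by default), plus counterions against the total
solute charge, making the box exactly neutral. Explicit water is never
placed: no analysis in this package uses water coordinates, so the
~4200–4500 waters of the original systems are metadata only. The
monosaccharide copy number per box defaults to 20 (the original count
is visible only in snapshots; 20 is a realistic monolayer load for a
6 nm tube).

## Synthetic trajectories

The generator emulates the statistical structure the analyses assume,
at the study's nominal schedule (frames 200 ps apart; 600 ns ↔ 3000
frames):

* **Kinetics** — each molecule is an independent two-state Markov
  chain (adsorbed/desorbed) with per-frame switching probabilities;
  defaults (p_detach = 0.01, p_attach = 0.2) give ~95% adsorbed
  occupancy with occasional transient detachments, the regime described
  for the monosaccharide systems.
* **Geometry** — adsorbed molecules sit at radial distance ~N(tube
  radius + 4 Å, 0.5 Å) with the scripted ring face turned toward the
  axis plus Gaussian tilt noise (default sd 20°); a monolayer clamp
  keeps every atom inside 15 Å unless disabled. Desorbed excursions are
  placed beyond 20 Å. Chains align their long axis with the tube.
* **Internal motion** — rigid bodies plus per-atom Gaussian jitter
  (default 0.3 Å); glycosidic torsions, when a surface is supplied, are
  redrawn each frame from a wrapped-normal basin mixture (exact
  mixture sampling) and imposed through the chain builder.

What this does *not* model: physical dynamics (no forces, no
correlation between successive poses beyond the state chain), solvent,
energy-consistent sampling, or internal ring flexibility. Passing
tests therefore establish the correctness of the analysis machinery on
data with known truth — not the physical conclusions about real
HA/Ch–fCNT systems, which require the original force fields and
hundreds of nanoseconds of explicit-solvent MD.

## Analyses: definitions and numerical choices

* **Radial profiles** — histogram of √((x−x₀)²+(y−y₀)²) over all
  selected atoms and frames, minimum image in x,y; raw counts (not
  volume-normalized), bin width 0.5 Å. Layer metrics report cumulative
  fractions at 15 and 20 Å and the 99% decay radius.
* **Orientation** — side-A and side-B profiles are smoothed with a
  3-bin moving average; the first local maximum above 5% of the global
  maximum is each face's peak; the face with the smaller peak radius is
  the adsorbed side, indeterminate below 1 Å separation. The statistic
  uses exactly the printed atom pairs (H1,H5 vs H2,H4/O4); H3 can be
  added to side A for geometric work but never enters the reported
  classification.
* **Detachment** — molecule position is the ring-atom center of
  geometry; an event is r > 20 Å (strict) for ≥ 3 consecutive frames.
* **Energetics** — plain truncation at 1.2 nm for both LJ and Coulomb
  under minimum image; Lorentz–Berthelot mixing (arithmetic σ,
  geometric ε), f = 138.935458 kJ·mol⁻¹·nm·e⁻². No reciprocal-space
  term: absolute Coulomb sums deliberately differ from mesh-Ewald
  engine output by the truncated tail. Means are per single molecule;
  the ± is the standard error of 5 block means over the frame series
  (a conventional choice — the original tables never define their
  bars). Pairs closer than 0.5 Å are flagged but still summed.
* **Hydrogen bonds** — strict d(A,D) < 3.0 Å and ∠(D→A, D→H) < 20°,
  the angle taken at the donor heavy atom (the standard small-angle
  form of the criterion); the 3.0–3.5 Å weak-bond band is never
  counted. Role split: carboxylate O acceptors only; acid O acceptors
  plus one O–H donor per motif; sugar hydroxyls/amide both. Only
  tube–carbohydrate pairs are counted.
* **Free-energy maps** — periodic 2D histogram of (φ, ψ) in 5° bins;
  F = −k_BT·ln(P/P_max) at T = 310 K (k_B = 0.0083144621 kJ/mol/K), so
  min F = 0; empty bins are capped at max finite F + k_BT. Basin depths
  are read as the window minimum around a basin center
  (`basin_minimum`), because a center on a bin edge splits its mass
  over four bins. Conformer windows: syn = ψ within ±60° of the built
  canonical value (−110°), anti = within ±60° of its 180° rotation,
  quasi-trans = ψ ∈ 180° ± 30° reported separately (the source names
  the classes but prints no windows; these are documented defaults and
  configurable).
* **RMSF** — √⟨|r_i − ⟨r_i⟩|²⟩; by default each frame is first
  least-squares superposed onto the selection's mean structure
  (removing diffusion and tumbling), with a no-fit mode for
  lab-frame fluctuations.
* **Ring pucker** — Cremer–Pople (Q, θ, φ_p) on O5,C1..C5; chair for
  θ < 45° (⁴C₁) or > 135° (¹C₄), otherwise boat when φ_p lies within
  15° of a multiple of 60°, else skew-boat; undefined below Q = 0.1 Å.

## Problem sizes used in the shipped checks

The test suite and acceptance script run at desk scale by design:
(10,0)×4-cell tubes and 3–6 molecule boxes for trajectory work, the
full 952-atom production tube for structural bookkeeping, 50,000
torsion samples for the Boltzmann-inversion check, 10,000 frames for
the RMSF closed form, 100 × 2,000-frame trajectories for the
orientation-recovery rate, 500-atom frames for the energy oracle and
1,000 random 200-atom frames for the hydrogen-bond oracle. These sizes
give comfortable statistical margins for every asserted tolerance.

## Known limitations

* Motif and glycan partial charges shipped here are synthetic
  placeholders for exercising bookkeeping; quantitative energetics
  requires importing real force-field parameters (a documented
  extension point — the parameter table format is deliberately
  trivial).
* Absolute pair-energy and hydrogen-bond values from synthetic
  trajectories are not comparable to production-MD tables; only the
  machinery is validated.
* The tube builder covers zigzag single-walled tubes with the carboxyl
  motif only (no armchair/chiral indices, multi-wall tubes, or other
  defects); glycans cover the β-anomer, unsulfated residues of HA/Ch.
* PDB atom names are limited to 4 characters, so motif atoms share
  names across motifs (CG/OGA/OGB/HG/HOG) and are disambiguated by
  order and motif id.
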