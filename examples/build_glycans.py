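"""Build glycan models: monosaccharides and HA/Ch decamers.

GlcNAc and GalNAc are C4 epimers: the axial O4 of GalNAc replaces H4 on
ring face B, which is exactly the atom pair the orientation analysis
tracks.  Hyaluronan (HA) repeats GlcA-beta1,3-GlcNAc; chondroitin (Ch)
swaps GlcNAc for GalNAc.  Glycosidic torsions are set exactly at build
time (syn basin, phi = -70, psi = -110).
"""
from glycotube import glycan
from glycotube.conformation import ring_pucker

for code in ("GlcA", "GlcNAc", "GalNAc"):
    chain = glycan.build_monosaccharide(code)
    res = chain.residues[0]
    pucker = ring_pucker(res.positions, [res.index(n) for n in glycan.RING_ORDER])
    print(f"{code}: {res.n_atoms} atoms, formal charge {res.formal_charge:+d} e, "
          f"ring {pucker.shape} (theta {pucker.theta:.1f} deg)")
    print(f"  side A = {glycan.face_atoms(code, 'A')}, "
          f"side B = {glycan.face_atoms(code, 'B')}")

for kind in ("HA", "Ch"):
    chain = glycan.build_decamer(kind)
    torsions = chain.measure_torsions()
    print(f"{kind} decamer: {len(chain.residues)} residues, "
          f"{len(chain.linkages)} linkages "
          f"({'/'.join(lk.kind for lk in chain.linkages[:2])} alternating), "
          f"formal charge {chain.formal_charge} e")
    print(f"  built torsions: phi {torsions[0, 0]:.1f}, psi {torsions[0, 1]:.1f} "
          "(same for every linkage)")
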