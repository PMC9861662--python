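"""Assemble a periodic simulation box: tube + glycans + 0.15 mol/L salt.

Ion counts follow round(c * N_A * V) per species plus enough Na+ to
neutralize the tube's -20 e and the GlcA charges, so the box is exactly
neutral.  The fifteen compositions of the study are enumerated by the
manifest.
"""
from glycotube import assemble as asm
from glycotube import fcnt, glycan

tube = fcnt.functionalized_tube(seed=11)
box = asm.BoxSpec.for_tube(tube)  # 5.5 x 5.5 nm cross-section, z = tube period
system = asm.assemble(tube, [glycan.build_monosaccharide("GlcA")], copies=5,
                      box=box, ions=asm.IonSpec(0.15), seed=12)

print(f"box {box.lx / 10:.2f} x {box.ly / 10:.2f} x {box.lz / 10:.3f} nm "
      f"({box.volume_nm3:.1f} nm^3)")
print(f"{system.n_atoms} solute atoms; Na+ {system.metadata['n_na']}, "
      f"Cl- {system.metadata['n_cl']} "
      f"({system.metadata['salt_pairs']} salt pairs at 0.15 mol/L)")
print(f"net charge: {system.net_charge:+.2e} e (neutral by construction)")

print("\nstudy manifest:")
for desc in asm.study_manifest():
    print(f"  {desc.label:<18s} copies={desc.n_copies}")
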