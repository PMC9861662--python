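"""Count strict hydrogen bonds between tube carboxyls and sugars.

The criterion is deliberately strict: acceptor-donor distance < 3 A and
acceptor-donor-H angle < 20 degrees (weak bonds out to 3.5 A are never
counted).  A carboxylate can only accept; a carboxylic acid also donates
through its O-H, which is why the donor column exists only for the
protonated tube.
"""
from glycotube import assemble as asm
from glycotube import fcnt, glycan, hbond
from glycotube.trajectory import AdsorptionScenario, generate

for kind, label in (("carboxylate", "CNT-COO-"), ("carboxylic_acid", "CNT-COOH")):
    tube = fcnt.functionalized_tube(chirality_n=10, cells=4,
                                    group_kind=kind, seed=5)
    system = asm.assemble(tube, [glycan.build_monosaccharide("GlcNAc")], 6,
                          asm.BoxSpec.for_tube(tube, 50.0, 50.0),
                          asm.IonSpec(0.0), seed=6)
    scenario = AdsorptionScenario(p_detach=0.0, p_attach=1.0, facing="B",
                                  r_ads_mean=tube.radius() + 3.0,
                                  initial_state="adsorbed")
    traj, _ = generate(system, scenario, n_frames=150, seed=7)
    roles = hbond.assign_roles(traj, kind)
    counts = hbond.mean_hbonds(traj, roles)
    print(f"{label}: {len(roles.carboxyl_acceptors)} carboxyl O acceptors, "
          f"{len(roles.carboxyl_donors)} O-H donors, "
          f"{len(roles.sugar_donors)} sugar donors")
    print(f"  mean HB (carboxyl as acceptor): "
          f"{counts.mean_carboxyl_acceptor:.3f} per frame")
    print(f"  mean HB (carboxyl as donor):    "
          f"{counts.mean_carboxyl_donor:.3f} per frame "
          "(zero by construction for the carboxylate)")
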