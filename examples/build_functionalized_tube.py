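"""Build the study's carboxylated nanotube and inspect its bookkeeping.

A (17,0) zigzag tube of 14 translational cells (952 carbons, 5.95 nm
period) is grafted with carboxylate groups on 2% of its carbons; the
residual motif charge is spread over the wall so the tube carries exactly
-1 e per group.
"""
import pandas as pd

from glycotube import fcnt
from glycotube.io import write_coordinates, write_topology

spec = fcnt.LatticeSpec(chirality_n=17, cells=14)
print(f"unfunctionalized tube: {spec.n_atoms} carbons, "
      f"period {spec.periodic_length / 10:.4f} nm, radius {spec.radius:.2f} A")

tube = fcnt.functionalized_tube(seed=2024)
print(f"grafted {tube.n_groups} carboxylate motifs "
      f"(ceil of 2% of {spec.n_atoms} carbons)")
print(f"net charge after redistribution: {tube.net_charge:+.12f} e "
      "(exactly -1 e per carboxylate group)")

cluster = fcnt.build_capped_cluster(10, 7, "carboxylate")
acid = fcnt.build_capped_cluster(10, 7, "carboxylic_acid")
print(f"(10,0) QM reference clusters: {cluster.n_atoms} atoms (COO-), "
      f"{acid.n_atoms} atoms (COOH)")

atoms = pd.DataFrame(dict(name=tube.names, element=tube.elements,
                          resname="CNT", resid=1, molid=-1,
                          charge=tube.charges))
write_coordinates("fcnt.pdb", atoms, tube.positions,
                  [60.0, 60.0, tube.periodic_length])
write_topology("fcnt.top", fcnt.generate_bonded_terms(tube))
print("wrote fcnt.pdb and fcnt.top (bonds/angles/dihedrals with periodic flags)")
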