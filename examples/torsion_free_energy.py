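"""Glycosidic torsion statistics: free-energy maps, conformers, RMSF, pucker.

A two-basin wrapped-normal surface (80% syn / 20% anti) is sampled and
Boltzmann-inverted: the recovered basin free-energy difference should be
-kT ln(0.25) = 3.57 kJ/mol at 310 K.  RMSF of pure isotropic jitter has
the closed form sqrt(3) * sd.
"""
import math

import numpy as np

from glycotube import conformation as conf
from glycotube import glycan
from glycotube.trajectory import TorsionSurfaceSpec
from glycotube.units import KB_KJ_MOL_K

spec = TorsionSurfaceSpec.two_basin(weight_syn=0.8, sd=10.0)
samples = spec.sample(np.random.default_rng(1), 50000)
fm = conf.free_energy_map(samples)
delta = fm.basin_minimum(-70.0, 70.0) - fm.basin_minimum(-70.0, -110.0)
print(f"two-basin surface: recovered dF = {delta:.2f} kJ/mol "
      f"(exact -kT ln 0.25 = {-KB_KJ_MOL_K * 310 * math.log(0.25):.2f})")

occ = conf.conformer_occupancy(samples)
print(f"conformer occupancies: syn {occ['syn']:.3f}, anti {occ['anti']:.3f}, "
      f"quasi-trans {occ['quasi_trans']:.3f}")

# ring pucker of a freshly built chondroitin decamer
chain = glycan.build_decamer("Ch")
shapes = [conf.ring_pucker(chain.positions, chain.ring_atom_indices(i)).shape
          for i in range(10)]
print(f"Ch decamer ring shapes: {set(shapes)} (built in the 4C1 chair)")

# RMSF closed form under isotropic jitter
import pandas as pd

from glycotube.trajectory import Trajectory

rng = np.random.default_rng(2)
sd, n_frames = 0.5, 5000
base = rng.uniform(0, 20, size=(4, 3))
frames = base[None] + rng.normal(0, sd, size=(n_frames, 4, 3))
atoms = pd.DataFrame(dict(name=["X"] * 4, element=["C"] * 4,
                          resname=["MOL"] * 4, resid=[1] * 4, molid=[0] * 4,
                          molclass=["glycan"] * 4, charge=[0.0] * 4))
traj = Trajectory(positions=frames, box=np.array([50.0, 50.0, 50.0]),
                  times=np.arange(n_frames, dtype=float), atoms=atoms)
fl = conf.rmsf(traj, np.arange(4), fit=False)
print(f"RMSF under jitter sd {sd} A: {fl.mean():.3f} A "
      f"(closed form sqrt(3)*{sd} = {math.sqrt(3) * sd:.3f})")
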