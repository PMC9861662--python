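"""Shared fixtures: small tubes, glycan templates, assembled systems."""
import warnings

import numpy as np
import pytest

from glycotube import assemble as asm
from glycotube import fcnt, glycan
from glycotube.trajectory import AdsorptionScenario, generate

warnings.filterwarnings("ignore", module="MDAnalysis")


@pytest.fixture(scope="session")
def small_tube():
    """Periodic (10,0) tube, 4 cells, functionalized with 4 carboxylates."""
    return fcnt.functionalized_tube(chirality_n=10, cells=4, seed=11)


@pytest.fixture(scope="session")
def study_tube():
    """The production tube: (17,0), 14 cells, 20 carboxylate groups."""
    return fcnt.functionalized_tube(seed=7)


@pytest.fixture(scope="session")
def glcnac():
    return glycan.build_monosaccharide("GlcNAc")


@pytest.fixture(scope="session")
def ha_decamer():
    return glycan.build_decamer("HA")


@pytest.fixture(scope="session")
def small_system(small_tube, glcnac):
    box = asm.BoxSpec.for_tube(small_tube, 50.0, 50.0)
    return asm.assemble(small_tube, [glcnac], 5, box, asm.IonSpec(0.15), seed=5)


@pytest.fixture
def monolayer_trajectory(small_system):
    """Always-adsorbed side-A monolayer, 60 frames."""
    scenario = AdsorptionScenario(p_detach=0.0, p_attach=1.0, facing="A",
                                  initial_state="adsorbed")
    traj, truth = generate(small_system, scenario, n_frames=60, seed=21)
    return traj, truth


def make_static_trajectory(positions, box, n_frames, atoms=None):
    """Trajectory with every frame identical to ``positions``."""
    import pandas as pd

    from glycotube.trajectory import Trajectory

    positions = np.asarray(positions, dtype=float)
    if atoms is None:
        n = len(positions)
        atoms = pd.DataFrame(
            dict(name=["X"] * n, element=["C"] * n, resname=["MOL"] * n,
                 resid=[1] * n, molid=[0] * n, molclass=["glycan"] * n,
                 charge=[0.0] * n)
        )
    return Trajectory(
        positions=np.tile(positions[None], (n_frames, 1, 1)),
        box=np.asarray(box, dtype=float),
        times=np.arange(n_frames, dtype=float),
        atoms=atoms,
    )
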