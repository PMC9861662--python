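"""Pair energies: closed forms, oracle agreement, scaling properties."""
import math

import numpy as np
import pytest

from glycotube.energetics import (
    AtomTypeParameters,
    ForceFieldParameters,
    PairEnergy,
    ForceFieldParameters as FFP,
    mean_pair_energy,
    pair_energy,
)
from glycotube.units import COULOMB_KJ_MOL_NM_E2

BOX = np.array([100.0, 100.0, 100.0])


def _single_pair(r_angstrom, sig_nm=0.0, eps=0.0, qa=0.0, qb=0.0, box=BOX,
                 params=None):
    pos_a = np.array([[0.0, 0.0, 0.0]])
    pos_b = np.array([[r_angstrom, 0.0, 0.0]])
    one = np.array([sig_nm]), np.array([eps]), np.array([qa])
    two = np.array([sig_nm]), np.array([eps]), np.array([qb])
    return pair_energy(pos_a, pos_b, *one, *two, box, params)


def brute_force_energy(pos_a, pos_b, sig_a, eps_a, q_a, sig_b, eps_b, q_b,
                       box, cutoff_nm=1.2, f=COULOMB_KJ_MOL_NM_E2):
    """Independent O(N^2) oracle: explicit python double loop."""
    e_lj = 0.0
    e_c = 0.0
    for i in range(len(pos_a)):
        for j in range(len(pos_b)):
            dx = [pos_a[i][k] - pos_b[j][k] for k in range(3)]
            for k in range(3):
                if box[k] > 0:
                    dx[k] -= box[k] * round(dx[k] / box[k])
            r = math.sqrt(sum(d * d for d in dx)) / 10.0  # nm
            if r > cutoff_nm or r == 0.0:
                continue
            sig = 0.5 * (sig_a[i] + sig_b[j])
            eps = math.sqrt(eps_a[i] * eps_b[j])
            sr6 = (sig / r) ** 6
            e_lj += 4.0 * eps * (sr6 * sr6 - sr6)
            e_c += f * q_a[i] * q_b[j] / r
    return e_lj, e_c


def test_coulomb_unit_charges_at_one_nm():
    e = _single_pair(10.0, qa=1.0, qb=-1.0)
    assert e.coulomb == pytest.approx(-COULOMB_KJ_MOL_NM_E2, abs=1e-10)
    assert e.lj == 0.0


def test_lj_zero_at_sigma():
    e = _single_pair(3.0, sig_nm=0.3, eps=1.0)
    assert e.lj == pytest.approx(0.0, abs=1e-10)


def test_lj_minimum_is_minus_epsilon_nacl():
    """Na+/Cl- with Lorentz-Berthelot mixing: E(2^(1/6) sigma) = -sqrt(eps_Na eps_Cl)."""
    sig_na, eps_na = 0.244, 0.366
    sig_cl, eps_cl = 0.448, 0.149
    sig_ij = 0.5 * (sig_na + sig_cl)
    r = 2 ** (1 / 6) * sig_ij * 10.0  # angstrom
    pos_a = np.array([[0.0, 0.0, 0.0]])
    pos_b = np.array([[r, 0.0, 0.0]])
    e = pair_energy(pos_a, pos_b,
                    np.array([sig_na]), np.array([eps_na]), np.array([0.0]),
                    np.array([sig_cl]), np.array([eps_cl]), np.array([0.0]),
                    BOX)
    assert e.lj == pytest.approx(-math.sqrt(eps_na * eps_cl), abs=1e-10)


def test_beyond_cutoff_contributes_zero():
    e = _single_pair(12.1, sig_nm=0.4, eps=1.0, qa=1.0, qb=1.0)
    assert e.lj == 0.0
    assert e.coulomb == 0.0


def test_overlap_flagged_but_energy_returned():
    e = _single_pair(0.3, qa=1.0, qb=1.0)
    assert e.n_overlaps == 1
    assert e.coulomb > 0


def test_empty_selection_rejected():
    with pytest.raises(ValueError):
        pair_energy(np.empty((0, 3)), np.ones((1, 3)),
                    np.array([]), np.array([]), np.array([]),
                    np.array([0.3]), np.array([1.0]), np.array([0.0]), BOX)


def _random_groups(rng, n_a, n_b, box_edge=30.0):
    # jittered grid keeps every pair > 3 angstrom apart (physical frames;
    # hard-core overlaps would amplify the 1/r^12 term past float precision)
    n = n_a + n_b
    side = int(np.ceil(n ** (1 / 3)))
    spacing = box_edge / side
    cells = np.array([[i, j, k] for i in range(side)
                      for j in range(side) for k in range(side)])[:n]
    pts = (cells + 0.5) * spacing + rng.uniform(-1.0, 1.0, size=(n, 3))
    order = rng.permutation(n)
    pos_a = pts[order[:n_a]]
    pos_b = pts[order[n_a:]]
    sig_a = rng.uniform(0.2, 0.45, n_a)
    sig_b = rng.uniform(0.2, 0.45, n_b)
    eps_a = rng.uniform(0.05, 0.8, n_a)
    eps_b = rng.uniform(0.05, 0.8, n_b)
    q_a = rng.uniform(-0.8, 0.8, n_a)
    q_b = rng.uniform(-0.8, 0.8, n_b)
    return pos_a, pos_b, sig_a, eps_a, q_a, sig_b, eps_b, q_b


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    args = _random_groups(rng, 40, 35)
    box = np.array([30.0, 30.0, 30.0])
    e = pair_energy(*args, box)
    lj_ref, c_ref = brute_force_energy(*args, box)
    assert e.lj == pytest.approx(lj_ref, abs=1e-8)
    assert e.coulomb == pytest.approx(c_ref, abs=1e-8)


def test_symmetry_under_group_exchange():
    rng = np.random.default_rng(5)
    pos_a, pos_b, sa, ea, qa, sb, eb, qb = _random_groups(rng, 20, 25)
    box = np.array([30.0, 30.0, 30.0])
    e_ab = pair_energy(pos_a, pos_b, sa, ea, qa, sb, eb, qb, box)
    e_ba = pair_energy(pos_b, pos_a, sb, eb, qb, sa, ea, qa, box)
    assert e_ab.lj == pytest.approx(e_ba.lj, abs=1e-10)
    assert e_ab.coulomb == pytest.approx(e_ba.coulomb, abs=1e-10)


def test_translation_invariance_lattice_shift():
    rng = np.random.default_rng(6)
    pos_a, pos_b, sa, ea, qa, sb, eb, qb = _random_groups(rng, 15, 15)
    box = np.array([30.0, 30.0, 30.0])
    e0 = pair_energy(pos_a, pos_b, sa, ea, qa, sb, eb, qb, box)
    shift = np.array([30.0, -60.0, 90.0]) + np.array([1.7, -4.2, 0.9])
    e1 = pair_energy(pos_a + shift, pos_b + shift, sa, ea, qa, sb, eb, qb, box)
    assert e1.lj == pytest.approx(e0.lj, abs=1e-10)
    assert e1.coulomb == pytest.approx(e0.coulomb, abs=1e-10)


def test_coulomb_quadratic_in_charge():
    rng = np.random.default_rng(7)
    pos_a, pos_b, sa, ea, qa, sb, eb, qb = _random_groups(rng, 10, 10)
    box = np.array([30.0, 30.0, 30.0])
    e1 = pair_energy(pos_a, pos_b, sa, ea, qa, sb, eb, qb, box)
    e2 = pair_energy(pos_a, pos_b, sa, ea, 2 * qa, sb, eb, 2 * qb, box)
    assert e2.coulomb == pytest.approx(4 * e1.coulomb, rel=1e-12)
    assert e2.lj == pytest.approx(e1.lj, rel=1e-12)


def test_total_is_sum_of_parts():
    e = PairEnergy(lj=-1.25, coulomb=0.75)
    assert e.total == -0.5


class TestMeanPairEnergy:
    def test_constant_configuration_zero_uncertainty(self, small_system):
        from conftest import make_static_trajectory

        rng = np.random.default_rng(0)
        pos = np.vstack([rng.uniform(0, 20, (4, 3)), rng.uniform(0, 20, (4, 3))])
        import pandas as pd

        atoms = pd.DataFrame(
            dict(name=["X"] * 8, element=["C"] * 8, resname=["MOL"] * 8,
                 resid=[1] * 8, molid=[0] * 4 + [1] * 4,
                 molclass=["fcnt"] * 4 + ["glycan"] * 4, charge=[0.1] * 8)
        )
        traj = make_static_trajectory(pos, [40.0, 40.0, 40.0], 10, atoms)
        params = ForceFieldParameters(
            types={"X": AtomTypeParameters(0.3, 0.4, 0.1)}
        )
        rec = mean_pair_energy(
            traj, np.arange(4), {1: np.arange(4, 8)}, ["X"] * 8, params
        )
        single = pair_energy(
            pos[:4], pos[4:],
            *(np.full(4, v) for v in (0.3, 0.4, 0.1)),
            *(np.full(4, v) for v in (0.3, 0.4, 0.1)),
            traj.box, params,
        )
        assert rec.mean_lj == pytest.approx(single.lj)
        assert rec.mean_coulomb == pytest.approx(single.coulomb)
        assert rec.err_lj == 0.0
        assert rec.err_coulomb == 0.0

    def test_per_molecule_average_of_two_molecules(self):
        """One molecule interacting (energy E), one far away (0): the
        reported per-single-molecule mean is E/2."""
        from conftest import make_static_trajectory
        import pandas as pd

        pos = np.array([[0.0, 0.0, 0.0],
                        [8.0, 0.0, 0.0],
                        [0.0, 40.0, 0.0]])
        atoms = pd.DataFrame(
            dict(name=["X"] * 3, element=["C"] * 3, resname=["MOL"] * 3,
                 resid=[1] * 3, molid=[-1, 0, 1],
                 molclass=["fcnt", "glycan", "glycan"], charge=[1.0, -1.0, -1.0])
        )
        traj = make_static_trajectory(pos, [100.0, 100.0, 100.0], 6, atoms)
        params = ForceFieldParameters(types={"X": AtomTypeParameters(0.0, 0.0, 1.0)})
        # give the molecules their charges through per-atom type override
        params.types["XP"] = AtomTypeParameters(0.0, 0.0, 1.0)
        params.types["XN"] = AtomTypeParameters(0.0, 0.0, -1.0)
        rec = mean_pair_energy(
            traj, np.array([0]), {0: np.array([1]), 1: np.array([2])},
            ["XP", "XN", "XN"], params,
        )
        e_single = -COULOMB_KJ_MOL_NM_E2 / 0.8
        assert rec.mean_coulomb == pytest.approx(e_single / 2.0, abs=1e-9)

    def test_requires_two_frames(self, small_system):
        from conftest import make_static_trajectory

        traj = make_static_trajectory(np.zeros((2, 3)), [10, 10, 10], 1)
        params = ForceFieldParameters(types={"X": AtomTypeParameters(0.3, 0.1, 0.0)})
        with pytest.raises(ValueError):
            mean_pair_energy(traj, np.array([0]), {0: np.array([1])},
                             ["X", "X"], params)


def test_parameter_file_round_trip(tmp_path):
    ff = FFP.with_ions()
    ff.types["CT"] = AtomTypeParameters(0.34, 0.457, -0.1)
    path = tmp_path / "params.dat"
    ff.dump(path)
    back = FFP.load(path)
    assert back.types["NA"].sigma_nm == pytest.approx(0.244)
    assert back.types["CT"].charge == pytest.approx(-0.1)


def test_malformed_parameter_file(tmp_path):
    path = tmp_path / "bad.dat"
    path.write_text("CT 0.3 0.4\n")
    with pytest.raises(ValueError, match="bad.dat:1"):
        FFP.load(path)
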