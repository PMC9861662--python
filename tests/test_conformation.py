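"""Torsions, Boltzmann inversion, conformer windows, RMSF, ring pucker."""
import math

import numpy as np
import pytest

from conftest import make_static_trajectory
from glycotube import conformation as conf
from glycotube import glycan
from glycotube.geometry import rotation_about_axis
from glycotube.trajectory import TorsionSurfaceSpec, Trajectory
from glycotube.units import KB_KJ_MOL_K


class TestTorsion:
    def test_planar_cis_is_zero(self):
        pos = np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]], dtype=float)
        assert conf.torsion(pos, (0, 1, 2, 3)) == pytest.approx(0.0, abs=1e-10)

    def test_planar_trans_is_180(self):
        pos = np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]], dtype=float)
        assert conf.torsion(pos, (0, 1, 2, 3)) == pytest.approx(180.0)

    def test_mirror_flips_sign(self):
        rng = np.random.default_rng(1)
        pos = rng.normal(size=(4, 3))
        t = conf.torsion(pos, (0, 1, 2, 3))
        mirrored = pos * np.array([1.0, 1.0, -1.0])
        assert conf.torsion(mirrored, (0, 1, 2, 3)) == pytest.approx(-t)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(2)
        pos = rng.normal(size=(4, 3))
        t = conf.torsion(pos, (0, 1, 2, 3))
        rot = rotation_about_axis([0.3, -1.0, 0.7], 77.0)
        moved = pos @ rot.T + np.array([5.0, -3.0, 2.0])
        assert conf.torsion(moved, (0, 1, 2, 3)) == pytest.approx(t, abs=1e-8)

    def test_collinear_rejected(self):
        pos = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]], dtype=float)
        with pytest.raises(ValueError):
            conf.torsion(pos, (0, 1, 2, 3))

    def test_distinct_atoms_required(self):
        with pytest.raises(ValueError):
            conf.torsion(np.zeros((4, 3)), (0, 1, 1, 3))


class TestFreeEnergyMap:
    def test_single_bin_is_zero_everywhere_else_capped(self):
        samples = np.tile([-70.0, -110.0], (100, 1))
        fm = conf.free_energy_map(samples)
        assert fm.value_at(-70.0, -110.0) == 0.0
        cap = np.nanmax(fm.free_energy)
        assert fm.value_at(100.0, 100.0) == pytest.approx(cap)
        assert np.all(fm.free_energy >= 0.0)

    def test_two_basin_free_energy_difference(self):
        """80/20 occupancy: dF = -kT ln(0.25) ~ 3.57 kJ/mol at 310 K."""
        spec = TorsionSurfaceSpec.two_basin(weight_syn=0.8, sd=10.0)
        rng = np.random.default_rng(11)
        samples = spec.sample(rng, 50000)
        fm = conf.free_energy_map(samples)
        f_syn = fm.basin_minimum(-70.0, -110.0)
        f_alt = fm.basin_minimum(-70.0, 70.0)
        expected = -KB_KJ_MOL_K * 310.0 * math.log(0.25)
        assert expected == pytest.approx(3.57, abs=0.01)
        assert (f_alt - f_syn) == pytest.approx(expected, abs=0.3)

    def test_uniform_samples_give_flat_map(self):
        rng = np.random.default_rng(3)
        n, bins = 400000, 72 * 72
        samples = rng.uniform(-180, 180, size=(n, 2))
        fm = conf.free_energy_map(samples)
        # multinomial noise: dF ~ kT * sigma(P)/P per bin; the max over
        # ~5e3 bins reaches ~4.5 sigma on both tails of the log ratio
        bound = fm.kt * 9.0 / math.sqrt(n / bins)
        occupied = fm.probability > 0
        assert fm.free_energy[occupied].max() < bound

    def test_round_trip_recovers_histogram(self):
        rng = np.random.default_rng(4)
        samples = rng.normal([-70, -110], 25.0, size=(5000, 2))
        fm = conf.free_energy_map(samples)
        occupied = fm.probability > 0
        back = np.exp(-fm.free_energy / fm.kt) * fm.probability.max()
        assert np.allclose(back[occupied], fm.probability[occupied], rtol=1e-10)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            conf.free_energy_map(np.empty((0, 2)))


class TestConformerOccupancy:
    def test_scripted_half_half(self):
        spec = TorsionSurfaceSpec.two_basin(weight_syn=0.5, sd=10.0)
        rng = np.random.default_rng(5)
        samples = spec.sample(rng, 20000)
        occ = conf.conformer_occupancy(samples)
        assert occ["syn"] == pytest.approx(0.5, abs=0.02)
        assert occ["anti"] == pytest.approx(0.5, abs=0.02)

    def test_all_syn(self):
        samples = np.tile([-70.0, -110.0], (50, 1))
        occ = conf.conformer_occupancy(samples)
        assert occ["syn"] == 1.0
        assert occ["anti"] == 0.0

    def test_empty_class_is_zero(self):
        occ = conf.conformer_occupancy(np.empty((0, 2)))
        assert occ == {"syn": 0.0, "anti": 0.0, "quasi_trans": 0.0}

    def test_quasi_trans_window(self):
        samples = np.column_stack([np.zeros(10), np.full(10, 175.0)])
        occ = conf.conformer_occupancy(samples)
        assert occ["quasi_trans"] == 1.0

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError):
            conf.conformer_occupancy(
                np.zeros((5, 2)),
                conf.ConformerWindows(syn_halfwidth=120.0, anti_halfwidth=120.0),
            )


class TestRmsf:
    def test_static_coordinates_give_zero(self):
        traj = make_static_trajectory(np.random.default_rng(0).normal(size=(5, 3)),
                                      [50, 50, 50], 10)
        assert np.allclose(conf.rmsf(traj, np.arange(5), fit=False), 0.0)

    def test_isotropic_jitter_converges_to_closed_form(self):
        """Gaussian jitter sd 0.5 per axis: RMSF -> sqrt(3)*0.5."""
        rng = np.random.default_rng(6)
        n_frames, n_atoms, sd = 4000, 8, 0.5
        base = rng.uniform(0, 20, size=(n_atoms, 3))
        frames = base[None] + rng.normal(0, sd, size=(n_frames, n_atoms, 3))
        traj = make_static_trajectory(base, [50, 50, 50], 1)
        traj = Trajectory(positions=frames, box=traj.box,
                          times=np.arange(n_frames, dtype=float), atoms=traj.atoms)
        fl = conf.rmsf(traj, np.arange(n_atoms), fit=False)
        expected = math.sqrt(3) * sd
        se = sd / math.sqrt(2 * n_frames)
        assert abs(fl.mean() - expected) < 3 * se

    def test_translation_invariance_without_fit(self):
        rng = np.random.default_rng(7)
        frames = rng.normal(size=(50, 4, 3))
        traj = make_static_trajectory(frames[0], [50, 50, 50], 1)
        t1 = Trajectory(positions=frames, box=traj.box,
                        times=np.arange(50, dtype=float), atoms=traj.atoms)
        t2 = Trajectory(positions=frames + np.array([3.0, -1.0, 8.0]),
                        box=traj.box, times=np.arange(50, dtype=float),
                        atoms=traj.atoms)
        assert np.allclose(conf.rmsf(t1, np.arange(4), fit=False),
                           conf.rmsf(t2, np.arange(4), fit=False))

    def test_fit_removes_rigid_tumbling(self):
        """Rigid-body rotation + jitter: after fitting, only jitter remains."""
        rng = np.random.default_rng(8)
        base = rng.uniform(-3, 3, size=(6, 3))
        sd = 0.2
        frames = np.empty((400, 6, 3))
        for f in range(400):
            rot = rotation_about_axis(rng.normal(size=3), rng.uniform(0, 360))
            frames[f] = base @ rot.T + rng.normal(0, sd, size=(6, 3))
        traj0 = make_static_trajectory(base, [50, 50, 50], 1)
        traj = Trajectory(positions=frames, box=traj0.box,
                          times=np.arange(400, dtype=float), atoms=traj0.atoms)
        fl = conf.rmsf(traj, np.arange(6), fit=True)
        nofit = conf.rmsf(traj, np.arange(6), fit=False)
        assert fl.mean() < 2.5 * math.sqrt(3) * sd  # near the jitter scale
        assert nofit.mean() > 2 * fl.mean()  # tumbling dominates unfitted

    def test_single_frame_rejected(self):
        traj = make_static_trajectory(np.zeros((3, 3)), [10, 10, 10], 1)
        with pytest.raises(ValueError):
            conf.rmsf(traj, np.arange(3))


class TestRingPucker:
    def _ring(self, z):
        return np.column_stack(
            [1.45 * np.cos(np.arange(6) * np.pi / 3),
             1.45 * np.sin(np.arange(6) * np.pi / 3), z]
        )

    def test_ideal_chair(self):
        ring = self._ring(0.25 * np.array([-1, 1, -1, 1, -1, 1.0]))
        p = conf.ring_pucker(ring, range(6))
        assert p.shape == "chair-4C1"
        assert p.theta < 5.0

    def test_inverted_chair(self):
        ring = self._ring(0.25 * np.array([1, -1, 1, -1, 1, -1.0]))
        p = conf.ring_pucker(ring, range(6))
        assert p.shape == "chair-1C4"
        assert p.theta > 175.0

    def test_ideal_boat(self):
        z = np.array([0.5, 0.0, 0.0, 0.5, 0.0, 0.0])
        p = conf.ring_pucker(self._ring(z), range(6))
        assert p.shape == "boat"
        assert abs(p.theta - 90.0) < 5.0
        assert min(p.phi_p % 60.0, 60.0 - p.phi_p % 60.0) <= 15.0

    def test_skew_boat(self):
        j = np.arange(6)
        z = 0.4 * np.cos(2 * np.pi * 2 * j / 6 - np.radians(30.0)) / math.sqrt(3)
        p = conf.ring_pucker(self._ring(z), range(6))
        assert p.shape == "skew-boat"

    def test_planar_ring_undefined(self):
        p = conf.ring_pucker(self._ring(np.zeros(6)), range(6))
        assert p.shape == "undefined"
        assert p.amplitude < 1e-10

    def test_wrong_atom_count_rejected(self):
        with pytest.raises(ValueError):
            conf.ring_pucker(np.zeros((6, 3)), range(5))

    def test_fresh_decamer_is_all_chair(self, ha_decamer):
        pos = ha_decamer.positions
        for ridx in range(10):
            assert conf.ring_pucker(pos, ha_decamer.ring_atom_indices(ridx)).shape \
                == "chair-4C1"
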