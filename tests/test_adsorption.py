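"""Radial profiles, layer metrics, orientation, detachment detection."""
import numpy as np
import pandas as pd
import pytest

from conftest import make_static_trajectory
from glycotube import adsorption as ads
from glycotube import assemble as asm
from glycotube import glycan
from glycotube.trajectory import AdsorptionScenario, Trajectory, generate

BOX = np.array([60.0, 60.0, 60.0])


def _traj_from_frames(frames, box=BOX, atoms=None):
    frames = np.asarray(frames, dtype=float)
    n = frames.shape[1]
    if atoms is None:
        atoms = pd.DataFrame(
            dict(name=["X"] * n, element=["C"] * n, resname=["MOL"] * n,
                 resid=[1] * n, molid=[0] * n, molclass=["glycan"] * n,
                 charge=[0.0] * n)
        )
    return Trajectory(positions=frames, box=box,
                      times=np.arange(len(frames), dtype=float), atoms=atoms)


def test_static_atom_counts_in_one_bin():
    pos = np.array([[40.0, 30.0, 10.0]])  # r = 10 from the box center (30, 30)
    traj = make_static_trajectory(pos, BOX, 100)
    prof = ads.radial_profile(traj, np.array([0]), bin_width=0.5)
    assert prof.total == 100
    target = (prof.edges[:-1] <= 10.0) & (prof.edges[1:] > 10.0)
    assert prof.counts[target][0] == 100
    assert prof.counts[~target].sum() == 0


def test_count_conservation(monolayer_trajectory):
    traj, _ = monolayer_trajectory
    sel = traj.indices(molclass="glycan")
    prof = ads.radial_profile(traj, sel)
    assert prof.total == len(sel) * traj.n_frames


def test_monolayer_has_zero_counts_beyond_15(monolayer_trajectory):
    traj, _ = monolayer_trajectory
    sel = traj.indices(molclass="glycan")
    prof = ads.radial_profile(traj, sel)
    beyond = prof.edges[:-1] >= 15.0
    assert prof.counts[beyond].sum() == 0
    assert ads.layer_metrics(prof).fraction_within_15 == 1.0


def test_profile_invariant_under_rotation(monolayer_trajectory):
    traj, _ = monolayer_trajectory
    sel = traj.indices(molclass="glycan")
    prof = ads.radial_profile(traj, sel)
    theta = np.radians(35.0)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    center = traj.axis_xy
    xy = traj.positions[..., :2] - center
    rotated = traj.positions.copy()
    rotated[..., :2] = xy @ rot.T + center
    traj2 = Trajectory(positions=rotated, box=traj.box, times=traj.times,
                       atoms=traj.atoms)
    prof2 = ads.radial_profile(traj2, sel)
    assert np.array_equal(prof.counts, prof2.counts)


def test_empty_selection_rejected(monolayer_trajectory):
    traj, _ = monolayer_trajectory
    with pytest.raises(ValueError):
        ads.radial_profile(traj, np.array([], dtype=int))


def test_layer_fractions_with_scripted_desorption():
    """90 frames at r = 10, 10 frames at r = 25: fraction(20) = 0.90."""
    center = BOX[:2] / 2
    frames = np.zeros((100, 1, 3))
    frames[:90, 0, :2] = center + [10.0, 0.0]
    frames[90:, 0, :2] = center + [25.0, 0.0]
    traj = _traj_from_frames(frames)
    prof = ads.radial_profile(traj, np.array([0]))
    lm = ads.layer_metrics(prof)
    assert lm.fraction_within_15 == pytest.approx(0.90)
    assert lm.fraction_within_20 == pytest.approx(0.90)
    assert lm.decay_radius >= 25.0


def test_layer_fraction_monotone_in_radius(monolayer_trajectory):
    traj, _ = monolayer_trajectory
    sel = traj.indices(molclass="glycan")
    prof = ads.radial_profile(traj, sel)
    radii = np.linspace(0, 30, 61)
    fracs = [prof.cumulative_fraction(r) for r in radii]
    assert np.all(np.diff(fracs) >= 0)


def test_decay_radius_tracks_last_occupied_bin():
    center = BOX[:2] / 2
    frames = np.zeros((10, 1, 3))
    frames[:, 0, :2] = center + [7.3, 0.0]
    traj = _traj_from_frames(frames)
    prof = ads.radial_profile(traj, np.array([0]), bin_width=0.5)
    lm = ads.layer_metrics(prof)
    assert lm.decay_radius == pytest.approx(7.5)


class TestOrientation:
    def _system(self, code="GlcNAc"):
        from glycotube import fcnt

        tube = fcnt.functionalized_tube(chirality_n=10, cells=4, seed=1)
        box = asm.BoxSpec.for_tube(tube, 50.0, 50.0)
        return asm.assemble(tube, [glycan.build_monosaccharide(code)], 4, box,
                            asm.IonSpec(0.0), seed=2)

    @pytest.mark.parametrize("facing,expected", [
        ("A", "A(H1-H5)"), ("B", "B(H2-H4/O4)"),
    ])
    def test_scripted_face_recovered(self, facing, expected):
        system = self._system()
        scenario = AdsorptionScenario(p_detach=0.0, p_attach=1.0, facing=facing,
                                      initial_state="adsorbed")
        traj, _ = generate(system, scenario, n_frames=300, seed=3)
        result = ads.orientation(traj, "GlcNAc")
        assert result.preferred == expected

    def test_galnac_uses_o4_side(self):
        system = self._system("GalNAc")
        scenario = AdsorptionScenario(p_detach=0.0, p_attach=1.0, facing="B",
                                      initial_state="adsorbed")
        traj, _ = generate(system, scenario, n_frames=300, seed=4)
        assert ads.orientation(traj, "GalNAc").preferred == "B(H2-H4/O4)"

    def test_isotropic_orientation_is_indeterminate(self):
        system = self._system()
        scenario = AdsorptionScenario(p_detach=0.0, p_attach=1.0, facing="iso",
                                      initial_state="adsorbed")
        traj, _ = generate(system, scenario, n_frames=2000, seed=5)
        assert ads.orientation(traj, "GlcNAc").preferred == "indeterminate"

    def test_missing_face_atoms_rejected(self, monolayer_trajectory):
        traj, _ = monolayer_trajectory
        with pytest.raises((ValueError, KeyError)):
            ads.orientation(traj, "GalNAc")  # system holds GlcNAc only


class TestDetachment:
    def _single_molecule_traj(self, radii):
        center = BOX[:2] / 2
        names = list(glycan.RING_ORDER)
        n = len(names)
        frames = np.zeros((len(radii), n, 3))
        for f, r in enumerate(radii):
            frames[f, :, 0] = center[0] + r
            frames[f, :, 1] = center[1]
            frames[f, :, 2] = np.arange(n) * 0.5  # small axial spread
        atoms = pd.DataFrame(
            dict(name=names, element=[x[0] for x in names],
                 resname=["NAG"] * n, resid=[1] * n, molid=[0] * n,
                 molclass=["glycan"] * n, charge=[0.0] * n)
        )
        return _traj_from_frames(frames, atoms=atoms)

    def test_attached_molecule_has_no_events(self):
        traj = self._single_molecule_traj([12.0] * 50)
        ev = ads.detachment_events(traj)
        assert ev.n_events == 0
        assert ev.beyond_fraction == 0.0

    def test_scripted_excursion_detected_once(self):
        radii = [12.0] * 20 + [25.0] * 10 + [12.0] * 20
        ev = ads.detachment_events(self._single_molecule_traj(radii))
        assert ev.events[0] == [(20, 29)]
        assert ev.beyond_fraction == pytest.approx(10 / 50)

    def test_short_excursion_below_min_frames_ignored(self):
        radii = [12.0] * 20 + [25.0] * 2 + [12.0] * 20
        ev = ads.detachment_events(self._single_molecule_traj(radii),
                                   min_frames=3)
        assert ev.n_events == 0

    def test_threshold_is_strict(self):
        radii = [20.0] * 10  # exactly at the threshold: not beyond
        ev = ads.detachment_events(self._single_molecule_traj(radii))
        assert ev.n_events == 0

    def test_trailing_excursion_closes_at_end(self):
        radii = [12.0] * 10 + [25.0] * 5
        ev = ads.detachment_events(self._single_molecule_traj(radii))
        assert ev.events[0] == [(10, 14)]
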