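"""Nanotube builder: lattice closure, grafting, charge bookkeeping."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycotube import fcnt
from glycotube.geometry import minimum_image


@pytest.mark.parametrize(
    "n,cells,expected",
    [(17, 14, 952), (10, 1, 40), (5, 2, 40), (12, 3, 144)],
)
def test_periodic_atom_count_closed_form(n, cells, expected):
    model = fcnt.build_zigzag_cnt(fcnt.LatticeSpec(n, cells))
    assert model.n_atoms == expected == 4 * n * cells


def test_periodic_length_from_default_bond():
    spec = fcnt.LatticeSpec(17, 14)
    assert spec.periodic_length == pytest.approx(3 * 1.417 * 14)
    # the study box z edge, printed as 5.952 nm
    assert abs(spec.periodic_length / 10.0 - 5.952) < 0.002


def test_degenerate_chirality_rejected():
    with pytest.raises(fcnt.DegenerateTubeError):
        fcnt.LatticeSpec(4, 1)


def test_wall_atoms_on_ideal_cylinder():
    spec = fcnt.LatticeSpec(17, 2)
    model = fcnt.build_zigzag_cnt(spec)
    r = np.linalg.norm(model.positions[:, :2], axis=1)
    assert np.abs(r - spec.radius).max() < 0.2


def test_periodic_bond_graph_three_coordinated():
    """Brute-force neighbor search incl. periodic images: every wall carbon
    has exactly 3 carbon neighbors."""
    spec = fcnt.LatticeSpec(8, 3)
    model = fcnt.build_zigzag_cnt(spec)
    pos = model.positions
    box = np.array([0.0, 0.0, spec.periodic_length])
    deg = np.zeros(model.n_atoms, dtype=int)
    for i in range(model.n_atoms):
        delta = minimum_image(pos - pos[i], box)
        d = np.linalg.norm(delta, axis=1)
        deg[i] = int(np.count_nonzero((d > 1e-6) & (d < 1.6)))
    assert np.all(deg == 3)


def test_sp3_carbons_have_four_bonds(small_tube):
    counts = np.zeros(small_tube.n_atoms, dtype=int)
    for i, j in small_tube.bonds:
        counts[i] += 1
        counts[j] += 1
    wall_sp3 = small_tube.is_wall & small_tube.sp3
    wall_sp2 = small_tube.is_wall & ~small_tube.sp3
    assert np.all(counts[wall_sp3] == 4)
    assert np.all(counts[wall_sp2] == 3)


def test_bond_list_has_no_duplicates(small_tube):
    canon = {tuple(sorted(b)) for b in small_tube.bonds.tolist()}
    assert len(canon) == len(small_tube.bonds)


@pytest.mark.parametrize(
    "group,expected",
    [("carboxylate", 164), ("carboxylic_acid", 165), (None, 160)],
)
def test_capped_cluster_atom_counts(group, expected):
    model = fcnt.build_capped_cluster(10, 7, group)
    assert model.n_atoms == expected


def test_capped_cluster_minimal_bare():
    model = fcnt.build_capped_cluster(10, 2, None)
    assert model.n_atoms == 60
    assert np.count_nonzero(np.array(model.elements) == "C") == 40
    assert np.count_nonzero(np.array(model.elements) == "H") == 20


def test_capped_cluster_too_short_for_motif():
    with pytest.raises(fcnt.PlacementError):
        fcnt.build_capped_cluster(10, 2, "carboxylate")


def test_coverage_ceiling_gives_twenty_groups(study_tube):
    assert np.count_nonzero(study_tube.is_wall) == 952
    assert study_tube.n_groups == 20 == math.ceil(0.02 * 952)


def test_zero_groups_leaves_model_unchanged():
    model = fcnt.build_zigzag_cnt(fcnt.LatticeSpec(10, 2))
    grafted = fcnt.graft_groups(
        model, fcnt.GraftSpec("carboxylate", n_groups=0, rng_seed=1)
    )
    assert grafted.n_atoms == model.n_atoms
    assert grafted.net_charge == 0.0


def test_graft_deterministic_per_seed():
    model = fcnt.build_zigzag_cnt(fcnt.LatticeSpec(12, 6))
    spec = fcnt.GraftSpec("carboxylate", n_groups=5, rng_seed=42)
    a = fcnt.graft_groups(model, spec)
    b = fcnt.graft_groups(model, spec)
    assert np.array_equal(a.motif_id, b.motif_id)
    assert np.allclose(a.positions, b.positions)
    c = fcnt.graft_groups(model, fcnt.GraftSpec("carboxylate", n_groups=5, rng_seed=43))
    assert not np.array_equal(a.motif_id, c.motif_id)


def test_infeasible_separation_reports_achievable_maximum():
    model = fcnt.build_zigzag_cnt(fcnt.LatticeSpec(5, 1))
    with pytest.raises(fcnt.PlacementError, match=r"admits only \d+"):
        fcnt.graft_groups(
            model, fcnt.GraftSpec("carboxylate", n_groups=15, rng_seed=0,
                                  min_anchor_separation=4)
        )


def test_motifs_share_no_atoms(study_tube):
    ids = study_tube.motif_id
    anchors = np.flatnonzero(study_tube.is_wall & (ids >= 0))
    # every motif has exactly two wall carbons (anchor + rehybridized neighbor)
    per_motif = np.bincount(ids[anchors])
    assert np.all(per_motif == 2)


class TestChargeRedistribution:
    def test_exact_integer_net_charge(self, study_tube):
        assert abs(study_tube.net_charge - (-20.0)) < 1e-12

    def test_acid_form_is_neutral(self):
        model = fcnt.functionalized_tube(
            chirality_n=10, cells=4, group_kind="carboxylic_acid", seed=3
        )
        assert abs(model.net_charge) < 1e-12

    def test_uniform_adjustment_arithmetic(self):
        """Motifs summing to -0.95 e each: per-carbon shift is -(n*0.05)/N_wall."""
        model = fcnt.build_zigzag_cnt(fcnt.LatticeSpec(12, 6))
        charges = fcnt.MotifChargeSet(
            anchor_c=0.05, neighbor_c=0.0, neighbor_h=0.0,
            carboxyl_c=0.6, carboxyl_o1=-0.8, carboxyl_o2=-0.8,
        )
        assert charges.group_sum("carboxylate") == pytest.approx(-0.95)
        grafted = fcnt.graft_groups(
            model, fcnt.GraftSpec("carboxylate", n_groups=4, rng_seed=0), charges
        )
        balanced, per_carbon = fcnt.redistribute_residual_charge(grafted)
        n_eligible = np.count_nonzero(balanced.is_wall & (balanced.motif_id < 0))
        assert per_carbon == pytest.approx(-(4 * 0.05) / n_eligible)
        assert abs(balanced.net_charge - (-4.0)) < 1e-12

    def test_idempotent_on_balanced_model(self, study_tube):
        again, per_carbon = fcnt.redistribute_residual_charge(study_tube)
        assert abs(per_carbon) < 1e-12
        assert np.allclose(again.charges, study_tube.charges, atol=1e-12)

    def test_positive_residual_acid_motif(self):
        """A single acid motif summing +0.02 e rebalances to exactly zero."""
        model = fcnt.build_zigzag_cnt(fcnt.LatticeSpec(10, 3))
        charges = fcnt.MotifChargeSet(
            anchor_c=0.02, neighbor_c=0.0, neighbor_h=0.0,
            carboxyl_c=0.5, carboxyl_o1=-0.5, carboxyl_o2=-0.5, acid_h=0.5,
        )
        grafted = fcnt.graft_groups(
            model, fcnt.GraftSpec("carboxylic_acid", n_groups=1, rng_seed=2), charges
        )
        assert grafted.net_charge == pytest.approx(0.02)
        balanced, _ = fcnt.redistribute_residual_charge(grafted)
        assert abs(balanced.net_charge) < 1e-12


@settings(max_examples=20, deadline=None, derandomize=True)
@given(n=st.integers(5, 14), cells=st.integers(1, 4))
def test_atom_count_property(n, cells):
    model = fcnt.build_zigzag_cnt(fcnt.LatticeSpec(n, cells))
    assert model.n_atoms == 4 * n * cells


@settings(max_examples=10, deadline=None, derandomize=True)
@given(n=st.integers(5, 12), rings=st.integers(2, 6))
def test_capped_cluster_count_property(n, rings):
    model = fcnt.build_capped_cluster(n, rings, None)
    assert model.n_atoms == 2 * n * rings + 2 * n
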