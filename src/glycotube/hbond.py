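"""Strict geometric hydrogen-bond counting between the tube's carboxyl
groups and carbohydrate molecules.

A hydrogen bond exists when the acceptor-donor heavy-atom distance is
strictly below 3 angstrom AND the angle at the donor heavy atom between
the D->A and D->H directions is strictly below 20 degrees.  Weak bonds
(3.0 <= d < 3.5 angstrom) are deliberately never counted.  Depending on
protonation, a surface carboxylate acts as acceptor only while a
carboxylic acid acts as both acceptor and donor; carbohydrate hydroxyl
and amide groups act as both.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import minimum_image
from .trajectory import Trajectory


@dataclass(frozen=True)
class HbondCriterion:
    d_max: float = 3.0  # angstrom, acceptor-donor, strict
    theta_max: float = 20.0  # degrees, acceptor-donor-H, strict

    def __post_init__(self):
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if not 0.0 < self.theta_max < 90.0:
            raise ValueError("theta_max must lie in (0, 90) degrees")


def count_hbonds(positions, donors, acceptors, box,
                 criterion: HbondCriterion | None = None) -> int:
    """Count (donor, acceptor) pairs meeting the strict criterion.

    ``donors`` is a sequence of (heavy atom index, hydrogen index) pairs;
    ``acceptors`` a sequence of heavy-atom indices.  Minimum image applies.
    A donor heavy atom serving also as an acceptor never bonds to itself.
    """
    if criterion is None:
        criterion = HbondCriterion()
    donors = list(donors)
    acceptors = np.asarray(list(acceptors), dtype=int)
    if not donors or acceptors.size == 0:
        return 0
    for d, h in donors:
        if d == h:
            raise ValueError("donor heavy atom must pair a distinct hydrogen")
    positions = np.asarray(positions, dtype=float)
    box = np.asarray(box, dtype=float)

    d_idx = np.array([d for d, _ in donors], dtype=int)
    h_idx = np.array([h for _, h in donors], dtype=int)
    da = minimum_image(positions[acceptors][None, :, :] - positions[d_idx][:, None, :], box)
    dh = minimum_image(positions[h_idx] - positions[d_idx], box)
    dist = np.linalg.norm(da, axis=-1)
    dh_norm = np.linalg.norm(dh, axis=-1)
    cosang = np.einsum("dak,dk->da", da, dh) / np.where(
        dist * dh_norm[:, None] > 0, dist * dh_norm[:, None], 1.0
    )
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    hits = (dist < criterion.d_max) & (angle < criterion.theta_max)
    hits &= acceptors[None, :] != d_idx[:, None]
    return int(np.count_nonzero(hits))


@dataclass
class RoleAssignments:
    """Donor/acceptor index lists for the carboxyl-vs-carbohydrate split."""

    carboxyl_acceptors: list  # tube carboxyl O indices (either form)
    carboxyl_donors: list  # (O, H) pairs; empty for the carboxylate form
    sugar_acceptors: list  # carbohydrate O/N heavy atoms
    sugar_donors: list  # carbohydrate (O/N, H) pairs
    group_kind: str | None = None


#: carbohydrate donor hydroxyl/amide pairs, per residue template
SUGAR_DONOR_PAIRS = {
    "GCA": [("O1", "HO1"), ("O2", "HO2"), ("O3", "HO3"), ("O4", "HO4")],
    "NAG": [("O1", "HO1"), ("O3", "HO3"), ("O4", "HO4"), ("O6", "HO6"),
            ("N2", "HN2")],
    "NGA": [("O1", "HO1"), ("O3", "HO3"), ("O4", "HO4"), ("O6", "HO6"),
            ("N2", "HN2")],
}

SUGAR_ACCEPTOR_NAMES = {
    "GCA": ["O1", "O2", "O3", "O4", "O5", "O6A", "O6B"],
    "NAG": ["O1", "O3", "O4", "O5", "O6", "O7", "N2"],
    "NGA": ["O1", "O3", "O4", "O5", "O6", "O7", "N2"],
}


def assign_roles(traj: Trajectory, group_kind: str) -> RoleAssignments:
    """Enumerate donors/acceptors from the atom table of an assembled system.

    Tube motif oxygens are named ``OGA``/``OGB`` (one pair per motif) and
    the acid hydroxyl hydrogen ``HOG``, written immediately after its
    ``OGB``; carbohydrate templates follow the IUPAC names of the glycan
    builder (atoms dropped by linkage formation are simply absent from
    the table).
    """
    atoms = traj.atoms
    is_cnt = (atoms["molclass"] == "fcnt").to_numpy()
    names = atoms["name"].astype(str).to_numpy()

    carboxyl_acceptors = [
        int(i) for i in np.flatnonzero(is_cnt)
        if names[i].startswith("OG")
    ]
    carboxyl_donors = []
    if group_kind == "carboxylic_acid":
        for i in np.flatnonzero(is_cnt & (names == "HOG")):
            # motif atom order is CG, OGA, OGB, HG, HOG
            o_idx = int(i) - 2
            if o_idx >= 0 and names[o_idx] == "OGB":
                carboxyl_donors.append((o_idx, int(i)))

    sugar_acceptors = []
    sugar_donors = []
    sugar = atoms[atoms["molclass"] == "glycan"]
    for (molid, resid), group in sugar.groupby(["molid", "resid"]):
        resname = group["resname"].iloc[0]
        by_name = {n: int(i) for i, n in zip(group.index, group["name"])}
        for n in SUGAR_ACCEPTOR_NAMES.get(resname, []):
            if n in by_name:
                sugar_acceptors.append(by_name[n])
        for heavy, hyd in SUGAR_DONOR_PAIRS.get(resname, []):
            if heavy in by_name and hyd in by_name:
                sugar_donors.append((by_name[heavy], by_name[hyd]))
    return RoleAssignments(
        carboxyl_acceptors=carboxyl_acceptors,
        carboxyl_donors=carboxyl_donors,
        sugar_acceptors=sugar_acceptors,
        sugar_donors=sugar_donors,
        group_kind=group_kind,
    )


@dataclass
class HbondCount:
    """Per-frame counts split by the carboxyl group's role."""

    per_frame: pd.DataFrame  # columns frame, carboxyl_acceptor, carboxyl_donor
    mean_carboxyl_acceptor: float
    mean_carboxyl_donor: float
    group_kind: str | None = None


def mean_hbonds(traj: Trajectory, roles: RoleAssignments,
                criterion: HbondCriterion | None = None) -> HbondCount:
    """Trajectory-mean hydrogen-bond counts, split by carboxyl role.

    'carboxyl acceptor' pairs sugar donors with tube carboxyl oxygens;
    'carboxyl donor' pairs the acid O-H with sugar acceptors (zero by
    construction for the carboxylate form, which cannot donate).
    """
    if criterion is None:
        criterion = HbondCriterion()
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    rows = []
    for f in range(traj.n_frames):
        pos = traj.positions[f]
        acc = count_hbonds(pos, roles.sugar_donors, roles.carboxyl_acceptors,
                           traj.box, criterion)
        don = count_hbonds(pos, roles.carboxyl_donors, roles.sugar_acceptors,
                           traj.box, criterion)
        rows.append(dict(frame=f, carboxyl_acceptor=acc, carboxyl_donor=don))
    table = pd.DataFrame(rows)
    return HbondCount(
        per_frame=table,
        mean_carboxyl_acceptor=float(table["carboxyl_acceptor"].mean()),
        mean_carboxyl_donor=float(table["carboxyl_donor"].mean()),
        group_kind=roles.group_kind,
    )
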