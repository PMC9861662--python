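"""Simulation-box composition: tube + glycans + counterions and salt.

The functionalized tube sits in the middle of the x,y cross-section with
its axis along z; the box z edge equals the tube's periodic length.
Glycan copies are dropped at random non-overlapping poses, then Na+/Cl-
are added for the requested ionic strength (0.15 mol/L in the study)
plus enough counterions to make the total system charge exactly zero.
Explicit water is never placed: the analyses operate on solute
coordinates only, and the study's ~4200-4500 water molecules are carried
as metadata.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fcnt import CARBOXYLATE, CARBOXYLIC_ACID, FcntModel, PlacementError
from .geometry import minimum_image
from .glycan import PDB_RESNAMES, GlycanChain
from .units import N_A_PER_NM3_MOLAR

MIN_SOLUTE_DISTANCE = 2.0  # angstrom, between distinct molecules

#: amber-family ion Lennard-Jones parameters (sigma nm, epsilon kJ/mol)
ION_LJ = {
    "NA": {"sigma_nm": 0.244, "epsilon_kj_mol": 0.366, "charge": 1.0},
    "CL": {"sigma_nm": 0.448, "epsilon_kj_mol": 0.149, "charge": -1.0},
}


@dataclass(frozen=True)
class BoxSpec:
    """Orthorhombic periodic box, edge lengths in angstrom."""

    lx: float
    ly: float
    lz: float

    @property
    def edges(self) -> np.ndarray:
        return np.array([self.lx, self.ly, self.lz])

    @property
    def volume_nm3(self) -> float:
        return self.lx * self.ly * self.lz / 1000.0

    @classmethod
    def for_tube(cls, fcnt: FcntModel, lx: float = 55.0, ly: float = 55.0) -> "BoxSpec":
        if fcnt.periodic_length is None:
            raise ValueError("finite cluster has no periodic length")
        return cls(lx, ly, fcnt.periodic_length)


@dataclass(frozen=True)
class IonSpec:
    """Salt content: ionic strength plus per-species LJ parameters."""

    ionic_strength: float = 0.15  # mol/L
    lj: dict = field(default_factory=lambda: dict(ION_LJ))

    def salt_pairs(self, volume_nm3: float) -> int:
        """Na+/Cl- pairs for the target concentration in the given volume."""
        if self.ionic_strength <= 0:
            return 0
        return int(round(self.ionic_strength * N_A_PER_NM3_MOLAR * volume_nm3))


@dataclass
class System:
    """Assembled solute coordinates with per-atom bookkeeping.

    ``atoms`` columns: name, element, resname, resid, molid, molclass
    (fcnt | glycan | ion), charge.  molid -1 marks the tube.
    """

    atoms: pd.DataFrame
    positions: np.ndarray
    box: np.ndarray  # angstrom
    fcnt: FcntModel | None
    glycan_templates: list
    metadata: dict = field(default_factory=dict)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def net_charge(self) -> float:
        return float(math.fsum(self.atoms["charge"].tolist()))

    def molecule_ids(self, molclass: str = "glycan"):
        sel = self.atoms[self.atoms["molclass"] == molclass]
        return sorted(sel["molid"].unique())

    def indices(self, molclass=None, molid=None, names=None, resname=None):
        mask = np.ones(self.n_atoms, dtype=bool)
        if molclass is not None:
            mask &= (self.atoms["molclass"] == molclass).to_numpy()
        if molid is not None:
            mask &= (self.atoms["molid"] == molid).to_numpy()
        if resname is not None:
            mask &= (self.atoms["resname"] == resname).to_numpy()
        if names is not None:
            mask &= self.atoms["name"].isin(list(names)).to_numpy()
        return np.flatnonzero(mask)

    @property
    def axis_xy(self) -> np.ndarray:
        """Tube axis position in the x,y plane (box center)."""
        return self.box[:2] / 2.0


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def _clash(candidate: np.ndarray, occupied: np.ndarray, box: np.ndarray,
           min_dist: float = MIN_SOLUTE_DISTANCE) -> bool:
    if len(occupied) == 0:
        return False
    delta = minimum_image(candidate[:, None, :] - occupied[None, :, :], box)
    return bool((np.linalg.norm(delta, axis=-1) < min_dist).any())


def assemble(fcnt: FcntModel | None, glycans, copies: int, box: BoxSpec,
             ions: IonSpec | None = None, seed: int = 0,
             max_tries: int = 2000) -> System:
    """Compose a periodic box; deterministic for a fixed seed.

    ``glycans`` is a list of template chains; each is placed ``copies``
    times at random non-overlapping poses (no interatomic distance below
    2 angstrom between distinct molecules, minimum image applied).  Ion
    counts are round(c * N_A * V) per species plus neutralizing Na+/Cl-.
    """
    rng = np.random.default_rng(seed)
    if ions is None:
        ions = IonSpec()
    edges = box.edges

    rows = []
    coords = []
    occupied = np.empty((0, 3))

    if fcnt is not None:
        shift = np.array([box.lx / 2.0, box.ly / 2.0, 0.0])
        pos = fcnt.positions + shift
        coords.append(pos)
        occupied = pos
        for k in range(fcnt.n_atoms):
            rows.append(
                dict(name=fcnt.names[k], element=fcnt.elements[k], resname="CNT",
                     resid=0, molid=-1, molclass="fcnt", charge=fcnt.charges[k])
            )

    molid = 0
    for template in glycans:
        tpl = template.positions - template.positions.mean(axis=0)
        for _ in range(copies):
            placed = False
            for _attempt in range(max_tries):
                rot = _random_rotation(rng)
                center = rng.random(3) * edges
                cand = tpl @ rot.T + center
                if not _clash(cand, occupied, edges):
                    placed = True
                    break
            if not placed:
                raise PlacementError(
                    f"could not place molecule copy {molid} after {max_tries} tries"
                )
            coords.append(cand)
            occupied = np.vstack([occupied, cand])
            names = template.names
            elements = template.elements
            charges = template.charges
            resids = np.concatenate(
                [np.full(r.n_atoms, ri + 1) for ri, r in enumerate(template.residues)]
            )
            resnames = np.concatenate(
                [np.full(r.n_atoms, PDB_RESNAMES[r.code], dtype=object)
                 for r in template.residues]
            )
            for k in range(template.n_atoms):
                rows.append(
                    dict(name=names[k], element=elements[k], resname=resnames[k],
                         resid=int(resids[k]), molid=molid, molclass="glycan",
                         charge=charges[k])
                )
            molid += 1

    solute_charge = math.fsum(r["charge"] for r in rows)
    n_salt = ions.salt_pairs(box.volume_nm3)
    n_na, n_cl = n_salt, n_salt
    # neutralize: counterions against the solute charge
    counter = int(round(-solute_charge))
    if counter > 0:
        n_na += counter
    elif counter < 0:
        n_cl += -counter

    for species, count in (("NA", n_na), ("CL", n_cl)):
        for _ in range(count):
            placed = False
            for _attempt in range(max_tries):
                cand = (rng.random(3) * edges)[None, :]
                if not _clash(cand, occupied, edges):
                    placed = True
                    break
            if not placed:
                raise PlacementError(f"could not place ion {species}")
            coords.append(cand)
            occupied = np.vstack([occupied, cand])
            rows.append(
                dict(name=species, element=species.capitalize(), resname=species,
                     resid=0, molid=molid, molclass="ion",
                     charge=ions.lj[species]["charge"])
            )
            molid += 1

    atoms = pd.DataFrame(rows)
    positions = np.vstack(coords) if coords else np.empty((0, 3))
    water_estimate = None
    if fcnt is not None and abs(box.lx - 55.0) < 1e-9:
        water_estimate = "ca. 4200-4500 (metadata only; water is never placed)"
    return System(
        atoms=atoms,
        positions=positions,
        box=edges,
        fcnt=fcnt,
        glycan_templates=list(glycans),
        metadata=dict(
            seed=seed,
            n_na=n_na,
            n_cl=n_cl,
            salt_pairs=n_salt,
            ionic_strength=ions.ionic_strength,
            water_count=water_estimate,
        ),
    )


@dataclass(frozen=True)
class SystemDescriptor:
    label: str
    fcnt_kind: str | None  # carboxylate / carboxylic_acid / None
    glycan_kind: str  # GlcA / GlcNAc / GalNAc / HA / Ch
    n_copies: int


def study_manifest(monosaccharide_copies: int = 20) -> list:
    """The fifteen simulated systems of the study.

    Ten base systems ({GlcA, GlcNAc, GalNAc, 1HA, 1Ch} x {CNT-COOH,
    CNT-COO-}), four crowded four-copy oligomer systems and one free Ch
    chain in water.  Monosaccharide copy number per box is configurable
    (the study shows it only in snapshots); the default is 20.
    """
    fcnt_label = {CARBOXYLATE: "CNT-COO⊖", CARBOXYLIC_ACID: "CNT-COOH"}
    out = []
    for glycan_kind in ("GlcA", "GalNAc", "GlcNAc", "HA", "Ch"):
        for fk in (CARBOXYLATE, CARBOXYLIC_ACID):
            if glycan_kind in ("HA", "Ch"):
                label = f"1{glycan_kind}/{fcnt_label[fk]}"
                copies = 1
            else:
                label = f"{glycan_kind}/{fcnt_label[fk]}"
                copies = monosaccharide_copies
            out.append(SystemDescriptor(label, fk, glycan_kind, copies))
    for glycan_kind in ("HA", "Ch"):
        for fk in (CARBOXYLATE, CARBOXYLIC_ACID):
            out.append(
                SystemDescriptor(f"4{glycan_kind}/{fcnt_label[fk]}", fk, glycan_kind, 4)
            )
    out.append(SystemDescriptor("1Ch in water", None, "Ch", 1))
    return out
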