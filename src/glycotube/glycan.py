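"""Idealized 3D builders for GlcA, GlcNAc, GalNAc and HA/Ch oligomers.

Residues are beta-D-pyranoses in the ideal 4C1 chair with IUPAC atom
naming (ring C1-C5 and O5, ring hydrogens H1-H5, hydroxyls O2/O3/O4/O6,
the N-acetyl group of the amino sugars, the deprotonated carboxylate of
GlcA).  In the 4C1 chair the ring hydrogens split over the two faces of
the ring: H1, H3, H5 on one face ("side A") and H2 plus H4 on the other
("side B"); the C4 epimerization that turns GlcNAc into GalNAc moves O4
from equatorial to axial, so for GalNAc side B is H2 plus O4.  These are
the atom pairs whose radial density profiles define the orientation of an
adsorbed monosaccharide on the nanotube surface.

Chains are grown residue by residue through beta-glycosidic linkages with
exact glycosidic torsions:

    phi = O5-C1-O1-C'n      psi = C1-O1-C'n-C'(n-1)      n = 3 or 4

Hyaluronan (HA) is the repeating GlcA-beta1,3-GlcNAc disaccharide joined
by beta1,4 linkages; chondroitin (Ch) replaces GlcNAc with GalNAc.  The
reducing end is left unfunctionalized.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import dihedral, kabsch, nerf_place, normalize

RING_RADIUS = 1.442  # angstrom; with z amplitude 0.25 every ring bond is 1.526
RING_Z = 0.25
RING_BOND_IDEAL = math.sqrt(RING_RADIUS**2 + (2 * RING_Z) ** 2)

CH_BOND = 1.10
CO_BOND = 1.43
CN_BOND = 1.45
CC_BOND = 1.52
OH_BOND = 0.96
NH_BOND = 1.01
C_DBL_O = 1.23
C_O_CARBOXYLATE = 1.25
AMIDE_CN = 1.35

GLYCOSIDIC_ANGLE = 117.0  # C1-O1-C'n, degrees
PHI_DEFAULT = -70.0
PSI_DEFAULT = -110.0

RESIDUE_CODES = ("GlcA", "GlcNAc", "GalNAc")
#: PDB-style 3-letter residue codes
PDB_RESNAMES = {"GlcA": "GCA", "GlcNAc": "NAG", "GalNAc": "NGA"}

RING_ORDER = ("O5", "C1", "C2", "C3", "C4", "C5")


class UnknownResidueError(KeyError):
    pass


@dataclass
class Residue:
    code: str
    names: list
    elements: list
    charges: np.ndarray
    positions: np.ndarray
    formal_charge: int

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError as err:
            raise KeyError(f"{self.code} has no atom {name!r}") from err

    def position(self, name: str) -> np.ndarray:
        return self.positions[self.index(name)]

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def drop(self, names_to_drop) -> "Residue":
        keep = [i for i, n in enumerate(self.names) if n not in set(names_to_drop)]
        return Residue(
            code=self.code,
            names=[self.names[i] for i in keep],
            elements=[self.elements[i] for i in keep],
            charges=self.charges[keep],
            positions=self.positions[keep],
            formal_charge=self.formal_charge,
        )


@dataclass(frozen=True)
class GlycosidicLinkage:
    """beta1-3 or beta1-4 linkage between chain residues donor -> acceptor."""

    kind: str  # "beta1-3" | "beta1-4"
    donor: int
    acceptor: int
    phi_atoms: tuple  # four (residue index, atom name) pairs
    psi_atoms: tuple

    @property
    def n(self) -> int:
        return 3 if self.kind == "beta1-3" else 4


@dataclass
class GlycanChain:
    """Ordered residues plus linkage records; coordinates are concatenated."""

    residues: list
    linkages: list
    kind: str | None = None  # HA / Ch / residue code

    @property
    def n_atoms(self) -> int:
        return sum(r.n_atoms for r in self.residues)

    @property
    def formal_charge(self) -> int:
        return sum(r.formal_charge for r in self.residues)

    def offsets(self):
        off, total = [], 0
        for r in self.residues:
            off.append(total)
            total += r.n_atoms
        return off

    @property
    def positions(self) -> np.ndarray:
        return np.vstack([r.positions for r in self.residues])

    @positions.setter
    def positions(self, value: np.ndarray):
        off = self.offsets()
        for r, o in zip(self.residues, off):
            r.positions = np.array(value[o : o + r.n_atoms], dtype=float)

    @property
    def names(self):
        return [n for r in self.residues for n in r.names]

    @property
    def elements(self):
        return [e for r in self.residues for e in r.elements]

    @property
    def charges(self) -> np.ndarray:
        return np.concatenate([r.charges for r in self.residues])

    def atom_index(self, residue_index: int, name: str) -> int:
        return self.offsets()[residue_index] + self.residues[residue_index].index(name)

    def torsion_indices(self, linkage: GlycosidicLinkage):
        phi = [self.atom_index(r, n) for r, n in linkage.phi_atoms]
        psi = [self.atom_index(r, n) for r, n in linkage.psi_atoms]
        return phi, psi

    def measure_torsions(self) -> np.ndarray:
        """(n_linkages, 2) array of (phi, psi) in degrees."""
        pos = self.positions
        out = []
        for lk in self.linkages:
            phi_idx, psi_idx = self.torsion_indices(lk)
            out.append(
                [dihedral(*(pos[i] for i in phi_idx)), dihedral(*(pos[i] for i in psi_idx))]
            )
        return np.array(out)

    def ring_atom_indices(self, residue_index: int):
        return [self.atom_index(residue_index, n) for n in RING_ORDER]


# ---------------------------------------------------------------------------
# residue templates


def _tetrahedral_directions(p, nb1, nb2):
    """The two free tetrahedral directions at ``p`` given two bonded neighbors."""
    u1 = normalize(nb1 - p)
    u2 = normalize(nb2 - p)
    m = normalize(-(u1 + u2))
    w = normalize(np.cross(u1, u2))
    half = math.radians(109.471 / 2.0)
    d1 = normalize(m * math.cos(half) + w * math.sin(half))
    d2 = normalize(m * math.cos(half) - w * math.sin(half))
    return d1, d2


def _axial_equatorial(p, nb1, nb2):
    d1, d2 = _tetrahedral_directions(p, nb1, nb2)
    return (d1, d2) if abs(d1[2]) > abs(d2[2]) else (d2, d1)


def build_residue(code: str) -> Residue:
    """Ideal 4C1 template of one residue, anomeric hydroxyl included."""
    if code not in RESIDUE_CODES:
        raise UnknownResidueError(f"unknown residue code {code!r}")

    ring_pos = {}
    for j, name in enumerate(RING_ORDER):
        theta = math.radians(60.0 * j)
        ring_pos[name] = np.array(
            [
                RING_RADIUS * math.cos(theta),
                RING_RADIUS * math.sin(theta),
                # alternating puckering phased so Cremer-Pople theta ~ 0 (4C1)
                RING_Z * (-1 if j % 2 == 0 else 1),
            ]
        )

    names, elements, charges, positions = [], [], [], []

    def add(name, element, pos, q=0.0):
        names.append(name)
        elements.append(element)
        charges.append(q)
        positions.append(np.asarray(pos, dtype=float))

    for name in RING_ORDER:
        add(name, name[0], ring_pos[name])

    def ring_neighbors(j):
        prev = RING_ORDER[(j - 1) % 6]
        nxt = RING_ORDER[(j + 1) % 6]
        return ring_pos[prev], ring_pos[nxt]

    def substituents(j):
        name = RING_ORDER[j]
        nb1, nb2 = ring_neighbors(j)
        return _axial_equatorial(ring_pos[name], nb1, nb2)

    # C1: axial H1, equatorial O1 (beta anomer) with its hydroxyl hydrogen
    ax, eq = substituents(1)
    add("H1", "H", ring_pos["C1"] + CH_BOND * ax)
    o1 = ring_pos["C1"] + CO_BOND * eq
    add("O1", "O", o1)
    add("HO1", "H", nerf_place(ring_pos["O5"], ring_pos["C1"], o1, OH_BOND, 108.0, 60.0))

    # C2: axial H2; equatorial hydroxyl (GlcA) or N-acetyl (amino sugars)
    ax, eq = substituents(2)
    add("H2", "H", ring_pos["C2"] + CH_BOND * ax)
    if code == "GlcA":
        o2 = ring_pos["C2"] + CO_BOND * eq
        add("O2", "O", o2)
        add("HO2", "H", nerf_place(ring_pos["C1"], ring_pos["C2"], o2, OH_BOND, 108.0, 180.0))
    else:
        n2 = ring_pos["C2"] + CN_BOND * eq
        add("N2", "N", n2)
        add("HN2", "H", nerf_place(ring_pos["C1"], ring_pos["C2"], n2, NH_BOND, 118.0, 60.0))
        c7 = nerf_place(ring_pos["C1"], ring_pos["C2"], n2, AMIDE_CN, 122.0, -120.0)
        add("C7", "C", c7)
        add("O7", "O", nerf_place(ring_pos["C2"], n2, c7, C_DBL_O, 122.0, 0.0))
        c8 = nerf_place(ring_pos["C2"], n2, c7, CC_BOND, 115.0, 180.0)
        add("C8", "C", c8)
        for k, chi in enumerate((60.0, 180.0, 300.0)):
            add(f"H8{k + 1}", "H", nerf_place(n2, c7, c8, CH_BOND, 109.5, chi))

    # C3: axial H3, equatorial hydroxyl
    ax, eq = substituents(3)
    add("H3", "H", ring_pos["C3"] + CH_BOND * ax)
    o3 = ring_pos["C3"] + CO_BOND * eq
    add("O3", "O", o3)
    add("HO3", "H", nerf_place(ring_pos["C2"], ring_pos["C3"], o3, OH_BOND, 108.0, 180.0))

    # C4: the Glc/Gal epimeric center - O4 equatorial (Glc-config) or axial (GalNAc)
    ax, eq = substituents(4)
    if code == "GalNAc":
        h4_dir, o4_dir = eq, ax
    else:
        h4_dir, o4_dir = ax, eq
    add("H4", "H", ring_pos["C4"] + CH_BOND * h4_dir)
    o4 = ring_pos["C4"] + CO_BOND * o4_dir
    add("O4", "O", o4)
    add("HO4", "H", nerf_place(ring_pos["C3"], ring_pos["C4"], o4, OH_BOND, 108.0, 180.0))

    # C5: axial H5; equatorial exocyclic carbon C6
    ax, eq = substituents(5)
    add("H5", "H", ring_pos["C5"] + CH_BOND * ax)
    c6 = ring_pos["C5"] + CC_BOND * eq
    add("C6", "C", c6)
    if code == "GlcA":
        # deprotonated carboxylate: two equivalent oxygens carrying -1 e total
        add("O6A", "O", nerf_place(ring_pos["C4"], ring_pos["C5"], c6, C_O_CARBOXYLATE, 118.0, 0.0), q=-0.5)
        add("O6B", "O", nerf_place(ring_pos["C4"], ring_pos["C5"], c6, C_O_CARBOXYLATE, 118.0, 180.0), q=-0.5)
    else:
        for k, chi in enumerate((60.0, 300.0)):
            add(f"H6{k + 1}", "H", nerf_place(ring_pos["C4"], ring_pos["C5"], c6, CH_BOND, 109.5, chi))
        o6 = nerf_place(ring_pos["C4"], ring_pos["C5"], c6, CO_BOND, 109.5, 180.0)
        add("O6", "O", o6)
        add("HO6", "H", nerf_place(ring_pos["C5"], c6, o6, OH_BOND, 108.0, 180.0))

    return Residue(
        code=code,
        names=names,
        elements=elements,
        charges=np.array(charges),
        positions=np.vstack(positions),
        formal_charge=-1 if code == "GlcA" else 0,
    )


def face_atoms(code: str, side: str, include_h3: bool = False):
    """Atom names defining a ring face.

    Side A is the H1-H5 face, side B the H2-H4 face (H2-O4 for GalNAc,
    whose O4 is axial).  ``include_h3`` adds H3 to side A for geometric
    robustness; the reported orientation statistic uses the printed pairs.
    """
    if code not in RESIDUE_CODES:
        raise UnknownResidueError(f"unknown residue code {code!r}")
    side = side.upper()
    if side == "A":
        return ["H1", "H5", "H3"] if include_h3 else ["H1", "H5"]
    if side == "B":
        return ["H2", "O4"] if code == "GalNAc" else ["H2", "H4"]
    raise ValueError("side must be 'A' or 'B'")


# ---------------------------------------------------------------------------
# chain construction


def _linkage_site(n: int):
    """(glycosidic oxygen, C'n, C'(n-1), hydroxyl H removed) on the acceptor."""
    if n == 3:
        return "O3", "C3", "C2", "HO3"
    if n == 4:
        return "O4", "C4", "C3", "HO4"
    raise ValueError("linkage position must be 3 or 4")


def build_chain(codes, linkage_kinds, torsions=None, kind=None) -> GlycanChain:
    """Grow a chain with exact glycosidic torsions.

    ``torsions`` is an (n_linkages, 2) array of (phi, psi) degrees; the
    default places every linkage in the syn basin at (-70, -110).  Residue 0
    is the non-reducing end; the last residue keeps its free anomeric
    hydroxyl (unfunctionalized reducing end).
    """
    codes = list(codes)
    linkage_kinds = list(linkage_kinds)
    if len(linkage_kinds) != len(codes) - 1:
        raise ValueError("need exactly len(codes)-1 linkage kinds")
    if torsions is None:
        torsions = np.tile([PHI_DEFAULT, PSI_DEFAULT], (len(linkage_kinds), 1))
    torsions = np.asarray(torsions, dtype=float)

    templates = [build_residue(c) for c in codes]
    placed = [templates[0]]
    linkages = []
    for i, lk_kind in enumerate(linkage_kinds):
        n = 3 if lk_kind == "beta1-3" else 4
        o_link, cn, cnm1, h_link = _linkage_site(n)
        donor = placed[i]
        acceptor = templates[i + 1]

        o5 = donor.position("O5")
        c1 = donor.position("C1")
        o1 = donor.position("O1")
        phi, psi = torsions[i]

        d_ocn = float(np.linalg.norm(acceptor.position(o_link) - acceptor.position(cn)))
        d_cc = float(np.linalg.norm(acceptor.position(cn) - acceptor.position(cnm1)))
        v1 = acceptor.position(o_link) - acceptor.position(cn)
        v2 = acceptor.position(cnm1) - acceptor.position(cn)
        ang_ocn = math.degrees(
            math.acos(float(np.dot(v1, v2)) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
        )

        cn_target = nerf_place(o5, c1, o1, d_ocn, GLYCOSIDIC_ANGLE, phi)
        cnm1_target = nerf_place(c1, o1, cn_target, d_cc, ang_ocn, psi)

        mobile = np.vstack(
            [acceptor.position(o_link), acceptor.position(cn), acceptor.position(cnm1)]
        )
        target = np.vstack([o1, cn_target, cnm1_target])
        rot, trans = kabsch(mobile, target)
        moved = Residue(
            code=acceptor.code,
            names=list(acceptor.names),
            elements=list(acceptor.elements),
            charges=acceptor.charges.copy(),
            positions=acceptor.positions @ rot.T + trans,
            formal_charge=acceptor.formal_charge,
        )
        # the donor's O1 becomes the glycosidic oxygen: drop the acceptor's
        # hydroxyl at the linkage site and the donor's anomeric hydrogen
        placed[i] = placed[i].drop(["HO1"])
        placed.append(moved.drop([o_link, h_link]))
        linkages.append(
            GlycosidicLinkage(
                kind=lk_kind,
                donor=i,
                acceptor=i + 1,
                phi_atoms=((i, "O5"), (i, "C1"), (i, "O1"), (i + 1, cn)),
                psi_atoms=((i, "C1"), (i, "O1"), (i + 1, cn), (i + 1, cnm1)),
            )
        )
    return GlycanChain(residues=placed, linkages=linkages, kind=kind)


def build_monosaccharide(code: str) -> GlycanChain:
    """Single-residue chain (no linkages) in the ideal 4C1 geometry."""
    return GlycanChain(residues=[build_residue(code)], linkages=[], kind=code)


def repeating_pattern(kind: str, length: int):
    """Residue codes and linkage kinds for an HA or Ch oligomer.

    HA repeats GlcA-beta1,3-GlcNAc joined by beta1,4; Ch uses GalNAc.
    """
    if kind not in ("HA", "Ch"):
        raise ValueError("kind must be 'HA' or 'Ch'")
    amino = "GlcNAc" if kind == "HA" else "GalNAc"
    codes = [("GlcA" if i % 2 == 0 else amino) for i in range(length)]
    links = [("beta1-3" if i % 2 == 0 else "beta1-4") for i in range(length - 1)]
    return codes, links


def build_decamer(kind: str, torsions=None) -> GlycanChain:
    """Decameric HA or Ch chain: 10 residues, 9 alternating linkages.

    Five GlcA residues carry one negative charge each, so the chain formal
    charge is -5 e.
    """
    codes, links = repeating_pattern(kind, 10)
    return build_chain(codes, links, torsions=torsions, kind=kind)


def rebuild_with_torsions(chain: GlycanChain, torsions) -> GlycanChain:
    """Same residue/linkage sequence, new glycosidic torsions."""
    codes = [r.code for r in chain.residues]
    links = [lk.kind for lk in chain.linkages]
    return build_chain(codes, links, torsions=torsions, kind=chain.kind)
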