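"""Carboxyl-functionalized zigzag carbon-nanotube builder.

Builds periodic (n,0) tubes and finite hydrogen-capped clusters, grafts
carboxylate (COO-) or carboxylic-acid (COOH) groups with the sp2->sp3
rehybridization motif (the anchor carbon carries the carboxyl group and a
bonded neighbor carbon is rehybridized and capped with hydrogen so valence
stays conserved), assigns motif partial charges from a configuration block,
and rebalances the residual charge uniformly over the remaining wall
carbons so the net charge is an exact integer: -1 e per carboxylate group,
0 per acid group.

Geometry conventions: tube axis along z, wall atoms on the ideal cylinder
of radius r = sqrt(3) n a_cc / (2 pi); the translational period of a zigzag
cell is 3 a_cc, with 4 n atoms per cell.  Bonded topology (bonds, angles,
proper dihedrals) is generated from the bond graph including the periodic
images across the z boundary, so the tube behaves as an infinite molecule.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import minimum_image
from .units import A_CC_DEFAULT

BOND_CUTOFF = 1.6  # angstrom, C-C neighbor search on the wall
CH_BOND = 1.09
C_C_SP3 = 1.52
C_O_CARBOXYL = 1.25
O_H_ACID = 0.97

CARBOXYLATE = "carboxylate"
CARBOXYLIC_ACID = "carboxylic_acid"
GROUP_KINDS = (CARBOXYLATE, CARBOXYLIC_ACID)


class DegenerateTubeError(ValueError):
    """Chirality too small to close into a meaningful cylinder."""


class PlacementError(RuntimeError):
    """Requested grafting cannot be satisfied."""


@dataclass(frozen=True)
class LatticeSpec:
    """Zigzag (n,0) lattice: ``cells`` translational cells of 4n carbons."""

    chirality_n: int
    cells: int
    a_cc: float = A_CC_DEFAULT  # angstrom

    def __post_init__(self):
        if self.chirality_n < 5:
            raise DegenerateTubeError(
                f"chirality n={self.chirality_n} < 5 gives a degenerate tube"
            )
        if self.cells < 1:
            raise ValueError("cells must be >= 1")
        if self.a_cc <= 0:
            raise ValueError("a_cc must be positive")

    @property
    def radius(self) -> float:
        """Ideal cylinder radius, angstrom (circumference n*sqrt(3)*a_cc)."""
        return math.sqrt(3.0) * self.chirality_n * self.a_cc / (2.0 * math.pi)

    @property
    def periodic_length(self) -> float:
        """Tube period along z, angstrom (3 a_cc per cell)."""
        return 3.0 * self.a_cc * self.cells

    @property
    def n_atoms(self) -> int:
        return 4 * self.chirality_n * self.cells


@dataclass(frozen=True)
class GraftSpec:
    """How many carboxyl groups to graft and how to pick anchors."""

    group_kind: str
    n_groups: int | None = None
    coverage_fraction: float | None = None
    rng_seed: int = 0
    min_anchor_separation: int = 3  # bond-graph distance between anchors

    def __post_init__(self):
        if self.group_kind not in GROUP_KINDS:
            raise ValueError(f"unknown group kind {self.group_kind!r}")
        if (self.n_groups is None) == (self.coverage_fraction is None):
            raise ValueError("give exactly one of n_groups / coverage_fraction")
        if self.n_groups is not None and self.n_groups < 0:
            raise ValueError("n_groups must be >= 0")

    def resolve_n_groups(self, n_carbons: int) -> int:
        """Ceiling rounding: 2% of 952 carbons -> 20 groups."""
        if self.n_groups is not None:
            return self.n_groups
        return math.ceil(self.coverage_fraction * n_carbons)


@dataclass(frozen=True)
class MotifChargeSet:
    """Partial charges (e) for the atoms of one grafted motif.

    The shipped defaults are synthetic placeholders chosen only so that a
    motif sums to a non-integral value and exercises the redistribution
    bookkeeping; quantum-chemically derived charges are supplied as
    configuration when available.
    """

    anchor_c: float
    neighbor_c: float
    neighbor_h: float
    carboxyl_c: float
    carboxyl_o1: float
    carboxyl_o2: float
    acid_h: float = 0.0

    def group_sum(self, group_kind: str) -> float:
        s = (
            self.anchor_c
            + self.neighbor_c
            + self.neighbor_h
            + self.carboxyl_c
            + self.carboxyl_o1
            + self.carboxyl_o2
        )
        if group_kind == CARBOXYLIC_ACID:
            s += self.acid_h
        return s

    @classmethod
    def default(cls, group_kind: str) -> "MotifChargeSet":
        if group_kind == CARBOXYLATE:
            return cls(
                anchor_c=0.10,
                neighbor_c=-0.10,
                neighbor_h=0.12,
                carboxyl_c=0.70,
                carboxyl_o1=-0.81,
                carboxyl_o2=-0.81,
            )
        return cls(
            anchor_c=0.10,
            neighbor_c=-0.12,
            neighbor_h=0.13,
            carboxyl_c=0.66,
            carboxyl_o1=-0.57,
            carboxyl_o2=-0.62,
            acid_h=0.44,
        )

    def formal_charge(self, group_kind: str) -> int:
        return -1 if group_kind == CARBOXYLATE else 0


@dataclass
class FcntModel:
    """Atoms plus pairwise-additive bonded topology of a (functionalized) CNT."""

    elements: np.ndarray  # str
    names: np.ndarray  # str
    charges: np.ndarray  # e
    positions: np.ndarray  # (N, 3) angstrom
    sp3: np.ndarray  # bool
    is_wall: np.ndarray  # bool: tube wall carbon
    motif_id: np.ndarray  # int, -1 outside motifs
    bonds: np.ndarray  # (M, 2) int
    bond_periodic: np.ndarray  # (M,) bool: term crosses the z boundary
    periodic_length: float | None  # angstrom; None for finite clusters
    group_kind: str | None = None
    n_groups: int = 0
    angles: np.ndarray | None = None
    dihedrals: np.ndarray | None = None
    angle_periodic: np.ndarray | None = None
    dihedral_periodic: np.ndarray | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def net_charge(self) -> float:
        return float(math.fsum(self.charges.tolist()))

    @property
    def formal_charge(self) -> int:
        if self.group_kind == CARBOXYLATE:
            return -self.n_groups
        return 0

    def radius(self) -> float:
        """Mean radial distance of wall atoms from the z axis through their centroid."""
        wall = self.positions[self.is_wall]
        center = wall[:, :2].mean(axis=0)
        return float(np.linalg.norm(wall[:, :2] - center, axis=1).mean())

    def wall_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_wall)

    def copy(self) -> "FcntModel":
        return replace(
            self,
            elements=self.elements.copy(),
            names=self.names.copy(),
            charges=self.charges.copy(),
            positions=self.positions.copy(),
            sp3=self.sp3.copy(),
            is_wall=self.is_wall.copy(),
            motif_id=self.motif_id.copy(),
            bonds=self.bonds.copy(),
            bond_periodic=self.bond_periodic.copy(),
        )


# ---------------------------------------------------------------------------
# lattice construction


def _zigzag_wall(n: int, cells: int, a_cc: float):
    """Cartesian wall-carbon coordinates of a zigzag (n,0) tube.

    Rolls the graphene sheet: circumferential coordinate x in [0, n*sqrt(3)*a_cc),
    axial coordinate z.  Per translational cell there are four n-atom layers at
    z offsets {0, 0.5, 1.5, 2.0} * a_cc.
    """
    a = math.sqrt(3.0) * a_cc
    radius = n * a / (2.0 * math.pi)
    circumference = n * a
    xs, zs = [], []
    for c in range(cells):
        z0 = 3.0 * a_cc * c
        for i in range(n):
            # sub-lattice A/B of the two graphene cells spanning the period
            xs += [i * a, i * a + a / 2.0, i * a + a / 2.0, i * a + a]
            zs += [z0, z0 + 0.5 * a_cc, z0 + 1.5 * a_cc, z0 + 2.0 * a_cc]
    x = np.mod(np.array(xs), circumference)
    theta = 2.0 * math.pi * x / circumference
    z = np.array(zs)
    pos = np.column_stack([radius * np.cos(theta), radius * np.sin(theta), z])
    return pos, radius


def _wall_bonds(positions: np.ndarray, periodic_length: float | None,
                cutoff: float = BOND_CUTOFF):
    """Brute-force neighbor search; z wraps when the tube is periodic."""
    box = np.array([0.0, 0.0, periodic_length or 0.0])
    delta = positions[:, None, :] - positions[None, :, :]
    delta = minimum_image(delta, box)
    dist = np.linalg.norm(delta, axis=-1)
    n = len(positions)
    iu, ju = np.triu_indices(n, k=1)
    near = dist[iu, ju] < cutoff
    bonds = np.column_stack([iu[near], ju[near]])
    if periodic_length:
        raw = np.abs(positions[bonds[:, 0], 2] - positions[bonds[:, 1], 2])
        periodic = raw > cutoff  # only wrapped images brought them close
    else:
        periodic = np.zeros(len(bonds), dtype=bool)
    return bonds, periodic


def _empty_model(positions, element="C", name="C", is_wall=True,
                 periodic_length=None) -> FcntModel:
    n = len(positions)
    bonds, periodic = _wall_bonds(positions, periodic_length)
    return FcntModel(
        elements=np.full(n, element, dtype=object),
        names=np.array([f"{name}{i + 1}" for i in range(n)], dtype=object),
        charges=np.zeros(n),
        positions=np.asarray(positions, dtype=float),
        sp3=np.zeros(n, dtype=bool),
        is_wall=np.full(n, is_wall, dtype=bool),
        motif_id=np.full(n, -1, dtype=int),
        bonds=bonds,
        bond_periodic=periodic,
        periodic_length=periodic_length,
    )


def build_zigzag_cnt(spec: LatticeSpec) -> FcntModel:
    """Periodic unfunctionalized zigzag tube; all partial charges zero.

    (17,0) with 14 cells yields 952 carbons and a 59.514 angstrom period.
    """
    pos, _ = _zigzag_wall(spec.chirality_n, spec.cells, spec.a_cc)
    return _empty_model(pos, periodic_length=spec.periodic_length)


def build_capped_cluster(n: int, rings: int,
                         group_kind: str | None = None,
                         a_cc: float = A_CC_DEFAULT,
                         charges: MotifChargeSet | None = None,
                         rng_seed: int = 0) -> FcntModel:
    """Finite (n,0) cluster of ``rings`` zigzag rings, hydrogen capped.

    A zigzag ring holds 2n wall carbons; capping adds 2n hydrogens along the
    axial dangling-bond directions.  With a single grafted motif the atom
    count is 2n*rings + 2n + 4 (carboxylate) or + 5 (acid): the (10,0)
    7-ring clusters have 164 and 165 atoms.
    """
    if rings < 2:
        raise PlacementError("need at least 2 rings for a capped cluster")
    if group_kind is not None and rings < 4:
        raise PlacementError("cluster too short to host a motif away from the caps")
    # a ring pairs two of the four layers of half a translational cell
    cells = math.ceil(rings / 2)
    pos, radius = _zigzag_wall(n, cells, a_cc)
    layer = np.round(pos[:, 2] / (0.5 * a_cc)).astype(int)  # 0,1,3,4 per cell
    # ring k occupies z layers {3k, 3k+1} in units of a_cc/2
    ring_of = layer // 3
    keep = ring_of < rings
    pos = pos[keep]
    layer = layer[keep]
    model = _empty_model(pos, periodic_length=None)

    # cap dangling bonds: wall carbons with < 3 carbon neighbors get an axial H
    deg = np.zeros(len(pos), dtype=int)
    for i, j in model.bonds:
        deg[i] += 1
        deg[j] += 1
    dangling = np.flatnonzero(deg < 3)
    h_pos = []
    for i in dangling:
        direction = -1.0 if layer[i] % 3 == 0 else 1.0  # bottom layer caps down
        h_pos.append(pos[i] + np.array([0.0, 0.0, direction * CH_BOND]))
    model = _append_atoms(
        model,
        positions=np.array(h_pos),
        elements=["H"] * len(h_pos),
        names=[f"HC{k + 1}" for k in range(len(h_pos))],
        charges=[0.0] * len(h_pos),
        sp3=[False] * len(h_pos),
        is_wall=[False] * len(h_pos),
        motif_id=[-1] * len(h_pos),
        new_bonds=[(int(i), model.n_atoms + k) for k, i in enumerate(dangling)],
    )

    if group_kind is not None:
        if charges is None:
            charges = MotifChargeSet.default(group_kind)
        # anchor mid-cluster: wall carbon nearest the axial center
        wall = model.wall_indices()
        zc = model.positions[wall, 2]
        anchor = int(wall[np.argmin(np.abs(zc - zc.mean()))])
        graft = GraftSpec(group_kind=group_kind, n_groups=1, rng_seed=rng_seed,
                          min_anchor_separation=0)
        model = graft_groups(model, graft, charges, _anchors=[anchor])
        model.group_kind = group_kind
    return model


def _append_atoms(model: FcntModel, positions, elements, names, charges,
                  sp3, is_wall, motif_id, new_bonds,
                  new_bond_periodic=None) -> FcntModel:
    n_new = len(positions)
    if n_new == 0:
        return model
    if new_bond_periodic is None:
        new_bond_periodic = [False] * len(new_bonds)
    return replace(
        model,
        elements=np.concatenate([model.elements, np.array(elements, dtype=object)]),
        names=np.concatenate([model.names, np.array(names, dtype=object)]),
        charges=np.concatenate([model.charges, np.asarray(charges, dtype=float)]),
        positions=np.vstack([model.positions, np.asarray(positions, dtype=float)]),
        sp3=np.concatenate([model.sp3, np.asarray(sp3, dtype=bool)]),
        is_wall=np.concatenate([model.is_wall, np.asarray(is_wall, dtype=bool)]),
        motif_id=np.concatenate([model.motif_id, np.asarray(motif_id, dtype=int)]),
        bonds=np.vstack([model.bonds, np.asarray(new_bonds, dtype=int)])
        if len(new_bonds)
        else model.bonds,
        bond_periodic=np.concatenate(
            [model.bond_periodic, np.asarray(new_bond_periodic, dtype=bool)]
        )
        if len(new_bonds)
        else model.bond_periodic,
    )


# ---------------------------------------------------------------------------
# grafting


def _bond_adjacency(model: FcntModel):
    adj: dict[int, list[int]] = {i: [] for i in range(model.n_atoms)}
    for i, j in model.bonds:
        adj[int(i)].append(int(j))
        adj[int(j)].append(int(i))
    return adj


def _graph_distance_within(adj, start: int, radius: int) -> set[int]:
    """Atoms within ``radius`` bonds of ``start`` (BFS)."""
    seen = {start}
    frontier = [start]
    for _ in range(radius):
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    nxt.append(v)
        frontier = nxt
    return seen


def graft_groups(model: FcntModel, graft: GraftSpec,
                 charges: MotifChargeSet | None = None,
                 _anchors: list[int] | None = None) -> FcntModel:
    """Graft carboxyl motifs onto randomly selected wall carbons.

    Each motif rehybridizes the anchor carbon (which receives the carboxyl
    carbon) and one randomly chosen bonded wall neighbor (which receives a
    hydrogen).  Anchor selection is without replacement, keeps anchors at
    least ``min_anchor_separation`` bonds apart, and is deterministic for a
    fixed ``rng_seed``.  Motif partial charges are applied; call
    :func:`redistribute_residual_charge` afterwards to restore an exact
    integer net charge.
    """
    if charges is None:
        charges = MotifChargeSet.default(graft.group_kind)
    model = model.copy()
    n_wall_c = int(np.count_nonzero(model.is_wall))
    n_groups = graft.resolve_n_groups(n_wall_c)
    if n_groups == 0:
        model.group_kind = graft.group_kind
        return model

    rng = np.random.default_rng(graft.rng_seed)
    adj = _bond_adjacency(model)

    if _anchors is None:
        candidates = [int(i) for i in model.wall_indices() if not model.sp3[i]]
        order = rng.permutation(len(candidates))
        anchors: list[int] = []
        blocked: set[int] = set()
        for idx in order:
            c = candidates[idx]
            if c in blocked:
                continue
            anchors.append(c)
            if len(anchors) == n_groups:
                break
            if graft.min_anchor_separation > 1:
                # exclude anything closer than min_anchor_separation bonds
                blocked |= _graph_distance_within(
                    adj, c, graft.min_anchor_separation - 1
                )
            else:
                blocked.add(c)
        if len(anchors) < n_groups:
            raise PlacementError(
                f"separation constraint admits only {len(anchors)} anchors; "
                f"{n_groups} requested"
            )
    else:
        anchors = list(_anchors)
        n_groups = len(anchors)

    acid = graft.group_kind == CARBOXYLIC_ACID
    wall = model.positions[model.is_wall]
    axis_xy = wall[:, :2].mean(axis=0)
    taken: set[int] = set(anchors)
    for gid, anchor in enumerate(anchors):
        neighbors = [v for v in adj[anchor]
                     if model.is_wall[v] and not model.sp3[v] and v not in taken]
        if not neighbors:
            raise PlacementError(f"anchor {anchor} has no free wall neighbor")
        neighbor = int(neighbors[rng.integers(len(neighbors))])
        taken.add(neighbor)

        model.sp3[anchor] = True
        model.sp3[neighbor] = True
        model.motif_id[anchor] = gid
        model.motif_id[neighbor] = gid
        model.charges[anchor] = charges.anchor_c
        model.charges[neighbor] = charges.neighbor_c

        # local frame: radial out of the wall, axial along z
        radial = np.zeros(3)
        radial[:2] = model.positions[anchor, :2] - axis_xy
        radial /= np.linalg.norm(radial[:2])
        axial = np.array([0.0, 0.0, 1.0])

        c_pos = model.positions[anchor] + C_C_SP3 * radial
        o1 = c_pos + C_O_CARBOXYL * (math.cos(math.radians(60)) * radial
                                     + math.sin(math.radians(60)) * axial)
        o2 = c_pos + C_O_CARBOXYL * (math.cos(math.radians(60)) * radial
                                     - math.sin(math.radians(60)) * axial)
        nrad = np.zeros(3)
        nrad[:2] = model.positions[neighbor, :2] - axis_xy
        nrad /= np.linalg.norm(nrad[:2])
        h_n = model.positions[neighbor] + CH_BOND * nrad

        base = model.n_atoms
        new_pos = [c_pos, o1, o2, h_n]
        new_el = ["C", "O", "O", "H"]
        # PDB-safe names (<= 4 chars), repeated per motif; motif_id disambiguates
        new_nm = ["CG", "OGA", "OGB", "HG"]
        new_q = [charges.carboxyl_c, charges.carboxyl_o1, charges.carboxyl_o2,
                 charges.neighbor_h]
        new_sp3 = [True, False, False, False]
        new_bonds = [(anchor, base), (base, base + 1), (base, base + 2),
                     (neighbor, base + 3)]
        if acid:
            h_o = o2 + O_H_ACID * (math.cos(math.radians(60)) * radial
                                   - math.sin(math.radians(60)) * axial)
            new_pos.append(h_o)
            new_el.append("H")
            new_nm.append("HOG")
            new_q.append(charges.acid_h)
            new_sp3.append(False)
            new_bonds.append((base + 2, base + 4))
        model = _append_atoms(
            model,
            positions=np.array(new_pos),
            elements=new_el,
            names=new_nm,
            charges=new_q,
            sp3=new_sp3,
            is_wall=[False] * len(new_pos),
            motif_id=[gid] * len(new_pos),
            new_bonds=new_bonds,
        )
    model.group_kind = graft.group_kind
    model.n_groups = model.n_groups + n_groups
    return model


def redistribute_residual_charge(model: FcntModel) -> tuple[FcntModel, float]:
    """Spread the residual charge uniformly over non-motif wall carbons.

    After redistribution the net charge equals the formal charge (-1 e per
    carboxylate group, 0 per acid group) exactly; the per-carbon adjustment
    applied is returned alongside the model.  Idempotent on a balanced model.
    """
    model = model.copy()
    target = float(model.formal_charge)
    residual = model.net_charge - target
    eligible = np.flatnonzero(model.is_wall & (model.motif_id < 0))
    if len(eligible) == 0:
        raise ValueError("no non-motif wall carbons available for redistribution")
    per_carbon = -residual / len(eligible)
    model.charges[eligible] += per_carbon
    # absorb the last floating-point crumb so the invariant holds to 1e-12
    crumb = model.net_charge - target
    model.charges[eligible[0]] -= crumb
    return model, per_carbon


def functionalized_tube(chirality_n: int = 17, cells: int = 14,
                        group_kind: str = CARBOXYLATE,
                        coverage: float = 0.02, seed: int = 0,
                        charges: MotifChargeSet | None = None,
                        a_cc: float = A_CC_DEFAULT) -> FcntModel:
    """Convenience pipeline: lattice -> graft -> charge rebalance.

    The default arguments reproduce the study tube: (17,0), 14 cells
    (952 carbons, 5.9514 nm period), 2% coverage -> 20 carboxyl groups,
    net charge -20 e in the carboxylate form.
    """
    spec = LatticeSpec(chirality_n=chirality_n, cells=cells, a_cc=a_cc)
    model = build_zigzag_cnt(spec)
    graft = GraftSpec(group_kind=group_kind, coverage_fraction=coverage,
                      rng_seed=seed)
    model = graft_groups(model, graft, charges)
    model, _ = redistribute_residual_charge(model)
    return model


def generate_bonded_terms(model: FcntModel) -> FcntModel:
    """Derive angles (bonded triplets) and proper dihedrals (bonded quadruplets).

    A term is flagged periodic when any of its constituent bonds crosses the
    z boundary.  No improper dihedrals are generated: the tube is treated as
    a large molecule with pairwise-additive terms only.
    """
    adj = _bond_adjacency(model)
    wrap = {}
    for (i, j), per in zip(model.bonds, model.bond_periodic):
        wrap[(int(i), int(j))] = bool(per)
        wrap[(int(j), int(i))] = bool(per)
    angles, angle_per = [], []
    for j in range(model.n_atoms):
        nb = sorted(adj[j])
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                i, k = nb[a], nb[b]
                angles.append((i, j, k))
                angle_per.append(wrap[(i, j)] or wrap[(j, k)])
    dihedrals, dihedral_per = [], []
    for (j, k), per_jk in zip(model.bonds, model.bond_periodic):
        j, k = int(j), int(k)
        for i in adj[j]:
            if i == k:
                continue
            for l in adj[k]:
                if l == j or l == i:
                    continue
                key = (i, j, k, l)
                if key[::-1] < key:
                    key = key[::-1]
                dihedrals.append(key)
                dihedral_per.append(wrap[(i, j)] or bool(per_jk) or wrap[(k, l)])
    dihedrals, order = np.unique(np.array(dihedrals, dtype=int), axis=0,
                                 return_index=True)
    model = model.copy()
    model.angles = np.array(angles, dtype=int)
    model.angle_periodic = np.array(angle_per, dtype=bool)
    model.dihedrals = dihedrals
    model.dihedral_periodic = np.array(dihedral_per, dtype=bool)[order]
    return model
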