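"""Pairwise Lennard-Jones / Coulomb interaction energies.

Plain cutoff truncation under the orthorhombic minimum-image convention:

    E_LJ      = sum 4 eps_ij [ (sig_ij/r)^12 - (sig_ij/r)^6 ],  r <= r_c
    E_Coulomb = sum f q_i q_j / r,                              r <= r_c

with f = 138.935458 kJ mol^-1 nm e^-2 and a 1.2 nm cutoff for both terms.
Lorentz-Berthelot mixing by default (arithmetic sigma, geometric epsilon),
matching the amber-family conventions behind the study's parameters.  No
reciprocal-space electrostatics is computed: the mesh-Ewald long-range
part belongs to the MD engine, so absolute Coulomb sums differ from
engine output by the truncated tail (a documented deviation).

Coordinates enter in angstrom and are converted to nm internally; sigma
is carried in nm as in the parameter tables.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import minimum_image
from .units import COULOMB_KJ_MOL_NM_E2, NM_PER_ANGSTROM

CUTOFF_NM_DEFAULT = 1.2
OVERLAP_NM = 0.05  # 0.5 angstrom: closer pairs are flagged


@dataclass(frozen=True)
class AtomTypeParameters:
    sigma_nm: float
    epsilon_kj_mol: float
    charge: float


@dataclass
class ForceFieldParameters:
    """Per-type LJ/charge table plus mixing rule and cutoff.

    ``types`` maps a type name to :class:`AtomTypeParameters`.  The shipped
    entries cover the study's Na+/Cl- ions; everything else (toy glycan and
    tube types for synthetic work) comes from parameter files or code.
    """

    types: dict = field(default_factory=dict)
    mixing: str = "lorentz-berthelot"  # or "geometric"
    cutoff_nm: float = CUTOFF_NM_DEFAULT
    coulomb_constant: float = COULOMB_KJ_MOL_NM_E2

    def __post_init__(self):
        if self.cutoff_nm <= 0:
            raise ValueError("cutoff must be positive")
        for name, p in self.types.items():
            if p.sigma_nm < 0 or p.epsilon_kj_mol < 0:
                raise ValueError(f"negative LJ parameters for type {name!r}")

    @classmethod
    def with_ions(cls, **kwargs) -> "ForceFieldParameters":
        ff = cls(**kwargs)
        ff.types.setdefault("NA", AtomTypeParameters(0.244, 0.366, 1.0))
        ff.types.setdefault("CL", AtomTypeParameters(0.448, 0.149, -1.0))
        return ff

    def arrays(self, type_names) -> tuple:
        sig = np.array([self.types[t].sigma_nm for t in type_names])
        eps = np.array([self.types[t].epsilon_kj_mol for t in type_names])
        q = np.array([self.types[t].charge for t in type_names])
        return sig, eps, q

    def mix(self, sig_a, eps_a, sig_b, eps_b):
        """Combined sigma_ij / eps_ij for broadcastable per-atom arrays."""
        if self.mixing == "lorentz-berthelot":
            sig = 0.5 * (sig_a[:, None] + sig_b[None, :])
        elif self.mixing == "geometric":
            sig = np.sqrt(sig_a[:, None] * sig_b[None, :])
        else:
            raise ValueError(f"unknown mixing rule {self.mixing!r}")
        eps = np.sqrt(eps_a[:, None] * eps_b[None, :])
        return sig, eps

    @staticmethod
    def load(path) -> "ForceFieldParameters":
        """Read the documented plain-text table: type, sigma nm, eps kJ/mol, q e."""
        types = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) != 4:
                    raise ValueError(f"{path}:{ln}: expected 4 columns, got {len(parts)}")
                types[parts[0]] = AtomTypeParameters(
                    float(parts[1]), float(parts[2]), float(parts[3])
                )
        return ForceFieldParameters(types=types)

    def dump(self, path):
        with open(path, "w") as fh:
            fh.write("# type  sigma_nm  epsilon_kJ_mol  charge_e\n")
            for name, p in self.types.items():
                fh.write(f"{name}  {p.sigma_nm:.6f}  {p.epsilon_kj_mol:.6f}  {p.charge:.6f}\n")


@dataclass
class PairEnergy:
    lj: float
    coulomb: float
    n_overlaps: int = 0

    @property
    def total(self) -> float:
        return self.lj + self.coulomb


def pair_energy(pos_a, pos_b, sig_a, eps_a, q_a, sig_b, eps_b, q_b,
                box, params: ForceFieldParameters | None = None) -> PairEnergy:
    """Group-group interaction energy for one frame.

    Positions in angstrom, sigma in nm.  The groups must be disjoint atom
    sets; pairs closer than 0.5 angstrom are counted in ``n_overlaps`` but
    still contribute (the caller decides what to do with flagged frames).
    """
    if params is None:
        params = ForceFieldParameters()
    pos_a = np.asarray(pos_a, dtype=float)
    pos_b = np.asarray(pos_b, dtype=float)
    if len(pos_a) == 0 or len(pos_b) == 0:
        raise ValueError("empty selection")
    delta = minimum_image(pos_a[:, None, :] - pos_b[None, :, :], np.asarray(box))
    r_nm = np.linalg.norm(delta, axis=-1) * NM_PER_ANGSTROM

    within = r_nm <= params.cutoff_nm
    n_overlaps = int(np.count_nonzero(r_nm < OVERLAP_NM))

    sig, eps = params.mix(np.asarray(sig_a, float), np.asarray(eps_a, float),
                          np.asarray(sig_b, float), np.asarray(eps_b, float))
    with np.errstate(divide="ignore", invalid="ignore"):
        sr6 = np.where(within & (r_nm > 0), (sig / np.where(r_nm > 0, r_nm, 1.0)) ** 6, 0.0)
        e_lj = float(np.sum(4.0 * eps * (sr6**2 - sr6) * within))
        inv_r = np.where(within & (r_nm > 0), 1.0 / np.where(r_nm > 0, r_nm, 1.0), 0.0)
    qq = np.asarray(q_a, float)[:, None] * np.asarray(q_b, float)[None, :]
    e_coul = float(params.coulomb_constant * np.sum(qq * inv_r))
    return PairEnergy(lj=e_lj, coulomb=e_coul, n_overlaps=n_overlaps)


@dataclass
class PairEnergyRecord:
    """Table 1 semantics: per-molecule means with a block-wise uncertainty."""

    per_frame: pd.DataFrame  # columns frame, molid, e_lj, e_coulomb, e_total
    mean_lj: float
    mean_coulomb: float
    err_lj: float
    err_coulomb: float
    n_molecules: int
    n_frames: int

    @property
    def mean_total(self) -> float:
        return self.mean_lj + self.mean_coulomb

    @property
    def err_total(self) -> float:
        return math.hypot(self.err_lj, self.err_coulomb)


def _block_standard_error(series: np.ndarray, n_blocks: int = 5) -> float:
    """Standard error of block means over the frame series."""
    n = len(series)
    if n < 2:
        return 0.0
    n_blocks = min(n_blocks, n)
    blocks = np.array_split(np.asarray(series, dtype=float), n_blocks)
    means = np.array([b.mean() for b in blocks])
    if len(means) < 2:
        return 0.0
    return float(means.std(ddof=1) / math.sqrt(len(means)))


def mean_pair_energy(traj, group_a_indices, molecule_indices: dict,
                     type_names, params: ForceFieldParameters,
                     n_blocks: int = 5) -> PairEnergyRecord:
    """Mean interaction energy per single molecule against a fixed group.

    ``molecule_indices`` maps molecule id -> atom index array; the reported
    mean is the per-molecule frame-mean averaged over molecules, and the
    uncertainty is the standard error of ``n_blocks`` block means of the
    molecule-averaged per-frame series.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    if len(group_a_indices) == 0 or not molecule_indices:
        raise ValueError("empty selection")
    type_names = np.asarray(type_names, dtype=object)
    sig_all, eps_all, q_all = params.arrays(type_names)

    rows = []
    for f in range(traj.n_frames):
        frame = traj.positions[f]
        for mid, idx in molecule_indices.items():
            e = pair_energy(
                frame[group_a_indices], frame[idx],
                sig_all[group_a_indices], eps_all[group_a_indices],
                q_all[group_a_indices],
                sig_all[idx], eps_all[idx], q_all[idx],
                traj.box, params,
            )
            rows.append(dict(frame=f, molid=mid, e_lj=e.lj,
                             e_coulomb=e.coulomb, e_total=e.total))
    table = pd.DataFrame(rows)
    per_frame = table.groupby("frame")[["e_lj", "e_coulomb"]].mean()
    return PairEnergyRecord(
        per_frame=table,
        mean_lj=float(per_frame["e_lj"].mean()),
        mean_coulomb=float(per_frame["e_coulomb"].mean()),
        err_lj=_block_standard_error(per_frame["e_lj"].to_numpy(), n_blocks),
        err_coulomb=_block_standard_error(per_frame["e_coulomb"].to_numpy(), n_blocks),
        n_molecules=len(molecule_indices),
        n_frames=traj.n_frames,
    )
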