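"""Conformational analysis: glycosidic torsions, Boltzmann-inverted
free-energy maps, conformer-class occupancies, RMSF, and ring pucker.

Free-energy maps use the Boltzmann inversion of a periodic 2D histogram
of (phi, psi): F = -kT ln(P / P_max), so the modal bin sits at F = 0 and
F >= 0 everywhere; empty bins are capped at max(finite F) + kT.  The
syn/anti conformer classes window psi around the canonical basin and its
180-degree rotation; the quasi-trans window around psi = 180 is reported
separately.  Ring geometry is classified by Cremer-Pople puckering
coordinates (Q, theta, phi_p): chairs near theta = 0/180, the boat /
skew-boat band near theta = 90 with phi_p deciding between the two.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import dihedral, dihedral_batch, kabsch, wrap_angle
from .trajectory import Trajectory
from .units import KB_KJ_MOL_K

TEMPERATURE_DEFAULT = 310.0  # K
BIN_DEG_DEFAULT = 5.0
SYN_WINDOW_DEG = 60.0
TRANS_WINDOW_DEG = 30.0
CHAIR_THETA_DEG = 45.0
BOAT_PHI_TOL_DEG = 15.0
PUCKER_MIN_Q = 0.1  # angstrom


@dataclass(frozen=True)
class ThermoContext:
    temperature: float = TEMPERATURE_DEFAULT

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def kt(self) -> float:
        """k_B T in kJ/mol."""
        return KB_KJ_MOL_K * self.temperature


def torsion(positions, atom_quadruple) -> float:
    """Signed glycosidic dihedral in degrees (IUPAC convention, cis = 0)."""
    i, j, k, l = atom_quadruple
    if len({i, j, k, l}) != 4:
        raise ValueError("torsion needs four distinct atoms")
    return dihedral(positions[i], positions[j], positions[k], positions[l])


def torsion_series(traj: Trajectory, atom_quadruple) -> np.ndarray:
    """Per-frame torsion over a trajectory, degrees."""
    i, j, k, l = atom_quadruple
    p = traj.positions
    return dihedral_batch(p[:, i], p[:, j], p[:, k], p[:, l])


@dataclass
class TorsionMap:
    phi_edges: np.ndarray
    psi_edges: np.ndarray
    probability: np.ndarray  # (n_phi, n_psi), sums to 1
    free_energy: np.ndarray  # kJ/mol, min 0 at the modal bin
    kt: float
    linkage: str = ""

    @property
    def phi_centers(self):
        return 0.5 * (self.phi_edges[:-1] + self.phi_edges[1:])

    @property
    def psi_centers(self):
        return 0.5 * (self.psi_edges[:-1] + self.psi_edges[1:])

    def basin_minimum(self, phi: float, psi: float, halfwidth: float = 15.0) -> float:
        """Minimum free energy within a periodic window around (phi, psi).

        The robust way to read a basin depth off the map: the exact center
        may fall on a bin edge, splitting its occupancy over neighbors.
        """
        dp = np.abs(wrap_angle(self.phi_centers - phi))
        ds = np.abs(wrap_angle(self.psi_centers - psi))
        window = self.free_energy[np.ix_(dp <= halfwidth, ds <= halfwidth)]
        return float(window.min())

    def value_at(self, phi: float, psi: float) -> float:
        i = int(np.searchsorted(self.phi_edges, wrap_angle(phi), side="right")) - 1
        j = int(np.searchsorted(self.psi_edges, wrap_angle(psi), side="right")) - 1
        i = min(max(i, 0), self.free_energy.shape[0] - 1)
        j = min(max(j, 0), self.free_energy.shape[1] - 1)
        return float(self.free_energy[i, j])


def free_energy_map(samples, thermo: ThermoContext | None = None,
                    bin_deg: float = BIN_DEG_DEFAULT,
                    linkage: str = "") -> TorsionMap:
    """Boltzmann inversion of a periodic (phi, psi) histogram.

    ``samples`` is (n, 2) in degrees.  Bin occupancies give P; the map is
    F = -kT ln(P / P_max) with empty bins capped one kT above the largest
    finite value, so re-exponentiating occupied bins recovers the input
    histogram exactly.
    """
    if thermo is None:
        thermo = ThermoContext()
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 2 or len(samples) == 0:
        raise ValueError("samples must be a non-empty (n, 2) array")
    edges = np.arange(-180.0, 180.0 + bin_deg, bin_deg)
    wrapped = wrap_angle(samples)
    hist, _, _ = np.histogram2d(wrapped[:, 0], wrapped[:, 1], bins=(edges, edges))
    prob = hist / hist.sum()
    pmax = prob.max()
    with np.errstate(divide="ignore"):
        fe = -thermo.kt * np.log(np.where(prob > 0, prob / pmax, np.nan))
    finite_max = np.nanmax(fe) if np.isfinite(np.nanmax(fe)) else 0.0
    fe = np.where(np.isnan(fe), finite_max + thermo.kt, fe)
    return TorsionMap(
        phi_edges=edges,
        psi_edges=edges,
        probability=prob,
        free_energy=fe,
        kt=thermo.kt,
        linkage=linkage,
    )


@dataclass(frozen=True)
class ConformerWindows:
    """psi windows for the syn / anti / quasi-trans classes, degrees.

    The canonical value is the builder's syn-basin psi; anti is rotated
    180 degrees.  Windows are half-widths around the wrapped centers.
    """

    psi_syn: float = -110.0
    syn_halfwidth: float = SYN_WINDOW_DEG
    anti_halfwidth: float = SYN_WINDOW_DEG
    trans_halfwidth: float = TRANS_WINDOW_DEG

    @property
    def psi_anti(self) -> float:
        return float(wrap_angle(self.psi_syn + 180.0))


def conformer_occupancy(samples, windows: ConformerWindows | None = None) -> dict:
    """Fractions of (phi, psi) samples in the syn / anti / quasi-trans windows.

    ``samples`` may be (n, 2) torsion pairs or a 1D psi series.  The
    quasi-trans window (psi within 30 degrees of 180) is reported
    separately and may overlap the anti window by construction.
    """
    if windows is None:
        windows = ConformerWindows()
    if windows.syn_halfwidth + windows.anti_halfwidth > 180.0:
        raise ValueError("syn/anti windows overlap")
    samples = np.asarray(samples, dtype=float)
    psi = samples[:, 1] if samples.ndim == 2 else samples
    if len(psi) == 0:
        return {"syn": 0.0, "anti": 0.0, "quasi_trans": 0.0}
    d_syn = np.abs(wrap_angle(psi - windows.psi_syn))
    d_anti = np.abs(wrap_angle(psi - windows.psi_anti))
    d_trans = np.abs(wrap_angle(psi - 180.0))
    n = len(psi)
    return {
        "syn": float(np.count_nonzero(d_syn < windows.syn_halfwidth) / n),
        "anti": float(np.count_nonzero(d_anti < windows.anti_halfwidth) / n),
        "quasi_trans": float(np.count_nonzero(d_trans < windows.trans_halfwidth) / n),
    }


def rmsf(traj: Trajectory, selection, fit: bool = True,
         fit_selection=None) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the mean position.

    With ``fit=True`` every frame is first rigid-body superposed (least
    squares) onto the running mean structure of ``fit_selection`` (default:
    the analyzed selection), which removes diffusion and tumbling; the
    no-fit mode measures fluctuations in the laboratory frame and is
    invariant under a constant translation of all frames.
    """
    selection = np.asarray(selection)
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    if selection.size == 0:
        raise ValueError("empty selection")
    fit_selection = selection if fit_selection is None else np.asarray(fit_selection)
    coords = traj.positions[:, selection, :].astype(float)
    if fit:
        fit_coords = traj.positions[:, fit_selection, :].astype(float)
        ref = fit_coords[0]
        # two passes: align to first frame, then to the aligned mean
        for _ in range(2):
            aligned = np.empty_like(coords)
            for f in range(traj.n_frames):
                rot, trans = kabsch(fit_coords[f], ref)
                aligned[f] = coords[f] @ rot.T + trans
            ref_fit = np.empty_like(fit_coords)
            for f in range(traj.n_frames):
                rot, trans = kabsch(fit_coords[f], ref)
                ref_fit[f] = fit_coords[f] @ rot.T + trans
            ref = ref_fit.mean(axis=0)
        coords = aligned
    mean = coords.mean(axis=0)
    return np.sqrt(((coords - mean) ** 2).sum(axis=-1).mean(axis=0))


def anomeric_carbons(traj: Trajectory, molid=None) -> np.ndarray:
    """Indices of the C1 atoms of glycan residues (optionally one molecule)."""
    return traj.indices(molclass="glycan", molid=molid, names=["C1"])


@dataclass
class RingPucker:
    amplitude: float  # Q, angstrom
    theta: float  # degrees, [0, 180]
    phi_p: float  # degrees, [0, 360)
    shape: str  # 'chair-4C1' | 'chair-1C4' | 'boat' | 'skew-boat' | 'undefined'


def ring_pucker(positions, ring_indices) -> RingPucker:
    """Cremer-Pople puckering coordinates of a six-membered ring.

    ``ring_indices`` must be ordered O5, C1..C5.  Chairs have theta near
    0 or 180 degrees; the equatorial band (45 < theta < 135) splits into
    boats (phi_p within 15 degrees of a multiple of 60) and skew-boats;
    amplitudes below 0.1 angstrom are classified as undefined (planar).
    """
    ring_indices = list(ring_indices)
    if len(ring_indices) != 6:
        raise ValueError("need exactly 6 ring atoms (O5, C1..C5)")
    r = np.asarray([positions[i] for i in ring_indices], dtype=float)
    center = r.mean(axis=0)
    r = r - center
    j = np.arange(6)
    rp = (r * np.sin(2 * np.pi * j / 6)[:, None]).sum(axis=0)
    rpp = (r * np.cos(2 * np.pi * j / 6)[:, None]).sum(axis=0)
    n = np.cross(rp, rpp)
    n /= np.linalg.norm(n)
    z = r @ n
    q2cos = math.sqrt(2.0 / 6.0) * float((z * np.cos(4 * np.pi * j / 6)).sum())
    q2sin = -math.sqrt(2.0 / 6.0) * float((z * np.sin(4 * np.pi * j / 6)).sum())
    q2 = math.hypot(q2cos, q2sin)
    phi2 = math.degrees(math.atan2(q2sin, q2cos)) % 360.0
    q3 = math.sqrt(1.0 / 6.0) * float((z * ((-1.0) ** j)).sum())
    amplitude = math.hypot(q2, q3)
    theta = math.degrees(math.atan2(q2, q3))  # [0, 180]

    if amplitude < PUCKER_MIN_Q:
        shape = "undefined"
    elif theta < CHAIR_THETA_DEG:
        shape = "chair-4C1"
    elif theta > 180.0 - CHAIR_THETA_DEG:
        shape = "chair-1C4"
    else:
        off = min(phi2 % 60.0, 60.0 - (phi2 % 60.0))
        shape = "boat" if off <= BOAT_PHI_TOL_DEG else "skew-boat"
    return RingPucker(amplitude=amplitude, theta=theta, phi_p=phi2, shape=shape)
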