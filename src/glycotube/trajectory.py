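"""Trajectory container and the synthetic-trajectory generator.

The study's observables come from 600 ns production MD sampled every
200 ps (3000 frames).  Desk-scale reimplementation cannot rerun that MD,
so every analysis here is exercised against synthetic trajectories whose
statistical structure is known exactly:

* adsorption/desorption is a two-state Markov chain per molecule
  (emulating the spontaneous detachment / re-adsorption events seen in
  the simulations),
* adsorbed molecules sit in a single layer at a radial distance near
  (tube radius + 4 angstrom) from the axis, desorbed excursions go beyond
  20 angstrom,
* a molecule can present a chosen ring face (A = H1-H5, B = H2-H4/O4)
  to the surface with configurable angular noise,
* glycosidic torsions are redrawn each frame from a wrapped-normal basin
  mixture (one- or two-basin free-energy surfaces).

Molecules are rigid bodies apart from the linkage torsions; per-atom
Gaussian jitter adds small-scale thermal motion.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import glycan as glycan_mod
from .assemble import System
from .geometry import normalize, rotation_about_axis, rotation_aligning, wrap_angle

FRAME_INTERVAL_PS = 200.0


class FrameSpacingError(ValueError):
    pass


def frame_count(duration_ns: float, interval_ps: float = FRAME_INTERVAL_PS) -> int:
    """Number of samples in a production run: 600 ns at 200 ps -> 3000."""
    if duration_ns <= 0 or interval_ps <= 0:
        raise FrameSpacingError("duration and interval must be positive")
    duration_ps = duration_ns * 1000.0
    n = duration_ps / interval_ps
    if abs(n - round(n)) > 1e-9:
        raise FrameSpacingError(
            f"{duration_ns} ns is not divisible by {interval_ps} ps"
        )
    return int(round(n))


@dataclass
class Trajectory:
    """Frames of positions with box, timestamps and atom metadata.

    ``atoms`` carries the same per-atom table as :class:`~glycotube.assemble.System`.
    """

    positions: np.ndarray  # (n_frames, n_atoms, 3) angstrom
    box: np.ndarray  # (3,) angstrom
    times: np.ndarray  # ps, strictly increasing
    atoms: pd.DataFrame

    def __post_init__(self):
        if self.positions.ndim != 3:
            raise ValueError("positions must be (n_frames, n_atoms, 3)")
        if len(self.times) != len(self.positions):
            raise ValueError("one timestamp per frame required")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    def indices(self, molclass=None, molid=None, names=None, resname=None,
                resid=None):
        mask = np.ones(self.n_atoms, dtype=bool)
        if molclass is not None:
            mask &= (self.atoms["molclass"] == molclass).to_numpy()
        if molid is not None:
            mask &= (self.atoms["molid"] == molid).to_numpy()
        if resname is not None:
            mask &= (self.atoms["resname"] == resname).to_numpy()
        if resid is not None:
            mask &= (self.atoms["resid"] == resid).to_numpy()
        if names is not None:
            mask &= self.atoms["name"].isin(list(names)).to_numpy()
        return np.flatnonzero(mask)

    def molecule_ids(self, molclass: str = "glycan"):
        sel = self.atoms[self.atoms["molclass"] == molclass]
        return sorted(sel["molid"].unique())

    @property
    def axis_xy(self) -> np.ndarray:
        return self.box[:2] / 2.0


# ---------------------------------------------------------------------------
# scenario specification


@dataclass(frozen=True)
class AdsorptionScenario:
    """Two-state (adsorbed/desorbed) kinetics plus pose statistics."""

    p_detach: float = 0.01  # per-frame probability adsorbed -> desorbed
    p_attach: float = 0.2  # per-frame probability desorbed -> adsorbed
    r_ads_mean: float | None = None  # angstrom; default tube radius + 4
    r_ads_sd: float = 0.5
    r_des_min: float = 20.0
    r_des_max: float | None = None  # default: half the smaller x/y edge - 1
    facing: str = "A"  # 'A' | 'B' | 'iso'
    angle_sd_deg: float = 20.0
    jitter_sd: float = 0.3  # per-atom, per-axis gaussian noise, angstrom
    monolayer_radius: float | None = 15.0  # clip adsorbed atoms inside; None disables
    initial_state: str = "stationary"  # 'stationary' | 'adsorbed' | 'desorbed'

    def __post_init__(self):
        for p in (self.p_detach, self.p_attach):
            if not 0.0 <= p <= 1.0:
                raise ValueError("switching probabilities must lie in [0, 1]")
        if self.facing not in ("A", "B", "iso"):
            raise ValueError("facing must be 'A', 'B' or 'iso'")

    @property
    def stationary_adsorbed_fraction(self) -> float:
        if self.p_attach + self.p_detach == 0.0:
            return 1.0 if self.initial_state != "desorbed" else 0.0
        return self.p_attach / (self.p_attach + self.p_detach)


@dataclass(frozen=True)
class TorsionBasin:
    phi: float  # degrees, basin center
    psi: float
    weight: float
    sd: float = 15.0  # angular standard deviation, degrees


@dataclass(frozen=True)
class TorsionSurfaceSpec:
    """Wrapped-normal basin mixture over (phi, psi); weights sum to one."""

    basins: tuple

    def __post_init__(self):
        total = sum(b.weight for b in self.basins)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"basin weights must sum to 1, got {total}")

    @classmethod
    def single(cls, phi=glycan_mod.PHI_DEFAULT, psi=glycan_mod.PSI_DEFAULT, sd=15.0):
        return cls((TorsionBasin(phi, psi, 1.0, sd),))

    @classmethod
    def two_basin(cls, weight_syn=0.8, sd=15.0,
                  syn=(glycan_mod.PHI_DEFAULT, glycan_mod.PSI_DEFAULT),
                  alt=None):
        """Syn basin plus an alternative (default anti: psi rotated 180)."""
        if alt is None:
            alt = (syn[0], wrap_angle(syn[1] + 180.0))
        return cls(
            (
                TorsionBasin(syn[0], syn[1], weight_syn, sd),
                TorsionBasin(float(alt[0]), float(alt[1]), 1.0 - weight_syn, sd),
            )
        )

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """(n, 2) array of (phi, psi) drawn from the wrapped mixture."""
        weights = np.array([b.weight for b in self.basins])
        comp = rng.choice(len(self.basins), size=n, p=weights)
        out = np.empty((n, 2))
        for k, basin in enumerate(self.basins):
            m = comp == k
            cnt = int(m.sum())
            if cnt:
                out[m, 0] = rng.normal(basin.phi, basin.sd, size=cnt)
                out[m, 1] = rng.normal(basin.psi, basin.sd, size=cnt)
        return wrap_angle(out)

    def component_of(self, samples: np.ndarray) -> np.ndarray:
        """Nearest-basin (periodic distance) classification of (phi, psi) samples."""
        d = []
        for basin in self.basins:
            dp = wrap_angle(samples[:, 0] - basin.phi)
            ds = wrap_angle(samples[:, 1] - basin.psi)
            d.append(dp**2 + ds**2)
        return np.argmin(np.array(d), axis=0)

    def marginal_pdf(self, axis: int, theta_deg: np.ndarray, n_wrap: int = 5):
        """Wrapped-normal mixture density of phi (axis 0) or psi (axis 1)."""
        theta = np.asarray(theta_deg, dtype=float)
        pdf = np.zeros_like(theta)
        for basin in self.basins:
            mu = (basin.phi, basin.psi)[axis]
            for k in range(-n_wrap, n_wrap + 1):
                x = theta - mu + 360.0 * k
                pdf += (
                    basin.weight
                    * np.exp(-0.5 * (x / basin.sd) ** 2)
                    / (basin.sd * math.sqrt(2 * math.pi))
                )
        return pdf


@dataclass
class GroundTruth:
    """What the generator actually did, for oracle-style checks."""

    adsorbed: np.ndarray  # (n_frames, n_molecules) bool
    radial_center: np.ndarray  # (n_frames, n_molecules) angstrom
    torsions: dict = field(default_factory=dict)  # molid -> (n_frames, n_links, 2)


# ---------------------------------------------------------------------------
# generation


def _pose_rotation(rng, template, face_a_idx, face_b_idx, inward, facing,
                   angle_sd_deg):
    """Rotation presenting the requested face toward the tube axis."""
    if facing == "iso" or face_a_idx is None:
        return _uniform_rotation(rng)
    f = normalize(
        template[face_a_idx].mean(axis=0) - template[face_b_idx].mean(axis=0)
    )
    spin = rotation_about_axis(f, rng.uniform(0.0, 360.0))
    target = inward if facing == "A" else -inward
    align = rotation_aligning(spin @ f, target)
    # tilt noise: gaussian angle about a random axis perpendicular to target
    perp = np.cross(target, _random_unit(rng))
    while np.linalg.norm(perp) < 1e-8:
        perp = np.cross(target, _random_unit(rng))
    tilt = rotation_about_axis(perp, rng.normal(0.0, angle_sd_deg))
    return tilt @ align @ spin


def _uniform_rotation(rng):
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


def _random_unit(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _principal_axis(points):
    c = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    return vt[0]


def generate(system: System, scenario: AdsorptionScenario,
             torsions: TorsionSurfaceSpec | None = None,
             n_frames: int = 100, seed: int = 0,
             interval_ps: float = FRAME_INTERVAL_PS,
             tube_radius: float | None = None):
    """Synthesize a trajectory over the assembled system.

    Non-glycan atoms (tube, ions) stay at their assembled positions; each
    glycan molecule is re-posed every frame as a rigid body whose state
    follows the two-state chain, optionally with linkage torsions redrawn
    from ``torsions``.  Deterministic for a fixed seed.  Returns
    ``(Trajectory, GroundTruth)``.
    """
    rng = np.random.default_rng(seed)
    box = np.asarray(system.box, dtype=float)
    axis_xy = system.axis_xy
    if tube_radius is None:
        tube_radius = system.fcnt.radius() if system.fcnt is not None else 7.0
    r_ads_mean = scenario.r_ads_mean
    if r_ads_mean is None:
        r_ads_mean = tube_radius + 4.0
    r_des_max = scenario.r_des_max
    if r_des_max is None:
        r_des_max = min(box[0], box[1]) / 2.0 - 1.0

    mol_ids = system.molecule_ids("glycan")
    n_mol = len(mol_ids)
    templates = {}
    face_idx = {}
    for mid in mol_ids:
        idx = system.indices(molclass="glycan", molid=mid)
        tpl_chain = _template_chain(system, mid)
        templates[mid] = (idx, tpl_chain)
        if tpl_chain is not None and len(tpl_chain.residues) == 1:
            code = tpl_chain.residues[0].code
            a_names = glycan_mod.face_atoms(code, "A")
            b_names = glycan_mod.face_atoms(code, "B")
            names = tpl_chain.residues[0].names
            face_idx[mid] = (
                [names.index(n) for n in a_names],
                [names.index(n) for n in b_names],
            )
        else:
            face_idx[mid] = (None, None)

    positions = np.tile(system.positions[None, :, :], (n_frames, 1, 1))
    adsorbed = np.zeros((n_frames, n_mol), dtype=bool)
    radial_center = np.zeros((n_frames, n_mol))
    truth_torsions = {}

    # initial states
    state = np.zeros(n_mol, dtype=bool)
    if scenario.initial_state == "adsorbed":
        state[:] = True
    elif scenario.initial_state == "desorbed":
        state[:] = False
    else:
        state[:] = rng.random(n_mol) < scenario.stationary_adsorbed_fraction

    for f in range(n_frames):
        if f > 0:
            detach = rng.random(n_mol) < scenario.p_detach
            attach = rng.random(n_mol) < scenario.p_attach
            state = np.where(state, ~detach, attach)
        adsorbed[f] = state
        for m, mid in enumerate(mol_ids):
            idx, tpl_chain = templates[mid]
            if torsions is not None and tpl_chain is not None and tpl_chain.linkages:
                tor = torsions.sample(rng, len(tpl_chain.linkages))
                tpl_chain = glycan_mod.rebuild_with_torsions(tpl_chain, tor)
                truth_torsions.setdefault(mid, []).append(tor)
            tpl = tpl_chain.positions if tpl_chain is not None else \
                system.positions[idx]
            tpl = tpl - tpl.mean(axis=0)

            alpha = rng.uniform(0.0, 2.0 * math.pi)
            inward = -np.array([math.cos(alpha), math.sin(alpha), 0.0])
            if state[m]:
                r_c = rng.normal(r_ads_mean, scenario.r_ads_sd)
                r_c = max(r_c, tube_radius + 1.5)
            else:
                extent = float(np.linalg.norm(tpl, axis=1).max())
                lo = scenario.r_des_min + extent + 0.1
                hi = max(r_des_max, lo + 0.5)
                r_c = rng.uniform(lo, hi)

            if tpl_chain is not None and len(tpl_chain.residues) > 1:
                # chains lie along the tube axis when adsorbed
                rot_axis = rotation_aligning(_principal_axis(tpl), [0.0, 0.0, 1.0])
                spin = rotation_about_axis([0.0, 0.0, 1.0], rng.uniform(0, 360.0))
                rot = spin @ rot_axis
            else:
                fa, fb = face_idx[mid]
                rot = _pose_rotation(rng, tpl, fa, fb, inward,
                                     scenario.facing, scenario.angle_sd_deg)
            posed = tpl @ rot.T

            if state[m] and scenario.monolayer_radius is not None:
                # keep every atom of an adsorbed molecule inside the monolayer
                radial_extent = float(
                    np.linalg.norm((posed - posed.mean(axis=0))[:, :2], axis=1).max()
                )
                r_c = min(r_c, scenario.monolayer_radius - radial_extent - 0.05)
                r_c = max(r_c, tube_radius + 1.0)

            center = np.array(
                [
                    axis_xy[0] - inward[0] * r_c,
                    axis_xy[1] - inward[1] * r_c,
                    rng.uniform(0.0, box[2]),
                ]
            )
            frame_pos = posed + center
            if scenario.jitter_sd > 0:
                frame_pos = frame_pos + rng.normal(
                    0.0, scenario.jitter_sd, size=frame_pos.shape
                )
            positions[f, idx] = frame_pos
            radial_center[f, m] = r_c

    traj = Trajectory(
        positions=positions,
        box=box,
        times=np.arange(n_frames, dtype=float) * interval_ps,
        atoms=system.atoms.copy(),
    )
    truth = GroundTruth(
        adsorbed=adsorbed,
        radial_center=radial_center,
        torsions={k: np.array(v) for k, v in truth_torsions.items()},
    )
    return traj, truth


def _template_chain(system: System, molid: int):
    """Recover the template chain backing a placed molecule, if known."""
    glycan_mols = system.molecule_ids("glycan")
    if not system.glycan_templates:
        return None
    # copies were placed template-by-template in order
    n_per = len(glycan_mols) // len(system.glycan_templates)
    if n_per == 0:
        return None
    t_index = min(glycan_mols.index(molid) // n_per,
                  len(system.glycan_templates) - 1)
    return system.glycan_templates[t_index]


def static_trajectory(system: System, n_frames: int,
                      interval_ps: float = FRAME_INTERVAL_PS) -> Trajectory:
    """All frames identical to the assembled coordinates (scripted baseline)."""
    return Trajectory(
        positions=np.tile(system.positions[None, :, :], (n_frames, 1, 1)),
        box=np.asarray(system.box, dtype=float),
        times=np.arange(n_frames, dtype=float) * interval_ps,
        atoms=system.atoms.copy(),
    )
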