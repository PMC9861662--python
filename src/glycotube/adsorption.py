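"""Axis-referenced adsorption structure: radial density profiles,
monolayer metrics, face-orientation classification, detachment events.

The radial density profile histograms the distance of selected atoms
from the tube axis over all frames, in raw counts (each count is one
atom observed once at that distance, as in the study's profiles).  A
monolayer shows up as all counts inside 15 angstrom of the axis; the
density decays to (almost) zero by 20 angstrom unless molecules detach.

Orientation of an adsorbed monosaccharide is read off the profiles of
its two ring faces (side A = H1-H5, side B = H2-H4 or O4): the face
whose first density peak sits at the smaller radius is the one lying on
the surface.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import glycan as glycan_mod
from .geometry import minimum_image
from .trajectory import Trajectory

BIN_WIDTH_DEFAULT = 0.5  # angstrom
MONOLAYER_RADIUS = 15.0
DECAY_RADIUS = 20.0
PEAK_SEPARATION_TOL = 1.0  # angstrom; below this the side is indeterminate
PEAK_MIN_FRACTION = 0.05  # first peak must exceed 5% of the global maximum


@dataclass
class RadialProfile:
    edges: np.ndarray  # angstrom, from the axis
    counts: np.ndarray  # raw counts
    selection: str
    n_frames: int
    n_atoms: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def cumulative_fraction(self, radius: float) -> float:
        """Fraction of all counts at distances <= radius."""
        if self.total == 0:
            return 0.0
        inside = self.edges[1:] <= radius + 1e-12
        return float(self.counts[inside].sum() / self.total)


def radial_distances(traj: Trajectory, selection, axis_xy=None) -> np.ndarray:
    """(n_frames, n_sel) distances from the tube axis, minimum image in x,y."""
    selection = np.asarray(selection)
    if selection.size == 0:
        raise ValueError("empty selection")
    if axis_xy is None:
        axis_xy = traj.axis_xy
    delta = traj.positions[:, selection, :2] - np.asarray(axis_xy)[None, None, :]
    box_xy = np.array([traj.box[0], traj.box[1], 0.0])
    delta3 = np.concatenate([delta, np.zeros_like(delta[..., :1])], axis=-1)
    delta3 = minimum_image(delta3, box_xy)
    return np.linalg.norm(delta3[..., :2], axis=-1)


def radial_profile(traj: Trajectory, selection, axis_xy=None,
                   bin_width: float = BIN_WIDTH_DEFAULT,
                   r_max: float | None = None,
                   label: str = "") -> RadialProfile:
    """Histogram of axis distances over all selected atoms and frames."""
    r = radial_distances(traj, selection, axis_xy)
    if r_max is None:
        # cover the whole cross section so counts are conserved
        r_max = float(np.hypot(traj.box[0], traj.box[1]) / 2.0 + bin_width)
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts, _ = np.histogram(r.ravel(), bins=edges)
    return RadialProfile(
        edges=edges,
        counts=counts,
        selection=label,
        n_frames=traj.n_frames,
        n_atoms=len(np.asarray(selection)),
    )


@dataclass
class LayerMetrics:
    fraction_within_15: float
    fraction_within_20: float
    decay_radius: float  # smallest r beyond which cumulative fraction >= 0.99


def layer_metrics(profile: RadialProfile,
                  monolayer_radius: float = MONOLAYER_RADIUS,
                  decay_threshold: float = DECAY_RADIUS) -> LayerMetrics:
    cum = np.cumsum(profile.counts)
    total = cum[-1] if len(cum) else 0
    if total == 0:
        return LayerMetrics(0.0, 0.0, 0.0)
    frac = cum / total
    decay_idx = int(np.searchsorted(frac, 0.99))
    decay_radius = float(profile.edges[min(decay_idx + 1, len(profile.edges) - 1)])
    return LayerMetrics(
        fraction_within_15=profile.cumulative_fraction(monolayer_radius),
        fraction_within_20=profile.cumulative_fraction(decay_threshold),
        decay_radius=decay_radius,
    )


def first_peak_radius(profile: RadialProfile,
                      min_fraction: float = PEAK_MIN_FRACTION) -> float | None:
    """First local maximum of the 3-bin moving average above the noise floor."""
    c = profile.counts.astype(float)
    if c.sum() == 0:
        return None
    smooth = np.convolve(c, np.ones(3) / 3.0, mode="same")
    floor = min_fraction * smooth.max()
    centers = profile.centers
    for i in range(1, len(smooth) - 1):
        if smooth[i] < floor:
            continue
        if smooth[i] >= smooth[i - 1] and smooth[i] > smooth[i + 1]:
            return float(centers[i])
    i = int(np.argmax(smooth))
    return float(centers[i])


@dataclass
class OrientationResult:
    peak_a: float | None  # angstrom, first-peak radius of the H1-H5 face
    peak_b: float | None  # first-peak radius of the H2-H4(O4) face
    preferred: str  # 'A(H1-H5)' | 'B(H2-H4/O4)' | 'indeterminate'

    @property
    def separation(self) -> float | None:
        if self.peak_a is None or self.peak_b is None:
            return None
        return self.peak_b - self.peak_a


def orientation(traj: Trajectory, residue_code: str,
                axis_xy=None, bin_width: float = BIN_WIDTH_DEFAULT,
                separation_tol: float = PEAK_SEPARATION_TOL,
                molclass: str = "glycan") -> OrientationResult:
    """Which ring face the residue class presents to the tube surface.

    Builds side-A and side-B radial profiles over every molecule carrying
    the residue, takes the first peak of each, and prefers the side whose
    peak is nearer the axis; below ``separation_tol`` of separation the
    orientation is indeterminate.
    """
    resname = glycan_mod.PDB_RESNAMES[residue_code]
    profiles = {}
    for side in ("A", "B"):
        names = glycan_mod.face_atoms(residue_code, side)
        sel = traj.indices(molclass=molclass, resname=resname, names=names)
        if sel.size == 0:
            raise ValueError(f"no side-{side} atoms ({names}) for {residue_code}")
        profiles[side] = radial_profile(
            traj, sel, axis_xy=axis_xy, bin_width=bin_width,
            label=f"{residue_code} side {side}",
        )
    peak_a = first_peak_radius(profiles["A"])
    peak_b = first_peak_radius(profiles["B"])
    if peak_a is None or peak_b is None or abs(peak_b - peak_a) < separation_tol:
        preferred = "indeterminate"
    elif peak_a < peak_b:
        preferred = "A(H1-H5)"
    else:
        preferred = "B(H2-H4/O4)"
    return OrientationResult(peak_a=peak_a, peak_b=peak_b, preferred=preferred)


@dataclass
class DetachmentEvents:
    """Per-molecule excursions beyond the layer threshold."""

    events: dict  # molid -> list of (start_frame, end_frame) inclusive
    beyond_fraction: float  # fraction of molecule-frames beyond threshold
    r_threshold: float
    min_frames: int

    @property
    def n_events(self) -> int:
        return sum(len(v) for v in self.events.values())


def detachment_events(traj: Trajectory, molecule_ids=None,
                      r_threshold: float = DECAY_RADIUS, min_frames: int = 3,
                      axis_xy=None) -> DetachmentEvents:
    """Excursions of molecule centers beyond ``r_threshold``.

    The molecule position is the center of geometry of its ring atoms
    (names O5, C1-C5); an event requires the strict inequality
    r > r_threshold for at least ``min_frames`` consecutive frames.
    """
    if molecule_ids is None:
        molecule_ids = traj.molecule_ids("glycan")
    events = {}
    beyond_total = 0
    frames_total = 0
    for mid in molecule_ids:
        ring = traj.indices(molclass="glycan", molid=mid,
                            names=list(glycan_mod.RING_ORDER))
        if ring.size == 0:
            ring = traj.indices(molclass="glycan", molid=mid)
        cog = traj.positions[:, ring, :].mean(axis=1)  # (n_frames, 3)
        ax = traj.axis_xy if axis_xy is None else np.asarray(axis_xy)
        delta = np.zeros_like(cog)
        delta[:, :2] = cog[:, :2] - ax[None, :]
        delta = minimum_image(delta, np.array([traj.box[0], traj.box[1], 0.0]))
        center_r = np.linalg.norm(delta[:, :2], axis=1)
        beyond = center_r > r_threshold
        beyond_total += int(beyond.sum())
        frames_total += len(beyond)
        ev = []
        start = None
        for f, b in enumerate(beyond):
            if b and start is None:
                start = f
            elif not b and start is not None:
                if f - start >= min_frames:
                    ev.append((start, f - 1))
                start = None
        if start is not None and len(beyond) - start >= min_frames:
            ev.append((start, len(beyond) - 1))
        events[mid] = ev
    fraction = beyond_total / frames_total if frames_total else 0.0
    return DetachmentEvents(
        events=events,
        beyond_fraction=fraction,
        r_threshold=r_threshold,
        min_frames=min_frames,
    )
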