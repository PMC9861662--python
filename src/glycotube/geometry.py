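"""Small geometry kernel: dihedrals, internal-coordinate placement, rigid fits.

These primitives are shared by the builders (chain growth by torsion),
the synthetic-trajectory generator (rigid-body poses) and the conformation
analyses (torsion measurement, superposition for RMSF).
"""
from __future__ import annotations

import numpy as np


def normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("cannot normalize a zero vector")
    return v / n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees, IUPAC convention (cis = 0).

    Mirror-image coordinates flip the sign; the value lies in (-180, 180].
    Raises ValueError when three consecutive atoms are collinear.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("collinear atoms: dihedral undefined")
    m = np.cross(n1, normalize(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m, n2))
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if np.isclose(ang, -180.0) else float(ang)


def dihedral_batch(p0, p1, p2, p3) -> np.ndarray:
    """Vectorized signed dihedral over leading axes; degrees in (-180, 180]."""
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    m = np.cross(n1, b2n)
    x = np.einsum("...i,...i", n1, n2)
    y = np.einsum("...i,...i", m, n2)
    ang = np.degrees(np.arctan2(y, x))
    return np.where(np.isclose(ang, -180.0), 180.0, ang)


def nerf_place(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D from internal coordinates relative to chain A-B-C.

    ``bond`` is |C-D|, ``angle_deg`` the B-C-D angle and ``dihedral_deg`` the
    A-B-C-D torsion, with the same sign convention as :func:`dihedral`.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = np.radians(angle_deg)
    chi = np.radians(dihedral_deg)
    bc = normalize(c - b)
    n = normalize(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(chi), -np.sin(theta) * np.sin(chi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def kabsch(mobile: np.ndarray, target: np.ndarray):
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns (R, t) with target ~= mobile @ R.T + t.  Proper rotation only
    (reflections are repaired through the determinant sign trick).
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    return rot, tc - rot @ mc


def apply_rigid(positions: np.ndarray, rot: np.ndarray, trans: np.ndarray) -> np.ndarray:
    return positions @ rot.T + trans


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis``."""
    axis = normalize(np.asarray(axis, dtype=float))
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    x, y, z = axis
    k = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) * c + s * k + (1 - c) * np.outer(axis, axis)


def rotation_aligning(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector ``src`` onto unit vector ``dst``."""
    src = normalize(np.asarray(src, float))
    dst = normalize(np.asarray(dst, float))
    c = float(np.dot(src, dst))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # pick any perpendicular axis for the 180 degree flip
        perp = np.cross(src, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-8:
            perp = np.cross(src, [0.0, 1.0, 0.0])
        return rotation_about_axis(perp, 180.0)
    axis = np.cross(src, dst)
    angle = np.degrees(np.arctan2(np.linalg.norm(axis), c))
    return rotation_about_axis(axis, angle)


def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the nearest periodic image.

    ``box`` holds orthorhombic edge lengths; entries <= 0 mark
    non-periodic directions and are left untouched.
    """
    delta = np.array(delta, dtype=float, copy=True)
    box = np.asarray(box, dtype=float)
    for k in range(3):
        if box[k] > 0:
            delta[..., k] -= box[k] * np.round(delta[..., k] / box[k])
    return delta


def wrap_angle(deg):
    """Wrap angles in degrees into (-180, 180]."""
    wrapped = np.mod(np.asarray(deg, dtype=float) + 180.0, 360.0) - 180.0
    return np.where(wrapped == -180.0, 180.0, wrapped)
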