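"""Low-level rigid-body and torsion geometry shared by all analysis stages.

Frames are represented as (origin, triad) where ``triad`` is a 3x3 matrix
whose *columns* are the x, y and z unit vectors expressed in lab coordinates.
All public angles are in degrees, all distances in Angstrom.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "wrap_angle",
    "rotation_about",
    "orthonormalize",
    "half_rotation",
    "decompose_frames",
    "compose_frames",
    "mid_frame",
    "signed_dihedral",
    "nerf_place",
    "superpose",
]


def wrap_angle(deg: float | np.ndarray) -> float | np.ndarray:
    """Wrap an angle in degrees to the interval (-180, 180]."""
    wrapped = np.mod(np.asarray(deg, dtype=float) + 180.0, 360.0) - 180.0
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    return float(wrapped) if np.ndim(deg) == 0 else wrapped


def rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis``."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0.0:
        raise ValueError("rotation axis must be non-zero")
    return Rotation.from_rotvec(axis / n * np.deg2rad(angle_deg)).as_matrix()


def orthonormalize(m: np.ndarray) -> np.ndarray:
    """Project a near-rotation 3x3 matrix onto SO(3) (special orthogonal)."""
    u, _, vt = np.linalg.svd(m)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


def half_rotation(r: np.ndarray) -> np.ndarray:
    """Geodesic square root of a rotation matrix (half the rotation angle)."""
    rv = Rotation.from_matrix(r).as_rotvec()
    return Rotation.from_rotvec(rv / 2.0).as_matrix()


def mid_frame(
    triad1: np.ndarray, triad2: np.ndarray, origin1: np.ndarray, origin2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mid frame between two frames: half-rotation triad, averaged origin."""
    rel = triad1.T @ triad2
    tm = triad1 @ half_rotation(rel)
    om = 0.5 * (np.asarray(origin1, float) + np.asarray(origin2, float))
    return om, tm


def decompose_frames(
    triad1: np.ndarray,
    triad2: np.ndarray,
    origin1: np.ndarray,
    origin2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Symmetric decomposition of the motion from frame 1 to frame 2.

    The relative rotation ``R = T1^T T2`` is factored in the symmetric
    El Hassan-Calladine form ``R = Rz(w/2 - p) Ry(G) Rz(w/2 + p)`` with the
    bend ``G`` split into components about the mid-frame y (roll-like) and
    x (tilt-like) directions; ``w`` is the twist-like angle about z.
    Translations are the origin displacement projected on the mid frame.

    Returns ``(rotations, translations, mid_origin, mid_triad)`` where
    ``rotations = (about_x, about_y, about_z)`` in degrees.  For basepair
    steps this is (tilt, roll, twist)/(shift, slide, rise); for intra-pair
    geometry it is (buckle, propeller, opening).
    """
    rel = triad1.T @ triad2
    with warnings.catch_warnings():
        # A pure twist (zero bend) gimbal-locks the ZYZ factorization; the
        # (a, b) split is then arbitrary but a + b and the bend stay exact.
        warnings.simplefilter("ignore", UserWarning)
        a, gamma, b = Rotation.from_matrix(rel).as_euler("ZYZ")
    omega = a + b
    phi = 0.5 * (b - a)
    # Keep the twist-like angle in (-pi, pi]; the compensating half-turn in
    # the bend phase keeps the factorization identical.
    if omega > np.pi:
        omega -= 2.0 * np.pi
        phi += np.pi
    elif omega <= -np.pi:
        omega += 2.0 * np.pi
        phi += np.pi
    about_z = np.rad2deg(omega)
    about_y = np.rad2deg(gamma * np.cos(phi))
    about_x = np.rad2deg(gamma * np.sin(phi))
    om, tm = mid_frame(triad1, triad2, origin1, origin2)
    disp = np.asarray(origin2, float) - np.asarray(origin1, float)
    translations = tm.T @ disp
    rotations = np.array([wrap_angle(about_x), wrap_angle(about_y), wrap_angle(about_z)])
    return rotations, translations, om, tm


def compose_frames(
    triad1: np.ndarray,
    origin1: np.ndarray,
    rotations_deg: np.ndarray,
    translations: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact inverse of :func:`decompose_frames`.

    Given frame 1 and the six parameters, return ``(origin2, triad2)`` such
    that decomposing (frame1, frame2) reproduces the parameters.
    """
    rx, ry, rz = np.deg2rad(np.asarray(rotations_deg, dtype=float))
    gamma = np.hypot(rx, ry)
    phi = np.arctan2(rx, ry) if gamma > 0.0 else 0.0
    omega = rz
    rel = Rotation.from_euler(
        "ZYZ", [omega / 2.0 - phi, gamma, omega / 2.0 + phi]
    ).as_matrix()
    triad2 = triad1 @ rel
    tm = triad1 @ half_rotation(rel)
    origin2 = np.asarray(origin1, float) + tm @ np.asarray(translations, float)
    return origin2, triad2


def signed_dihedral(
    p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray
) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b1 = np.asarray(p1, float) - np.asarray(p0, float)
    b2 = np.asarray(p2, float) - np.asarray(p1, float)
    b3 = np.asarray(p3, float) - np.asarray(p2, float)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = n1 @ n2
    y = m1 @ n2
    return float(wrap_angle(np.rad2deg(np.arctan2(-y, x))))


def nerf_place(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle_deg: float,
    dihedral_deg: float,
) -> np.ndarray:
    """Place atom D bonded to C with given C-D bond length, B-C-D angle and
    A-B-C-D dihedral (natural-extension-of-reference-frame construction)."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    theta = np.deg2rad(angle_deg)
    chi = np.deg2rad(dihedral_deg)
    d_local = bond * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(chi), np.sin(theta) * np.sin(chi)]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def superpose(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns ``(rot, shift, rmsd)`` with ``rot @ x + shift`` the fitted map
    (Kabsch algorithm via SVD; proper rotation enforced).
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must be matched (n, 3) arrays")
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    h = (mobile - cm).T @ (target - ct)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    shift = ct - rot @ cm
    moved = mobile @ rot.T + shift
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return rot, shift, rmsd
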