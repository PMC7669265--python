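"""Small rotation helpers shared by the phantom generator and the aligner.

All vectors are in (z, y, x) component order, matching array axes.
Rotation matrices act on such vectors: ``v_rotated = R @ v``.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

_FLIP = np.eye(3)[::-1]  # reverses (x, y, z) <-> (z, y, x) component order

X_AXIS = np.array([0.0, 0.0, 1.0])  # +X grid axis in (z, y, x) order


def _to_zyx(r_xyz: np.ndarray) -> np.ndarray:
    return _FLIP @ r_xyz @ _FLIP


def rotation_about_yz(angle_y_deg: float, angle_z_deg: float) -> np.ndarray:
    """Rigid rotation: first about the Y axis, then about the Z axis.

    Applied to a rod lying along +X this tilts it out of the XY plane
    (Y rotation) and swings it within the XY plane (Z rotation).
    """
    # extrinsic sequence: the Y rotation is applied first, then the Z rotation
    r = Rotation.from_euler("yz", [angle_y_deg, angle_z_deg], degrees=True)
    return _to_zyx(r.as_matrix())


def rotation_to_x(direction: np.ndarray) -> np.ndarray:
    """Minimal rotation taking the unit vector ``direction`` (zyx) onto +X."""
    d = np.asarray(direction, dtype=float)
    n = np.linalg.norm(d)
    if not np.isfinite(n) or n == 0:
        raise ValueError("direction must be a nonzero finite vector")
    d = d / n
    c = float(d @ X_AXIS)
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        # 180° turn: rotate about Z (any axis perpendicular to X works)
        return np.diag([1.0, -1.0, -1.0])
    # Work in xyz order for the Rodrigues step, then convert once.
    d_xyz = d[::-1]
    axis_xyz = np.cross(d_xyz, [1.0, 0.0, 0.0])
    angle = np.arccos(np.clip(c, -1.0, 1.0))
    axis_xyz = axis_xyz / np.linalg.norm(axis_xyz)
    r_xyz = Rotation.from_rotvec(angle * axis_xyz).as_matrix()
    return _to_zyx(r_xyz)


def angle_between_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Unsigned angle between two direction vectors, in degrees (axis-like: <= 90°)."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    c = abs(float(u @ v)) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
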