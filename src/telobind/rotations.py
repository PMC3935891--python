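"""Best-fit rigid-body rotations and their Euler decomposition.

The orientation of the protein relative to its initial structure is the
Kabsch rotation (mass-weighted least-squares after centroid removal, proper
rotation enforced), decomposed as R = R_x(a) R_y(b) R_z(c) with
b in [-pi/2, pi/2]; at gimbal lock (|cos b| ~ 0) the convention a = 0 is
applied.
"""

from __future__ import annotations

import numpy as np

__all__ = ["best_fit_rotation", "euler_xyz", "rotation_xyz", "superpose"]


def best_fit_rotation(coords: np.ndarray, reference: np.ndarray,
                      masses: np.ndarray | None = None) -> np.ndarray:
    """Kabsch rotation R (3x3, det +1) minimizing the mass-weighted RMSD of
    ``R @ (reference - centroid)`` to ``coords - centroid``: R carries the
    reference orientation onto the instantaneous one, so a structure that is
    the reference rotated by R0 yields exactly R0."""
    x = np.asarray(coords, dtype=float)
    y = np.asarray(reference, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3 or x.shape[0] < 3:
        raise ValueError("need matched (n>=3, 3) coordinate arrays")
    w = np.ones(x.shape[0]) if masses is None else np.asarray(masses, float)
    w = w / w.sum()
    xc = x - np.average(x, axis=0, weights=w)
    yc = y - np.average(y, axis=0, weights=w)
    h = (w[:, None] * yc).T @ xc
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-12 * max(s[0], 1e-300):
        raise ValueError("degenerate (collinear) coordinates: rotation "
                         "is not uniquely defined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    return vt.T @ flip @ u.T


def rotation_xyz(theta_x: float, theta_y: float, theta_z: float) -> np.ndarray:
    """Compose R = R_x R_y R_z from the three axis rotations."""
    ca, sa = np.cos(theta_x), np.sin(theta_x)
    cb, sb = np.cos(theta_y), np.sin(theta_y)
    cc, sc = np.cos(theta_z), np.sin(theta_z)
    rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    rz = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
    return rx @ ry @ rz


def euler_xyz(R: np.ndarray, tol: float = 1e-6) -> tuple[float, float, float]:
    """Angles (theta_x, theta_y, theta_z) with R = R_x R_y R_z.

    theta_y in [-pi/2, pi/2]; gimbal lock (|cos theta_y| < 1e-8) resolved by
    theta_x = 0.  Raises if R is not orthonormal with det +1 (within tol).
    """
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3) \
            or np.abs(R @ R.T - np.eye(3)).max() > 10 * tol \
            or abs(np.linalg.det(R) - 1.0) > 10 * tol:
        raise ValueError("input is not a proper rotation matrix")
    # R[0,2] = sin(b); R[0,0] = cb*cc; R[0,1] = -cb*sc;
    # R[1,2] = -sa*cb; R[2,2] = ca*cb
    sb = np.clip(R[0, 2], -1.0, 1.0)
    b = np.arcsin(sb)
    if abs(np.cos(b)) < 1e-8:
        a = 0.0
        # with a = 0 and b = +-pi/2: R[1,0] = sc*?  -> use R[1,1], R[1,0]
        c = np.arctan2(R[1, 0], R[1, 1])
    else:
        a = np.arctan2(-R[1, 2], R[2, 2])
        c = np.arctan2(-R[0, 1], R[0, 0])
    return float(a), float(b), float(c)


def superpose(coords: np.ndarray, reference: np.ndarray,
              masses: np.ndarray | None = None) -> np.ndarray:
    """Coordinates rigidly fitted (rotation + translation) onto the
    reference; used before covariance/occupancy analyses."""
    R = best_fit_rotation(coords, reference, masses)
    w = (np.ones(coords.shape[0]) if masses is None
         else np.asarray(masses, float))
    w = w / w.sum()
    cx = np.average(coords, axis=0, weights=w)
    cy = np.average(reference, axis=0, weights=w)
    # coords ~ R @ reference, so the inverse map is a right-multiply by R
    return (coords - cx) @ R + cy
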