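"""Small rigid-body geometry helpers shared across the package."""

from __future__ import annotations

import numpy as np

__all__ = ["kabsch", "rotation_about_axis", "unit"]


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("cannot normalise the zero vector")
    return v / n


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis`` (Rodrigues)."""
    k = unit(axis)
    theta = np.deg2rad(angle_deg)
    K = np.array([
        [0, -k[2], k[1]],
        [k[2], 0, -k[0]],
        [-k[1], k[0], 0],
    ])
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)


def kabsch(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``moving`` onto ``fixed``.

    Returns ``(R, t, rmsd)`` such that ``moving @ R.T + t`` best fits
    ``fixed``; R is a proper rotation (det = +1, reflections excluded by
    the usual sign correction on the smallest singular value).
    """
    P = np.asarray(moving, float)
    Q = np.asarray(fixed, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"point sets must both be (n, 3); got {P.shape} and {Q.shape}")
    if len(P) < 3:
        raise ValueError(f"need at least 3 points for superposition, got {len(P)}")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff ** 2).sum() / len(P)))
    return R, t, rmsd
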