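"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: superposition via
Horn's quaternion method instead of Kabsch/SVD, interface detection via
a dense all-pairs distance scan instead of a KD-tree, and plane fitting
via an SVD of raw coordinates instead of helix-axis averaging.
"""

from __future__ import annotations

import numpy as np


def quaternion_superpose(moving: np.ndarray, fixed: np.ndarray):
    """Horn's closed-form quaternion superposition of moving onto fixed.

    Returns (R, t, rmsd).
    """
    P = np.asarray(moving, float)
    Q = np.asarray(fixed, float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    A = P - pc
    B = Q - qc
    M = A.T @ B
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    eigvals, eigvecs = np.linalg.eigh(K)
    q = eigvecs[:, -1]  # eigenvector of the largest eigenvalue
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = qc - R @ pc
    diff = P @ R.T + t - Q
    rmsd = float(np.sqrt((diff ** 2).sum() / len(P)))
    return R, t, rmsd


def brute_force_interface(complex_model, cutoff: float):
    """Interface residue sets via a dense all-pairs distance scan."""
    xs, rs = complex_model.subject.atom_array()
    xp, rp = complex_model.partner.atom_array()
    d = np.linalg.norm(xs[:, None, :] - xp[None, :, :], axis=2)
    mask = d < cutoff
    subj = {int(r) for r in rs[mask.any(axis=1)]}
    part = {int(r) for r in rp[mask.any(axis=0)]}
    return subj, part


def brute_force_helix_counts(complex_model, cutoff: float):
    """Interface-residue count per subject TM helix from the dense scan."""
    subj, _ = brute_force_interface(complex_model, cutoff)
    counts: dict[int, int] = {}
    for resseq in subj:
        seg = complex_model.subject.segment_of(resseq)
        if seg is not None and not seg.is_h8:
            counts[seg.index] = counts.get(seg.index, 0) + 1
    return counts


def svd_plane_normal(points: np.ndarray) -> np.ndarray:
    """Least-squares plane normal of a point cloud (smallest-variance axis)."""
    X = np.asarray(points, float)
    X = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    return vt[-1]
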