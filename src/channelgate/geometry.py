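"""Rigid-body superposition primitives (Kabsch) shared across modules."""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import GeometryError, InputError

_DEGENERACY_TOL = 1e-8


def superpose(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rigid superposition of paired point sets (Kabsch).

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best matches ``reference`` in
    the least-squares sense; the rotation is proper (det +1).

    Raises :class:`GeometryError` for degenerate input (fewer than three
    points, or collinear/coincident points, where the rotation is not
    unique).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise InputError("mobile and reference must have identical shapes")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise GeometryError("superposition needs >= 3 paired 3D points")

    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    mc, rc = mobile - cm, reference - cr
    # collinear or coincident sets leave a free rotation axis
    spread = np.linalg.svd(mc, compute_uv=False)
    scale = max(spread[0], 1.0)
    if spread[1] / scale < _DEGENERACY_TOL:
        raise GeometryError("degenerate (collinear or coincident) point set")

    rot, rssd = Rotation.align_vectors(rc, mc)
    rotation = rot.as_matrix()
    translation = cr - rotation @ cm
    rmsd = rssd / np.sqrt(mobile.shape[0])
    return rotation, translation, float(rmsd)


def apply_transform(coords: np.ndarray, rotation: np.ndarray,
                    translation: np.ndarray) -> np.ndarray:
    return coords @ rotation.T + translation


def rmsd_after_superposition(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD between two conformations over rigid motions."""
    _, _, rmsd = superpose(np.asarray(a), np.asarray(b))
    return rmsd


def batched_min_rmsd(frames: np.ndarray, references: np.ndarray) -> np.ndarray:
    """Minimum RMSD of every frame against every reference conformation.

    ``frames``: (F, N, 3); ``references``: (K, N, 3).  Returns (F, K).
    Uses the closed-form Kabsch objective via batched 3x3 SVD: with both
    sets centered, min RMSD^2 = (|P|^2 + |Q|^2 - 2 * sum of corrected
    singular values of P^T Q) / N, the smallest singular value signed by
    det(V U^T) to enforce a proper rotation.
    """
    frames = np.asarray(frames, dtype=np.float64)
    references = np.asarray(references, dtype=np.float64)
    if frames.shape[-2:] != references.shape[-2:]:
        raise InputError("frames and references must share (n_atoms, 3)")
    n = frames.shape[1]
    fc = frames - frames.mean(axis=1, keepdims=True)
    rc = references - references.mean(axis=1, keepdims=True)
    f_sq = np.einsum("fni,fni->f", fc, fc)
    r_sq = np.einsum("kni,kni->k", rc, rc)
    # covariance per (frame, reference) pair: (F, K, 3, 3)
    cov = np.einsum("fni,knj->fkij", fc, rc)
    u, s, vt = np.linalg.svd(cov)
    det = np.linalg.det(u) * np.linalg.det(vt)
    s[..., -1] *= np.sign(det)
    msd = (f_sq[:, None] + r_sq[None, :] - 2.0 * s.sum(axis=-1)) / n
    return np.sqrt(np.maximum(msd, 0.0))


def rotation_angle_about_axis(rotation: np.ndarray, axis: np.ndarray) -> float:
    """Signed right-handed rotation angle component about a unit axis (deg).

    Axis-angle decomposition of the rotation, projected onto ``axis``.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    rotvec = Rotation.from_matrix(rotation).as_rotvec(degrees=True)
    return float(rotvec @ axis)


def rotation_total_angle(rotation: np.ndarray) -> float:
    """Total rotation angle (deg) of a rotation matrix."""
    return float(np.linalg.norm(Rotation.from_matrix(rotation).as_rotvec(degrees=True)))


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Right-handed rotation matrix about an axis (degrees)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return Rotation.from_rotvec(np.deg2rad(angle_deg) * axis).as_matrix()


def rotations_about_axis(axis: np.ndarray, angles_deg: np.ndarray) -> np.ndarray:
    """Stack of right-handed rotation matrices about one axis, (F, 3, 3)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    rotvecs = np.deg2rad(np.asarray(angles_deg, dtype=float))[:, None] * axis
    return Rotation.from_rotvec(rotvecs).as_matrix()
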