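"""Kabsch least-squares superposition and batch RMSD."""

from __future__ import annotations

import numpy as np

__all__ = ["kabsch_rotation", "superpose", "rmsd", "pairwise_rmsd_matrix"]


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal rotation matrix mapping centered ``mobile`` onto ``reference``."""
    h = mobile.T @ reference
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    correction = np.diag([1.0, 1.0, d])
    return u @ correction @ vt


def superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Rigid-body fit of ``mobile`` (n_atoms, 3) onto ``reference``."""
    mc = mobile - mobile.mean(axis=0)
    rc_mean = reference.mean(axis=0)
    rot = kabsch_rotation(mc, reference - rc_mean)
    return mc @ rot + rc_mean


def rmsd(a: np.ndarray, b: np.ndarray, superposition: bool = True) -> float:
    """Backbone RMSD (A) between two coordinate sets, after optimal fit."""
    if superposition:
        a = superpose(a, b)
        b = b  # already in place
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def pairwise_rmsd_matrix(coords: np.ndarray) -> np.ndarray:
    """All-pairs minimum RMSD for frames (n_frames, n_atoms, 3).

    Each pair is superposed independently (no global reference).  Uses the
    closed-form Kabsch RMSD via batched 3x3 SVDs, so the full matrix for a
    few hundred frames takes seconds.
    """
    x = np.asarray(coords, dtype=float)
    n, m, _ = x.shape
    xc = x - x.mean(axis=1, keepdims=True)
    sq = np.einsum("nai,nai->n", xc, xc)
    # 3x3 cross-covariances for every ordered pair
    h = np.einsum("nai,maj->nmij", xc, xc)
    s = np.linalg.svd(h, compute_uv=False)
    det = np.linalg.det(h)
    trace = s[..., 0] + s[..., 1] + np.where(det < 0, -s[..., 2], s[..., 2])
    d2 = (sq[:, None] + sq[None, :] - 2.0 * trace) / m
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(np.maximum(d2, 0.0))
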