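"""Backbone torsion angles and circular arithmetic.

All angles in this package are handled in degrees, wrapped into the
half-open interval (-180, 180] (-180 normalizes to +180).  Radians appear
only transiently inside trigonometric calls.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "wrap_angle",
    "circular_difference",
    "dihedral",
    "compute_phi_psi",
]

#: cross-product norm below which four atoms are treated as degenerate
#: (colinear triple) and the dihedral is undefined.
DEGENERATE_CROSS_NORM = 1e-8


def wrap_angle(angle_deg):
    """Wrap angle(s) in degrees into (-180, 180].

    Works elementwise on arrays; NaN propagates (undefined angles stay
    undefined).
    """
    a = np.asarray(angle_deg, dtype=float)
    wrapped = np.mod(a - 180.0, -360.0) + 180.0
    if wrapped.ndim == 0:
        return float(wrapped)
    return wrapped


def circular_difference(a_deg, b_deg):
    """Signed circular deviation ``wrap(a - b)`` in degrees, in (-180, 180].

    Antisymmetric up to wrapping: ``circular_difference(a, b) ==
    -circular_difference(b, a)`` except when the deviation is exactly 180.
    Undefined (NaN) inputs yield NaN.
    """
    return wrap_angle(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float))


def dihedral(p0, p1, p2, p3):
    """Signed dihedral angle (degrees) of four points, IUPAC convention.

    Uses the atan2 formulation, which is numerically stable near +-90 deg.
    Supports stacked coordinates: inputs of shape (..., 3) give an output
    of shape (...).  Degenerate (colinear) triples yield NaN with a warning.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)

    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2

    n1 = np.cross(b0, b1)
    n2 = np.cross(b2, b1)
    degenerate = (np.linalg.norm(n1, axis=-1) < DEGENERATE_CROSS_NORM) | (
        np.linalg.norm(n2, axis=-1) < DEGENERATE_CROSS_NORM
    )

    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    ang = np.degrees(np.arctan2(y, x))

    if np.any(degenerate):
        warnings.warn(
            "degenerate (colinear) atom geometry: dihedral undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        ang = np.where(degenerate, np.nan, ang)
    return wrap_angle(ang)


def compute_phi_psi(trajectory):
    """Compute per-residue, per-frame backbone phi/psi for a trajectory.

    phi(k) is the dihedral C(k-1)-N(k)-CA(k)-C(k) and psi(k) is
    N(k)-CA(k)-C(k)-N(k+1).  Capping groups (an acetyl carbonyl carbon
    before residue 1, an N-methylamide nitrogen after the last residue)
    supply the terminal partner atoms; where a partner atom is absent the
    angle is undefined (NaN).

    Parameters
    ----------
    trajectory : turnprop.trajectory_io.Trajectory

    Returns
    -------
    turnprop.trajectory_io.TorsionSeries
    """
    from .trajectory_io import TorsionSeries

    top = trajectory.topology
    coords = trajectory.coordinates  # (n_frames, n_atoms, 3)
    n_frames = coords.shape[0]
    res_ids = top.amino_acid_ids()
    n_res = len(res_ids)

    phi = np.full((n_frames, n_res), np.nan)
    psi = np.full((n_frames, n_res), np.nan)

    def _atom(res_id, name):
        idx = top.atom_index(res_id, name)
        return None if idx is None else coords[:, idx, :]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for j, rid in enumerate(res_ids):
            n = _atom(rid, "N")
            ca = _atom(rid, "CA")
            c = _atom(rid, "C")
            if n is None or ca is None or c is None:
                continue
            c_prev = _atom(rid - 1, "C")
            if c_prev is not None:
                phi[:, j] = dihedral(c_prev, n, ca, c)
            n_next = _atom(rid + 1, "N")
            if n_next is not None:
                psi[:, j] = dihedral(n, ca, c, n_next)

    return TorsionSeries(
        residue_ids=list(res_ids),
        residue_names=[top.residue_name(r) for r in res_ids],
        phi=phi,
        psi=psi,
    )
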