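"""Beta-turn detection, classification and population tables.

A beta-turn is four consecutive residues i..i+3 with the Ca(i)-Ca(i+3)
distance strictly below 7 A and central residues that are not part of a
helix.  Turns are typed by the phi/psi of residues i+1 and i+2 against
the ideal Thornton quadruples: a classical type (I, I', II, II', VIII)
matches when all four circular deviations are within 30 deg, with at
most one angle allowed up to 45 deg (the relaxation PROMOTIF-style
assignment permits; a strict-30 mode disables it).  A window passing the
distance/non-helix criteria but matching no classical type is the
miscellaneous type IV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dihedrals import circular_difference
from .reference_data import CLASSICAL_TYPES, get_ideal_angles, get_turn_definition

__all__ = [
    "classify_turn_window",
    "classify_windows",
    "helical_residue_flags",
    "scan_turns",
    "population_table",
    "CA_DISTANCE_CUTOFF",
]

CA_DISTANCE_CUTOFF = 7.0  # Angstrom, strict '<'

#: alpha-helical region center and per-angle circular tolerance used for
#: the "central residues are not helical" exclusion
HELIX_CENTER = (-60.0, -47.0)
HELIX_TOLERANCE = 40.0
HELIX_MIN_RUN = 4  # helical residues must sit in a run of >= 4


def _deviations(phi1, psi1, phi2, psi2, ideal):
    return np.stack(
        [
            np.abs(circular_difference(phi1, ideal[0])),
            np.abs(circular_difference(psi1, ideal[1])),
            np.abs(circular_difference(phi2, ideal[2])),
            np.abs(circular_difference(psi2, ideal[3])),
        ],
        axis=-1,
    )


def classify_windows(phi1, psi1, phi2, psi2, ca_distance,
                     helical1=False, helical2=False, strict=False):
    """Vectorized turn-type assignment for arrays of windows.

    Returns an object array of labels ('I', ..., 'IV') with None for
    windows failing the distance or helix criteria or with undefined
    angles.  Ties between classical types (possible only through the
    one-angle relaxation) are broken by the smallest total deviation,
    then by the fixed priority order I, II, I', II', VIII.
    """
    phi1, psi1, phi2, psi2 = (np.atleast_1d(np.asarray(x, dtype=float))
                              for x in (phi1, psi1, phi2, psi2))
    ca_distance = np.broadcast_to(
        np.atleast_1d(np.asarray(ca_distance, dtype=float)), phi1.shape
    )
    helical1 = np.broadcast_to(np.atleast_1d(helical1), phi1.shape)
    helical2 = np.broadcast_to(np.atleast_1d(helical2), phi1.shape)

    defined = ~(np.isnan(phi1) | np.isnan(psi1) | np.isnan(phi2) | np.isnan(psi2))
    eligible = defined & (ca_distance < CA_DISTANCE_CUTOFF) & ~(helical1 & helical2)

    tol = get_turn_definition("I").tolerance_deg
    relaxed = get_turn_definition("I").relaxed_tolerance_deg

    n = phi1.shape[0]
    best_label = np.full(n, None, dtype=object)
    best_score = np.full(n, np.inf)
    # priority order: later types only replace on strictly smaller score
    for label in CLASSICAL_TYPES:
        dev = _deviations(phi1, psi1, phi2, psi2, get_ideal_angles(label))
        with np.errstate(invalid="ignore"):
            over_tol = np.sum(dev > tol, axis=-1)
            over_relaxed = np.sum(dev > relaxed, axis=-1)
            if strict:
                match = over_tol == 0
            else:
                match = (over_relaxed == 0) & (over_tol <= 1)
            score = np.sum(dev, axis=-1)
        take = eligible & match & (score < best_score)
        best_label[take] = label
        best_score[take] = score[take]
    best_label[eligible & (best_score == np.inf)] = "IV"
    return best_label


def classify_turn_window(phi1, psi1, phi2, psi2, ca_distance,
                         helical_flags=(False, False), strict=False):
    """Classify a single 4-residue window; returns a label or None."""
    if ca_distance < 0:
        raise ValueError("ca_distance must be >= 0")
    result = classify_windows(
        phi1, psi1, phi2, psi2, ca_distance,
        helical_flags[0], helical_flags[1], strict=strict,
    )
    return result[0]


def helical_residue_flags(torsion_series) -> np.ndarray:
    """Boolean (n_frames, n_residues) mask of helix-assigned residues.

    A residue is helix-like when both phi and psi lie within 40 deg
    (circular) of the alpha-helical center (-60, -47); it counts as
    *helical* only inside a run of at least four consecutive helix-like
    residues, mirroring the convention that a turn may overlap a helix
    end by up to three residues.
    """
    phi, psi = torsion_series.phi, torsion_series.psi
    with np.errstate(invalid="ignore"):
        like = (
            (np.abs(circular_difference(phi, HELIX_CENTER[0])) <= HELIX_TOLERANCE)
            & (np.abs(circular_difference(psi, HELIX_CENTER[1])) <= HELIX_TOLERANCE)
        )
    like = np.where(np.isnan(phi) | np.isnan(psi), False, like)
    n_frames, n_res = like.shape
    flags = np.zeros_like(like, dtype=bool)
    if n_res < HELIX_MIN_RUN:
        return flags
    # run-length scan: mark residues inside any run of >= HELIX_MIN_RUN
    run = np.zeros(n_frames, dtype=int)
    for j in range(n_res):
        run = np.where(like[:, j], run + 1, 0)
        done = run >= HELIX_MIN_RUN
        for back in range(HELIX_MIN_RUN):
            flags[done, j - back] = True
    return flags


def scan_turns(trajectory, torsion_series, strict=False) -> pd.DataFrame:
    """Assign a turn type to every 4-residue window of every frame.

    Returns a tidy DataFrame with columns frame (0-based), window_start
    (residue id i), type (label or None), ca_distance, dev_phi1,
    dev_psi1, dev_phi2, dev_psi2 (deviations from the assigned type's
    ideal angles; NaN for IV and unassigned windows) and
    helical_excluded.
    """
    if trajectory.n_frames != torsion_series.n_frames:
        raise ValueError(
            f"frame-count mismatch: trajectory has {trajectory.n_frames}, "
            f"torsions have {torsion_series.n_frames}"
        )
    res_ids = torsion_series.residue_ids
    n_frames = trajectory.n_frames
    helical = helical_residue_flags(torsion_series)

    rows = []
    for wi in range(len(res_ids) - 3):
        i = res_ids[wi]
        ca_i = trajectory.atom_coordinates(i, "CA")
        ca_i3 = trajectory.atom_coordinates(res_ids[wi + 3], "CA")
        dist = np.linalg.norm(ca_i - ca_i3, axis=1)
        phi1 = torsion_series.phi[:, wi + 1]
        psi1 = torsion_series.psi[:, wi + 1]
        phi2 = torsion_series.phi[:, wi + 2]
        psi2 = torsion_series.psi[:, wi + 2]
        hel1, hel2 = helical[:, wi + 1], helical[:, wi + 2]
        labels = classify_windows(phi1, psi1, phi2, psi2, dist, hel1, hel2, strict)

        dev = np.full((n_frames, 4), np.nan)
        for label in CLASSICAL_TYPES:
            mask = labels == label
            if mask.any():
                dev[mask] = _deviations(
                    phi1[mask], psi1[mask], phi2[mask], psi2[mask],
                    get_ideal_angles(label),
                )
        frame_idx = np.arange(n_frames)
        rows.append(
            pd.DataFrame(
                {
                    "frame": frame_idx,
                    "window_start": i,
                    "type": labels,
                    "ca_distance": dist,
                    "dev_phi1": dev[:, 0],
                    "dev_psi1": dev[:, 1],
                    "dev_phi2": dev[:, 2],
                    "dev_psi2": dev[:, 3],
                    "helical_excluded": hel1 & hel2,
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["frame", "window_start", "type", "ca_distance",
                     "dev_phi1", "dev_psi1", "dev_phi2", "dev_psi2",
                     "helical_excluded"]
        )
    return pd.concat(rows, ignore_index=True)


def population_table(assignments: pd.DataFrame, central_pairs, n_frames=None) -> pd.DataFrame:
    """Turn-type populations (% of frames) per central-residue pair.

    ``central_pairs`` maps a column label (e.g. 'Asn-Gly') to the
    window-start residue id whose central residues form that pair.  The
    Total row is the column sum over the six types.
    """
    if assignments.empty:
        raise ValueError("assignments must be non-empty")
    if n_frames is None:
        n_frames = int(assignments["frame"].max()) + 1
    types = list(CLASSICAL_TYPES) + ["IV"]
    known_starts = set(assignments["window_start"].unique())
    table = {}
    for label, window_start in central_pairs.items():
        if window_start not in known_starts:
            raise KeyError(f"no scanned window starting at residue {window_start} "
                           f"for pair {label!r}")
        sub = assignments[assignments["window_start"] == window_start]
        counts = sub["type"].value_counts()
        col = [100.0 * counts.get(t, 0) / n_frames for t in types]
        col.append(sum(col))
        table[label] = col
    return pd.DataFrame(table, index=types + ["Total"])
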