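"""Good-Turing estimation of unobserved conformational variability.

The question answered here: given the structures already observed in an
ensemble, how probable is it that a *new* structure — one differing from
every observed structure by at least some backbone RMSD r — would appear
if sampling continued?  Frames are subsampled, the pairwise minimum
backbone RMSD matrix is computed (each pair superposed independently by
Kabsch), species are defined by single-linkage clustering at radius r,
and the classical Good-Turing frequency-of-frequencies estimator
p_unobserved(r) = N1 / N (N1 = species seen exactly once) is evaluated
along an ascending RMSD grid, followed by a decreasing isotonic pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .superpose import pairwise_rmsd_matrix
from .trajectory_io import Trajectory

__all__ = ["GoodTuringCurve", "good_turing_curve", "temperature_filter",
            "backbone_atom_indices"]

DEFAULT_RMSD_GRID = np.round(np.arange(0.05, 4.0001, 0.05), 10)


@dataclass
class GoodTuringCurve:
    rmsd_grid: np.ndarray  # Angstrom, ascending
    p_unobserved: np.ndarray  # in [0, 1], non-increasing
    selection: str
    n_samples: int
    seed: int


def backbone_atom_indices(trajectory: Trajectory, residues=None) -> list:
    """Indices of backbone N/CA/C atoms, optionally restricted to residues."""
    top = trajectory.topology
    if residues is None:
        residues = top.amino_acid_ids()
    idx = []
    for rid in residues:
        for name in ("N", "CA", "C"):
            i = top.atom_index(rid, name)
            if i is not None:
                idx.append(i)
    return idx


def temperature_filter(trajectory: Trajectory, t_max_kelvin: float) -> Trajectory:
    """Frames whose per-frame temperature is <= t_max, order preserved."""
    if trajectory.temperatures is None:
        raise ValueError("trajectory has no per-frame temperature metadata")
    keep = np.nonzero(trajectory.temperatures <= t_max_kelvin)[0]
    if keep.size == 0:
        warnings.warn(
            f"temperature filter at {t_max_kelvin} K retains no frames",
            RuntimeWarning,
        )
    return trajectory.subset(keep)


def good_turing_curve(
    trajectory: Trajectory,
    residues=None,
    n_samples: int = 500,
    rmsd_grid=None,
    seed: int = 0,
    selection_label: str | None = None,
) -> GoodTuringCurve:
    """Estimate p(new structure at RMSD >= r) over an RMSD grid.

    ``n_samples`` frames are drawn without replacement (seeded) to keep
    the O(n^2) RMSD matrix small; clustering at each grid radius uses
    single linkage.
    """
    if rmsd_grid is None:
        rmsd_grid = DEFAULT_RMSD_GRID
    rmsd_grid = np.asarray(rmsd_grid, dtype=float)
    if rmsd_grid.size == 0 or np.any(np.diff(rmsd_grid) <= 0):
        raise ValueError("rmsd_grid must be ascending and non-empty")
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    n_samples = min(n_samples, trajectory.n_frames)

    atom_idx = backbone_atom_indices(trajectory, residues)
    if not atom_idx:
        raise ValueError("atom selection is empty")

    rng = np.random.default_rng(seed)
    sample = np.sort(rng.choice(trajectory.n_frames, size=n_samples, replace=False))
    coords = trajectory.coordinates[np.ix_(sample, np.asarray(atom_idx))]

    dmat = pairwise_rmsd_matrix(coords)
    condensed = squareform(dmat, checks=False)
    tree = linkage(condensed, method="single")

    p = np.empty(rmsd_grid.size)
    for gi, r in enumerate(rmsd_grid):
        species = fcluster(tree, t=r, criterion="distance")
        _, counts = np.unique(species, return_counts=True)
        p[gi] = np.sum(counts == 1) / n_samples
    # enforce monotone non-increase along the ascending grid
    p = np.minimum.accumulate(p)

    if selection_label is None:
        selection_label = "backbone" if residues is None else (
            f"backbone residues {min(residues)}-{max(residues)}"
        )
    return GoodTuringCurve(
        rmsd_grid=rmsd_grid,
        p_unobserved=p,
        selection=selection_label,
        n_samples=n_samples,
        seed=seed,
    )
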