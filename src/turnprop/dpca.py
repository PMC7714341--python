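"""Dihedral principal component analysis and conformational clustering.

Backbone phi/psi of a residue selection (typically the four central
residues of the peptide) are embedded periodicity-safely as (cos, sin)
pairs, decomposed by PCA, and the frames are clustered by grid density
in the space of the top three principal components.  Cluster
representatives are the members closest (backbone RMSD) to the cluster's
average structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .superpose import superpose

__all__ = [
    "DPCAResult",
    "ClusterSet",
    "dihedral_embedding",
    "pca",
    "cluster_density",
    "representative_frame",
]


@dataclass
class DPCAResult:
    eigenvalues: np.ndarray  # descending, >= 0
    components: np.ndarray  # (n_components, n_features) rows are PCs
    projections: np.ndarray  # (n_frames, n_components)
    explained_variance_ratio: np.ndarray
    mean: np.ndarray


@dataclass
class ClusterSet:
    """Density-based clusters in principal-component space.

    ``members`` maps 1-based cluster id (ordered by population,
    descending) to frame indices; ``populations`` are % of clustered
    frames; ``fraction_clustered`` is % of all frames that fall in a
    kept bin.
    """

    members: dict
    populations: dict
    fraction_clustered: float
    n_frames: int
    density_cutoff: float
    representatives: dict | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.members)

    def unassigned(self) -> np.ndarray:
        assigned = np.concatenate(list(self.members.values())) if self.members else []
        mask = np.ones(self.n_frames, dtype=bool)
        mask[np.asarray(assigned, dtype=int)] = False
        return np.nonzero(mask)[0]


def dihedral_embedding(torsion_series, residue_selection) -> np.ndarray:
    """Sin/cos embedding of phi/psi for the selected residues.

    Column order is residue-major with phi before psi and cos before
    sin: for each residue r in selection order the four columns are
    (cos phi_r, sin phi_r, cos psi_r, sin psi_r).  Undefined angles in
    the selection raise, listing the offending frames.
    """
    cols = []
    for rid in residue_selection:
        for which in ("phi", "psi"):
            series = torsion_series.column(rid, which)
            bad = np.nonzero(np.isnan(series))[0]
            if bad.size:
                shown = ", ".join(map(str, bad[:10]))
                more = "..." if bad.size > 10 else ""
                raise ValueError(
                    f"undefined {which} for residue {rid} in frames {shown}{more}"
                )
            rad = np.radians(series)
            cols.append(np.cos(rad))
            cols.append(np.sin(rad))
    return np.column_stack(cols)


def pca(embedding: np.ndarray) -> DPCAResult:
    """Eigendecomposition of the column-centered covariance of the embedding.

    Eigenvalues are returned in descending order; each principal
    component's sign is fixed so that its largest-magnitude loading is
    positive.
    """
    x = np.asarray(embedding, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("PCA needs at least 2 frames")
    mean = x.mean(axis=0)
    xc = x - mean
    cov = (xc.T @ xc) / (x.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.maximum(eigvals[order], 0.0)
    comps = eigvecs[:, order].T
    # sign convention: largest-magnitude loading positive
    for row in comps:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    projections = xc @ comps.T
    total = eigvals.sum()
    ratio = eigvals / total if total > 0 else np.zeros_like(eigvals)
    return DPCAResult(
        eigenvalues=eigvals,
        components=comps,
        projections=projections,
        explained_variance_ratio=ratio,
        mean=mean,
    )


def _grid_assign(projections, k_dims, grid_bins, extent_sigmas):
    proj = projections[:, :k_dims]
    center = proj.mean(axis=0)
    sigma = proj.std(axis=0)
    sigma = np.where(sigma == 0, 1.0, sigma)
    lo = center - extent_sigmas * sigma
    hi = center + extent_sigmas * sigma
    width = (hi - lo) / grid_bins
    # clip into edge bins so every frame lands on the grid
    idx = np.floor((proj - lo) / width).astype(int)
    idx = np.clip(idx, 0, grid_bins - 1)
    return idx


def cluster_density(
    projections: np.ndarray,
    k_dims: int = 3,
    grid_bins: int = 32,
    density_cutoff: float | None = None,
    target_fraction: float = 0.35,
    extent_sigmas: float = 3.0,
) -> ClusterSet:
    """Grid-density flood-fill clustering in top-k PC space.

    Frames are binned on a regular grid spanning +-``extent_sigmas``
    standard deviations per principal component (outliers are clipped
    into the edge bins).  Bins with a count above ``density_cutoff`` are
    kept and merged by face adjacency into clusters; frames in discarded
    bins stay unassigned.  When ``density_cutoff`` is None it is chosen
    so that the kept high-density bins hold about ``target_fraction`` of
    all frames.  Deterministic given its inputs.
    """
    proj = np.asarray(projections, dtype=float)
    n_frames = proj.shape[0]
    if k_dims > proj.shape[1]:
        raise ValueError("k_dims exceeds available principal components")
    idx = _grid_assign(proj, k_dims, grid_bins, extent_sigmas)

    shape = (grid_bins,) * k_dims
    flat = np.ravel_multi_index(idx.T, shape)
    counts_grid = np.bincount(flat, minlength=int(np.prod(shape))).reshape(shape)

    if density_cutoff is None:
        counts_desc = np.sort(counts_grid.ravel())[::-1]
        cum = np.cumsum(counts_desc)
        pos = np.searchsorted(cum, target_fraction * n_frames)
        pos = min(pos, counts_desc.size - 1)
        density_cutoff = max(float(counts_desc[pos]) - 1.0, 0.0)

    kept = counts_grid > density_cutoff
    if not kept.any():
        warnings.warn("all grid bins at or below the density cutoff; "
                      "empty cluster set", RuntimeWarning)
        return ClusterSet({}, {}, 0.0, n_frames, float(density_cutoff))

    structure = ndimage.generate_binary_structure(k_dims, 1)  # faces only
    labeled, n_raw = ndimage.label(kept, structure=structure)
    frame_label = labeled[tuple(idx.T)]

    members = {}
    for raw_id in range(1, n_raw + 1):
        frames = np.nonzero(frame_label == raw_id)[0]
        if frames.size:
            members[raw_id] = frames
    # order clusters by population, re-id from 1
    order = sorted(members, key=lambda cid: (-members[cid].size, cid))
    members = {new_id: members[cid] for new_id, cid in enumerate(order, start=1)}
    n_clustered = sum(m.size for m in members.values())
    populations = {
        cid: 100.0 * m.size / n_clustered for cid, m in members.items()
    }
    return ClusterSet(
        members=members,
        populations=populations,
        fraction_clustered=100.0 * n_clustered / n_frames,
        n_frames=n_frames,
        density_cutoff=float(density_cutoff),
    )


def log_density_landscape(projections, grid_bins=64, extent_sigmas=3.0):
    """2-D natural-log density on the top-two-PC grid (landscape export).

    Returns (pc1_centers, pc2_centers, log(count + 1)).
    """
    proj = np.asarray(projections, dtype=float)[:, :2]
    center = proj.mean(axis=0)
    sigma = np.where(proj.std(axis=0) == 0, 1.0, proj.std(axis=0))
    lo, hi = center - extent_sigmas * sigma, center + extent_sigmas * sigma
    counts, xedges, yedges = np.histogram2d(
        proj[:, 0], proj[:, 1], bins=grid_bins,
        range=[[lo[0], hi[0]], [lo[1], hi[1]]],
    )
    return (
        0.5 * (xedges[:-1] + xedges[1:]),
        0.5 * (yedges[:-1] + yedges[1:]),
        np.log(counts + 1.0),
    )


def representative_frame(member_frames, trajectory, atom_selection=None) -> int:
    """Member frame with the lowest backbone RMSD to the cluster average.

    The average structure is the coordinate mean after two passes of
    Kabsch superposition onto the running mean.  Ties go to the lowest
    frame index.
    """
    member_frames = np.asarray(member_frames, dtype=int)
    if member_frames.size == 0:
        raise ValueError("cluster is empty")
    top = trajectory.topology
    if atom_selection is None:
        atom_selection = [
            top.atom_index(rid, name)
            for rid in top.amino_acid_ids()
            for name in ("N", "CA", "C")
            if top.atom_index(rid, name) is not None
        ]
    coords = trajectory.coordinates[np.ix_(member_frames,
                                           np.asarray(atom_selection, dtype=int))]
    reference = coords[0]
    for _ in range(2):
        aligned = np.stack([superpose(c, reference) for c in coords])
        reference = aligned.mean(axis=0)
    dev = np.sqrt(np.mean(np.sum((aligned - reference) ** 2, axis=2), axis=1))
    return int(member_frames[int(np.argmin(dev))])
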