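"""Synthetic peptide conformational ensembles with known ground truth.

The generator emulates the statistical structure of a folding trajectory
of a short capped peptide that interconverts among a mixture of turn
conformers and coil: per-frame hidden conformer labels (iid or Markov
switching), von Mises angular noise of configurable concentration around
each conformer's central angles, and 3-D backbone coordinates built from
the torsions by sequential NeRF-style internal-to-Cartesian placement.

No physics is involved — no force field, solvent or energies.  The point
is programmable, exactly known statistical structure against which the
analysis stages can be validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dihedrals import wrap_angle
from .trajectory_io import (
    Topology,
    Trajectory,
    TorsionSeries,
    write_dihedral_table,
    write_multi_model_pdb,
    write_temperature_table,
)

__all__ = [
    "BackboneGeometry",
    "ConformerSpec",
    "EnsembleSpec",
    "SimulationResult",
    "build_backbone",
    "build_backbone_frames",
    "simulate_ensemble",
    "write_ensemble",
    "kappa_from_sigma_deg",
    "sigma_deg_from_kappa",
]


@dataclass(frozen=True)
class BackboneGeometry:
    """Idealized bond lengths (A) and angles (deg) of the peptide backbone."""

    n_ca: float = 1.458
    ca_c: float = 1.525
    c_n: float = 1.329
    c_o: float = 1.231
    ca_cb: float = 1.530
    ch3_c: float = 1.508  # acetyl cap methyl-carbonyl
    n_ch3: float = 1.449  # N-methylamide cap
    ang_c_n_ca: float = 121.7
    ang_n_ca_c: float = 111.2
    ang_ca_c_n: float = 116.2
    ang_ca_c_o: float = 120.8
    ang_n_ca_cb: float = 110.4
    ang_ch3_c_n: float = 116.6
    ang_ch3_c_o: float = 120.4
    ang_c_n_ch3: float = 121.7
    omega: float = 180.0

    def __post_init__(self):
        for name in ("n_ca", "ca_c", "c_n", "c_o", "ca_cb", "ch3_c", "n_ch3"):
            v = getattr(self, name)
            if not (1.2 < v < 1.6):
                raise ValueError(f"bond length {name}={v} outside (1.2, 1.6) A")
        for name in (
            "ang_c_n_ca",
            "ang_n_ca_c",
            "ang_ca_c_n",
            "ang_ca_c_o",
            "ang_n_ca_cb",
            "ang_ch3_c_n",
            "ang_ch3_c_o",
            "ang_c_n_ch3",
        ):
            v = getattr(self, name)
            if not (100.0 < v < 130.0):
                raise ValueError(f"bond angle {name}={v} outside (100, 130) deg")


@dataclass(frozen=True)
class ConformerSpec:
    """One component of the conformer mixture.

    ``central_angles`` are the (phi_i+1, psi_i+1, phi_i+2, psi_i+2)
    centers of the turn window starting at residue ``window_start``;
    ``None`` makes the conformer pure coil (all angles random).
    ``flank_angle_mode`` controls the non-central angles: 'coil-random'
    draws them uniformly, 'fixed' holds them at an extended-strand
    center (-120, 140) plus the same angular noise.
    """

    name: str
    weight: float
    window_start: int = 2
    central_angles: tuple | None = None
    flank_angle_mode: str = "coil-random"

    def __post_init__(self):
        if not (0.0 <= self.weight <= 1.0):
            raise ValueError("conformer weight must be in [0, 1]")
        if self.flank_angle_mode not in ("coil-random", "fixed"):
            raise ValueError("flank_angle_mode must be 'coil-random' or 'fixed'")
        if self.central_angles is not None and len(self.central_angles) != 4:
            raise ValueError("central_angles must be a quadruple")


@dataclass(frozen=True)
class EnsembleSpec:
    """Full recipe for one synthetic ensemble."""

    sequence: tuple = ("ALA", "ALA", "ASN", "GLY", "ALA", "ALA")
    conformers: tuple = ()
    kappa: float = 50.0  # von Mises concentration; sigma ~ 1/sqrt(kappa) rad
    switching: str = "iid"  # 'iid' or 'markov'
    stay_prob: float = 0.0  # markov only
    n_frames: int = 1000
    seed: int = 0
    temperature_model: tuple | None = None  # (base_K, amplitude_K)
    temperature_period: int = 500  # frames per sinusoidal cycle

    def __post_init__(self):
        if not self.conformers:
            raise ValueError("at least one conformer is required")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.switching not in ("iid", "markov"):
            raise ValueError("switching must be 'iid' or 'markov'")
        if not (0.0 <= self.stay_prob < 1.0):
            raise ValueError("stay_prob must be in [0, 1)")
        total = sum(c.weight for c in self.conformers)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"conformer weights sum to {total}, not 1")
        if self.temperature_model is not None:
            base, amp = self.temperature_model
            if not (280.0 <= base - abs(amp) and base + abs(amp) <= 480.0):
                raise ValueError("temperature series must stay within [280, 480] K")


@dataclass
class SimulationResult:
    trajectory: Trajectory
    torsions: TorsionSeries
    labels: np.ndarray  # per-frame conformer index into spec.conformers
    spec: EnsembleSpec = field(repr=False, default=None)

    @property
    def label_names(self) -> list[str]:
        return [self.spec.conformers[i].name for i in self.labels]


def kappa_from_sigma_deg(sigma_deg: float) -> float:
    """Von Mises concentration whose large-kappa width matches sigma (deg)."""
    return 1.0 / np.radians(sigma_deg) ** 2


def sigma_deg_from_kappa(kappa: float) -> float:
    return np.degrees(1.0 / np.sqrt(kappa))


# --------------------------------------------------------------------------
# NeRF-style internal-to-Cartesian construction


def _nerf_place(a, b, c, bond, angle_deg, torsion_deg):
    """Place atom D bonded to C given the A-B-C frame (vectorized).

    The returned point satisfies |CD| = bond, angle(B, C, D) = angle_deg
    and dihedral(A, B, C, D) = torsion_deg (IUPAC sign convention).
    Inputs a, b, c have shape (..., 3); torsion_deg broadcasts.
    """
    theta = np.radians(angle_deg)
    tau = np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc, axis=-1, keepdims=True)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n, bc)
    tau = np.asarray(tau)[..., None]
    d_local = np.concatenate(
        [
            np.broadcast_to(-bond * np.cos(theta), tau.shape),
            bond * np.sin(theta) * np.cos(tau),
            bond * np.sin(theta) * np.sin(tau),
        ],
        axis=-1,
    )
    return c + d_local[..., 0:1] * bc + d_local[..., 1:2] * m + d_local[..., 2:3] * n


def _topology_for(sequence, include_cb) -> Topology:
    res_ids, res_names, atom_names = [], [], []

    def add(rid, rname, aname):
        res_ids.append(rid)
        res_names.append(rname)
        atom_names.append(aname)

    add(0, "ACE", "CH3")
    add(0, "ACE", "C")
    add(0, "ACE", "O")
    for k, rname in enumerate(sequence, start=1):
        for aname in ("N", "CA", "C", "O"):
            add(k, rname, aname)
        if include_cb and rname != "GLY":
            add(k, rname, "CB")
    n = len(sequence)
    add(n + 1, "NME", "N")
    add(n + 1, "NME", "CH3")
    return Topology(res_ids=np.array(res_ids), res_names=res_names, atom_names=atom_names)


def build_backbone_frames(
    sequence,
    phi,
    psi,
    omega=None,
    geometry: BackboneGeometry | None = None,
    include_cb: bool = False,
) -> Trajectory:
    """Build capped-peptide backbone coordinates for many frames at once.

    Parameters
    ----------
    sequence : list of residue names (>= 2 residues; caps are implicit)
    phi, psi : arrays (n_frames, n_residues), degrees in (-180, 180]
    omega : optional array of the same shape; omega[k] is the peptide
        bond preceding residue k (the acetyl bond for residue 1).
        Defaults to trans (180) everywhere.

    Returns a Trajectory whose recomputed torsions equal the inputs and
    whose bond lengths equal the input geometry.
    """
    geometry = geometry or BackboneGeometry()
    sequence = list(sequence)
    if len(sequence) < 2:
        raise ValueError("sequence must have at least 2 residues")
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    psi = np.atleast_2d(np.asarray(psi, dtype=float))
    n_frames, n_res = phi.shape
    if psi.shape != phi.shape or n_res != len(sequence):
        raise ValueError("phi/psi must have shape (n_frames, n_residues)")
    if omega is None:
        omega = np.full_like(phi, geometry.omega)
    else:
        omega = np.atleast_2d(np.asarray(omega, dtype=float))
    for name, arr in (("phi", phi), ("psi", psi), ("omega", omega)):
        if np.isnan(arr).any():
            raise ValueError(f"{name} contains undefined angles")
        if np.any(arr <= -180.0) or np.any(arr > 180.0):
            raise ValueError(f"{name} angles must lie in (-180, 180]")

    g = geometry
    top = _topology_for(sequence, include_cb)
    coords = np.empty((n_frames, top.n_atoms, 3))

    def put(rid, aname, xyz):
        coords[:, top.atom_index(rid, aname), :] = xyz

    # seed triple: acetyl CH3 at origin, its carbonyl C on +x, N1 in xy-plane
    ch3 = np.zeros((n_frames, 3))
    c_prev = np.zeros((n_frames, 3))
    c_prev[:, 0] = g.ch3_c
    theta = np.radians(g.ang_ch3_c_n)
    n1 = c_prev + g.c_n * np.array([-np.cos(theta), np.sin(theta), 0.0])
    put(0, "CH3", ch3)
    put(0, "C", c_prev)
    # acetyl carbonyl O: planar sp2, anti to N1 across the C
    put(0, "O", _nerf_place(n1, ch3, c_prev, g.c_o, g.ang_ch3_c_o, 180.0))

    a, b, c, n = ch3, c_prev, n1, n1  # A-B-C frame walks along the chain
    ca_prev = None
    for k in range(n_res):
        rid = k + 1
        put(rid, "N", n)
        ca = _nerf_place(a, b, n, g.n_ca, g.ang_c_n_ca, omega[:, k])
        put(rid, "CA", ca)
        cc = _nerf_place(b, n, ca, g.ca_c, g.ang_n_ca_c, phi[:, k])
        put(rid, "C", cc)
        put(rid, "O", _nerf_place(n, ca, cc, g.c_o, g.ang_ca_c_o,
                                  wrap_angle(psi[:, k] - 180.0)))
        if include_cb and sequence[k] != "GLY":
            put(rid, "CB", _nerf_place(cc, n, ca, g.ca_cb, g.ang_n_ca_cb, 122.55))
        n_next = _nerf_place(n, ca, cc, g.c_n, g.ang_ca_c_n, psi[:, k])
        a, b, ca_prev = ca, cc, ca
        n = n_next

    # N-methylamide cap
    put(n_res + 1, "N", n)
    put(n_res + 1, "CH3",
        _nerf_place(ca_prev, b, n, g.n_ch3, g.ang_c_n_ch3, g.omega))
    return Trajectory(topology=top, coordinates=coords)


def build_backbone(sequence, torsions, geometry=None, include_cb=False) -> Trajectory:
    """Single-frame convenience wrapper around :func:`build_backbone_frames`.

    ``torsions`` is a sequence of (phi, psi) or (phi, psi, omega) per
    residue, degrees.
    """
    arr = np.asarray(torsions, dtype=float)
    if arr.ndim != 2 or arr.shape[1] not in (2, 3):
        raise ValueError("torsions must be (n_residues, 2 or 3)")
    omega = arr[:, 2][None, :] if arr.shape[1] == 3 else None
    return build_backbone_frames(
        sequence, arr[:, 0][None, :], arr[:, 1][None, :], omega, geometry, include_cb
    )


# --------------------------------------------------------------------------
# ensemble simulation

_EXTENDED = (-120.0, 140.0)  # fixed-flank (phi, psi) center


def _draw_labels(spec: EnsembleSpec, rng: np.random.Generator) -> np.ndarray:
    weights = np.array([c.weight for c in spec.conformers])
    k = len(weights)
    if spec.switching == "iid" or k == 1:
        return rng.choice(k, size=spec.n_frames, p=weights)
    labels = np.empty(spec.n_frames, dtype=int)
    labels[0] = rng.choice(k, p=weights)
    stays = rng.random(spec.n_frames - 1) < spec.stay_prob
    for t in range(1, spec.n_frames):
        if stays[t - 1]:
            labels[t] = labels[t - 1]
        else:
            # switch: successor drawn among the *other* conformers by weight,
            # so dwell times are exactly Geometric(1 - stay_prob)
            w = weights.copy()
            w[labels[t - 1]] = 0.0
            labels[t] = rng.choice(k, p=w / w.sum())
    return labels


def simulate_ensemble(spec: EnsembleSpec, include_cb: bool = False) -> SimulationResult:
    """Draw an ensemble: labels, noisy torsions, built 3-D coordinates.

    Identical spec (including seed) gives byte-identical output.  The
    per-frame hidden conformer label is returned as ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    n_res = len(spec.sequence)
    labels = _draw_labels(spec, rng)

    # baseline: every angle coil-random (uniform over the circle)
    phi = wrap_angle(rng.uniform(-180.0, 180.0, size=(spec.n_frames, n_res)))
    psi = wrap_angle(rng.uniform(-180.0, 180.0, size=(spec.n_frames, n_res)))
    noise = np.degrees(
        rng.vonmises(0.0, spec.kappa, size=(spec.n_frames, n_res, 2))
    )

    for ci, conf in enumerate(spec.conformers):
        mask = labels == ci
        if not mask.any():
            continue
        if conf.flank_angle_mode == "fixed":
            phi[mask] = wrap_angle(_EXTENDED[0] + noise[mask, :, 0])
            psi[mask] = wrap_angle(_EXTENDED[1] + noise[mask, :, 1])
        if conf.central_angles is not None:
            c1, c2 = conf.window_start + 1, conf.window_start + 2  # residues i+1, i+2
            for col, (phi_c, psi_c) in zip((c1, c2), np.reshape(conf.central_angles, (2, 2))):
                j = col - 1  # residue ids are 1-based
                phi[mask, j] = wrap_angle(phi_c + noise[mask, j, 0])
                psi[mask, j] = wrap_angle(psi_c + noise[mask, j, 1])

    trajectory = build_backbone_frames(spec.sequence, phi, psi, include_cb=include_cb)
    if spec.temperature_model is not None:
        base, amp = spec.temperature_model
        t = np.arange(spec.n_frames)
        temps = base + amp * np.sin(2.0 * np.pi * t / spec.temperature_period)
        trajectory.temperatures = np.clip(temps, 280.0, 480.0)

    torsions = TorsionSeries(
        residue_ids=list(range(1, n_res + 1)),
        residue_names=list(spec.sequence),
        phi=phi,
        psi=psi,
    )
    return SimulationResult(trajectory=trajectory, torsions=torsions,
                            labels=labels, spec=spec)


def write_ensemble(result: SimulationResult, out_dir) -> dict:
    """Write an ensemble to a directory; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "pdb": out / "trajectory.pdb",
        "torsions": out / "torsions.tsv",
        "labels": out / "labels.tsv",
    }
    write_multi_model_pdb(result.trajectory, paths["pdb"])
    write_dihedral_table(result.torsions, paths["torsions"])
    lines = ["# ground-truth conformer label per frame; frame numbers are 1-based",
             "frame\tlabel"]
    for f, name in enumerate(result.label_names, start=1):
        lines.append(f"{f}\t{name}")
    paths["labels"].write_text("\n".join(lines) + "\n")
    if result.trajectory.temperatures is not None:
        paths["temperatures"] = out / "temperatures.tsv"
        write_temperature_table(result.trajectory.temperatures, paths["temperatures"])
    return paths
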