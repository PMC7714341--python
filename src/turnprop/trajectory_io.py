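"""Trajectory and torsion-series containers and their on-disk formats.

Exchange formats are deliberately plain text: multi-model PDB for
coordinates (the lingua franca of structural analysis tools), and
tab-separated tables for torsion angles and per-frame temperatures.

Conventions, stated once and used everywhere:

* residue indexing is 1-based (PDB convention); capping groups carry
  residue ids 0 (N-terminal acetyl) and n+1 (C-terminal N-methylamide);
* frame indexing is 0-based internally and 1-based in written reports;
* angles are degrees wrapped into (-180, 180].
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .dihedrals import wrap_angle

__all__ = [
    "Topology",
    "Trajectory",
    "TorsionSeries",
    "read_multi_model_pdb",
    "write_multi_model_pdb",
    "read_dihedral_table",
    "write_dihedral_table",
    "read_temperature_table",
    "write_temperature_table",
]

CAP_RESIDUES = {"ACE", "NME"}


@dataclass
class Topology:
    """Per-atom residue/atom naming for one peptide chain."""

    res_ids: np.ndarray  # (n_atoms,) int
    res_names: list[str]  # per atom
    atom_names: list[str]  # per atom
    chain_id: str = "A"
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        if not self._index:
            self._index = {
                (int(r), a): i
                for i, (r, a) in enumerate(zip(self.res_ids, self.atom_names))
            }

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def atom_index(self, res_id: int, atom_name: str):
        """Index of an atom, or None if absent."""
        return self._index.get((int(res_id), atom_name))

    def residue_name(self, res_id: int) -> str:
        mask = self.res_ids == int(res_id)
        if not mask.any():
            raise KeyError(f"no residue with id {res_id}")
        return self.res_names[int(np.nonzero(mask)[0][0])]

    def amino_acid_ids(self) -> list[int]:
        """Sorted residue ids excluding capping groups."""
        ids = []
        for rid in np.unique(self.res_ids):
            if self.residue_name(int(rid)) not in CAP_RESIDUES:
                ids.append(int(rid))
        return ids


@dataclass
class Trajectory:
    """Ordered conformational frames of one peptide.

    coordinates have shape (n_frames, n_atoms, 3) in Angstrom;
    temperatures, if present, hold one Kelvin value per frame.
    """

    topology: Topology
    coordinates: np.ndarray
    temperatures: np.ndarray | None = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise ValueError("coordinate atom count does not match topology")
        if not np.isfinite(self.coordinates).all():
            raise ValueError("coordinates must be finite")
        if self.temperatures is not None:
            self.temperatures = np.asarray(self.temperatures, dtype=float)
            if self.temperatures.shape != (self.n_frames,):
                raise ValueError("temperatures must have one value per frame")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    def subset(self, frame_indices) -> "Trajectory":
        """New trajectory restricted to the given frames (order preserved)."""
        idx = np.asarray(frame_indices, dtype=int)
        temps = None if self.temperatures is None else self.temperatures[idx]
        return Trajectory(self.topology, self.coordinates[idx], temps)

    def atom_coordinates(self, res_id: int, atom_name: str) -> np.ndarray:
        i = self.topology.atom_index(res_id, atom_name)
        if i is None:
            raise KeyError(f"atom {atom_name} of residue {res_id} not present")
        return self.coordinates[:, i, :]


@dataclass
class TorsionSeries:
    """Per-frame backbone phi/psi (degrees) for each amino-acid residue.

    phi and psi have shape (n_frames, n_residues); NaN marks undefined
    angles (e.g. terminal angles of an uncapped chain).
    """

    residue_ids: list[int]
    phi: np.ndarray
    psi: np.ndarray
    residue_names: list[str] | None = None

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        if self.phi.shape != self.psi.shape:
            raise ValueError("phi and psi must have identical shapes")
        if self.phi.shape[1] != len(self.residue_ids):
            raise ValueError("angle columns must match residue_ids")
        for name, arr in (("phi", self.phi), ("psi", self.psi)):
            defined = arr[~np.isnan(arr)]
            if defined.size and (np.any(defined <= -180.0) or np.any(defined > 180.0)):
                raise ValueError(f"{name} angles must lie in (-180, 180]")

    @property
    def n_frames(self) -> int:
        return self.phi.shape[0]

    def column(self, res_id: int, which: str) -> np.ndarray:
        """Per-frame series of one angle; ``which`` is 'phi' or 'psi'."""
        j = self.residue_ids.index(int(res_id))
        if which == "phi":
            return self.phi[:, j]
        if which == "psi":
            return self.psi[:, j]
        raise ValueError("which must be 'phi' or 'psi'")

    def subset(self, frame_indices) -> "TorsionSeries":
        idx = np.asarray(frame_indices, dtype=int)
        return TorsionSeries(
            residue_ids=list(self.residue_ids),
            phi=self.phi[idx],
            psi=self.psi[idx],
            residue_names=self.residue_names,
        )


# --------------------------------------------------------------------------
# multi-model PDB


def _element_of(atom_name: str) -> str:
    if atom_name.startswith(("CH3", "C")):
        return "C"
    if atom_name.startswith("N"):
        return "N"
    if atom_name.startswith("O"):
        return "O"
    return atom_name[0]


def write_multi_model_pdb(trajectory: Trajectory, path) -> None:
    """Write a trajectory as a standard multi-model PDB (MODEL/ENDMDL)."""
    top = trajectory.topology
    n_atoms = top.n_atoms
    stack = struc.AtomArrayStack(trajectory.n_frames, n_atoms)
    stack.coord = trajectory.coordinates.astype(np.float32)
    stack.chain_id = np.full(n_atoms, top.chain_id)
    stack.res_id = top.res_ids.copy()
    stack.res_name = np.array(top.res_names)
    stack.atom_name = np.array(top.atom_names)
    stack.element = np.array([_element_of(a) for a in top.atom_names])
    stack.hetero = np.isin(stack.res_name, list(CAP_RESIDUES))
    pdb_file = PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def _check_model_atom_counts(text: str) -> None:
    counts = []
    current = None
    for line in text.splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            current = 0
        elif rec == "ENDMDL":
            counts.append(current or 0)
            current = None
        elif rec in ("ATOM", "HETATM") and current is not None:
            current += 1
    for k, c in enumerate(counts[1:], start=2):
        if c != counts[0]:
            raise ValueError(f"inconsistent atom count at MODEL {k}")


def read_multi_model_pdb(path, temperatures=None) -> Trajectory:
    """Read a (multi-)model PDB file into a Trajectory.

    Models must share one atom list; a mismatch raises naming the model
    index.  A file without MODEL records is read as a single frame.
    """
    text = Path(path).read_text()
    _check_model_atom_counts(text)
    pdb_file = PDBFile.read(io.StringIO(text))
    structure = pdb_file.get_structure(model=None)
    if isinstance(structure, struc.AtomArray):  # single implicit model
        structure = struc.stack([structure])
    topology = Topology(
        res_ids=structure.res_id[:],
        res_names=list(structure.res_name),
        atom_names=list(structure.atom_name),
        chain_id=str(structure.chain_id[0]) if structure.array_length() else "A",
    )
    return Trajectory(
        topology=topology,
        coordinates=np.asarray(structure.coord, dtype=float),
        temperatures=temperatures,
    )


# --------------------------------------------------------------------------
# dihedral tables

_DIHEDRAL_HEADER = ("frame", "residue", "phi", "psi")


def write_dihedral_table(series: TorsionSeries, path) -> None:
    """Write a TorsionSeries as TSV (columns frame, residue, phi, psi).

    Frames are reported 1-based; angles are printed with full precision so
    that the read/write round trip is exact.  Undefined angles are written
    as NA.
    """
    lines = [
        "# backbone phi/psi in degrees, wrapped into (-180, 180]",
        "# frame numbers are 1-based; residue ids are 1-based PDB-style",
        "\t".join(_DIHEDRAL_HEADER),
    ]
    for f in range(series.n_frames):
        for j, rid in enumerate(series.residue_ids):
            phi, psi = series.phi[f, j], series.psi[f, j]
            lines.append(
                "\t".join(
                    [
                        str(f + 1),
                        str(rid),
                        "NA" if np.isnan(phi) else format(phi, ".17g"),
                        "NA" if np.isnan(psi) else format(psi, ".17g"),
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_angle(token: str, line_no: int) -> float:
    token = token.strip()
    if token in ("", "NA", "NaN", "nan"):
        return np.nan
    try:
        return float(token)
    except ValueError:
        raise ValueError(f"non-numeric angle {token!r} at line {line_no}") from None


def read_dihedral_table(path) -> TorsionSeries:
    """Read a TSV dihedral table (frame, residue, phi, psi) into a series.

    Angles are wrapped into (-180, 180]; missing cells become undefined
    (NaN).  A non-numeric angle raises with the offending line number.
    """
    records = []
    header_seen = False
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if [f.strip().lower() for f in fields[:4]] != list(_DIHEDRAL_HEADER):
                    raise ValueError(
                        f"expected header {'/'.join(_DIHEDRAL_HEADER)} at line {line_no}"
                    )
                header_seen = True
                continue
            if len(fields) < 4:
                raise ValueError(f"expected 4 columns at line {line_no}")
            try:
                frame = int(fields[0])
                residue = int(fields[1])
            except ValueError:
                raise ValueError(f"non-integer frame/residue at line {line_no}") from None
            phi = _parse_angle(fields[2], line_no)
            psi = _parse_angle(fields[3], line_no)
            records.append((frame, residue, phi, psi))
    if not records:
        raise ValueError("no frames in dihedral table")

    frames = sorted({r[0] for r in records})
    residues = sorted({r[1] for r in records})
    f_pos = {f: i for i, f in enumerate(frames)}
    r_pos = {r: j for j, r in enumerate(residues)}
    phi = np.full((len(frames), len(residues)), np.nan)
    psi = np.full((len(frames), len(residues)), np.nan)
    for frame, residue, p, s in records:
        phi[f_pos[frame], r_pos[residue]] = p
        psi[f_pos[frame], r_pos[residue]] = s
    phi = np.where(np.isnan(phi), np.nan, wrap_angle(phi))
    psi = np.where(np.isnan(psi), np.nan, wrap_angle(psi))
    return TorsionSeries(residue_ids=residues, phi=phi, psi=psi)


# --------------------------------------------------------------------------
# temperature tables


def write_temperature_table(temperatures, path) -> None:
    """Write per-frame temperatures as TSV (frame, kelvin), frames 1-based."""
    temps = np.asarray(temperatures, dtype=float)
    lines = ["# per-frame temperature in Kelvin; frame numbers are 1-based",
             "frame\tkelvin"]
    for f, t in enumerate(temps, start=1):
        lines.append(f"{f}\t{format(float(t), '.17g')}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_temperature_table(path) -> np.ndarray:
    """Read a TSV temperature table back into a per-frame array."""
    values = {}
    header_seen = False
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if [f.strip().lower() for f in fields[:2]] != ["frame", "kelvin"]:
                    raise ValueError(f"expected header frame/kelvin at line {line_no}")
                header_seen = True
                continue
            try:
                values[int(fields[0])] = float(fields[1])
            except (ValueError, IndexError):
                raise ValueError(f"malformed temperature row at line {line_no}") from None
    if not values:
        raise ValueError("no frames in temperature table")
    frames = sorted(values)
    if frames != list(range(1, len(frames) + 1)):
        warnings.warn("temperature table frames are not contiguous", RuntimeWarning)
    return np.array([values[f] for f in frames], dtype=float)
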