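"""Packaged reference torsion angles for beta-turn analysis.

Two data sets ship with the package as versioned JSON:

* ``ideal_turns.json`` — ideal central-residue angle quadruples
  (phi_i+1, psi_i+1, phi_i+2, psi_i+2) of the classical Thornton turn
  types I, I', II, II' and VIII, plus the matching tolerances.  Type IV
  is the miscellaneous category and has no ideal angles.
* ``dft_table1.json`` — DFT-optimized turn geometries (eight backbone
  torsions of residues i..i+3) of three Asn-Gly capped heptapeptides,
  four turn types each, used as reference values for deviation
  statistics.

Both files can be overridden with a user-supplied JSON of the same shape.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = [
    "TurnTypeDefinition",
    "DFTReferenceGeometry",
    "TURN_TYPES",
    "CLASSICAL_TYPES",
    "get_turn_definition",
    "get_ideal_angles",
    "get_dft_geometry",
    "iter_dft_geometries",
    "dft_peptides",
    "load_ideal_turns",
    "load_dft_table",
]

#: all turn-type labels handled by this package, in fixed priority order
TURN_TYPES = ("I", "II", "I'", "II'", "VIII", "IV")
#: types with an ideal angle quadruple (everything except miscellaneous IV)
CLASSICAL_TYPES = ("I", "II", "I'", "II'", "VIII")


@dataclass(frozen=True)
class TurnTypeDefinition:
    type_label: str
    ideal_angles: tuple | None  # (phi1, psi1, phi2, psi2) degrees; None for IV
    tolerance_deg: float = 30.0
    relaxed_tolerance_deg: float = 45.0

    def __post_init__(self):
        if self.ideal_angles is not None:
            for a in self.ideal_angles:
                if not (-180.0 < a <= 180.0):
                    raise ValueError(f"ideal angle {a} outside (-180, 180]")


@dataclass(frozen=True)
class DFTReferenceGeometry:
    """One DFT-optimized turn geometry: torsions of residues i..i+3."""

    peptide_id: str
    turn_type: str
    angles: tuple  # (phi_i, psi_i, phi_i+1, psi_i+1, phi_i+2, psi_i+2, phi_i+3, psi_i+3)

    def __post_init__(self):
        if len(self.angles) != 8:
            raise ValueError("a turn geometry has exactly eight torsions")
        for a in self.angles:
            if not (-180.0 < a <= 180.0):
                raise ValueError(f"angle {a} outside (-180, 180]")

    @property
    def central_quadruple(self) -> tuple:
        """(phi_i+1, psi_i+1, phi_i+2, psi_i+2) — the classifying angles."""
        return self.angles[2:6]


def _read_packaged(name: str, override=None) -> dict:
    if override is not None:
        with open(override) as fh:
            return json.load(fh)
    with resources.files("turnprop.data").joinpath(name).open() as fh:
        return json.load(fh)


def load_ideal_turns(path=None) -> dict[str, TurnTypeDefinition]:
    """Load the ideal turn-type definitions (packaged, or from ``path``)."""
    raw = _read_packaged("ideal_turns.json", path)
    tol = float(raw.get("tolerance_deg", 30.0))
    relaxed = float(raw.get("relaxed_tolerance_deg", 45.0))
    defs = {}
    for label, angles in raw["types"].items():
        defs[label] = TurnTypeDefinition(
            type_label=label,
            ideal_angles=None if angles is None else tuple(float(a) for a in angles),
            tolerance_deg=tol,
            relaxed_tolerance_deg=relaxed,
        )
    return defs


def load_dft_table(path=None) -> dict:
    """Load the DFT reference table (packaged, or from ``path``).

    Returns a dict with keys ``peptides`` (id -> sequence/turn_start) and
    ``geometries`` ((peptide_id, turn_type) -> DFTReferenceGeometry).
    """
    raw = _read_packaged("dft_table1.json", path)
    geometries = {}
    for entry in raw["geometries"]:
        geo = DFTReferenceGeometry(
            peptide_id=entry["peptide"],
            turn_type=entry["turn_type"],
            angles=tuple(float(a) for a in entry["angles"]),
        )
        key = (geo.peptide_id, geo.turn_type)
        if key in geometries:
            raise ValueError(f"duplicate DFT geometry for {key}")
        geometries[key] = geo
    return {"peptides": raw["peptides"], "geometries": geometries}


_IDEAL = load_ideal_turns()
_DFT = load_dft_table()


def get_turn_definition(type_label: str) -> TurnTypeDefinition:
    try:
        return _IDEAL[type_label]
    except KeyError:
        raise KeyError(f"unknown turn type {type_label!r}") from None


def get_ideal_angles(type_label: str) -> tuple:
    """Ideal (phi_i+1, psi_i+1, phi_i+2, psi_i+2) of a classical turn type.

    Raises for unknown labels and for type IV, which as the miscellaneous
    category has no ideal angles.
    """
    definition = get_turn_definition(type_label)
    if definition.ideal_angles is None:
        raise ValueError(f"turn type {type_label!r} has no ideal angles")
    return definition.ideal_angles


def get_dft_geometry(peptide_id: str, turn_type: str) -> DFTReferenceGeometry:
    """Look up one DFT-optimized geometry by (peptide, turn type)."""
    try:
        return _DFT["geometries"][(peptide_id, turn_type)]
    except KeyError:
        raise KeyError(
            f"no DFT reference geometry for peptide {peptide_id!r}, "
            f"turn type {turn_type!r}"
        ) from None


def iter_dft_geometries():
    """All packaged DFT geometries, in table order."""
    return list(_DFT["geometries"].values())


def dft_peptides() -> dict:
    """Peptide metadata: id -> {sequence, turn_start}."""
    return {
        pid: {"sequence": list(meta["sequence"]), "turn_start": int(meta["turn_start"])}
        for pid, meta in _DFT["peptides"].items()
    }


def angle_array(quadruple) -> np.ndarray:
    return np.asarray(quadruple, dtype=float)
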