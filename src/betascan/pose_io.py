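"""Ligand pose coordinates in a fixed receptor frame.

Poses are ligand-only coordinate sets expressed in the receptor frame of an
experimentally determined complex.  Nothing here ever superposes, recentres
or otherwise re-fits coordinates: displacement of a pose relative to the
reference ligand is a physical displacement within the binding pocket, and
keeping the frame fixed is what makes the displacement descriptor meaningful.

Two text dialects are supported: multi-model PDB (MODEL/ENDMDL blocks with
fixed-width ATOM/HETATM records) and a read-only PDBQT subset (ATOM records;
ROOT/BRANCH/TORSDOF bookkeeping ignored).  Docking scores travel in a
``REMARK SCORE`` line inside each model block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Pose",
    "ResidueSelection",
    "PoseParseError",
    "SelectionError",
    "read_poses",
    "write_poses",
    "select_residue",
    "phenyl_ring_selection",
]

#: Cyclic order of the six aromatic ring carbons of a Phe-like side chain.
RING_ATOM_CYCLE = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")


class PoseParseError(ValueError):
    """Malformed pose file; message carries the offending line number."""


class SelectionError(KeyError):
    """A residue selection could not be resolved against a pose."""


@dataclass(frozen=True)
class AtomRecord:
    atom_name: str
    element: str
    residue_index: int
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise ValueError(f"residue_index must be >= 1, got {self.residue_index}")
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError("non-finite coordinate")

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass(frozen=True)
class Pose:
    compound_id: str
    model_id: int
    atoms: tuple[AtomRecord, ...]
    score: float | None = None

    def __post_init__(self) -> None:
        if len(self.atoms) < 1:
            raise ValueError("pose must contain at least one atom")
        object.__setattr__(self, "atoms", tuple(self.atoms))

    def coordinates(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms])


@dataclass(frozen=True)
class ResidueSelection:
    """Named atoms of one residue, with optional ring-flip symmetry.

    Each symmetry group lists atom names in cyclic (ring) order; the group
    contributes the ring-flip automorphism that reverses the cycle about its
    first atom — for a phenyl ring attached through CG this is the 180° flip
    exchanging CD1/CD2 and CE1/CE2.
    """

    residue_index: int
    atom_names: tuple[str, ...]
    symmetry_groups: tuple[tuple[str, ...], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "atom_names", tuple(self.atom_names))
        object.__setattr__(
            self, "symmetry_groups", tuple(tuple(g) for g in self.symmetry_groups)
        )
        if len(set(self.atom_names)) != len(self.atom_names):
            raise ValueError("duplicate atom names in selection")
        names = set(self.atom_names)
        for group in self.symmetry_groups:
            if not set(group) <= names:
                raise ValueError(
                    f"symmetry group {group} not a subset of selected atoms"
                )


def phenyl_ring_selection(residue_index: int = 4) -> ResidueSelection:
    """The six aromatic ring carbons of a Phe-like residue with flip symmetry."""
    return ResidueSelection(
        residue_index=residue_index,
        atom_names=RING_ATOM_CYCLE,
        symmetry_groups=(RING_ATOM_CYCLE,),
    )


def select_residue(pose: Pose, selection: ResidueSelection) -> np.ndarray:
    """Coordinates of the selected atoms, in the selection's atom order."""
    by_name = {
        a.atom_name: a for a in pose.atoms if a.residue_index == selection.residue_index
    }
    missing = [n for n in selection.atom_names if n not in by_name]
    if missing:
        raise SelectionError(
            f"atoms {missing} absent from residue {selection.residue_index} "
            f"of pose {pose.compound_id!r}"
        )
    return np.array([by_name[n].xyz for n in selection.atom_names])


# --- file formats -----------------------------------------------------------

_GUESSABLE_ELEMENTS = {"C", "N", "O", "S", "H", "P", "F"}


def _element_from_name(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha() and ch.upper() in _GUESSABLE_ELEMENTS:
            return ch.upper()
    return atom_name.strip()[:1].upper()


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    try:
        name = line[12:16].strip()
        resseq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = line[76:78].strip() if len(line) >= 77 else ""
    except (ValueError, IndexError) as exc:
        raise PoseParseError(f"line {lineno}: malformed ATOM record: {exc}") from None
    if not name:
        raise PoseParseError(f"line {lineno}: empty atom name")
    if not element or not element.isalpha():
        element = _element_from_name(name)
    try:
        return AtomRecord(name, element, resseq, x, y, z)
    except ValueError as exc:
        raise PoseParseError(f"line {lineno}: {exc}") from None


def read_poses(
    path: str | Path, dialect: str = "pdb_multimodel", compound_id: str | None = None
) -> list[Pose]:
    """Read ligand poses, one per MODEL block (a file without MODEL records
    is treated as a single model).  Atom order and coordinates are preserved
    exactly as printed; no recentring or alignment is applied."""
    if dialect not in ("pdb_multimodel", "pdbqt"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    cid = compound_id or path.stem
    poses: list[Pose] = []
    atoms: list[AtomRecord] = []
    score: float | None = None
    model_id = 0
    in_model = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            if in_model:
                raise PoseParseError(f"line {lineno}: nested MODEL record")
            in_model = True
            atoms, score = [], None
            try:
                model_id = int(line.split()[1])
            except (IndexError, ValueError):
                model_id = len(poses) + 1
        elif rec == "ENDMDL":
            if not in_model:
                raise PoseParseError(f"line {lineno}: ENDMDL without MODEL")
            if not atoms:
                raise PoseParseError(f"line {lineno}: model with no atoms")
            poses.append(Pose(cid, model_id, tuple(atoms), score))
            in_model = False
            atoms, score = [], None
        elif rec in ("ATOM", "HETATM"):
            atoms.append(_parse_atom_line(line, lineno))
        elif rec == "REMARK" and "SCORE" in line:
            try:
                score = float(line.split()[-1])
            except ValueError:
                raise PoseParseError(f"line {lineno}: unreadable SCORE remark")
        # ROOT/ENDROOT/BRANCH/ENDBRANCH/TORSDOF (PDBQT), TER, COMPND etc.
        # carry no coordinates and are skipped.
    if in_model:
        raise PoseParseError("unterminated MODEL block at end of file")
    if atoms:  # single-model file without MODEL/ENDMDL wrapping
        poses.append(Pose(cid, 1, tuple(atoms), score))
    if not poses:
        raise PoseParseError(f"no models found in {path}")
    return poses


_RESNAMES = {1: "TYR", 2: "ALA", 3: "PHE", 4: "PHE"}


def _format_atom_line(
    serial: int, atom: AtomRecord, dialect: str, record: str = "ATOM"
) -> str:
    resname = _RESNAMES.get(atom.residue_index, "LIG")
    name = atom.atom_name
    # wwPDB convention: atom names of 1-3 chars start in column 14
    padded = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    line = (
        f"{record:<6s}{serial:>5d} {padded} {resname:<3s} A{atom.residue_index:>4d}    "
        f"{atom.x:>8.3f}{atom.y:>8.3f}{atom.z:>8.3f}{1.0:>6.2f}{0.0:>6.2f}"
    )
    if dialect == "pdbqt":
        return f"{line}    {0.0:>6.3f} {atom.element:<2s}"
    return f"{line}          {atom.element:>2s}"


def write_poses(
    poses: Sequence[Pose] | Pose, path: str | Path, dialect: str = "pdb_multimodel"
) -> Path:
    """Write poses as a multi-model PDB (or a PDBQT-flavoured variant used
    for reader testing).  Coordinates are printed at 1e-3 Å precision."""
    if isinstance(poses, Pose):
        poses = [poses]
    if dialect not in ("pdb_multimodel", "pdbqt"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    lines: list[str] = []
    for pose in poses:
        lines.append(f"MODEL {pose.model_id:>8d}")
        if pose.score is not None:
            lines.append(f"REMARK   1 SCORE {pose.score:.4f}")
        if dialect == "pdbqt":
            lines.append("ROOT")
        for serial, atom in enumerate(pose.atoms, start=1):
            lines.append(_format_atom_line(serial, atom, dialect))
        if dialect == "pdbqt":
            lines.append("ENDROOT")
            lines.append("TORSDOF 0")
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path
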