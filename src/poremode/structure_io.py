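"""PDB structure and multi-model trajectory I/O plus atom selection.

All geometric work in the package runs on the containers defined here:
:class:`StructureModel` (an ordered list of atoms with chain / residue
identity) and :class:`Trajectory` (a stack of coordinate frames sharing one
topology, with an optional orthorhombic box per frame).

Conventions
-----------
* Coordinates are in Angstrom, residue numbers are 1-based as in the source
  file, and no unit conversion happens internally (nm appears only in
  reporting layers, factor 0.1).
* Alternate locations: altloc ``'A'`` or blank is kept, every other altloc
  is dropped on read, which yields a deterministic single-conformer geometry
  for elastic-network work.
* Insertion codes are carried verbatim; residue identity is the full
  (chain, resid, insertion_code) key and no arithmetic is ever done on them.
* HETATM records are retained and selectable (ions / water pseudo-atoms).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "StructureModel",
    "ResidueKey",
    "Trajectory",
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "select_atoms",
    "calpha_subset",
]


class PDBParseError(ValueError):
    """Raised for malformed or empty PDB input; names the offending line."""


@dataclass(frozen=True)
class ResidueKey:
    """Identity of one residue: chain, residue number, insertion code."""

    chain: str
    resid: int
    insertion_code: str = ""

    def __str__(self) -> str:  # used in error messages and CSV headers
        return f"{self.chain}{self.resid}{self.insertion_code}"


@dataclass
class AtomRecord:
    """One ATOM/HETATM record; ``coords`` is a length-3 float array [Å]."""

    serial: int
    name: str
    resname: str
    chain: str
    resid: int
    coords: np.ndarray
    insertion_code: str = ""
    element: str = ""
    altloc: str = ""
    het: bool = False

    @property
    def residue_key(self) -> ResidueKey:
        return ResidueKey(self.chain, self.resid, self.insertion_code)


@dataclass
class StructureModel:
    """An ordered set of atoms forming one structural model."""

    atoms: list[AtomRecord]
    model_id: int = 1

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array [Å], copied from the records."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        """A copy of this model carrying new coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coords shape {coords.shape} != ({len(self.atoms)}, 3)"
            )
        new_atoms = [replace(a, coords=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return StructureModel(new_atoms, model_id=self.model_id)

    def residue_keys(self) -> list[ResidueKey]:
        """Residue key of every atom, in atom order."""
        return [a.residue_key for a in self.atoms]


@dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed topology.

    ``box`` holds per-frame orthorhombic box edge lengths [Å] (shape
    ``(n_frames, 3)``) or ``None`` for non-periodic data.
    """

    frames: np.ndarray  # (n_frames, n_atoms, 3)
    topology: StructureModel
    box: np.ndarray | None = None
    frame_times: np.ndarray | None = None  # [ns]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != len(self.topology):
            raise ValueError(
                f"frames have {self.frames.shape[1]} atoms but topology has "
                f"{len(self.topology)}"
            )
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.ndim == 1:
                self.box = np.tile(self.box, (self.n_frames, 1))
            if self.box.shape != (self.n_frames, 3):
                raise ValueError("box must broadcast to (n_frames, 3)")
            if not np.all(self.box > 0):
                raise ValueError("box lengths must be strictly positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = lineno  # some generators leave serial blank / overflowed
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PDBParseError(
            f"line {lineno}: malformed coordinate field: {line.rstrip()!r}"
        ) from exc
    coords = np.array([x, y, z], dtype=float)
    if not np.all(np.isfinite(coords)):
        raise PDBParseError(f"line {lineno}: non-finite coordinate")
    resid_str = line[22:26].strip()
    try:
        resid = int(resid_str)
    except ValueError as exc:
        raise PDBParseError(
            f"line {lineno}: malformed residue number {resid_str!r}"
        ) from exc
    return AtomRecord(
        serial=serial,
        name=line[12:16].strip(),
        altloc=line[16].strip(),
        resname=line[17:20].strip(),
        chain=line[21].strip(),
        resid=resid,
        insertion_code=line[26].strip(),
        coords=coords,
        element=line[76:78].strip() if len(line) >= 78 else "",
        het=line.startswith("HETATM"),
    )


def read_pdb(path: str | Path, model_policy: str = "first"):
    """Read a PDB file.

    Parameters
    ----------
    path:
        PDB file with at least one ATOM/HETATM record.
    model_policy:
        ``"first"`` returns the first MODEL as a :class:`StructureModel`;
        ``"all"`` returns a :class:`Trajectory` over every MODEL block
        (topology taken from model 1). Single-model files under ``"all"``
        give a one-frame trajectory.

    Altlocs other than 'A'/blank are dropped. Multi-model files whose models
    disagree in atom count are rejected (they cannot form a trajectory).
    """
    if model_policy not in ("first", "all"):
        raise ValueError(f"model_policy must be 'first' or 'all', got {model_policy!r}")
    path = Path(path)
    models: list[list[AtomRecord]] = []
    current: list[AtomRecord] = []
    in_model_block = False
    saw_model_record = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                saw_model_record = True
                if current:
                    models.append(current)
                    current = []
                in_model_block = True
            elif rec == "ENDMDL":
                models.append(current)
                current = []
                in_model_block = False
                if model_policy == "first" and models:
                    break
            elif rec in ("ATOM  ", "HETATM"):
                atom = _parse_atom_line(line, lineno)
                if atom.altloc not in ("", "A"):
                    continue
                current.append(atom)
    if current:
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")

    structures = [StructureModel(atoms, model_id=i + 1) for i, atoms in enumerate(models)]
    if model_policy == "first":
        return structures[0]
    counts = {len(s) for s in structures}
    if len(counts) != 1:
        raise PDBParseError(
            f"{path}: models have heterogeneous atom counts {sorted(counts)}; "
            "cannot form a trajectory"
        )
    frames = np.stack([s.coords for s in structures])
    del saw_model_record  # single-model 'all' is a 1-frame trajectory by contract
    return Trajectory(frames=frames, topology=structures[0])


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _format_atom_line(a: AtomRecord, serial: int, coords: np.ndarray) -> str:
    if np.any(np.abs(coords) >= 1e5):
        raise ValueError(
            f"coordinate magnitude >= 1e5 Å overflows the fixed-width PDB field "
            f"(atom serial {serial})"
        )
    record = "HETATM" if a.het else "ATOM  "
    # atom name column convention: names of <4 chars start in column 14
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    return (
        f"{record}{serial % 100000:5d} {name:<4.4s}{a.altloc or ' ':1s}"
        f"{a.resname:>3.3s} {a.chain or ' ':1s}{a.resid:4d}{a.insertion_code or ' ':1s}"
        f"   {coords[0]:8.3f}{coords[1]:8.3f}{coords[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2.2s}\n"
    )


def write_pdb(obj: StructureModel | Trajectory, path: str | Path) -> None:
    """Write a structure, or a trajectory as MODEL/ENDMDL blocks.

    Coordinates are emitted fixed-width ``%8.3f``; magnitudes ≥ 1e5 Å are
    refused (field overflow). Single structures get no MODEL records.
    """
    path = Path(path)
    with open(path, "w") as fh:
        if isinstance(obj, StructureModel):
            coords = obj.coords
            if not np.all(np.isfinite(coords)):
                raise ValueError("coordinates must be finite")
            for i, a in enumerate(obj.atoms):
                fh.write(_format_atom_line(a, i + 1, coords[i]))
            fh.write("END\n")
        elif isinstance(obj, Trajectory):
            if not np.all(np.isfinite(obj.frames)):
                raise ValueError("coordinates must be finite")
            for f in range(obj.n_frames):
                fh.write(f"MODEL     {f + 1:4d}\n")
                for i, a in enumerate(obj.topology.atoms):
                    fh.write(_format_atom_line(a, i + 1, obj.frames[f, i]))
                fh.write("ENDMDL\n")
            fh.write("END\n")
        else:  # pragma: no cover - defensive
            raise TypeError(f"cannot write object of type {type(obj).__name__}")


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

ANY = None  # sentinel: match anything


def select_atoms(
    structure: StructureModel,
    chain: str | None = ANY,
    resids: Iterable[int] | None = ANY,
    names: Iterable[str] | None = ANY,
) -> list[int]:
    """Indices (ascending atom order) of atoms matching every given filter.

    ``None`` for a filter means "match anything". An empty result is valid;
    callers decide whether that is an error.
    """
    if not structure.atoms:
        raise ValueError("cannot select from an empty structure")
    resid_set = None if resids is ANY else set(resids)
    name_set = None if names is ANY else set(names)
    out: list[int] = []
    for i, a in enumerate(structure.atoms):
        if chain is not ANY and a.chain != chain:
            continue
        if resid_set is not None and a.resid not in resid_set:
            continue
        if name_set is not None and a.name not in name_set:
            continue
        out.append(i)
    return out


def resolve_residue(structure: StructureModel, key: ResidueKey, name: str | None = None) -> list[int]:
    """Atom indices of one residue (optionally one named atom); errors if absent."""
    out = [
        i
        for i, a in enumerate(structure.atoms)
        if a.chain == key.chain
        and a.resid == key.resid
        and a.insertion_code == key.insertion_code
        and (name is None or a.name == name)
    ]
    if not out:
        what = f"atom {name} of residue {key}" if name else f"residue {key}"
        raise KeyError(f"{what} not found in structure")
    return out


def calpha_subset(structure: StructureModel) -> StructureModel:
    """The Cα-only substructure, order preserved, one CA per residue.

    Where CA altlocs survived reading (altloc 'A' and blank both present),
    the first occurrence per residue is kept. Idempotent.
    """
    seen: set[ResidueKey] = set()
    atoms: list[AtomRecord] = []
    for a in structure.atoms:
        if a.name != "CA":
            continue
        key = a.residue_key
        if key in seen:
            continue
        seen.add(key)
        atoms.append(a)
    if not atoms:
        raise ValueError("structure contains no CA atoms")
    return StructureModel(atoms, model_id=structure.model_id)
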