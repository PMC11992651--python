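"""Structural data model, fixed-column PDB I/O, and residue-range selections.

The containers here are deliberately small: an atom, a structure (one
model), a trajectory (many coordinate sets over one topology), and a
region scheme naming residue ranges (CDR loops, hinge spans) by author
numbering.  Multi-model PDB is the trajectory interchange format; frames
are MODEL/ENDMDL blocks sharing one atom ordering.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Residue",
    "Structure",
    "Trajectory",
    "RegionScheme",
    "Selection",
    "PDBParseError",
    "StructuralInconsistencyError",
    "MissingAtomError",
    "EmptySelectionWarning",
    "read_pdb",
    "write_pdb",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "select_region",
    "ca_coordinates",
    "default_region_scheme",
]


class PDBParseError(ValueError):
    """A PDB record could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class StructuralInconsistencyError(ValueError):
    """Models of a multi-model file disagree on atom count or ordering."""


class MissingAtomError(KeyError):
    """A residue lacks an atom required by the requested operation."""


class EmptySelectionWarning(UserWarning):
    """A region selection matched no residues in the structure."""


_HYDROGEN_ELEMENTS = {"H", "D"}


@dataclass(frozen=True)
class AtomRecord:
    """One ATOM/HETATM record in author numbering.

    ``xyz`` is in Angstrom. ``is_heavy`` is derived from the element
    symbol (everything except hydrogen/deuterium).
    """

    serial: int
    name: str
    residue_name: str
    chain_id: str
    residue_number: int
    xyz: np.ndarray
    element: str

    def __post_init__(self):
        xyz = np.asarray(self.xyz, dtype=float)
        if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
            raise ValueError(f"atom {self.serial}: xyz must be a finite 3-vector")
        object.__setattr__(self, "xyz", xyz)

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in _HYDROGEN_ELEMENTS


@dataclass(frozen=True)
class Residue:
    """All atoms sharing one (chain, residue number)."""

    chain_id: str
    residue_number: int
    residue_name: str
    atoms: tuple[AtomRecord, ...]

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_number)

    def atom(self, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.name == name:
                return a
        raise MissingAtomError(
            f"residue {self.chain_id}/{self.residue_name}{self.residue_number} "
            f"has no atom named {name!r}"
        )

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def heavy_atom_coords(self) -> np.ndarray:
        coords = [a.xyz for a in self.atoms if a.is_heavy]
        if not coords:
            raise MissingAtomError(
                f"residue {self.chain_id}/{self.residue_number} has no heavy atoms"
            )
        return np.asarray(coords)


class Structure:
    """An ordered list of atoms with a derived per-chain residue index.

    Atoms of one residue must be contiguous and (chain, residue number,
    atom name) must be unique — both are validated on construction.
    """

    def __init__(self, atoms: Sequence[AtomRecord]):
        self.atoms: tuple[AtomRecord, ...] = tuple(atoms)
        if not self.atoms:
            raise ValueError("Structure requires at least one atom")
        self._residues: list[Residue] = []
        self._index: dict[tuple[str, int], Residue] = {}
        self._build_index()

    def _build_index(self) -> None:
        seen_atom_keys: set[tuple[str, int, str]] = set()
        current: list[AtomRecord] = []

        def flush():
            if not current:
                return
            res = Residue(
                chain_id=current[0].chain_id,
                residue_number=current[0].residue_number,
                residue_name=current[0].residue_name,
                atoms=tuple(current),
            )
            if res.key in self._index:
                raise ValueError(
                    f"atoms of residue {res.key} are not contiguous in the atom list"
                )
            self._residues.append(res)
            self._index[res.key] = res

        for atom in self.atoms:
            akey = (atom.chain_id, atom.residue_number, atom.name)
            if akey in seen_atom_keys:
                raise ValueError(f"duplicate atom {akey}")
            seen_atom_keys.add(akey)
            if current and (atom.chain_id, atom.residue_number) != (
                current[0].chain_id,
                current[0].residue_number,
            ):
                flush()
                current = []
            current.append(atom)
        flush()

    @property
    def residues(self) -> tuple[Residue, ...]:
        return tuple(self._residues)

    @property
    def chains(self) -> dict[str, tuple[Residue, ...]]:
        out: dict[str, list[Residue]] = {}
        for res in self._residues:
            out.setdefault(res.chain_id, []).append(res)
        return {c: tuple(rs) for c, rs in out.items()}

    def residue(self, chain_id: str, residue_number: int) -> Residue:
        try:
            return self._index[(chain_id, residue_number)]
        except KeyError:
            raise MissingAtomError(
                f"no residue {chain_id}/{residue_number} in structure"
            ) from None

    def has_residue(self, chain_id: str, residue_number: int) -> bool:
        return (chain_id, residue_number) in self._index

    def coordinates(self) -> np.ndarray:
        return np.asarray([a.xyz for a in self.atoms])

    def with_coordinates(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coordinate array shape {coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        atoms = [
            AtomRecord(a.serial, a.name, a.residue_name, a.chain_id,
                       a.residue_number, xyz, a.element)
            for a, xyz in zip(self.atoms, coords)
        ]
        return Structure(atoms)

    def __len__(self) -> int:
        return len(self.atoms)


class Trajectory:
    """Ordered coordinate frames over one topology, with frame times in ns."""

    def __init__(self, topology: Structure, frames: np.ndarray, times: Sequence[float]):
        frames = np.asarray(frames, dtype=float)
        times_arr = np.asarray(times, dtype=float)
        if frames.ndim != 3 or frames.shape[1] != len(topology.atoms) or frames.shape[2] != 3:
            raise ValueError(
                f"frames must have shape (n_frames, {len(topology.atoms)}, 3); "
                f"got {frames.shape}"
            )
        if len(times_arr) != frames.shape[0]:
            raise ValueError("times length must equal frame count")
        if len(times_arr) > 1 and not np.all(np.diff(times_arr) > 0):
            raise ValueError("frame times must be strictly increasing")
        self.topology = topology
        self.frames = frames
        self.times = times_arr

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_structure(self, index: int) -> Structure:
        return self.topology.with_coordinates(self.frames[index])

    def __len__(self) -> int:
        return self.n_frames


@dataclass(frozen=True)
class RegionScheme:
    """Named residue-range sets in author numbering.

    A region is a set of (chain_id, residue_number) pairs; ``chain_id``
    of ``None`` matches any chain, which keeps toy fixtures independent
    of chain labelling.  ``chain_offsets`` lets callers reconcile author
    numbering against renumbered constructs (mature-sequence numbering
    vs. expression-construct numbering) without touching the structure.
    """

    regions: Mapping[str, frozenset[tuple[str | None, int]]]
    numbering_note: str = ""
    chain_offsets: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for name, members in self.regions.items():
            if not members:
                raise ValueError(f"region {name!r} is empty")

    def region_names(self) -> tuple[str, ...]:
        return tuple(self.regions)

    def members(self, name: str) -> frozenset[tuple[str | None, int]]:
        if name not in self.regions:
            raise KeyError(
                f"unknown region {name!r}; known: {sorted(self.regions)}"
            )
        return self.regions[name]

    def union(self, names: Iterable[str]) -> frozenset[tuple[str | None, int]]:
        out: set[tuple[str | None, int]] = set()
        for n in names:
            out |= self.members(n)
        return frozenset(out)


def _range_region(lo: int, hi: int, chain: str | None = None) -> frozenset:
    return frozenset((chain, i) for i in range(lo, hi + 1))


def default_region_scheme() -> RegionScheme:
    """The TREM2/ApoE region scheme used throughout the analysis.

    TREM2 Ig-domain CDR loops: CDR1 aa40-47, CDR2 aa67-78, CDR3
    aa115-120.  ApoE hinge: canonical aa167-191, extended aa192-231;
    ``hinge_full`` is the combined span used by the docking-pose filter.
    """
    return RegionScheme(
        regions={
            "CDR1": _range_region(40, 47),
            "CDR2": _range_region(67, 78),
            "CDR3": _range_region(115, 120),
            "hinge": _range_region(167, 191),
            "extended_hinge": _range_region(192, 231),
            "hinge_full": _range_region(167, 231),
        },
        numbering_note=(
            "TREM2 Ig domain in mature-protein numbering (domain spans "
            "N20-D131); ApoE numbered 1-299 on the mature chain"
        ),
    )


def scheme_from_toml(text: str) -> RegionScheme:
    """Build a RegionScheme from a TOML block.

    Expected layout::

        numbering_note = "..."
        [regions]
        CDR2 = [67, 78]          # inclusive range, any chain
        hinge = ["B", 167, 191]  # chain-qualified range

        [chain_offsets]
        A = 0
    """
    import tomllib

    data = tomllib.loads(text)
    regions: dict[str, frozenset] = {}
    for name, spec in data.get("regions", {}).items():
        if len(spec) == 2:
            chain, lo, hi = None, int(spec[0]), int(spec[1])
        elif len(spec) == 3:
            chain, lo, hi = str(spec[0]), int(spec[1]), int(spec[2])
        else:
            raise ValueError(
                f"region {name!r}: expected [lo, hi] or [chain, lo, hi]"
            )
        regions[name] = _range_region(lo, hi, chain)
    return RegionScheme(
        regions=regions,
        numbering_note=data.get("numbering_note", ""),
        chain_offsets={str(k): int(v) for k, v in data.get("chain_offsets", {}).items()},
    )


@dataclass(frozen=True)
class Selection:
    """Resolved region selection: present residues plus the skipped set."""

    name: str
    residues: tuple[Residue, ...]
    skipped: tuple[tuple[str | None, int], ...]

    def __len__(self) -> int:
        return len(self.residues)

    def keys(self) -> tuple[tuple[str, int], ...]:
        return tuple(r.key for r in self.residues)


# ---------------------------------------------------------------------------
# PDB fixed-column parsing

def _parse_float(line: str, lo: int, hi: int, what: str, lineno: int) -> float:
    text = line[lo:hi].strip()
    try:
        return float(text)
    except ValueError:
        raise PDBParseError(f"malformed {what} field {text!r}", lineno) from None


def _parse_int(line: str, lo: int, hi: int, what: str, lineno: int) -> int:
    text = line[lo:hi].strip()
    try:
        return int(text)
    except ValueError:
        raise PDBParseError(f"malformed {what} field {text!r}", lineno) from None


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip()
    # Leading digits (e.g. 1HB) indicate hydrogens in some conventions
    core = stripped.lstrip("0123456789")
    if not core:
        return ""
    if core[0] in "HD" and len(stripped) <= 4:
        return core[0]
    return core[0]


def _parse_atom_line(line: str, lineno: int, seen_altloc: dict) -> AtomRecord | None:
    line = line.rstrip("\n")
    if len(line) < 54:
        raise PDBParseError("ATOM record shorter than coordinate fields", lineno)
    serial = _parse_int(line, 6, 11, "serial", lineno)
    name = line[12:16].strip()
    altloc = line[16:17]
    resname = line[17:20].strip()
    chain = line[21:22]
    resnum = _parse_int(line, 22, 26, "residue number", lineno)
    icode = line[26:27]
    if icode not in (" ", ""):
        raise PDBParseError(
            f"insertion code {icode!r} not supported", lineno
        )
    x = _parse_float(line, 30, 38, "x coordinate", lineno)
    y = _parse_float(line, 38, 46, "y coordinate", lineno)
    z = _parse_float(line, 46, 54, "z coordinate", lineno)
    if altloc not in (" ", ""):
        # keep only the first altloc seen per atom site
        site = (chain, resnum, name)
        kept = seen_altloc.setdefault(site, altloc)
        if altloc != kept:
            return None
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = _guess_element(line[12:16])
    return AtomRecord(serial, name, resname, chain, resnum, np.array([x, y, z]), element)


def _as_lines(source) -> list[str]:
    if isinstance(source, str):
        return source.splitlines()
    if isinstance(source, io.IOBase) or hasattr(source, "read"):
        return source.read().splitlines()
    raise TypeError("source must be PDB text or a text stream")


def read_pdb(source) -> Structure:
    """Parse a single-model PDB from text or a text stream.

    Raises :class:`PDBParseError` (with the offending line number) on a
    malformed record, and ``ValueError`` if the file contains no atoms
    or more than one MODEL block.
    """
    lines = _as_lines(source)
    atoms: list[AtomRecord] = []
    seen_altloc: dict = {}
    model_count = 0
    for lineno, line in enumerate(lines, start=1):
        rec = line[:6]
        if rec == "MODEL ":
            model_count += 1
            if model_count > 1:
                raise ValueError(
                    "multi-model file passed to read_pdb; use read_multimodel_pdb"
                )
        elif rec in ("ATOM  ", "HETATM"):
            atom = _parse_atom_line(line, lineno, seen_altloc)
            if atom is not None:
                atoms.append(atom)
    if not atoms:
        raise ValueError("no ATOM/HETATM records found")
    return Structure(atoms)


def read_multimodel_pdb(source, frame_dt: float = 0.5) -> Trajectory:
    """Parse a multi-model PDB into a Trajectory.

    One frame per MODEL block; frame times are ``0, dt, 2*dt, ...`` ns.
    A file without MODEL records is read as a single frame.  All models
    must share the atom ordering of the first; a mismatch raises
    :class:`StructuralInconsistencyError` naming the model.
    """
    if frame_dt <= 0:
        raise ValueError("frame_dt must be positive")
    lines = _as_lines(source)
    models: list[list[AtomRecord]] = []
    current: list[AtomRecord] | None = None
    seen_altloc: dict = {}
    saw_model = False
    for lineno, line in enumerate(lines, start=1):
        rec = line[:6]
        if rec == "MODEL ":
            saw_model = True
            current = []
        elif rec == "ENDMDL":
            if current is None:
                raise PDBParseError("ENDMDL without MODEL", lineno)
            models.append(current)
            current = None
            seen_altloc = {}
        elif rec in ("ATOM  ", "HETATM"):
            atom = _parse_atom_line(line, lineno, seen_altloc)
            if atom is None:
                continue
            if current is None:
                if saw_model:
                    raise PDBParseError("ATOM record outside MODEL block", lineno)
                current = []
                saw_model = False
            current.append(atom)
    if current:
        models.append(current)
    if not models or not models[0]:
        raise ValueError("no ATOM/HETATM records found")

    topology = Structure(models[0])
    ref_ids = [(a.chain_id, a.residue_number, a.name) for a in models[0]]
    frames = np.empty((len(models), len(ref_ids), 3))
    for m, model_atoms in enumerate(models, start=1):
        ids = [(a.chain_id, a.residue_number, a.name) for a in model_atoms]
        if ids != ref_ids:
            raise StructuralInconsistencyError(
                f"model {m} has {len(ids)} atoms / ordering inconsistent with "
                f"model 1 ({len(ref_ids)} atoms)"
            )
        frames[m - 1] = [a.xyz for a in model_atoms]
    times = frame_dt * np.arange(len(models))
    return Trajectory(topology, frames, times)


def _format_atom_line(atom: AtomRecord) -> str:
    name = atom.name
    # standard PDB justification: names of <4 chars start in column 14
    if len(name) < 4:
        name = f" {name:<3s}"
    return (
        f"ATOM  {atom.serial:>5d} {name:<4s} {atom.residue_name:>3s} "
        f"{atom.chain_id:1s}{atom.residue_number:>4d}    "
        f"{atom.xyz[0]:8.3f}{atom.xyz[1]:8.3f}{atom.xyz[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}"
    )


def write_pdb(structure: Structure, stream=None) -> str:
    """Serialize a single-model structure to PDB text (also returned)."""
    lines = [_format_atom_line(a) for a in structure.atoms]
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if stream is not None:
        stream.write(text)
    return text


def write_multimodel_pdb(trajectory: Trajectory, stream=None) -> str:
    """Serialize a trajectory as MODEL/ENDMDL blocks."""
    out: list[str] = []
    for i in range(trajectory.n_frames):
        out.append(f"MODEL {i + 1:>8d}")
        frame = trajectory.frame_structure(i)
        out.extend(_format_atom_line(a) for a in frame.atoms)
        out.append("ENDMDL")
    out.append("END")
    text = "\n".join(out) + "\n"
    if stream is not None:
        stream.write(text)
    return text


def select_region(structure: Structure, scheme: RegionScheme, name: str) -> Selection:
    """Resolve a named region against a structure.

    Residues in the region but absent from the structure are skipped and
    reported in ``Selection.skipped``.  An empty intersection emits
    :class:`EmptySelectionWarning` rather than raising.  Output order is
    (chain, residue_number)-sorted and stable.
    """
    members = scheme.members(name)
    found: list[Residue] = []
    skipped: list[tuple[str | None, int]] = []
    chains = sorted(structure.chains)
    for chain, resnum in sorted(members, key=lambda m: ("" if m[0] is None else m[0], m[1])):
        offset = scheme.chain_offsets.get(chain or "", 0)
        target = resnum + offset
        if chain is None:
            hits = [structure.residue(c, target) for c in chains
                    if structure.has_residue(c, target)]
            if hits:
                found.extend(hits)
            else:
                skipped.append((chain, resnum))
        elif structure.has_residue(chain, target):
            found.append(structure.residue(chain, target))
        else:
            skipped.append((chain, resnum))
    found.sort(key=lambda r: r.key)
    if not found:
        warnings.warn(
            f"region {name!r} matched no residues in structure",
            EmptySelectionWarning,
            stacklevel=2,
        )
    return Selection(name=name, residues=tuple(found), skipped=tuple(skipped))


def ca_coordinates(trajectory: Trajectory, residues: Sequence[Residue]) -> np.ndarray:
    """Cα coordinates per frame for the given residues.

    Returns an array of shape (n_frames, n_residues, 3) whose column
    order matches the input residue order.  Raises
    :class:`MissingAtomError` naming any residue without a CA atom.
    """
    if not residues:
        raise ValueError("residue list is empty")
    atom_index = {
        (a.chain_id, a.residue_number, a.name): i
        for i, a in enumerate(trajectory.topology.atoms)
    }
    cols = []
    for res in residues:
        key = (res.chain_id, res.residue_number, "CA")
        if key not in atom_index:
            raise MissingAtomError(
                f"residue {res.chain_id}/{res.residue_name}{res.residue_number} "
                "has no CA atom"
            )
        cols.append(atom_index[key])
    return trajectory.frames[:, cols, :]
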