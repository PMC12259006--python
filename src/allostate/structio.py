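"""Structure and trajectory I/O for multi-model PDB files, plus atom selection.

Conformational ensembles are interchanged as fixed-column, multi-model PDB
text (one MODEL/ENDMDL block per frame).  The in-memory containers are a
:class:`Topology` (atom metadata) and a :class:`Trajectory`
(``n_frames x n_atoms x 3`` coordinates in Angstrom).  Residue numbering is
1-based and taken verbatim from the PDB columns; residue identifiers used in
analyses (e.g. the linchpin lysine) are interpreted in the reference file's
own numbering.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Topology",
    "Trajectory",
    "AtomSelection",
    "PDBParseError",
    "SelectionError",
    "read_structure",
    "write_trajectory",
    "select_atoms",
    "strip_chains",
]

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})

#: residue names treated as solvent/ions and skipped from HETATM records
_SKIP_HET_RESNAMES = frozenset(
    {"HOH", "WAT", "SOL", "TIP3", "TIP4", "NA", "CL", "K", "MG", "CA", "ZN", "MN", "FE"}
)

_TWO_LETTER_ELEMENTS = frozenset(
    {"FE", "ZN", "MG", "NA", "CL", "BR", "SE", "MN", "CU", "NI", "CO", "CD", "HG"}
)


class PDBParseError(ValueError):
    """Raised when a PDB record cannot be parsed; names the offending line."""


class SelectionError(ValueError):
    """Raised when a selection expression cannot be parsed."""


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str


@dataclass
class Topology:
    """Ordered atom metadata shared by every frame of a trajectory."""

    atoms: list[Atom]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def names(self) -> np.ndarray:
        return np.array([a.name for a in self.atoms])

    def elements(self) -> np.ndarray:
        return np.array([a.element for a in self.atoms])

    def residue_indices(self) -> np.ndarray:
        return np.array([a.residue_index for a in self.atoms])

    def residue_names(self) -> np.ndarray:
        return np.array([a.residue_name for a in self.atoms])

    def chain_ids(self) -> np.ndarray:
        return np.array([a.chain_id for a in self.atoms])

    def residues(self) -> list[tuple[str, int, str]]:
        """Unique ``(chain_id, residue_index, residue_name)`` in file order."""
        seen: dict[tuple[str, int], str] = {}
        for a in self.atoms:
            seen.setdefault((a.chain_id, a.residue_index), a.residue_name)
        return [(c, r, n) for (c, r), n in seen.items()]

    def atom_index(self, chain_id: str, residue_index: int, name: str) -> int | None:
        for i, a in enumerate(self.atoms):
            if a.chain_id == chain_id and a.residue_index == residue_index and a.name == name:
                return i
        return None

    def validate(self) -> None:
        keys = {(a.chain_id, a.residue_index, a.name) for a in self.atoms}
        if len(keys) != len(self.atoms):
            raise ValueError("duplicate (chain, residue, atom name) in topology")
        for a in self.atoms:
            if not a.element:
                raise ValueError(f"atom serial {a.serial} has empty element")
        last: dict[str, int] = {}
        for a in self.atoms:
            if a.chain_id in last and a.residue_index < last[a.chain_id]:
                raise ValueError(
                    f"residue index decreases within chain {a.chain_id!r} at serial {a.serial}"
                )
            last[a.chain_id] = a.residue_index


@dataclass
class Trajectory:
    """A topology plus ``n_frames x n_atoms x 3`` coordinates in Angstrom."""

    topology: Topology
    coords: np.ndarray
    frame_interval: float | None = None  # ns between frames, if known

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coords second dimension {self.coords.shape[1]} != "
                f"topology atom count {self.topology.n_atoms}"
            )
        if self.coords.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]


@dataclass
class AtomSelection:
    """An ordered, strictly increasing list of atom positions."""

    indices: np.ndarray
    spec: str = ""

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.intp)
        if self.indices.size and np.any(np.diff(self.indices) <= 0):
            raise ValueError("selection indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.indices.size)


def _infer_element(name_field: str) -> str:
    """Guess the element from the atom-name columns when cols 77-78 are blank."""
    raw = name_field.strip()
    stripped = raw.lstrip("0123456789")
    if not stripped:
        return ""
    # two-letter elements occupy column 13 (name_field[0] non-blank)
    cand = stripped[:2].upper()
    if len(name_field) >= 2 and name_field[0] != " " and cand in _TWO_LETTER_ELEMENTS:
        return cand.capitalize()
    return stripped[0].upper()


def read_structure(pdb_text: str, keep_hetero: bool = True) -> Trajectory:
    """Parse fixed-column (multi-model) PDB text into a :class:`Trajectory`.

    One frame per MODEL block (a single frame if no MODEL records).  Alternate
    locations other than ``' '``/``'A'`` are dropped; HETATM records for water
    and common ions are always skipped, other HETATM records are kept when
    ``keep_hetero``.
    """
    frames: list[list[tuple[float, float, float]]] = []
    atoms: list[Atom] = []
    current: list[tuple[float, float, float]] | None = None
    first_model_done = False

    def finish_model() -> None:
        nonlocal current, first_model_done
        if current is None:
            return
        if first_model_done and len(current) != len(atoms):
            raise PDBParseError(
                f"model {len(frames) + 1} has {len(current)} atoms, expected {len(atoms)}"
            )
        frames.append(current)
        first_model_done = True
        current = None

    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6]
        if rec.startswith("MODEL"):
            finish_model()
            current = []
        elif rec.startswith("ENDMDL"):
            finish_model()
        elif rec in ("ATOM  ", "HETATM") or rec.rstrip() in ("ATOM", "HETATM"):
            altloc = line[16] if len(line) > 16 else " "
            if altloc not in (" ", "A"):
                continue
            resname = line[17:20].strip()
            if rec.startswith("HETATM") and (
                resname in _SKIP_HET_RESNAMES or not keep_hetero
            ):
                continue
            try:
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as exc:
                raise PDBParseError(f"line {lineno}: bad coordinate field: {exc}") from None
            if current is None:
                current = []
            if not first_model_done:
                try:
                    serial = int(line[6:11])
                except ValueError:
                    raise PDBParseError(f"line {lineno}: bad serial field") from None
                name = line[12:16].strip()
                try:
                    resid = int(line[22:26])
                except ValueError:
                    raise PDBParseError(f"line {lineno}: bad residue number") from None
                chain = line[21] if len(line) > 21 else " "
                element = line[76:78].strip().capitalize() if len(line) > 76 else ""
                if not element:
                    element = _infer_element(line[12:16])
                if not element:
                    raise PDBParseError(f"line {lineno}: cannot determine element")
                atoms.append(Atom(serial, name, element, resid, resname, chain))
            current.append((x, y, z))

    finish_model()
    if not atoms or not frames:
        raise PDBParseError("no ATOM records found")
    top = Topology(atoms)
    top.validate()
    return Trajectory(top, np.array(frames, dtype=np.float64))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a multi-model PDB (MODEL/ENDMDL per frame, 3-decimal coordinates)."""
    if traj.n_frames < 1 or traj.n_atoms < 1:
        raise ValueError("cannot write an empty trajectory")
    lines: list[str] = []
    for f in range(traj.n_frames):
        lines.append(f"MODEL     {f + 1:4d}")
        for i, a in enumerate(traj.topology.atoms):
            x, y, z = traj.coords[f, i]
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            lines.append(
                f"ATOM  {a.serial % 100000:5d} {name:<4s} {a.residue_name:<3s} "
                f"{a.chain_id}{a.residue_index:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{a.element.upper():>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def strip_chains(traj: Trajectory, chains: Iterable[str]) -> Trajectory:
    """Return a trajectory with all atoms of the given chains removed.

    Used to compute interface burial on one binding partner alone (e.g. the
    bundle SASA of the dimer computed with the partner chain absent).
    """
    drop = set(chains)
    keep = [i for i, a in enumerate(traj.topology.atoms) if a.chain_id not in drop]
    if not keep:
        raise ValueError("stripping chains would remove every atom")
    top = Topology([traj.topology.atoms[i] for i in keep])
    return Trajectory(top, traj.coords[:, keep, :], traj.frame_interval)


def _parse_int_list(text: str, offset: int) -> list[int]:
    out: list[int] = []
    for part in text.replace(",", " ").split():
        if "-" in part[1:]:  # allow negative start even though resids are 1-based
            lo_s, hi_s = part.rsplit("-", 1)
            try:
                lo, hi = int(lo_s), int(hi_s)
            except ValueError:
                raise SelectionError(f"bad residue range {part!r} at position {offset}")
            if hi < lo:
                raise SelectionError(f"empty residue range {part!r} at position {offset}")
            out.extend(range(lo, hi + 1))
        else:
            try:
                out.append(int(part))
            except ValueError:
                raise SelectionError(f"bad residue number {part!r} at position {offset}")
    if not out:
        raise SelectionError(f"residue clause without residues at position {offset}")
    return out


def select_atoms(top: Topology, spec: str) -> AtomSelection:
    """Select atoms with a small conjunctive grammar.

    Clauses are joined with ``and`` and intersected (order-independent):

    - ``resid 16-85`` / ``resid 14,88`` — residue ranges and lists (1-based)
    - ``name CA CB`` — atom names
    - ``resname LYS ARG`` — residue names
    - ``chain A`` — chain id
    - ``CA`` | ``heavy`` | ``backbone`` | ``sidechain-heavy`` — atom classes

    ``backbone`` means atoms named N/CA/C/O; ``heavy`` means element != H;
    ``sidechain-heavy`` means heavy and not backbone.  An empty result is
    allowed but emits a warning.
    """
    mask = np.ones(top.n_atoms, dtype=bool)
    names = top.names()
    elements = top.elements()
    resids = top.residue_indices()
    resnames = top.residue_names()
    chains = top.chain_ids()
    is_heavy = elements != "H"
    is_backbone = np.isin(names, list(BACKBONE_NAMES))

    pos = 0
    for clause in spec.split(" and "):
        clause_stripped = clause.strip()
        offset = spec.find(clause_stripped, pos)
        pos = offset + len(clause_stripped)
        words = clause_stripped.split(None, 1)
        if not words:
            raise SelectionError(f"empty clause at position {offset}")
        head = words[0].lower()
        arg = words[1] if len(words) > 1 else ""
        if head == "resid":
            mask &= np.isin(resids, _parse_int_list(arg, offset))
        elif head == "name":
            if not arg:
                raise SelectionError(f"'name' clause without names at position {offset}")
            mask &= np.isin(names, arg.split())
        elif head == "resname":
            if not arg:
                raise SelectionError(f"'resname' clause without names at position {offset}")
            mask &= np.isin(resnames, [w.upper() for w in arg.split()])
        elif head == "chain":
            if not arg:
                raise SelectionError(f"'chain' clause without id at position {offset}")
            mask &= np.isin(chains, arg.split())
        elif head == "ca" and not arg:
            mask &= names == "CA"
        elif head == "heavy" and not arg:
            mask &= is_heavy
        elif head == "backbone" and not arg:
            mask &= is_backbone
        elif head in ("sidechain-heavy", "sidechain_heavy") and not arg:
            mask &= is_heavy & ~is_backbone
        else:
            raise SelectionError(f"cannot parse clause {clause_stripped!r} at position {offset}")

    idx = np.flatnonzero(mask)
    if idx.size == 0:
        warnings.warn(f"selection {spec!r} matched no atoms", stacklevel=2)
    return AtomSelection(idx, spec)
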