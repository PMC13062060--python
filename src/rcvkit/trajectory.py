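"""Core data model: topologies, trajectories and named component selections.

Coordinates are stored in Å throughout.  Residue numbering is 1-based
(matching PDB); atom indices are 0-based.  The only formats handled here are
the ones needed to move small test systems around as plain text: PDB
(ATOM/HETATM with MODEL/ENDMDL) and a trivial ``frames-csv`` dialect with one
row per atom per frame (``frame,atom_index,x,y,z``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Topology",
    "Trajectory",
    "ComponentSelection",
    "PDBParseError",
    "SelectionError",
    "read_structure",
    "read_trajectory",
    "write_pdb",
    "write_frames_csv",
    "resolve_selection",
    "BACKBONE_ATOMS",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class PDBParseError(ValueError):
    """Raised when a PDB record cannot be parsed; carries the line number."""


class SelectionError(ValueError):
    """Raised when a component selection resolves to no atoms."""


@dataclass(frozen=True)
class Atom:
    atom_index: int
    atom_name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str


@dataclass
class Topology:
    """An ordered list of atoms with derived residue grouping.

    Invariants: atom indices are contiguous ``0..N-1``; every atom belongs to
    exactly one ``(chain_id, residue_number)`` pair.
    """

    atoms: list[Atom]

    def __post_init__(self) -> None:
        for i, a in enumerate(self.atoms):
            if a.atom_index != i:
                raise ValueError(f"atom indices must be contiguous; got {a.atom_index} at position {i}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def residues(self) -> list[tuple[str, int, str, list[int]]]:
        """Grouped view: (chain_id, residue_number, residue_name, atom indices)."""
        out: list[tuple[str, int, str, list[int]]] = []
        key = None
        for a in self.atoms:
            k = (a.chain_id, a.residue_number)
            if k != key:
                out.append((a.chain_id, a.residue_number, a.residue_name, []))
                key = k
            out[-1][3].append(a.atom_index)
        return out

    def heavy_indices(self) -> np.ndarray:
        return np.array([a.atom_index for a in self.atoms if a.element != "H"], dtype=int)


@dataclass
class Trajectory:
    """Per-frame Cartesian coordinates (Å) bound to a Topology."""

    topology: Topology
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    times: np.ndarray | None = None  # ns
    replica_id: str = "r0"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError(f"frames must have shape (n_frames, n_atoms, 3); got {self.frames.shape}")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} != topology atom count {self.topology.n_atoms}"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("trajectory contains non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.frames.shape[1])


@dataclass(frozen=True)
class ComponentSelection:
    """A named structural element: residue ranges plus an atom-name filter.

    ``atom_filter`` is one of ``"backbone"`` (N, CA, C, O), ``"heavy"``
    (everything but hydrogen), ``"all"``, or an explicit tuple of atom names.
    """

    name: str
    ranges: tuple[tuple[str, int, int], ...]  # (chain_id, start_res, end_res) inclusive
    atom_filter: str | tuple[str, ...] = "backbone"

    def __post_init__(self) -> None:
        if not self.ranges:
            raise ValueError("selection needs at least one residue range")
        for chain, start, end in self.ranges:
            if start > end:
                raise ValueError(f"range ({chain},{start},{end}): start > end")


def resolve_selection(topology: Topology, sel: ComponentSelection) -> np.ndarray:
    """Resolve a ComponentSelection to a sorted array of 0-based atom indices.

    Idempotent and order-independent over ranges; raises SelectionError naming
    the unmatched ranges if nothing resolves.
    """
    wanted: set[int] = set()
    unmatched = []
    for chain, start, end in sel.ranges:
        hits = [
            a.atom_index
            for a in topology.atoms
            if a.chain_id == chain and start <= a.residue_number <= end and _atom_passes(a, sel.atom_filter)
        ]
        if not hits:
            unmatched.append((chain, start, end))
        wanted.update(hits)
    if not wanted:
        raise SelectionError(f"selection {sel.name!r}: no atoms matched ranges {unmatched}")
    return np.array(sorted(wanted), dtype=int)


def _atom_passes(atom: Atom, atom_filter: str | tuple[str, ...]) -> bool:
    if isinstance(atom_filter, tuple):
        return atom.atom_name in atom_filter
    if atom_filter == "all":
        return True
    if atom_filter == "heavy":
        return atom.element != "H"
    if atom_filter == "backbone":
        return atom.atom_name in BACKBONE_ATOMS
    raise ValueError(f"unknown atom_filter {atom_filter!r}")


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

_ION_NAMES = {"CA": "Ca", "NA": "Na", "MG": "Mg", "ZN": "Zn", "CL": "Cl", "K": "K"}


def _guess_element(atom_name: str, residue_name: str) -> str:
    """Fallback element inference for files lacking columns 77-78.

    A bare ion (atom name == residue name, e.g. CA/CA) is the metal; otherwise
    the first alphabetic character of the atom name is the element, which is
    correct for protein heavy atoms and hydrogens.
    """
    name = atom_name.strip().lstrip("0123456789")
    if atom_name.strip() == residue_name.strip() and name.upper() in _ION_NAMES:
        return _ION_NAMES[name.upper()]
    return name[:1].upper()


def _parse_atom_line(line: str, lineno: int):
    try:
        atom_name = line[12:16].strip()
        altloc = line[16].strip()
        res_name = line[17:20].strip() or line[17:21].strip()
        chain = line[21].strip() or "A"
        res_num = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            element = _guess_element(atom_name, res_name)
        element = element.capitalize() if len(element) > 1 else element.upper()
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"line {lineno}: malformed ATOM/HETATM record: {line.rstrip()!r}") from exc
    if icode:
        raise PDBParseError(f"line {lineno}: insertion codes are not supported (residue {res_num}{icode})")
    return atom_name, altloc, res_name, chain, res_num, x, y, z, occupancy, element


def _read_pdb_models(path: str | Path):
    """Parse a PDB file into a list of models.

    Each model is a list of parsed atom tuples.  Alternate locations are
    resolved to the highest-occupancy conformer (ties: first seen).
    """
    models: list[list] = []
    current: list = []
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec.startswith("MODEL"):
                if current:
                    models.append(current)
                    current = []
                in_model = True
            elif rec.startswith("ENDMDL"):
                models.append(current)
                current = []
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                current.append(_parse_atom_line(line, lineno))
    if current or not models:
        if current:
            models.append(current)
    if not models or all(len(m) == 0 for m in models):
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    return [_resolve_altlocs(m) for m in models if m]


def _resolve_altlocs(parsed: list) -> list:
    # key: (chain, res_num, atom_name) -> keep highest occupancy
    best: dict[tuple, tuple] = {}
    order: list[tuple] = []
    for tup in parsed:
        atom_name, altloc, res_name, chain, res_num, *_rest, occupancy, _el = tup
        key = (chain, res_num, atom_name)
        if key not in best:
            best[key] = tup
            order.append(key)
        elif tup[8] > best[key][8]:  # occupancy comparison
            best[key] = tup
    return [best[k] for k in order]


def read_structure(path: str | Path) -> tuple[Topology, Trajectory]:
    """Read a PDB file into a Topology and a single-frame Trajectory.

    Only the first model defines the returned frame; use
    :func:`read_trajectory` for multi-model files.
    """
    models = _read_pdb_models(path)
    atoms = []
    coords = []
    for i, tup in enumerate(models[0]):
        atom_name, _altloc, res_name, chain, res_num, x, y, z, _occ, element = tup
        atoms.append(Atom(i, atom_name, element, res_name, res_num, chain))
        coords.append((x, y, z))
    topo = Topology(atoms)
    traj = Trajectory(topo, np.asarray(coords, dtype=float)[None, :, :])
    return topo, traj


def read_trajectory(
    paths: Sequence[str | Path],
    topology: Topology,
    fmt: str = "pdb",
    replica_id: str = "r0",
) -> Trajectory:
    """Read coordinate frames from multi-model PDB files or frames-csv files.

    Frames are concatenated in path order; every frame must match the
    topology's atom count.
    """
    frames: list[np.ndarray] = []
    for path in paths:
        if fmt == "pdb":
            for k, model in enumerate(_read_pdb_models(path)):
                if len(model) != topology.n_atoms:
                    raise ValueError(
                        f"{path} model {k + 1}: {len(model)} atoms, expected {topology.n_atoms}"
                    )
                frames.append(np.array([[t[5], t[6], t[7]] for t in model], dtype=float))
        elif fmt == "frames-csv":
            frames.extend(_read_frames_csv(path, topology.n_atoms))
        else:
            raise ValueError(f"unknown trajectory format {fmt!r}")
    return Trajectory(topology, np.stack(frames, axis=0), replica_id=replica_id)


def _read_frames_csv(path: str | Path, n_atoms: int) -> list[np.ndarray]:
    by_frame: dict[int, dict[int, tuple[float, float, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("frame"):
                continue
            parts = line.split(",")
            if len(parts) != 5 or any(p.strip() == "" for p in parts):
                raise ValueError(f"{path} line {lineno}: expected frame,atom_index,x,y,z")
            try:
                f, a = int(parts[0]), int(parts[1])
                xyz = (float(parts[2]), float(parts[3]), float(parts[4]))
            except ValueError as exc:
                raise ValueError(f"{path} line {lineno}: unparsable value") from exc
            by_frame.setdefault(f, {})[a] = xyz
    frames = []
    for f in sorted(by_frame):
        rows = by_frame[f]
        if len(rows) != n_atoms:
            raise ValueError(f"{path} frame {f}: {len(rows)} atoms, expected {n_atoms}")
        frames.append(np.array([rows[i] for i in range(n_atoms)], dtype=float))
    return frames


def write_pdb(path: str | Path, traj: Trajectory, frame_indices: Iterable[int] | None = None) -> None:
    """Write a (multi-model) PDB file; coordinates at the format's 0.001 Å precision."""
    idx = list(frame_indices) if frame_indices is not None else list(range(traj.n_frames))
    topo = traj.topology
    with open(path, "w") as fh:
        for k, fi in enumerate(idx, start=1):
            if len(idx) > 1:
                fh.write(f"MODEL     {k:4d}\n")
            for a in topo.atoms:
                x, y, z = traj.frames[fi, a.atom_index]
                rec = "HETATM" if a.residue_name in ("CA", "NA", "HOH", "ION") else "ATOM  "
                name = a.atom_name if len(a.atom_name) == 4 else f" {a.atom_name:<3s}"
                fh.write(
                    f"{rec}{(a.atom_index + 1) % 100000:5d} {name:<4s}"
                    f" {a.residue_name:<3.3s} {a.chain_id:1.1s}{a.residue_number:4d} "
                    f"   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {a.element:>2.2s}\n"
                )
            if len(idx) > 1:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def write_frames_csv(path: str | Path, traj: Trajectory) -> None:
    with open(path, "w") as fh:
        fh.write("frame,atom_index,x,y,z\n")
        for f in range(traj.n_frames):
            for a in range(traj.n_atoms):
                x, y, z = traj.frames[f, a]
                fh.write(f"{f},{a},{x:.6f},{y:.6f},{z:.6f}\n")
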