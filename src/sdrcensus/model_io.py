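"""Structures, trajectories and atom selections.

Containers are deliberately small: a :class:`Topology` is an ordered list of
:class:`AtomRecord`, a :class:`Frame` is an ``(N, 3)`` coordinate array in
Angstrom, and a :class:`Trajectory` pairs one topology with an ordered list of
frames.  Readers cover the two mandatory text formats (fixed-column PDB with
MODEL/ENDMDL blocks, and XYZ) plus optional binary DCD when mdtraj is
importable.  All text readers accept plain or gzip-compressed input.

Distances downstream are plain Euclidean distances; input frames are expected
to be imaged (no periodic-boundary treatment anywhere in the package).
"""

from __future__ import annotations

import fnmatch
import gzip
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    EmptyInputError,
    EmptySelectionError,
    ParseError,
    TopologyMismatchError,
    TruncationError,
)

try:  # optional capability: binary DCD reading
    from mdtraj.formats import DCDTrajectoryFile as _DCDFile

    HAS_DCD = True
except Exception:  # pragma: no cover - absent mdtraj
    _DCDFile = None
    HAS_DCD = False

__all__ = [
    "AtomRecord",
    "Topology",
    "Frame",
    "Trajectory",
    "Selection",
    "read_structure",
    "read_trajectory",
    "write_frames",
    "resolve_selection",
    "HAS_DCD",
]


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a topology, identified by author numbering."""

    serial: int
    name: str
    resname: str
    resid: int
    chain: str
    element: str = ""
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self):
        if not self.name.strip():
            raise ValueError("atom name must be non-empty")


class Topology:
    """Ordered atom list with index maps by (chain, resid, name).

    Atom order is stable and shared by every frame of a trajectory.
    """

    def __init__(self, atoms: Sequence[AtomRecord]):
        self.atoms: tuple[AtomRecord, ...] = tuple(atoms)
        index: dict[tuple[str, int, str], int] = {}
        for i, a in enumerate(self.atoms):
            key = (a.chain, a.resid, a.name)
            if key in index:
                raise ValueError(f"duplicate atom {key} in topology")
            index[key] = i
        self._index = index

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def __len__(self) -> int:
        return len(self.atoms)

    def index_of(self, chain: str, resid: int, name: str) -> int:
        return self._index[(chain, resid, name)]

    def select(self, sel: "Selection") -> list[int]:
        return resolve_selection(self, sel)

    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain, resid, resname) triples."""
        seen, out = set(), []
        for a in self.atoms:
            key = (a.chain, a.resid, a.resname)
            if key not in seen:
                seen.add(key)
                out.append(key)
        return out


@dataclass
class Frame:
    """One coordinate snapshot; lengths in Angstrom."""

    index: int
    coordinates: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be an (N, 3) array")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError(f"frame {self.index}: non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


class Trajectory:
    """A topology plus an ordered sequence of frames sharing it."""

    def __init__(self, topology: Topology, frames: Sequence[Frame]):
        frames = list(frames)
        if not frames:
            raise EmptyInputError("a trajectory needs at least one frame")
        for f in frames:
            if f.n_atoms != topology.n_atoms:
                raise TopologyMismatchError(
                    f"frame {f.index} has {f.n_atoms} atoms, "
                    f"topology has {topology.n_atoms}"
                )
        self.topology = topology
        self.frames: list[Frame] = frames

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def coordinates(self) -> np.ndarray:
        """Stacked (n_frames, N, 3) coordinate array."""
        return np.stack([f.coordinates for f in self.frames])


@dataclass(frozen=True)
class Selection:
    """Named atom selection; ``name`` accepts fnmatch-style wildcards."""

    chain: str | None = None
    resid: int | None = None
    resname: str | None = None
    name: str | None = None

    def matches(self, atom: AtomRecord) -> bool:
        if self.chain is not None and atom.chain != self.chain:
            return False
        if self.resid is not None and atom.resid != self.resid:
            return False
        if self.resname is not None and atom.resname != self.resname:
            return False
        if self.name is not None and not fnmatch.fnmatchcase(atom.name, self.name):
            return False
        return True

    def __str__(self) -> str:
        parts = [
            f"{k}={v}"
            for k, v in (
                ("chain", self.chain),
                ("resid", self.resid),
                ("resname", self.resname),
                ("name", self.name),
            )
            if v is not None
        ]
        return "Selection(" + ", ".join(parts) + ")" if parts else "Selection(all)"


def resolve_selection(topology: Topology, sel: Selection) -> list[int]:
    """Resolve a selection to a strictly increasing list of atom indices.

    Raises :class:`EmptySelectionError` (naming the unmatched fields) when no
    atom matches; resolution is deterministic given a topology.
    """
    if topology.n_atoms == 0:
        raise EmptyInputError("empty topology")
    idx = [i for i, a in enumerate(topology.atoms) if sel.matches(a)]
    if not idx:
        raise EmptySelectionError(f"{sel} matched no atom in topology")
    return idx


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_ALTLOC_KEEP = ("", " ", "A")


def _open_text(path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def _infer_format(path) -> str:
    name = Path(path).name
    if name.endswith(".gz"):
        name = name[:-3]
    suffix = Path(name).suffix.lower().lstrip(".")
    if suffix in ("pdb", "ent"):
        return "pdb"
    if suffix == "xyz":
        return "xyz"
    if suffix == "dcd":
        return "dcd"
    raise ValueError(f"cannot infer format of {path!r}")


def _parse_pdb_atom(line: str, lineno: int, path) -> tuple[AtomRecord, np.ndarray]:
    # wwPDB fixed columns; both ATOM and HETATM accepted (ligands are HETATM)
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:21].strip()
        chain = line[21].strip() or "A"
        resid = int(line[22:26])
        xyz = np.array(
            [float(line[30:38]), float(line[38:46]), float(line[46:54])]
        )
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip() if len(line) >= 77 else ""
    except (ValueError, IndexError) as exc:
        raise ParseError(f"malformed ATOM/HETATM record ({exc})", path, lineno)
    if not name:
        raise ParseError("empty atom name", path, lineno)
    record = AtomRecord(serial, name, resname, resid, chain, element, occupancy, altloc)
    return record, xyz


def _read_pdb(path) -> tuple[Topology, list[Frame]]:
    models: list[tuple[list[AtomRecord], list[np.ndarray]]] = []
    current_atoms: list[AtomRecord] = []
    current_xyz: list[np.ndarray] = []
    in_model = False
    saw_model_records = False
    dropped_altlocs = 0
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            rec = line[:6].strip()
            if rec == "MODEL":
                saw_model_records = True
                in_model = True
                current_atoms, current_xyz = [], []
            elif rec == "ENDMDL":
                in_model = False
                models.append((current_atoms, current_xyz))
                current_atoms, current_xyz = [], []
            elif rec in ("ATOM", "HETATM"):
                atom, xyz = _parse_pdb_atom(line, lineno, path)
                if atom.altloc not in _ALTLOC_KEEP:
                    dropped_altlocs += 1
                    continue
                current_atoms.append(atom)
                current_xyz.append(xyz)
    if current_atoms:
        if saw_model_records and in_model:
            # MODEL without ENDMDL; tolerate and close it
            models.append((current_atoms, current_xyz))
        elif not saw_model_records:
            models.append((current_atoms, current_xyz))
    if not models or not models[0][0]:
        raise EmptyInputError(f"{path}: no atoms found")
    if dropped_altlocs:
        warnings.warn(
            f"{path}: dropped {dropped_altlocs} alternate-location record(s) "
            "(kept altloc ' '/'A')",
            stacklevel=3,
        )
    topo = Topology(models[0][0])
    frames = []
    for i, (atoms, xyz) in enumerate(models):
        if len(atoms) != topo.n_atoms:
            raise TopologyMismatchError(
                f"{path}: MODEL {i + 1} has {len(atoms)} atoms, "
                f"MODEL 1 has {topo.n_atoms}"
            )
        frames.append(Frame(i, np.array(xyz)))
    return topo, frames


def _read_xyz(path) -> tuple[Topology, list[Frame]]:
    elements_first: list[str] | None = None
    frames: list[Frame] = []
    with _open_text(path) as fh:
        lines = [ln.rstrip("\r\n") for ln in fh]
    pos = 0
    n_lines = len(lines)
    while pos < n_lines:
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n_atoms = int(lines[pos].strip())
        except ValueError:
            raise ParseError("expected atom-count line", path, pos + 1)
        if pos + 2 + n_atoms > n_lines:
            raise TruncationError(
                f"frame truncated: need {n_atoms} atom lines", path, pos + 1
            )
        elements: list[str] = []
        xyz = np.empty((n_atoms, 3))
        for k in range(n_atoms):
            lineno = pos + 2 + k
            parts = lines[lineno].split()
            if len(parts) < 4:
                raise ParseError("expected 'element x y z'", path, lineno + 1)
            try:
                xyz[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError as exc:
                raise ParseError(f"bad coordinate ({exc})", path, lineno + 1)
            elements.append(parts[0])
        if elements_first is None:
            elements_first = elements
        elif elements != elements_first:
            raise TopologyMismatchError(
                f"{path}: frame {len(frames)} atom list differs from frame 0"
            )
        frames.append(Frame(len(frames), xyz))
        pos += 2 + n_atoms
    if elements_first is None:
        raise EmptyInputError(f"{path}: no atoms found")
    # XYZ carries no residue structure: each atom gets its own resid so the
    # (chain, resid, name) key stays unique for repeated elements
    atoms = [
        AtomRecord(serial=i + 1, name=el, resname="XYZ", resid=i + 1, chain="A", element=el)
        for i, el in enumerate(elements_first)
    ]
    return Topology(atoms), frames


def read_structure(path, format: str | None = None) -> tuple[Topology, list[Frame]]:
    """Read a structure file; multi-model PDB yields one frame per MODEL."""
    fmt = format or _infer_format(path)
    if fmt == "pdb":
        return _read_pdb(path)
    if fmt == "xyz":
        return _read_xyz(path)
    raise ValueError(f"unsupported structure format {fmt!r}")


def _read_dcd(topology: Topology, path) -> list[Frame]:
    if not HAS_DCD:  # pragma: no cover
        raise RuntimeError("DCD support requires the optional mdtraj dependency")
    with _DCDFile(str(path)) as fh:
        xyz, _, _ = fh.read()  # file units: Angstrom
    if xyz.shape[1] != topology.n_atoms:
        raise TopologyMismatchError(
            f"{path}: DCD has {xyz.shape[1]} atoms, topology has {topology.n_atoms}"
        )
    return [Frame(i, xyz[i]) for i in range(xyz.shape[0])]


def read_trajectory(topology: Topology, path, format: str | None = None) -> Trajectory:
    """Read frames against an existing topology; frame indices are 0-based."""
    fmt = format or _infer_format(path)
    if fmt == "xyz":
        file_topo, frames = _read_xyz(path)
    elif fmt == "pdb":
        file_topo, frames = _read_pdb(path)
    elif fmt == "dcd":
        return Trajectory(topology, _read_dcd(topology, path))
    else:
        raise ValueError(f"unsupported trajectory format {fmt!r}")
    if file_topo.n_atoms != topology.n_atoms:
        raise TopologyMismatchError(
            f"{path}: file frames have {file_topo.n_atoms} atoms, "
            f"topology has {topology.n_atoms}"
        )
    return Trajectory(topology, frames)


def _format_pdb_atom(atom: AtomRecord, xyz: np.ndarray, serial: int) -> str:
    name = atom.name
    # short names start in column 14 by convention
    field = f" {name:<3s}" if len(name) < 4 else name[:4]
    return (
        f"HETATM{serial:>5d} {field}{'':1s}{atom.resname:<4s}{atom.chain:1s}"
        f"{atom.resid:>4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{atom.occupancy:6.2f}{0.0:6.2f}          {atom.element:>2s}"
    )


def write_frames(
    topology: Topology, frames: Iterable[Frame], path, format: str | None = None
) -> None:
    """Write frames as XYZ or multi-model PDB (plain text)."""
    fmt = format or _infer_format(path)
    frames = list(frames)
    if not frames:
        raise EmptyInputError("no frames to write")
    with open(path, "w", encoding="utf-8") as fh:
        if fmt == "xyz":
            for f in frames:
                fh.write(f"{topology.n_atoms}\n")
                fh.write(f"frame {f.index}\n")
                for atom, xyz in zip(topology.atoms, f.coordinates):
                    el = atom.element or atom.name[:1]
                    fh.write(f"{el} {xyz[0]:.5f} {xyz[1]:.5f} {xyz[2]:.5f}\n")
        elif fmt == "pdb":
            for m, f in enumerate(frames, start=1):
                fh.write(f"MODEL     {m:>4d}\n")
                for serial, (atom, xyz) in enumerate(
                    zip(topology.atoms, f.coordinates), start=1
                ):
                    fh.write(_format_pdb_atom(atom, xyz, serial) + "\n")
                fh.write("ENDMDL\n")
            fh.write("END\n")
        else:
            raise ValueError(f"unsupported output format {fmt!r}")
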