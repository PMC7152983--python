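"""Structure and trajectory I/O.

Reads single- and multi-model PDB files into a :class:`Topology` plus a
:class:`FrameSeries`, resolves atom selections with a small expression
grammar, and dumps selected coordinates to CSV.  Multi-model PDB is the
reference trajectory dialect; every frame must contain the same atoms.

PDB parsing and writing are delegated to :mod:`biotite`; this module owns
the residue bookkeeping (author numbering preserved verbatim, ligand and
water flagging) that the downstream metrics rely on.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Standard amino-acid residue names (three-letter, protonation variants included).
STANDARD_AA = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR
    TRP TYR VAL ASH GLH HID HIE HIP LYN CYX CYM SEC PYL""".split()
)

#: Residue names treated as water (never flagged as ligand).
WATER_NAMES = frozenset({"HOH", "WAT", "SOL", "TIP3", "TIP4", "SPC", "T3P", "T4P"})


class PDBParseError(ValueError):
    """Malformed PDB content (carries a line number where known)."""


class StructureError(ValueError):
    """Structurally inconsistent trajectory (e.g. varying atom count)."""


class SelectionError(ValueError):
    """Unknown token or unusable selection expression."""


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str
    is_ligand: bool
    is_heavy: bool


@dataclass
class Topology:
    """Ordered atom metadata; the static half of a trajectory.

    Residue identity is the triple ``(chain_id, residue_number,
    residue_name)`` with author numbering preserved verbatim.
    """

    atoms: list[Atom]

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise StructureError("atom serials are not unique")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Distinct residues in file order as (chain, number, name)."""
        seen: dict[tuple[str, int, str], None] = {}
        for a in self.atoms:
            seen.setdefault((a.chain_id, a.residue_number, a.residue_name), None)
        return list(seen)

    def residue_label(self, key: tuple[str, int, str]) -> str:
        """``RESNAME_NUMBER`` label, e.g. ``VAL_332``."""
        return f"{key[2]}_{key[1]}"

    def atoms_by_residue(self) -> dict[tuple[str, int, str], list[int]]:
        out: dict[tuple[str, int, str], list[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault((a.chain_id, a.residue_number, a.residue_name), []).append(i)
        return out


@dataclass
class FrameSeries:
    """Per-frame coordinates congruent with a :class:`Topology`.

    coords has shape ``(n_frames, n_atoms, 3)`` in Å; times are in ns and
    strictly increasing.
    """

    coords: np.ndarray
    times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise StructureError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise StructureError("a trajectory needs at least one frame")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("coordinates contain non-finite values")
        if self.times is None:
            self.times = np.arange(self.coords.shape[0], dtype=float)
        else:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (self.coords.shape[0],):
                raise StructureError("times must have one entry per frame")
            if self.coords.shape[0] > 1 and not np.all(np.diff(self.times) > 0):
                raise StructureError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


@dataclass(frozen=True)
class Selection:
    """Ordered, unique atom indices into a Topology."""

    indices: tuple[int, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(set(self.indices)) != len(self.indices):
            raise SelectionError("selection indices must be unique")

    def __len__(self) -> int:
        return len(self.indices)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=int)


def _classify(res_name: str, hetero: bool) -> bool:
    """True if a residue counts as ligand: HETATM outside amino acids and water."""
    return bool(hetero) and res_name not in STANDARD_AA and res_name not in WATER_NAMES


def read_pdb(path: str | Path, times: Sequence[float] | None = None) -> tuple[Topology, FrameSeries]:
    """Read a (multi-model) PDB file.

    Each MODEL becomes one frame; files without MODEL records yield a
    single frame.  HETATM residues outside the standard amino-acid set
    (and not water) are flagged ``is_ligand``.  Insertion codes are
    rejected.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None, extra_fields=["atom_id"])
    except Exception as exc:  # biotite raises several types for bad records
        line = _find_bad_line(path)
        raise PDBParseError(f"{path}: unparseable PDB content"
                            + (f" near line {line}" if line else "")) from exc
    if stack.array_length() == 0:
        raise PDBParseError(f"{path}: no ATOM/HETATM records")
    if isinstance(stack, struc.AtomArray):  # single model
        stack = struc.stack([stack])
    ins = stack.ins_code[0] if stack.ins_code.ndim == 1 else stack.ins_code
    if any(c.strip() for c in np.atleast_1d(ins)):
        raise PDBParseError(f"{path}: insertion codes are not supported")

    first = stack[0]
    atoms = []
    for i in range(first.array_length()):
        name = str(first.atom_name[i])
        element = str(first.element[i]).strip().capitalize() or _guess_element(name)
        atoms.append(
            Atom(
                serial=int(first.atom_id[i]),
                name=name,
                element=element,
                residue_number=int(first.res_id[i]),
                residue_name=str(first.res_name[i]),
                chain_id=str(first.chain_id[i]),
                is_ligand=_classify(str(first.res_name[i]), bool(first.hetero[i])),
                is_heavy=element.upper() != "H",
            )
        )
    topology = Topology(atoms)
    coords = np.asarray(stack.coord, dtype=float)
    series = FrameSeries(coords, None if times is None else np.asarray(times, float))
    return topology, series


def _find_bad_line(path: Path) -> int | None:
    """Best-effort line number of the first malformed ATOM/HETATM record."""
    try:
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                if line.startswith(("ATOM", "HETATM")):
                    try:
                        float(line[30:38]); float(line[38:46]); float(line[46:54])
                        int(line[22:26])
                    except (ValueError, IndexError):
                        return ln
    except OSError:
        return None
    return None


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    if stripped[0] == "H":
        return "H"
    if len(stripped) >= 2 and stripped[:2].capitalize() in {"Cl", "Br", "Na", "Mg", "Zn", "Fe", "Ca"}:
        return stripped[:2].capitalize()
    return stripped[0].upper()


def write_pdb(path: str | Path, topology: Topology, series: FrameSeries) -> None:
    """Write a multi-model PDB (one MODEL per frame) from Topology + FrameSeries."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = topology.n_atoms
    if series.n_atoms != n:
        raise StructureError("topology and frame series disagree on atom count")
    arr = struc.AtomArray(n)
    arr.add_annotation("atom_id", int)
    for i, a in enumerate(topology.atoms):
        arr.atom_name[i] = a.name
        arr.element[i] = a.element.upper()
        arr.res_id[i] = a.residue_number
        arr.res_name[i] = a.residue_name
        arr.chain_id[i] = a.chain_id
        arr.hetero[i] = a.is_ligand or a.residue_name in WATER_NAMES
        arr.atom_id[i] = a.serial
    stack = struc.stack([arr] * series.n_frames)
    stack.coord = np.asarray(series.coords, dtype=np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(Path(path)))


# ---------------------------------------------------------------------------
# Selection grammar
# ---------------------------------------------------------------------------
_RANGE_RE = re.compile(r"^(-?\d+)[:\-](-?\d+)$")


def select(topology: Topology, expression: str, label: str | None = None) -> Selection:
    """Resolve a selection expression to ordered atom indices.

    Grammar: clauses joined by ``and``; each clause is one of

    - ``name <ATOM_NAME>`` (e.g. ``name CA``)
    - ``heavy`` — non-hydrogen atoms
    - ``ligand`` / ``protein`` / ``water``
    - ``chain <ID>``
    - ``resid <a>:<b>`` or ``resid <a>-<b>`` — inclusive residue-number range
    - ``resid <n>`` — single residue number

    Empty results are allowed but logged as a warning.
    """
    mask = np.ones(topology.n_atoms, dtype=bool)
    tokens = expression.split()
    i = 0
    while i < len(tokens):
        tok = tokens[i].lower()
        if tok == "and":
            i += 1
            continue
        if tok == "name":
            if i + 1 >= len(tokens):
                raise SelectionError("'name' requires an atom name")
            want = tokens[i + 1].upper()
            mask &= np.array([a.name.upper() == want for a in topology.atoms])
            i += 2
        elif tok == "heavy":
            mask &= np.array([a.is_heavy for a in topology.atoms])
            i += 1
        elif tok == "ligand":
            mask &= np.array([a.is_ligand for a in topology.atoms])
            i += 1
        elif tok == "protein":
            mask &= np.array([a.residue_name in STANDARD_AA for a in topology.atoms])
            i += 1
        elif tok == "water":
            mask &= np.array([a.residue_name in WATER_NAMES for a in topology.atoms])
            i += 1
        elif tok == "chain":
            if i + 1 >= len(tokens):
                raise SelectionError("'chain' requires a chain identifier")
            want = tokens[i + 1]
            mask &= np.array([a.chain_id == want for a in topology.atoms])
            i += 2
        elif tok == "resid":
            if i + 1 >= len(tokens):
                raise SelectionError("'resid' requires a number or range")
            arg = tokens[i + 1]
            m = _RANGE_RE.match(arg)
            if m:
                lo, hi = int(m.group(1)), int(m.group(2))
            else:
                try:
                    lo = hi = int(arg)
                except ValueError as exc:
                    raise SelectionError(f"bad residue range {arg!r}") from exc
            if hi < lo:
                raise SelectionError(f"empty residue range {arg!r}")
            mask &= np.array([lo <= a.residue_number <= hi for a in topology.atoms])
            i += 2
        else:
            raise SelectionError(f"unknown selection token {tokens[i]!r}")
    indices = tuple(int(k) for k in np.nonzero(mask)[0])
    if not indices:
        logger.warning("selection %r matched no atoms", expression)
    return Selection(indices, label if label is not None else expression)


def write_frames_csv(series: FrameSeries, selection: Selection, path: str | Path) -> None:
    """Dump selected coordinates as CSV rows (frame, time_ns, atom_index, x, y, z).

    Coordinates are written at 3 decimals (PDB precision); an empty
    selection yields a header-only file with a warning.
    """
    idx = selection.as_array()
    if len(idx) == 0:
        logger.warning("writing header-only CSV: empty selection %r", selection.label)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "time_ns", "atom_index", "x", "y", "z"])
        for f in range(series.n_frames):
            t = series.times[f]
            for a in idx:
                x, y, z = series.coords[f, a]
                writer.writerow([f, f"{t:.6g}", int(a), f"{x:.3f}", f"{y:.3f}", f"{z:.3f}"])


def read_frames_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a CSV written by :func:`write_frames_csv`.

    Returns (coords with shape (n_frames, n_sel, 3), times, atom_indices).
    """
    frames: dict[int, list[tuple[int, float, float, float]]] = {}
    times: dict[int, float] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            f = int(row["frame"])
            frames.setdefault(f, []).append(
                (int(row["atom_index"]), float(row["x"]), float(row["y"]), float(row["z"]))
            )
            times[f] = float(row["time_ns"])
    if not frames:
        return np.zeros((0, 0, 3)), np.zeros(0), np.zeros(0, dtype=int)
    keys = sorted(frames)
    atom_idx = np.array([r[0] for r in frames[keys[0]]], dtype=int)
    coords = np.array([[r[1:] for r in frames[f]] for f in keys], dtype=float)
    return coords, np.array([times[f] for f in keys]), atom_idx
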