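"""Structures, trajectories and atom selections.

PDB is the interchange format: single-model files for crystal conformations,
multi-model files (one ``MODEL`` per frame) for trajectories.  Coordinates are
Ångström everywhere; no unit conversion happens downstream.

Residue identity is ``(chain_id, res_seq)``.  Insertion codes are rejected,
alternate locations are resolved to the highest-occupancy conformer (ties
broken toward altloc ``'A'``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "Selection",
    "PDBParseError",
    "EmptyInputError",
    "EmptySelectionError",
    "TopologyMismatchError",
    "read_pdb",
    "write_pdb",
    "read_trajectory",
    "write_trajectory",
    "read_frame_times",
    "resolve_selection",
]

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})


class PDBParseError(ValueError):
    """A malformed record in a PDB file; message names the line number."""


class EmptyInputError(ValueError):
    """A file or structure with zero atoms where atoms are required."""


class EmptySelectionError(ValueError):
    """A selection that resolves to no atoms; metrics never run on nothing."""


class TopologyMismatchError(ValueError):
    """Models of a trajectory file disagree on atom count or order."""


@dataclass(frozen=True)
class Atom:
    """One atom record: identity plus a 3-vector of coordinates in Å."""

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain_id: str
    coords: tuple[float, float, float]
    is_hydrogen: bool = False

    @property
    def residue(self) -> tuple[str, int]:
        return (self.chain_id, self.res_seq)


class Structure:
    """One conformation: an ordered atom list plus an (n, 3) coordinate array.

    ``atoms`` carries identity; ``coords`` carries geometry and is the array
    all metrics index into.  ``with_coords`` swaps geometry while sharing the
    topology, which is how trajectory frames are materialised cheaply.
    """

    def __init__(self, atoms: Sequence[Atom], model_id: int = 1, label: str = ""):
        if len(atoms) == 0:
            raise EmptyInputError("structure with zero atoms")
        self.atoms = list(atoms)
        self.model_id = model_id
        self.label = label
        self.coords = np.array([a.coords for a in self.atoms], dtype=float)
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")
        seen: set[tuple[str, int, str]] = set()
        chains: list[str] = []
        for a in self.atoms:
            key = (a.chain_id, a.res_seq, a.name)
            if key in seen:
                raise ValueError(f"duplicate atom {key} within one model")
            seen.add(key)
            if a.chain_id not in chains:
                chains.append(a.chain_id)
        self.chains = chains

    def __len__(self) -> int:
        return len(self.atoms)

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "Structure":
        """Same topology, new geometry (no per-atom re-validation)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"coords shape {coords.shape} != ({len(self.atoms)}, 3)")
        new = object.__new__(Structure)
        new.atoms = self.atoms
        new.model_id = self.model_id
        new.label = self.label if label is None else label
        new.coords = coords
        new.chains = self.chains
        return new

    def atom_index(self, chain_id: str, res_seq: int, name: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.chain_id == chain_id and a.res_seq == res_seq and a.name == name:
                return i
        raise KeyError(f"no atom {chain_id}:{res_seq}:{name}")

    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain_id, res_seq, res_name) triples."""
        out: list[tuple[str, int, str]] = []
        seen: set[tuple[str, int]] = set()
        for a in self.atoms:
            if a.residue not in seen:
                seen.add(a.residue)
                out.append((a.chain_id, a.res_seq, a.res_name))
        return out


@dataclass
class Trajectory:
    """Frames sharing one topology, each stamped with a time in ns."""

    topology: Structure
    frames: list[np.ndarray]
    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.frames) != len(self.times):
            raise ValueError("len(frames) != len(times)")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        n = len(self.topology)
        for i, f in enumerate(self.frames):
            if f.shape != (n, 3):
                raise TopologyMismatchError(
                    f"frame {i} has shape {f.shape}, topology has {n} atoms"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])


@dataclass(frozen=True)
class Selection:
    """Declarative atom filter; empty criteria match every atom.

    ``backbone_only`` keeps N, CA, C, O; ``heavy_only`` drops hydrogens.
    """

    chain_ids: frozenset[str] | None = None
    res_seq_ranges: tuple[tuple[int, int], ...] | None = None
    atom_names: frozenset[str] | None = None
    heavy_only: bool = False
    backbone_only: bool = False

    @staticmethod
    def make(
        chain_ids: Iterable[str] | None = None,
        res_seq_ranges: Iterable[Sequence[int]] | None = None,
        atom_names: Iterable[str] | None = None,
        heavy_only: bool = False,
        backbone_only: bool = False,
    ) -> "Selection":
        return Selection(
            chain_ids=frozenset(chain_ids) if chain_ids is not None else None,
            res_seq_ranges=tuple((int(lo), int(hi)) for lo, hi in res_seq_ranges)
            if res_seq_ranges is not None
            else None,
            atom_names=frozenset(atom_names) if atom_names is not None else None,
            heavy_only=heavy_only,
            backbone_only=backbone_only,
        )


def resolve_selection(structure: Structure, sel: Selection) -> list[int]:
    """Deterministic, topology-ordered atom indices matching ``sel``.

    Raises :class:`EmptySelectionError` when nothing matches, so downstream
    metrics can never silently operate on an empty atom set.
    """
    out: list[int] = []
    for i, a in enumerate(structure.atoms):
        if sel.chain_ids is not None and a.chain_id not in sel.chain_ids:
            continue
        if sel.res_seq_ranges is not None and not any(
            lo <= a.res_seq <= hi for lo, hi in sel.res_seq_ranges
        ):
            continue
        if sel.atom_names is not None and a.name not in sel.atom_names:
            continue
        if sel.heavy_only and a.is_hydrogen:
            continue
        if sel.backbone_only and a.name not in BACKBONE_NAMES:
            continue
        out.append(i)
    if not out:
        raise EmptySelectionError(f"selection matched zero atoms: {sel}")
    return out


# ---------------------------------------------------------------------------
# PDB fixed-column I/O


def _infer_element(raw_element: str, atom_name: str) -> str:
    el = raw_element.strip()
    if el:
        return el.capitalize() if len(el) > 1 else el.upper()
    # MD-written PDBs often omit columns 77-78: fall back to the atom name,
    # stripping leading digits (e.g. "1HG1" -> H).
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element for atom name {atom_name!r}")
    if stripped[:2].upper() in {"CL", "BR", "NA", "MG", "ZN", "FE", "CA"} and len(
        atom_name.strip()
    ) <= 2:
        # two-letter elements only when the name itself is the bare element
        return stripped[:2].capitalize()
    return stripped[0].upper()


def _parse_atom_line(line: str, lineno: int) -> tuple[Atom, str, float]:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16]
        res_name = line[17:20].strip()
        chain_id = line[21].strip() or " "
        res_seq = int(line[22:26])
        icode = line[26]
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = _infer_element(line[76:78] if len(line) >= 78 else "", name)
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed ATOM/HETATM record at line {lineno}: {exc}") from exc
    if icode.strip():
        raise PDBParseError(
            f"insertion code {icode!r} at line {lineno}: insertion codes are not supported"
        )
    atom = Atom(
        serial=serial,
        name=name,
        element=element,
        res_name=res_name,
        res_seq=res_seq,
        chain_id=chain_id,
        coords=(x, y, z),
        is_hydrogen=(element == "H"),
    )
    return atom, altloc, occupancy


def _dedupe_altlocs(
    records: list[tuple[Atom, str, float]]
) -> list[Atom]:
    """Keep the highest-occupancy altloc per (chain, res_seq, name); ties -> 'A'."""
    best: dict[tuple[str, int, str], tuple[float, str, int]] = {}
    atoms: dict[tuple[str, int, str], Atom] = {}
    order: list[tuple[str, int, str]] = []
    for pos, (atom, altloc, occ) in enumerate(records):
        key = (atom.chain_id, atom.res_seq, atom.name)
        if key not in best:
            best[key] = (occ, altloc, pos)
            atoms[key] = atom
            order.append(key)
        else:
            occ0, alt0, _ = best[key]
            if occ > occ0 or (occ == occ0 and altloc == "A" and alt0 != "A"):
                best[key] = (occ, altloc, best[key][2])
                atoms[key] = atom
    return [atoms[k] for k in order]


def read_pdb(path: str | Path) -> list[Structure]:
    """Read a PDB file into one :class:`Structure` per MODEL.

    Files without MODEL records yield a single structure.  Coordinates come
    from the fixed columns; elements from columns 77–78 with an atom-name
    fallback; hydrogens are flagged from the element.
    """
    path = Path(path)
    models: list[list[tuple[Atom, str, float]]] = []
    current: list[tuple[Atom, str, float]] = []
    model_ids: list[int] = []
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                if current:
                    models.append(current)
                    current = []
                in_model = True
                try:
                    model_ids.append(int(line[6:].strip() or len(models) + 1))
                except ValueError:
                    model_ids.append(len(models) + 1)
            elif rec == "ENDMDL":
                models.append(current)
                current = []
            elif rec in ("ATOM  ", "HETATM"):
                current.append(_parse_atom_line(line, lineno))
    if current:
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise EmptyInputError(f"{path}: no ATOM/HETATM records")
    structures = []
    for k, recs in enumerate(models):
        mid = model_ids[k] if k < len(model_ids) else k + 1
        structures.append(Structure(_dedupe_altlocs(recs), model_id=mid, label=path.stem))
    return structures


def _format_atom_line(atom: Atom, serial: int, coords: np.ndarray, hetero: bool) -> str:
    record = "HETATM" if hetero else "ATOM  "
    name = atom.name
    # PDB convention: 1-3 char names start in column 14 unless 4 chars long
    name_field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    el = atom.element.rjust(2)
    return (
        f"{record}{serial:>5d} {name_field} {atom.res_name:<3s} {atom.chain_id}"
        f"{atom.res_seq:>4d}    "
        f"{coords[0]:8.3f}{coords[1]:8.3f}{coords[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {el}"
    )


STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


def _write_model(fh, structure: Structure, coords: np.ndarray) -> None:
    for i, atom in enumerate(structure.atoms):
        hetero = atom.res_name not in STANDARD_RESIDUES
        fh.write(_format_atom_line(atom, i + 1, coords[i], hetero) + "\n")


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a single-model PDB (fixed columns, 3-decimal coordinates)."""
    with open(path, "w") as fh:
        _write_model(fh, structure, structure.coords)
        fh.write("END\n")


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a multi-model PDB, one MODEL per frame."""
    with open(path, "w") as fh:
        for i, frame in enumerate(traj.frames):
            fh.write(f"MODEL {i + 1:>8d}\n")
            _write_model(fh, traj.topology, frame)
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_frame_times(path: str | Path) -> np.ndarray:
    """Read a 2-column CSV (frame_index, time_ns) into a time array."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 columns (frame_index, time_ns)")
    df = df.sort_values(df.columns[0])
    return df.iloc[:, 1].to_numpy(dtype=float)


def read_trajectory(
    path: str | Path, times: Sequence[float] | np.ndarray | None = None
) -> Trajectory:
    """Read a multi-model PDB as a trajectory.

    The first model supplies the topology; every model must have the same
    atom count and order.  ``times`` defaults to 0, 1, 2, … ns.
    """
    structures = read_pdb(path)
    top = structures[0]
    keys0 = [(a.chain_id, a.res_seq, a.name) for a in top.atoms]
    frames = []
    for m, s in enumerate(structures):
        if len(s) != len(top):
            raise TopologyMismatchError(
                f"model {m + 1} has {len(s)} atoms, model 1 has {len(top)}"
            )
        keys = [(a.chain_id, a.res_seq, a.name) for a in s.atoms]
        if keys != keys0:
            raise TopologyMismatchError(f"model {m + 1} atom order differs from model 1")
        frames.append(s.coords)
    if times is None:
        times = np.arange(len(frames), dtype=float)
    return Trajectory(topology=top, frames=frames, times=np.asarray(times, dtype=float))
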