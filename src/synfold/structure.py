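"""Structures, trajectories and atom selection.

A :class:`Structure` is a flat atom table (names, elements, residue and
chain labels, coordinates in Angstrom) holding a single model.  A
:class:`Trajectory` is a stack of coordinate frames over the same atom
set with a uniform frame interval ``dt`` in picoseconds, and a
:class:`TrajectoryEnsemble` is a set of independent runs sharing atom
set and ``dt`` (e.g. independent high-temperature unfolding runs).

PDB input/output goes through biotite; binary DCD trajectories through
mdtraj.  A minimal multi-frame XYZ text format is supported for plain
fixtures.  Residue identity is keyed by ``(chain id, residue number)``
using the author numbering printed in the PDB file.
"""

from __future__ import annotations

import dataclasses
import os
import tempfile
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import ValidationError

#: residue names of terminal capping groups, excluded from contact and
#: geometry analysis (simulation constructs, not part of the sequence)
CAP_RESIDUES = frozenset({"ACE", "NME", "NH2", "CT3", "NMA"})

#: backbone heavy-atom names (used to split off side chains)
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT", "OT1", "OT2"})


def _infer_element(atom_name: str) -> str:
    name = atom_name.strip().lstrip("0123456789")
    if not name:
        return ""
    if len(name) >= 2 and name[:2].upper() in ("FE", "ZN", "MG", "MN", "CL", "BR", "NA"):
        return name[:2].capitalize()
    return name[0].upper()


@dataclasses.dataclass
class Structure:
    """Single-model atom table with coordinates in Angstrom."""

    atom_names: np.ndarray
    elements: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    chain_ids: np.ndarray
    coords: np.ndarray
    model: int = 1

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError("coordinates must be an (n_atoms, 3) array")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("coordinates contain non-finite values")
        for name in ("atom_names", "elements", "res_ids", "res_names", "chain_ids"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != self.coords.shape[0]:
                raise ValidationError(f"{name} length does not match atom count")
            setattr(self, name, arr)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def residue_table(self) -> list[tuple[str, int, str, np.ndarray]]:
        """Residues in file order as (chain, res id, res name, atom indices)."""
        out: list[tuple[str, int, str, np.ndarray]] = []
        key = None
        start = 0
        for i in range(self.n_atoms):
            k = (str(self.chain_ids[i]), int(self.res_ids[i]))
            if k != key:
                if key is not None:
                    out.append((key[0], key[1], str(self.res_names[start]),
                                np.arange(start, i)))
                key, start = k, i
        if key is not None:
            out.append((key[0], key[1], str(self.res_names[start]),
                        np.arange(start, self.n_atoms)))
        return out

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(str(c))
        return list(seen)

    def heavy_mask(self) -> np.ndarray:
        return np.array([e.upper() != "H" for e in self.elements], dtype=bool)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return dataclasses.replace(self, coords=np.asarray(coords, dtype=float))


@dataclasses.dataclass
class Trajectory:
    """Time-ordered coordinate frames (n_frames, n_atoms, 3) in Angstrom."""

    coords: np.ndarray
    dt: float  # ps
    temperature: float | None = None  # K

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError("trajectory coordinates must be (frames, atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValidationError("trajectory must contain at least one frame")
        if not self.dt > 0:
            raise ValidationError("frame interval dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame times in ps, starting at 0."""
        return np.arange(self.n_frames) * self.dt


@dataclasses.dataclass
class TrajectoryEnsemble:
    """Independent runs over a shared atom set with uniform dt."""

    runs: list[Trajectory]
    temperature: float | None = None  # K

    def __post_init__(self) -> None:
        if not self.runs:
            raise ValidationError("ensemble must contain at least one run")
        n = self.runs[0].n_atoms
        dt = self.runs[0].dt
        for i, run in enumerate(self.runs):
            if run.n_atoms != n:
                raise ValidationError(f"run {i} atom count {run.n_atoms} != {n}")
            if run.dt != dt:
                raise ValidationError(f"run {i} dt {run.dt} != {dt}")

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def dt(self) -> float:
        return self.runs[0].dt


@dataclasses.dataclass
class Selection:
    """Declarative atom selection over (chain, residue range, atom names)."""

    chain: str | None = None
    res_range: tuple[int, int] | None = None
    res_ids: Sequence[int] | None = None
    atom_names: Iterable[str] | None = None
    heavy_only: bool = False
    exclude_caps: bool = True

    def resolve(self, structure: Structure) -> np.ndarray:
        mask = np.ones(structure.n_atoms, dtype=bool)
        if self.chain is not None:
            if self.chain not in structure.chains:
                raise ValidationError(
                    f"chain {self.chain!r} not in structure "
                    f"(available: {structure.chains})")
            mask &= structure.chain_ids.astype(str) == self.chain
        if self.res_range is not None:
            lo, hi = self.res_range
            rid = structure.res_ids.astype(int)
            mask &= (rid >= lo) & (rid <= hi)
        if self.res_ids is not None:
            mask &= np.isin(structure.res_ids.astype(int), list(self.res_ids))
        if self.atom_names is not None:
            names = {n.strip().upper() for n in self.atom_names}
            mask &= np.array(
                [a.strip().upper() in names for a in structure.atom_names])
        if self.heavy_only:
            mask &= structure.heavy_mask()
        if self.exclude_caps:
            mask &= ~np.isin(structure.res_names.astype(str), list(CAP_RESIDUES))
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValidationError(f"selection {self} matched no atoms")
        return idx


def select(structure: Structure, **kwargs) -> np.ndarray:
    """Resolve a selection; raises :class:`ValidationError` if empty."""
    return Selection(**kwargs).resolve(structure)


# ---------------------------------------------------------------------------
# PDB input / output (via biotite)
# ---------------------------------------------------------------------------

def _from_atom_array(atoms: struc.AtomArray, model: int) -> Structure:
    elements = np.asarray(atoms.element, dtype="U3")
    blank = np.array([e.strip() == "" for e in elements])
    if blank.any():
        names = np.asarray(atoms.atom_name, dtype="U5")
        elements = elements.copy()
        for i in np.flatnonzero(blank):
            elements[i] = _infer_element(str(names[i]))
    return Structure(
        atom_names=np.asarray(atoms.atom_name, dtype="U5"),
        elements=elements,
        res_ids=np.asarray(atoms.res_id, dtype=int),
        res_names=np.asarray(atoms.res_name, dtype="U4"),
        chain_ids=np.asarray(atoms.chain_id, dtype="U4"),
        coords=np.asarray(atoms.coord, dtype=float),
        model=model,
    )


def read_structure(path: str | os.PathLike, model: int = 1) -> Structure:
    """Read one model from a PDB file.

    Alternate locations resolve to the highest-occupancy atom.  Author
    chain and residue numbering are preserved.
    """
    if not os.path.exists(path):
        raise ValidationError(f"structure file not found: {path}")
    try:
        pdb = PDBFile.read(str(path))
        n_models = pdb.get_model_count()
    except Exception as exc:  # malformed record
        raise ValidationError(f"cannot parse PDB {path}: {exc}") from exc
    if not (1 <= model <= n_models):
        raise ValidationError(
            f"model {model} not in {path}: available models are 1..{n_models}")
    try:
        atoms = pdb.get_structure(model=model, altloc="occupancy")
    except Exception as exc:
        raise ValidationError(f"cannot parse PDB {path}: {exc}") from exc
    return _from_atom_array(atoms, model)


def _to_atom_array(structure: Structure) -> struc.AtomArray:
    n = structure.n_atoms
    atoms = struc.AtomArray(n)
    atoms.coord = structure.coords.astype(np.float32)
    atoms.chain_id = structure.chain_ids.astype("U4")
    atoms.res_id = structure.res_ids.astype(int)
    atoms.res_name = structure.res_names.astype("U5")
    atoms.atom_name = structure.atom_names.astype("U6")
    atoms.element = structure.elements.astype("U2")
    atoms.hetero = np.zeros(n, dtype=bool)
    return atoms


def write_structure(structure: Structure, path: str | os.PathLike) -> None:
    """Write a single-model PDB file (3-decimal coordinate precision)."""
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(structure))
    pdb.write(str(path))


def write_trajectory_pdb(structure: Structure, trajectory: Trajectory,
                         path: str | os.PathLike) -> None:
    """Write a trajectory as a multi-model PDB over the structure's atoms."""
    if trajectory.n_atoms != structure.n_atoms:
        raise ValidationError("trajectory atom count does not match topology")
    stack = struc.stack([
        _to_atom_array(structure.with_coords(frame))
        for frame in trajectory.coords
    ])
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Plain-text XYZ trajectory fixtures
# ---------------------------------------------------------------------------

def write_trajectory_xyz(atom_names: Sequence[str], trajectory: Trajectory,
                         path: str | os.PathLike) -> None:
    """Write frames in plain multi-frame XYZ; dt is stored in the comment."""
    names = [str(n) for n in atom_names]
    if len(names) != trajectory.n_atoms:
        raise ValidationError("atom name count does not match trajectory")
    with open(path, "w") as fh:
        for f, frame in enumerate(trajectory.coords):
            fh.write(f"{len(names)}\n")
            fh.write(f"frame {f} dt_ps={trajectory.dt}\n")
            for name, (x, y, z) in zip(names, frame):
                fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


def _read_trajectory_xyz(path: str | os.PathLike,
                         dt: float | None) -> Trajectory:
    frames: list[np.ndarray] = []
    file_dt: float | None = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError as exc:
            raise ValidationError(
                f"malformed XYZ atom count at line {pos + 1} of {path}") from exc
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        for tok in comment.split():
            if tok.startswith("dt_ps="):
                file_dt = float(tok.split("=", 1)[1])
        body = lines[pos + 2: pos + 2 + n]
        if len(body) < n:
            raise ValidationError(
                f"truncated XYZ frame in {path}: last complete frame is "
                f"{len(frames)}")
        coords = np.array([[float(v) for v in ln.split()[1:4]] for ln in body])
        frames.append(coords)
        pos += 2 + n
    if not frames:
        raise ValidationError(f"no frames found in {path}")
    eff_dt = dt if dt is not None else file_dt
    if eff_dt is None:
        raise ValidationError(
            f"{path} carries no time metadata; pass dt explicitly")
    return Trajectory(coords=np.stack(frames), dt=eff_dt)


def read_trajectory(topology: Structure, path: str | os.PathLike,
                    dt: float | None = None,
                    temperature: float | None = None) -> Trajectory:
    """Read a trajectory (multi-model PDB, DCD, or plain XYZ).

    ``dt`` (ps) overrides any interval stored in the file; it is
    required when the file format carries no time metadata.
    """
    if not os.path.exists(path):
        raise ValidationError(f"trajectory file not found: {path}")
    suffix = os.path.splitext(str(path))[1].lower()
    if suffix == ".dcd":
        import mdtraj as md
        with tempfile.TemporaryDirectory() as tmp:
            top_path = os.path.join(tmp, "top.pdb")
            write_structure(topology, top_path)
            traj = md.load_dcd(str(path), top=top_path)
        coords = np.asarray(traj.xyz, dtype=float) * 10.0  # nm -> A
        eff_dt = dt if dt is not None else (
            float(traj.timestep) if traj.n_frames > 1 and traj.timestep > 0
            else None)
        if eff_dt is None:
            raise ValidationError(
                f"{path} carries no usable time metadata; pass dt explicitly")
        out = Trajectory(coords=coords, dt=eff_dt, temperature=temperature)
    elif suffix == ".xyz":
        out = _read_trajectory_xyz(path, dt)
        out.temperature = temperature
    else:  # multi-model PDB
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(altloc="occupancy")
        coords = np.asarray(stack.coord, dtype=float)
        if coords.ndim == 2:
            coords = coords[None]
        if dt is None:
            raise ValidationError(
                f"PDB trajectories carry no time metadata; pass dt explicitly")
        out = Trajectory(coords=coords, dt=dt, temperature=temperature)
    if out.n_atoms != topology.n_atoms:
        raise ValidationError(
            f"trajectory atom count {out.n_atoms} does not match topology "
            f"atom count {topology.n_atoms}")
    return out


def write_trajectory_dcd(structure: Structure, trajectory: Trajectory,
                         path: str | os.PathLike) -> None:
    """Write a binary DCD trajectory (coordinates converted to nm)."""
    import mdtraj as md
    with tempfile.TemporaryDirectory() as tmp:
        top_path = os.path.join(tmp, "top.pdb")
        write_structure(structure, top_path)
        top = md.load(top_path).topology
    traj = md.Trajectory(trajectory.coords / 10.0, top,
                         time=trajectory.times)
    traj.save_dcd(str(path))
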