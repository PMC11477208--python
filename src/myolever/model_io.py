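"""Structure and trajectory I/O plus atom selection.

All other modules consume the in-memory types defined here
(:class:`MolecularModel`, :class:`Trajectory`, :class:`Selection`) and never
touch file formats directly.  Standard PDB is the mandatory on-disk dialect;
trajectories are multi-model PDB files.  Parsing and writing are delegated to
:mod:`biotite.structure.io.pdb`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "MolecularModel",
    "Trajectory",
    "Selection",
    "SelectionSyntaxError",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "select",
]

# Backbone heavy atoms of the peptide unit; the tail-vector definition uses
# exactly this set.
BACKBONE_ATOMS = ("N", "CA", "C")

_METALS_AND_IONS = {"MG", "ZN", "FE", "NA", "CL", "BR", "MN", "CU", "K", "CA"}


class SelectionSyntaxError(ValueError):
    """Raised when a selection expression cannot be parsed."""


@dataclass
class MolecularModel:
    """A single structure: per-atom identity plus Cartesian coordinates (Å).

    Arrays are parallel, one entry per atom.  ``(chain, resid, icode, name)``
    is unique within a model.
    """

    chain: np.ndarray          # str, chain identifier
    resid: np.ndarray          # int, author residue number
    icode: np.ndarray          # str, insertion code ('' if none)
    resname: np.ndarray        # str, residue name
    name: np.ndarray           # str, atom name
    element: np.ndarray        # str, element symbol (upper case)
    coords: np.ndarray         # (N, 3) float64, Å
    source: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (N, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        n = len(self.coords)
        for attr in ("chain", "resid", "icode", "resname", "name", "element"):
            arr = np.asarray(getattr(self, attr))
            if len(arr) != n:
                raise ValueError(f"annotation '{attr}' length {len(arr)} != {n} atoms")
            setattr(self, attr, arr)
        key = list(zip(self.chain, self.resid, self.icode, self.name))
        if len(set(key)) != n:
            raise ValueError("(chain, residue, insertion code, atom name) not unique")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def residue_key(self) -> list[tuple[str, int, str]]:
        """Per-atom (chain, resid, icode) identity tuples."""
        return list(zip(self.chain, self.resid, self.icode))

    def subset(self, indices: np.ndarray, source: str | None = None) -> "MolecularModel":
        idx = np.asarray(indices, dtype=int)
        return MolecularModel(
            chain=self.chain[idx], resid=self.resid[idx], icode=self.icode[idx],
            resname=self.resname[idx], name=self.name[idx], element=self.element[idx],
            coords=self.coords[idx].copy(),
            source=source if source is not None else self.source,
        )

    def with_coords(self, coords: np.ndarray) -> "MolecularModel":
        return replace(self, coords=np.array(coords, dtype=float))

    @property
    def is_heavy(self) -> np.ndarray:
        return self.element != "H"


@dataclass
class Selection:
    """An ordered, duplicate-free list of atom indices into one topology."""

    indices: np.ndarray
    provenance: str = ""
    warning: str | None = None

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.ndim != 1:
            raise ValueError("indices must be 1-D")
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("selection indices must be unique")

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)


@dataclass
class Trajectory:
    """An ordered stack of coordinate frames over a fixed topology.

    ``timestep`` is the time between consecutive stored frames in ps.
    """

    topology: MolecularModel
    frames: np.ndarray          # (F, N, 3) float64, Å
    timestep: float = 100.0     # ps
    replicate: str = "1"
    condition: str = "other"    # apo | holo | other

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (F, N, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"topology atom count {self.topology.n_atoms}"
            )
        if not self.timestep > 0:
            raise ValueError("timestep must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    @property
    def duration(self) -> float:
        """Spanned time in ps (F - 1 intervals)."""
        return (self.n_frames - 1) * self.timestep

    def strided(self, stride: int) -> "Trajectory":
        if stride < 1:
            raise ValueError("stride must be >= 1")
        return replace(self, frames=self.frames[::stride], timestep=self.timestep * stride)

    def discard_equilibration(self, discard_ps: float) -> "Trajectory":
        """Drop leading frames covering ``discard_ps`` picoseconds."""
        n_drop = int(round(discard_ps / self.timestep))
        if n_drop >= self.n_frames:
            raise ValueError(
                f"discarding {discard_ps} ps removes all {self.n_frames} frames"
            )
        return replace(self, frames=self.frames[n_drop:])


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _guess_element(atom_name: str, hetero: bool) -> str:
    name = atom_name.strip()
    stripped = name.lstrip("0123456789")
    if not stripped:
        return "X"
    if stripped[0] == "H":
        return "H"
    if hetero and stripped.upper() in _METALS_AND_IONS:
        return stripped.upper()
    return stripped[0].upper()


def _find_bad_pdb_line(path: str) -> int | None:
    """Locate the first ATOM/HETATM record with an unparseable coordinate field."""
    try:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.startswith(("ATOM", "HETATM")):
                    try:
                        for lo, hi in ((30, 38), (38, 46), (46, 54)):
                            float(line[lo:hi])
                    except (ValueError, IndexError):
                        return lineno
    except OSError:
        return None
    return None


def _read_pdb(path: str) -> PDBFile:
    try:
        return PDBFile.read(path)
    except Exception as exc:  # re-raise with line info when we can find it
        raise _parse_error(path, exc) from exc


def _parse_error(path: str, exc: Exception) -> ValueError:
    bad = _find_bad_pdb_line(str(path))
    if bad is not None:
        return ValueError(f"unparseable PDB record at {path}:{bad}")
    return ValueError(f"cannot parse PDB file {path}: {exc}")


def _get_structure(pdb: PDBFile, path: str, **kwargs):
    try:
        return pdb.get_structure(altloc="occupancy", **kwargs)
    except Exception as exc:
        raise _parse_error(path, exc) from exc


def _stack_to_arrays(atoms) -> dict:
    n = atoms.array_length()
    hetero = atoms.hetero
    element = np.array(
        [
            el.upper() if el else _guess_element(nm, het)
            for el, nm, het in zip(atoms.element, atoms.atom_name, hetero)
        ],
        dtype=object,
    )
    icode = atoms.ins_code if "ins_code" in atoms.get_annotation_categories() else np.full(n, "")
    return dict(
        chain=atoms.chain_id.astype(object),
        resid=atoms.res_id.astype(int),
        icode=np.asarray(icode, dtype=object),
        resname=atoms.res_name.astype(object),
        name=atoms.atom_name.astype(object),
        element=element,
    )


def read_structure(
    path: str,
    chains: list[str] | None = None,
    heavy_only: bool = False,
    model: int = 1,
) -> MolecularModel:
    """Read one model from a PDB file.

    Altloc policy: the highest-occupancy alternate location is kept (ties go
    to altloc 'A', biotite's occupancy rule).  Insertion codes are preserved
    as part of the residue identity.

    Parameters
    ----------
    chains
        Optional chain filter; an empty result after filtering is an error.
    heavy_only
        Drop hydrogens (any atom whose element is H).
    """
    pdb = _read_pdb(str(path))
    atoms = _get_structure(pdb, str(path), model=model)
    ann = _stack_to_arrays(atoms)
    coords = np.asarray(atoms.coord, dtype=float)

    mask = np.ones(len(coords), dtype=bool)
    if chains is not None:
        mask &= np.isin(ann["chain"], list(chains))
        if not mask.any():
            raise ValueError(
                f"no atoms left after chain filter {chains!r} in {path}"
            )
    if heavy_only:
        mask &= ann["element"] != "H"
    if not mask.any():
        raise ValueError(f"empty atom selection after filtering {path}")
    idx = np.where(mask)[0]
    return MolecularModel(
        coords=coords[idx], source=str(path),
        **{k: v[idx] for k, v in ann.items()},
    )


def _model_to_atom_array(model: MolecularModel, coords: np.ndarray) -> struc.AtomArray:
    arr = struc.AtomArray(model.n_atoms)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.chain_id = model.chain.astype("U4")
    arr.res_id = model.resid
    arr.ins_code = model.icode.astype("U1")
    arr.res_name = model.resname.astype("U5")
    arr.atom_name = model.name.astype("U6")
    arr.element = model.element.astype("U2")
    arr.hetero = np.zeros(model.n_atoms, dtype=bool)
    return arr


def write_structure(model: MolecularModel, path: str) -> None:
    """Write a single-model PDB file."""
    pdb = PDBFile()
    pdb.set_structure(_model_to_atom_array(model, model.coords))
    pdb.write(str(path))


def write_trajectory(traj: Trajectory, path: str) -> None:
    """Write a trajectory as a multi-model PDB file (one MODEL per frame)."""
    stack = struc.stack(
        [_model_to_atom_array(traj.topology, f) for f in traj.frames]
    )
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_trajectory(
    path: str,
    topology: MolecularModel,
    stride: int = 1,
    timestep: float = 100.0,
    replicate: str = "1",
    condition: str = "other",
) -> Trajectory:
    """Read a multi-model PDB file as a trajectory over ``topology``.

    Frames are kept in storage order; ``stride=k`` keeps frames 0, k, 2k, ...
    ``timestep`` is the spacing of the *stored* frames; the returned
    trajectory's timestep is scaled by the stride.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    pdb = _read_pdb(str(path))
    stack = _get_structure(pdb, str(path), model=None)
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    if coords.shape[1] != topology.n_atoms:
        raise ValueError(
            f"atom count mismatch: topology has {topology.n_atoms} atoms, "
            f"trajectory frames have {coords.shape[1]}"
        )
    return Trajectory(
        topology=topology,
        frames=coords[::stride],
        timestep=timestep * stride,
        replicate=replicate,
        condition=condition,
    )


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

def _parse_int_set(tokens: list[str], what: str) -> set[int]:
    out: set[int] = set()
    for tok in tokens:
        tok = tok.replace("–", "-").rstrip(",")  # tolerate en dash / comma lists
        if not tok:
            continue
        if "-" in tok[1:]:
            split_at = tok.index("-", 1)
            try:
                lo, hi = int(tok[:split_at]), int(tok[split_at + 1:])
            except ValueError as exc:
                raise SelectionSyntaxError(f"bad {what} range '{tok}'") from exc
            if hi < lo:
                raise SelectionSyntaxError(f"descending {what} range '{tok}'")
            out.update(range(lo, hi + 1))
        else:
            try:
                out.add(int(tok))
            except ValueError as exc:
                raise SelectionSyntaxError(f"bad {what} token '{tok}'") from exc
    return out


def select(model: MolecularModel, expression: str) -> Selection:
    """Resolve a selection expression against a model.

    Grammar: clauses joined by ``and``; each clause is one of::

        chain <id> [<id> ...]
        resid <n | lo-hi> [...]        (author numbering, e.g. "resid 712-766")
        name <atom name> [...]
        resname <residue name> [...]
        element <symbol> [...]
        backbone                       (atoms N, CA, C)
        heavy                          (element != H)
        all

    The result preserves model atom order and is deterministic.  An empty
    result is returned with a warning attached rather than raised, so callers
    decide whether emptiness is an error.
    """
    if not expression or not expression.strip():
        raise SelectionSyntaxError("empty selection expression")
    mask = np.ones(model.n_atoms, dtype=bool)
    for clause in (c.strip() for c in expression.split(" and ")):
        if not clause:
            raise SelectionSyntaxError(f"empty clause in '{expression}'")
        parts = clause.split()
        kw, args = parts[0].lower(), parts[1:]
        if kw == "all":
            continue
        elif kw == "heavy":
            mask &= model.element != "H"
        elif kw == "backbone":
            mask &= np.isin(model.name, BACKBONE_ATOMS)
        elif kw == "chain":
            if not args:
                raise SelectionSyntaxError("'chain' needs at least one id")
            mask &= np.isin(model.chain, args)
        elif kw == "resid":
            if not args:
                raise SelectionSyntaxError("'resid' needs at least one number/range")
            wanted = _parse_int_set(args, "residue")
            mask &= np.isin(model.resid, sorted(wanted))
        elif kw == "name":
            if not args:
                raise SelectionSyntaxError("'name' needs at least one atom name")
            mask &= np.isin(model.name, args)
        elif kw == "resname":
            if not args:
                raise SelectionSyntaxError("'resname' needs at least one residue name")
            mask &= np.isin(model.resname, args)
        elif kw == "element":
            if not args:
                raise SelectionSyntaxError("'element' needs at least one symbol")
            mask &= np.isin(model.element, [a.upper() for a in args])
        else:
            raise SelectionSyntaxError(f"unknown selection keyword '{kw}'")
    indices = np.where(mask)[0]
    warning = None
    if len(indices) == 0:
        warning = f"selection '{expression}' matched no atoms"
        warnings.warn(warning, stacklevel=2)
    return Selection(indices=indices, provenance=expression, warning=warning)
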