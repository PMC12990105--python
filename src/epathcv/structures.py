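"""Structure and trajectory handling: I/O, atom selection, superposition, RMSD.

Coordinates are stored in nanometres throughout the package (the convention
of GROMACS and PLUMED); PDB files are converted from/to angstroms at the I/O
boundary, GRO files are natively in nm.

The central geometric operation is :func:`rmsd_superposed`: a least-squares
rigid-body fit (proper rotation + translation, reflections excluded) computed
on an *align* atom set, with the RMSD then evaluated over a possibly different
*measure* set.  Both PATH collective-variable flavours are built on it.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import GeometryError, ParseError, ValidationError

ANGSTROM_PER_NM = 10.0

__all__ = [
    "Structure",
    "Trajectory",
    "AtomSelection",
    "read_structure",
    "read_trajectory",
    "write_pdb",
    "select_calpha",
    "superposition",
    "rmsd_superposed",
    "extract_milestones",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Structure:
    """A single conformation: atom labels, residue ids and coordinates in nm."""

    atom_names: np.ndarray
    residue_ids: np.ndarray
    coordinates: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "atom_names", np.asarray(self.atom_names, dtype=object))
        object.__setattr__(self, "residue_ids", np.asarray(self.residue_ids, dtype=int))
        coords = np.asarray(self.coordinates, dtype=float)
        object.__setattr__(self, "coordinates", coords)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValidationError("coordinates must be an (n_atoms, 3) array")
        n = coords.shape[0]
        if len(self.atom_names) != n or len(self.residue_ids) != n:
            raise ValidationError("atom_names, residue_ids and coordinates must share length")
        if not np.all(np.isfinite(coords)):
            raise ValidationError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]

    def with_coordinates(self, coords: np.ndarray) -> "Structure":
        """Same topology, new coordinates (nm)."""
        return Structure(self.atom_names, self.residue_ids, coords)


@dataclass
class Trajectory:
    """An ordered stack of frames sharing one topology.

    ``frames`` is (n_frames, n_atoms, 3) in nm; ``times`` (ps), if present,
    must be strictly increasing.
    """

    topology: Structure
    frames: np.ndarray
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValidationError("frames must be an (n_frames, n_atoms, 3) array")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValidationError(
                f"frames have {self.frames.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}"
            )
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if len(self.times) != self.n_frames:
                raise ValidationError("times length must equal frame count")
            if np.any(np.diff(self.times) <= 0):
                raise ValidationError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_structure(self, i: int) -> Structure:
        return self.topology.with_coordinates(self.frames[i])


@dataclass(frozen=True)
class AtomSelection:
    """Ordered, unique 0-based atom indices."""

    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        object.__setattr__(self, "indices", idx)
        if idx.ndim != 1 or idx.size == 0:
            raise ValidationError("selection must be a non-empty 1-D index list")
        if idx.min() < 0:
            raise ValidationError("selection indices must be non-negative")
        if len(np.unique(idx)) != len(idx):
            raise ValidationError("selection indices must be unique")

    def __len__(self) -> int:
        return len(self.indices)

    def validate_against(self, n_atoms: int) -> None:
        if self.indices.max() >= n_atoms:
            raise ValidationError(
                f"selection index {self.indices.max()} out of bounds for {n_atoms} atoms"
            )

    @classmethod
    def all(cls, n_atoms: int) -> "AtomSelection":
        return cls(np.arange(n_atoms))


# ---------------------------------------------------------------------------
# Reading structures and trajectories
# ---------------------------------------------------------------------------

def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    if ext in ("pdb", "gro"):
        return ext
    raise ValidationError(f"cannot infer format from extension of {path!r}")


def _locate_bad_pdb_line(path: str) -> int | None:
    """Best-effort scan for the first malformed ATOM/HETATM record."""
    try:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.startswith(("ATOM", "HETATM")):
                    try:
                        float(line[30:38])
                        float(line[38:46])
                        float(line[46:54])
                    except (ValueError, IndexError):
                        return lineno
    except OSError:
        return None
    return None


def _load_atom_array_stack(path: str, fmt: str):
    # biotite works in angstrom internally for both formats
    import warnings

    import biotite.structure.io.gro as gro_io
    import biotite.structure.io.pdb as pdb_io

    if fmt == "pdb":
        f = pdb_io.PDBFile.read(path)
        with warnings.catch_warnings():
            # element guessing from atom names is fine for C-alpha traces
            warnings.filterwarnings("ignore", message=".*guessed from atom name.*")
            return f.get_structure()  # AtomArrayStack over MODELs
    if fmt == "gro":
        f = gro_io.GROFile.read(path)
        return f.get_structure()
    raise ValidationError(f"unsupported structure format {fmt!r}")


def read_structure(path: str, fmt: str | None = None) -> Structure:
    """Read a single-conformation structure file (PDB or GRO) into nm.

    For a multi-MODEL PDB, the first model is returned; use
    :func:`read_trajectory` to keep all models.
    """
    fmt = _infer_format(path, fmt)
    if not os.path.exists(path):
        raise ParseError(f"no such file: {path}")
    try:
        stack = _load_atom_array_stack(path, fmt)
    except ValidationError:
        raise
    except Exception as exc:  # biotite raises format-specific errors
        lineno = _locate_bad_pdb_line(path) if fmt == "pdb" else None
        where = f" (line {lineno})" if lineno else ""
        raise ParseError(f"failed to parse {path!r} as {fmt}{where}: {exc}") from exc
    if stack.array_length() == 0 or stack.stack_depth() == 0:
        raise ParseError(f"{path!r} contains no atoms")
    arr = stack[0]
    coords = np.asarray(arr.coord, dtype=float) / ANGSTROM_PER_NM
    return Structure(np.asarray(arr.atom_name, dtype=object),
                     np.asarray(arr.res_id, dtype=int), coords)


def read_trajectory(path: str, fmt: str | None = None) -> Trajectory:
    """Read a multi-frame file (multi-MODEL PDB at minimum) into a Trajectory.

    The hook point for binary trajectory formats: any reader producing an
    (n_frames, n_atoms, 3) nm array and a topology satisfies the same contract.
    """
    fmt = _infer_format(path, fmt)
    if not os.path.exists(path):
        raise ParseError(f"no such file: {path}")
    try:
        stack = _load_atom_array_stack(path, fmt)
    except Exception as exc:
        lineno = _locate_bad_pdb_line(path) if fmt == "pdb" else None
        where = f" (line {lineno})" if lineno else ""
        raise ParseError(f"failed to parse {path!r} as {fmt}{where}: {exc}") from exc
    if stack.array_length() == 0 or stack.stack_depth() == 0:
        raise ParseError(f"{path!r} contains no atoms")
    arr0 = stack[0]
    topo = Structure(np.asarray(arr0.atom_name, dtype=object),
                     np.asarray(arr0.res_id, dtype=int),
                     np.asarray(arr0.coord, dtype=float) / ANGSTROM_PER_NM)
    frames = np.asarray(stack.coord, dtype=float) / ANGSTROM_PER_NM
    return Trajectory(topo, frames)


# ---------------------------------------------------------------------------
# Writing PDB (fixed-width ATOM records, angstrom)
# ---------------------------------------------------------------------------

def format_atom_record(serial: int, name: str, res_id: int, xyz_ang: np.ndarray,
                       occupancy: float = 1.0, bfactor: float = 0.0,
                       res_name: str = "ALA", chain: str = "A") -> str:
    """One fixed-width PDB ATOM line; coordinates given in angstrom."""
    name_f = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    return (
        f"ATOM  {serial:>5d} {name_f} {res_name:>3s} {chain}{res_id:>4d}    "
        f"{xyz_ang[0]:8.3f}{xyz_ang[1]:8.3f}{xyz_ang[2]:8.3f}"
        f"{occupancy:6.2f}{bfactor:6.2f}"
    )


def write_pdb(obj: Structure | Trajectory, path: str,
              occupancy: np.ndarray | None = None,
              bfactor: np.ndarray | None = None) -> None:
    """Write a Structure (single MODEL) or Trajectory (multi-MODEL) PDB in angstrom."""
    if isinstance(obj, Structure):
        topo, frames = obj, obj.coordinates[None]
    else:
        topo, frames = obj.topology, obj.frames
    n = topo.n_atoms
    occ = np.ones(n) if occupancy is None else np.asarray(occupancy, dtype=float)
    bf = np.zeros(n) if bfactor is None else np.asarray(bfactor, dtype=float)
    multi = frames.shape[0] > 1
    with open(path, "w") as fh:
        for m, coords in enumerate(frames, start=1):
            if multi:
                fh.write(f"MODEL     {m:>4d}\n")
            ang = coords * ANGSTROM_PER_NM
            for i in range(n):
                fh.write(format_atom_record(
                    i + 1, str(topo.atom_names[i]), int(topo.residue_ids[i]),
                    ang[i], occ[i], bf[i]) + "\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Atom selection
# ---------------------------------------------------------------------------

def select_calpha(structure: Structure,
                  residue_ranges: Sequence[tuple[int, int]] | None = None
                  ) -> AtomSelection:
    """All CA atoms, optionally restricted to inclusive residue-id intervals.

    Secondary-structure detection is deliberately not performed: callers
    supply explicit residue ranges (e.g. the helical segments) or default to
    every C-alpha.
    """
    is_ca = np.asarray([str(n).strip() == "CA" for n in structure.atom_names])
    if not is_ca.any():
        raise ValidationError("structure contains no CA atoms")
    mask = is_ca.copy()
    if residue_ranges is not None:
        res = structure.residue_ids
        lo_all, hi_all = res[is_ca].min(), res[is_ca].max()
        in_range = np.zeros(structure.n_atoms, dtype=bool)
        for lo, hi in residue_ranges:
            if lo > hi:
                raise ValidationError(f"invalid residue interval ({lo}, {hi})")
            if hi < lo_all or lo > hi_all:
                raise ValidationError(
                    f"residue interval ({lo}, {hi}) outside residue range "
                    f"[{lo_all}, {hi_all}]")
            in_range |= (res >= lo) & (res <= hi)
        mask &= in_range
    if not mask.any():
        raise ValidationError("C-alpha selection is empty for the given ranges")
    return AtomSelection(np.flatnonzero(mask))


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------

def _as_coords(obj) -> np.ndarray:
    coords = obj.coordinates if isinstance(obj, Structure) else np.asarray(obj, float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValidationError("expected an (n_atoms, 3) coordinate array")
    return coords


def superposition(mobile, reference, align: AtomSelection
                  ) -> tuple[Rotation, np.ndarray, np.ndarray]:
    """Least-squares proper-rotation fit of mobile onto reference.

    Returns (rotation, mobile_centroid, reference_centroid) such that
    ``rotation.apply(x - mobile_centroid) + reference_centroid`` maps mobile
    coordinates into the reference frame.  Centroids are those of the align
    atoms.  Reflections are excluded (determinant correction), preserving
    chirality.
    """
    mob = _as_coords(mobile)
    ref = _as_coords(reference)
    idx = align.indices
    if idx.max() >= mob.shape[0] or idx.max() >= ref.shape[0]:
        raise ValidationError("align selection out of bounds for the coordinate sets")
    if len(idx) < 3:
        raise GeometryError("superposition requires at least 3 align atoms")
    a = mob[idx]
    b = ref[idx]
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    sv = np.linalg.svd(a0, compute_uv=False)
    if sv[1] <= 1e-10 * max(sv[0], 1e-30):
        raise GeometryError("align atoms are (near-)collinear; rotation is underdetermined")
    rot, _ = Rotation.align_vectors(b0, a0)
    return rot, ca, cb


def rmsd_superposed(mobile, reference, align: AtomSelection,
                    measure: AtomSelection | None = None) -> float:
    """RMSD (nm) over `measure` atoms after a rigid fit on `align` atoms.

    Invariant under rigid motions of either argument; symmetric in its two
    arguments when align == measure.
    """
    measure = align if measure is None else measure
    mob = _as_coords(mobile)
    ref = _as_coords(reference)
    if measure.indices.max() >= mob.shape[0] or measure.indices.max() >= ref.shape[0]:
        raise ValidationError("measure selection out of bounds for the coordinate sets")
    rot, ca, cb = superposition(mob, ref, align)
    moved = rot.apply(mob[measure.indices] - ca) + cb
    diff = moved - ref[measure.indices]
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


# ---------------------------------------------------------------------------
# Milestone extraction from a transition trajectory
# ---------------------------------------------------------------------------

EXHAUSTIVE_FRAME_LIMIT = 20


def _pairwise_rmsd(traj: Trajectory, align: AtomSelection,
                   measure: AtomSelection, idx: np.ndarray) -> np.ndarray:
    k = len(idx)
    mat = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            r = rmsd_superposed(traj.frames[idx[a]], traj.frames[idx[b]], align, measure)
            mat[a, b] = mat[b, a] = r
    return mat


def extract_milestones(traj: Trajectory, n: int, align: AtomSelection,
                       measure: AtomSelection | None = None) -> list[Structure]:
    """Pick n frames as path milestones with near-uniform consecutive RMSDs.

    End frames are always kept.  Interior frames are a monotone subsequence
    minimizing the variance of consecutive-milestone RMSD gaps: exhaustively
    for small trajectories, by an arc-length heuristic (frames closest to
    equal cumulative-RMSD targets) for large ones.
    """
    measure = align if measure is None else measure
    if n < 2:
        raise ValidationError("need at least 2 milestones")
    f = traj.n_frames
    if n > f:
        raise ValidationError(f"requested {n} milestones from {f} frames")
    if n == 2 or f == n:
        chosen = [0, f - 1] if n == 2 else list(range(f))
        return [traj.frame_structure(i) for i in chosen]

    if f <= EXHAUSTIVE_FRAME_LIMIT:
        mat = _pairwise_rmsd(traj, align, measure, np.arange(f))
        best, best_var = None, np.inf
        for interior in combinations(range(1, f - 1), n - 2):
            seq = (0,) + interior + (f - 1,)
            gaps = np.array([mat[seq[i], seq[i + 1]] for i in range(n - 1)])
            var = float(np.var(gaps))
            if var < best_var - 1e-15:
                best, best_var = seq, var
        chosen = list(best)
    else:
        # cumulative arc length along consecutive frames; nearest frame to
        # each equal-arc target, kept strictly monotone
        arc = np.zeros(f)
        for i in range(f - 1):
            arc[i + 1] = arc[i] + rmsd_superposed(
                traj.frames[i], traj.frames[i + 1], align, measure)
        targets = np.linspace(0.0, arc[-1], n)
        chosen = [0]
        for t in targets[1:-1]:
            i = int(np.argmin(np.abs(arc - t)))
            i = max(i, chosen[-1] + 1)
            i = min(i, f - 1 - (n - 1 - len(chosen)))
            chosen.append(i)
        chosen.append(f - 1)
    return [traj.frame_structure(i) for i in chosen]
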