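"""PATH collective variables: progress s and deviation z along a milestone path.

Two flavours are implemented:

* RPATH — the classic structure-based form.  Milestones are full reference
  conformations X_i and the metric is the superposed RMSD R[X - X_i]:

      s(X) = sum_i i * exp(-lam * R_i) / sum_i exp(-lam * R_i)
      z(X) = -(1/lam) * ln sum_i exp(-lam * R_i)

  The exponent is linear in R (lam in 1/nm).  A ``squared`` flag switches to
  exponents in R^2 for engines that use mean-square-deviation conventions.

* EPATH — the Euclidean form.  A conformation is encoded as the point
  M = (RMSD_inactive, RMSD_active) in the plane of RMSDs to the two end-state
  references; milestones M_i are points in that plane and the metric is the
  squared Euclidean distance d(M, M_i)^2 (lam in 1/nm^2):

      s(M) = sum_i i * exp(-lam * d_i^2) / sum_i exp(-lam * d_i^2)
      z(M) = -(1/lam) * ln sum_i exp(-lam * d_i^2)

  Only the two end milestones need real structures; interior milestones are
  drawn on a slightly arched curve above the RMSD-plane diagonal, which keeps
  the path away from the improbable region where both RMSDs are small while
  still skirting the vast high-RMSD region.

All exponential sums are evaluated max-shifted (log-sum-exp) so arbitrarily
large lam is exact to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .structures import AtomSelection, Structure, rmsd_superposed

__all__ = [
    "Milestone2D",
    "PathDefinition",
    "WindowedHarmonic",
    "DeviationWall",
    "epath_distance",
    "epath_sz",
    "rpath_sz",
    "build_arched_path",
    "endpoint_distance",
    "suggest_lambda",
    "analysis_lambda",
    "restraint_energy",
    "project_trajectory",
    "save_path_config",
    "load_path_config",
]

#: multiplier on the sampling-oriented lambda used when *projecting*
#: trajectories for analysis; see docs/methods.md
ANALYSIS_LAMBDA_FACTOR = 4.0

DEFAULT_N_MILESTONES = 8
DEFAULT_ARCH = 0.3


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Milestone2D:
    """A path node in the (RMSD_inactive, RMSD_active) plane, in nm."""

    index: int
    rmsd_inactive: float
    rmsd_active: float

    def __post_init__(self) -> None:
        if self.rmsd_inactive < 0 or self.rmsd_active < 0:
            raise ValidationError("milestone RMSD components must be >= 0")

    @property
    def point(self) -> np.ndarray:
        return np.array([self.rmsd_inactive, self.rmsd_active])


@dataclass
class PathDefinition:
    """An ordered milestone sequence plus the smoothness parameter lambda.

    ``flavor`` is "EPATH" (milestones are :class:`Milestone2D`) or "RPATH"
    (milestones are :class:`Structure` references).  ``lam`` has units 1/nm^2
    for EPATH and 1/nm for RPATH.  ``align``/``measure`` are the selections
    used for every RMSD the path involves.
    """

    flavor: str
    milestones: list
    lam: float
    align: AtomSelection | None = None
    measure: AtomSelection | None = None
    squared: bool = False  # RPATH only: exponent in R^2 instead of R

    def __post_init__(self) -> None:
        if self.flavor not in ("EPATH", "RPATH"):
            raise ValidationError(f"unknown path flavor {self.flavor!r}")
        if len(self.milestones) < 2:
            raise ValidationError("a path needs at least 2 milestones")
        if not (self.lam > 0):
            raise ValidationError("lambda must be positive")
        if self.flavor == "EPATH":
            idx = [m.index for m in self.milestones]
            if idx != list(range(1, len(idx) + 1)):
                raise ValidationError("milestone indices must be 1..N consecutive")
            pts = np.array([m.point for m in self.milestones])
            if np.any(np.linalg.norm(np.diff(pts, axis=0), axis=1) == 0.0):
                raise ValidationError("consecutive milestones must be distinct")

    @property
    def n_milestones(self) -> int:
        return len(self.milestones)

    def milestone_points(self) -> np.ndarray:
        """(N, 2) array of EPATH milestone coordinates."""
        if self.flavor != "EPATH":
            raise ValidationError("milestone_points is defined for EPATH paths")
        return np.array([m.point for m in self.milestones])


# ---------------------------------------------------------------------------
# Distances and the s/z core
# ---------------------------------------------------------------------------

def _as_point(m) -> np.ndarray:
    if isinstance(m, Milestone2D):
        return m.point
    p = np.asarray(m, dtype=float)
    if p.shape != (2,):
        raise ValidationError("a path-plane point is a pair (rmsd_inactive, rmsd_active)")
    if not np.all(np.isfinite(p)):
        raise ValidationError("path-plane point must be finite")
    if np.any(p < 0):
        raise ValidationError("RMSD components must be >= 0")
    return p


def epath_distance(m, mi) -> float:
    """Euclidean distance (nm) between two points of the RMSD plane."""
    return float(np.linalg.norm(_as_point(m) - _as_point(mi)))


def _sz_from_metric(metric: np.ndarray, lam: float) -> tuple[float, float]:
    """s and z from per-milestone metric values (d^2 for EPATH, R for RPATH).

    Max-shifted so the result is finite and exact for any lam > 0.
    """
    a = -lam * np.asarray(metric, dtype=float)
    shift = a.max()
    w = np.exp(a - shift)
    total = w.sum()
    idx = np.arange(1, len(a) + 1)
    s = float((idx * w).sum() / total)
    z = float(-(shift + math.log(total)) / lam)
    return s, z


def epath_sz(point, path: PathDefinition) -> tuple[float, float]:
    """Progress s and deviation z of an RMSD-plane point along an EPATH."""
    if path.flavor != "EPATH":
        raise ValidationError("epath_sz requires an EPATH path")
    p = _as_point(point)
    d2 = np.sum((path.milestone_points() - p) ** 2, axis=1)
    return _sz_from_metric(d2, path.lam)


def rpath_sz(frame, path: PathDefinition) -> tuple[float, float]:
    """Progress s and deviation z of a conformation along a structural RPATH.

    The metric is the superposed RMSD to each milestone structure (linear in
    R by default; squared if the path's ``squared`` flag is set).
    """
    if path.flavor != "RPATH":
        raise ValidationError("rpath_sz requires an RPATH path")
    if path.align is None:
        raise ValidationError("RPATH evaluation needs align/measure selections")
    r = np.array([
        rmsd_superposed(frame, ms, path.align, path.measure)
        for ms in path.milestones
    ])
    metric = r * r if path.squared else r
    return _sz_from_metric(metric, path.lam)


# ---------------------------------------------------------------------------
# Arched path construction
# ---------------------------------------------------------------------------

def _bezier(t: np.ndarray, p0: np.ndarray, c: np.ndarray, p2: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)[..., None]
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * c + t ** 2 * p2


def build_arched_path(end_distance: float, n_milestones: int = DEFAULT_N_MILESTONES,
                      arch: float = DEFAULT_ARCH, lam: float | None = None,
                      align: AtomSelection | None = None,
                      measure: AtomSelection | None = None,
                      _grid: int = 20001) -> PathDefinition:
    """Milestones on a quadratic Bezier arching above the RMSD-plane diagonal.

    End milestones are pinned to the end states, M_1 = (0, D) and
    M_N = (D, 0) with D = end_distance.  ``arch`` sets the fractional bulge
    of the curve apex: the t = 1/2 Bezier point lies at
    ((1 + arch) D / 2, (1 + arch) D / 2), i.e. arch = 0 is the straight
    chord.  Interior milestones are placed at equal arc-length intervals
    (dense numeric arc-length parameterization, symmetrized so the
    construction is exactly invariant under swapping the two RMSD axes and
    reversing milestone order).

    If lam is omitted, :func:`suggest_lambda` is applied to the finished path.
    """
    if not end_distance > 0:
        raise ValidationError("end_distance must be positive")
    if n_milestones < 2:
        raise ValidationError("need at least 2 milestones")
    if arch < 0:
        raise ValidationError("arch must be >= 0")
    d = float(end_distance)
    p0 = np.array([0.0, d])
    p2 = np.array([d, 0.0])
    # control point such that the curve APEX (t=1/2) sits at (1+arch)*D/2
    # on the diagonal: B(1/2) = (P0 + 2C + P2)/4
    c = np.array([(1 + 2 * arch) * d / 2.0] * 2)

    n = n_milestones
    if n == 2:
        pts = np.vstack([p0, p2])
    else:
        t_dense = np.linspace(0.0, 1.0, _grid)
        pts_dense = _bezier(t_dense, p0, c, p2)
        seg = np.linalg.norm(np.diff(pts_dense, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        targets = np.linspace(0.0, arc[-1], n)
        t_nodes = np.interp(targets, arc, t_dense)
        t_nodes = 0.5 * (t_nodes + (1.0 - t_nodes[::-1]))  # exact symmetry
        pts = _bezier(t_nodes, p0, c, p2)

    milestones = [Milestone2D(i + 1, float(x), float(y))
                  for i, (x, y) in enumerate(pts)]
    path = PathDefinition("EPATH", milestones, lam=1.0, align=align, measure=measure)
    path.lam = float(lam) if lam is not None else suggest_lambda(path)
    return path


def endpoint_distance(inactive: Structure, active: Structure,
                      align: AtomSelection, measure: AtomSelection | None = None
                      ) -> float:
    """Superposed RMSD (nm) between the two end-state structures.

    This is the D feeding :func:`build_arched_path`.
    """
    return rmsd_superposed(active, inactive, align, measure)


def suggest_lambda(path: PathDefinition) -> float:
    """A lambda in the sweet spot between step-like and washed-out projections.

    Chosen so the exponential weight at a neighbouring milestone is ~1/2:
    lam = ln 2 / <consecutive metric>, where the metric is the consecutive
    squared milestone distance (EPATH, 1/nm^2) or the consecutive milestone
    RMSD (RPATH, 1/nm).
    """
    if path.flavor == "EPATH":
        pts = path.milestone_points()
        gaps = np.sum(np.diff(pts, axis=0) ** 2, axis=1)
    else:
        if path.align is None:
            raise ValidationError("RPATH lambda suggestion needs align/measure selections")
        gaps = np.array([
            rmsd_superposed(path.milestones[i].coordinates,
                            path.milestones[i + 1].coordinates,
                            path.align, path.measure)
            for i in range(path.n_milestones - 1)
        ])
        if path.squared:
            gaps = gaps ** 2
    mean_gap = float(np.mean(gaps))
    if mean_gap == 0.0 or np.any(gaps == 0.0):
        raise ValidationError("coincident consecutive milestones; cannot set lambda")
    return math.log(2.0) / mean_gap


def analysis_lambda(path: PathDefinition) -> float:
    """A sharper lambda for trajectory *projection* (not biasing).

    Sampling wants a smooth s (neighbour weight ~1/2); analysis wants s to
    localize at the milestones so basin windows in s are meaningful.  The
    factor-of-four sharpening drops the neighbour weight to 1/16, pinning a
    frame at an end milestone to within ~0.06 of the end index.
    """
    return ANALYSIS_LAMBDA_FACTOR * suggest_lambda(path)


# ---------------------------------------------------------------------------
# Restraints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowedHarmonic:
    """kappa * (cv - center)^2, smoothly gated on a progress window.

    The gate w(s) is a cosine-taper bump: 0 outside [s_lo, s_hi], 1 on
    [s_lo + taper, s_hi - taper], half-cosine ramps in between.  Windows are
    meant to cover intermediate s only, leaving the end states unrestrained
    so their relative stability is untouched.
    """

    cv: str
    center: float
    kappa: float       # kJ/mol per cv-unit^2
    s_lo: float
    s_hi: float
    taper: float = 0.25

    def __post_init__(self) -> None:
        if not (self.s_lo < self.s_hi):
            raise ValidationError("window requires s_lo < s_hi")
        if self.taper < 0 or 2 * self.taper > (self.s_hi - self.s_lo):
            raise ValidationError("taper must fit inside the window")

    def weight(self, s: float) -> float:
        if s <= self.s_lo or s >= self.s_hi:
            return 0.0
        if self.taper == 0.0:
            return 1.0
        w = 1.0
        u = (s - self.s_lo) / self.taper
        if u < 1.0:
            w *= 0.5 * (1.0 - math.cos(math.pi * u))
        v = (self.s_hi - s) / self.taper
        if v < 1.0:
            w *= 0.5 * (1.0 - math.cos(math.pi * v))
        return w


@dataclass(frozen=True)
class DeviationWall:
    """One-sided wall kappa * max(0, cv - upper)^2, typically loose and on z."""

    upper: float
    kappa: float
    cv: str = "z"


def restraint_energy(s: float, aux: Mapping[str, float],
                     spec: Sequence[WindowedHarmonic | DeviationWall]) -> float:
    """Total restraint energy (kJ/mol) at progress s with auxiliary CV values.

    ``aux`` maps CV names (microswitch distances, the deviation z, ...) to
    their current values.  Windowed terms vanish identically outside their
    s-window — in particular at the end states; wall terms are global.
    """
    total = 0.0
    for term in spec:
        if term.cv not in aux:
            raise ValidationError(f"restraint names unknown CV {term.cv!r}")
        x = float(aux[term.cv])
        if isinstance(term, WindowedHarmonic):
            w = term.weight(s)
            if w > 0.0:
                total += w * term.kappa * (x - term.center) ** 2
        elif isinstance(term, DeviationWall):
            over = x - term.upper
            if over > 0.0:
                total += term.kappa * over * over
        else:
            raise ValidationError(f"unknown restraint type {type(term).__name__}")
    return total


# ---------------------------------------------------------------------------
# Trajectory projection
# ---------------------------------------------------------------------------

def project_trajectory(traj, inactive: Structure, active: Structure,
                       path: PathDefinition):
    """Project every frame onto (rmsd_inactive, rmsd_active, s, z).

    Returns a pandas DataFrame with columns time, rmsd_inactive, rmsd_active,
    s, z — the package's CV-series carrier, directly writable as a COLVAR
    table.
    """
    import pandas as pd

    if path.flavor != "EPATH":
        raise ValidationError("projection onto the RMSD plane requires an EPATH path")
    align = path.align if path.align is not None else AtomSelection.all(traj.topology.n_atoms)
    measure = path.measure if path.measure is not None else align
    n = traj.n_frames
    times = traj.times if traj.times is not None else np.arange(n, dtype=float)
    ri = np.empty(n)
    ra = np.empty(n)
    s = np.empty(n)
    z = np.empty(n)
    for k in range(n):
        ri[k] = rmsd_superposed(traj.frames[k], inactive, align, measure)
        ra[k] = rmsd_superposed(traj.frames[k], active, align, measure)
        s[k], z[k] = epath_sz((ri[k], ra[k]), path)
    return pd.DataFrame({
        "time": times, "rmsd_inactive": ri, "rmsd_active": ra, "s": s, "z": z,
    })


# ---------------------------------------------------------------------------
# Plain-text path config serialization
# ---------------------------------------------------------------------------

def save_path_config(path: PathDefinition, filename: str,
                     milestones_pdb: str | None = None) -> None:
    """Write an EPATH definition (or an RPATH stub) as a key-value text file.

    RPATH milestone structures are not embedded; pass ``milestones_pdb`` to
    record where the multi-MODEL PDB holding them lives.
    """
    with open(filename, "w") as fh:
        fh.write(f"flavor = {path.flavor}\n")
        fh.write(f"n_milestones = {path.n_milestones}\n")
        fh.write(f"lambda = {path.lam!r}\n")
        if path.flavor == "RPATH":
            fh.write(f"squared = {int(path.squared)}\n")
            if milestones_pdb is not None:
                fh.write(f"milestones_pdb = {milestones_pdb}\n")
        else:
            for m in path.milestones:
                fh.write(f"milestone {m.index} {m.rmsd_inactive!r} {m.rmsd_active!r}\n")


def load_path_config(filename: str, align: AtomSelection | None = None,
                     measure: AtomSelection | None = None) -> PathDefinition:
    """Read a path config written by :func:`save_path_config` (EPATH only)."""
    kv: dict[str, str] = {}
    milestones: list[Milestone2D] = []
    with open(filename) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("milestone "):
                parts = line.split()
                if len(parts) != 4:
                    raise ValidationError(
                        f"{filename}:{lineno}: milestone line needs index and 2 values")
                milestones.append(Milestone2D(int(parts[1]),
                                              float(parts[2]), float(parts[3])))
            elif "=" in line:
                key, _, val = line.partition("=")
                kv[key.strip()] = val.strip()
            else:
                raise ValidationError(f"{filename}:{lineno}: unrecognized line {line!r}")
    flavor = kv.get("flavor", "EPATH")
    if flavor != "EPATH":
        raise ValidationError("only EPATH configs can be fully reloaded from text; "
                              "RPATH milestones live in their PDB file")
    if "lambda" not in kv:
        raise ValidationError(f"{filename}: missing lambda")
    milestones.sort(key=lambda m: m.index)
    return PathDefinition("EPATH", milestones, float(kv["lambda"]),
                          align=align, measure=measure)
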