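"""Synthetic systems: toy end states, transition trajectories, biased samples.

Every stage of the workflow is exercisable without external data:

* :func:`make_toy_endstates` builds a pair of same-topology C-alpha chains
  related by a hinge bend of the terminal segment — a caricature of the
  inactive/active conformations of a receptor whose activation moves one
  helix;
* :func:`make_transition_trajectory` interpolates between them, optionally
  bulging away from both references (mimicking the entropic intermediate
  basin where both end-state RMSDs are high) and with Gaussian coordinate
  noise enveloped to vanish at the end points (end basins are tight, the
  middle is diffuse);
* :func:`make_biased_samples` draws Metropolis Monte-Carlo samples from an
  analytically known double-well potential under a recorded bias, the
  stand-in for enhanced-sampling COLVAR output whose ground truth is
  available by quadrature.

All generators are deterministic per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .plumed_io import ColvarTable
from .reweighting import DEFAULT_KT
from .structures import AtomSelection, Structure, Trajectory, rmsd_superposed, superposition

__all__ = [
    "ToySystemSpec",
    "ModelPotentialSpec",
    "make_toy_endstates",
    "make_transition_trajectory",
    "make_biased_samples",
    "double_well_energy",
    "bias_energy",
]


# ---------------------------------------------------------------------------
# Toy end states
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToySystemSpec:
    """Parameters of the toy two-state system.

    ``geometry`` is "helix" (ideal alpha-helical C-alpha trace: 0.23 nm
    radius, 0.15 nm rise, 100 degrees per residue) or "straight" (0.38 nm
    C-alpha spacing).  ``bend_angle`` (degrees) rotates the terminal 40% of
    the chain about a hinge to produce the active state.  ``noise`` (nm) is
    a seeded Gaussian perturbation of the shared base chain — the same
    realization enters both end states, so bend_angle = 0 gives RMSD 0.
    """

    n_atoms: int = 30
    geometry: str = "helix"
    bend_angle: float = 60.0
    noise: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_atoms < 4:
            raise ValidationError("need at least 4 atoms")
        if self.geometry not in ("helix", "straight"):
            raise ValidationError(f"unknown geometry {self.geometry!r}")
        if self.noise < 0:
            raise ValidationError("noise must be >= 0")


def _base_chain(spec: ToySystemSpec) -> np.ndarray:
    i = np.arange(spec.n_atoms)
    if spec.geometry == "helix":
        theta = np.deg2rad(100.0) * i
        return np.column_stack([0.23 * np.cos(theta), 0.23 * np.sin(theta), 0.15 * i])
    return np.column_stack([0.38 * i, np.zeros_like(i, dtype=float),
                            np.zeros_like(i, dtype=float)])


def _rotation_about(axis: np.ndarray, origin: np.ndarray, angle_deg: float):
    from scipy.spatial.transform import Rotation
    rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis / np.linalg.norm(axis))
    return lambda x: rot.apply(x - origin) + origin


def make_toy_endstates(spec: ToySystemSpec = ToySystemSpec()
                       ) -> tuple[Structure, Structure]:
    """Deterministic (inactive, active) pair differing by a terminal hinge bend."""
    rng = np.random.default_rng(spec.seed)
    base = _base_chain(spec)
    base = base + spec.noise * rng.standard_normal(base.shape)
    hinge = int(round(0.6 * spec.n_atoms))
    names = np.array(["CA"] * spec.n_atoms, dtype=object)
    res_ids = np.arange(1, spec.n_atoms + 1)
    inactive = Structure(names, res_ids, base)

    active_coords = base.copy()
    if spec.bend_angle != 0.0:
        # bend about an axis perpendicular to the local chain direction
        local = base[min(hinge + 1, spec.n_atoms - 1)] - base[hinge - 1]
        axis = np.cross(local, [0.0, 0.0, 1.0])
        if np.linalg.norm(axis) < 1e-12:
            axis = np.array([1.0, 0.0, 0.0])
        bend = _rotation_about(axis, base[hinge], spec.bend_angle)
        active_coords[hinge:] = bend(base[hinge:])
    active = Structure(names, res_ids, active_coords)

    if spec.bend_angle != 0.0 and spec.noise > 0.0:
        sel = AtomSelection.all(spec.n_atoms)
        if rmsd_superposed(active, inactive, sel) <= 5.0 * spec.noise:
            raise ValidationError(
                "end states not separated: superposed RMSD <= 5x noise; "
                "increase bend_angle or lower noise")
    return inactive, active


# ---------------------------------------------------------------------------
# Transition trajectory
# ---------------------------------------------------------------------------

def make_transition_trajectory(inactive: Structure, active: Structure,
                               n_frames: int = 40, noise: float = 0.02,
                               detour: float = 0.0, seed: int = 0) -> Trajectory:
    """Interpolated transition with optional off-path bulge and enveloped noise.

    The active state is first superposed onto the inactive one; frame k at
    t = k/(n-1) is the linear interpolation plus
    ``detour * sin(pi t)`` times a fixed random unit-RMS displacement field
    (pushing mid-path frames away from BOTH references) plus Gaussian noise
    of scale ``noise * sin(pi t)`` — so the first/last frames are exactly
    the end states and the ensemble tightens into the end basins.
    """
    if inactive.n_atoms != active.n_atoms or \
            list(inactive.atom_names) != list(active.atom_names):
        raise ValidationError("end states must share a topology")
    if n_frames < 2:
        raise ValidationError("need at least 2 frames")
    if noise < 0 or detour < 0:
        raise ValidationError("noise and detour must be >= 0")
    rng = np.random.default_rng(seed)
    n = inactive.n_atoms
    sel = AtomSelection.all(n)
    rot, ca, cb = superposition(active.coordinates, inactive.coordinates, sel)
    b = rot.apply(active.coordinates - ca) + cb
    a = inactive.coordinates

    field = rng.standard_normal((n, 3))
    field /= np.sqrt(np.mean(np.sum(field ** 2, axis=1)))  # unit RMS

    frames = np.empty((n_frames, n, 3))
    for k in range(n_frames):
        t = k / (n_frames - 1)
        env = math.sin(math.pi * t)
        x = (1 - t) * a + t * b + detour * env * field
        if 0 < k < n_frames - 1 and noise > 0:
            x = x + noise * env * rng.standard_normal((n, 3))
        frames[k] = x
    frames[0] = a
    frames[-1] = b
    return Trajectory(inactive, frames, times=np.arange(n_frames, dtype=float))


# ---------------------------------------------------------------------------
# Biased Monte-Carlo samples on model potentials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelPotentialSpec:
    """A double-well potential with a proportional bias, sampled by Metropolis.

    U(x) = barrier * ((x/well_sep)^2 - 1)^2  (kcal/mol), minima at
    +-well_sep; the 2-D form adds a harmonic transverse coordinate
    0.5 * k_y * y^2 with k_y = 2 kcal/mol.  The bias is
    V(x) = -bias_scale * U(clamp(x, -bias_cap, bias_cap)): proportional to
    the potential inside the well region and constant beyond ``bias_cap``,
    the way a deposited sampling bias fills basins while the confining
    walls of the landscape survive (bias_scale = 1 flattens the wells and
    barrier but never unbinds the walker).  V is recorded in the output so
    weights exp(V/kT) recover U.
    """

    form: str = "double_well_1d"
    barrier: float = 5.0        # kcal/mol
    well_sep: float = 1.0       # well positions at +-well_sep
    bias_scale: float = 0.8
    bias_cap: float | None = None   # default 1.5 * well_sep
    kT: float = DEFAULT_KT      # kcal/mol
    n_samples: int = 200_000
    seed: int = 0
    step: float = 0.25          # Metropolis proposal width
    burn_in: int = 1000

    def __post_init__(self) -> None:
        if self.form not in ("double_well_1d", "double_well_2d"):
            raise ValidationError(f"unknown potential form {self.form!r}")
        if self.barrier <= 0:
            raise ValidationError("barrier must be positive")
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if self.kT <= 0 or self.step <= 0:
            raise ValidationError("kT and step must be positive")
        if self.bias_cap is None:
            object.__setattr__(self, "bias_cap", 1.5 * self.well_sep)
        if self.bias_cap <= 0:
            raise ValidationError("bias_cap must be positive")


K_TRANSVERSE = 2.0  # kcal/mol per unit^2, 2-D transverse stiffness


def double_well_energy(x, spec: ModelPotentialSpec, y=None):
    """U (kcal/mol) of the model potential; vectorized."""
    x = np.asarray(x, dtype=float)
    u = spec.barrier * ((x / spec.well_sep) ** 2 - 1.0) ** 2
    if spec.form == "double_well_2d":
        y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)
        u = u + 0.5 * K_TRANSVERSE * y ** 2
    return u


def bias_energy(x, spec: ModelPotentialSpec):
    """V (kcal/mol): -bias_scale * U along x, held constant beyond bias_cap."""
    xc = np.clip(np.asarray(x, dtype=float), -spec.bias_cap, spec.bias_cap)
    return -spec.bias_scale * spec.barrier * ((xc / spec.well_sep) ** 2 - 1.0) ** 2


def make_biased_samples(spec: ModelPotentialSpec = ModelPotentialSpec()
                        ) -> ColvarTable:
    """Metropolis samples from exp(-(U+V)/kT) with the bias column recorded.

    Columns: time, cv (and cv2 for the 2-D form), bias.  The acceptance
    rate is stored in ``table.df.attrs["acceptance_rate"]``.
    """
    rng = np.random.default_rng(spec.seed)
    ndim = 2 if spec.form == "double_well_2d" else 1
    x = np.zeros(ndim)
    x[0] = -spec.well_sep  # start in the left well

    def total_energy(pt):
        u = float(double_well_energy(pt[0], spec, pt[1] if ndim == 2 else None))
        return u + float(bias_energy(pt[0], spec))

    e = total_energy(x)
    accepted = 0
    n_total = spec.burn_in + spec.n_samples
    out = np.empty((spec.n_samples, ndim))
    bias = np.empty(spec.n_samples)
    for i in range(n_total):
        prop = x + spec.step * rng.standard_normal(ndim)
        e_prop = total_energy(prop)
        if e_prop <= e or rng.random() < math.exp(-(e_prop - e) / spec.kT):
            x, e = prop, e_prop
            accepted += 1
        if i >= spec.burn_in:
            k = i - spec.burn_in
            out[k] = x
            bias[k] = float(bias_energy(x[0], spec))
    rate = accepted / n_total
    if accepted == 0:
        raise ValidationError(
            "Metropolis chain accepted no moves; reduce the proposal step")
    cols = {"time": np.arange(spec.n_samples, dtype=float), "cv": out[:, 0]}
    if ndim == 2:
        cols["cv2"] = out[:, 1]
    cols["bias"] = bias
    df = pd.DataFrame(cols)
    df.attrs["acceptance_rate"] = rate
    df.attrs["spec"] = spec
    return ColvarTable(df)
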