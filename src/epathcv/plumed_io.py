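"""Bridge to the enhanced-sampling engine (PLUMED text dialect).

Three concerns live here:

* parsing COLVAR tables ("#! FIELDS ..." whitespace tables, with restart
  headers and duplicated-time overlaps handled the way PLUMED users expect);
* writing PLUMED-style reference PDBs, where the occupancy column carries
  alignment weights and the B-factor column carries measure (displacement)
  weights;
* emitting a deterministic PLUMED input file that computes the Euclidean
  PATH CV as an explicit arithmetic expression over the two end-state RMSD
  variables, plus restraint blocks.

No installed library reads or writes these dialects, so the parsers/writers
here are purpose-built.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .path_cv import DeviationWall, PathDefinition, WindowedHarmonic
from .structures import ANGSTROM_PER_NM, AtomSelection, Structure, format_atom_record

__all__ = [
    "ColvarTable",
    "read_colvar",
    "write_colvar",
    "write_reference_pdb",
    "write_epath_plumed",
]

#: engine dialect the emitted input targets (header comment only)
PLUMED_DIALECT = "2.9"

#: default name of the bias-energy column in COLVAR output
DEFAULT_BIAS_COLUMN = "opes.bias"

MILESTONE_SIG_DIGITS = 6


# ---------------------------------------------------------------------------
# COLVAR tables
# ---------------------------------------------------------------------------

@dataclass
class ColvarTable:
    """A time-indexed table of named CV / bias-energy columns."""

    df: pd.DataFrame
    time_column: str = "time"

    def __post_init__(self) -> None:
        if self.time_column not in self.df.columns:
            raise ValidationError(
                f"time column {self.time_column!r} not among {list(self.df.columns)}")

    @property
    def column_names(self) -> list[str]:
        return list(self.df.columns)

    @property
    def times(self) -> np.ndarray:
        return self.df[self.time_column].to_numpy()

    def column(self, name: str) -> np.ndarray:
        if name not in self.df.columns:
            raise ValidationError(f"no column {name!r} in COLVAR table")
        return self.df[name].to_numpy()


def read_colvar(path: str, time_column: str = "time") -> ColvarTable:
    """Parse a PLUMED COLVAR file.

    The first line must be a "#! FIELDS ..." header.  Interior FIELDS
    headers (restart convention) are accepted if identical to the first;
    "#! SET" and other comment lines are skipped.  Duplicate time stamps
    from restart overlaps are resolved by keeping the last occurrence.
    """
    if not os.path.exists(path):
        raise ParseError(f"no such file: {path}")
    fields: list[str] | None = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#!"):
                tokens = line.split()
                if len(tokens) >= 2 and tokens[1] == "FIELDS":
                    names = tokens[2:]
                    if fields is None:
                        fields = names
                    elif names != fields:
                        raise ParseError(
                            f"{path}:{lineno}: restart FIELDS header differs "
                            f"from the first header")
                # "#! SET ..." and other metadata: skipped
                continue
            if line.startswith("#"):
                continue
            if fields is None:
                raise ParseError(f"{path}:{lineno}: data before '#! FIELDS' header")
            values = line.split()
            if len(values) != len(fields):
                raise ParseError(
                    f"{path}:{lineno}: row has {len(values)} values, "
                    f"expected {len(fields)}")
            try:
                rows.append([float(v) for v in values])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric value: {exc}") from exc
    if fields is None:
        raise ParseError(f"{path}: missing '#! FIELDS' header")
    df = pd.DataFrame(rows, columns=fields)
    if time_column in df.columns:
        # restart overlap: last occurrence of each time wins, order preserved
        df = df.drop_duplicates(subset=time_column, keep="last").reset_index(drop=True)
    return ColvarTable(df, time_column=time_column)


def write_colvar(table: ColvarTable | pd.DataFrame, path: str,
                 sig_digits: int = 12) -> None:
    """Write a COLVAR text table (lossless round trip at sig_digits)."""
    df = table.df if isinstance(table, ColvarTable) else table
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(df.columns) + "\n")
        fmt = f"%.{sig_digits}g"
        for row in df.itertuples(index=False):
            fh.write(" ".join(fmt % v for v in row) + "\n")


# ---------------------------------------------------------------------------
# Reference PDB with weight columns
# ---------------------------------------------------------------------------

def write_reference_pdb(structure: Structure, align: AtomSelection,
                        measure: AtomSelection, path: str) -> None:
    """Write a PLUMED reference PDB (angstrom).

    Occupancy carries the alignment weight (1 for align members, else 0);
    the B-factor column carries the measure/displacement weight.
    """
    align.validate_against(structure.n_atoms)
    measure.validate_against(structure.n_atoms)
    occ = np.zeros(structure.n_atoms)
    occ[align.indices] = 1.0
    bf = np.zeros(structure.n_atoms)
    bf[measure.indices] = 1.0
    ang = structure.coordinates * ANGSTROM_PER_NM
    with open(path, "w") as fh:
        for i in range(structure.n_atoms):
            fh.write(format_atom_record(
                i + 1, str(structure.atom_names[i]), int(structure.residue_ids[i]),
                ang[i], occ[i], bf[i]) + "\n")
        fh.write("END\n")


def read_reference_weights(path: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read back (coordinates nm, align weights, measure weights) from a reference PDB."""
    coords, occ, bf = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            try:
                coords.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
                occ.append(float(line[54:60]))
                bf.append(float(line[60:66]))
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed ATOM record") from exc
    if not coords:
        raise ParseError(f"{path}: no ATOM records")
    return np.asarray(coords) / ANGSTROM_PER_NM, np.asarray(occ), np.asarray(bf)


# ---------------------------------------------------------------------------
# PLUMED input emission
# ---------------------------------------------------------------------------

def _g(value: float, sig: int = MILESTONE_SIG_DIGITS) -> str:
    return f"{value:.{sig}g}"


def _bump_expr(var: str, lo: float, hi: float, taper: float) -> str:
    """Cosine-taper bump w(var) on [lo, hi] using step() for the clamps."""
    if taper == 0.0:
        return f"step({var}-{_g(lo)})*step({_g(hi)}-{var})"

    def ramp(u: str) -> str:
        # clamp(u, 0, 1) = u*step(u)*step(1-u) + step(u-1); half-cosine of it
        clamped = f"({u})*step({u})*step(1-({u}))+step(({u})-1)"
        return f"0.5*(1-cos(pi*({clamped})))"

    u_lo = f"({var}-{_g(lo)})/{_g(taper)}"
    u_hi = f"({_g(hi)}-{var})/{_g(taper)}"
    return f"({ramp(u_lo)})*({ramp(u_hi)})"


def write_epath_plumed(path: PathDefinition, inactive: Structure, active: Structure,
                       directory: str, restraints=(),
                       colvar_file: str = "COLVAR", stride: int = 500,
                       bias_column: str = DEFAULT_BIAS_COLUMN) -> str:
    """Emit a PLUMED input implementing the EPATH CV; returns the input text.

    Writes into ``directory``: the two reference PDBs (occupancy = align
    weights, B-factor = measure weights) and ``plumed.dat`` defining the
    RMSD variables, the explicit s/z expressions over the N milestone tuples
    (constants embedded at 6 significant digits), and restraint blocks.
    Output is byte-identical across runs for identical inputs.
    """
    if path.flavor != "EPATH":
        raise ValidationError("engine emission implements the EPATH flavor only")
    align = path.align if path.align is not None else AtomSelection.all(inactive.n_atoms)
    measure = path.measure if path.measure is not None else align
    os.makedirs(directory, exist_ok=True)
    ref_inactive = "epath_ref_inactive.pdb"
    ref_active = "epath_ref_active.pdb"
    write_reference_pdb(inactive, align, measure, os.path.join(directory, ref_inactive))
    write_reference_pdb(active, align, measure, os.path.join(directory, ref_active))

    lam = _g(path.lam, 10)
    pts = path.milestone_points()
    n = path.n_milestones

    def d2(i: int) -> str:
        return (f"(x-{_g(pts[i, 0])})^2+(y-{_g(pts[i, 1])})^2")

    num = "+".join(f"{i + 1}*exp(-{lam}*({d2(i)}))" for i in range(n))
    den = "+".join(f"exp(-{lam}*({d2(i)}))" for i in range(n))

    lines = [
        f"# epathcv: Euclidean PATH CV input (PLUMED dialect {PLUMED_DIALECT})",
        f"# N={n} LAMBDA={lam} (1/nm^2); milestones at {MILESTONE_SIG_DIGITS} significant digits",
        "UNITS LENGTH=nm",
        "",
        f"rmsd_inactive: RMSD REFERENCE={ref_inactive} TYPE=OPTIMAL",
        f"rmsd_active: RMSD REFERENCE={ref_active} TYPE=OPTIMAL",
        "",
        ("epath_num: CUSTOM ARG=rmsd_inactive,rmsd_active VAR=x,y "
         f"FUNC={num} PERIODIC=NO"),
        ("epath_den: CUSTOM ARG=rmsd_inactive,rmsd_active VAR=x,y "
         f"FUNC={den} PERIODIC=NO"),
        "s: CUSTOM ARG=epath_num,epath_den VAR=x,y FUNC=x/y PERIODIC=NO",
        f"z: CUSTOM ARG=epath_den VAR=x FUNC=-(1/{lam})*log(x) PERIODIC=NO",
    ]

    wall_args = []
    harm_idx = 0
    for term in restraints:
        if isinstance(term, DeviationWall):
            wall_args.append(term)
        elif isinstance(term, WindowedHarmonic):
            harm_idx += 1
            bump = _bump_expr("x", term.s_lo, term.s_hi, term.taper)
            lines += [
                "",
                (f"rst_{term.cv}_{harm_idx}: CUSTOM ARG=s,{term.cv} VAR=x,y "
                 f"FUNC=({bump})*{_g(term.kappa)}*(y-{_g(term.center)})^2 PERIODIC=NO"),
                f"rst_{term.cv}_{harm_idx}_bias: BIASVALUE ARG=rst_{term.cv}_{harm_idx}",
            ]
        else:
            raise ValidationError(f"unknown restraint type {type(term).__name__}")
    for term in wall_args:
        lines += [
            "",
            (f"wall_{term.cv}: UPPER_WALLS ARG={term.cv} AT={_g(term.upper)} "
             f"KAPPA={_g(term.kappa)} EXP=2 EPS=1 OFFSET=0"),
        ]

    lines += [
        "",
        f"# append your sampling bias here; its energy appears as {bias_column}",
        f"PRINT ARG=rmsd_inactive,rmsd_active,s,z FILE={colvar_file} STRIDE={stride}",
        "",
    ]
    text = "\n".join(lines)
    with open(os.path.join(directory, "plumed.dat"), "w") as fh:
        fh.write(text)
    return text
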