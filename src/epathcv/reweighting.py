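"""Bias reweighting: free-energy surfaces and convergence traces.

Biased samples carry recorded bias energies V(t).  Unbiased equilibrium
statistics are recovered with per-frame weights w = exp(sum_b V_b / kT)
(static final-bias reweighting).  Free energies are -kT ln of the weighted
histogram, min-shifted so the global minimum is 0; empty bins are flagged
as unobserved rather than assigned an energy.

Energies are in kcal/mol; the default kT corresponds to 310 K.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .plumed_io import ColvarTable

__all__ = [
    "KCAL_PER_MOL_K",
    "DEFAULT_KT",
    "FES1D",
    "FES2D",
    "DeltaGTrace",
    "reweight_fes",
    "deltag_trace",
    "replica_average",
    "block_bootstrap_deltag",
]

#: Boltzmann constant in kcal/mol/K
KCAL_PER_MOL_K = 0.0019872041
#: kT at 310 K, kcal/mol
DEFAULT_KT = KCAL_PER_MOL_K * 310.0


@dataclass
class FES1D:
    """1-D free-energy estimate on a binned CV axis (kcal/mol, min-shifted)."""

    bin_edges: np.ndarray
    free_energy: np.ndarray          # NaN where unobserved
    counts: np.ndarray               # contributing samples per bin
    kT: float
    n_rejected: int = 0

    @property
    def observed(self) -> np.ndarray:
        return self.counts > 0

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("# epathcv FES1D; columns: bin_center free_energy(kcal/mol) count\n")
            fh.write(f"# kT = {self.kT!r} kcal/mol; unobserved bins printed as nan\n")
            for c, f, n in zip(self.bin_centers, self.free_energy, self.counts):
                fh.write(f"{c!r} {f!r} {int(n)}\n")


@dataclass
class FES2D:
    """2-D free-energy estimate on a rectangular CV grid (kcal/mol, min-shifted)."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: np.ndarray          # shape (nx, ny); NaN where unobserved
    counts: np.ndarray
    kT: float
    n_rejected: int = 0

    @property
    def observed(self) -> np.ndarray:
        return self.counts > 0

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("# epathcv FES2D; free energy (kcal/mol) matrix, rows = x bins\n")
            fh.write(f"# kT = {self.kT!r} kcal/mol\n")
            fh.write("# x_edges: " + " ".join(repr(v) for v in self.x_edges) + "\n")
            fh.write("# y_edges: " + " ".join(repr(v) for v in self.y_edges) + "\n")
            for row in self.free_energy:
                fh.write(" ".join(repr(v) for v in row) + "\n")


@dataclass
class DeltaGTrace:
    """Free-energy difference (active minus inactive, kcal/mol) over time."""

    times: np.ndarray
    delta_g: np.ndarray
    kT: float
    std: np.ndarray | None = None          # populated by replica_average
    replicas: list[np.ndarray] | None = None

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("# epathcv deltaG trace; columns: time(ps) deltaG(kcal/mol)"
                     + (" std" if self.std is not None else "") + "\n")
            for i, (t, g) in enumerate(zip(self.times, self.delta_g)):
                extra = f" {self.std[i]!r}" if self.std is not None else ""
                fh.write(f"{t!r} {g!r}{extra}\n")


# ---------------------------------------------------------------------------
# Weights
# ---------------------------------------------------------------------------

def _weights(df: pd.DataFrame, bias_columns: Sequence[str], kT: float
             ) -> tuple[np.ndarray, np.ndarray]:
    """Per-row reweighting factors exp(sum V/kT) and a finite-row mask.

    The bias sum is max-shifted before exponentiation; free energies are
    invariant under any constant shift of the bias, so this is exact.
    """
    if kT <= 0:
        raise ValidationError("kT must be positive")
    if not bias_columns:
        total = np.zeros(len(df))
    else:
        for b in bias_columns:
            if b not in df.columns:
                raise ValidationError(f"no bias column {b!r}")
        total = df[list(bias_columns)].to_numpy().sum(axis=1)
    finite = np.isfinite(total)
    shifted = np.where(finite, total, -np.inf)
    if finite.any():
        shifted = shifted - shifted[finite].max()
    w = np.where(finite, np.exp(shifted / kT), 0.0)
    return w, finite


def _as_df(table: ColvarTable | pd.DataFrame) -> pd.DataFrame:
    return table.df if isinstance(table, ColvarTable) else table


# ---------------------------------------------------------------------------
# Free-energy surfaces
# ---------------------------------------------------------------------------

def reweight_fes(table: ColvarTable | pd.DataFrame, cv_columns: Sequence[str],
                 bias_columns: Sequence[str] = (), kT: float = DEFAULT_KT,
                 grid=None) -> FES1D | FES2D:
    """Reweighted free-energy surface over one or two CV columns.

    ``grid`` is a bin-edge array (1 CV) or a pair of edge arrays (2 CVs);
    if omitted, 60 bins spanning the observed range are used per axis.
    With zero bias everywhere the result is exactly -kT ln of the plain
    normalized histogram, min-shifted.
    """
    df = _as_df(table)
    cv_columns = list(cv_columns)
    if len(cv_columns) not in (1, 2):
        raise ValidationError("cv_columns must name one or two columns")
    for c in cv_columns:
        if c not in df.columns:
            raise ValidationError(f"no CV column {c!r}")
    w, finite = _weights(df, bias_columns, kT)
    cv_finite = np.isfinite(df[cv_columns].to_numpy()).all(axis=1)
    keep = finite & cv_finite
    n_rejected = int((~keep).sum())
    x = df[cv_columns[0]].to_numpy()[keep]
    wk = w[keep]

    if len(cv_columns) == 1:
        edges = np.linspace(x.min(), x.max(), 61) if grid is None else np.asarray(grid, float)
        hist, edges = np.histogram(x, bins=edges, weights=wk)
        counts, _ = np.histogram(x, bins=edges)
        if hist.sum() == 0:
            raise ValidationError("no samples fall inside the grid")
        p = hist / hist.sum()
        with np.errstate(divide="ignore"):
            f = -kT * np.log(p)
        f[counts == 0] = np.nan
        f = f - np.nanmin(f)
        return FES1D(edges, f, counts, kT, n_rejected)

    y = df[cv_columns[1]].to_numpy()[keep]
    if grid is None:
        gx = np.linspace(x.min(), x.max(), 61)
        gy = np.linspace(y.min(), y.max(), 61)
    else:
        gx, gy = (np.asarray(g, float) for g in grid)
    hist, gx, gy = np.histogram2d(x, y, bins=(gx, gy), weights=wk)
    counts, _, _ = np.histogram2d(x, y, bins=(gx, gy))
    if hist.sum() == 0:
        raise ValidationError("no samples fall inside the grid")
    p = hist / hist.sum()
    with np.errstate(divide="ignore"):
        f = -kT * np.log(p)
    f[counts == 0] = np.nan
    f = f - np.nanmin(f)
    return FES2D(gx, gy, f, counts, kT, n_rejected)


# ---------------------------------------------------------------------------
# Basin free-energy differences over time
# ---------------------------------------------------------------------------

def _window_mask(x: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    if not lo < hi:
        raise ValidationError(f"window ({lo}, {hi}) must have lo < hi")
    return (x >= lo) & (x <= hi)


def deltag_trace(table: ColvarTable | pd.DataFrame, s_column: str,
                 bias_columns: Sequence[str] = (), kT: float = DEFAULT_KT,
                 inactive_window: tuple[float, float] = (1.0, 1.5),
                 active_window: tuple[float, float] | None = None,
                 stride: float | None = None,
                 time_column: str = "time") -> DeltaGTrace:
    """Cumulative-population free-energy difference over simulation time.

    At each stride time t, dG(t) = -kT ln( W_active(<=t) / W_inactive(<=t) )
    with W the cumulative reweighted population of each s-window.  The trace
    starts at the first time where both basins have at least one sample.
    """
    df = _as_df(table)
    if s_column not in df.columns:
        raise ValidationError(f"no CV column {s_column!r}")
    if active_window is None:
        raise ValidationError("active_window must be given")
    ia, ib = inactive_window
    aa, ab = active_window
    if not (ib <= aa or ab <= ia):
        raise ValidationError("inactive and active windows must be disjoint")
    times = df[time_column].to_numpy() if time_column in df.columns \
        else np.arange(len(df), dtype=float)
    order = np.argsort(times, kind="stable")
    times = times[order]
    s = df[s_column].to_numpy()[order]
    w, finite = _weights(df.iloc[order], bias_columns, kT)
    w = np.where(finite, w, 0.0)

    in_mask = _window_mask(s, inactive_window)
    ac_mask = _window_mask(s, active_window)
    cum_in = np.cumsum(w * in_mask)
    cum_ac = np.cumsum(w * ac_mask)
    if cum_in[-1] == 0 or cum_ac[-1] == 0:
        empty = []
        if cum_in[-1] == 0:
            empty.append(f"inactive {inactive_window}")
        if cum_ac[-1] == 0:
            empty.append(f"active {active_window}")
        raise ValidationError("basin(s) with no samples: " + "; ".join(empty))

    if stride is None:
        eval_times = times
        idx = np.arange(len(times))
    else:
        if stride <= 0:
            raise ValidationError("stride must be positive")
        eval_times = np.arange(times[0] + stride, times[-1] + 0.5 * stride, stride)
        idx = np.searchsorted(times, eval_times, side="right") - 1
    valid = (cum_in[idx] > 0) & (cum_ac[idx] > 0)
    idx, eval_times = idx[valid], eval_times[valid]
    dg = -kT * np.log(cum_ac[idx] / cum_in[idx])
    return DeltaGTrace(eval_times, dg, kT)


def replica_average(traces: Sequence[DeltaGTrace]) -> DeltaGTrace:
    """Pointwise mean and sample standard deviation (n-1) across replicas."""
    if len(traces) < 2:
        raise ValidationError("replica averaging needs at least 2 traces")
    t0 = traces[0].times
    for tr in traces[1:]:
        if len(tr.times) != len(t0) or not np.allclose(tr.times, t0):
            raise ValidationError("replica traces must share an identical time grid")
        if tr.kT != traces[0].kT:
            raise ValidationError("replica traces must share kT")
    stack = np.vstack([tr.delta_g for tr in traces])
    return DeltaGTrace(t0.copy(), stack.mean(axis=0), traces[0].kT,
                       std=stack.std(axis=0, ddof=1),
                       replicas=[tr.delta_g.copy() for tr in traces])


def block_bootstrap_deltag(table: ColvarTable | pd.DataFrame, s_column: str,
                           bias_columns: Sequence[str] = (), kT: float = DEFAULT_KT,
                           inactive_window: tuple[float, float] = (1.0, 1.5),
                           active_window: tuple[float, float] | None = None,
                           n_blocks: int = 20, n_boot: int = 200,
                           seed: int | None = None) -> tuple[float, float]:
    """Final dG with a block-bootstrap standard error.

    Rows are split into ``n_blocks`` contiguous blocks (preserving serial
    correlation within a block); blocks are resampled with replacement and
    dG recomputed ``n_boot`` times.  Returns (delta_g, standard_error).
    """
    df = _as_df(table)
    if active_window is None:
        raise ValidationError("active_window must be given")
    s = df[s_column].to_numpy()
    w, finite = _weights(df, bias_columns, kT)
    w = np.where(finite, w, 0.0)
    w_in = w * _window_mask(s, inactive_window)
    w_ac = w * _window_mask(s, active_window)
    if w_in.sum() == 0 or w_ac.sum() == 0:
        raise ValidationError("a basin has no samples; cannot bootstrap")
    dg = -kT * np.log(w_ac.sum() / w_in.sum())

    blocks = np.array_split(np.arange(len(df)), n_blocks)
    bw_in = np.array([w_in[b].sum() for b in blocks])
    bw_ac = np.array([w_ac[b].sum() for b in blocks])
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for k in range(n_boot):
        pick = rng.integers(0, n_blocks, size=n_blocks)
        wi, wa = bw_in[pick].sum(), bw_ac[pick].sum()
        boot[k] = np.nan if (wi == 0 or wa == 0) else -kT * np.log(wa / wi)
    se = float(np.nanstd(boot, ddof=1))
    return float(dg), se
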