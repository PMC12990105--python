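"""Conformational clustering (gromos algorithm) and Shannon-entropy profiling.

The gromos scheme is the greedy neighbor-count clustering of gmx cluster:
compute all pairwise superposed RMSDs on a selection, then repeatedly take
the unassigned frame with the most unassigned neighbors within the cutoff
as the next cluster center, assigning it together with those neighbors.
Ties go to the lowest frame index; clusters are reported by decreasing
population (equal sizes ordered by center frame index).

The Shannon entropy S/k_B = -sum_i p_i ln p_i of the fractional cluster
populations quantifies conformational heterogeneity; profiled along
progress-coordinate intervals it shows where a transition path traverses a
structurally diverse ensemble (high S) versus a tight basin (S near 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .structures import AtomSelection, Trajectory, rmsd_superposed

__all__ = [
    "DEFAULT_CUTOFF_NM",
    "ClusterAssignment",
    "EntropyProfile",
    "pairwise_rmsd_matrix",
    "gromos_cluster",
    "shannon_entropy",
    "entropy_profile",
]

#: clustering cutoff (nm); 0.14 nm = 1.4 angstrom on secondary-structure CAs
DEFAULT_CUTOFF_NM = 0.14


@dataclass
class ClusterAssignment:
    """Per-frame cluster labels (0-based, by decreasing population)."""

    labels: np.ndarray
    centers: np.ndarray       # representative frame index per cluster
    populations: np.ndarray   # fractional, sums to 1
    cutoff: float             # nm; recorded for provenance

    @property
    def n_clusters(self) -> int:
        return len(self.centers)

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"# epathcv gromos clusters; cutoff = {self.cutoff!r} nm\n")
            fh.write("# columns: frame cluster\n")
            for i, lab in enumerate(self.labels):
                fh.write(f"{i} {int(lab)}\n")


@dataclass
class EntropyProfile:
    """Shannon entropy of cluster populations per progress-coordinate interval."""

    interval_edges: np.ndarray
    entropy: np.ndarray            # S/k_B; NaN for empty intervals
    clusters_per_interval: np.ndarray
    frames_per_interval: np.ndarray
    cutoff: float

    @property
    def empty(self) -> np.ndarray:
        return self.frames_per_interval == 0

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"# epathcv entropy profile; cutoff = {self.cutoff!r} nm\n")
            fh.write("# columns: s_lo s_hi entropy(S/kB) n_clusters n_frames\n")
            for i in range(len(self.entropy)):
                fh.write(f"{self.interval_edges[i]!r} {self.interval_edges[i + 1]!r} "
                         f"{self.entropy[i]!r} {int(self.clusters_per_interval[i])} "
                         f"{int(self.frames_per_interval[i])}\n")


# ---------------------------------------------------------------------------
# gromos clustering
# ---------------------------------------------------------------------------

def pairwise_rmsd_matrix(traj: Trajectory, selection: AtomSelection) -> np.ndarray:
    """Symmetric matrix of superposed RMSDs over the selection (align == measure)."""
    selection.validate_against(traj.topology.n_atoms)
    n = traj.n_frames
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = rmsd_superposed(traj.frames[i], traj.frames[j], selection)
            mat[i, j] = mat[j, i] = r
    return mat


def gromos_cluster(traj: Trajectory, selection: AtomSelection,
                   cutoff: float = DEFAULT_CUTOFF_NM,
                   rmsd_matrix: np.ndarray | None = None) -> ClusterAssignment:
    """Greedy RMSD-cutoff clustering of trajectory frames (gromos rule).

    Neighborhood is inclusive (RMSD <= cutoff).  A precomputed RMSD matrix
    may be passed to avoid recomputation.
    """
    if cutoff <= 0:
        raise ValidationError("cutoff must be positive")
    if traj.n_frames < 1:
        raise ValidationError("cannot cluster an empty trajectory")
    mat = pairwise_rmsd_matrix(traj, selection) if rmsd_matrix is None \
        else np.asarray(rmsd_matrix, float)
    n = mat.shape[0]
    adj = mat <= cutoff
    np.fill_diagonal(adj, False)

    unassigned = np.ones(n, dtype=bool)
    labels = np.full(n, -1, dtype=int)
    raw: list[tuple[int, np.ndarray]] = []  # (center, member indices)
    while unassigned.any():
        # unassigned neighbors among unassigned candidates; argmax -> lowest index tie-break
        counts = (adj & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        center = int(np.argmax(counts))
        members = np.flatnonzero((adj[center] & unassigned) | (np.arange(n) == center))
        unassigned[members] = False
        raw.append((center, members))

    sizes = np.array([len(m) for _, m in raw])
    order = sorted(range(len(raw)), key=lambda k: (-sizes[k], raw[k][0]))
    centers = np.array([raw[k][0] for k in order])
    for new_id, k in enumerate(order):
        labels[raw[k][1]] = new_id
    populations = np.array([len(raw[k][1]) for k in order], dtype=float) / n
    return ClusterAssignment(labels, centers, populations, cutoff)


# ---------------------------------------------------------------------------
# Shannon entropy
# ---------------------------------------------------------------------------

def shannon_entropy(populations) -> float:
    """-sum p_i ln p_i in units of k_B, with 0 ln 0 := 0.

    Populations must be non-negative; if they do not sum to 1 within 1e-9
    they are renormalized with a warning.
    """
    p = np.asarray(populations, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("populations must be a non-empty 1-D array")
    if np.any(p < 0):
        raise ValidationError("populations must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValidationError("populations sum to zero")
    if abs(total - 1.0) > 1e-9:
        warnings.warn(f"populations sum to {total!r}; renormalizing", stacklevel=2)
    p = p / total
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum())


def entropy_profile(traj: Trajectory, selection: AtomSelection,
                    s_values, interval_edges,
                    cutoff: float = DEFAULT_CUTOFF_NM) -> EntropyProfile:
    """Per-interval cluster entropy along a progress coordinate.

    Frames are grouped by which [edge_i, edge_{i+1}) interval their s value
    falls in (the last interval is closed on the right); each group is
    clustered independently and its population entropy computed.  Empty
    intervals are flagged with NaN entropy.
    """
    s = np.asarray(s_values, dtype=float)
    edges = np.asarray(interval_edges, dtype=float)
    if len(s) != traj.n_frames:
        raise ValidationError("s_values length must equal the frame count")
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValidationError("interval_edges must be strictly increasing, length >= 2")
    k = len(edges) - 1
    which = np.digitize(s, edges) - 1
    which[s == edges[-1]] = k - 1  # close the last interval on the right

    entropy = np.full(k, np.nan)
    n_clusters = np.zeros(k, dtype=int)
    n_frames = np.zeros(k, dtype=int)
    any_inside = False
    for i in range(k):
        members = np.flatnonzero(which == i)
        n_frames[i] = len(members)
        if len(members) == 0:
            continue
        any_inside = True
        sub = Trajectory(traj.topology, traj.frames[members])
        assign = gromos_cluster(sub, selection, cutoff)
        n_clusters[i] = assign.n_clusters
        entropy[i] = shannon_entropy(assign.populations)
    if not any_inside:
        raise ValidationError("no frames fall inside the interval edges")
    return EntropyProfile(edges, entropy, n_clusters, n_frames, cutoff)
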