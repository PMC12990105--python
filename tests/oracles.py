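"""Independent reference computations used to check the implementation.

Everything here is deliberately naive and shares no code path with the
package: dense random-rotation searches instead of the closed-form fit,
direct unshifted summation instead of log-sum-exp, loop-based greedy
clustering, and numeric quadrature for free-energy truths.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def rotation_search_rmsd(mobile: np.ndarray, reference: np.ndarray,
                         n_rotations: int, rng: np.random.Generator,
                         polish: bool = False) -> float:
    """Min RMSD over random proper rotations (align set == measure set).

    For any rotation the optimal translation matches the centroids, so both
    sets are centered and only rotations are searched.  With ``polish`` the
    best sampled rotation seeds a local minimization over rotation vectors.
    """
    a = mobile - mobile.mean(axis=0)
    b = reference - reference.mean(axis=0)
    rots = Rotation.random(n_rotations, rng=rng)
    moved = np.einsum("rij,nj->rni", rots.as_matrix(), a)
    rmsds = np.sqrt(np.mean(np.sum((moved - b[None]) ** 2, axis=2), axis=1))
    best = int(np.argmin(rmsds))
    if not polish:
        return float(rmsds[best])

    def f(rotvec):
        r = Rotation.from_rotvec(rotvec)
        return np.sqrt(np.mean(np.sum((r.apply(a) - b) ** 2, axis=1)))

    res = minimize(f, rots[best].as_rotvec(), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000})
    return float(min(res.fun, rmsds[best]))


def naive_sz(metric: np.ndarray, lam: float) -> tuple[float, float]:
    """Direct unshifted summation of the progress/deviation definitions."""
    w = np.array([np.exp(-lam * m) for m in metric], dtype=float)
    s = sum((i + 1) * w[i] for i in range(len(w))) / sum(w)
    z = -np.log(sum(w)) / lam
    return float(s), float(z)


def naive_epath_sz(point, milestones: np.ndarray, lam: float) -> tuple[float, float]:
    d2 = [(point[0] - m[0]) ** 2 + (point[1] - m[1]) ** 2 for m in milestones]
    return naive_sz(np.array(d2), lam)


def naive_gromos(rmsd_matrix: np.ndarray, cutoff: float) -> list[list[int]]:
    """Greedy neighbor-count clustering, plain loops; returns clusters by
    decreasing size (ties by center frame index), each as a sorted member list."""
    n = rmsd_matrix.shape[0]
    unassigned = set(range(n))
    clusters: list[tuple[int, list[int]]] = []
    while unassigned:
        best_center, best_count = None, -1
        for i in sorted(unassigned):
            count = sum(1 for j in unassigned
                        if j != i and rmsd_matrix[i, j] <= cutoff)
            if count > best_count:
                best_center, best_count = i, count
        members = sorted(j for j in unassigned
                         if j == best_center or rmsd_matrix[best_center, j] <= cutoff)
        clusters.append((best_center, members))
        unassigned -= set(members)
    clusters.sort(key=lambda c: (-len(c[1]), c[0]))
    return [m for _, m in clusters]


def bezier_arc_lengths(p0, c, p2, t_nodes, n_dense: int = 200001) -> np.ndarray:
    """Consecutive arc lengths between t_nodes by very dense polyline summation."""
    t = np.linspace(0.0, 1.0, n_dense)
    tt = t[:, None]
    pts = (1 - tt) ** 2 * p0 + 2 * tt * (1 - tt) * c + tt ** 2 * p2
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    node_arc = np.interp(t_nodes, t, arc)
    return np.diff(node_arc)


def quadrature_deltag(u_func, kT: float, window_a: tuple[float, float],
                      window_b: tuple[float, float]) -> float:
    """-kT ln( Z_b / Z_a ) with Z_w the Boltzmann integral over window w."""
    za = quad(lambda x: np.exp(-u_func(x) / kT), *window_a, limit=200)[0]
    zb = quad(lambda x: np.exp(-u_func(x) / kT), *window_b, limit=200)[0]
    return float(-kT * np.log(zb / za))
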