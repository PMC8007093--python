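"""Periodic-aware k-medoids clustering of collective-variable tables.

All CVs handled here are angles (degrees, period 360), so the metric wraps
each periodic coordinate difference onto [0, 180] before taking a weighted
Euclidean norm.  The clustering is plain k-medoids:

* deterministic greedy BUILD seeding (the first medoid minimises total
  distance to all points; each subsequent medoid maximises the cost decrease),
* alternating refinement (reassign to the nearest medoid, then recompute each
  cluster's medoid), which never increases the cost,
* a PAM-style SWAP phase (best-improvement medoid/non-medoid exchanges,
  evaluated in O(n) per candidate from nearest/second-nearest distances)
  that escapes the local optima alternating refinement cannot leave.

Ties (equal distances or equal gains) are broken towards the lowest frame
index.  Given the same data, k and seed the result is bit-reproducible.
Distance computations are chunked so the full n x n matrix is never held in
memory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import math
import numpy as np
import pandas as pd

from .geometry import CVTable, Frame, Trajectory, wrap_angle
from .interactions import extract_shell

__all__ = [
    "ClusterModel",
    "circular_distance",
    "kmedoids",
    "cluster_table",
    "medoid_frames",
    "circular_mean",
]

_CHUNK = 512  # rows per distance-matrix chunk


def _wrapped_diffs(u: np.ndarray, v: np.ndarray, periodic: np.ndarray) -> np.ndarray:
    """Coordinate differences with periodic columns wrapped onto [-180, 180]."""
    d = u - v
    if periodic.any():
        dp = d[..., periodic]
        d[..., periodic] = (dp + 180.0) % 360.0 - 180.0
    return d


def circular_distance(
    u,
    v,
    periodic: Optional[Sequence[bool]] = None,
    weights: Optional[Sequence[float]] = None,
) -> float:
    """Weighted Euclidean norm of wrapped coordinate differences (degrees).

    Each periodic coordinate difference is wrapped to [0, 180] in absolute
    value; non-periodic coordinates contribute their plain difference.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("CV vectors must have equal length")
    per = np.ones(u.shape[-1], bool) if periodic is None else np.asarray(periodic, bool)
    if per.shape[0] != u.shape[-1]:
        raise ValueError("periodic flags length mismatch")
    w = np.ones(u.shape[-1]) if weights is None else np.asarray(weights, dtype=float)
    if w.shape[0] != u.shape[-1]:
        raise ValueError("weights length mismatch")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    d = _wrapped_diffs(u.copy(), v, per)
    return float(np.sqrt(np.sum((w * d) ** 2, axis=-1)))


def _dist_to_point(data: np.ndarray, point: np.ndarray, periodic: np.ndarray, weights: np.ndarray) -> np.ndarray:
    d = _wrapped_diffs(data - 0.0, point, periodic)
    return np.sqrt(np.sum((weights * d) ** 2, axis=1))


def _dist_block(a: np.ndarray, b: np.ndarray, periodic: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """(len(a), len(b)) distance block."""
    d = a[:, None, :] - b[None, :, :]
    if periodic.any():
        dp = d[..., periodic]
        d[..., periodic] = (dp + 180.0) % 360.0 - 180.0
    return np.sqrt(np.sum((weights * d) ** 2, axis=-1))


def circular_mean(values: np.ndarray, resultant_tol: float = 1e-9) -> float:
    """Wrapped mean (degrees) via atan2 of mean sine/cosine.

    Returns NaN when the mean resultant length is below ``resultant_tol``
    (uniformly spread angles: the mean is undefined).
    """
    rad = np.radians(np.asarray(values, dtype=float))
    s, c = np.mean(np.sin(rad)), np.mean(np.cos(rad))
    if math.hypot(s, c) < resultant_tol:
        return float("nan")
    return float(wrap_angle(math.degrees(math.atan2(s, c))))


@dataclass
class ClusterModel:
    """Fitted k-medoids model over a CV table."""

    k: int
    medoid_rows: np.ndarray  # positional row indices into the CV table
    medoid_frames: np.ndarray  # frame indices (CV table index values)
    assignment: np.ndarray  # per-row cluster id in 0..k-1
    populations: np.ndarray  # fraction per cluster, sums to 1
    cv_means: pd.DataFrame  # per-cluster circular mean of each CV (degrees)
    cost: float
    seed: int
    n_iter: int
    converged: bool
    cv_names: list
    cost_history: list = None  # total cost after each assignment step

    def __post_init__(self):
        assert abs(self.populations.sum() - 1.0) < 1e-12


def _prepare(cvs: CVTable, weights) -> tuple:
    data = cvs.values.to_numpy(dtype=float)
    if np.isnan(data).any():
        bad = cvs.values.columns[np.isnan(data).any(axis=0)].tolist()
        raise ValueError(
            f"undefined CV cells in column(s) {bad}; filter frames "
            "(CVTable.dropna()) before clustering"
        )
    periodic = cvs.periodic_flags()
    w = np.ones(data.shape[1]) if weights is None else np.asarray(weights, dtype=float)
    return data, periodic, w


def kmedoids(
    cvs: CVTable,
    k: int,
    seed: int = 0,
    max_iter: int = 100,
    weights: Optional[Sequence[float]] = None,
    max_candidates: int = 1024,
    n_restarts: int = 3,
) -> ClusterModel:
    """k-medoids on a CV table with the wrapped-angle metric.

    Deterministic given (data, k, seed); the cost (sum of frame-to-medoid
    distances) is non-increasing over refinement iterations.

    ``max_candidates`` caps the number of medoid candidates examined per
    seeding/update/swap step (a deterministic, seed-derived subsample, always
    including the incumbent medoid, evaluated against *all* points).  This
    keeps the fit near-linear in n; set it to n for exhaustive PAM-style
    search on small inputs.  ``n_restarts`` independent fits (differing only
    in their candidate subsamples) are run and the lowest-cost one returned:
    BUILD seeding can enter a basin that neither alternating refinement nor
    single swaps escape, and restarts are the standard remedy.
    """
    best = None
    for r in range(max(1, n_restarts)):
        model = _kmedoids_once(cvs, k, seed, r, max_iter, weights, max_candidates)
        if best is None or model.cost < best.cost - 1e-12:
            best = model
    return best


def _kmedoids_once(cvs, k, seed, restart, max_iter, weights, max_candidates) -> ClusterModel:
    data, periodic, w = _prepare(cvs, weights)
    n = len(data)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of frames n={n}")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(restart,)))

    def candidate_pool(pool: np.ndarray) -> np.ndarray:
        if pool.size <= max_candidates:
            return pool
        return np.sort(rng.choice(pool, size=max_candidates, replace=False))

    # --- BUILD seeding -----------------------------------------------------
    # First medoid: the candidate with minimal total distance to all points.
    build_cands = candidate_pool(np.arange(n))
    totals = np.zeros(build_cands.size)
    for i, j in enumerate(build_cands):
        totals[i] = _dist_to_point(data, data[j], periodic, w).sum()
    medoids = [int(build_cands[int(np.argmin(totals))])]
    nearest = _dist_to_point(data, data[medoids[0]], periodic, w)
    # Subsequent medoids: maximise the decrease of the total cost.
    while len(medoids) < k:
        best_gain, best_j = -1.0, -1
        for j in build_cands:
            if j in medoids:
                continue
            gain = float(np.maximum(0.0, nearest - _dist_to_point(data, data[j], periodic, w)).sum())
            if gain > best_gain + 1e-12:
                best_gain, best_j = gain, int(j)
        medoids.append(best_j)
        nearest = np.minimum(nearest, _dist_to_point(data, data[best_j], periodic, w))

    # --- alternating refinement -------------------------------------------
    medoids = np.array(sorted(medoids))
    assignment = None
    converged = False
    n_iter = 0
    cost_history = []
    for n_iter in range(1, max_iter + 1):
        dmat = np.stack([_dist_to_point(data, data[m], periodic, w) for m in medoids], axis=1)
        assignment = np.argmin(dmat, axis=1)  # argmin breaks ties to lowest cluster
        cost_history.append(float(dmat[np.arange(n), assignment].sum()))
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(assignment == c)
            if members.size == 0:  # keep the old medoid for an emptied cluster
                continue
            cands = candidate_pool(members)
            if medoids[c] not in cands and medoids[c] in members:
                cands = np.sort(np.append(cands, medoids[c]))
            sub = data[members]
            tot = np.zeros(cands.size)
            for i, j in enumerate(cands):
                tot[i] = _dist_to_point(sub, data[j], periodic, w).sum()
            new_medoids[c] = int(cands[int(np.argmin(tot))])
        if np.array_equal(new_medoids, medoids):
            converged = True
            break
        medoids = new_medoids

    # --- SWAP phase ---------------------------------------------------------
    # Best-improvement medoid/non-medoid exchanges; a swap's cost change is
    # computed in O(n) per candidate from the nearest and second-nearest
    # medoid distances.  Each accepted swap strictly lowers the cost.
    for _ in range(8 * k):
        dmat = np.stack([_dist_to_point(data, data[m], periodic, w) for m in medoids], axis=1)
        order2 = np.argsort(dmat, axis=1)
        a1 = order2[:, 0]
        n1 = dmat[np.arange(n), a1]
        n2 = dmat[np.arange(n), order2[:, 1]] if k > 1 else np.full(n, np.inf)
        current_cost = float(n1.sum())
        cost_history.append(current_cost)
        cands = candidate_pool(np.setdiff1d(np.arange(n), medoids))
        best = (0.0, -1, -1)  # (cost decrease, medoid slot, candidate)
        for j in cands:
            dj = _dist_to_point(data, data[j], periodic, w)
            base = np.minimum(dj, n1)
            base_sum = float(base.sum())
            for c in range(k):
                mask = a1 == c
                corr = float(np.minimum(dj[mask], n2[mask]).sum() - base[mask].sum())
                decrease = current_cost - (base_sum + corr)
                if decrease > best[0] + 1e-9:
                    best = (decrease, c, int(j))
        if best[1] < 0:
            break
        medoids = medoids.copy()
        medoids[best[1]] = best[2]
        converged = True

    dmat = np.stack([_dist_to_point(data, data[m], periodic, w) for m in medoids], axis=1)
    assignment = np.argmin(dmat, axis=1)
    cost = float(dmat[np.arange(n), assignment].sum())
    cost_history.append(cost)
    populations = np.bincount(assignment, minlength=k) / n

    names = cvs.names
    means = pd.DataFrame(
        [[circular_mean(data[assignment == c, j]) if (assignment == c).any() else float("nan")
          for j in range(data.shape[1])] for c in range(k)],
        columns=names,
    )
    frame_index = cvs.values.index.to_numpy()
    return ClusterModel(
        k=k,
        medoid_rows=medoids,
        medoid_frames=frame_index[medoids],
        assignment=assignment,
        populations=populations,
        cv_means=means,
        cost=cost,
        seed=seed,
        n_iter=n_iter,
        converged=converged,
        cv_names=names,
        cost_history=cost_history,
    )


def cluster_table(model: ClusterModel, cvs: CVTable) -> pd.DataFrame:
    """Cluster summary table: id, population %, circular mean of each CV.

    Rows sorted by descending population; percentages rounded to one decimal
    (the resolution at which such populations are conventionally reported).
    """
    if list(cvs.names) != list(model.cv_names):
        raise ValueError("model was not fitted on this CV table")
    order = np.argsort(-model.populations, kind="stable")
    rows = []
    for rank, c in enumerate(order, start=1):
        row = {"cluster": rank, "population_pct": round(float(model.populations[c] * 100.0), 1),
               "medoid_frame": int(model.medoid_frames[c])}
        for name in model.cv_names:
            row[name] = round(float(model.cv_means.loc[c, name]), 1)
        rows.append(row)
    return pd.DataFrame(rows)


def medoid_frames(
    model: ClusterModel,
    traj: Trajectory,
    shell_radius: Optional[float] = None,
    solute=None,
) -> list:
    """The medoid frame of each cluster, in descending-population order.

    With ``shell_radius`` set, each frame is reduced to the solute molecules
    plus whole solvent molecules within the radius.  The comment line carries
    the cluster id and population.
    """
    frame_pos = {int(f): i for i, f in enumerate(traj.frame_indices)}
    order = np.argsort(-model.populations, kind="stable")
    out = []
    for rank, c in enumerate(order, start=1):
        fidx = int(model.medoid_frames[c])
        if fidx not in frame_pos:
            raise ValueError(f"medoid frame {fidx} not present in trajectory")
        frame = traj[frame_pos[fidx]]
        if shell_radius is not None:
            solute_ids = frame.molecules() if solute is None else solute
            frame = extract_shell(frame, solute_ids, shell_radius)
        frame.comment = (
            f"cluster {rank} population {model.populations[c] * 100.0:.1f}% "
            f"medoid_frame {fidx}"
        )
        out.append(frame)
    return out
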