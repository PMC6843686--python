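"""Markov state modelling of pooled trajectories under the all-Cα
minRMSD metric.

The analysis discretises conformations by k-medoids clustering with the
pairwise minimum-RMSD metric (no a-priori residue selection, no feature
embedding), then estimates a lag-time transition matrix by the sliding
window count estimator, its stationary distribution, implied
timescales, stationary net fluxes, and validates Markovianity with the
Chapman-Kolmogorov test.  Defaults mirror the analysis conditions of
the study this package operationalises: six states at a 0.1 ns lag with
10 ps frames, and 50 randomly selected representative structures per
state.

No detailed-balance symmetrisation is applied by default; an optional
reversible estimator (symmetrised counts) is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eig
from scipy.sparse.csgraph import connected_components

from .errors import InputError
from .geometry import batched_min_rmsd, rmsd_after_superposition
from .trajectory import Trajectory

DEFAULT_N_STATES = 6
DEFAULT_LAG_NS = 0.1
DEFAULT_ENSEMBLE_SIZE = 50
DEFAULT_CK_TOLERANCE = 0.1


def pairwise_rmsd(frame_a: np.ndarray, frame_b: np.ndarray) -> float:
    """Minimum Cα RMSD between two conformations after optimal
    superposition (Å)."""
    frame_a, frame_b = np.asarray(frame_a), np.asarray(frame_b)
    if frame_a.shape != frame_b.shape:
        raise InputError("Cα sets must have matching shapes")
    return rmsd_after_superposition(frame_a, frame_b)


# ---------------------------------------------------------------------
# clustering


@dataclass
class ClusterResult:
    labels: np.ndarray          # per-frame state index
    medoid_frames: np.ndarray   # frame index of each medoid
    n_states: int


def _coords_of(traj) -> np.ndarray:
    if isinstance(traj, Trajectory):
        ca = np.nonzero(traj.catalog.atom_name == "CA")[0]
        return traj.coords[:, ca]
    return np.asarray(traj)


def _kmedoids(dist: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """Deterministic k-medoids (Voronoi iteration) on a distance matrix.

    Seeding: the global medoid first, then maximin (farthest-point)
    selection; ties resolve to the lowest index.  Returns medoid row
    indices.
    """
    n = dist.shape[0]
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        nearest = dist[:, medoids].min(axis=1)
        candidate = int(np.argmax(nearest))
        if nearest[candidate] <= 0.0:
            raise InputError(
                f"cannot seed {k} distinct medoids: only {len(medoids)} "
                "distinct conformations present"
            )
        medoids.append(candidate)
    medoids = np.array(sorted(medoids))

    for _ in range(max_iter):
        assign = np.argmin(dist[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for j in range(k):
            members = np.nonzero(assign == j)[0]
            if members.size == 0:
                continue
            within = dist[np.ix_(members, members)].sum(axis=1)
            new_medoids[j] = members[int(np.argmin(within))]
        new_medoids = np.sort(new_medoids)
        if np.array_equal(new_medoids, medoids):
            break
        medoids = new_medoids
    return medoids


def _landmark_distance_matrix(coords: np.ndarray, block: int = 256) -> np.ndarray:
    n = coords.shape[0]
    dist = np.zeros((n, n))
    for start in range(0, n, block):
        stop = min(start + block, n)
        dist[start:stop] = batched_min_rmsd(coords[start:stop], coords)
    return (dist + dist.T) / 2.0


def cluster_states(traj, n_states: int = DEFAULT_N_STATES, seed: int = 0,
                   max_landmarks: int = 2000) -> ClusterResult:
    """Cluster frames into conformational states under minRMSD k-medoids.

    For trajectories longer than ``max_landmarks`` frames, a random
    landmark subsample (deterministic per seed) is clustered exactly and
    the remaining frames are assigned to the nearest medoid — the
    subsample-then-assign strategy.
    """
    coords = _coords_of(traj)
    n_frames = coords.shape[0]
    if n_states < 2:
        raise InputError("n_states must be >= 2")
    if n_frames < n_states:
        raise InputError(f"{n_frames} frames cannot form {n_states} states")

    rng = np.random.default_rng(seed)
    if n_frames > max_landmarks:
        landmarks = np.sort(rng.choice(n_frames, size=max_landmarks, replace=False))
    else:
        landmarks = np.arange(n_frames)

    sub = np.ascontiguousarray(coords[landmarks], dtype=np.float64)
    dist = _landmark_distance_matrix(sub)
    medoid_rows = _kmedoids(dist, n_states)
    medoid_frames = landmarks[medoid_rows]

    refs = np.ascontiguousarray(coords[medoid_frames], dtype=np.float64)
    labels = np.empty(n_frames, dtype=np.int32)
    block = max(1, int(2e7 // max(1, coords.shape[1] * n_states)))
    for start in range(0, n_frames, block):
        stop = min(start + block, n_frames)
        d = batched_min_rmsd(coords[start:stop], refs)
        labels[start:stop] = np.argmin(d, axis=1)
    return ClusterResult(labels, medoid_frames, n_states)


# ---------------------------------------------------------------------
# estimation


@dataclass
class MSMModel:
    """Estimated Markov state model at a fixed lag time."""

    n_states: int
    lag_ns: float
    frame_interval_ps: float
    labels: np.ndarray
    count_matrix: np.ndarray            # integer transition counts at lag
    transition_matrix: np.ndarray       # row-stochastic
    stationary_distribution: np.ndarray
    implied_timescales_ns: np.ndarray
    net_flux_matrix: np.ndarray         # pi_i T_ij - pi_j T_ji
    active_states: np.ndarray           # largest strongly connected set
    empty_rows: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def lag_steps(self) -> int:
        return int(round(self.lag_ns * 1000.0 / self.frame_interval_ps))

    @property
    def is_connected(self) -> bool:
        return len(self.active_states) == self.n_states

    def summary(self) -> str:
        lines = [
            f"Markov state model: {self.n_states} states, "
            f"lag {self.lag_ns:g} ns ({self.lag_steps} frames)",
            f"connected: {self.is_connected} "
            f"(active states: {list(self.active_states)})",
            "state  population   net outflow",
        ]
        outflow = self.net_flux_matrix.clip(min=0).sum(axis=1)
        for i in range(self.n_states):
            lines.append(f"{i:>5}  {self.stationary_distribution[i]:10.4f}  "
                         f"{outflow[i]:12.3e}")
        ts = ", ".join(f"{t:.3g}" for t in self.implied_timescales_ns[:5])
        lines.append(f"implied timescales (ns): {ts}")
        return "\n".join(lines)


def _segment_bounds(n: int, segment_lengths) -> list[tuple[int, int]]:
    if segment_lengths is None:
        return [(0, n)]
    if sum(segment_lengths) != n:
        raise InputError("segment lengths must sum to the label count")
    bounds, start = [], 0
    for length in segment_lengths:
        bounds.append((start, start + length))
        start += length
    return bounds


def count_transitions(labels: np.ndarray, lag_steps: int, n_states: int,
                      segment_lengths=None) -> np.ndarray:
    """Sliding-window transition counts at a lag, within segments only."""
    labels = np.asarray(labels)
    counts = np.zeros((n_states, n_states), dtype=np.int64)
    for start, stop in _segment_bounds(len(labels), segment_lengths):
        seg = labels[start:stop]
        if len(seg) <= lag_steps:
            continue
        np.add.at(counts, (seg[:-lag_steps], seg[lag_steps:]), 1)
    return counts


def stationary_from_transition(T: np.ndarray) -> np.ndarray:
    """Leading left eigenvector of a row-stochastic matrix, normalised."""
    vals, vecs = eig(T.T)
    idx = int(np.argmax(vals.real))
    pi = np.abs(vecs[:, idx].real)
    return pi / pi.sum()


def estimate_msm(labels, frame_interval_ps: float = 10.0,
                 lag_ns: float = DEFAULT_LAG_NS, n_states: int | None = None,
                 segment_lengths=None, reversible: bool = False) -> MSMModel:
    """Estimate a Markov state model from a state-label sequence.

    The lag must be an integer multiple of the frame interval.  The
    transition matrix is the row-normalised sliding-window count matrix
    (optionally symmetrised for a reversible estimate); the stationary
    distribution is computed on the largest strongly connected state set
    and zero elsewhere; implied timescales are -tau/ln|lambda_i| for the
    non-leading eigenvalues.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise InputError("empty label sequence")
    lag_steps_f = lag_ns * 1000.0 / frame_interval_ps
    lag_steps = int(round(lag_steps_f))
    if lag_steps < 1 or abs(lag_steps_f - lag_steps) > 1e-9:
        raise InputError(
            f"lag {lag_ns} ns is not a positive integer multiple of the "
            f"frame interval {frame_interval_ps} ps"
        )
    if n_states is None:
        n_states = int(labels.max()) + 1

    counts = count_transitions(labels, lag_steps, n_states, segment_lengths)
    effective = counts + counts.T if reversible else counts

    T = np.zeros((n_states, n_states))
    row_sums = effective.sum(axis=1)
    empty = np.nonzero(row_sums == 0)[0]
    ok = row_sums > 0
    T[ok] = effective[ok] / row_sums[ok, None]
    T[empty, empty] = 1.0  # flagged; absorbing placeholder

    n_comp, comp = connected_components(counts > 0, directed=True,
                                        connection="strong")
    sizes = np.bincount(comp, weights=counts.sum(axis=1), minlength=n_comp)
    active = np.nonzero(comp == int(np.argmax(sizes)))[0]
    if len(active) < n_states:
        warnings.warn(
            f"state space disconnected: stationary distribution computed on "
            f"the largest connected set {list(active)}", stacklevel=2)

    pi = np.zeros(n_states)
    T_active = T[np.ix_(active, active)]
    T_active = T_active / T_active.sum(axis=1, keepdims=True)
    pi[active] = stationary_from_transition(T_active)

    tau_ns = lag_steps * frame_interval_ps / 1000.0
    vals = np.linalg.eigvals(T_active)
    order = np.argsort(-np.abs(vals))
    its = []
    for lam in np.abs(vals[order])[1:]:
        if 0.0 < lam < 1.0 - 1e-12:
            its.append(-tau_ns / np.log(lam))
    implied = np.array(its)

    flux = pi[:, None] * T - pi[None, :] * T.T
    return MSMModel(n_states, lag_ns, frame_interval_ps, labels, counts, T,
                    pi, implied, flux, active, empty)


# ---------------------------------------------------------------------
# validation


@dataclass
class CKReport:
    """Chapman-Kolmogorov test: propagated vs directly estimated."""

    ks: list
    max_deviation: dict       # k -> element-wise max |T(k*tau) - T(tau)^k|
    passed: dict              # k -> bool at the tolerance
    tolerance: float
    skipped: list

    @property
    def all_passed(self) -> bool:
        return all(self.passed.values()) and bool(self.passed)


def ck_test(model: MSMModel, labels=None, ks=(2, 3, 4, 5),
            tol: float = DEFAULT_CK_TOLERANCE, segment_lengths=None) -> CKReport:
    """Chapman-Kolmogorov validation of an estimated model.

    For each k, the transition matrix estimated directly at lag k*tau is
    compared element-wise with the k-th matrix power of the lag-tau
    matrix, over the model's active state set.  k values whose lag
    exceeds the trajectory are skipped with a warning; k = 1 is 0 by
    construction.
    """
    labels = model.labels if labels is None else np.asarray(labels, dtype=int)
    max_dev, passed, skipped = {}, {}, []
    active = model.active_states
    for k in ks:
        lag_k = model.lag_steps * int(k)
        counts_k = count_transitions(labels, lag_k, model.n_states,
                                     segment_lengths)
        rows = counts_k.sum(axis=1)
        if len(labels) <= lag_k or rows[active].min() == 0:
            warnings.warn(f"CK test: insufficient frames at k={k}; skipped",
                          stacklevel=2)
            skipped.append(k)
            continue
        T_direct = counts_k[np.ix_(active, active)] / rows[active, None]
        T_prop = np.linalg.matrix_power(
            model.transition_matrix[np.ix_(active, active)], int(k))
        dev = float(np.abs(T_direct - T_prop).max())
        max_dev[k] = dev
        passed[k] = dev <= tol
    return CKReport(list(ks), max_dev, passed, tol, skipped)


def representative_ensemble(model: MSMModel, n: int = DEFAULT_ENSEMBLE_SIZE,
                            seed: int = 0) -> dict:
    """Randomly selected representative frame indices per state.

    ``n`` frames drawn uniformly without replacement from each state's
    member frames (all of them if a state holds fewer); reproducible per
    seed.
    """
    if n < 1:
        raise InputError("ensemble size must be >= 1")
    rng = np.random.default_rng(seed)
    out = {}
    for state in range(model.n_states):
        members = np.nonzero(model.labels == state)[0]
        if members.size <= n:
            out[state] = members
        else:
            out[state] = np.sort(rng.choice(members, size=n, replace=False))
    return out
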