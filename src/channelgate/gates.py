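"""Gate geometry: cross-pore distances, permeability, modes, hydration.

The channel's permeability observable is the pair of diagonal Cα-Cα
distances across the pore at a named constriction: the GluN1-GluN1
diagonal (Thr648-Thr648 for the TTTT gate) and the GluN2B-GluN2B
diagonal (Thr647-Thr647).  An open, ion-permeable channel requires both
diagonals to exceed a diameter threshold (default 10.0 Å, the midpoint
of the two observed open-state maxima at 8.5 and 11.5 Å); the threshold
is configurable because the diameter needed for ion transport is itself
uncertain.

Frame labels follow the state-code semantics of the distance histogram
analysis: ``C`` (closed, asymmetric — tight GluN2B/C2 with separated
GluN1/C1), ``R`` (symmetric agonist-activated arrangement, R1/R2),
``O1a`` (GluN2B separated/O2 but GluN1 transiently tight), and ``O``
(fully open, O1b/O2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .errors import ConfigurationError, InputError
from .topology import ReceptorTopology, ResidueSelector
from .trajectory import Trajectory

DEFAULT_OPEN_THRESHOLD = 10.0   # Å, midpoint of the 8.5/11.5 Å maxima
DEFAULT_BANDWIDTH = 0.5         # Å, kernel bandwidth for mode detection
DEFAULT_GRID_STEP = 0.05        # Å, density evaluation grid
DEFAULT_HISTOGRAM_BIN = 0.5     # Å


def ca_distance(frame: np.ndarray, catalog, a: ResidueSelector,
                b: ResidueSelector) -> float:
    """Euclidean Cα-Cα distance (Å) between two selections in one frame."""
    ia, ib = catalog.resolve(a), catalog.resolve(b)
    return float(np.linalg.norm(frame[ia] - frame[ib]))


def ca_distance_series(traj: Trajectory, a: ResidueSelector,
                       b: ResidueSelector) -> np.ndarray:
    """Per-frame Cα-Cα distance between two selections."""
    ia, ib = traj.catalog.resolve(a), traj.catalog.resolve(b)
    return np.linalg.norm(traj.coords[:, ia] - traj.coords[:, ib], axis=1)


@dataclass
class GateDistanceSeries:
    """Diagonal cross-pore distance time series for one gate."""

    gate: str
    d_glun1: np.ndarray     # GluN1-GluN1 diagonal, Å
    d_glun2b: np.ndarray    # GluN2B-GluN2B diagonal, Å
    times_ps: np.ndarray

    def __post_init__(self):
        if len(self.d_glun1) != len(self.d_glun2b):
            raise InputError("diagonal series must have equal length")
        if np.any(self.d_glun1 < 0) or np.any(self.d_glun2b < 0):
            raise InputError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.d_glun1)

    def state_codes(self, threshold: float = DEFAULT_OPEN_THRESHOLD,
                    symmetry_tol: float = 1.5) -> np.ndarray:
        """Per-frame state code: C / R / O1a / O (see module docstring)."""
        d1, d2 = self.d_glun1, self.d_glun2b
        codes = np.full(len(self), "R", dtype="<U3")
        codes[(d2 > threshold) & (d1 > threshold)] = "O"
        codes[(d2 > threshold) & (d1 <= threshold)] = "O1a"
        codes[(d2 <= threshold) & (np.abs(d1 - d2) > symmetry_tol)] = "C"
        return codes


def gate_series(traj: Trajectory, topology: ReceptorTopology,
                gate: str) -> GateDistanceSeries:
    """Diagonal distance series of a named gate (TTTT or LILI).

    The diagonals are role-homotypic: GluN1_A-GluN1_C and
    GluN2B_B-GluN2B_D across the pore.
    """
    if gate not in topology.gates:
        raise ConfigurationError(f"unknown gate {gate!r}")
    selectors = topology.gate_selectors(gate)  # chain order A, B, C, D
    by_role = {s.chain_role: s for s in selectors}
    d1 = ca_distance_series(traj, by_role["GluN1_A"], by_role["GluN1_C"])
    d2 = ca_distance_series(traj, by_role["GluN2B_B"], by_role["GluN2B_D"])
    return GateDistanceSeries(gate, d1, d2, traj.times_ps)


@dataclass
class ModeReport:
    """Modes of a kernel-smoothed distance density."""

    modes: np.ndarray       # Å, ascending
    weights: np.ndarray     # basin mass fractions, sum to 1
    bandwidth: float        # Å
    minima: np.ndarray      # Å, density minima separating the basins

    @property
    def n_modes(self) -> int:
        return len(self.modes)


def detect_modes(series, bandwidth: float = DEFAULT_BANDWIDTH,
                 grid_step: float = DEFAULT_GRID_STEP) -> ModeReport:
    """Locate modes of a distance distribution by Gaussian KDE.

    Local maxima of the smoothed density on a fixed grid; ties on a
    plateau are broken toward the lower distance.  Basin weights are the
    fractions of samples falling between consecutive density minima.
    Reliable multi-mode detection needs on the order of >= 100 samples.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size == 0:
        raise InputError("empty distance series")
    sd = x.std(ddof=1) if x.size > 1 else 0.0
    if sd == 0.0:
        value = float(x[0])
        return ModeReport(np.array([value]), np.array([1.0]), bandwidth,
                          np.array([]))

    kde = gaussian_kde(x, bw_method=bandwidth / sd)
    lo, hi = x.min() - 3 * bandwidth, x.max() + 3 * bandwidth
    grid = np.arange(lo, hi + grid_step, grid_step)
    dens = kde(grid)

    # strict rise followed by (possibly flat then) fall -> take the first
    # grid point of the plateau, i.e. the lower distance
    maxima = []
    i = 1
    while i < len(dens) - 1:
        if dens[i] > dens[i - 1]:
            j = i
            while j + 1 < len(dens) and dens[j + 1] == dens[j]:
                j += 1
            if j + 1 < len(dens) and dens[j + 1] < dens[j]:
                maxima.append(i)
            i = j + 1
        else:
            i += 1
    if not maxima:
        maxima = [int(np.argmax(dens))]

    modes = grid[maxima]
    minima = []
    for a, b in zip(maxima[:-1], maxima[1:]):
        k = a + int(np.argmin(dens[a:b + 1]))
        minima.append(grid[k])
    minima = np.array(minima)

    edges = np.concatenate([[-np.inf], minima, [np.inf]])
    weights = np.array([
        np.mean((x >= lo_e) & (x < hi_e))
        for lo_e, hi_e in zip(edges[:-1], edges[1:])
    ])
    weights = weights / weights.sum()
    return ModeReport(modes, weights, bandwidth, minima)


def open_probability(series, threshold: float) -> float:
    """Fraction of frames in which the gate exceeds the diameter threshold.

    For a :class:`GateDistanceSeries`, both diagonals must exceed the
    threshold; for a plain 1D array, the fraction of samples above it.
    Monotonically non-increasing in the threshold.
    """
    if threshold < 0:
        raise InputError("threshold must be non-negative")
    if isinstance(series, GateDistanceSeries):
        if len(series) == 0:
            raise InputError("empty gate series")
        both = (series.d_glun1 > threshold) & (series.d_glun2b > threshold)
        return float(np.mean(both))
    x = np.asarray(series, dtype=float).ravel()
    if x.size == 0:
        raise InputError("empty distance series")
    return float(np.mean(x > threshold))


def asymmetry_index(series: GateDistanceSeries) -> np.ndarray:
    """Per-frame signed diagonal asymmetry: GluN1 minus GluN2B (Å).

    Positive when the GluN1 pair is more separated than the GluN2B pair
    (the closed-state arrangement); exactly antisymmetric under exchange
    of the subunit roles.
    """
    return series.d_glun1 - series.d_glun2b


def gate_histogram(series, bin_width: float = DEFAULT_HISTOGRAM_BIN):
    """Distance histogram with fixed-width bins (counts, edges)."""
    x = np.asarray(series, dtype=float).ravel()
    if x.size == 0:
        raise InputError("empty distance series")
    lo = np.floor(x.min() / bin_width) * bin_width
    hi = np.ceil(x.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, _ = np.histogram(x, bins=edges)
    return counts, edges


@dataclass
class HydrationReport:
    """Water-oxygen occupancy of the inter-gate cylinder per frame."""

    counts: np.ndarray          # per-frame water count, >= 0
    radius: float               # cylinder radius, Å
    axis_points: np.ndarray     # (n_frames, 2, 3): TTTT and LILI centroids


def pore_hydration(traj: Trajectory, topology: ReceptorTopology,
                   radius: float = 5.0) -> HydrationReport:
    """Count water oxygens strictly between the TTTT and LILI gate planes.

    The pore axis of each frame is the line through the TTTT Cα centroid
    and the LILI Cα centroid; a water counts when its axial coordinate
    lies strictly between the two gate centroids and its radial distance
    from the axis is at most ``radius``.
    """
    waters = traj.water_indices
    if waters.size == 0:
        raise InputError("trajectory declares no water oxygens")
    tttt = traj.catalog.resolve_many(topology.gate_selectors("TTTT"))
    lili = traj.catalog.resolve_many(topology.gate_selectors("LILI"))

    c_tttt = traj.coords[:, tttt].mean(axis=1)           # (F, 3)
    c_lili = traj.coords[:, lili].mean(axis=1)
    axis = c_lili - c_tttt
    length = np.linalg.norm(axis, axis=1, keepdims=True)
    u = axis / length

    w = traj.coords[:, waters]                            # (F, W, 3)
    rel = w - c_tttt[:, None]
    t = np.einsum("fwi,fi->fw", rel, u)
    radial = np.linalg.norm(rel - t[..., None] * u[:, None], axis=2)
    inside = (t > 0) & (t < length) & (radial <= radius)
    counts = inside.sum(axis=1)
    axis_points = np.stack([c_tttt, c_lili], axis=1)
    return HydrationReport(counts, radius, axis_points)
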