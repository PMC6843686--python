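"""Asp-Arg-Glu salt-bridge triad detection and state classification.

In the open-like arrangement the GluN1 Arg695 guanidinium forms a
double salt bridge: inter-subunit with GluN2B Asp786 (upper LBD lobe of
the neighbouring chain) and intra-subunit with GluN1 Glu522.  In the
closed-like arrangement the arginine keeps only the intra-subunit
contact with Glu522.  Classification is a pure distance criterion:

    OPEN_LIKE    both d(Arg-Asp) and d(Arg-Glu) <= cutoff
    CLOSED_LIKE  only d(Arg-Glu) <= cutoff
    NONE         otherwise

Distances are minimum heavy-atom separations between the charged groups
(Arg NE/NH1/NH2 vs Asp OD1/OD2 or Glu OE1/OE2; default cutoff 4.0 Å,
the standard structural-biology salt-bridge criterion) or, for Cα-only
models, Cα-Cα proxies with a wider default cutoff of 10.0 Å.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InputError, ResolutionError
from .topology import ReceptorTopology, ResidueSelector
from .trajectory import Trajectory

OPEN_LIKE = "OPEN_LIKE"
CLOSED_LIKE = "CLOSED_LIKE"
NONE = "NONE"

DEFAULT_CUTOFF = 4.0        # Å, charged heavy-atom groups
DEFAULT_CA_CUTOFF = 10.0    # Å, Cα-proxy mode

_ARG_ATOMS = ("NE", "NH1", "NH2")
_CARBOXYLATE = {"asp": ("OD1", "OD2"), "glu": ("OE1", "OE2")}


def _group_distance(frame: np.ndarray, catalog, sel_a: ResidueSelector,
                    atoms_a, sel_b: ResidueSelector, atoms_b) -> float:
    """Minimum pairwise distance between two named atom groups."""
    try:
        ia = [catalog.resolve(replace(sel_a, atom_name=name)) for name in atoms_a]
        ib = [catalog.resolve(replace(sel_b, atom_name=name)) for name in atoms_b]
    except ResolutionError as exc:
        raise ResolutionError(
            f"charged-group mode needs side-chain atoms: {exc}"
        ) from exc
    diff = frame[ia][:, None] - frame[ib][None, :]
    return float(np.sqrt((diff ** 2).sum(axis=-1)).min())


def bridge_distances(frame: np.ndarray, catalog, topology: ReceptorTopology,
                     pair: str = "AB", mode: str = "CA-proxy"):
    """Triad distances (d_Arg-Asp, d_Arg-Glu) in Å for one frame.

    ``mode`` is 'charged-group' (minimum heavy-atom distance between the
    guanidinium and carboxylate groups) or 'CA-proxy' (Cα-Cα).
    """
    sel = topology.bridge_selectors(pair)
    if mode == "CA-proxy":
        ia = catalog.resolve(sel["arg"])
        d_rd = float(np.linalg.norm(frame[ia] - frame[catalog.resolve(sel["asp"])]))
        d_re = float(np.linalg.norm(frame[ia] - frame[catalog.resolve(sel["glu"])]))
    elif mode == "charged-group":
        d_rd = _group_distance(frame, catalog, sel["arg"], _ARG_ATOMS,
                               sel["asp"], _CARBOXYLATE["asp"])
        d_re = _group_distance(frame, catalog, sel["arg"], _ARG_ATOMS,
                               sel["glu"], _CARBOXYLATE["glu"])
    else:
        raise InputError(f"mode must be 'charged-group' or 'CA-proxy', got {mode!r}")
    return d_rd, d_re


def bridge_distance_series(traj: Trajectory, topology: ReceptorTopology,
                           pair: str = "AB", mode: str = "CA-proxy"):
    """Per-frame triad distances (d_RD, d_RE) over a trajectory."""
    sel = topology.bridge_selectors(pair)
    if mode == "CA-proxy":
        ia = traj.catalog.resolve(sel["arg"])
        i_d = traj.catalog.resolve(sel["asp"])
        i_e = traj.catalog.resolve(sel["glu"])
        d_rd = np.linalg.norm(traj.coords[:, ia] - traj.coords[:, i_d], axis=1)
        d_re = np.linalg.norm(traj.coords[:, ia] - traj.coords[:, i_e], axis=1)
        return d_rd, d_re
    out = np.array([
        bridge_distances(traj.coords[f], traj.catalog, topology, pair, mode)
        for f in range(traj.n_frames)
    ])
    return out[:, 0], out[:, 1]


@dataclass
class BridgeState:
    """Per-frame salt-bridge classification for one GluN1/GluN2B pair."""

    labels: np.ndarray        # OPEN_LIKE / CLOSED_LIKE / NONE
    d_rd: np.ndarray          # Arg695-Asp786, Å
    d_re: np.ndarray          # Arg695-Glu522, Å
    cutoff: float
    transitions: np.ndarray   # frame indices where the label changes

    def fractions(self) -> dict:
        n = len(self.labels)
        return {lab: float(np.mean(self.labels == lab))
                for lab in (OPEN_LIKE, CLOSED_LIKE, NONE)} if n else {}


def classify_bridge(d_rd, d_re, cutoff: float = DEFAULT_CUTOFF,
                    min_dwell: int = 0) -> BridgeState:
    """Classify each frame by the triad distance criterion.

    Deterministic and piecewise constant in the two distances; raising
    the cutoff can only move labels from NONE toward CLOSED_LIKE or
    OPEN_LIKE.  ``min_dwell`` (frames) optionally suppresses label
    flickers shorter than the given dwell by reassigning them to the
    preceding label; off by default.
    """
    if cutoff <= 0:
        raise InputError("cutoff must be positive")
    d_rd = np.asarray(d_rd, dtype=float)
    d_re = np.asarray(d_re, dtype=float)
    if d_rd.shape != d_re.shape:
        raise InputError("distance series must have equal length")

    labels = np.full(d_rd.shape, NONE, dtype="<U11")
    labels[(d_re <= cutoff)] = CLOSED_LIKE
    labels[(d_re <= cutoff) & (d_rd <= cutoff)] = OPEN_LIKE

    if min_dwell > 1 and labels.size:
        labels = _suppress_flickers(labels, min_dwell)

    change = np.nonzero(labels[1:] != labels[:-1])[0] + 1
    return BridgeState(labels, d_rd, d_re, float(cutoff), change)


def _suppress_flickers(labels: np.ndarray, min_dwell: int) -> np.ndarray:
    out = labels.copy()
    start = 0
    for i in range(1, len(out) + 1):
        if i == len(out) or out[i] != out[start]:
            if i - start < min_dwell and start > 0:
                out[start:i] = out[start - 1]
            start = i
    return out


def bridge_state_series(traj: Trajectory, topology: ReceptorTopology,
                        pair: str = "AB", mode: str = "CA-proxy",
                        cutoff: float | None = None,
                        min_dwell: int = 0) -> BridgeState:
    """End-to-end classification for one pair over a trajectory."""
    if cutoff is None:
        cutoff = DEFAULT_CA_CUTOFF if mode == "CA-proxy" else DEFAULT_CUTOFF
    d_rd, d_re = bridge_distance_series(traj, topology, pair, mode)
    return classify_bridge(d_rd, d_re, cutoff, min_dwell)
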