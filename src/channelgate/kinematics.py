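"""Rigid-body kinematics of the extracellular domains.

The descriptors follow the superposition convention of the trajectory
analysis: every frame is first aligned onto a reference frame using the
Cα atoms of the four pore-lining TMD M3 helices, so that global rigid
motion of the receptor and membrane drift are removed.  The residual
rotation of a domain block (ATD, LBD, or the combined extracellular
part ATD+LBD) is then fitted by a second Kabsch superposition and
decomposed into axis-angle form; the reported twist is the component of
that rotation about the pore (longitudinal) axis.

Sign convention: positive twist is clockwise as viewed from the
extracellular side looking down the pore axis toward the membrane.
With the pore axis pointing extracellularly (+z), a clockwise rotation
in that view is a negative right-handed rotation about the axis, hence
twist = -(rotation-vector . axis).  The synthetic generator uses the
same convention, so programmed and recovered angles agree in sign.

The lift angle tracks the elevation of each chain's outer (upper-lobe)
ATD subdomain centroid relative to that chain's whole-ATD centre of
mass, averaged over the four chains and reported as the change from the
reference frame.  The longitudinal axis is operationalised as the
principal axis of the reference frame's M3 Cα set, oriented toward the
extracellular side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .geometry import (apply_transform, rotation_angle_about_axis,
                       rotation_total_angle, superpose)
from .topology import ReceptorTopology
from .trajectory import Trajectory


def _m3_indices(traj: Trajectory, topology: ReceptorTopology) -> np.ndarray:
    idx = []
    for chain in topology.chains:
        residues = topology.domain_residues(chain.kind, "M3")
        idx.append(traj.catalog.indices_for(chain.role, residues))
    return np.concatenate(idx)


def _block_indices(traj: Trajectory, topology: ReceptorTopology,
                   block: str) -> np.ndarray:
    by_kind = topology.block_residues(block)
    idx = []
    for chain in topology.chains:
        idx.append(traj.catalog.indices_for(chain.role, by_kind[chain.kind]))
    out = np.concatenate(idx)
    if out.size == 0:
        raise ConfigurationError(f"block {block!r} selects no atoms")
    return out


def principal_axis(points: np.ndarray, orient_toward: np.ndarray | None = None
                   ) -> np.ndarray:
    """First principal axis of a point set (unit vector).

    If ``orient_toward`` is given, the sign is fixed so the axis points
    from the point-set centroid toward that position.
    """
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if orient_toward is not None:
        direction = orient_toward - points.mean(axis=0)
        if axis @ direction < 0:
            axis = -axis
    return axis / np.linalg.norm(axis)


@dataclass
class TwistResult:
    """Per-frame extracellular twist/lift relative to a reference frame."""

    twist_deg: np.ndarray        # signed; + = clockwise from extracellular
    lift_deg: np.ndarray         # outer-ATD elevation change
    total_rotation_deg: np.ndarray  # full 3D block rotation magnitude
    rmsd_align_A: np.ndarray     # M3 alignment RMSD per frame
    times_ps: np.ndarray
    reference_frame: int
    block: str
    axis: np.ndarray             # pore axis (unit, extracellular-positive)


def _elevation_deg(vector: np.ndarray) -> float:
    horizontal = np.hypot(vector[0], vector[1])
    return float(np.degrees(np.arctan2(vector[2], horizontal)))


def _mean_outer_elevation(frame: np.ndarray, traj: Trajectory,
                          topology: ReceptorTopology) -> float:
    elevations = []
    for chain in topology.chains:
        atd_idx = traj.catalog.indices_for(
            chain.role, topology.domain_residues(chain.kind, "ATD"))
        outer_idx = traj.catalog.indices_for(
            chain.role, topology.domain_residues(chain.kind, "outer_atd"))
        com = frame[atd_idx].mean(axis=0)
        outer = frame[outer_idx].mean(axis=0)
        elevations.append(_elevation_deg(outer - com))
    return float(np.mean(elevations))


def twist_series(traj: Trajectory, topology: ReceptorTopology,
                 block: str = "ATD+LBD", reference_frame: int = 0) -> TwistResult:
    """Per-frame rotation of a domain block about the pore axis.

    Each frame is aligned onto the reference frame on the TMD M3 Cα
    atoms; the residual rotation of the block (relative to the reference
    block) is fitted by Kabsch superposition and its component about the
    pore axis reported with the clockwise-from-extracellular sign
    convention.  The block must not overlap the M3 alignment selection
    (ATD/LBD blocks never do).
    """
    m3_idx = _m3_indices(traj, topology)
    block_idx = _block_indices(traj, topology, block)
    if np.intersect1d(m3_idx, block_idx).size:
        raise ConfigurationError("block overlaps the M3 alignment selection")

    ref = traj.coords[reference_frame]
    ref_m3 = ref[m3_idx]
    ref_block = ref[block_idx]

    # extracellular direction: from the TMD (M3) toward the ATD centroids
    atd_idx = _block_indices(traj, topology, "ATD")
    axis = principal_axis(ref_m3, orient_toward=ref[atd_idx].mean(axis=0))

    n = traj.n_frames
    twist = np.empty(n)
    lift = np.empty(n)
    total = np.empty(n)
    rmsd_align = np.empty(n)
    elev_ref = _mean_outer_elevation(ref, traj, topology)

    for f in range(n):
        rot_a, t_a, rmsd_a = superpose(traj.coords[f][m3_idx], ref_m3)
        aligned = apply_transform(traj.coords[f], rot_a, t_a)
        # rotation carrying the reference block onto this frame's block
        rot_b, _, _ = superpose(ref_block, aligned[block_idx])
        twist[f] = -rotation_angle_about_axis(rot_b, axis)
        total[f] = rotation_total_angle(rot_b)
        rmsd_align[f] = rmsd_a
        lift[f] = _mean_outer_elevation(aligned, traj, topology) - elev_ref

    return TwistResult(twist, lift, total, rmsd_align, traj.times_ps,
                       reference_frame, block, axis)


@dataclass
class TerminiDistanceSeries:
    """Cα distances between ATD N-termini across the receptor."""

    d_glun2b_glun2b: np.ndarray   # B-D
    d_glun1_glun1: np.ndarray     # A-C
    d_neighbor_ab: np.ndarray     # GluN1_A-GluN2B_B
    d_neighbor_bc: np.ndarray     # GluN2B_B-GluN1_C
    times_ps: np.ndarray


def termini_distances(traj: Trajectory, topology: ReceptorTopology
                      ) -> TerminiDistanceSeries:
    """Distance series between N-terminal Cα atoms of the four chains.

    Homotypic diagonals (GluN2B-GluN2B, GluN1-GluN1) plus the two
    symmetry-distinct neighbouring GluN1-GluN2B pairs.
    """
    selectors = topology.terminus_selectors()  # chain order A, B, C, D
    idx = traj.catalog.resolve_many(selectors)
    a, b, c, d = (traj.coords[:, i] for i in idx)

    def dist(p, q):
        return np.linalg.norm(p - q, axis=1)

    return TerminiDistanceSeries(
        d_glun2b_glun2b=dist(b, d),
        d_glun1_glun1=dist(a, c),
        d_neighbor_ab=dist(a, b),
        d_neighbor_bc=dist(b, c),
        times_ps=traj.times_ps,
    )
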