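"""Synthetic pseudo-receptor structures and programmed trajectories.

Every analysis stage in this package is exercised against trajectories
whose ground truth is known exactly, generated here: a coarse Cα-only
heterotetramer with stacked ATD/LBD/TMD pseudo-domain point clouds and
ideal pore-lining M3 helices, animated by programmed rigid-body
twist/lift schedules, stochastic gate-distance models, salt-bridge
toggles, landmark pair-distance models, optional water placement and
Markov jump dynamics among conformational basins.  The generator
produces geometry with programmed statistics — not physical dynamics —
and records every programmed value per frame in a ground-truth log.

Default statistical parameters are the observed study conditions: 10 ps
frame interval, an equal-weight open-state gate mixture with modes at
8.5 and 11.5 Å (sd 0.5 Å), a 45° maximum closing twist of the
extracellular part, a 15° ATD twist with 10° outer-subdomain lift for
the relaxation schedule, and a 7.9 +/- 0.9 Å liganded-state landmark
distance.

Sign convention matches the kinematics module: programmed twist angles
are clockwise viewed from the extracellular side, implemented as
right-handed rotations by the negated angle about the +z pore axis.
Gate-distance models override the rigid-body placement of the gate
residues, so gate statistics and twist kinematics stay independently
controllable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InputError
from .topology import ReceptorTopology, role_kind
from .trajectory import AtomCatalog, Trajectory, WATER_CHAIN_ID, WATER_ROLE

# geometry layout constants (Å, degrees)
HELIX_RISE = 1.5
HELIX_RADIUS = 2.3
HELIX_PHASE_PER_RES = 100.0
TMD_Z0 = 8.0                 # z of the first M3 residue
LILI_RADIAL_OFFSET = 0.8     # LILI sits slightly wider than TTTT
DEFAULT_PORE_RADIUS = 4.5

_RESOLUTIONS = {
    "default": dict(stride=6, m3_stride=1),
    "compact": dict(stride=24, m3_stride=2),
}

OPEN_LIKE = "OPEN_LIKE"
CLOSED_LIKE = "CLOSED_LIKE"

# programmed bridge-triad distances (d_Arg-Glu, d_Arg-Asp) per state,
# Cα-proxy scale
BRIDGE_GEOMETRY = {OPEN_LIKE: (4.0, 6.0), CLOSED_LIKE: (4.0, 12.0)}
BRIDGE_ED_SEPARATION = 9.0   # base Glu522-Asp786 distance


# ---------------------------------------------------------------------
# gate-distance models


@dataclass(frozen=True)
class GateModel:
    """Distance model for one gate diagonal: Gaussian or 2-mixture."""

    kind: str                      # 'normal' | 'mixture'
    mu: float = 0.0
    sigma: float = 0.5
    mu2: float = 0.0
    sigma2: float = 0.5
    weight: float = 0.5            # mass of the first component

    def __post_init__(self):
        if self.kind not in ("normal", "mixture"):
            raise ConfigurationError(f"unknown gate model kind {self.kind!r}")
        if self.kind == "mixture" and not 0.0 < self.weight < 1.0:
            raise ConfigurationError("mixture weight must lie in (0, 1)")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "normal":
            return rng.normal(self.mu, self.sigma, size=n)
        first = rng.random(n) < self.weight
        out = np.where(first,
                       rng.normal(self.mu, self.sigma, size=n),
                       rng.normal(self.mu2, self.sigma2, size=n))
        return out


def default_open_gate_model() -> GateModel:
    """Equal-weight open-state mixture: modes 8.5 / 11.5 Å, sd 0.5 Å."""
    return GateModel("mixture", mu=8.5, sigma=0.5, mu2=11.5, sigma2=0.5,
                     weight=0.5)


def sample_gate_model(model: GateModel, n: int, seed: int) -> np.ndarray:
    """Draw gate-distance samples from a model (standalone helper)."""
    return model.sample(np.random.default_rng(seed), n)


# ---------------------------------------------------------------------
# pseudo-receptor construction


@dataclass
class BaseStructure:
    """Cα-only pseudo-receptor: one coordinate table + catalog."""

    coords: np.ndarray      # (n_atoms, 3), Å
    catalog: AtomCatalog
    pore_radius: float
    chain_azimuth_deg: dict  # chain role -> construction azimuth


def _spiral_cloud(n: int, center, spread, rng: np.random.Generator,
                  jitter: float) -> np.ndarray:
    """Deterministic quasi-uniform ellipsoidal point cloud."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    pts = np.stack([
        np.sin(phi) * np.cos(theta),
        np.sin(phi) * np.sin(theta),
        np.cos(phi),
    ], axis=1)
    pts = pts * np.asarray(spread) + np.asarray(center)
    return pts + rng.normal(0.0, jitter, size=pts.shape)


def _strided(residues, stride, keep=()):
    ordered = sorted(residues)
    chosen = set(ordered[::stride]) | (set(keep) & set(ordered))
    return sorted(chosen)


def _rz(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _kind_template(kind: str, topology: ReceptorTopology, pore_radius: float,
                   stride: int, m3_stride: int, rng: np.random.Generator):
    """Residue numbers and template (azimuth-0) coordinates for one kind."""
    m3 = sorted(topology.domain_residues(kind, "M3"))
    tttt = topology.gates["TTTT"][kind][0]
    lili = topology.gates["LILI"][kind][0]
    m3_keep = {tttt, lili}
    m3_res = _strided(m3, m3_stride, keep=m3_keep)

    tmd_all = topology.domain_residues(kind, "TMD") - set(m3)
    lbd_all = topology.domain_residues(kind, "LBD")
    atd_all = topology.domain_residues(kind, "ATD")
    outer = topology.domain_residues(kind, "outer_atd")

    refs = topology.reference_residues.get(kind, {})
    keep_tmd = {r for r in refs.values() if r in tmd_all}
    keep_lbd = {r for r in refs.values() if r in lbd_all}
    for member, (bkind, resnum, _n) in topology.bridges.items():
        if bkind == kind and resnum in lbd_all:
            keep_lbd.add(resnum)
    n_term = topology.n_termini[kind]

    tmd_res = _strided(tmd_all, stride, keep=keep_tmd)
    lbd_res = _strided(lbd_all, stride, keep=keep_lbd)
    atd_res = _strided(atd_all, stride, keep={n_term})

    residues, coords = [], []

    # M3: ideal helix, its axis at pore_radius + helix radius so the
    # gating threonine phase points straight into the pore
    axis_r = pore_radius + HELIX_RADIUS
    i_tttt = tttt - m3[0]
    phase0 = 180.0 - HELIX_PHASE_PER_RES * i_tttt
    for r in m3_res:
        i = r - m3[0]
        psi = np.deg2rad(phase0 + HELIX_PHASE_PER_RES * i)
        z = TMD_Z0 + HELIX_RISE * i
        coords.append([axis_r + HELIX_RADIUS * np.cos(psi),
                       HELIX_RADIUS * np.sin(psi), z])
        residues.append(r)
    # exact gate placements
    for r, radius in ((tttt, pore_radius),
                      (lili, pore_radius + LILI_RADIAL_OFFSET)):
        k = residues.index(r)
        z = TMD_Z0 + HELIX_RISE * (r - m3[0])
        coords[k] = [radius, 0.0, z]

    # remaining TMD helices: outer arc
    arc = _spiral_cloud(len(tmd_res), center=(12.0, 0.0, 26.0),
                        spread=(2.0, 5.0, 22.0), rng=rng, jitter=0.3)
    for r, xyz in zip(tmd_res, arc):
        residues.append(r)
        coords.append(list(xyz))

    # LBD blob
    lbd = _spiral_cloud(len(lbd_res), center=(17.0, 0.0, 78.0),
                        spread=(6.0, 7.0, 14.0), rng=rng, jitter=0.5)
    for r, xyz in zip(lbd_res, lbd):
        residues.append(r)
        coords.append(list(xyz))

    # ATD: core blob + outer (upper-lobe) sub-blob
    atd_core = [r for r in atd_res if r not in outer]
    atd_outer = [r for r in atd_res if r in outer]
    core = _spiral_cloud(len(atd_core), center=(14.0, 0.0, 112.0),
                         spread=(6.0, 7.0, 9.0), rng=rng, jitter=0.5)
    lobe = _spiral_cloud(len(atd_outer), center=(22.0, 0.0, 138.0),
                         spread=(4.0, 5.0, 6.0), rng=rng, jitter=0.5)
    for r, xyz in zip(atd_core, core):
        residues.append(r)
        coords.append(list(xyz))
    for r, xyz in zip(atd_outer, lobe):
        residues.append(r)
        coords.append(list(xyz))
    # N-terminus pinned at the top of the outer lobe
    k = residues.index(n_term)
    coords[k] = [22.0, 0.0, 148.0]

    return residues, np.asarray(coords, dtype=float)


def _place_interface_residues(coords, catalog, topology):
    """Pin the salt-bridge triad and landmark residues to their nominal
    interface positions (pairs A-B at azimuth ~45°, C-D opposite)."""
    e_a = np.array([14.0 * np.cos(np.deg2rad(40.0)),
                    14.0 * np.sin(np.deg2rad(40.0)), 82.0])
    d_b = e_a + np.array([0.0, 0.0, BRIDGE_ED_SEPARATION])
    for pair, rot in (("AB", _rz(0.0)), ("CD", _rz(180.0))):
        sel = topology.bridge_selectors(pair)
        e_pos, d_pos = rot @ e_a, rot @ d_b
        coords[catalog.resolve(sel["glu"])] = e_pos
        coords[catalog.resolve(sel["asp"])] = d_pos
        d_re, d_rd = BRIDGE_GEOMETRY[OPEN_LIKE]
        coords[catalog.resolve(sel["arg"])] = _solve_triad_position(
            e_pos[None], d_pos[None], d_re, d_rd)[0]

    landmarks = {
        ("GluN1_A", "Glu698"): np.array([12.0, 4.0, 75.0]),
        ("GluN1_A", "Arg673"): np.array([9.0, 0.0, 52.0]),
        ("GluN2B_B", "Leu795"): _rz(90.0) @ np.array([9.0, -2.0, 54.0]),
    }
    for (role, name), pos in list(landmarks.items()):
        partner_role = {"GluN1_A": "GluN1_C", "GluN2B_B": "GluN2B_D"}[role]
        sel = topology.reference_selector(role, name)
        coords[catalog.resolve(sel)] = pos
        sel2 = topology.reference_selector(partner_role, name)
        coords[catalog.resolve(sel2)] = _rz(180.0) @ pos


def build_pseudo_receptor(topology: ReceptorTopology, seed: int = 0,
                          resolution: str = "default",
                          pore_radius: float = DEFAULT_PORE_RADIUS
                          ) -> BaseStructure:
    """Construct the coarse Cα tetramer (deterministic per seed).

    Chains sit at azimuths 0/90/180/270° around the +z pore axis; the
    two chains of each subunit kind share one template, so the build is
    exactly C2-pseudo-symmetric and the TTTT Cα diagonals equal
    ``2 * pore_radius`` by construction.
    """
    if resolution not in _RESOLUTIONS:
        raise ConfigurationError(f"unknown resolution {resolution!r}")
    params = _RESOLUTIONS[resolution]
    rng = np.random.default_rng(seed)

    templates = {
        kind: _kind_template(kind, topology, pore_radius,
                             params["stride"], params["m3_stride"], rng)
        for kind in ("GluN1", "GluN2B")
    }

    roles, chain_ids, resnums, resnames, atomnames, coords = [], [], [], [], [], []
    azimuths = {}
    for c, chain in enumerate(topology.chains):
        azimuth = 90.0 * c
        azimuths[chain.role] = azimuth
        residues, template = templates[chain.kind]
        rotated = template @ _rz(azimuth).T
        for r, xyz in zip(residues, rotated):
            roles.append(chain.role)
            chain_ids.append(chain.chain_id)
            resnums.append(r)
            resnames.append("GLY")
            atomnames.append("CA")
            coords.append(xyz)

    catalog = AtomCatalog(
        chain_role=np.array(roles, dtype="<U8"),
        chain_id=np.array(chain_ids),
        residue_number=np.array(resnums, dtype=int),
        residue_name=np.array(resnames),
        atom_name=np.array(atomnames),
    )
    coords = np.asarray(coords, dtype=float)
    _place_interface_residues(coords, catalog, topology)
    return BaseStructure(coords, catalog, pore_radius, azimuths)


def add_waters(base: BaseStructure, topology: ReceptorTopology,
               mode: str = "below_TTTT_only",
               custom_coords: np.ndarray | None = None,
               n_waters: int = 24) -> BaseStructure:
    """Extend a base structure with water oxygens.

    ``below_TTTT_only`` places waters in the pore vestibule below the
    TTTT gate plane, leaving the inter-gate (TTTT-LILI) space dry;
    ``custom`` uses caller-provided coordinates.
    """
    if mode == "none":
        return base
    if mode == "below_TTTT_only":
        tttt_idx = base.catalog.resolve_many(topology.gate_selectors("TTTT"))
        z_gate = base.coords[tttt_idx][:, 2].mean()
        i = np.arange(n_waters)
        radius = base.pore_radius * 0.6 * (0.3 + 0.7 * ((i * 7) % n_waters) / n_waters)
        theta = np.deg2rad(137.5 * i)
        z = z_gate - 3.0 - 14.0 * i / n_waters
        water = np.stack([radius * np.cos(theta), radius * np.sin(theta), z],
                         axis=1)
    elif mode == "custom":
        if custom_coords is None:
            raise ConfigurationError("custom water mode needs coordinates")
        water = np.asarray(custom_coords, dtype=float).reshape(-1, 3)
    else:
        raise ConfigurationError(f"unknown water mode {mode!r}")

    n = len(water)
    catalog = AtomCatalog(
        chain_role=np.concatenate([base.catalog.chain_role,
                                   np.full(n, WATER_ROLE, dtype="<U8")]),
        chain_id=np.concatenate([base.catalog.chain_id,
                                 np.full(n, WATER_CHAIN_ID)]),
        residue_number=np.concatenate([base.catalog.residue_number,
                                       1001 + np.arange(n)]),
        residue_name=np.concatenate([base.catalog.residue_name,
                                     np.full(n, "HOH")]),
        atom_name=np.concatenate([base.catalog.atom_name, np.full(n, "O")]),
    )
    coords = np.concatenate([base.coords, water], axis=0)
    return BaseStructure(coords, catalog, base.pore_radius,
                         base.chain_azimuth_deg)


# ---------------------------------------------------------------------
# programmed trajectory generation


@dataclass
class GeneratorSpec:
    """Programmed study conditions for one synthetic trajectory."""

    seed: int
    n_frames: int
    frame_interval_ps: float = 10.0
    twist_block: str = "ATD+LBD"
    twist_deg: np.ndarray | None = None        # per-frame clockwise twist
    lift_deg: np.ndarray | None = None         # per-frame outer-ATD lift
    gate_models: dict = field(default_factory=dict)   # (gate, kind) -> GateModel
    pair_models: dict = field(default_factory=dict)   # ((role, name), (role, name)) -> (mu, sd)
    bridge_schedule: np.ndarray | None = None  # per-frame OPEN_LIKE/CLOSED_LIKE
    termini_drift: dict = field(default_factory=dict)  # kind -> per-frame inward Å
    basin_centroids: np.ndarray | None = None  # (K, n_atoms, 3)
    jump_matrix: np.ndarray | None = None      # (K, K) row-stochastic
    basin_steps_per_jump: int = 1              # frames per jump epoch
    water_mode: str = "none"
    water_coords: np.ndarray | None = None
    noise_sigma: float = 0.1
    dtype: type = np.float64

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ConfigurationError("n_frames must be >= 1")
        for name in ("twist_deg", "lift_deg", "bridge_schedule"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != self.n_frames:
                raise ConfigurationError(
                    f"{name} schedule length {len(arr)} != n_frames {self.n_frames}")
        for kind, arr in self.termini_drift.items():
            if len(arr) != self.n_frames:
                raise ConfigurationError(
                    f"termini_drift[{kind}] length mismatch")
        if (self.basin_centroids is None) != (self.jump_matrix is None):
            raise ConfigurationError(
                "basin_centroids and jump_matrix must be given together")
        if self.jump_matrix is not None:
            _check_stochastic(self.jump_matrix)


def ramp(n_frames: int, start: float, end: float) -> np.ndarray:
    """Linear schedule from start to end across all frames."""
    return np.linspace(start, end, n_frames)


def _check_stochastic(T: np.ndarray) -> None:
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise InputError("jump matrix must be square")
    if np.any(T < 0) or not np.allclose(T.sum(axis=1), 1.0, atol=1e-8):
        raise InputError("jump matrix rows must be non-negative and sum to 1")


def generate_jump_labels(T: np.ndarray, n_steps: int, seed: int,
                         initial: int | None = None) -> np.ndarray:
    """Realise a Markov chain from a row-stochastic jump matrix."""
    _check_stochastic(T)
    T = np.asarray(T, dtype=float)
    cum = np.cumsum(T, axis=1)
    rng = np.random.default_rng(seed)
    labels = np.empty(n_steps, dtype=np.int32)
    state = int(initial) if initial is not None else int(rng.integers(T.shape[0]))
    u = rng.random(n_steps)
    for i in range(n_steps):
        labels[i] = state
        state = int(np.searchsorted(cum[state], u[i], side="right"))
        state = min(state, T.shape[0] - 1)
    return labels


def _solve_triad_position(e_pos: np.ndarray, d_pos: np.ndarray,
                          d_re: float, d_rd: float) -> np.ndarray:
    """Point at distance d_re from E and d_rd from D (batched, (F, 3)).

    Deterministic branch: the in-plane solution on the side of the
    radial direction at E.
    """
    ed = d_pos - e_pos
    length = np.linalg.norm(ed, axis=1, keepdims=True)
    e_hat = ed / length
    radial = e_pos.copy()
    radial[:, 2] = 0.0
    radial /= np.maximum(np.linalg.norm(radial, axis=1, keepdims=True), 1e-12)
    n_hat = np.cross(e_hat, radial)
    n_hat /= np.maximum(np.linalg.norm(n_hat, axis=1, keepdims=True), 1e-12)
    m_hat = np.cross(n_hat, e_hat)

    L = length[:, 0]
    a = (d_re ** 2 - d_rd ** 2 + L ** 2) / (2.0 * L)
    h = np.sqrt(np.maximum(d_re ** 2 - a ** 2, 0.0))
    return e_pos + a[:, None] * e_hat + h[:, None] * m_hat


def _solve_lift_angles(alpha_deg: np.ndarray, w: np.ndarray,
                       outer_fraction: float) -> np.ndarray:
    """Lobe rotation angles producing programmed elevation changes.

    Rotating the outer lobe by beta about an axis through the whole-ATD
    centre of mass also moves that centre of mass (the lobe is part of
    it), so the realised elevation change of (lobe centroid - ATD COM)
    is a shrunken, slightly nonlinear function of beta; solve for beta
    by bisection in the vertical plane.
    """
    rho = float(np.hypot(w[0], w[1]))
    hz = float(w[2])
    base_elev = np.degrees(np.arctan2(hz, rho))
    m = outer_fraction

    def realised(beta_deg):
        b = np.deg2rad(beta_deg)
        rho_r = rho * np.cos(b) - hz * np.sin(b)
        hz_r = rho * np.sin(b) + hz * np.cos(b)
        v_rho = (1 - m) * rho_r + m * rho
        v_h = (1 - m) * hz_r + m * hz
        return np.degrees(np.arctan2(v_h, np.abs(v_rho))) - base_elev

    alpha = np.asarray(alpha_deg, dtype=float)
    scale = np.maximum(np.abs(alpha) / (1 - m) * 2.0 + 5.0, 10.0)
    lo = np.where(alpha >= 0, 0.0, -scale)
    hi = np.where(alpha >= 0, scale, 0.0)
    for _ in range(60):
        mid = (lo + hi) / 2.0
        too_low = realised(mid) < alpha
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    beta = (lo + hi) / 2.0
    return np.where(alpha == 0.0, 0.0, beta)


def _rodrigues_stack(axis: np.ndarray, angles_deg: np.ndarray) -> np.ndarray:
    a = axis / np.linalg.norm(axis)
    t = np.deg2rad(np.asarray(angles_deg, dtype=float))
    c, s = np.cos(t), np.sin(t)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    eye = np.eye(3)
    outer = np.outer(a, a)
    return (c[:, None, None] * eye + s[:, None, None] * K
            + (1 - c)[:, None, None] * outer)


def generate_trajectory(spec: GeneratorSpec, base: BaseStructure,
                        topology: ReceptorTopology):
    """Produce a programmed trajectory and its ground-truth log.

    Operations are applied in order: basin selection (if any), outer-ATD
    lift, extracellular twist, ATD radial drift, gate-distance
    overrides, landmark pair-distance overrides, bridge-triad placement,
    water placement, then isotropic Gaussian coordinate noise.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    truth: dict = {}

    if spec.water_mode != "none":
        base = add_waters(base, topology, spec.water_mode, spec.water_coords)
    catalog = base.catalog
    n_frames, dtype = spec.n_frames, spec.dtype

    if spec.basin_centroids is not None:
        centroids = np.asarray(spec.basin_centroids, dtype=dtype)
        steps = int(spec.basin_steps_per_jump)
        n_jumps = -(-n_frames // steps)
        epochs = generate_jump_labels(
            spec.jump_matrix, n_jumps,
            seed=int(rng.integers(2 ** 31 - 1)))
        labels = np.repeat(epochs, steps)[:n_frames]
        coords = centroids[labels].copy()
        truth["basin_labels"] = labels
    else:
        coords = np.broadcast_to(
            base.coords.astype(dtype), (n_frames,) + base.coords.shape).copy()

    # -- lift: rotate each chain's outer ATD lobe about a horizontal
    #    axis through the chain's ATD centre of mass
    if spec.lift_deg is not None and np.any(np.asarray(spec.lift_deg) != 0):
        alpha = np.asarray(spec.lift_deg, dtype=float)
        truth["lift_deg"] = alpha
        for chain in topology.chains:
            atd_idx = catalog.indices_for(
                chain.role, topology.domain_residues(chain.kind, "ATD"))
            outer_idx = catalog.indices_for(
                chain.role, topology.domain_residues(chain.kind, "outer_atd"))
            com = base.coords[atd_idx].mean(axis=0)
            w = base.coords[outer_idx].mean(axis=0) - com
            m_frac = outer_idx.size / atd_idx.size
            beta = _solve_lift_angles(alpha, w, m_frac)
            w_xy = np.array([w[0], w[1], 0.0])
            # axis = w_hat x z: rotation by +beta raises the elevation
            axis = np.cross(w_xy / np.linalg.norm(w_xy), [0.0, 0.0, 1.0])
            rots = _rodrigues_stack(axis, beta)
            rel = base.coords[outer_idx] - com
            coords[:, outer_idx] = (
                np.einsum("fij,nj->fni", rots, rel) + com).astype(dtype)

    # -- extracellular twist: clockwise (viewed from outside) = -angle
    #    right-handed about +z
    if spec.twist_deg is not None and np.any(np.asarray(spec.twist_deg) != 0):
        theta = np.asarray(spec.twist_deg, dtype=float)
        truth["twist_deg"] = theta
        truth["twist_block"] = spec.twist_block
        by_kind = topology.block_residues(spec.twist_block)
        idx = np.concatenate([
            catalog.indices_for(c.role, by_kind[c.kind])
            for c in topology.chains])
        rots = _rodrigues_stack(np.array([0.0, 0.0, 1.0]), -theta)
        coords[:, idx] = np.einsum(
            "fij,fnj->fni", rots, coords[:, idx]).astype(dtype)

    # -- per-kind radial drift of the ATD blocks (termini rearrangement)
    for kind, drift in spec.termini_drift.items():
        drift = np.asarray(drift, dtype=float)
        truth.setdefault("termini_drift", {})[kind] = drift
        for chain in topology.chains:
            if chain.kind != kind:
                continue
            atd_idx = catalog.indices_for(
                chain.role, topology.domain_residues(chain.kind, "ATD"))
            centroid_xy = coords[:, atd_idx, :2].mean(axis=1)
            norm = np.linalg.norm(centroid_xy, axis=1, keepdims=True)
            inward = -centroid_xy / np.maximum(norm, 1e-12)
            coords[:, atd_idx, :2] += (drift[:, None] * inward)[:, None, :]

    # -- gate-distance overrides: the sampled diagonal takes precedence
    #    over rigid-body placement of the gate residues
    for (gate, kind), model in spec.gate_models.items():
        d = model.sample(rng, n_frames)
        truth.setdefault("gate_samples", {})[(gate, kind)] = d
        selectors = [s for s in topology.gate_selectors(gate)
                     if role_kind(s.chain_role) == kind]
        for s in selectors:
            i = catalog.resolve(s)
            azim = np.deg2rad(base.chain_azimuth_deg[s.chain_role])
            z = base.coords[i, 2]
            coords[:, i, 0] = (d / 2.0) * np.cos(azim)
            coords[:, i, 1] = (d / 2.0) * np.sin(azim)
            coords[:, i, 2] = z

    # -- landmark pair-distance overrides: partner placed at the sampled
    #    distance along the current anchor->partner direction
    for ((anchor_role, anchor_name), (partner_role, partner_name)), (mu, sd) \
            in spec.pair_models.items():
        d = rng.normal(mu, sd, size=n_frames)
        truth.setdefault("pair_samples", {})[
            (anchor_name, partner_name)] = d
        ia = catalog.resolve(topology.reference_selector(anchor_role, anchor_name))
        ip = catalog.resolve(topology.reference_selector(partner_role, partner_name))
        direction = coords[:, ip] - coords[:, ia]
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        coords[:, ip] = coords[:, ia] + d[:, None] * direction

    # -- salt-bridge triad: per-frame Arg695 placement per schedule
    if spec.bridge_schedule is not None:
        schedule = np.asarray(spec.bridge_schedule)
        truth["bridge_labels"] = schedule
        for pair in ("AB", "CD"):
            sel = topology.bridge_selectors(pair)
            i_e = catalog.resolve(sel["glu"])
            i_d = catalog.resolve(sel["asp"])
            i_r = catalog.resolve(sel["arg"])
            e_pos = coords[:, i_e].astype(float)
            d_pos = coords[:, i_d].astype(float)
            arg = np.empty_like(e_pos)
            for label, (d_re, d_rd) in BRIDGE_GEOMETRY.items():
                mask = schedule == label
                if mask.any():
                    arg[mask] = _solve_triad_position(
                        e_pos[mask], d_pos[mask], d_re, d_rd)
            coords[:, i_r] = arg.astype(dtype)

    if spec.noise_sigma > 0:
        noise_dtype = np.float32 if dtype == np.float32 else np.float64
        coords += spec.noise_sigma * rng.standard_normal(
            coords.shape, dtype=noise_dtype)

    traj = Trajectory(coords, catalog, spec.frame_interval_ps)
    return traj, truth


# ---------------------------------------------------------------------
# basins and presets


def basin_centroids(base: BaseStructure, topology: ReceptorTopology,
                    twist_angles_deg, block: str = "ATD+LBD") -> np.ndarray:
    """Centroid structures differing by programmed extracellular twists."""
    by_kind = topology.block_residues(block)
    idx = np.concatenate([
        base.catalog.indices_for(c.role, by_kind[c.kind])
        for c in topology.chains])
    out = np.repeat(base.coords[None], len(twist_angles_deg), axis=0)
    for k, angle in enumerate(twist_angles_deg):
        out[k, idx] = base.coords[idx] @ _rz(-angle).T
    return out


RELAXATION_TWIST_DEG = 15.0   # ATD clockwise twist during relaxation
RELAXATION_LIFT_DEG = 10.0    # outer ATD subdomain lift
CLOSING_TWIST_DEG = 45.0      # maximum extracellular closing rotation
LIGANDED_PAIR_MU = 7.9        # Leu795-Glu698 mean distance, Å
LIGANDED_PAIR_SD = 0.9
LIGANDED_PAIR2_MU = 9.9       # Leu795-Arg673 mean distance, Å
LIGANDED_PAIR2_SD = 0.3
MSM_BASIN_TWISTS = (0.0, 9.0, 18.0, 27.0, 36.0, 45.0)
MSM_STAY_PROBABILITY = 0.7   # per-frame; mean basin dwell ~33 ps


def default_jump_matrix(n_states: int = 6,
                        stay: float = MSM_STAY_PROBABILITY) -> np.ndarray:
    T = np.full((n_states, n_states), (1.0 - stay) / (n_states - 1))
    np.fill_diagonal(T, stay)
    return T


def make_preset(name: str, seed: int, n_frames: int | None = None,
                topology: ReceptorTopology | None = None,
                base: BaseStructure | None = None,
                twist_endpoint_deg: float | None = None,
                noise_sigma: float = 0.1):
    """Build (spec, base) for a named scenario.

    Presets: ``relaxation`` (15° ATD twist + 10° lift), ``opening``
    (bimodal GluN1 gate, separated GluN2B gate, liganded landmark
    distances, inward GluN2B ATD drift), ``closing`` (45° extracellular
    twist by default, asymmetric closed gate, bridge toggle at
    mid-trajectory, dry inter-gate pore), ``msm6`` (Markov jumps among
    six twist basins on the compact receptor).
    """
    from .topology import default_topology

    topology = topology or default_topology()
    if name == "relaxation":
        n = n_frames or 500
        end = (twist_endpoint_deg if twist_endpoint_deg is not None
               else RELAXATION_TWIST_DEG)
        spec = GeneratorSpec(
            seed=seed, n_frames=n, twist_block="ATD",
            twist_deg=ramp(n, 0.0, end),
            lift_deg=ramp(n, 0.0, RELAXATION_LIFT_DEG),
            noise_sigma=noise_sigma)
        base = base or build_pseudo_receptor(topology, seed=seed)
    elif name == "opening":
        n = n_frames or 15000
        spec = GeneratorSpec(
            seed=seed, n_frames=n, twist_block="ATD+LBD",
            gate_models={
                ("TTTT", "GluN1"): default_open_gate_model(),
                ("TTTT", "GluN2B"): GateModel("normal", mu=13.0, sigma=0.5),
            },
            pair_models={
                (("GluN2B_B", "Leu795"), ("GluN1_A", "Glu698")):
                    (LIGANDED_PAIR_MU, LIGANDED_PAIR_SD),
                (("GluN2B_B", "Leu795"), ("GluN1_A", "Arg673")):
                    (LIGANDED_PAIR2_MU, LIGANDED_PAIR2_SD),
            },
            bridge_schedule=np.full(n, OPEN_LIKE),
            termini_drift={"GluN2B": ramp(n, 0.0, 5.0)},
            noise_sigma=noise_sigma)
        base = base or build_pseudo_receptor(topology, seed=seed)
    elif name == "closing":
        n = n_frames or 1500
        end = (twist_endpoint_deg if twist_endpoint_deg is not None
               else CLOSING_TWIST_DEG)
        schedule = np.full(n, OPEN_LIKE, dtype="<U11")
        schedule[n // 2:] = CLOSED_LIKE
        spec = GeneratorSpec(
            seed=seed, n_frames=n, twist_block="ATD+LBD",
            twist_deg=ramp(n, 0.0, end),
            gate_models={
                ("TTTT", "GluN1"): GateModel("normal", mu=12.5, sigma=0.4),
                ("TTTT", "GluN2B"): GateModel("normal", mu=6.5, sigma=0.3),
            },
            bridge_schedule=schedule,
            water_mode="below_TTTT_only",
            noise_sigma=noise_sigma)
        base = base or build_pseudo_receptor(topology, seed=seed)
    elif name == "msm6":
        n = n_frames or 20000
        base = base or build_pseudo_receptor(topology, seed=seed,
                                             resolution="compact")
        centroids = basin_centroids(base, topology, MSM_BASIN_TWISTS)
        # per-frame jump chain; its mixing rate keeps the sliding-window
        # estimator's sampling noise well inside the documented recovery
        # tolerances at the default trajectory length
        spec = GeneratorSpec(
            seed=seed, n_frames=n,
            basin_centroids=centroids,
            jump_matrix=default_jump_matrix(len(MSM_BASIN_TWISTS)),
            noise_sigma=0.25, dtype=np.float32)
    else:
        raise ConfigurationError(f"unknown preset {name!r}")
    return spec, base, topology
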