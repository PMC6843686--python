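"""Trajectory container and multi-model PDB input/output.

A :class:`Trajectory` holds an ordered stack of coordinate frames
(Å, shape ``(n_frames, n_atoms, 3)``) sharing one :class:`AtomCatalog`
that maps each atom index to chain role, residue number, residue name
and atom name.  Frames are snapshots at a fixed interval (default 10 ps).

The portable on-disk format is multi-model PDB (MODEL/ENDMDL records),
read and written through biotite.  Water molecules travel as ``HOH``
oxygen records on their own chain and are exposed via
``Trajectory.water_indices`` rather than through chain roles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io import pdb as pdbio

from .errors import FormatError, InputError, ResolutionError
from .topology import ReceptorTopology, ResidueSelector

WATER_ROLE = "water"
WATER_CHAIN_ID = "W"


@dataclass
class AtomCatalog:
    """Per-atom metadata shared by every frame of a trajectory."""

    chain_role: np.ndarray   # dtype '<U8'; 'water' for solvent oxygens
    chain_id: np.ndarray
    residue_number: np.ndarray
    residue_name: np.ndarray
    atom_name: np.ndarray

    def __post_init__(self):
        n = len(self.chain_role)
        for arr in (self.chain_id, self.residue_number, self.residue_name, self.atom_name):
            if len(arr) != n:
                raise InputError("catalog annotation arrays must share one length")
        self._index = {}
        for i in range(n):
            key = (
                str(self.chain_role[i]),
                int(self.residue_number[i]),
                str(self.atom_name[i]),
            )
            # injectivity: a selector key must map to exactly one atom
            if key in self._index and self.chain_role[i] != WATER_ROLE:
                raise FormatError(f"duplicate atom for selection {key}")
            self._index.setdefault(key, i)

    def __len__(self) -> int:
        return len(self.chain_role)

    def resolve(self, selector: ResidueSelector) -> int:
        """Atom index for a selector; ResolutionError if absent."""
        key = (selector.chain_role, selector.residue_number, selector.atom_name)
        try:
            return self._index[key]
        except KeyError:
            raise ResolutionError(
                f"no atom {selector.atom_name} for {selector.chain_role} "
                f"residue {selector.residue_number}"
            ) from None

    def resolve_many(self, selectors) -> np.ndarray:
        return np.array([self.resolve(s) for s in selectors], dtype=np.intp)

    def indices_for(self, role: str, residues: set[int] | None = None,
                    atom_name: str = "CA") -> np.ndarray:
        """Atom indices of one chain role, optionally restricted to residues."""
        mask = (self.chain_role == role) & (self.atom_name == atom_name)
        if residues is not None:
            mask &= np.isin(self.residue_number, sorted(residues))
        return np.nonzero(mask)[0]


@dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed atom catalog."""

    coords: np.ndarray            # (n_frames, n_atoms, 3) in Å
    catalog: AtomCatalog
    frame_interval_ps: float = 10.0
    segment_lengths: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.coords = np.asarray(self.coords)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise InputError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.catalog):
            raise FormatError(
                f"frame atom count {self.coords.shape[1]} does not match "
                f"catalog size {len(self.catalog)}"
            )
        if self.frame_interval_ps <= 0:
            raise InputError("frame_interval_ps must be positive")
        if not self.segment_lengths:
            self.segment_lengths = [self.n_frames]
        if sum(self.segment_lengths) != self.n_frames:
            raise InputError("segment lengths must sum to the frame count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def times_ps(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_ps

    @property
    def water_indices(self) -> np.ndarray:
        return np.nonzero(self.catalog.chain_role == WATER_ROLE)[0]

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]


def _role_for_chain_id(chain_id: str, topology: ReceptorTopology) -> str:
    if chain_id == WATER_CHAIN_ID:
        return WATER_ROLE
    return topology.chain_by_id(chain_id).role


def read_trajectory(paths, topology: ReceptorTopology,
                    frame_interval_ps: float = 10.0) -> Trajectory:
    """Read one or more multi-model PDB files as a pooled trajectory.

    Frames follow file order; every file must carry the same atoms.  The
    atom catalog is cross-checked against the topology: all four chains
    must be present and every gate residue must resolve.
    """
    if isinstance(paths, (str, bytes)) or hasattr(paths, "__fspath__"):
        paths = [paths]
    stacks = []
    for path in paths:
        pdb_file = pdbio.PDBFile.read(str(path))
        model = pdb_file.get_structure()
        if isinstance(model, struc.AtomArray):
            model = struc.stack([model])
        stacks.append(model)

    first = stacks[0]
    for stack in stacks[1:]:
        if stack.array_length() != first.array_length():
            raise FormatError("atom count differs between trajectory files")
    coords = np.concatenate([s.coord for s in stacks], axis=0)
    segment_lengths = [s.stack_depth() for s in stacks]

    roles = np.array(
        [_role_for_chain_id(cid, topology) for cid in first.chain_id], dtype="<U8"
    )
    catalog = AtomCatalog(
        chain_role=roles,
        chain_id=np.asarray(first.chain_id),
        residue_number=np.asarray(first.res_id, dtype=int),
        residue_name=np.asarray(first.res_name),
        atom_name=np.asarray(first.atom_name),
    )
    traj = Trajectory(coords, catalog, frame_interval_ps, segment_lengths)

    present_roles = set(catalog.chain_role) - {WATER_ROLE}
    declared = {c.role for c in topology.chains}
    if present_roles != declared:
        raise ResolutionError(
            f"trajectory chains {sorted(present_roles)} do not match "
            f"declared roles {sorted(declared)}"
        )
    for gate in topology.gates:
        catalog.resolve_many(topology.gate_selectors(gate))
    return traj


def write_trajectory(traj: Trajectory, path, topology: ReceptorTopology | None = None) -> None:
    """Write a trajectory as a multi-model PDB file (3-decimal coordinates)."""
    n = traj.n_atoms
    stack = struc.AtomArrayStack(traj.n_frames, n)
    stack.coord[:] = traj.coords
    stack.chain_id = np.asarray(traj.catalog.chain_id, dtype="<U4")
    stack.res_id = np.asarray(traj.catalog.residue_number, dtype=int)
    stack.res_name = np.asarray(traj.catalog.residue_name, dtype="<U5")
    stack.atom_name = np.asarray(traj.catalog.atom_name, dtype="<U6")
    stack.element = np.array(
        ["O" if r == "HOH" else "C" for r in traj.catalog.residue_name], dtype="<U2"
    )
    stack.hetero = np.asarray(traj.catalog.residue_name == "HOH")
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))
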