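"""Receptor architecture: chains, domains, gates, bridge residues.

The receptor is a pseudo-symmetric heterotetramer with two GluN1 and two
GluN2B subunits arranged alternately (roles ``GluN1_A``, ``GluN2B_B``,
``GluN1_C``, ``GluN2B_D``).  Each subunit stacks three domains: the
amino-terminal domain (ATD) on top, the ligand-binding domain (LBD) in
the middle and the transmembrane domain (TMD) anchored in the membrane.
The four pore-lining M3 helices of the TMD carry two constrictions: the
main TTTT gate (GluN1 Thr648 / GluN2B Thr647) and the auxiliary LILI
gate above it (GluN1 Leu657 / GluN2B Ile655).

A :class:`ReceptorTopology` resolves symbolic selections (gate residues,
bridge triad residues, domain blocks) against a declared residue
numbering; all numbering is author/UniProt-aligned, 1-based, inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import yaml

from .errors import ConfigurationError

CHAIN_ROLES = ("GluN1_A", "GluN2B_B", "GluN1_C", "GluN2B_D")
SUBUNIT_KINDS = ("GluN1", "GluN2B")
DOMAIN_NAMES = ("ATD", "LBD", "TMD")

_TOP_KEYS = {"chains", "domains", "gates", "bridges", "reference_residues", "pore_axis"}
_CHAIN_KEYS = {"id", "role", "range"}


def role_kind(role: str) -> str:
    """Subunit kind ('GluN1' or 'GluN2B') of a chain role."""
    kind = role.split("_")[0]
    if kind not in SUBUNIT_KINDS:
        raise ConfigurationError(f"unknown chain role {role!r}")
    return kind


@dataclass(frozen=True)
class ResidueSelector:
    """A single-atom selection: chain role + residue number + atom name."""

    chain_role: str
    residue_number: int
    residue_name: str | None = None
    atom_name: str = "CA"

    def __post_init__(self):
        if self.chain_role not in CHAIN_ROLES:
            raise ConfigurationError(
                f"chain_role must be one of {CHAIN_ROLES}, got {self.chain_role!r}"
            )


@dataclass(frozen=True)
class ChainSpec:
    chain_id: str
    role: str
    first_residue: int
    last_residue: int

    @property
    def kind(self) -> str:
        return role_kind(self.role)

    def contains(self, residue_number: int) -> bool:
        return self.first_residue <= residue_number <= self.last_residue


@dataclass
class ReceptorTopology:
    """Fully resolved chain/domain/gate/bridge architecture.

    ``domains`` maps subunit kind -> domain name -> list of [start, end]
    intervals; ``gates`` maps gate name -> kind -> (residue_number,
    residue_name); ``bridges`` maps triad member ('arg', 'asp', 'glu') ->
    (kind, residue_number, residue_name).
    """

    chains: list[ChainSpec]
    domains: dict
    gates: dict
    bridges: dict
    reference_residues: dict
    pore_axis: tuple = (0.0, 0.0, 1.0)
    n_termini: dict = field(default_factory=dict)

    # -- validation ---------------------------------------------------

    def validate(self) -> None:
        if len(self.chains) != 4:
            raise ConfigurationError(f"expected 4 chains, got {len(self.chains)}")
        roles = tuple(c.role for c in self.chains)
        if roles != CHAIN_ROLES:
            raise ConfigurationError(
                f"chains must declare roles {CHAIN_ROLES} in order, got {roles}"
            )
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != 4:
            raise ConfigurationError(f"duplicate chain IDs: {ids}")
        for kind in SUBUNIT_KINDS:
            if kind not in self.domains:
                raise ConfigurationError(f"missing domain table for {kind}")
            self._check_domains(kind)
        for gate, table in self.gates.items():
            for kind in SUBUNIT_KINDS:
                if kind not in table:
                    raise ConfigurationError(f"gate {gate} missing {kind} residue")
                self._check_in_range(kind, table[kind][0], f"gate {gate}")
        for member, (kind, resnum, _name) in self.bridges.items():
            self._check_in_range(kind, resnum, f"bridge {member}")

    def _check_domains(self, kind: str) -> None:
        table = self.domains[kind]
        covered: set[int] = set()
        for dom in DOMAIN_NAMES:
            if dom not in table:
                raise ConfigurationError(f"{kind} missing {dom} interval(s)")
            residues = set()
            for start, end in table[dom]:
                if start > end:
                    raise ConfigurationError(f"{kind} {dom}: bad interval {start}-{end}")
                residues.update(range(start, end + 1))
            if covered & residues:
                raise ConfigurationError(f"{kind}: overlapping domain intervals at {dom}")
            covered |= residues
        m3 = self.domain_residues(kind, "M3")
        if not m3 <= self.domain_residues(kind, "TMD"):
            raise ConfigurationError(f"{kind}: M3 selection must lie within the TMD")
        outer = self.domain_residues(kind, "outer_atd")
        if not outer <= self.domain_residues(kind, "ATD"):
            raise ConfigurationError(f"{kind}: outer_atd must lie within the ATD")

    def _check_in_range(self, kind: str, resnum: int, what: str) -> None:
        for chain in self.chains:
            if chain.kind == kind and not chain.contains(resnum):
                from .errors import ResolutionError

                raise ResolutionError(
                    f"{what}: residue {resnum} outside {chain.role} "
                    f"range {chain.first_residue}-{chain.last_residue}"
                )

    # -- lookups ------------------------------------------------------

    def chain_by_role(self, role: str) -> ChainSpec:
        for chain in self.chains:
            if chain.role == role:
                return chain
        raise ConfigurationError(f"no chain with role {role!r}")

    def chain_by_id(self, chain_id: str) -> ChainSpec:
        for chain in self.chains:
            if chain.chain_id == chain_id:
                return chain
        raise ConfigurationError(f"no chain with ID {chain_id!r}")

    def roles_of_kind(self, kind: str) -> list[str]:
        return [c.role for c in self.chains if c.kind == kind]

    def domain_intervals(self, kind: str, domain: str) -> list[tuple[int, int]]:
        try:
            return [tuple(iv) for iv in self.domains[kind][domain]]
        except KeyError as exc:
            raise ConfigurationError(f"no domain {domain!r} for {kind}") from exc

    def domain_residues(self, kind: str, domain: str) -> set[int]:
        residues: set[int] = set()
        for start, end in self.domain_intervals(kind, domain):
            residues.update(range(start, end + 1))
        return residues

    def block_residues(self, block: str) -> dict[str, set[int]]:
        """Residue sets per subunit kind for a domain block spec.

        ``block`` is 'ATD', 'LBD' or 'ATD+LBD' (the extracellular part).
        """
        parts = [p.strip() for p in block.split("+")]
        for p in parts:
            if p not in ("ATD", "LBD"):
                raise ConfigurationError(f"unknown block component {p!r}")
        return {
            kind: set().union(*(self.domain_residues(kind, p) for p in parts))
            for kind in SUBUNIT_KINDS
        }

    def gate_selectors(self, gate: str) -> list[ResidueSelector]:
        """One Cα selector per chain for a named gate, in chain order."""
        if gate not in self.gates:
            raise ConfigurationError(
                f"unknown gate {gate!r}; declared gates: {sorted(self.gates)}"
            )
        table = self.gates[gate]
        out = []
        for chain in self.chains:
            resnum, resname = table[chain.kind]
            out.append(ResidueSelector(chain.role, resnum, resname))
        return out

    def bridge_selectors(self, pair: str) -> dict[str, ResidueSelector]:
        """Triad selectors for one GluN1/GluN2B pair ('AB' or 'CD').

        The arginine and glutamate live on the GluN1 chain of the pair,
        the aspartate on the neighbouring GluN2B chain.
        """
        if pair == "AB":
            glun1, glun2b = "GluN1_A", "GluN2B_B"
        elif pair == "CD":
            glun1, glun2b = "GluN1_C", "GluN2B_D"
        else:
            raise ConfigurationError(f"bridge pair must be 'AB' or 'CD', got {pair!r}")
        out = {}
        for member, (kind, resnum, resname) in self.bridges.items():
            role = glun1 if kind == "GluN1" else glun2b
            out[member] = ResidueSelector(role, resnum, resname)
        return out

    def reference_selector(self, role: str, name: str) -> ResidueSelector:
        kind = role_kind(role)
        try:
            resnum = self.reference_residues[kind][name]
        except KeyError as exc:
            raise ConfigurationError(f"no reference residue {name!r} for {kind}") from exc
        return ResidueSelector(role, resnum)

    def terminus_selectors(self) -> list[ResidueSelector]:
        """N-terminal Cα selector per chain, in chain order."""
        return [
            ResidueSelector(c.role, self.n_termini[c.kind]) for c in self.chains
        ]


def _parse_gate_entry(entry: dict, where: str) -> tuple[int, str]:
    unknown = set(entry) - {"residue_number", "residue_name"}
    if unknown:
        raise ConfigurationError(f"{where}: unknown keys {sorted(unknown)}")
    return int(entry["residue_number"]), str(entry.get("residue_name", ""))


def load_topology(config_text: str) -> ReceptorTopology:
    """Parse a plain-text (YAML) topology document into a validated topology.

    Unknown top-level or per-chain keys are rejected so typos fail loudly.
    """
    doc = yaml.safe_load(config_text)
    if not isinstance(doc, dict):
        raise ConfigurationError("topology document must be a key-value mapping")
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
    for key in ("chains", "domains", "gates", "bridges"):
        if key not in doc:
            raise ConfigurationError(f"missing required section {key!r}")

    chains = []
    for entry in doc["chains"]:
        unknown = set(entry) - _CHAIN_KEYS
        if unknown:
            raise ConfigurationError(f"chain entry: unknown keys {sorted(unknown)}")
        lo, hi = entry["range"]
        chains.append(ChainSpec(str(entry["id"]), str(entry["role"]), int(lo), int(hi)))

    domains = {}
    n_termini = {}
    for kind, table in doc["domains"].items():
        if kind not in SUBUNIT_KINDS:
            raise ConfigurationError(f"unknown subunit kind {kind!r} in domains")
        domains[kind] = {}
        for dom, value in table.items():
            if dom == "n_terminus":
                n_termini[kind] = int(value)
                continue
            if dom not in DOMAIN_NAMES + ("M3", "outer_atd"):
                raise ConfigurationError(f"unknown domain name {dom!r} for {kind}")
            domains[kind][dom] = [[int(a), int(b)] for a, b in value]

    gates = {}
    for gate, table in doc["gates"].items():
        gates[gate] = {
            kind: _parse_gate_entry(table[kind], f"gate {gate}/{kind}")
            for kind in table
        }

    bridges = {}
    for member, entry in doc["bridges"].items():
        if member not in ("arg", "asp", "glu"):
            raise ConfigurationError(f"bridge member must be arg/asp/glu, got {member!r}")
        bridges[member] = (
            str(entry["subunit"]),
            int(entry["residue_number"]),
            str(entry.get("residue_name", "")),
        )

    refs = {
        kind: {name: int(num) for name, num in table.items()}
        for kind, table in doc.get("reference_residues", {}).items()
    }
    axis = tuple(float(x) for x in doc.get("pore_axis", (0.0, 0.0, 1.0)))

    topology = ReceptorTopology(
        chains=chains,
        domains=domains,
        gates=gates,
        bridges=bridges,
        reference_residues=refs,
        pore_axis=axis,
        n_termini=n_termini,
    )
    topology.validate()
    return topology


def default_topology_text() -> str:
    """The bundled default topology document (GluN1/GluN2B tetramer)."""
    return (
        resources.files("channelgate.data")
        .joinpath("default_topology.yaml")
        .read_text()
    )


def default_topology() -> ReceptorTopology:
    """Load the bundled default GluN1/GluN2B receptor topology."""
    return load_topology(default_topology_text())
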