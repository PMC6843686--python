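# Default GluN1/GluN2B heterotetramer architecture.
#
# Residue numbers are author (UniProt-aligned) numbering, 1-based and
# inclusive.  Chain IDs map PDB chains onto subunit roles; PDB chain
# order is not guaranteed, so the mapping is explicit.
chains:
  - id: A
    role: GluN1_A
    range: [23, 847]
  - id: B
    role: GluN2B_B
    range: [30, 852]
  - id: C
    role: GluN1_C
    range: [23, 847]
  - id: D
    role: GluN2B_D
    range: [30, 852]

# Per-subunit-kind domain intervals (disjoint within a chain).  M3 is the
# pore-lining helix subset of the TMD used as the superposition reference;
# outer_atd is the upper ATD lobe used for the lift-angle descriptor.
domains:
  GluN1:
    ATD: [[23, 400]]
    LBD: [[401, 539], [675, 788]]
    TMD: [[540, 674], [789, 843]]
    M3: [[634, 662]]
    outer_atd: [[23, 150]]
    n_terminus: 23
  GluN2B:
    ATD: [[30, 402]]
    LBD: [[403, 534], [677, 791]]
    TMD: [[535, 676], [792, 845]]
    M3: [[633, 661]]
    outer_atd: [[30, 150]]
    n_terminus: 30

# Channel constrictions: main TTTT gate (gating threonines) and the
# auxiliary LILI gate above it.
gates:
  TTTT:
    GluN1: {residue_number: 648, residue_name: THR}
    GluN2B: {residue_number: 647, residue_name: THR}
  LILI:
    GluN1: {residue_number: 657, residue_name: LEU}
    GluN2B: {residue_number: 655, residue_name: ILE}

# Asp-Arg-Glu salt-bridge triad: GluN1 Arg695 bridges GluN2B Asp786
# (inter-subunit) and GluN1 Glu522 (intra-subunit).
bridges:
  arg: {subunit: GluN1, residue_number: 695, residue_name: ARG}
  asp: {subunit: GluN2B, residue_number: 786, residue_name: ASP}
  glu: {subunit: GluN1, residue_number: 522, residue_name: GLU}

# Additional landmark residues used by distance descriptors and
# ligand-site bookkeeping.
reference_residues:
  GluN1: {Glu698: 698, Arg673: 673, Arg524: 524}
  GluN2B: {Leu795: 795, Arg519: 519}

# +z points toward the extracellular side.
pore_axis: [0.0, 0.0, 1.0]
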