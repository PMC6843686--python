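# channelgate

Trajectory analysis for the gating cycle of the GluN1/GluN2B NMDA
receptor — a heterotetrameric glutamate-gated ion channel whose two
GluN1 and two GluN2B subunits each stack an amino-terminal domain
(ATD), a ligand-binding domain (LBD) and a transmembrane domain (TMD).
The package quantifies, from molecular-dynamics-style coordinate
trajectories, the observables that describe channel opening and
closing:

- **Gate geometry** — diagonal Cα–Cα distances across the pore at the
  main TTTT constriction (GluN1 Thr648 / GluN2B Thr647) and the
  auxiliary LILI constriction (GluN1 Leu657 / GluN2B Ile655); kernel
  density mode detection for the bimodal open-state distance
  distribution; open probability above a permeability threshold;
  asymmetry of the M3 helix arrangement; water occupancy of the
  inter-gate pore section.
- **Domain kinematics** — after Kabsch superposition onto the TMD M3
  helices of a reference frame, the residual rotation of the
  extracellular block (ATD, LBD or ATD+LBD) is decomposed axis–angle
  and reported as a signed twist about the pore axis
  (positive = clockwise viewed from outside the cell), together with
  the elevation ("lift") of the outer ATD subdomains relative to the
  ATD centre of mass and the ATD N-termini distance network.
- **Salt-bridge states** — the GluN1 Arg695 / GluN2B Asp786 / GluN1
  Glu522 triad is classified per frame as OPEN_LIKE (double bridge),
  CLOSED_LIKE (intra-subunit Glu contact only) or NONE by a distance
  criterion (4.0 Å between charged groups; 10.0 Å Cα proxy).
- **Markov state model** — k-medoids clustering of frames under the
  all-Cα minRMSD metric, sliding-window transition counts at a lag
  time τ (default 0.1 ns, six states), the row-stochastic transition
  matrix T, stationary distribution π (πT = π), implied timescales
  t_i = −τ/ln|λ_i|, net stationary fluxes π_iT_ij − π_jT_ji,
  Chapman–Kolmogorov validation of T(kτ) against T(τ)^k, and random
  representative ensembles (50 structures per state).
- **Conservation** — exact column profiles, motif counts (e.g. the GDG
  motif around GluN2B Asp786) and subunit-group-specific residue
  distributions from user-supplied FASTA multiple sequence alignments.
- **Synthetic generator** — a coarse Cα pseudo-receptor with programmed
  twist/lift schedules, stochastic gate models, bridge toggles and
  Markov jump dynamics, so every stage can be validated against known
  ground truth without any external data.

Trajectories are multi-model PDB files (optionally pooled); the
receptor architecture is a plain-text YAML document (a bundled default
encodes the GluN1/GluN2B numbering: GluN1 23–847 with TMD 540–674 ∪
789–843, GluN2B 30–852 with TMD 535–676 ∪ 792–845).

## Worked example

```python
import channelgate as cg
from channelgate.synthetic import make_preset, generate_trajectory

# a closing run: extracellular twist ramped to 45 deg, GluN2B gate
# tightening, bridge toggled open -> closed at mid-trajectory
spec, base, top = make_preset("closing", seed=1, n_frames=1500)
traj, truth = generate_trajectory(spec, base, top)

tw = cg.twist_series(traj, top, block="ATD+LBD", reference_frame=0)
print(f"final twist {tw.twist_deg[-1]:.2f} deg")

gs = cg.gate_series(traj, top, "TTTT")
print(f"mean asymmetry {float(cg.asymmetry_index(gs).mean()):.2f} A")

st = cg.bridge_state_series(traj, top, pair="AB")
print("bridge transition at frame", st.transitions)
```

prints

```
final twist 45.01 deg
mean asymmetry 5.97 A
bridge transition at frame [750]
```

The recovered twist matches the 45° programmed closing rotation within
the analysis noise; the positive asymmetry (GluN1 diagonal minus GluN2B
diagonal ≈ 6 Å) is the closed-state signature of a tight GluN2B M3 pair
with separated GluN1 helices; and the salt-bridge classifier finds the
single programmed open→closed toggle at frame 750.

The same stages are available from the shell:

```sh
channelgate simulate --preset opening --seed 1 --frames 15000 --out traj.pdb
channelgate gates --traj traj.pdb --gate TTTT --threshold 10.0 --out gates.csv
channelgate twist --traj traj.pdb --block ATD+LBD --ref 0 --out twist.csv
channelgate msm --traj traj.pdb --states 6 --lag-ns 0.1 --seed 1 --out msm.json
channelgate run --config config.yaml --outdir results/
```

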