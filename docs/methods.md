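# Methods

## Scope and model of the receptor

The package analyses coordinate trajectories of a pseudo-symmetric
GluN1/GluN2B heterotetramer.  Each subunit is treated as three stacked
rigid-ish blocks — ATD (top), LBD (middle), TMD (membrane-anchored
bottom) — with the four TMD M3 helices lining the ion channel.  Two
constrictions define permeability: the main TTTT gate (GluN1 Thr648,
GluN2B Thr647) and the auxiliary LILI gate above it (GluN1 Leu657,
GluN2B Ile655).  All residue numbering is author/UniProt-aligned,
1-based and inclusive (GluN1 23–847, TMD 540–674 ∪ 789–843; GluN2B
30–852, TMD 535–676 ∪ 792–845); chain-ID→role mapping is declared in
the topology document because PDB chain order is not guaranteed.
Missing atoms are a hard error, never silently skipped: every
descriptor indexes fixed atoms.

## Gate geometry

Permeability is read from the two role-homotypic diagonal Cα–Cα
distances across the pore (GluN1–GluN1 and GluN2B–GluN2B), not from a
pore-radius profile — the diagonals are the directly interpretable
printed observable of this kind of analysis.  A frame counts as open
when **both** diagonals exceed a diameter threshold; the default
threshold is 10.0 Å, the midpoint between the two open-state
distribution maxima (8.5 and 11.5 Å), and is configurable because the
diameter required for ion transport is itself uncertain.

Mode detection smooths the distance sample with a Gaussian kernel of
fixed bandwidth (default 0.5 Å — about one component standard
deviation, wide enough to suppress sampling ripple and narrow enough to
keep 3 Å-separated modes distinct) evaluated on a 0.05 Å grid; local
maxima are modes (plateau ties break toward the lower distance), and
basin weights are the sample fractions between consecutive density
minima.  Distance histograms default to 0.5 Å bins.  Reliable
multi-mode detection needs on the order of ≥100 samples; the degenerate
all-equal sample returns a single mode of weight 1.

The asymmetry index is the GluN1 diagonal minus the GluN2B diagonal;
positive values are the closed-state signature (tight GluN2B pair,
separated GluN1 pair), and the index is exactly antisymmetric under
role exchange.

Hydration counts water oxygens whose axial coordinate lies strictly
between the TTTT and LILI gate-plane positions and whose radial
distance from the pore axis is at most a configurable radius.  The
per-frame pore axis is the line through the TTTT-Cα centroid and the
LILI-Cα centroid: the four TTTT Cα atoms alone are nearly coplanar, so
their principal axis is transverse (degenerate as a pore axis), whereas
the two gate centroids define the local channel direction robustly.

## Domain kinematics

Every frame is first superposed onto a reference frame (default frame
0) using the Cα atoms of the four M3 helices (Kabsch, proper rotation
enforced), which removes global rigid motion; all kinematic outputs are
therefore invariant under whole-receptor rotation/translation.  The
residual rotation of the analysis block (ATD, LBD or ATD+LBD; the block
may not overlap the alignment selection) is fitted by a second Kabsch
superposition and decomposed into a rotation vector; the twist is its
component along the pore axis, with the full 3D rotation magnitude kept
as a diagnostic.

Conventions fixed here (the descriptors are meaningless without them):

- the longitudinal (pore) axis is the first principal axis of the
  reference frame's M3 Cα set, oriented toward the extracellular side
  (toward the ATD centroid);
- positive twist is clockwise viewed from the extracellular side
  looking down the axis, i.e. twist = −(rotation vector · axis);
  the synthetic generator programs rotations in the same convention,
  so signs are self-consistent end to end;
- the lift angle of a chain is the elevation (angle above the
  horizontal plane) of the vector from the chain's whole-ATD centre of
  mass to its outer (upper-lobe) subdomain centroid, averaged over the
  four chains and reported as the change from the reference frame.
  The outer-subdomain residue interval (default: the first ~128
  residues of each ATD) is a topology-document choice, since upper-lobe
  boundaries are not a universally fixed annotation.

Noiseless programmed rotations recover to better than 0.01°; coaxial
rotations compose additively (mod 360°).

## Salt-bridge classification

The triad — GluN1 Arg695 bridging GluN2B Asp786 (inter-subunit) and
GluN1 Glu522 (intra-subunit) — is classified per frame from two
distances: OPEN_LIKE when both are within the cutoff (double bridge),
CLOSED_LIKE when only the Arg–Glu contact remains, NONE otherwise
(an Asp-only contact is not a defined state and maps to NONE).
Distances are minimum separations between the charged heavy-atom groups
(Arg NE/NH1/NH2 vs carboxylate oxygens) with a 4.0 Å default cutoff —
the standard structural-biology salt-bridge criterion — or Cα–Cα
proxies with a 10.0 Å cutoff for Cα-only models.  Both GluN1/GluN2B
pairs of the tetramer are classified independently.  Labels are
deterministic and piecewise constant in the distances; raising the
cutoff can only move frames out of NONE.  An optional minimum-dwell
filter suppresses single-frame flickers at the cutoff boundary; it is
off by default so the transition log is exact.

## Markov state model

Frames are discretised by k-medoids clustering under the pairwise
minimum-RMSD metric over all Cα atoms (no a-priori residue selection,
no feature embedding): k-medoids works directly in a metric space
without coordinates, which is why it is used here.  Seeding is
deterministic — the global medoid first, then maximin selection — and
trajectories longer than a landmark budget (default 2000 frames) are
clustered on a seed-deterministic subsample with all remaining frames
assigned to the nearest medoid.  The batched minRMSD kernel is a
vectorised closed-form Kabsch (3×3 SVD per pair, smallest singular
value sign-corrected for properness), cross-checked in the tests
against a rotation-search brute force.

Estimation at lag τ (default 0.1 ns; the lag must be an integer
multiple of the frame interval, default 10 ps) uses the sliding-window
count estimator restricted to contiguous trajectory segments; rows
without counts are flagged.  No detailed-balance symmetrisation is
applied by default (an optional reversible estimator symmetrises the
counts).  π is the leading left eigenvector of T on the largest
strongly connected state set (zero elsewhere, with a warning);
implied timescales are −τ/ln|λ_i| for the non-leading eigenvalues; flux
is reported as the stationary net flux π_iT_ij − π_jT_ji.  The
Chapman–Kolmogorov test compares T(τ)^k against the directly estimated
T(kτ) element-wise (default tolerance 0.1 absolute; k values without
sufficient frames are skipped with a warning).  Representative
ensembles draw 50 frames per state uniformly without replacement
(all frames when a state is smaller), reproducibly per seed.

## Synthetic generator

The generator exists so that every stage can be validated against known
ground truth; it produces geometry with programmed statistics, not
physical dynamics — no force field, no energetics, no solvent physics.

The base structure is a Cα-only tetramer built deterministically per
seed: chains at azimuths 0/90/180/270° around the +z pore axis, one
template per subunit kind (hence exact C2 pseudo-symmetry), M3 as ideal
helices (1.5 Å rise, 100°/residue) whose gating-threonine phase points
into the pore so the TTTT diagonal equals twice the pore radius by
construction, and quasi-uniform jittered point clouds for the remaining
TMD, LBD and ATD (outer lobe as a distinct upper sub-cloud).  The
salt-bridge triad and landmark residues are pinned at interface
positions with the Glu–Asp separation fixed at 9 Å so that both
programmed bridge states are geometrically constructible.

Frames apply, in order: outer-lobe lift rotations (the lobe is part of
the ATD centre of mass, so the rotation angle is solved per frame by
bisection to make the *realised* elevation change equal the programmed
one), extracellular twist about the pore axis (clockwise convention as
above), per-kind radial ATD drift, gate-distance overrides (the
sampled diagonal takes precedence over rigid-body placement, keeping
gate statistics and kinematics independently controllable), landmark
pair-distance overrides (the partner is placed at the sampled distance
along the current direction), bridge-triad placement by two-sphere
intersection per the scheduled label, optional water placement, then
isotropic Gaussian coordinate noise (default σ = 0.1 Å).  Every
programmed value is recorded per frame in a ground-truth log.

Default statistical parameters mirror the documented study conditions:
10 ps frames; the open-state GluN1 gate as an equal-weight mixture at
8.5/11.5 Å with σ = 0.5 Å; closing twist endpoint 45° (relaxation: 15°
ATD twist with 10° lift); the closed gate as GluN1 12.5 ± 0.4 Å over
GluN2B 6.5 ± 0.3 Å (asymmetric, values chosen to bracket the open-state
modes since closed-state distances are not printed); liganded landmark
distances Leu795–Glu698 = 7.9 ± 0.9 Å and Leu795–Arg673 = 9.9 ± 0.3 Å;
three replicas per condition with closing endpoints spanning 28–45°.

The six MSM basins are copies of the base structure at extracellular
twists 0–45° in 9° steps, far enough apart in minRMSD (≳2 Å) that
clustering at noise σ = 0.25 Å is essentially exact.  The programmed
jump chain is a per-frame Markov chain with stay probability 0.7 and
uniform off-diagonal mass.  That mixing rate is a design constraint,
not a free dial: the sliding-window estimator's per-element noise grows
with basin dwell (overlapping windows are correlated), while the
stationary-distribution noise grows with the relaxation time, so a
chain must mix on the order of a few frames for both recovery
tolerances documented in the tests (T within 0.02 element-wise, π
within 0.03 at 10⁵ frames) to be statistically attainable at all.  The
MSM validation trajectory uses the compact-resolution receptor
(~210 Cα) and float32 frames; at 10⁵ frames the clustering subsample is
1000 landmark frames.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: internal domain flexibility (blocks move
rigidly), correlated motions between descriptors (gate, bridge and
twist schedules are independent unless programmed jointly), realistic
water dynamics (waters are placed, not simulated), side-chain packing
(Cα only, except constructed bridge test frames), and any free-energy
or kinetic realism of the basin dwell times.

## Numerical choices and degenerate inputs

- Superposition requires ≥3 non-collinear points; collinear or
  coincident sets raise a geometry error (the rotation is not unique).
- Mode detection on a zero-variance sample short-circuits to a single
  exact mode; KDE bandwidth is absolute (Å), converted internally to a
  factor of the sample standard deviation.
- k-medoids raises an error when fewer distinct conformations than
  requested states exist (maximin distance hits zero during seeding).
- The stationary eigenvector is taken with absolute values and
  renormalised to guard against sign/phase artefacts of the
  eigensolver; row-stochasticity and πT = π hold to 1e−10.
- Transition counting never crosses segment boundaries of pooled
  trajectories.
- All randomness flows through `numpy.random.default_rng` seeds;
  identical seeds give bit-identical structures, trajectories, cluster
  seedings and ensemble draws.

## Problem sizes

Validation and the results script use: 1500-frame closing and 500-frame
relaxation trajectories (noise 0.1 Å), 15 000 gate-distance samples,
7500-frame liganded trajectories, three 600-frame closing replicas, and
a 10⁵-frame six-basin jump trajectory for the MSM stage.  These sizes
put sampling error comfortably inside each documented tolerance while
keeping a full run in minutes on one CPU.

## Known limitations

- The hydration cylinder uses a straight axis between the two gate
  centroids; a curved pore would need an axis spline.
- The CK test reports element-wise maximum deviation without error
  bars; a Bayesian MSM would quantify count uncertainty.
- Conservation analysis consumes alignments as given — no alignment
  construction, no phylogenetic weighting, so over-represented clades
  inflate conservation estimates.
- The open/closed threshold and the salt-bridge cutoffs are criteria,
  not measurements; conclusions near the boundaries are
  threshold-sensitive by construction, which is why both are exposed as
  parameters.
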