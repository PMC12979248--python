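# Methods

This note documents the models, estimators and numerical choices behind
`memdiverge`, and what the synthetic ground-truth generators do and do not
emulate.

## Coordinate model and units

All lengths are nanometres and all times nanoseconds internally;
conversion happens only at file boundaries (PDB files are Ångström).
Only orthorhombic boxes are supported — every analysis treats the membrane
normal as the laboratory z axis, and axis-aligned boxes keep the
minimum-image convention exact. Triclinic input raises an explicit error
rather than silently approximating. Trajectory formats without time
stamps (multi-model PDB, most DCDs) leave `dt` unset; kinetic analyses
then refuse to run until the configuration supplies `dt` explicitly —
there is no silent default frame spacing.

## Bilayer deformation

The bilayer midplane is defined per frame as the mean z coordinate of all
phosphate beads; phosphate z positions are normalised to it, and leaflet
labels (EC = extracellular/luminal, IC = intracellular/cytoplasmic) are
fixed from the sign of the normalised z at the assignment frame (frame 0
by default). Leaflet flip-flop is not tracked: at the time scales and
lipid compositions this analysis targets, inter-leaflet exchange is
negligible.

Deformation maps are 2D (x, y) bins of time-averaged normalised z per
leaflet, computed in a protein-centred frame: each frame is re-centred on
the protein's (x, y) centroid, with no rotational fitting, so that
elastic-network wobble of a coarse-grained protein does not blur the map.
The default bin edge is 0.4 nm (about one CG bead diameter). Empty bins
are reported as missing (NaN with zero count), never zero-filled, and the
count-weighted mean of the binned values reproduces the leaflet mean
exactly.

Global deformation is the reduction in bilayer width between the most
extreme deformation adjacent to the protein and the far field: the mean
|normalised z| over all phosphates (EC + IC) minus the |mean shell z| at
the extreme residues (EC + IC), where a residue's shell is all phosphates
within 0.8 nm of any of its particles. Local deformation replaces the
far-field baseline with protein-contacting phosphates only (within
0.8 nm of any protein particle). Both are per-frame series, reported as
mean ± SD. The width reduction is the **sum** of the per-leaflet
deviations; per-leaflet components are also emitted so either convention
can be reported. Negative reductions are reported signed, with a warning,
never clipped.

Extreme residues can be supplied explicitly or found by an automatic
scan (the residue minimising |shell z| per leaflet). The scan carries a
known conditioning bias: a residue sitting below the deformed surface
captures surface phosphates only in frames where thermal noise pulls them
downward, so its conditional shell mean is biased toward the midplane
(about +0.06 nm on the recovered deformation at 0.1 nm noise). Recovery
benchmarks therefore use the explicit designated-residue mode, which is
also how the original-style analysis is specified (a marked residue
list); the scan is a convenience for exploration.

## Lipid-binding kinetics

Contacts use a dual-cutoff (hysteresis) scheme: a residue–lipid contact
switches on only when the minimum inter-particle distance drops below
0.475 nm and off only when it exceeds 0.7 nm, which suppresses boundary
flicker at a single threshold. The initial state is on iff the first
frame is already below the lower cutoff. With equal cutoffs the scheme
reduces to a plain threshold.

Residence times come from the empirical survival function
S(t) = fraction of contact durations ≥ t, evaluated on the observed
duration grid (0 prepended, one point beyond the maximum appended), and a
least-squares biexponential fit
S(t) ≈ A·exp(−k₁t) + (1−A)·exp(−k₂t) with k₁ ≤ k₂. The residence time is
τ = 1/k₁, the slow component, matching the convention that τ = 1/k_off of
the fitted decay; both components are always emitted. Numerical choices:

- Multi-start Levenberg–Marquardt (four initialisations scaled by the
  mean duration) with box constraints A ∈ [0, 1], k > 0; the best
  sum-of-squares wins.
- A fitted slow component carrying less than 5% of the weight is treated
  as unidentifiable — its rate is essentially unconstrained by the data
  and would dominate τ — and the fit collapses to a monoexponential.
- All-equal durations make k₂ unidentifiable; the fallback is the
  exponential maximum-likelihood rate (1/mean), flagged monoexponential.
- Fewer than 5 events: only the mean duration is reported.
- Durations censored by the trajectory end are kept in S(t) and flagged;
  dropping them would bias τ low for long-lived sites.
- Asymmetric confidence bounds on τ are the 2.5/97.5 percentiles over
  200 bootstrap resamples of the durations (seeded).

Binding sites are residue communities: each residue with at least one
contact event is a node carrying its occupancy count series (summed over
lipids); edges are weighted by the pairwise Pearson correlation of these
series, non-positive weights dropped; the Louvain algorithm (seeded,
resolution 1.0 by default) partitions the graph, and communities smaller
than 3 residues are discarded. Correlating boolean occupancy rather than
raw distances is the robust reading of distance-vector correlation and is
the default; a configuration switch selects minimum-distance series
instead. Site-level kinetics apply the hysteresis rule to the per-lipid
minimum distance over all site residues, making durations independent of
residue ordering; the representative pose is the (lipid, frame) pair
maximising simultaneous site-residue contacts, earliest frame on ties —
a deliberate simplification of density-based pose ranking.

## Residue interactions

A salt bridge is present in a frame when any atom from the anionic set
(Glu OE1/OE2, Asp OD1/OD2) is within 0.4 nm of any atom from the cationic
set (Lys NZ, Arg NH1/NH2/NE, protonated His ND1/NE2). Histidine counts
as cationic only when the configuration marks it protonated; neutral
tautomers (e.g. the Nδ form, CHARMM HSD) are rejected as cations unless
flagged, but can of course act as hydrogen-bond donors.

Hydrogen bonds use a standard geometric definition: donor–acceptor
distance ≤ 0.35 nm and donor–H–acceptor angle ≥ 150°, both configurable.
Topologies without hydrogens produce an explicit error advising
distance-only criteria.

Prevalence is the fraction of frames an interaction is present, per
replicate, with mean ± SD across replicates (SD 0 for a single
replicate). Tail dissociation is classified from an RMSD series measured
after superposing each frame on a separate fit selection (the measured
selection is carried by the fitted transform, never refit): the tail is
dissociated when the RMSD exceeds a threshold for a full window of
consecutive frames (defaults 0.6 nm and 25 frames; both are declared
substitutes for unpublished values and are recorded in output metadata).
The rupture frame is the first frame of the qualifying run, and the
result restates the bond-rupture correlation as whether bond prevalence
after rupture is lower than before.

## Hydration

The water density grid counts water oxygens per voxel per frame, averages
over frames and divides by the voxel volume (number density, nm⁻³),
reported only within 1 nm of the protein. Number density rather than
occupancy fraction makes the conservation property exact: the integral of
the masked density equals the mean per-frame water count in the masked
region by construction. Voxel edge defaults to 0.1 nm. Grids export to
OpenDX.

Pocket hydration counts distinct water oxygens within 0.4 nm of any atom
of a substrate subset per frame — the acyl tail up to and including the
thioester sulfur, or the CoA headgroup (all other substrate atoms) — and
divides by the subset's atom count, so pockets of different size compare
directly. A water near several subset atoms counts once per subset.
Frames are weighted equally (uniform dt). When a reference structure and
fit selection are given, frames are rigid-body aligned (Kabsch) before
counting, and an alignment RMSD above 0.5 nm triggers a
reference-mismatch warning. Cross-protein comparisons of per-replicate
means reuse the shared t-test; SDs are across replicates by default, with
a frames mode available.

## Hydrophobic gating

Per frame, the gate statistic is the minimum distance between side-chain
heavy atoms of the two gating residues (hydrogens excluded; glycine falls
back to Cα) versus the number of water oxygens within a 0.4 nm sphere
centred on the minimum-image midpoint of the pair's Cα atoms, the sphere
tracking the midpoint every frame. The joint distribution is binned
(integer water counts, 0.05 nm distance bins) and summarised by quadrant
fractions at 0.35 nm (direct residue interaction at or below) and 2
waters ("dry", i.e. permeation prevented, strictly below).

## Statistics

Group comparisons use the two-sided unpaired Student's t test with pooled
variance (df = n₁ + n₂ − 2); Welch's correction is available by flag.
Significance stars follow ns for p > 0.05 and ∗/∗∗/∗∗∗/∗∗∗∗ at
p ≤ 0.05/0.01/0.001/0.0001, inclusive at each boundary, with the smallest
satisfied threshold reported. Both groups constant and equal yields
t = 0, p = 1 rather than NaN. No multiple-testing correction is applied.

## Synthetic ground truth

The generators place particles with prescribed statistical structure —
no forcefield, no integrator — so each estimator has a parameter-recovery
test at desk scale. All randomness flows through one seeded NumPy
generator; identical seeds give bit-identical trajectories, and every
generator emits its planted parameters as a JSON sidecar.

- **Bilayer**: phosphate beads on jittered square grids at z = ±half-width
  (2 nm default, 400 lipids per leaflet in a 15 nm box, 200 frames, 0.1 nm
  Gaussian noise), pulled toward the midplane by a radial funnel around a
  static protein column. The funnel holds full depth inside a 0.8 nm core
  (matching the analysis shell) with a Gaussian shoulder (0.6 nm scale)
  outside, so the planted amplitude is exactly realised at the extreme and
  is a well-defined recovery target; a pure Gaussian profile would leave
  the amplitude unattained by any finite shell average. Recovery carries a
  small negative bias (≤ 0.06 nm at the largest amplitudes) because the
  funnel's footprint slightly depresses the all-phosphate far-field
  baseline.
- **Binding kinetics**: each lipid is an independent continuous-time
  two-state Markov chain (k_on = 0.1 ns⁻¹, k_off = 0.05 ns⁻¹ defaults,
  optionally a two-rate mixture for biexponential residence laws) sampled
  every 0.5 ns for 800 frames; bound lipids sit below the lower cutoff of
  the site residues and unbound lipids beyond the upper cutoff, so the
  dual-cutoff detector reproduces the sampled chain exactly. Exponential
  waiting times give exact exponential duration laws for fit validation.
  Point-sampling at dt adds a small discretisation bias to short
  durations; a warning fires when dt exceeds 1/(10·k_off).
- **Pocket waters**: Poisson-distributed water counts (rate 3 per frame
  by default) placed uniformly within the 0.4 nm pocket shell; surplus
  water particles are parked far from the pocket so the particle count is
  constant.
- **Gating**: i.i.d. Bernoulli open/closed states per frame; closed
  frames place the side-chain tips at 0.30 nm with a dry midpoint sphere,
  open frames at 0.55 nm with a configured number of sphere waters.
- **Bond toggle**: Bernoulli bond formation (donor–acceptor at 0.28 nm
  when bonded, 0.60 nm otherwise, with an on-axis hydrogen) plus a Cα
  tail rigidly displaced by 1 nm from a configured jump frame against
  static fit anchors.

What passing recovery tests show — and what they do not: the estimators
are unbiased and correctly calibrated against the statistical structure
each analysis assumes (Gaussian surface noise, Markov switching, Poisson
occupancy, Bernoulli toggling). Real trajectories add correlated lipid
motion, undulations, non-exponential unbinding, water structure and
alignment error; agreement on synthetic data validates the machinery, not
those physical assumptions.

## Problem sizes

Default benchmark sizes (200-frame bilayers of 800 phosphates, 800-frame
kinetics runs of 30 lipids yielding ~400 events, 1000-frame hydration and
gating runs, 1500-frame bond toggles) were chosen so each recovery
tolerance is a few standard errors wide — large enough that a correct
estimator passes reliably, small enough to run interactively.

## Known limitations

- No triclinic boxes, velocities, or trajectory editing.
- The automatic extreme-residue scan has the conditioning bias described
  above; prefer explicit residue lists for quantitative work.
- Survival fits assume at most two exponential components; heavier-tailed
  duration laws will load everything onto the slow component.
- π-stacking is reported only as an inter-ring centroid distance series;
  there is no orientation criterion.
- Pose ranking is max-simultaneous-contacts, not spatial-density based.
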