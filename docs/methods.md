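# Methods

This note documents the models, estimators and numerical choices
behind scramblekit, in the spirit of a methods section: what is
computed, under which assumptions, and what the synthetic validation
does and does not establish about real membrane trajectories.

Units are fixed package-wide: lengths in nm, times in ns, energies in
kJ mol⁻¹, temperatures in K; the membrane normal is +z. Boxes are
orthorhombic only — membrane simulations with semi-isotropic pressure
coupling produce rectangular boxes, and triclinic input raises an
explicit unsupported-box error rather than being silently mistreated.
Residue ids are kept 1-based as printed in GRO/PDB files; internal
particle indices are 0-based.

## Leaflet assignment and scrambling statistics

A lipid's leaflet is decided solely by its phosphate particle ("PO4"
for coarse-grained lipids, "P" atomistic) relative to the membrane
centre along z. Under periodic boundaries the bilayer may straddle
the z boundary, so the centre is computed by wrapping all phosphate z
into [0, Lz), cutting the sorted values at the largest circular gap
(the solvent slab), unwrapping across the cut and averaging. The
centre is recomputed at every analysed snapshot, which tolerates slow
drift of the membrane in the box. Comparisons use the signed
minimum-image difference, and a phosphate exactly at the centre keeps
its previous label (upper if there is no history) so that
measure-zero configurations cannot generate spurious events. No
hysteresis deadband is applied by default: at 10-ns analysis spacing
the sign rule is the method of record, and a deadband would change
the event count systematically.

Two quantities are tracked separately because they answer different
questions. The *instantaneous scrambled count* — lipids currently in
the opposite leaflet to their first-snapshot leaflet — fluctuates and
can decrease (a lipid may flip back); it is what a "scrambled lipids
vs time" plot shows, optionally with a centred running average
(default window 200 ns). The *cumulative transition-event count* is
non-decreasing and is what a rate should be computed from: rate =
events / observation span, in events per μs. The 95% confidence
interval comes from a block bootstrap over per-snapshot event
increments (default block 10 snapshots), which respects the
short-range correlation between consecutive snapshots. Note that
counting at finite snapshot spacing is a *crossing* count at that
resolution: a lipid that flips and returns within one interval
contributes no event. Coarsening the interval can therefore only
merge events, never create them.

## The flip-flop collective variable

The CV is ξ = z(phosphate) − z(local membrane COM), where the local
COM is taken over membrane beads whose xy minimum-image distance from
the tracked phosphate is at most R (2.0 nm in a bare bilayer, 3.0 nm
next to a protein, matching the cylinder pull geometry of common MD
engines). Member z coordinates are taken in the periodic image
nearest the target so a z-connected membrane is averaged correctly;
the tracked phosphate itself is excluded from the reference COM. The
COM is unweighted by default — coarse-grained beads are effectively
equal-mass — with a mass-weighted option for atomistic systems where
masses are available. Which beads count as "membrane" is a
selection-level choice (all lipid beads by default, not phosphates
only); both choices are exposed because the reference definition is
genuinely underdetermined at this level of description.

Biases: harmonic umbrella ½k(ξ−ξᵢ)²; flat-bottom xy restraint that is
zero inside the reference distance (default d₀ = 2.5 nm) and
½k_fb(d−d₀)² outside (default k_fb = 500 kJ mol⁻¹ nm⁻²), used to keep
a translocating lipid near a pathway without biasing the interior.
Components sum.

Umbrella windows can be seeded from a pulling trace by nearest-CV
frame lookup (earliest frame on ties), either at explicit centers or
from a spacing scheme that is dense (0.03 nm) near the membrane
centre and coarser (0.1 nm) near the surfaces. Window sample files
are two-column (time, ξ) text tolerant of `#`/`@` comment lines, the
dialect of common pull outputs; the first 10 ns of each window are
discarded as equilibration by default. Adjacent windows whose sample
distributions show less than ~1% overlap (1st/99th percentile test)
trigger a warning that is attached to downstream results, never
silent.

## WHAM

The standard self-consistent equations are iterated in log space
(log-sum-exp throughout), with offsets reported relative to the first
window, convergence declared when the largest offset update falls
below 10⁻⁸ kJ mol⁻¹, and a hard cap of 10⁵ iterations (exceeding it
raises an error carrying the residual — results from an unconverged
solve are never returned). The solution is deterministic given the
windows and bins, and invariant under window reordering, window
duplication and constant shifts of all biases.

Bins default to 0.05 nm, finer than the tightest recommended window
spacing, and are aligned so that ξ = 0 falls on a bin *center*: the
top of a symmetric barrier then sits on a bin center rather than an
edge, removing a small systematic underestimate of the barrier.

The profile is F = −k_BT ln P shifted so its global minimum is zero;
the flip-flop barrier is then simply max F. Bins with fewer samples
(summed over windows) than a `min_count` threshold are masked as NaN
*before* the shift: a nearly-empty bin carries an essentially
unconstrained free energy, and letting such a bin set the zero point
can corrupt the whole profile by several kJ mol⁻¹. The default keeps
every sampled bin (`min_count = 1`); quantitative barrier extraction
in the pipeline and validation scripts uses `min_count = 100`, the
support level at which the recovered profile is statistically
meaningful at the default bin width. Masked bins are never
extrapolated.

Two error estimates are provided. The asymmetry heuristic
max|F(ξ)−F(−ξ)|/2 exploits the physical symmetry of a bilayer (the
true profile must be even in ξ), interpolating the mirrored profile
onto the common support; it costs nothing but is blind to symmetric
errors. The optional Bayesian bootstrap reweights windows with
Dirichlet weights and re-solves WHAM, giving a per-bin resampling
spread; it is seeded and off by default because of its cost. Where a
calculation yields one profile per pulling direction, both are
reported and `mean_profile` provides their labelled pointwise mean —
combining directions into one number is a reporting choice, not a
statistical operation, so the package keeps all three.

## Alignment, RMSD and density maps

Superposition is a full six-degree-of-freedom least-squares rigid fit
(Kabsch) over a fit selection, with reflections excluded so chirality
is preserved; collinear fit sets are rejected. RMSD series fit on
one selection and report on another — the usual protocol of fitting
on the whole backbone while reporting, say, the cavity-forming
helices (residues 1–31, 74–100, 117–151, 182–207, 216–247 in the
scramblase this toolkit was built around).

Density accumulation analyses one snapshot per interval (default
10 ns), aligns it to the reference if one is given, and bins the
target particles on a regular grid (default voxel 0.1 nm, which
resolves the coarse-grained bead scale without producing huge grids).
The stored density is counts/(frames × voxel volume) in nm⁻³, so
Σ(density × voxel volume) equals the mean in-bounds particle count
per frame exactly — a conservation identity the tests enforce to
1e-12 relative. Out-of-bounds particles are counted and reported.
When several replicas are merged, everything is aligned to one
explicit reference structure. Grids are written as plain-text OpenDX
scalar fields (values in C order, full float precision, lengths in
nm) and round-trip exactly; the files parse under the common
third-party OpenDX grid readers.

## The synthetic membrane model

The generator is a validation instrument, not a membrane model. Each
lipid is reduced to its phosphate bead moving independently by
overdamped (Brownian) Langevin dynamics,

z ← z − (D/k_BT) U′(z) dt + √(2D dt) η,

in the quartic double well U(z) = B(x,y)(1 − (z/z0)²)², the simplest
smooth form with prescribed minima (±z0) and barrier (B at z = 0).
z0 defaults to 2.0 nm, a POPC phosphate half-thickness consistent
with typical flip-flop pulling start distances; T = 310 K
(k_BT = 2.577 kJ mol⁻¹); D = 0.1 nm² ns⁻¹ and dt = 0.01 ns are chosen
for desk-scale event statistics, not physical fidelity. The
stability requirement dt·max|U′|·D/k_BT < 0.1·z0 is checked up front,
and any single step larger than z0 aborts the integration with advice
to reduce dt. xy is free diffusion with periodic wrapping; D = 0 is
accepted as the degenerate no-motion limit.

A scramblase is represented purely energetically: inside a
cylindrical groove region the barrier drops to a much lower value
(7 kJ mol⁻¹ by default against 62 bulk), blended smoothly over a
radial margin by a cubic smoothstep so the potential is continuous in
xy; an optional Gaussian bump on the groove path reproduces the
secondary maximum a hydrophobic gate leaves in a profile. Default
scenario sizes mirror the reference systems: ~290 lipids for a
proteinless patch, ~920 with a protein.

All randomness flows from one scenario seed through a counter-based
Philox stream; per-lipid independence is realised as columns of that
single stream, and identical scenario + seed reproduces trajectories
bit-for-bit.

Biased CV sampling does not integrate dynamics at all: the 1-D
marginal p(ξ) ∝ exp(−(U0+U_bias)/k_BT) is tabulated on a fine
adaptive grid (support located on an 8001-point scan, refined to
4001 points) and sampled exactly by inverse-CDF transform, giving
i.i.d. Boltzmann samples. A deliberately naive Metropolis chain is
kept alongside as an independent sampler and used as an oracle in the
tests. A bias whose support barely intersects the potential range
triggers a warning.

Planted-event fixtures place lipids at ±z0 and deterministically flip
scheduled lipids at scheduled times, making the schedule an exact
oracle for the event counter. Two flips of one lipid within a single
snapshot interval are rejected at construction — they would cancel
invisibly and break the oracle property. One caveat discovered in
validation: if a schedule empties an entire leaflet, there is no
bilayer left and the midplane (hence leaflet assignment) is genuinely
undefined; randomized oracle tests therefore keep at least one
resident lipid per leaflet. Real membranes are nowhere near this
regime.

What passing the synthetic suite shows: the event counter is exact
against planted ground truth; the sampler is distributionally correct
(closed-form Gaussian checks, chi-square against Boltzmann, agreement
with an independent Metropolis chain); flip rates fall monotonically
with barrier height as Kramers theory requires; and WHAM recovers a
known 62 kJ mol⁻¹ double well from 67 windows and a 7 kJ mol⁻¹ groove
well from 44 windows to within 2 kJ mol⁻¹ on the barrier and
0.5 kJ mol⁻¹ RMS on the profile (20,000+ samples per window,
k = 1000 kJ mol⁻¹ nm⁻², fixed seeds). What it does not show: anything
about force-field accuracy, lipid–lipid cooperativity, membrane
deformation near a protein, or absolute kinetics — the toy model has
no interactions and an uncalibrated attempt prefactor, so only
barrier-driven relative behaviour is meaningful. Scenario statistics
in the test suite are sized for a single CPU (e.g. equilibrium
distribution checks use D = 1 nm² ns⁻¹ and 100-ns snapshot spacing so
successive samples are decorrelated across the slow inter-well
exchange and the chi-square null actually holds).

## Pipeline and reproducibility

The pipeline runs stages (simulate → scramble → wham → report) from a
flat YAML config with one section per stage. Validation happens
before any stage runs: unknown stages or keys are named in the error.
Every run writes a manifest recording the package version, the
effective config with all defaults resolved, a config hash, the seed
and every output file with stage provenance; per-stage progress,
sample counts and warnings go to the console and a log file. With a
fixed seed, numeric outputs are byte-identical across runs. The
`cv` and `density` operations are exposed as standalone `scramble-kit`
subcommands rather than pipeline stages, since they require an
external reference structure that the synthetic pipeline does not
produce.

## Known limitations

- Orthorhombic boxes only; no velocities/forces; no trajectory
  writing beyond the `.npz` fixture container.
- The midplane is a single flat plane per snapshot; strongly curved
  or deformed membranes would need a surface-aware midplane, which is
  out of scope.
- The asymmetry error is a lower-bound-style heuristic; the bootstrap
  complements but does not replace a convergence analysis over
  simulation time.
- The synthetic generator cannot calibrate absolute scrambling rates
  (no attempt-frequency information), so rate comparisons against
  real trajectories are qualitative by design.
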