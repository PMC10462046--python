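# scramblekit

Analysis toolkit for quantifying **lipid scrambling** in membrane
molecular-dynamics trajectories, built around the question of how a
scramblase protein lowers the free-energy barrier for lipid flip-flop.
It is aimed at computational membrane biophysicists who have
coarse-grained or atomistic trajectories (and umbrella-sampling window
outputs) and want the complete chain from raw coordinates to a
flip-flop free-energy profile and a scrambling rate.

## What it computes

**Scrambling events.** Each lipid is assigned to the upper or lower
leaflet by the position of its phosphate bead relative to the membrane
centre (periodic boundaries handled by making the bilayer z-connected
before averaging). A lipid is *scrambled* when it currently sits in
the opposite leaflet to the one it started in; leaflet-transition
events are counted separately, and the rate is events per μs with a
block-bootstrap confidence interval. Snapshots are analysed every
10 ns with an optional 200 ns running average.

**Flip-flop collective variable.** The CV is the oriented distance

ξ = z(P) − z(COM of membrane beads within a cylinder of radius R
around the phosphate's axis),

with R = 2.0 nm for a bare bilayer and 3.0 nm next to a protein.
Biases are a harmonic umbrella ½k(ξ−ξᵢ)² plus an optional flat-bottom
xy restraint (zero inside d₀ = 2.5 nm, ½·500·(d−d₀)² outside).

**WHAM.** Umbrella windows are combined by the standard
weighted-histogram self-consistency

P(b) = Σᵢ nᵢ(b) / Σᵢ Nᵢ exp[(fᵢ − Uᵢ(ξ_b))/k_BT],
fᵢ = −k_BT ln Σ_b P(b) exp(−Uᵢ(ξ_b)/k_BT),

iterated in log space to a 10⁻⁸ kJ/mol offset tolerance. The profile
F(ξ) = −k_BT ln P(ξ) is shifted so its minimum is zero, the barrier is
its maximum, the error estimate is the profile asymmetry
max|F(ξ)−F(−ξ)|/2 (optionally a Bayesian bootstrap over windows), and
the reduction relative to a reference profile is reported in percent.

**Density and RMSD maps.** Frames are Kabsch-superposed onto a
reference over a fit selection (proper rotations only); RMSD series
can be reported on a different selection (e.g. cavity helices only),
and time-averaged number-density grids (nm⁻³) of phosphates or water
are exported as plain-text OpenDX.

**Synthetic membrane.** A seeded overdamped-Langevin simulator evolves
per-lipid phosphate z coordinates in a quartic double-well
U(z) = B(x,y)·(1−(z/z0)²)², where the local barrier B drops from the
bulk value to a much lower one inside a cylindrical "groove" region
(smoothly blended, optional hydrophobic-gate bump). It generates
unbiased trajectories, exact Boltzmann umbrella samples and
planted-flip fixtures with known ground truth, so every stage of the
chain is validated against its construction.

## Worked example

```
$ scramble-kit demo --out demo --seed 7
```

runs an end-to-end synthetic experiment: a 64-lipid membrane with a
10 kJ/mol flip-flop barrier is simulated for 500 ns, scrambling is
counted, and the free-energy profile is reconstructed by WHAM from 47
umbrella windows. The run prints (via the pipeline log):

```
scramble: 48 events in 0.500 us (96.00 events/us)
wham: barrier 10.20 kJ/mol from 47 windows
```

and `demo/report.txt` contains

```
scrambling: 48 events over 0.500 us -> 96.00 events/us (95% CI 62.00-114.05)
flip-flop barrier: 10.20 kJ/mol
barrier reduction vs reference 62.0 kJ/mol: 83.5%
```

Reading: at a 10 kJ/mol barrier (≈4 k_BT) lipids flip constantly —
about a hundred events per μs in this small patch — whereas the same
membrane at the bare bilayer's 62 kJ/mol barrier shows none on any
reachable time scale.
The WHAM estimate recovers the built-in 10 kJ/mol barrier to within
the discretisation/statistics error, and the reduction line is the
percentage drop relative to a 62 kJ/mol reference barrier. The
`demo/` directory also holds the scrambling trace TSV, the profile
TSV, the trajectory and a manifest with the effective config and its
hash.

Library use mirrors the CLI:

```python
from scramblekit.synthetic_membrane import SyntheticScenario, FlipFlopPotential, simulate_unbiased
from scramblekit.scrambling_analysis import scrambling_trace, scrambling_rate

scen = SyntheticScenario(n_lipids=290, duration=10_000.0,
                         potential=FlipFlopPotential(barrier=62.0))
trace = scrambling_trace(simulate_unbiased(scen))
print(scrambling_rate(trace).rate)   # 0.0 — no flip-flop at 62 kJ/mol
```

## Layout

- `scramblekit.trajectory_io` — GRO/PDB/XTC/TRR reading (via
  MDAnalysis), `.npz` array trajectories, selection mini-language,
  periodic wrapping
- `scramblekit.synthetic_membrane` — ground-truth potentials, Langevin
  simulator, biased sampling, planted events
- `scramblekit.scrambling_analysis` — leaflet assignment, scrambling
  traces and rates
- `scramblekit.reaction_coordinate` — cylinder CV, bias potentials,
  window placement and harvesting
- `scramblekit.free_energy` — WHAM, profiles, barriers, error
  estimates
- `scramblekit.density_mapper` — Kabsch superposition, RMSD series,
  density grids, OpenDX I/O
- `scramblekit.cli_pipeline` / `scramblekit.cli` — config-driven
  pipeline and the `scramble-kit` command

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
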