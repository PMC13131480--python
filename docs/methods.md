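# Methods

This note documents the models and algorithms implemented in `wepath`, the
assumptions behind them, the defaults, and the numerical choices — in the
spirit of a methods appendix a maintainer can audit.

## Problem setting

Given two conformations A and B of the same protein (Cα resolution), the
package (1) generates a coarse-grained transition pathway between them with
an adaptive anisotropic network model, (2) compresses that pathway into a
one-dimensional progress coordinate, and (3) uses the coordinate to drive
weighted-ensemble (WE) path sampling with adaptive binning.  A built-in
synthetic two-state system exercises the full workflow with a Brownian
propagator, standing in for the all-atom molecular dynamics a production
study would use.

## Structures and metric

All structural operations act on ordered Cα coordinate sets (Å).  Optimal
superposition is the Kabsch SVD fit with a sign correction on the smallest
singular vector, so reflections are never returned even for mirror-image
inputs.  Fitted RMSD is the global minimum over rigid transforms and is the
metric for every pairwise comparison (meeting criteria, the 2D embedding,
target-state predicates).  PDB I/O goes through biotite; alternate
locations resolve to the highest-occupancy atom and Cα atoms are ordered by
chain, then residue number and insertion code.

## Anisotropic network model (ANM)

Identical springs (constant γ) connect all Cα pairs within a cutoff r_c.
The 3N x 3N Hessian has off-diagonal superelements
−(γ/r²)·(Δr ⊗ Δr) for contacts and diagonal superelements equal to minus
the row sums.  Defaults: r_c = 15 Å, γ = 1 (energy units absorbed) —
standard ANM practice for Cα networks; both are configuration-exposed and
should be treated as assumptions.

Eigendecomposition uses a dense symmetric solver.  Exactly six eigenvalues
must fall below 1e-8 × (largest eigenvalue); fewer indicates a degenerate
geometry (collinear or planar coordinates), more a disconnected network,
and both are rejected with a diagnostic rather than silently repaired.
"Soft modes" are the lowest nonzero-eigenvalue modes; pathway generation
retains min(20, 3N−6) per rebuilt network by default.

## Adaptive pathway generation

The two endpoints are deformed toward each other iteratively:

1. The deformation vector d is the coordinate difference to the opposite
   frontier after superposition (so |d| = √N × fitted RMSD).
2. The smallest prefix of ascending-frequency modes whose cumulative
   squared overlap with d̂ reaches `overlap_threshold` (default 0.5) is
   selected.
3. The frontier moves along the projection of d onto that subspace, scaled
   so the step RMSD never exceeds `step_rmsd` (default 2.0 Å) — a cap
   chosen to stay within the harmonic validity of the current network.
4. The network is rebuilt on the moved conformer (the adaptive
   re-evaluation), and sides alternate each cycle with A moving first.

Termination: frontiers meeting at fitted RMSD < `meet_rmsd` (default
1.5 Å), or the intermediate count reaching `max_intermediates` (default
40), whichever comes first.  A step that improves the gap by less than
0.01 Å widens the mode subset by one and retries; if all retained modes are
exhausted the search stops, reported as unconverged.  The procedure is
fully deterministic.

Design choices that were genuinely open:

- The deformation target is the *current* opposite frontier, recomputed
  every step (not the fixed endpoint).
- The network is rebuilt after every step, not once per cycle.
- The step-size rule is a hard RMSD cap on the projected displacement;
  other scalings (e.g. eigenvalue-weighted amplitudes) are plausible and
  would produce alternative, equally legitimate pathways.
- No energy minimization of intermediates is performed; instead a
  harmonic-validity monitor logs a warning when milestone virtual bonds
  deviate more than 25% from the endpoint average.  On the default hinge
  fixture the worst deviation is ~46% at the barrier-top milestones —
  expected for a purely geometric interpolation and harmless for the
  coordinate-compression role the milestones play here.

## Progress coordinate

Conformations embed into the plane (fitted RMSD to A, fitted RMSD to B).
The embedded milestones define the midpoint polyline: first vertex =
embedded A, interior vertices = midpoints of consecutive embedded
milestones, last vertex = embedded B; M intermediates give M+3 vertices and
M+2 segments.  Progress = X + F with X the index of the nearest segment and
F the clamped fractional projection along it.

Numerical conventions: nearest-segment ties go to the lowest index; F = 1
folds into (X+1, 0) so each point has a unique value, except the terminal
vertex which reports the full M+2; points beyond either end clamp to
[0, M+2] rather than extrapolate; consecutive polyline vertices closer than
1e-9 are merged (adjusting M).  The reverse-direction coordinate is the
same polyline traversed backwards (progress maps v ↦ (M+2) − v), not a
regenerated pathway.  The segment-index range [0, M+1] is the
self-consistent reading of the construction: the worked check — a query 10%
of the way along the middle of three segments (M = 1) scoring exactly
1.1 — requires it.

## Weighted ensemble

Each iteration propagates every walker for a fixed interval τ, recomputes
progress, assigns bins, and resamples every occupied bin to `target_count`
(default 5) trajectories: bins below target repeatedly split their
largest-weight walker into two half-weight children; bins above target
repeatedly merge the two smallest-weight walkers, the survivor drawn with
probability proportional to weight and carrying the sum (the standard
unbiased merge rule; the choice is a convention where the underlying
method is silent).  Total weight is exactly 1 at every iteration boundary;
drift beyond 1e-9 aborts the run.

Minimal adaptive binning (MAB) over the scalar progress coordinate:
the leading and trailing walkers (extremes along the run's direction) get
dedicated boundary bins; the spanned interval is cut into `n_mab_bins`
(default 5) equal-width bins; and the walker immediately preceding the
largest increase of −ln(weight), walking in the progress direction, gets a
dedicated bottleneck bin (default 1; ties resolve to the lowest progress;
boundary status takes precedence).  The bottleneck formula has published
variants; ours (max −Δln w along progress) is one documented
interpretation.  The conventional control uses fixed radial bins every 5°
(18 bins over [0°, 90°]) in the 2D RMSD plane, the angle measured from the
RMSD-to-A axis.

Target state: fitted RMSD to the destination endpoint below a configurable
radius (default 2.0 Å; the underlying method leaves this definition open).
With recycling enabled, arriving walkers teleport back to the initial
state and their weight is recorded as flux.  Reproducibility: every walker
draws from its own (seed, iteration, walker-id) random substream, so runs
are bit-for-bit identical regardless of evaluation order; seeds must be
below 2^31.

Runs persist to HDF5 (per-iteration walker tables, bin labels, split
archive, coordinates) plus a CSV summary.  `combine_runs` pools the walker
ensembles of independent runs at one iteration boundary (final by
default), dividing each weight by the run count so the merged ensemble
again carries total weight 1 — the multi-run normalization used when
plotting pooled distributions.  Time to first pathway is the aggregate
simulation time (Σ over iterations of n_walkers × τ) up to and including
the first iteration whose arriving walker traces an unbroken genealogy to
an initial walker.

## The synthetic two-state system

`make_hinge_endpoints` builds a hinge "protein": two rigid arms of
`n_per_arm` beads (default 10) around a central hinge bead, inter-arm
angle 140° (open, A) vs 70° (closed, B), virtual bonds exactly 3.8 Å.
Each arm winds helically (15° bond tilt, 120° phase advance per bead)
around a straight axis: a literally collinear or planar trace would give
the elastic network more than six zero modes, which the decomposition
correctly rejects, so the helical wobble is what makes the fixture a valid
ANM substrate while keeping "straight rigid arms" in the axis sense.
Optional seeded Gaussian jitter roughens both endpoints.

The landscape is a smooth double basin,
V = −(1/β_mix)·ln(e^(−β_mix·V_A) + e^(−β_mix·V_B)), where V_X is the
elastic pair potential of endpoint X built from its contacts within
r_c = 10 Å (defaults: γ = 1, β_mix = 5).  Its soft directions align with
the hinge motion — the same reason soft-mode guidance works for real
domain motions.  Gradients are analytic (log-sum-exp guarded) and
vectorize over batches of structures, which is what makes the brute-force
reference ensembles in the test suite affordable.

Dynamics are overdamped Langevin: R ← R − (dt/ζ)∇V + √(2kT·dt/ζ)·ξ with
dt = 1e-3 toy-time, friction ζ = 1, kT order 1.  One step plays the role
of ~1 ps, so the default 100-step propagation interval is the toy analogue
of the 100 ps WE interval; all aggregate "times" for the toy system are
reported in these units (or directly as propagation steps).

### What the toy system does and does not emulate

It reproduces the *structure* of the real problem: two metastable states
separated by a barrier, soft modes aligned with the transition, a
progress coordinate built from a generated pathway, and WE bookkeeping
identical to a production run.  It does not emulate force-field detail,
solvent, realistic time scales, or the ruggedness of an atomistic
landscape; passing tests therefore validate the algorithms and their
statistical exactness, not any biophysical prediction for a specific
protein.  Published wall-clock/μs figures for real proteins require
all-atom MD and are out of scope here.

## Problem sizes used in the validation suite

Chosen so the full suite runs comfortably on a single CPU:

- Pathway-generation checks use the default hinge (N = 21).
- Dynamics-heavy checks use a small hinge (n_per_arm = 5, N = 11) with a
  gentler angle pair (120°/80°, barrier ≈ 3.7 energy units) where
  spontaneous transitions occur on the simulated horizon, at kT = 3.5 and
  an arrival radius of 3.0 Å (thermal RMSD fluctuation at this temperature
  makes a 2.0 Å radius essentially unreachable even inside the destination
  basin).
- Statistical exactness compares WE (16 independent runs, recycling on)
  against 10^4 independent brute-force trajectories following the
  identical propagate/teleport-on-arrival Markov chain, on cumulative
  arrival flux and a basin-indicator population, within three combined
  standard errors.
- The binning comparison uses the steeper 140°/70° small hinge at kT = 2.0
  (barrier high enough that guided sampling matters) over five matched
  seed pairs, 60 iterations each.

## Known limitations

- Single deterministic pathway per parameter set; alternative pathways are
  explored by varying the overlap threshold / step size, not sampled.
- The MAB bottleneck rule is one interpretation among published variants.
- The aggregate-time accounting assumes equal τ per iteration.
- The dense eigendecomposition is O((3N)³); fine for desk-scale and
  medium proteins, but large complexes would want sparse/iterative
  solvers.
- Elastic-network energetics only; no sidechains, no sequence specificity.
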