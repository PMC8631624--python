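# Methods

`chromoswitch` simulates how a chromosome segment's 3D organization changes
when the cell it belongs to switches state — for example from a normal,
terminally differentiated cell to a cancer cell — and quantifies that
transition with contact-map and polymer-shape statistics.  This note
documents the model, the algorithms, the tunable parameters, and the
numerical choices, in enough detail to reproduce or modify any stage.

## The polymer model

A chromosome segment binned at fixed resolution (100 kb by default) is
represented as a bead-spring homopolymer, one bead per bin.  All quantities
use reduced units: the energy unit is ε, the length unit is the bond length
σ, and the time unit is τ.  The potential is

```
V(r | S) = V_FENE + V_angle + V_hardcore + V_softcore + V_confine
           + Σ_{|i-j|>1} α_ij(S) · P(r_ij)
```

with:

* **FENE bonds** between consecutive beads,
  `V_FENE = -0.5 K_b R0² ln[1 - (r/R0)²]`, `K_b = 30 ε/σ²`, `R0 = 1.5 σ`.
* **Angle stiffness** `V_angle = K_a [1 - cos(θ - π)]`, `K_a = 2 ε`: zero
  for a straight chain, maximal (2 K_a) when folded back on itself.
* **Hard-core excluded volume** between bonded neighbours only: the shifted
  Lennard-Jones potential `V_LJ = 4ε[(σ/r)¹² - (σ/r)⁶] + ε` below its
  minimum at 2^(1/6) σ, zero beyond.
* **Soft-core excluded volume** between all non-bonded pairs: equal to
  `V_LJ` on (r0, 2^(1/6) σ] and to the bounded plateau
  `2ε(1 + tanh[0.5 V_LJ(r)/ε - 1])` for r ≤ r0, with
  `r0 = σ/((1+√2)/2)^(1/6)` so both branches equal 2ε at the join.  The
  plateau caps the overlap energy at 4ε, letting chains pass through each
  other — the coarse-grained signature of abundant topoisomerase activity.
  The soft-core term is identical in every phase of every simulation.
* **Spherical confinement** keeping the chromosome at ~10% volume
  fraction.  The wall is a per-bead half-harmonic,
  `V_confine = k_wall (|r| - R_C)²` outside radius `R_C`, zero inside,
  with `k_wall = 50 ε/σ²` (stiff enough that equilibrium leakage beyond
  `R_C + 0.2 σ` is negligible).  The reference system (857 beads) uses
  `R_C = 9.7 σ`; desk-scale systems rescale `R_C ∝ N^(1/3)` so the density
  is preserved.
* **Contact restraints**: each non-bonded pair (including the angle-adjacent
  pair i-1, i+1) carries a restraint `α_ij P(r_ij)` where
  `P(r) = [1 + tanh(μ(r_c - r))]/2` is a smooth contact indicator with
  steepness `μ = 3/σ` and midpoint `r_c`.  Positive α penalizes contact.
  The indicator midpoint is a parameter of its own; we default it to
  `r_c = 1.5 σ`.  It is conceptually distinct from the FENE maximum
  extension even though both default to 1.5 σ.

Forces are analytic for every term; `polymer.total_energy_forces` is the
reference (NumPy) implementation and is tested against central finite
differences at 1e-5 relative tolerance.  A numba kernel reimplements the
same formulas for the integrator and is cross-checked against the
reference.  The kernel takes two standard molecular-dynamics shortcuts on
the restraint force, both far below thermal force scales: a cutoff at
`r = r_c + 8/μ`, where the indicator derivative has decayed to
sech²(8) ≈ 4.5e-7 (truncated force < 2e-5 ε/σ at the α cap of 30), and a
linearly interpolated lookup table for the radial force factor
`-(μ/2) sech²(μ(r_c - r))` with 0.0005 σ spacing (interpolation error
< 1e-6).

## Dynamics

Underdamped Langevin dynamics with unit bead mass, friction
γ = 10 τ⁻¹, temperature T = 1 (energy units) and time step dt = 0.0005 τ,
integrated with the BAOAB splitting (half kick, half drift, exact
Ornstein-Uhlenbeck velocity refresh, half drift, half kick).  BAOAB is a
standard, well-characterized sampler for this friction regime; the
free-diffusion and displacement-variance tests pin its behaviour (MSD
exponent 1.00 ± 0.05, amplitude 6 D t with D = T/γ).  Initial velocities
are Maxwell-Boltzmann.  All randomness comes from one seeded NumPy
generator per run; identical seeds give bitwise-identical trajectories.

Snapshots are recorded at the integration step nearest each requested
time.  Transition phases use a logarithmic grid (60 points per phase by
default, starting at 0.05 τ) because the interesting structural
rearrangements span 0.1–10⁴ τ; uniform grids are used where time averaging
needs them (MSD).

## Maximum-entropy fitting

The restraints of a state S are the Lagrange multipliers of the constraints
⟨P_ij⟩ = f_ij, where f is the target contact map.  They are found by dual
ascent: simulate under the current α, compare the simulated contact map to
the target, and update

```
α ← clip(α + η (⟨P⟩ - f), ±30)        on pairs |i-j| > 1.
```

Two stabilizers matter at desk scale, where per-sweep ensembles are small:

1. **A pool of independent chains** (4 by default) is advanced each sweep
   and pooled into one estimate.  A single continuing chain develops
   glassy memory — a region glued by transiently attractive α stays glued
   for many sweeps, the update overshoots, and the fit oscillates around
   Pearson ~0.7.  Independent chains decorrelate the estimate and remove
   the oscillation.
2. **A running mean of the last 3 sweeps' maps** is used for the update
   and the convergence check, damping estimator noise.

The default schedule is η = 1.5 with geometric decay 0.98, 30 sweeps,
6 samples per chain per sweep spaced 0.5 τ after a 3 τ burn-in, and a 5 τ
polymer-only pre-equilibration of the pool.  Iteration stops when the raw
Pearson correlation between the (smoothed) simulated map and the target
reaches `tol` (0.95 by default).  On the 60-bead synthetic benchmark the
fit crosses Pearson 0.9 in about 5–10 sweeps.

Fit quality is reported as Pearson correlations on the raw and log scales
(log computed after removing pairs where either map is zero) plus the
maximum absolute deviation, over the restrainable pairs.  Desk-scale
log-scale correlations are substantially lower than raw ones because
long-range contact probabilities are small and their finite-sample
estimates are dominated by counting noise; this is a sampling-budget
artifact, not a property of the fit (see Limitations).

Two recovery properties validate the machinery: fitting a target generated
by the bare polymer returns restraints with mean |α| < 0.1 (no spurious
structure), and fitting a target generated under a planted α reproduces
the planted ensemble's map even though α itself need not be identified —
the map, not α, is the observable.

## Landscape switching

A cell-state transition is modelled as an instantaneous replacement of one
state's fitted potential by the other's:

1. Sample an equilibrium ensemble under the pre-switch landscape.
2. Cluster it hierarchically (average linkage) on the pairwise-distance
   RMS metric d_rms, cutting the tree at 3 σ; from every cluster with
   population ≥ 0.3%, take the 2 members nearest the cluster medoid as
   representative starting structures.
3. From each representative: equilibrate under the pre-switch landscape
   (t_pre), then swap the α matrix in place — coordinates and velocities
   are untouched at the switch instant — and relax under the post-switch
   landscape (t_post).

Desk-scale defaults are t_pre = 50 τ and t_post = 200 τ for N ≈ 120 beads;
the full-scale protocol (5000/10000 τ at 857 beads) is a configuration
choice away.  Each run draws its seeds from a master seed via
`numpy.random.SeedSequence` spawning.

## Transition statistics

* **P(l) and its slope**: mean contact probability per genomic separation;
  log-log slope fitted over 0.5–7 Mb.
* **ΔP frame differences**: `ΔP^{I,J} = Σ|P^I - P^J| / Σ P^I` over the
  selected pairs (total, local < 2 Mb, or non-local ≥ 2 Mb), min-max
  normalized.  Hierarchical clustering of this matrix, separately for the
  local and non-local ranges, yields the transition's stage structure: the
  change points of both cut dendrograms are pooled and adjacent time
  blocks merged (smallest mean inter-block difference first, earlier pair
  on ties) until 8 contiguous stages remain.
* **ΔP to a reference state**: the same formula with the reference map in
  place of frame J, giving a per-frame similarity curve to the normal,
  cancer, or embryonic-stem-like map.
* **Observed/expected and compartments**: P_ij divided by the mean at its
  separation (zero-mean separations masked, never zero-filled);
  compartments are the sign of PC1 of the Pearson correlation of obs/exp,
  oriented so that A has the higher mean gene density.
* **Insulation**: sliding-square mean of contacts crossing each bin
  (window 5 bins = 500 kb), log2-normalized by its genome-wide mean; TAD
  boundaries are local minima with prominence ≥ 0.1; boundary sets are
  compared by greedy nearest matching within ±1 bin.
* **Shape**: gyration-tensor eigenvalues λ1 ≥ λ2 ≥ λ3 give
  Rg² = Σλ, asphericity Δ = (3/2)Σ(λ_i − λ̄)²/(Σλ)² (0 = sphere, 1 = rod)
  and prolateness S = 27Π(λ_i − λ̄)/(Σλ)³ (negative = oblate).  Principal-
  axis extensions are max-minus-min bead projections on the eigenvectors.
* **Q (fraction of native contacts)**: mean over banded pairs of
  `exp[-(r_ij - ⟨r_ij⟩)²/(2(0.5σ)²)]` with ⟨r_ij⟩ from the end state's
  equilibrium ensemble; bands default to local (0–2 Mb) and long-range
  (10–15 Mb).
* **Radial density**: shell counts about the confinement centre (not the
  instantaneous centre of mass), 20 shells of width R_C/20, normalized so
  the unweighted profile integrates to 1; variants restrict to
  compartment-A or -B loci or weight by gene density.  Profiles are
  compared by `Δρ = ∫|ρ_t - ρ_S| dr / R_C` (Riemann sum on the shared
  shells).
* **Contact-evolution PCA and hysteresis**: per-frame obs/exp matrices are
  vectorized within a genomic-distance band and projected on two principal
  components fitted jointly on the forward series, the reverse series, and
  the reference states, so all paths share one plane.  The hysteresis loop
  area ω is the absolute shoelace area of the polygon formed by the
  forward mean path followed by the reversed reverse mean path.  Bands
  mirror the full-scale analysis (<2, 2–5, 5–10, 10–15, 15–20, 20–40,
  >40 Mb) rescaled proportionally to the actual segment length.

## The synthetic data generator

Real Hi-C inputs are replaced by seeded synthetic contact maps so the
whole pipeline runs in minutes with no downloads.  A generated map is

```
P_ij = clip(A·|i-j|^(-γ) · (1 + plaid·a_i a_j) · tad(i,j) + noise, 0, 1)
```

power-law distance decay (γ = 1, the observed slope of chromatin contact
scaling in differentiated cells over the 0.5–7 Mb band), a plaid
compartment pattern from a blocky ±1 profile (segments of 8–15 bins),
multiplicative TAD-block enhancement on the diagonal, and truncated-
Gaussian multiplicative noise on the upper triangle before
symmetrization.  The main diagonal carries no information and is pinned
to 1; it is excluded from all fitting and analysis sums.

The three-state benchmark fixes the study conditions: the cancer-like
state has a strictly larger compartment-A fraction than the normal-like
state (0.60 vs 0.40 target fractions), amplitudes order the P(l) curves as
ES < cancer < normal (0.40 / 0.72 / 0.80) so the ES-like state is globally
the most open, and the ES-like map carries weaker TAD enhancement.  Gene
densities are Poisson per bin with compartment-dependent means (8 genes
per A bin, 1 per B bin), anchoring the compartment sign convention.

What the generator does **not** emulate: ICE/KR matrix balancing and its
artifacts, translocations or copy-number changes, distance-dependent noise
correlations, and loop-anchor (corner-peak) enrichment.  Passing tests on
synthetic maps therefore validate the machinery and the qualitative
transition phenomenology, not any claim about a particular cell line.

## Numerical choices and degenerate inputs

* Bead counting is inclusive at both segment endpoints
  (`floor(end/res) - floor(start/res) + 1`), reproducing the 857-bead
  count of chr14:20.5–106.1 Mb at 100 kb.
* Contact maps must be symmetric to 1e-12 in memory; file readers average
  asymmetries below 1e-6 and reject anything larger, naming the worst
  entry.
* The stage-merging tie-break is "earlier pair first", making stage
  reduction deterministic on constant inputs.
* Distance bins with zero expected contact are masked (NaN) in obs/exp
  and dropped from PCA vectors and compartment correlations.
* A distance-only map has a constant obs/exp matrix; compartment calling
  raises a degenerate-input error rather than returning the sign pattern
  of floating-point jitter.
* FENE overstretch anywhere raises an error carrying the bond index;
  integration aborts if any coordinate leaves a 10 R_C ball or goes
  non-finite.

## Problem sizes

Default desk-scale sizes: 120-bead systems for the switching study (10
runs per direction, 50/200 τ phases, 15-sweep fits — the 120-bead fits
plateau near Pearson 0.9 by sweep ~10), 60-bead systems for the fitting
benchmarks, ensembles of 60 structures per state.  These sizes were chosen
so the full study completes on one CPU in tens of minutes while keeping
every qualitative observable (stage structure, transient expansion,
stem-like intermediate, hysteresis band ordering) resolvable above its
seed-to-seed variability.

## Known limitations

* Log-scale fit correlations at desk scale are bounded by counting noise
  on long-range contacts (tens of samples vs probabilities of 1e-3);
  meaningful log-scale agreement needs ensembles orders of magnitude
  larger than a desk budget.
* The effective landscapes are equilibrium fits; the switching protocol
  models a single nonadiabatic jump, not repeated switching or gradual
  interpolation between states.
* Each run's pre- and post-switch phases use one friction and temperature;
  no hydrodynamics, no heterogeneous bead types, no cell-cycle dynamics.
* The hysteresis band ranking is asserted as a rank property of the
  synthetic benchmark; its absolute ω values are scale- and
  band-definition-dependent.  At desk scale the largest loop areas sit in
  the longest-range bands rather than the moderate ones, for two reasons
  the analysis itself exposes: the synthetic plaid keeps full-strength
  compartment correlation at every separation, so the longest bands carry
  real state differences, and the scaled-down post-switch phase leaves
  the slowest (longest-range) contacts incompletely relaxed, a genuine
  irreversibility of the shortened protocol.  Forward/reverse path
  separation itself exceeds its same-direction split-half null across the
  moderate bands, so the irreversibility signal is not a sampling
  artifact.
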