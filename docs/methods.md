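# Methods

## The model

Peptides are represented as linear chains of identical coarse-grained
beads ("superatoms"), one per residue — SA8 denotes an 8-residue
homopeptide, SA16 a 16-residue one.  There are no side chains, charges
or dihedral terms: the model isolates the role of backbone–backbone
attraction and backbone stiffness in aggregation, and can be read as a
minimal model of intrinsically disordered homopeptides (polyalanine,
polyasparagine, polyglutamine).

The potential energy is a sum of three terms:

* **Bonds** — harmonic, `V_b = ½ k_b (r − r0)²`, with
  `k_b = 1250 kJ mol⁻¹ nm⁻²` and `r0 = 0.35 nm`.
* **Bending** — cosine-harmonic on consecutive triplets,
  `V_a = ½ k_θ (cos θ − cos θ0)²` with `θ0 = 180°`, so straight chains
  are the minimum and the form is regular there (no `1/sin θ`
  singularity).  `k_θ` is the stiffness control parameter; the study
  grid spans 10–1000 kJ/mol.
* **Nonbonded** — 12-6 Lennard-Jones,
  `V_lj = 4ε[(σ/r)¹² − (σ/r)⁶]`, `σ = 0.47 nm`; the well depth ε is the
  attraction control parameter (grid 1.3–2.0 kJ/mol).

Solvent is implicit: it enters only through the friction and matched
random forces of the stochastic integrator.

Units everywhere: nm, ps, amu, kJ/mol, K.  In this system
kJ/mol ≡ amu·nm²·ps⁻², so no conversion constants appear in the
integrator.

### Choices the model statement leaves open

* **Cutoff and truncation.** The nonbonded cutoff is 1.2 nm (several σ,
  conventional for this bead scale) with the potential shifted to zero
  at the cutoff; the force is truncated, not shifted.  Both are
  configurable (`ForceField.lj_cutoff`, `shift_lj`).
* **Exclusions.** Only directly bonded (1-2) pairs are excluded from
  LJ.  Since σ = 0.47 nm exceeds r0 = 0.35 nm, including 1-2 LJ would
  put every bond on the steep repulsive wall; 1-3 pairs sit near
  0.70 nm when straight and are governed by the angle term.  A
  `bonds+angles` policy (also excluding 1-3) is available.
* **Bead mass.** 72 amu, the standard coarse-grained four-heavy-atom
  bead mass of the force field whose single-molecule diffusion the
  friction was matched to.  Configurable.

## Dynamics

Propagation is an impulse leap-frog Langevin ("stochastic dynamics")
scheme: a deterministic leap-frog kick followed by an exact
Ornstein–Uhlenbeck velocity update,

    v(t+dt/2) = a·[v(t−dt/2) + (dt/m)·F(t)] + √(1−a²)·√(kB·T/m)·ξ
    x(t+dt)   = x(t) + dt·v(t+dt/2),         a = exp(−dt/τ_f)

with `dt = 0.025 ps`, `T = 303 K` and the inverse friction coefficient
`τ_f = 0.17 ps` interpreted as the velocity-relaxation time
(γᵢ = mᵢ/τ_f).  The friction–noise pair doubles as the thermostat.  For
a free particle the stationary velocity distribution is exactly
Maxwell–Boltzmann at any dt, and the scheme reduces to plain leap-frog
as τ_f → ∞.  Reported kinetic energies follow the leap-frog convention
(average of the two half-step kinetic energies adjacent to each full
step), which removes the O((ω·dt)²) oscillation a single half-step
estimate carries.

Measured contracts (test suite): frictionless total-energy drift below
10⁻³ (relative) over 10⁴ steps at the study concentration; kinetic
temperature within 2% of 303 K on 10⁵-step runs across the (ε, k_θ)
grid corners; free-bead diffusion within 5% of the Einstein value
D = kB·T·τ_f/m; bit-identical trajectories for identical seeds.

The exact stochastic-dynamics discretisation of the original
simulation package differs at O(dt) in velocity correlations; kinetic
observables agree at the reported dt, bit-wise trajectories do not.

## System construction

A run starts all-monomer.  The cubic box edge realises the requested
monomer concentration, `L = (N/(c0·N_A))^{1/3}` (72 chains at
c0 = 2.8 mM give L ≈ 35.0 nm; superatom concentration
c_SA = c0 × chain length ≈ 22.4 mM).  Chains are laid out straight at
exactly r0 bond length with random positions and orientations,
rejecting placements with any inter-chain bead pair closer than
`min_sep = 0.6 nm` — above the 0.55 nm cluster cutoff, so frame 0
contains exactly N clusters of size 1.  Velocities are drawn from
Maxwell–Boltzmann at the set temperature.  No jitter or minimisation is
applied: the cosine bending term is regular at θ = 180°, and the
thermostat equilibrates the built state within a few steps.  The build
is deterministic given the seed.

## Cluster analysis

Two chains are in contact iff any inter-chain bead pair lies within
5.5 Å (inclusive) under the minimum-image convention; clusters are the
single-linkage connected components of the chain-contact graph.
Periodic contacts must count, otherwise clusters spanning a box face
fragment spuriously.  From each frame the analysis records the size
multiset, the free-monomer count N_m and the largest-cluster size
M_max (written m below).  Sizes sum to the chain count in every frame.

## Structural descriptors

Computed per cluster after unwrapping it through the periodic boundary
(breadth-first walk of the contact graph, each chain placed by minimum
image relative to an already-placed contact partner):

* **Radius of gyration** R_g from the unweighted gyration tensor (all
  beads identical).
* **Asphericity** `b = λ_z² − (λ_x² + λ_y²)/2` with the squared
  principal moments sorted `λ_x² ≤ λ_y² ≤ λ_z²`; 0 for spherically
  symmetric clusters, R_g² in the rod limit.
* **End-to-end correlation**
  `C_n = 2/(M(M−1)) · Σ_{i<j} (n̂_i · n̂_j)²` over the unit end-to-end
  vectors of the M chains in a cluster.  The squared form is fixed by
  its two anchors: 1 for parallel (or antiparallel) alignment and 1/3
  for isotropic orientations (the absolute-value alternative would give
  1/2 for isotropic and is excluded).  C_n is evaluated per cluster —
  its use is as a function of aggregate size M — and is undefined for
  monomers.

Averages versus cluster size pool all frames and repeats per M and
report the sample standard deviation (not the SD of the mean), which
better represents scatter when non-equilibrium trajectories visit some
sizes only transiently; sizes never visited are absent from the table.

## Kinetic analysis

Three kinetic modes are distinguished: **no-aggregation** (monomers
equilibrate with small transient oligomers; no stable large cluster),
**nucleated** (a lag phase ends at the nucleation time t*, then
sigmoidal monomer decay) and **downhill** (decay from t = 0, no lag).

* **Change-point (CP) lag estimator.**  A two-segment piecewise-linear
  fit of a monomer trajectory, breakpoint chosen by least total squared
  error.  The trailing equilibrium plateau is cut off first (at 25% of
  the head-to-tail drop) so the decay→equilibrium corner cannot attract
  the breakpoint; the two-segment model then describes lag + decay.
  The breakpoint is accepted as t* when the post/pre slope-magnitude
  ratio exceeds a configurable factor (default 5) — "a large change of
  slope" made operational.  A curve with no significant decay (under
  3σ of the point noise) has no change point; a significant decay
  without a flat lag is downhill, t* = 0.  CP applies per repeat;
  repeat lags are averaged into τ*_CP.
* **Master-curve scaling.**  `N_sc = (N_m − N̄_eq)/(N̄_lag − N̄_eq)`
  with time shifted by t* and divided by the half-time t_half (first
  time the mean curve falls to half the lag plateau).  The lag plateau
  maps to 1, equilibrium to 0; affinely related curves collapse
  exactly.  N̄_lag is estimated over [0, t*), N̄_eq over the final 20%
  of the run (configurable).
* **MFPT.**  The first time m(t) *reaches* each size (≥, so coalescence
  jumps count), averaged over repeats; repeats never reaching a size
  are excluded there and counted.  The curve is fitted with

      τ(m) = (τ*/2)·[1 + erf(Z·√π·(m − m*))] + H(m − m*)·(m − m*)/G

  (H the unit step): critical nucleus m*, Zeldovich factor Z, growth
  rate G, average nucleation time τ*.  The fit is nonlinear least
  squares with curve-derived starts (steepest-ascent point for m*,
  tail slope for 1/G) and a few alternative m* starts to step over the
  kink; on noiseless forward-generated curves the inversion is exact to
  well under 1%.  When the barrier is sharp relative to the integer
  size grid, m* and Z are only loosely identified (the step completes
  between two integers) while τ* and G remain well determined.
* **TPM.**  Transitions between consecutive samples of m(t) are
  counted and row-normalised; `P_growth(m) = P(m→m+1) − P(m→m−1)`, and
  m*_TPM is the smallest m ≥ 2 with P_growth ≥ 0.  Multi-step jumps
  (coalescence) enter the row denominator but not the ±1 numerators,
  following the literal m→m±1 definition; a sign-collapsed counting is
  available.  States with no outgoing transitions are excluded and
  reported.  The sampling stride is the analysis stride of the input
  series and is echoed in output metadata.
* **Mode classifier.**  A run is *no-aggregation* when no stable large
  cluster forms (ensemble-mean M_max at or above
  max(4, 25% of chains) in at least 80% of the final quarter of frames)
  **and** the change-point criterion does not fire; *nucleated* when CP
  fires with t* of at least 5% of the run; *downhill* otherwise.  The
  thresholds have no counterpart in the underlying description of the
  three modes, so they are explicit configuration, defaulted as above
  and echoed in every result.  Keying "no-aggregation" on the absence
  of a stable cluster (not on the absence of any monomer decay)
  matters: at high concentration the fast monomer↔oligomer
  equilibration drops N_m early without any aggregation taking place.

τ* averages include only repeats that nucleated; both counts
(nucleated/total) are reported alongside.

## Synthetic fixtures

Estimators are validated without MD by a Gillespie birth–death chain on
cluster sizes 1..N (reflecting boundaries) standing in for m(t):
its drift crossing, first-passage statistics (closed-form recursion
`h_j = 1/λ_j + (μ_j/λ_j)h_{j−1}`) and barrier position are known
exactly.  Deterministic geometric configurations (parallel lattice,
separated random gas, boundary-spanning pair, rod, cube) provide
clusters with analytically known descriptors and partitions.  The
fixtures are code, not data files, and make no attempt at thermodynamic
realism: passing estimator tests shows the analysis is correct, not
that the physical model nucleates.

## Problem sizes

Desk-scale runs used throughout the tests and examples are deliberate
reductions of the production campaign (which is 72 chains × 10 μs ×
≥5–25 repeats per grid point, i.e. 4×10⁸ steps per repeat):

* integrator contracts: 1–5 chains (8–64 beads), 10⁴–10⁵ steps;
* the aggregation-mode demonstration: 24 SA8 chains at 11.2 mM (4× the
  reference concentration, to shorten encounter times), 2×10⁶ steps
  = 50 ns, ε ∈ {1.3, 2.0}, k_θ = 1000.  Strong attraction yields
  downhill aggregation with cluster–cluster coalescence jumps; weak
  attraction yields no-aggregation; the mode ordering with ε is
  monotone.
* estimator validation: 20–25 birth–death repeats of a few thousand
  time units.

At these sizes the desk runs reproduce the qualitative phenomenology
(mode crossover with ε, coalescence under downhill kinetics, monomeric
starts).  Quantities tied to the production scale — the Table-style
critical-nucleus and nucleation-time values for specific (ε, k_θ) grid
points at 2.8 mM, equilibrium monomer concentrations — require the
full campaign and are out of desk reach; the pipeline that would
compute them is exercised end-to-end on the synthetic nucleated
ensembles instead.

## Known limitations

* No electrostatics, side chains or dihedrals; no fibril formation —
  the model produces amorphous or parallel-ordered clusters only.
* No pressure coupling, constraints or multiple time-stepping;
  cubic boxes only, box ≥ 2× cutoff enforced.
* The all-pairs force kernel is O(N²); fine to a few hundred beads,
  not meant for production-scale systems.
* CP thresholds and classifier thresholds are heuristics; borderline
  systems (long lag vs no aggregation) are sensitive to run length,
  as they are in the underlying method.
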