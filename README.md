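# peptagg

Coarse-grained simulation and kinetic analysis of homopeptide
aggregation.

Peptide and protein aggregation shows two experimentally distinct
kinetic faces: sigmoidal curves with a lag phase attributed to the
nucleation of a critical aggregate, and "downhill" curves where the
monomers decay from the start with no lag at all.  `peptagg` implements
a minimal bead-spring model that reproduces both, plus the
no-aggregation regime, and the full analysis chain used to classify and
quantify them.  It is aimed at people studying aggregation mechanisms
with coarse-grained models: run desk-scale simulations, or feed your
own largest-cluster/monomer time series straight into the estimators.

## The model and the statistics

Peptides are chains of identical beads (one per residue; SA8 = 8
beads).  Bonds are harmonic, `½k_b(r−r0)²`; bending is cosine-harmonic,
`½k_θ(cos θ − cos θ0)²` with θ0 = 180°; non-bonded beads attract via a
12-6 Lennard-Jones well of depth ε (σ = 0.47 nm).  The solvent is
implicit: a leap-frog stochastic-dynamics integrator (dt = 25 fs,
inverse friction 0.17 ps) doubles as a 303 K thermostat.  The two
control parameters are the inter-chain attraction ε and the chain
stiffness k_θ.

Aggregates are chains linked by any bead–bead contact within 5.5 Å
(single linkage, periodic boundaries respected).  From the cluster
series the package computes:

* monomer count N_m(t) and largest-cluster size m(t) = M_max(t);
* structural descriptors vs cluster size M: radius of gyration R_g,
  asphericity `b = λ_z² − (λ_x²+λ_y²)/2`, and the end-to-end
  orientational order `C_n = 2/(M(M−1)) Σ_{i<j} (n̂_i·n̂_j)²`
  (1 = parallel, ≈1/3 = isotropic);
* the nucleation time and critical nucleus size by three routes:
  change-point (two-segment) fits of N_m(t); mean first-passage times
  fitted with `τ(m) = (τ*/2)[1 + erf(Z√π(m−m*))] + H(m−m*)(m−m*)/G`;
  and the transition probability matrix, where m* is the smallest size
  whose growth probability `P_f(m) − P_b(m)` is non-negative;
* a kinetic-mode label: no-aggregation / nucleated / downhill.

Details, defaults and the reasoning behind every open choice are in
[docs/methods.md](docs/methods.md).

## Worked example

Eight chains at high concentration and strong attraction aggregate
within a few nanoseconds:

```python
import peptagg as pa

ff = pa.ForceField(epsilon=2.0, k_theta=1000.0)          # kJ/mol
spec = pa.SystemSpec(n_chains=8, chain_length=8, c0=20.0, seed=1)
state, topo = pa.random_initial_config(spec, ff)
print(f"box edge: {state.box:.2f} nm")

res = pa.simulate(state, topo, ff, pa.IntegratorParams(seed=2),
                  n_steps=400_000, traj_stride=1000, log_stride=10_000)
print(f"mean kinetic T: {res.log['temperature'][1:].mean():.1f} K")

series = pa.cluster_time_series(res.positions, res.times, state.box, topo)
mode = pa.classify_mode(series.times, series.n_monomers, series.m_max,
                        topo.n_chains)
print(f"mode: {mode.mode}; final N_m = {series.n_monomers[-1]}, "
      f"M_max = {series.m_max[-1]}")

rec = pa.structural_records(res.positions, series, state.box, topo)
print(pa.conditional_average_vs_M(rec[rec.M >= 2]).head(4).round(3))
```

Output:

```
box edge: 8.73 nm
mean kinetic T: 307.2 K
mode: downhill; final N_m = 1, M_max = 7
   M  b_mean   b_sd  R_g_mean  R_g_sd  C_n_mean  C_n_sd  n_records
0  2   0.562  0.215     0.882   0.109     0.598   0.316        217
1  3   0.565  0.187     0.894   0.097     0.735   0.190        135
2  4   0.987  0.319     1.155   0.123     0.615   0.148         30
3  5   0.473  0.172     0.944   0.114     0.706   0.153         80
```

The 10-ns run is downhill: monomers decay from the start with no lag
phase, and seven of the eight chains end in a single aggregate
(N_m = 1, M_max = 7).  The kinetic temperature sits within 1.5% of the
303 K set point, and these stiff (k_θ = 1000), strongly attractive
chains order as they aggregate: C_n ≈ 0.6–0.7, well above the ≈1/3 of
isotropic orientations.

The same pipeline is available from the shell:

```sh
peptagg run -c config.yaml -o out/
peptagg analyze -t out/ -c out/config.yaml -o out/analysis/
peptagg sweep -c config.yaml -o sweep/ -e 1.3 -e 2.0 -k 10 -k 1000 -r 2
```

`analyze` writes the cluster series (`series.csv`), per-cluster
descriptors, size-conditioned averages and a `estimates.json` with the
mode label and nucleation estimates; `sweep` tabulates modes over an
(ε, k_θ) grid — the kinetic phase-diagram workflow.

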