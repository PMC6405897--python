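# fragsim

**Geometric fragmentation effects on species abundance and survival.**

When natural habitat is converted, two very different things happen to a
species: a purely *geometric* effect — individuals that happen to sit in the
converted matrix are lost, individuals inside the remaining fragments
survive — and *demographic* effects that play out afterwards (isolation,
edge effects, stochasticity in small fragments). Empirical fragmentation
studies routinely need the geometric part as a null expectation, yet it is
rarely quantified. `fragsim` is a simulation toolkit for exactly that: it
predicts landscape-scale abundance and survival probability from (a) the
species' spatial distribution prior to landscape change and (b) the amount
and spatial configuration ("fragmentation per se") of remaining habitat,
with habitat acting as a cookie-cutter and no demography at all. It is aimed
at landscape and conservation ecologists who want a quantitative geometric
null for SLOSS-type questions.

## Model

Species distributions are point patterns in the unit square (toroidal), with
every point one individual:

* **random** — homogeneous Poisson / CSR with n_P points;
* **aggregated** — Thomas cluster process: centres with intensity ρ,
  Poisson(μ) offspring per centre displaced by an isotropic Gaussian with
  per-axis sd σ; expected abundance n_P = ρAμ (a conditioned variant fixes
  n_P exactly);
* **regular** — Strauss process with density ∝ γ^{s(x)}, s(x) the number of
  pairs closer than r = 1/√n_P; γ=1 is CSR, γ=0 a hard core; sampled by
  Metropolis–Hastings.

Landscapes are binary habitat maps: midpoint-displacement fractal surfaces
(Hurst factor H; fractal dimension D = 3 − H) thresholded by rank so that
exactly round(p · 16,641) of the 129×129 cells are habitat. H controls
fragmentation per se at fixed habitat amount p: H = 0.9 gives few large
fragments, H = 0.1 many scattered ones. Overlaying pattern and map labels
survivors; replicating both draws gives the mean and cv of surviving
abundance and the survival probability P(abundance > 0).

Two analytic anchors: for CSR, survival is exactly 1 − (1−p)^{n_P}; for the
Thomas process on equal circular fragments, survival follows from the
cluster-process generating functional,
1 − E[exp(−ρ ∫ (1 − e^{−μ q(c,W)}) dc)], evaluated semi-analytically
(`survival_thomas_disks`) and used to cross-validate the simulations.

## Worked example

```python
from fragsim import (SpeciesSpec, LandscapeSpec, estimate_survival,
                     survival_csr)

aggregated = SpeciesSpec("thomas", 100, n_clusters=5, sigma=0.02)

high_frag = estimate_survival(aggregated, LandscapeSpec(0.1, hurst=0.1),
                              n_reps=2000, master_seed=31)
low_frag = estimate_survival(aggregated, LandscapeSpec(0.1, hurst=0.9),
                             n_reps=2000, master_seed=32)
print(f"mean abundance: {low_frag.mean_abundance:.2f}")
print(f"survival, many small fragments (H=0.1): {high_frag.survival_prob:.3f}")
print(f"survival, few large fragments  (H=0.9): {low_frag.survival_prob:.3f}")
print(f"CSR closed form at same n, p:          {survival_csr(100, 0.1):.3f}")
```

prints

```
mean abundance: 9.82
survival, many small fragments (H=0.1): 0.950
survival, few large fragments  (H=0.9): 0.638
CSR closed form at same n, p:          1.000
```

Read: with 10% habitat, a species of 100 clustered individuals (5 clusters
of scale σ=0.02) keeps on average 10 individuals regardless of habitat
configuration — mean abundance is always n_P·p — but its chance of keeping
*at least one* individual is 0.95 when the habitat is scattered into many
small fragments versus 0.64 when it is a single large block: a positive
geometric effect of fragmentation per se. A randomly distributed species
with the same abundance would survive almost surely either way.

The `fragsim` command line exposes the same machinery
(`fragsim simulate`, `fragsim landscape`, `fragsim run --config`,
`fragsim compare-analytic`), and `fragsim.experiments.default_grids()`
returns the full factorial designs (abundance × clustering/inhibition ×
habitat amount × Hurst factor) with `run_experiment` /
`plot_survival_curves` producing the long-format CSV and panel figures.

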