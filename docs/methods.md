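# Methods

## The geometric view of fragmentation

`fragsim` quantifies *geometric* fragmentation effects: changes in a
species' landscape-scale abundance and survival that arise purely from
overlaying its spatial distribution on the geometry of remaining habitat
("cookie-cutter" sampling). Individuals falling in habitat survive;
individuals in the matrix are removed. No demography — no dispersal, edge
effects, Allee effects, or fragment-size dynamics — enters anywhere.
Landscape-scale survival is the event that at least one individual remains
after conversion.

The quantities reported per scenario are the mean surviving abundance, the
coefficient of variation (cv = sd/mean) of surviving abundance across
replicates, and the survival probability, each over `n_reps` independent
replicates in which **both** the point pattern and the landscape are redrawn.
Redrawing both per replicate is a deliberate choice: the reported quantities
are marginal over the two sources of randomness, and the independence of CSR
survival from fragmentation per se holds exactly only in that marginal sense.
By construction, mean abundance is n_P · p for every distribution type
(each individual's marginal chance of landing in habitat is exactly the
habitat amount p), so the interesting signal is in the cv and in survival.

## Species distributions

All patterns live in the unit square with toroidal topology (the default;
planar distances are available for external data). Toroidal wrapping keeps
the intensity of every generator spatially uniform and avoids edge
artefacts; rejection at the boundary would thin peripheral clusters.

**Random (CSR).** n independent uniform points.

**Aggregated (Thomas cluster process).** Cluster centres uniform; offspring
displaced from their centre by an isotropic bivariate Gaussian with per-axis
standard deviation σ and wrapped into the window. The per-axis-variance-σ²
normalisation is the standard one for this cluster process; a variant with
the exponent scaled by σ² rather than 2σ² appears in parts of the applied
literature but does not integrate to one and is not used here. Two modes:

* `conditioned` (default): exactly `n_clusters` centres and exactly
  `n_points` offspring, allocated to centres by an equal-probability
  multinomial. This matches factorial designs that fix abundance exactly
  (e.g. "100 individuals" scenarios).
* `poisson`: centres ~ Poisson(n_clusters), offspring per centre ~
  Poisson(μ), μ = n_points/n_clusters. This is the regime in which the
  analytic survival solution is exact, and is used for that comparison.

**Regular (Strauss process).** Fixed-n Gibbs density ∝ γ^{s(x)}, where s(x)
is the number of unordered pairs strictly closer than the interaction radius
r (default r = 1/√n, the spacing of a lattice of n points tiling the unit
landscape). γ=1 is CSR and is sampled directly; γ=0 is a hard core. Sampling
is single-point Metropolis–Hastings: each update proposes, with probability
1/2, a fresh uniform location, otherwise a Gaussian jitter of scale r/2
(the mixture crosses inter-cluster gaps while still refining locally);
acceptance probability min(1, γ^{Δs}) with the 0⁰ = 1 convention at γ=0.
Defaults: 10⁵ single-point updates, the first half treated as burn-in. A
small-state validation (n=3) checks the chain's distribution of s against an
independently integrated exact density to <2% total variation; equilibrium
at e.g. n=100, γ=0.01 was verified by agreement of chains started from CSR
(s≈155) and from a hard-core state (s=0).

**Hard-core initialisation.** At γ=0 with the default r = 1/√n the required
disk coverage is exactly π/4 ≈ 0.785 of the window — close to the packing
limit — so a feasible start is nontrivial. Three strategies are tried in
order: random sequential adsorption (when coverage < 0.4); the densest
sheared lattice on the torus (an exhaustive search over the finite subgroups
of the torus of order n), randomly translated and reflected so replicates
differ; and bounded overlap-penalty minimisation from random starts.
Coverage beyond the hexagonal bound π/√12 raises a feasibility error
immediately. A subtlety: for n a sum of two integer squares (n = 10
included), the optimal packing is a rotated square lattice whose minimum
distance equals 1/√n *exactly*; pair comparisons therefore use a 1e-9
relative guard band on squared distances so that pairs mathematically at
distance r are not miscounted as closer through float roundoff. For
continuous random configurations the band is hit with probability ≈ 0.

## Landscapes

**Fractal habitat maps.** Midpoint displacement (diamond–square, without the
random-additions variant) on a (2^levels + 1)² grid, default 129×129. At
recursion level l the midpoint perturbation has standard deviation
(1/2)^{lH} (the square step additionally scaled by (1/2)^{H/2}, the
standard fractional-Brownian schedule). The Hurst factor H ∈ (0,1) sets the
surface roughness (fractal dimension D = 3 − H): smooth surfaces (H→1)
threshold into few large fragments, rugged surfaces (H→0) into many small
ones — this is how fragmentation per se is varied at fixed habitat amount.

Thresholding is by rank, not by a fixed elevation: exactly
k = round-half-up(p · n_cells) highest-valued cells become habitat, so the
habitat amount is exact in every map (e.g. 3,328 of 16,641 cells at p=0.2).
Ties at the cut value — measure-zero for continuous surfaces, but possible
for degenerate inputs — are broken uniformly at random with a recorded seed.
Raster cells tile the window exactly (cell size 1/side); point-in-cell
queries use half-open cells with the x=1/y=1 boundary assigned to the last
cell.

**Disk landscapes.** n_disks equal-radius disks with uniform random centres
on the torus; the common radius satisfies n_disks·πR² = p·A, so the
*nominal* coverage is p and overlaps (permitted, Boolean-model style) make
realized coverage ≤ p. Realized coverage can be measured on demand. These
landscapes exist for the analytic cross-check, which assumes exactly this
placement model.

## Analytic survival for the Thomas process on circular fragments

For a Poisson cluster process, the void probability of a region W follows
from the generating functional:

    P(no point in W) = exp( −ρ ∫ [1 − exp(−μ q(c, W))] dc ),

with ρ the centre intensity, μ the mean offspring count, and q(c, W) the
probability that one offspring of a cluster centred at c lands in W.
Survival is 1 − E[void], the expectation taken over random fragment
placements by Monte Carlo (default 2,000 landscape draws, standard error
reported; the SE at 2,000 draws is already far below the 3-SE bands used in
comparisons).

For W a union of disks, q(c, W) and the outer integral are evaluated on the
torus by FFT convolution of a high-resolution antialiased raster of the
disk union (boundary cells get fractional coverage from the signed distance
to the disk edge) with the wrapped Gaussian kernel, discretely normalised so
it is an exact probability mass over lags. This route handles arbitrary
disk overlap natively and uniformly — no inclusion–exclusion case analysis —
with accuracy set by the raster resolution (default 256²; the σ→0
indicator limit is resolution-bound, ~3·10⁻³ at 512²). The single-disk
Gaussian mass has the closed Marcum-Q / noncentral-χ² form
P(d², σ) = F_{χ'²₂,(d/σ)²}((R/σ)²), exposed as `gaussian_disk_mass` and
checked against brute-force 2-D quadrature to 10⁻⁶; it serves as an
independent oracle for the FFT pipeline's limits.

Two limit behaviours worth noting. (i) As σ→0 with a single disk and
Poisson counts, survival → 1 − exp(−ρπR²(1−e^{−μ})); a conditioned single
cluster would instead give the centre-in-disk probability πR²/A, so the
limit depends on the count model. (ii) As σ → large the *spatial* clustering
washes out, but the clustered *count* distribution remains: the void
probability tends to exp(−ρ(1−e^{−μp})), which matches the CSR closed form
1−(1−p)^{ρμ} only when μp is small or survival is near one. The
reduction-to-CSR check is therefore pinned to such a regime (μ=5, ρ=20,
p=0.1).

## Defaults, tolerances and problem sizes

* n_reps = 1,000 replicates per scenario cell (the design's standard);
  statistical checks raise this (up to 10,000) where the band being tested
  requires it, and the Monte-Carlo comparisons use 3-SE bands (binomial SE
  for survival, sample SE for means, bootstrap SE for the cv).
* Factorial grids: n_P ∈ {10, 100, 1000}; Thomas n_C ∈ {1, 2, 5, 10},
  σ ∈ {0.01, 0.02, 0.05, 0.1}; Strauss γ ∈ {0, 0.01, 0.1, 1};
  habitat amount ∈ {0.01, 0.02, 0.05, 0.1, 0.2, 0.5} (a log-ish ladder over
  the studied 0.01–0.5 range); H ∈ {0.1, 0.3, 0.5, 0.7, 0.9}. All
  overridable in config.
* Reproducibility: one master seed per scenario; per-replicate child seeds
  are spawned deterministically, so every replicate is independent and the
  whole pipeline (including CSV output) is byte-reproducible.
* cv is reported as missing (NaN), not 0, when mean abundance is 0 or only
  one replicate exists.

## What the generators do and do not emulate

The synthetic species and landscapes reproduce the *structure* of the study
design — independent control of abundance, aggregation/regularity, habitat
amount, and fragmentation per se — not any particular ecosystem. Real
species distributions mix aggregation scales, respond to environmental
heterogeneity, and correlate with the pattern of habitat loss; real
landscapes are anisotropic and land conversion is selective (valleys,
riparian zones first). Passing tests therefore demonstrate the internal
consistency and statistical correctness of the geometric sampling machinery,
not predictions for any specific landscape. One known saturation: at
n_P = 100 and p ≥ 0.1 the survival probabilities of regular and random
patterns both sit within ~3·10⁻⁵ of 1, so their ordering — though real — is
not resolvable at feasible replicate counts; the regular-vs-random contrast
is informative only at low abundance or very low habitat amount.

## Known limitations

* The Strauss sampler is a fixed-length MCMC, not a perfect sampler; the
  default 10⁵ updates were validated for the design's parameter ranges
  (n ≤ 1000) but very dense interactions with small γ may need more sweeps.
* The analytic module assumes a square toroidal window.
* Patch counting uses 4-connectivity only; no broader landscape-metric
  suite is provided.
* Hard-core feasibility between the lattice-friendly cases and the hexagonal
  bound relies on a bounded stochastic search and may report infeasibility
  for adversarial (n, r) combinations that are in fact feasible.
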