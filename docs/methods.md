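# Methods

This note documents the models behind `genspec`, the choices that were
genuinely open, and what the synthetic ground truth does and does not
show about real communities.

## Data model

The central object is a nonnegative integer count matrix, samples × OTUs,
with unique identifiers on both axes. Relative abundances are always
recomputed from counts (row-normalised) rather than stored, so every
statistic sees one canonical normalisation. All-zero OTUs are dropped
with a warning before analysis; all-zero samples are a validation error.
Trees are scikit-bio `TreeNode` phylogenies over OTU identifiers with
nonnegative branch lengths; metadata carries grid coordinates in metres
plus named covariates grouped into blocks (light: CC, SR, LT; plant: BA,
DEN; topography: ASP).

## Niche breadth and classification

Levins niche breadth for OTU *j* over *N* samples is
`B_j = 1 / Σ_i P_ij²` with `P_ij` the proportion of *j*'s total abundance
found in sample *i* (`Σ_i P_ij = 1`), so `1 ≤ B_j ≤ N`. The alternative
convention (within-sample relative abundances) is available via
`normalization="within_sample"` but is not the default because it breaks
the `B ≤ N` bound the classification envelope relies on.

The null model is the count quasiswap: each null table has exactly the
observed row sums, column sums, and number of nonzero cells. A null is
built by (1) an r2dtable-distribution draw — pooled individuals labelled
by OTU are shuffled and dealt to samples by their row sums, which samples
the multivariate-hypergeometric distribution over fixed-marginal tables —
followed by (2) unit 2×2 diagonal shifts that never increase fill until
the fill matches the observed table. Each null starts from an independent
draw (no serial chain); the first emitted matrix additionally receives
10 × fill fill-neutral mixing attempts. The swap kernel is numba-compiled
with an inline xorshift64* generator; a chain makes millions of proposals
per matrix.

An OTU is a generalist when its observed statistic (B by default,
occurrence optionally) exceeds the empirical upper `1 − α/2` null
quantile (linear/type-7 interpolation), a specialist when below the
lower `α/2` quantile; ties resolve to neutral (conservative). Defaults:
1000 permutations, α = 0.05. Kruskal–Wallis (scipy) compares per-sample
richness across the overall/generalist/specialist/neutral groups.

Fill preservation is what gives the test its power: in a sparse table
the fixed-fill null concentrates every OTU relative to multinomial
placement, so an evenly spread OTU exceeds the envelope and a strongly
patchy one falls below it. With exactly hypergeometric placement
(no fill constraint) an evenly-spread OTU would sit at its own null
median and nothing could ever be called a generalist.

## Assembly processes

**βMNTD / βNTI.** For samples *k*, *l*:
`βMNTD = ½ [ Σ_j f_jk · min_{j′∈l} d(j,j′) + Σ_j f_jl · min_{j′∈k} d(j,j′) ]`
with *f* within-sample relative abundances (abundance-weighted by
default; counts are available, so weighting uses them) and *d* patristic
distances. The null shuffles tip–OTU associations; βNTI is the per-pair
z-score over 999 shuffles (the conventional count; the analysis defines
no canonical value). Pairs with zero null spread (e.g. star trees) are
NaN with a warning and excluded from partition denominators. Nearest-
taxon lookups walk per-OTU distance-sorted index rows (numba), so a full
null replicate costs one matrix product plus an O(OTUs × samples) scan.

**RC-Bray.** Null assemblages preserve each sample's richness and total
reads: species drawn without replacement with probability ∝ occurrence
frequency (Gumbel top-k), one individual each, remaining reads
multinomial ∝ mean relative abundance. One null community is drawn per
sample per replicate and compared pairwise — the per-pair null
distribution is identical to independent per-pair draws because draws
are independent across samples, and the cost drops from O(pairs) to
O(samples) per replicate. `RC = (#null < obs + ½·#null = obs)/n_null`,
rescaled to `2(RC − ½) ∈ [−1, 1]`.

**Partition.** βNTI > +2 heterogeneous selection; < −2 homogeneous
selection; otherwise RC > +0.95 dispersal limitation, RC < −0.95
homogenising dispersal, else drift. Stochastic fraction = the last three.

**Sloan neutral model.** Occurrence frequency is predicted as
`f(p) = 1 − BetaCDF(d; Nmp, Nm(1−p))` with N the mean read depth. The
migration rate m is fitted by least squares on a bounded log₁₀ m search;
R² = 1 − SSE/SST (Östman; may be negative). The detection limit defaults
to `ln 2 / N`: under multinomial read sampling an OTU at relative
abundance x is seen with probability `1 − (1 − x)^N`, and `ln 2 / N` is
the hard threshold matching that curve's half-detection point. (A 1/N
threshold systematically overestimates m — by ≈ +40% at m = 0.5 on
communities generated by this package's own neutral simulator — because
it credits the model with detections the read sampling actually misses.)
The 95% envelope uses Wilson score intervals with n = number of samples.

**C-score.** Mean over OTU pairs of `(r_i − S_ij)(r_j − S_ij)`.
Sequential-swap nulls flip random 2×2 checkerboards on the binary matrix
(marginals preserved exactly); defaults burn-in 30 000 swaps, thinning
1 000 swaps — conventional chain settings, exposed in the API.
SES = (obs − null mean)/null sd; a checkerboard-free matrix yields an
undefined SES with a warning.

## Co-occurrence network

Spearman correlations on within-sample relative abundances after a 20%
prevalence filter; two-sided p-values BH-adjusted over all tested pairs;
edges where |ρ| ≥ 0.6 and adjusted p ≤ 0.05 (the dominant convention in
microbial network studies — the analysis itself fixes no recipe, so all
three thresholds are parameters and the run report records them). Module
detection is seeded Louvain on the unsigned graph, modules renumbered by
size; topology reports node/edge counts, 2E/N average degree, unweighted
average path length on the largest component, mean local clustering
(degree < 2 counts 0), modularity Q, and the positive-edge ratio. Node
roles use within-module degree z-score Zi and participation
Pi = 1 − Σ_m (k_im/k_i)², with the standard thresholds (hub Zi > 2.5,
connector Pi > 0.62); keystones are the non-peripheral nodes.

## Spatial eigenvectors and path model

PCNM: Euclidean distances truncated at the largest minimum-spanning-tree
edge (the spacing itself on a regular grid; a relative 1e-8 tolerance
keeps threshold-distance pairs as neighbours under coordinate rotation),
distances beyond it set to 4 × threshold, Gower double-centring,
eigendecomposition; positive-eigenvalue axes scaled by √eigenvalue.

Forward selection is greedy on R² with two stopping rules. The
permutation test compares the observed best gain against the permuted
distribution of the **maximum** gain over all remaining candidates —
screening ~80 axes makes the naive single-candidate test anti-
conservative enough to select spurious axes on pure noise almost always,
while the max-statistic test holds the step-wise error at α. Selection
also stops once cumulative adjusted R² exceeds the full-axis model's
adjusted R². Ties break by axis order.

PLS-PM: Lohmöller iteration, reflective (mode A) outer weights, path
scheme inner weighting by default (centroid available); convergence when
the largest outer-weight change drops below 1e-6. Latent scores are
unit-variance; each latent is oriented so its mean loading is positive.
Inner path coefficients are OLS among latent scores; effects decompose
by path tracing (total = direct + Σ products along indirect routes);
GoF = √(mean communality × mean R²) with communality averaged over all
indicators (single-indicator blocks contribute 1). Percentile bootstrap
(500 seeded resamples) is available for path CIs.

## Synthetic ground truth

The generator emulates a 12 × 10 grid of 400 m² quadrats at 20 m spacing,
10⁴ reads per sample, 1000 OTUs with a lognormal(0, 2) abundance
distribution. A unit-variance latent environmental gradient with
exponential spatial covariance (range 60 m) drives specialists through a
Gaussian kernel `exp(−(env − optimum)²/2σ²)`; σ = 0.15 puts specialist
occupancy at ~16% of samples (design target 10–20%). Generalists have
uniform expected relative abundance; background taxa carry aspatial
lognormal overdispersion (sd 1.0) so their evenness falls between the
planted extremes. Two deliberate design choices: planted classes draw
their base abundances from the abundant part of the SAD
(lognormal(1.5, 1)), and the specialist kernel is mass-normalised
(filtering concentrates a specialist in its niche rather than thinning
it out of the pool). Both exist because a niche label on a taxon
observed a handful of times is not verifiable ground truth — no
statistic can distinguish a rare specialist from a rare generalist — so
planting labels there would make recovery metrics meaningless.

Phylogenies are Yule trees (uniform splitting, exponential waiting
times); habitat optima evolve by Brownian motion and are blended with an
independent draw by `signal_strength` (1 = fully heritable, 0 =
independent of the tree). Neutral tables draw local relative abundances
from Sloan's Beta stationary approximation and multinomial-sample reads —
exactly the model the NCM fit assumes, making parameter recovery a clean
test. Environmental covariates are one latent Gaussian field per block,
indicators loading 0.8 on it; known path coefficients generate richness
responses with noise completing the variance to 1, so nominal
coefficients are on the standardised scale the path model estimates.

What the generator does **not** emulate: compositional coupling beyond
the multinomial constraint, PCR/sequencing error and chimeras, taxon
interactions (network edges in synthetic data arise from shared
environmental filtering only), multivariate or temporally varying
niches, and uneven read depth. Passing recovery tests therefore show the
estimators are correct under their own assumptions, not that those
assumptions hold in any particular soil data set.

## Problem sizes and numerics

The test suite exercises full-scale classification (120 × 1000, 1000
permutations, three seeds) and otherwise uses a 24-sample / 200-OTU
miniature of the same design with null counts of 99–999, sized so the
whole suite runs in minutes on one core. The acceptance script runs the
complete pipeline at full scale with 1000 classification permutations,
199 assembly nulls and 200 swap nulls per subcommunity. All randomness
flows from one integer seed through `numpy.random.SeedSequence`
spawning; per-stage seeds derive from the master seed and the stage name
(CRC32), so every stage is independently reproducible. Quantile
estimates are linear (type-7); βNTI pairs with null sd ≤ 1e-12 are
treated as degenerate; Beta draws are clipped away from 0 before
renormalisation to avoid 0/0 in extremely small Nm·p regimes.

## Known limitations

* The quasiswap fill-adjustment assumes the observed fill is reachable
  from the hypergeometric draw by fill-monotone unit swaps; for
  pathological marginals the generator emits the closest-fill matrix
  with a warning rather than failing.
* RC-Bray null draws require sample richness ≤ OTU count and nonzero
  occurrence frequencies; tables should be cleaned with
  `drop_empty_otus` first.
* PLS-PM is estimated, not tested: no measurement-model fit indices
  beyond GoF are reported, and formative (mode B) blocks are out of
  scope.
* Subcommunity analyses renormalise within the subset and drop samples
  that lose all their OTUs; comparisons across subcommunities of very
  different sizes inherit the usual caveats of unequal pair counts.
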