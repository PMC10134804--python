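# Methods

This note documents the models, their numerical conventions, the synthetic
data the test suite relies on, and the design choices made where more than
one defensible option existed.

## Preprocessing

Counts are rarefied to a common depth by exact multivariate-hypergeometric
subsampling (without replacement); samples below the target depth are
dropped, not padded, so every retained row sums to the depth exactly. The
default depth (30,082) and the 20% prevalence filter reflect a typical
two-season amplicon survey design; both are configuration fields. The
prevalence cutoff keeps taxa with nonzero counts in at least
⌈fraction × n_samples⌉ samples, so a taxon sitting exactly on the boundary is
kept. Shannon diversity uses the natural log. Faith's PD is root-inclusive:
the branch length of the union of root-to-tip paths of the present taxa, so
PD over all tips equals the tree's total branch length. Bray–Curtis is
computed on counts; after rarefaction this is equivalent to using relative
abundances.

## Co-occurrence network

Edges require |Spearman ρ| > 0.8 **and** BH-adjusted q < 0.01, both strict,
evaluated on the upper triangle of the all-pairs matrix (a raw-p mode is
available via `use_adjusted=False`). Zero-variance taxa are kept in the
matrix with ρ = 0 and q = 1 and flagged, so matrix shape is stable; isolated
nodes are pruned from the graph by default (node counts then refer to
connected taxa). Modules come from seeded Louvain modularity maximisation;
module ids are ordered by decreasing size. The degree-distribution power law
is a descriptive OLS fit of log₁₀ P(k) on log₁₀ k over observed nonzero
degrees — it mirrors the R²-style reporting customary in this literature and
makes no maximum-likelihood claim.

Natural connectivity is computed as logsumexp(λ) − ln n for overflow safety
and equals the dense-eigendecomposition value to 1e−9 (tested exhaustively on
small graphs against a matrix-exponential-trace oracle). Robustness curves
remove a grid of node fractions (random removals averaged over repetitions,
or deterministic descending-degree order) and refit a line. Two slopes are
reported: the absolute slope of λ̄, and the slope of λ̄ normalised to its
intact value. Networks of different density are only comparable on the
normalised scale — a dense network starts at λ̄ ≈ mean degree and therefore
loses more absolute λ̄ per removed fraction even when it is structurally the
more redundant one. Vulnerability follows the efficiency definition
exactly: E = 0 networks get V = 0 with a warning. Node-level betweenness is
reported unnormalised.

## Neutral community model

The Sloan model gives each taxon a Beta(Nmp, Nm(1−p)) marginal for local
relative abundance. Predicted occupancy is, by default, the exact
probability of detection at depth N:

F(p) = 1 − E[(1−q)^N] = 1 − B(Nmp, Nm(1−p)+N) / B(Nmp, Nm(1−p)),

i.e. the beta marginal pushed through binomial sampling. The classical
hard-threshold form F(p) = 1 − BetaCDF(d; Nmp, Nm(1−p)) with d = 1/N is
available as `detection="threshold"`; the two agree for common taxa but the
threshold form understates rare-taxon occupancy at finite depth, which
biases the fitted Nm upward by ~15–20% on depth-30,000 data. m is fitted by
bounded least squares multi-started from {0.01, 0.1, 0.5}; N is the mean
sample depth; occupancy uses presence = count ≥ 1; R² is computed on
occupancies and may be negative for ill-fitting data.

Taxa are classified against a 95% Wilson score interval computed at the
predicted frequency with n = number of samples. This is the conventional
construction, and it is worth being explicit about what it is not: a Wilson
interval is a confidence interval for a proportion given an observation, not
an acceptance region for a future binomial observation. For a taxon with
predicted occupancy near 1 the observed occupancy is exactly 1 with high
probability, yet the interval's upper bound sits just below 1, so saturated
taxa are systematically labelled "above"; estimation noise in p adds further
spread for rare taxa. On ideal neutral simulations the "within" fraction is
therefore ~0.65–0.8, not the nominal 0.95 — a property of the construction
itself, visible in published occupancy–abundance figures as the row of
occupancy-1 points above the band.

## Phylogenetic-bin null models

Binning marks, in post-order, the smallest clades containing at least
`n_min` (default 24) yet-unassigned analysed tips; leftover strays join the
bin of their nearest analysed neighbour by patristic distance. The
partition is deterministic given the tree.

βMPD between samples k and l within a bin is the abundance-weighted mean
pairwise patristic distance fₖᵀ D fₗ (within-bin relative abundances). The
βNRI null shuffles the bin's taxa across the bin's tip positions (distances
permuted jointly, abundances fixed); βNRI is the z-score over (default)
1,000 shuffles, with βNRI := 0 when the null sd is at rounding-error scale
(e.g. a star tree, where no shuffle can move the statistic). Whole-tree
shuffling is not used: the statistic is a *within-bin* standardised effect.
One statistic (standardised βMPD) with the ±1.96 cutoff is used throughout;
the nearest-taxon variant (βMNTD/βNTI) is an extension point, not
implemented.

RC_Bray builds null communities per sample preserving observed within-bin
richness and total abundance: taxa drawn without replacement with
probability ∝ occupancy frequency, individuals filled multinomially ∝ pool
relative abundance; RC = 2·[P(null BC < obs) + ½P(null BC = obs)] − 1.
Pairs in which the bin is absent from either sample are skipped and logged.
Classification uses strict inequalities; boundary values (±1.96, ±0.95) fall
to the stochastic side.

Community-level fractions weight each bin's call fractions by its mean
relative abundance (computed on the analysed, optionally top-K, taxa and
renormalised over bins with calls). Scopes: all pairs, within-season,
per-season, within-group/between-group, per-group. Environmental
correlations pair each sample pair's process weight with the *mean* of the
two samples' environmental values (a difference-based convention would be a
one-line change); BH correction is applied across each output table.

## Distance-matrix statistics

Mantel uses the correlation (Spearman by default) of off-diagonal vectors
with joint row/column permutation of one matrix; p is one-sided greater,
(1 + #{r_perm ≥ r_obs})/(1 + n_perm), so it can never be 0; an exact mode
enumerates all n! relabelings for tiny n. bioenv standardises the
environmental variables and searches *all* nonempty subsets (2¹¹ − 1 at the
full variable set is cheap); ties break toward smaller subsets, then
lexicographically. MRM regresses the vectorised distance matrix on the
predictors' vectorised matrices with an intercept; coefficients come from
least squares (pseudo-inverse under collinearity, with the condition number
logged) and p-values from joint permutation of the response matrix,
two-sided on |β|. The module×environment grid computes Bray–Curtis on each
of the top-5 modules' relative-abundance sub-tables against per-variable
Euclidean distances plus richness and PD distances, BH-corrected across the
grid.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical structure each stage assumes, at
sizes chosen so the full validation runs in minutes on one CPU (the study
design they mirror — 120 samples in two seasons across 7 groups, rarefied
depth ≈ 3×10⁴, thousands of taxa — is reachable by configuration).

* `simulate_neutral` draws per-sample relative abundances
  Dirichlet(Nm·p) and counts multinomially — exactly the finite-sample
  realisation of the Sloan beta marginals, so the NCM fit has a true Nm to
  recover. The default pool is lognormal with σ = 2.0, a moderate
  species-abundance-distribution skew typical of soil amplicon data; a
  log-series option exists.
* `simulate_assembly` implements four regimes. Their defaults are the
  regimes' definitions, not neutral knobs: the drift regime couples local
  communities weakly to the pool (Nm = 50), so composition is
  drift-dominated; the filtering regime couples tightly (Nm = 2000) and
  weights taxa by a Gaussian response of a phylogenetically conserved trait
  to a group-level optimum. Traits evolve by Brownian motion with steps
  suppressed on branches subtending fewer than 8 tips, putting trait
  variance at clade level — the pattern of ecological coherence documented
  for deep bacterial lineages, and the signal a within-bin phylogenetic null
  model can actually detect. Optima are identical within a group and spread
  across groups, so same-group pairs experience homogeneous selection and
  cross-group pairs heterogeneous selection. The dispersal-limited regime
  gives each spatial block its own disjoint pool support softened by a
  migration rate. The selection regime uses a flatter pool (lognormal
  σ = 0.8) so the niche response, not pool dominance, decides which clade
  members carry abundance; the stochastic regimes use σ = 1.5.
* `simulate_correlated_blocks` plants module-shared latent factors in
  log-abundance space; `sampled=False` returns un-closed absolute
  intensities so the planted rank structure is exact (compositional closure
  would cancel a factor shared by *all* taxa).
* `simulate_environment` draws the 11 edaphic/climatic variables from
  season-specific Gaussians whose default means follow a temperate-monsoon
  riparian soil (wet season = summer: higher temperature, precipitation,
  pH, moisture, carbon; nitrate higher in the dry season).

What passing tests on these data do **not** show: robustness to sequencing
noise, chimeras or compositional artefacts; correct behaviour when the tree
is badly mis-estimated; realistic co-variation between environment and
phylogeny beyond the single conserved trait; or survey-scale taxon counts
(tens of thousands), where runtime rather than correctness becomes the
constraint.

Detection of homogeneous selection by a βMPD-based within-bin statistic is
intrinsically realisation-dependent: it requires the favoured taxa to be
phylogenetically clustered inside bins, and any trait model with independent
clade effects produces some realisations where they are not. Validation
therefore pools replicate simulations (4 seeds) and evaluates the
within-environment pair fractions, where homogeneous selection is reliably
the largest community-level fraction.

## Numerical conventions and degenerate inputs

Seeds: every stochastic stage consumes a child seed derived from the global
seed via `numpy.random.SeedSequence.spawn` (all children < 2³¹). Louvain
ties and module ordering are made deterministic by size-then-lexicographic
sorting. All-zero samples get richness/Shannon/PD of 0; Bray–Curtis between
two all-zero samples is defined as 0 with a warning. Mantel/bioenv require
≥ 4 samples; Spearman p-values require ≥ 4 observations. The unknown-key
check on the pipeline configuration is a hard error to protect against
threshold typos.

## Validation problem sizes

The default validation runs use 150-tip trees, 24–28 samples, depth 3,000,
bins of ≥ 25 taxa and 200 null randomisations (scaled from the production
default of 1,000); neutral-model recovery uses the study-scale 60 samples ×
500 taxa × depth 30,000 over 20 seeds. These sizes give stable statistics
(binomial standard errors of a few percent on the calibration fractions)
while keeping the whole suite and the acceptance script each within a few
minutes on a single CPU.
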