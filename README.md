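# riparia

Analysis toolkit for seasonal soil/sediment microbiome surveys: co-occurrence
network inference with stability and robustness metrics, Sloan's neutral
community model, and phylogenetic-bin null models that partition community
assembly into five ecological processes, together with the distance-matrix
statistics (Mantel, bioenv, MRM) that link all of it to the environment.

It is aimed at microbial ecologists working with an OTU/ASV count table
(samples × taxa), a rooted phylogeny over the taxa, and per-sample metadata
(season, site group, edaphic variables). A seeded synthetic-data module
generates communities with known assembly regimes, so every stage of the
pipeline can be validated against a ground truth.

## The models

**Co-occurrence network.** All-pairs Spearman correlations between taxa;
edges where |ρ| > 0.8 and the Benjamini–Hochberg-adjusted p-value is < 0.01
(both strict). Topology is summarised by modularity (seeded Louvain),
clustering, path length and a descriptive power-law fit of the degree
distribution, and compared against Erdős–Rényi G(n, m) nulls. Stability is
measured by natural connectivity

λ̄ = ln( (1/n) Σᵢ exp(λᵢ) ),

with λᵢ the adjacency eigenvalues, tracked while removing growing fractions
of nodes; network efficiency E = mean of 1/d(i,j) over pairs, and
vulnerability V = maxᵢ (E − E₋ᵢ)/E.

**Neutral community model (Sloan).** For a taxon with metacommunity mean
relative abundance p, the local relative abundance is Beta(Nmp, Nm(1−p));
predicted occupancy is the probability of detecting at least one read at
depth N. The single parameter m (immigration) is fitted by nonlinear least
squares on the occupancy–abundance cloud; taxa are classified against a 95%
Wilson score band around the fitted curve.

**Assembly-process partition.** Taxa are grouped into phylogenetic bins
(smallest clades with ≥ 24 analysed tips; strays merged to the nearest
neighbour's bin). Per bin and sample pair, βNRI (the z-score of the
abundance-weighted between-community mean pairwise phylogenetic distance
against a within-bin taxon shuffle) and RC_Bray (Raup–Crick on Bray–Curtis
under a richness- and abundance-preserving null) classify the pair:
βNRI < −1.96 → homogeneous selection (HoS), βNRI > 1.96 → heterogeneous
selection (HeS), otherwise RC > 0.95 → dispersal limitation (DL),
RC < −0.95 → homogenising dispersal (HD), else drift (DR). Bin-level
fractions are aggregated to community level weighted by bin relative
abundance.

## Worked example

```python
from riparia.simulate import NeutralSimConfig, simulate_neutral
from riparia.ncm import SloanNCM

cfg = NeutralSimConfig(n_taxa_pool=500, n_samples=60, depth=30_000,
                       Nm=1000, seed=1)
table = simulate_neutral(cfg)
print(SloanNCM(table).fit().summary())
```

```
Sloan neutral community model
==================================
samples           60
taxa              500
N (mean depth)    30000.0
m (immigration)   0.03418
Nm                1025.4
R2                0.9675
above / within / below band   0.254 / 0.696 / 0.050
```

The community was simulated with Nm = 1000; the fit recovers Nm = 1025 (2.5%
off) with R² = 0.97, and classifies each taxon against the 95% band (here
70% fall within; see `docs/methods.md` for why saturated taxa sit above it).

The network stage works the same way:

```python
from riparia.simulate import NetworkSimConfig, simulate_correlated_blocks
from riparia.network import CooccurrenceNetwork

net = NetworkSimConfig(n_taxa=100, n_samples=60, n_modules=5,
                       loading=0.9, noise_sd=0.3, seed=2)
res = CooccurrenceNetwork(simulate_correlated_blocks(net)).fit(seed=0)
print(res.summary())
```

```
Co-occurrence network summary
==================================
taxa analysed     100
nodes (connected) 100
edges             893
positive edges    1.000
average degree    17.860
clustering coeff  0.956
avg path length   1.095
modularity Q      0.799
power-law gamma   -2.465 (R2 0.460)
edge rule         |rho| > 0.8, q < 0.01
```

The five planted modules are recovered exactly (ARI = 1.0 against the
generator's labels) and the modularity of 0.80 stands far outside the
Erdős–Rényi null. `res.robustness()`, `res.node_metrics()` and
`res.random_ensemble()` give the stability quantities.

A command-line interface mirrors the library
(`riparia simulate|preprocess|network|ncm|assembly|envassoc|run|compare`);
`riparia run --config cfg.yaml` executes the full pipeline with a provenance
manifest.

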