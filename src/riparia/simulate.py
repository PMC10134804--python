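"""Seeded synthetic-data generators.

These produce community tables, trees and environment frames with the
statistical structure each analysis stage assumes:

* :func:`simulate_neutral` draws Dirichlet-multinomial communities whose
  relative-abundance marginals are exactly the beta distributions of the
  Sloan neutral model, so the NCM fit has a true parameter to recover.
* :func:`simulate_assembly` assembles communities under neutral drift,
  Brownian-trait environmental filtering, or block-structured dispersal
  limitation (or a per-taxon mixture), the regimes the bin-based null models
  are meant to tell apart.
* :func:`simulate_correlated_blocks` plants modular rank-correlation
  structure for the co-occurrence network machinery.
* :func:`simulate_environment` emulates a two-season, seven-group sampling
  design with season-shifted edaphic variables.

Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .core import CommunityTable, PhyloTree, SampleFrame, ENV_VARIABLES, GROUP_LEVELS

__all__ = [
    "NeutralSimConfig",
    "AssemblySimConfig",
    "NetworkSimConfig",
    "simulate_tree",
    "simulate_neutral",
    "simulate_assembly",
    "simulate_correlated_blocks",
    "simulate_environment",
    "DEFAULT_SEASON_EFFECTS",
]


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass
class NeutralSimConfig:
    """Dirichlet-multinomial neutral community simulation settings.

    ``Nm`` is the metacommunity-size x immigration product of the Sloan
    model (dimensionless); per-sample relative abundances are Dirichlet with
    concentration ``Nm * p`` around metacommunity proportions ``p``.
    """

    n_taxa_pool: int = 500
    n_samples: int = 60
    depth: int = 30_000
    Nm: float = 1000.0
    pool_distribution: tuple = ("lognormal", 2.0)  # or ("logseries", theta)
    seed: int = 0

    def __post_init__(self):
        if self.Nm <= 0:
            raise ValueError("Nm must be > 0")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


@dataclass
class AssemblySimConfig:
    """Community-assembly regime simulation settings.

    regime
        ``drift`` (neutral sampling from a shared pool), ``filtering``
        (Brownian-conserved environmental optima with Gaussian responses,
        optima identical within a group), ``dispersal_limited`` (independent
        per-block pools mixed by ``migration_rate``), or ``mixture``
        (per-taxon regime assignment).
    trait_conservatism
        Brownian-motion rate for trait evolution on the tree.
    trait_clade_size
        Trait steps on branches subtending fewer than this many tips are
        suppressed, so habitat preference is conserved within small clades
        and diverges among larger ones (the documented pattern of ecological
        coherence in deep bacterial lineages).
    env_optimum, env_between_sd
        Group-level selective optima are drawn as
        ``env_optimum + N(0, env_between_sd)`` on the standardised trait
        scale and shared by every sample of the group, so same-group pairs
        experience homogeneous selection and different-group pairs
        heterogeneous selection.
    """

    regime: str = "drift"
    n_samples: int = 30
    depth: int = 3000
    Nm: float | None = None
    n_groups: int = 7
    env_optimum: float = 0.0
    env_between_sd: float = 1.2
    niche_width: float = 0.4
    trait_conservatism: float = 1.0
    trait_clade_size: int = 8
    n_blocks: int = 3
    migration_rate: float = 0.05
    mixture_weights: tuple = (0.4, 0.3, 0.3)  # drift, filtering, dispersal
    pool_distribution: tuple | None = None
    seed: int = 0

    REGIMES = ("drift", "filtering", "dispersal_limited", "mixture")
    #: per-regime local-community coupling to the (possibly selected) pool:
    #: the drift regime is drift-dominated (weak coupling), the selection
    #: regime is selection-dominated (tight coupling)
    DEFAULT_NM = {
        "drift": 50.0,
        "filtering": 2000.0,
        "dispersal_limited": 200.0,
        "mixture": 200.0,
    }
    #: per-regime metacommunity evenness: stochastic regimes use the long-
    #: tailed pool typical of neutral assemblages; the selection regime uses
    #: a flatter pool so the niche response, not pool dominance, sets which
    #: clade members carry abundance
    DEFAULT_POOL = {
        "drift": ("lognormal", 1.5),
        "filtering": ("lognormal", 0.8),
        "dispersal_limited": ("lognormal", 1.5),
        "mixture": ("lognormal", 1.2),
    }

    def __post_init__(self):
        if self.regime not in self.REGIMES:
            raise ValueError(f"regime must be one of {self.REGIMES}")
        if self.regime == "mixture" and abs(sum(self.mixture_weights) - 1) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if self.Nm is None:
            self.Nm = self.DEFAULT_NM[self.regime]
        if self.pool_distribution is None:
            self.pool_distribution = self.DEFAULT_POOL[self.regime]
        if self.Nm <= 0:
            raise ValueError("Nm must be > 0")
        if self.trait_clade_size < 1:
            raise ValueError("trait_clade_size must be >= 1")


@dataclass
class NetworkSimConfig:
    """Planted-module correlation structure settings."""

    n_taxa: int = 100
    n_samples: int = 60
    n_modules: int = 5
    loading: float = 0.9
    noise_sd: float = 0.3
    depth: int = 20_000
    seed: int = 0

    def __post_init__(self):
        if self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")
        if not 0 < self.loading <= 1:
            raise ValueError("loading must be in (0, 1]")


# ---------------------------------------------------------------------------
# tree
# ---------------------------------------------------------------------------

def simulate_tree(n_tips: int, seed: int, branch_scale: float = 0.1) -> PhyloTree:
    """Random Yule (pure-birth) tree with exponential branch lengths.

    Tips are labelled ``T0001`` ... in birth order; the tree is rooted and
    binary but not ultrametric.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    labels = [f"T{i+1:04d}" for i in range(n_tips)]
    root = TreeNode(length=None)
    a, b = TreeNode(name=labels[0]), TreeNode(name=labels[1])
    root.extend([a, b])
    tips = [a, b]
    for i in range(2, n_tips):
        parent = tips[rng.integers(len(tips))]
        left = TreeNode(name=parent.name)
        right = TreeNode(name=labels[i])
        parent.name = None
        parent.extend([left, right])
        tips.remove(parent)
        tips.extend([left, right])
    for node in root.traverse(include_self=False):
        node.length = float(rng.exponential(branch_scale)) + 1e-6
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# pools and neutral sampling
# ---------------------------------------------------------------------------

def _draw_pool(rng, n_taxa, pool_distribution) -> np.ndarray:
    """Metacommunity proportions with a long-tailed (log-series-like) shape."""
    kind = pool_distribution[0]
    if kind == "lognormal":
        sigma = pool_distribution[1]
        raw = rng.lognormal(mean=0.0, sigma=sigma, size=n_taxa)
    elif kind == "logseries":
        theta = pool_distribution[1]
        raw = rng.logseries(theta, size=n_taxa).astype(float)
        raw *= rng.uniform(0.5, 1.5, size=n_taxa)  # break integer ties
    else:
        raise ValueError(f"unknown pool distribution {kind!r}")
    return raw / raw.sum()


def _dirichlet_multinomial(rng, pool, Nm, n_samples, depth):
    """Sample counts whose relative abundances are Dirichlet(Nm * pool)."""
    alpha = np.maximum(Nm * pool, 1e-12)
    counts = np.empty((n_samples, pool.size), dtype=np.int64)
    for i in range(n_samples):
        rel = rng.dirichlet(alpha)
        counts[i] = rng.multinomial(depth, rel)
    return counts


def simulate_neutral(config: NeutralSimConfig) -> CommunityTable:
    """Neutral communities with exact Sloan-model beta marginals."""
    rng = np.random.default_rng(config.seed)
    pool = _draw_pool(rng, config.n_taxa_pool, config.pool_distribution)
    counts = _dirichlet_multinomial(
        rng, pool, config.Nm, config.n_samples, config.depth
    )
    return CommunityTable(
        counts,
        [f"S{i+1:03d}" for i in range(config.n_samples)],
        [f"T{i+1:04d}" for i in range(config.n_taxa_pool)],
    )


# ---------------------------------------------------------------------------
# assembly regimes
# ---------------------------------------------------------------------------

def _brownian_traits(
    tree: PhyloTree, rate: float, rng, min_clade: int = 1, damp: float = 0.01
) -> dict:
    """Evolve a trait by Brownian motion along the tree; returns tip values.

    Branches subtending fewer than ``min_clade`` tips take only ``damp`` of
    the Brownian rate, so trait variance concentrates on the clade-level
    structure: members of small clades share near-identical values while
    larger clades diverge.  ``min_clade=1`` is plain Brownian motion.
    """
    sizes = {}
    for node in tree.tree.postorder(include_self=True):
        sizes[id(node)] = (
            1 if node.is_tip() else sum(sizes[id(c)] for c in node.children)
        )
    values = {id(tree.tree): 0.0}
    for node in tree.tree.preorder(include_self=False):
        parent_val = values[id(node.parent)]
        length = node.length or 0.0
        if sizes[id(node)] < min_clade:
            length *= damp
        step = rng.normal(0.0, np.sqrt(max(rate * length, 1e-12)))
        values[id(node)] = parent_val + step
    return {tip.name: values[id(tip)] for tip in tree.tree.tips()}


def _sample_layout(n_samples, n_groups):
    seasons = ["wet" if i < n_samples // 2 else "dry" for i in range(n_samples)]
    groups = [GROUP_LEVELS[i % n_groups] for i in range(n_samples)]
    ids = [f"S{i+1:03d}" for i in range(n_samples)]
    return ids, seasons, groups


def _env_frame(ids, seasons, groups, temperature, rng) -> SampleFrame:
    """Metadata frame; ``temperature`` carries the selective gradient, the
    remaining variables are season-shifted fillers."""
    data = {"season": seasons, "group": groups}
    effects = DEFAULT_SEASON_EFFECTS
    for var in ENV_VARIABLES:
        if var == "temperature":
            data[var] = temperature
        else:
            wet_mu, dry_mu, sd = effects[var]
            mu = np.where(np.array(seasons) == "wet", wet_mu, dry_mu)
            data[var] = mu + rng.normal(0, sd, size=len(ids))
    return SampleFrame(pd.DataFrame(data, index=ids))


def simulate_assembly(config: AssemblySimConfig, tree: PhyloTree):
    """Communities assembled under a chosen ecological regime.

    Returns ``(CommunityTable, SampleFrame)``; taxa are the tree's tips.
    """
    rng = np.random.default_rng(config.seed)
    taxa = list(tree.tip_names)
    n_taxa = len(taxa)
    ids, seasons, groups = _sample_layout(config.n_samples, config.n_groups)
    pool = _draw_pool(rng, n_taxa, config.pool_distribution)

    if config.regime == "mixture":
        regime_of_taxon = rng.choice(3, size=n_taxa, p=list(config.mixture_weights))
    elif config.regime == "drift":
        regime_of_taxon = np.zeros(n_taxa, dtype=int)
    elif config.regime == "filtering":
        regime_of_taxon = np.ones(n_taxa, dtype=int)
    else:
        regime_of_taxon = np.full(n_taxa, 2, dtype=int)

    # environmental optima with phylogenetic signal; the selective optimum
    # sits in a trait tail (a derived state), so the favoured taxa form a
    # phylogenetically coherent set rather than the ancestral middle
    traits = _brownian_traits(tree, config.trait_conservatism, rng,
                              min_clade=config.trait_clade_size)
    trait_vec = np.array([traits[t] for t in taxa])
    trait_vec = (trait_vec - trait_vec.mean()) / (trait_vec.std() or 1.0)
    group_env = {g: config.env_optimum + rng.normal(0.0, config.env_between_sd)
                 for g in dict.fromkeys(groups)}
    env_of_sample = np.array([group_env[g] for g in groups])

    # block pools for dispersal limitation: disjoint supports mixed with the
    # global pool by the migration rate
    block_of_sample = np.array(
        [GROUP_LEVELS.index(g) % config.n_blocks for g in groups]
    )
    taxon_block = rng.integers(config.n_blocks, size=n_taxa)
    block_pools = []
    for b in range(config.n_blocks):
        mask = taxon_block == b
        own = np.where(mask, pool, 0.0)
        if own.sum() == 0:
            own = pool.copy()
        own = own / own.sum()
        mixed = (1 - config.migration_rate) * own + config.migration_rate * pool
        block_pools.append(mixed / mixed.sum())

    counts = np.empty((config.n_samples, n_taxa), dtype=np.int64)
    for s in range(config.n_samples):
        w = pool.copy()
        sel = regime_of_taxon == 1
        if sel.any():
            gauss = np.exp(
                -((trait_vec[sel] - env_of_sample[s]) ** 2)
                / (2 * config.niche_width**2)
            )
            w[sel] = pool[sel] * np.maximum(gauss, 1e-12)
        disp = regime_of_taxon == 2
        if disp.any():
            w[disp] = block_pools[block_of_sample[s]][disp]
        w = np.maximum(w, 0)
        w = w / w.sum()
        rel = rng.dirichlet(np.maximum(config.Nm * w, 1e-12))
        counts[s] = rng.multinomial(config.depth, rel)

    table = CommunityTable(counts, ids, taxa)
    frame = _env_frame(ids, seasons, groups, env_of_sample, rng)
    return table, frame


# ---------------------------------------------------------------------------
# correlated blocks for network recovery
# ---------------------------------------------------------------------------

def simulate_correlated_blocks(
    config: NetworkSimConfig, sampled: bool = True
) -> CommunityTable:
    """Taxa grouped into modules sharing a latent factor over samples.

    Log-abundance of taxon i in sample s is ``loading * z_{m(i)}(s) +
    noise_sd * eps``; exponentiated, normalised, and (if ``sampled``)
    multinomially resampled at ``depth`` reads.  Within-module pairs are
    strongly rank-correlated, across-module pairs approximately independent.
    The planted module label is stored in ``taxonomy``.
    """
    rng = np.random.default_rng(config.seed)
    module_of = np.arange(config.n_taxa) % config.n_modules
    z = rng.normal(size=(config.n_samples, config.n_modules))
    base = rng.lognormal(0.0, 1.0, size=config.n_taxa)
    log_ab = config.loading * z[:, module_of] + config.noise_sd * rng.normal(
        size=(config.n_samples, config.n_taxa)
    )
    intensity = base * np.exp(log_ab)
    if sampled:
        rel = intensity / intensity.sum(axis=1, keepdims=True)
        counts = np.vstack(
            [rng.multinomial(config.depth, rel[s]) for s in range(config.n_samples)]
        )
    else:
        # absolute intensities (no compositional closure): preserves the
        # planted rank structure exactly
        counts = np.round(intensity * 1e5).astype(np.int64)
    taxa = [f"T{i+1:04d}" for i in range(config.n_taxa)]
    taxonomy = {t: f"Module{module_of[i] + 1}" for i, t in enumerate(taxa)}
    return CommunityTable(
        counts,
        [f"S{i+1:03d}" for i in range(config.n_samples)],
        taxa,
        taxonomy=taxonomy,
    )


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------

#: per-variable (wet mean, dry mean, sd): a temperate-monsoon riparian soil,
#: wet season = summer flood period.  Units: temperature degC, precipitation
#: mm/month, SM %, DOC/DON/NH4/NO3 mg/kg, TC/TN g/kg.
DEFAULT_SEASON_EFFECTS = {
    "temperature": (26.0, 5.0, 2.0),
    "precipitation": (180.0, 15.0, 20.0),
    "pH": (8.3, 8.0, 0.15),
    "SM": (26.0, 18.0, 4.0),
    "DOC": (120.0, 90.0, 15.0),
    "DON": (12.0, 9.0, 2.0),
    "NH4_N": (6.5, 4.0, 1.0),
    "NO3_N": (8.0, 10.5, 2.0),
    "TC": (12.5, 10.0, 1.5),
    "TN": (1.25, 1.2, 0.15),
    "CN_ratio": (10.0, 8.5, 1.0),
}


def simulate_environment(
    n_samples: int = 120,
    season_effects: dict | None = None,
    seed: int = 0,
    n_groups: int = 7,
) -> SampleFrame:
    """Two-season x seven-group environment frame with Gaussian variables.

    The default layout is 60 wet + 60 dry samples spread across the groups;
    ``season_effects`` maps variable -> (wet mean, dry mean, sd).
    """
    effects = dict(DEFAULT_SEASON_EFFECTS)
    if season_effects:
        effects.update(season_effects)
    rng = np.random.default_rng(seed)
    half = n_samples // 2
    seasons = ["wet"] * half + ["dry"] * (n_samples - half)
    groups = [GROUP_LEVELS[i % n_groups] for i in range(half)] + [
        GROUP_LEVELS[i % n_groups] for i in range(n_samples - half)
    ]
    ids = [f"{seasons[i]}_{groups[i]}_r{i+1:03d}" for i in range(n_samples)]
    data = {"season": seasons, "group": groups}
    for var in ENV_VARIABLES:
        wet_mu, dry_mu, sd = effects[var]
        mu = np.where(np.array(seasons) == "wet", wet_mu, dry_mu)
        data[var] = mu + rng.normal(0.0, sd, size=n_samples)
    return SampleFrame(pd.DataFrame(data, index=ids))
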