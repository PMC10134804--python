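"""Phylogenetic-bin null models partitioning community assembly processes.

Taxa are grouped into phylogenetic bins (smallest monophyletic clades with at
least ``n_min`` analysed tips; strays merged to their nearest neighbour's
bin).  Within each bin and for every pair of samples two null-model statistics
are computed:

* beta-NRI — the standardised (z-score) abundance-weighted between-community
  mean pairwise phylogenetic distance (betaMPD), against a null that shuffles
  the bin's taxa across its tip positions.  |betaNRI| > 1.96 indicates
  deterministic selection: homogeneous (HoS) if betaNRI < -1.96,
  heterogeneous (HeS) if > +1.96.
* RC-Bray — Raup-Crick on Bray-Curtis under a null preserving each sample's
  within-bin richness and abundance, taxa drawn proportionally to occupancy
  and filled proportionally to pool abundance.  For pairs not under
  selection, RC > +0.95 calls dispersal limitation (DL), RC < -0.95
  homogenising dispersal (HD), and anything between is drift (DR).

Bin-level process fractions are aggregated to community level weighted by bin
relative abundance.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy import stats as ss

from .core import CommunityTable, PhyloTree, SampleFrame
from .stats import bh_fdr, spawn_seeds

logger = logging.getLogger("riparia")

__all__ = [
    "PROCESSES",
    "PhyloBin",
    "bin_taxa",
    "beta_mpd",
    "bnri",
    "rc_bray",
    "classify_pair",
    "AssemblyModel",
    "AssemblyResults",
    "ProcessPartition",
    "process_env_correlation",
]

PROCESSES = ("HoS", "HeS", "DL", "HD", "DR")


@dataclass
class PhyloBin:
    bin_id: str
    members: list
    weight: float = float("nan")  # mean relative-abundance share


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def bin_taxa(tree: PhyloTree, taxa, n_min: int = 24) -> list[PhyloBin]:
    """Partition analysed taxa into phylogenetic bins.

    Post-order traversal marks the smallest clades containing at least
    ``n_min`` yet-unassigned analysed tips as bins; leftover strays are
    merged into the bin holding their nearest analysed neighbour by
    patristic distance.  Deterministic given the tree.
    """
    if n_min < 2:
        raise ValueError("n_min must be >= 2")
    taxa = list(taxa)
    analysed = set(taxa)
    missing = analysed - set(tree.tip_names)
    if missing:
        raise KeyError(f"taxa not in tree: {sorted(missing)}")
    if len(taxa) < n_min:
        warnings.warn(
            f"fewer than n_min={n_min} taxa; returning a single bin", stacklevel=2
        )
        return [PhyloBin("Bin1", sorted(taxa))]

    carried: dict[int, list] = {}
    bins: list[list] = []
    for node in tree.tree.postorder(include_self=True):
        if node.is_tip():
            carried[id(node)] = [node.name] if node.name in analysed else []
        else:
            acc = []
            for child in node.children:
                acc.extend(carried.pop(id(child), []))
            if len(acc) >= n_min:
                bins.append(sorted(acc))
                acc = []
            carried[id(node)] = acc
    strays = carried.pop(id(tree.tree), [])

    if not bins:  # cannot happen given the n_min guard, but stay safe
        return [PhyloBin("Bin1", sorted(taxa))]
    if strays:
        dm = tree.patristic_distances(taxa)
        index = {t: i for i, t in enumerate(taxa)}
        bin_of = {}
        for b, members in enumerate(bins):
            for t in members:
                bin_of[t] = b
        for stray in strays:
            i = index[stray]
            others = [t for t in taxa if t != stray and t in bin_of]
            nearest = min(others, key=lambda t: (dm.data[i, index[t]], t))
            bins[bin_of[nearest]].append(stray)
        bins = [sorted(b) for b in bins]
    return [PhyloBin(f"Bin{i+1}", members) for i, members in enumerate(bins)]


# ---------------------------------------------------------------------------
# betaMPD / betaNRI
# ---------------------------------------------------------------------------

def beta_mpd(f_k: np.ndarray, f_l: np.ndarray, d: np.ndarray) -> float:
    """Abundance-weighted between-community mean pairwise distance.

    ``f_k``/``f_l`` are within-bin relative abundances (each sums to 1) and
    ``d`` the patristic distance matrix over the bin's taxa.
    """
    f_k = np.asarray(f_k, float)
    f_l = np.asarray(f_l, float)
    if f_k.sum() <= 0 or f_l.sum() <= 0:
        raise ValueError("bin absent from a community; betaMPD undefined")
    f_k = f_k / f_k.sum()
    f_l = f_l / f_l.sum()
    return float(0.5 * (f_k @ d @ f_l + f_l @ d @ f_k))


def _normalise_rows(x: np.ndarray) -> np.ndarray:
    totals = x.sum(axis=1, keepdims=True)
    out = np.zeros_like(x, dtype=float)
    nz = totals[:, 0] > 0
    out[nz] = x[nz] / totals[nz]
    return out


def bnri(
    sub_counts: np.ndarray,
    d: np.ndarray,
    pairs: list[tuple[int, int]],
    n_null: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Per-pair betaNRI for one bin.

    ``sub_counts`` is samples x bin-taxa; the null shuffles the bin's taxa
    across the bin's tip positions (rows/columns of ``d`` permuted jointly)
    with abundances fixed.  Pairs whose observed betaMPD null sd is 0 get
    betaNRI = 0 (no phylogenetic structure to standardise against).
    """
    if n_null < 100:
        raise ValueError("n_null must be >= 100")
    rng = np.random.default_rng(seed)
    F = _normalise_rows(np.asarray(sub_counts, float))
    obs = F @ d @ F.T
    b = d.shape[0]
    acc = np.zeros_like(obs)
    acc2 = np.zeros_like(obs)
    for _ in range(n_null):
        perm = rng.permutation(b)
        dp = d[np.ix_(perm, perm)]
        val = F @ dp @ F.T
        acc += val
        acc2 += val**2
    mean = acc / n_null
    var = np.maximum(acc2 / n_null - mean**2, 0.0)
    sd = np.sqrt(var)
    # a null sd at rounding-error scale means the permutations cannot move
    # the statistic (e.g. a star tree): no structure to standardise against
    floor = 1e-6 * np.maximum(np.abs(mean), 1.0)
    out = np.empty(len(pairs))
    for idx, (k, l) in enumerate(pairs):
        out[idx] = (obs[k, l] - mean[k, l]) / sd[k, l] if sd[k, l] > floor[k, l] else 0.0
    return out


# ---------------------------------------------------------------------------
# Raup-Crick on Bray-Curtis
# ---------------------------------------------------------------------------

def rc_bray(
    sub_counts: np.ndarray,
    pairs: list[tuple[int, int]],
    n_null: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Per-pair RC-Bray for one bin.

    Null communities preserve each sample's observed within-bin richness and
    total abundance: taxa are drawn without replacement with probability
    proportional to occupancy frequency, then the remaining individuals are
    filled multinomially proportional to pool relative abundance.
    RC = 2 * [P(null BC < obs) + 0.5 P(null BC = obs)] - 1, in [-1, 1].
    """
    if n_null < 100:
        raise ValueError("n_null must be >= 100")
    rng = np.random.default_rng(seed)
    counts = np.asarray(sub_counts, dtype=np.int64)
    n_samples, b = counts.shape
    occ = (counts > 0).sum(axis=0).astype(float)
    pool = counts.sum(axis=0).astype(float)
    occ_p = occ / occ.sum()
    pool_p = pool / pool.sum()
    richness = (counts > 0).sum(axis=1)
    depths = counts.sum(axis=1)

    with np.errstate(invalid="ignore"):
        obs_bc = squareform(pdist(counts.astype(float), metric="braycurtis"))
    obs_bc = np.nan_to_num(obs_bc, nan=0.0)

    less = np.zeros((n_samples, n_samples))
    equal = np.zeros((n_samples, n_samples))
    null = np.zeros((n_samples, b))
    for _ in range(n_null):
        null[:] = 0.0
        for s in range(n_samples):
            r, dep = int(richness[s]), int(depths[s])
            if r == 0 or dep == 0:
                continue
            chosen = rng.choice(b, size=min(r, b), replace=False, p=occ_p)
            null[s, chosen] = 1.0
            rest = dep - chosen.size
            if rest > 0:
                w = pool_p[chosen]
                w = w / w.sum()
                null[s, chosen] += rng.multinomial(rest, w)
        with np.errstate(invalid="ignore"):
            null_bc = squareform(pdist(null, metric="braycurtis"))
        null_bc = np.nan_to_num(null_bc, nan=0.0)
        less += null_bc < obs_bc - 1e-12
        equal += np.abs(null_bc - obs_bc) <= 1e-12
    rc = 2.0 * (less + 0.5 * equal) / n_null - 1.0
    return np.array([rc[k, l] for k, l in pairs])


# ---------------------------------------------------------------------------
# classification and aggregation
# ---------------------------------------------------------------------------

def classify_pair(bnri_value: float, rc_value: float) -> str:
    """Five-process classification of one (betaNRI, RC-Bray) pair.

    Strict thresholds: betaNRI < -1.96 -> HoS; betaNRI > 1.96 -> HeS;
    otherwise RC > 0.95 -> DL; RC < -0.95 -> HD; else DR.  Boundary values
    fall to the stochastic side.
    """
    if not (np.isfinite(bnri_value) and np.isfinite(rc_value)):
        raise ValueError("betaNRI and RC must be finite")
    if bnri_value < -1.96:
        return "HoS"
    if bnri_value > 1.96:
        return "HeS"
    if rc_value > 0.95:
        return "DL"
    if rc_value < -0.95:
        return "HD"
    return "DR"


@dataclass
class ProcessPartition:
    """Per-bin and community-level process fractions for one scope."""

    scope: str
    bin_fractions: pd.DataFrame  # bins x PROCESSES, rows sum to 1
    weights: pd.Series  # bin weights, renormalised over bins with calls
    community: pd.Series  # abundance-weighted fractions, sums to 1

    @property
    def dominant_process(self) -> pd.Series:
        return self.bin_fractions.idxmax(axis=1)


def partition_processes(
    calls: pd.DataFrame, bins: list[PhyloBin], scope: str = "all"
) -> ProcessPartition:
    """Aggregate per-pair calls into bin and community process fractions.

    ``calls`` needs columns ``bin`` and ``process`` (already restricted to
    the pairs in scope).  Community fractions weight each bin's fraction
    vector by its relative abundance, renormalised over bins with calls.
    """
    if calls.empty:
        raise ValueError("no pair calls to aggregate")
    counts = (
        calls.groupby("bin")["process"].value_counts().unstack(fill_value=0)
    )
    for p in PROCESSES:
        if p not in counts.columns:
            counts[p] = 0
    counts = counts[list(PROCESSES)]
    fracs = counts.div(counts.sum(axis=1), axis=0)
    w = pd.Series({b.bin_id: b.weight for b in bins})
    w = w.loc[fracs.index]
    w = w / w.sum()
    community = fracs.mul(w, axis=0).sum(axis=0)
    community = community / community.sum()
    return ProcessPartition(scope, fracs, w, community)


def process_env_correlation(
    pair_weights: pd.DataFrame, frame: SampleFrame, variables=None
) -> pd.DataFrame:
    """Spearman correlation of per-pair process weights with pair-mean
    environment, BH-corrected across the whole table.

    ``pair_weights`` must carry ``sample_k``/``sample_l`` columns plus one
    column per process holding that pair's abundance-weighted process
    weight.
    """
    variables = list(variables or frame.env_columns)
    env = frame.env_matrix()
    rows = []
    for var in variables:
        vals = env[var]
        pair_env = 0.5 * (
            vals.loc[pair_weights["sample_k"]].to_numpy()
            + vals.loc[pair_weights["sample_l"]].to_numpy()
        )
        for proc in PROCESSES:
            y = pair_weights[proc].to_numpy(dtype=float)
            if np.std(y) < 1e-12 or np.std(pair_env) < 1e-12:
                rho, p = 0.0, 1.0  # constant vector: no correlation defined
            else:
                rho, p = ss.spearmanr(pair_env, y)
                if not np.isfinite(rho):
                    rho, p = 0.0, 1.0
            rows.append((var, proc, float(rho), float(p)))
    out = pd.DataFrame(rows, columns=["variable", "process", "rho", "p"])
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class AssemblyModel:
    """Phylogenetic-bin null-model partition of community assembly.

    Parameters
    ----------
    table : CommunityTable
        Rarefied counts.
    tree : PhyloTree
        Rooted tree covering the analysed taxa.
    frame : SampleFrame, optional
        Needed for season/group scoping and environmental correlations.
    top_k : int, optional
        Restrict the analysis to the ``top_k`` most abundant taxa (by total
        count) before binning.
    n_min : int
        Minimum analysed tips per bin.
    n_null : int
        Null-model randomisations for both betaNRI and RC-Bray.
    """

    def __init__(
        self,
        table: CommunityTable,
        tree: PhyloTree,
        frame: SampleFrame | None = None,
        top_k: int | None = None,
        n_min: int = 24,
        n_null: int = 1000,
    ):
        if frame is not None:
            frame.check_against(table)
        if top_k is not None and top_k < table.n_taxa:
            totals = table.counts.sum(axis=0)
            order = np.argsort(-totals, kind="stable")[:top_k]
            keep = [table.taxon_ids[i] for i in sorted(order)]
            table = table.select_taxa(keep)
        self.table = table
        self.tree = tree
        self.frame = frame
        self.n_min = n_min
        self.n_null = n_null
        self.bins = bin_taxa(tree, table.taxon_ids, n_min=n_min)
        rel = table.relative_abundance()
        mean_rel = rel.mean(axis=0)
        idx = {t: i for i, t in enumerate(table.taxon_ids)}
        total = mean_rel.sum()
        for b in self.bins:
            b.weight = float(sum(mean_rel[idx[t]] for t in b.members) / total)

    def fit(self, seed: int = 0) -> "AssemblyResults":
        """Compute betaNRI and RC-Bray for every bin and sample pair."""
        idx = {t: i for i, t in enumerate(self.table.taxon_ids)}
        sample_ids = self.table.sample_ids
        n = len(sample_ids)
        all_pairs = list(itertools.combinations(range(n), 2))
        records = []
        seeds = spawn_seeds(seed, 2 * len(self.bins))
        for bi, pbin in enumerate(self.bins):
            cols = [idx[t] for t in pbin.members]
            sub = self.table.counts[:, cols]
            present = sub.sum(axis=1) > 0
            pairs = [(k, l) for k, l in all_pairs if present[k] and present[l]]
            skipped = len(all_pairs) - len(pairs)
            if skipped:
                logger.info("%s: skipped %d pairs with the bin absent",
                            pbin.bin_id, skipped)
            if not pairs:
                continue
            d = self.tree.patristic_distances(pbin.members).data
            z = bnri(sub, d, pairs, n_null=self.n_null, seed=seeds[2 * bi])
            rc = rc_bray(sub, pairs, n_null=self.n_null, seed=seeds[2 * bi + 1])
            for (k, l), zv, rv in zip(pairs, z, rc):
                records.append(
                    (
                        sample_ids[k],
                        sample_ids[l],
                        pbin.bin_id,
                        float(zv),
                        float(rv),
                        classify_pair(zv, rv),
                    )
                )
        calls = pd.DataFrame(
            records, columns=["sample_k", "sample_l", "bin", "bnri", "rc", "process"]
        )
        return AssemblyResults(self, calls)


@dataclass
class AssemblyResults:
    """Per-pair process calls plus aggregation and correlation accessors."""

    model: AssemblyModel
    calls: pd.DataFrame

    @property
    def bins(self) -> list[PhyloBin]:
        return self.model.bins

    def _scope_mask(self, scope: str) -> pd.Series:
        if scope == "all" or self.model.frame is None:
            return pd.Series(True, index=self.calls.index)
        meta = self.model.frame.data
        k = self.calls["sample_k"].map(meta["season"])
        l = self.calls["sample_l"].map(meta["season"])
        if scope in ("wet", "dry"):
            return (k == scope) & (l == scope)
        if scope == "within-season":
            return k == l
        gk = self.calls["sample_k"].map(meta["group"])
        gl = self.calls["sample_l"].map(meta["group"])
        if scope == "within-group":
            return gk == gl
        if scope == "between-group":
            return gk != gl
        if scope.startswith("FP"):
            return (gk == scope) & (gl == scope)
        raise ValueError(f"unknown scope {scope!r}")

    def partition(self, scope: str = "all") -> ProcessPartition:
        mask = self._scope_mask(scope)
        return partition_processes(self.calls[mask], self.bins, scope)

    def pair_weights(self, scope: str = "all") -> pd.DataFrame:
        """Per-pair community-level process weights (bin-abundance weighted)."""
        mask = self._scope_mask(scope)
        sub = self.calls[mask]
        w = pd.Series({b.bin_id: b.weight for b in self.bins})
        rows = {}
        for (k, l), grp in sub.groupby(["sample_k", "sample_l"]):
            wb = w.loc[grp["bin"]].to_numpy()
            wb = wb / wb.sum()
            vec = {p: 0.0 for p in PROCESSES}
            for weight, proc in zip(wb, grp["process"]):
                vec[proc] += weight
            rows[(k, l)] = vec
        out = pd.DataFrame.from_dict(rows, orient="index")
        out.index.names = ["sample_k", "sample_l"]
        return out.reset_index()

    def env_correlation(self, scope: str = "all", variables=None) -> pd.DataFrame:
        if self.model.frame is None:
            raise ValueError("no SampleFrame attached")
        return process_env_correlation(
            self.pair_weights(scope), self.model.frame, variables
        )

    def summary(self, scope: str = "all") -> str:
        part = self.partition(scope)
        lines = [
            "Assembly process partition",
            "=" * 34,
            f"scope             {scope}",
            f"bins              {len(self.bins)} (n_min={self.model.n_min})",
            f"pair calls        {int(self._scope_mask(scope).sum())}",
            "community-level fractions:",
        ]
        for p in PROCESSES:
            lines.append(f"  {p:<4} {part.community[p]:.3f}")
        return "\n".join(lines)
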