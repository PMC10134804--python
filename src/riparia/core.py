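"""Core domain containers and table-level preprocessing.

The central object is :class:`CommunityTable`, a validated samples x taxa
count matrix (an OTU/ASV table).  Alongside it live the sample metadata frame
(:class:`SampleFrame`), a thin rooted-tree wrapper over scikit-bio's
``TreeNode`` (:class:`PhyloTree`), and a tagged symmetric
:class:`DistanceMatrix`.  Table-level preprocessing — rarefaction, prevalence
filtering, alpha diversity, Bray–Curtis — operates on these containers and is
shared by every downstream analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from skbio import TreeNode

logger = logging.getLogger("riparia")

__all__ = [
    "CommunityTable",
    "SampleFrame",
    "PhyloTree",
    "DistanceMatrix",
    "rarefy",
    "prevalence_filter",
    "alpha_diversity",
    "bray_curtis",
]

SEASON_LEVELS = ("wet", "dry")
GROUP_LEVELS = tuple(f"FP{i}" for i in range(1, 8))
#: the edaphic/climatic variables carried by a SampleFrame, in canonical order
ENV_VARIABLES = (
    "temperature",
    "precipitation",
    "pH",
    "SM",
    "DOC",
    "DON",
    "NH4_N",
    "NO3_N",
    "TC",
    "TN",
    "CN_ratio",
)


def _check_unique(ids, what):
    ids = list(ids)
    seen, dups = set(), []
    for x in ids:
        if x in seen:
            dups.append(x)
        seen.add(x)
    if dups:
        raise ValueError(f"duplicate {what} ids: {sorted(set(dups))}")
    return ids


@dataclass
class CommunityTable:
    """Samples x taxa matrix of non-negative integer counts.

    Parameters
    ----------
    counts : ndarray of shape (n_samples, n_taxa)
        Non-negative integer read counts.
    sample_ids, taxon_ids : sequence of str
        Unique ordered identifiers for rows and columns.
    taxonomy : dict, optional
        Map taxon id -> ranked lineage string (e.g. an order-level label).
    """

    counts: np.ndarray
    sample_ids: list = field(default_factory=list)
    taxon_ids: list = field(default_factory=list)
    taxonomy: dict | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if not np.issubdtype(self.counts.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}"
            )
        if np.any(self.counts != np.floor(self.counts)):
            raise ValueError("counts must be integers")
        self.counts = self.counts.astype(np.int64)
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.taxon_ids = _check_unique(self.taxon_ids, "taxon")
        if self.counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )

    # -- basic views ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    @property
    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> np.ndarray:
        """Row-normalised view; all-zero samples stay at zero."""
        totals = self.sample_sums.astype(float)
        out = np.zeros_like(self.counts, dtype=float)
        nz = totals > 0
        out[nz] = self.counts[nz] / totals[nz, None]
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    def select_taxa(self, taxa) -> "CommunityTable":
        idx = [self.taxon_ids.index(t) for t in taxa]
        return CommunityTable(
            self.counts[:, idx], list(self.sample_ids), list(taxa), self.taxonomy
        )

    def select_samples(self, samples) -> "CommunityTable":
        idx = [self.sample_ids.index(s) for s in samples]
        return CommunityTable(
            self.counts[idx], list(samples), list(self.taxon_ids), self.taxonomy
        )


@dataclass
class SampleFrame:
    """Per-sample metadata: season, group, and the edaphic variables."""

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        _check_unique(df.index, "sample")
        for col in ("season", "group"):
            if col not in df.columns:
                raise ValueError(f"SampleFrame requires a {col!r} column")
        bad = set(df["season"]) - set(SEASON_LEVELS)
        if bad:
            raise ValueError(f"unknown season labels: {sorted(bad)}")
        env = df[[c for c in df.columns if c in ENV_VARIABLES]]
        if env.size and not np.all(np.isfinite(env.to_numpy(dtype=float))):
            raise ValueError("environmental values must be finite")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def env_columns(self) -> list:
        return [c for c in self.data.columns if c in ENV_VARIABLES]

    def env_matrix(self) -> pd.DataFrame:
        return self.data[self.env_columns].astype(float)

    def check_against(self, table: CommunityTable) -> None:
        """Raise if the sample sets of frame and table differ."""
        mine, theirs = set(self.sample_ids), set(table.sample_ids)
        if mine != theirs:
            raise ValueError(
                "sample id mismatch; only in table: "
                f"{sorted(theirs - mine)}; only in metadata: {sorted(mine - theirs)}"
            )

    def subset(self, sample_ids) -> "SampleFrame":
        return SampleFrame(self.data.loc[list(sample_ids)].copy())


class PhyloTree:
    """Rooted, branch-length-annotated tree over the community's taxa.

    Wraps a ``skbio.TreeNode``; provides patristic distances, Faith's PD and
    the tip bookkeeping the bin-based null models need.
    """

    def __init__(self, tree: TreeNode):
        if len(tree.children) == 0:
            raise ValueError("tree has no children; not a rooted tree")
        tips = [t.name for t in tree.tips()]
        _check_unique(tips, "tip")
        for node in tree.traverse(include_self=False):
            if node.length is None:
                raise ValueError(f"branch without length above {node.name!r}")
            if node.length < 0:
                raise ValueError("negative branch length")
        self.tree = tree
        self.tip_names = tips
        self._tip_lookup = None

    @classmethod
    def from_newick(cls, source) -> "PhyloTree":
        return cls(TreeNode.read(source, format="newick"))

    def __str__(self):
        return str(self.tree)

    @property
    def n_tips(self) -> int:
        return len(self.tip_names)

    def total_branch_length(self) -> float:
        return sum(n.length or 0.0 for n in self.tree.traverse(include_self=False))

    def patristic_distances(self, taxa=None) -> "DistanceMatrix":
        """Pairwise tip-to-tip (patristic) distances, optionally restricted."""
        dm = self.tree.tip_tip_distances()
        ids = list(dm.ids)
        mat = np.asarray(dm.data, dtype=float)
        if taxa is not None:
            missing = [t for t in taxa if t not in set(ids)]
            if missing:
                raise KeyError(f"taxa missing from tree: {missing}")
            idx = [ids.index(t) for t in taxa]
            mat = mat[np.ix_(idx, idx)]
            ids = list(taxa)
        return DistanceMatrix(mat, ids, metric="patristic")

    def faith_pd(self, counts: np.ndarray, taxon_ids) -> float:
        """Faith's phylogenetic diversity (root-inclusive convention).

        Total branch length of the union of root-to-tip paths over the
        present taxa, so PD over all tips equals the tree's total branch
        length.
        """
        counts = np.asarray(counts)
        present = {t for t, c in zip(taxon_ids, counts) if c > 0}
        if not present:
            return 0.0
        if self._tip_lookup is None:
            self._tip_lookup = {t.name: t for t in self.tree.tips()}
        marked = set()
        for name in present:
            node = self._tip_lookup[name]
            while node.parent is not None and id(node) not in marked:
                marked.add(id(node))
                node = node.parent
        total = 0.0
        for node in self.tree.traverse(include_self=False):
            if id(node) in marked:
                total += node.length or 0.0
        return total

    def mismatch_report(self, taxon_ids) -> dict:
        """Asymmetric difference between tree tips and a taxon set."""
        tips, taxa = set(self.tip_names), set(taxon_ids)
        return {
            "only_in_tree": sorted(tips - taxa),
            "only_in_table": sorted(taxa - tips),
        }


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix over an ordered id list with a metric tag."""

    data: np.ndarray
    ids: list
    metric: str = "unknown"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.ids = _check_unique(self.ids, "distance-matrix")
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.data), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.data < -1e-12):
            raise ValueError("distances must be non-negative")
        if self.metric == "bray-curtis" and np.any(self.data > 1 + 1e-9):
            raise ValueError("bray-curtis distances must be <= 1")

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle vector in scipy ``squareform`` order."""
        return squareform(self.data, checks=False)

    def filter(self, ids) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(self.data[np.ix_(idx, idx)], list(ids), self.metric)


# ---------------------------------------------------------------------------
# table-level preprocessing
# ---------------------------------------------------------------------------

def rarefy(table: CommunityTable, depth: int, seed: int) -> CommunityTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped (and logged).  The draw
    per sample is multivariate hypergeometric, i.e. exact subsampling without
    replacement, deterministic for a given ``seed``.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.sample_sums
    keep = totals >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        logger.info("rarefy: dropping %d samples below depth %d: %s",
                    len(dropped), depth, dropped)
    out = np.empty((int(keep.sum()), table.n_taxa), dtype=np.int64)
    r = 0
    for i in range(table.n_samples):
        if not keep[i]:
            continue
        row = table.counts[i]
        if totals[i] == depth:
            out[r] = row
        else:
            out[r] = rng.multivariate_hypergeometric(row, depth)
        r += 1
    return CommunityTable(
        out,
        [s for s, k in zip(table.sample_ids, keep) if k],
        list(table.taxon_ids),
        table.taxonomy,
    )


def prevalence_filter(table: CommunityTable, min_fraction: float) -> CommunityTable:
    """Keep taxa present (count > 0) in at least ``min_fraction`` of samples.

    The occupancy cutoff is ``ceil(min_fraction * n_samples)`` so a taxon on
    the boundary (e.g. present in exactly 20% of samples) is kept.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    need = int(np.ceil(min_fraction * table.n_samples))
    occ = (table.counts > 0).sum(axis=0)
    keep = occ >= need
    if not keep.any():
        warnings.warn("prevalence filter removed every taxon", stacklevel=2)
    kept = [t for t, k in zip(table.taxon_ids, keep) if k]
    return CommunityTable(table.counts[:, keep], list(table.sample_ids),
                          kept, table.taxonomy)


def alpha_diversity(table: CommunityTable, tree: PhyloTree | None = None) -> pd.DataFrame:
    """Per-sample richness, Shannon H (natural log) and optional Faith PD."""
    rel = table.relative_abundance()
    richness = (table.counts > 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(rel > 0, rel * np.log(rel), 0.0)
    shannon = -plogp.sum(axis=1)
    cols = {"richness": richness.astype(float), "shannon": shannon}
    if tree is not None:
        cols["faith_pd"] = np.array(
            [tree.faith_pd(table.counts[i], table.taxon_ids)
             for i in range(table.n_samples)]
        )
    return pd.DataFrame(cols, index=table.sample_ids)


def bray_curtis(table: CommunityTable, relative: bool = False) -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarity, BC(u,v) = sum|u-v| / sum(u+v)."""
    if table.n_samples < 2:
        raise ValueError("need at least two samples")
    x = table.relative_abundance() if relative else table.counts.astype(float)
    empty = x.sum(axis=1) == 0
    if empty.sum() >= 2:
        warnings.warn("Bray-Curtis between all-zero samples defined as 0",
                      stacklevel=2)
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(x, metric="braycurtis"))
    d = np.nan_to_num(d, nan=0.0)
    return DistanceMatrix(d, list(table.sample_ids), metric="bray-curtis")
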