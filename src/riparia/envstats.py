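"""Distance-matrix statistics linking environment, diversity and modules.

Mantel tests (permutation, with exact enumeration for tiny n), the bioenv
exhaustive best-subset search, multiple regression on distance matrices
(MRM), and the module x environment Mantel grid.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as ss
from scipy.spatial.distance import pdist, squareform

from .core import (
    CommunityTable,
    DistanceMatrix,
    PhyloTree,
    SampleFrame,
    alpha_diversity,
    bray_curtis,
)
from .stats import bh_fdr

__all__ = [
    "MantelResult",
    "BioenvResult",
    "MrmResult",
    "mantel",
    "bioenv",
    "mrm",
    "module_env_mantel",
]


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    method: str


@dataclass
class BioenvResult:
    best_subset: tuple
    best_r: float
    ranking: pd.DataFrame  # all subsets, sorted by r descending


@dataclass
class MrmResult:
    coefficients: pd.Series  # includes "intercept"
    p_values: pd.Series
    r2: float
    n_perm: int
    condition_number: float


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "spearman":
        x = ss.rankdata(x)
        y = ss.rankdata(y)
    elif method != "pearson":
        raise ValueError("method must be 'spearman' or 'pearson'")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def mantel(
    dx: DistanceMatrix,
    dy: DistanceMatrix,
    method: str = "spearman",
    n_perm: int = 9999,
    seed: int = 0,
    exact: bool = False,
) -> MantelResult:
    """Mantel test between two distance matrices over the same samples.

    The statistic is the (Spearman by default) correlation of the
    off-diagonal vectors; the null permutes dy's rows and columns jointly;
    p is one-sided greater, p = (1 + #{r_perm >= r_obs}) / (1 + n_perm).
    ``exact=True`` enumerates every relabelling instead (feasible for tiny
    n), with p = #{r_perm >= r_obs} / n! over all n! relabelings.
    """
    if dx.ids != dy.ids:
        raise ValueError("distance matrices must share the same id order")
    n = dx.n
    if n < 4:
        raise ValueError("need at least 4 samples")
    x = dx.condensed()
    ymat = dy.data
    r_obs = _corr(x, dy.condensed(), method)
    if exact:
        perms = list(itertools.permutations(range(n)))
        count = 0
        for perm in perms:
            perm = np.asarray(perm)
            yp = ymat[np.ix_(perm, perm)]
            if _corr(x, squareform(yp, checks=False), method) >= r_obs - 1e-12:
                count += 1
        return MantelResult(r_obs, count / len(perms), len(perms), method)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = ymat[np.ix_(perm, perm)]
        if _corr(x, squareform(yp, checks=False), method) >= r_obs - 1e-12:
            count += 1
    return MantelResult(r_obs, (1 + count) / (1 + n_perm), n_perm, method)


def bioenv(
    community: DistanceMatrix,
    frame: SampleFrame,
    max_vars: int | None = None,
    method: str = "spearman",
) -> BioenvResult:
    """Exhaustive best-subset search for environmental drivers.

    Every nonempty subset of (z-standardised) environmental variables is
    turned into a Euclidean distance matrix and rank-correlated with the
    community distances; the subset with maximal correlation wins, ties
    broken by smaller subset then lexicographic order.
    """
    env = frame.env_matrix().loc[community.ids]
    if env.isnull().any().any():
        raise ValueError("non-numeric or missing environmental values")
    cols = list(env.columns)
    z = (env - env.mean()) / env.std(ddof=1).replace(0, 1.0)
    x = community.condensed()
    rows = []
    max_vars = max_vars or len(cols)
    for k in range(1, max_vars + 1):
        for subset in itertools.combinations(cols, k):
            d = pdist(z[list(subset)].to_numpy(), metric="euclidean")
            rows.append((subset, _corr(x, d, method)))
    ranking = pd.DataFrame(rows, columns=["subset", "r"])
    ranking["size"] = ranking["subset"].map(len)
    ranking = ranking.sort_values(
        ["r", "size", "subset"], ascending=[False, True, True]
    ).reset_index(drop=True)
    best = ranking.iloc[0]
    return BioenvResult(tuple(best["subset"]), float(best["r"]),
                        ranking[["subset", "size", "r"]])


def _mrm_fit(y: np.ndarray, X: np.ndarray):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return beta, r2


def mrm(
    dy: DistanceMatrix,
    dxs: list[DistanceMatrix],
    n_perm: int = 999,
    seed: int = 0,
    names=None,
) -> MrmResult:
    """Multiple regression of one distance matrix on several others.

    OLS with intercept on the vectorised off-diagonals; coefficient
    significance by jointly permuting dy's rows/columns and refitting,
    two-sided on |beta_j|.
    """
    ids = dy.ids
    for d in dxs:
        if d.ids != ids:
            raise ValueError("all matrices must share the same id order")
    names = list(names or [f"x{i+1}" for i in range(len(dxs))])
    y = dy.condensed()
    X = np.column_stack([np.ones_like(y)] + [d.condensed() for d in dxs])
    if X.shape[1] >= X.shape[0]:
        raise ValueError("more predictors than off-diagonal entries")
    cond = float(np.linalg.cond(X))
    if cond > 1e8:
        warnings.warn(f"predictors nearly collinear (cond={cond:.2e}); "
                      "pseudo-inverse solution", stacklevel=2)
    beta, r2 = _mrm_fit(y, X)
    rng = np.random.default_rng(seed)
    n = dy.n
    exceed = np.zeros(len(beta))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = squareform(dy.data[np.ix_(perm, perm)], checks=False)
        bp, _ = _mrm_fit(yp, X)
        exceed += np.abs(bp) >= np.abs(beta) - 1e-15
    p = (1 + exceed) / (1 + n_perm)
    labels = ["intercept"] + names
    return MrmResult(
        pd.Series(beta, index=labels),
        pd.Series(p, index=labels),
        r2,
        n_perm,
        cond,
    )


def module_env_mantel(
    modules: dict,
    table: CommunityTable,
    frame: SampleFrame,
    tree: PhyloTree | None = None,
    top_k: int = 5,
    n_perm: int = 999,
    seed: int = 0,
    method: str = "spearman",
) -> pd.DataFrame:
    """Mantel grid relating network modules to environment and diversity.

    For each of the ``top_k`` largest modules, Bray-Curtis on the module
    members' relative abundances is tested against the Euclidean distance of
    each environmental variable, plus OTU-richness and (if a tree is given)
    phylogenetic-diversity distances.  p-values are BH-corrected across the
    grid.  Modules with fewer than 2 members are skipped with a warning.
    """
    frame.check_against(table)
    groups: dict[int, list] = {}
    for taxon, mod in modules.items():
        groups.setdefault(mod, []).append(taxon)
    ranked = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))[:top_k]

    alpha = alpha_diversity(table, tree)
    meta = frame.data.loc[table.sample_ids]
    predictors: dict[str, np.ndarray] = {}
    for var in frame.env_columns:
        predictors[var] = meta[var].to_numpy(dtype=float)[:, None]
    predictors["richness"] = alpha["richness"].to_numpy()[:, None]
    if tree is not None:
        predictors["faith_pd"] = alpha["faith_pd"].to_numpy()[:, None]

    rows = []
    for mod, members in ranked:
        members = [t for t in members if t in table.taxon_ids]
        if len(members) < 2:
            warnings.warn(f"module {mod} has < 2 members; skipped", stacklevel=2)
            continue
        sub = table.select_taxa(members)
        dm = bray_curtis(sub, relative=True)
        for name, vec in predictors.items():
            d_env = DistanceMatrix(
                squareform(pdist(vec, metric="euclidean")),
                table.sample_ids,
                metric="euclidean",
            )
            res = mantel(dm, d_env, method=method, n_perm=n_perm, seed=seed)
            rows.append((f"Mod{mod+1}", name, res.r, res.p))
    out = pd.DataFrame(rows, columns=["module", "variable", "r", "p"])
    if not out.empty:
        out["q"] = bh_fdr(out["p"].to_numpy())
    return out
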