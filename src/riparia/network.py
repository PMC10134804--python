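"""Co-occurrence network inference, topology, and robustness.

The model object :class:`CooccurrenceNetwork` is built from a
:class:`~riparia.core.CommunityTable`; ``fit()`` computes the all-pairs
Spearman matrix, applies the conjunctive edge rule (|rho| > rho_min AND
FDR-adjusted q < alpha, both strict), and returns a :class:`NetworkResults`
carrying the graph, its module partition, topology summary, random-graph
null comparison, robustness curves and node-level metrics.

Free functions (:func:`natural_connectivity`, :func:`efficiency`,
:func:`vulnerability`, ...) operate on plain ``networkx`` graphs so they can
be tested against closed forms on small graphs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.spatial.distance import squareform

from .core import CommunityTable
from .stats import bh_fdr, spearman_matrix, spawn_seeds

__all__ = [
    "CooccurrenceNetwork",
    "NetworkResults",
    "TopologySummary",
    "RobustnessCurve",
    "build_network",
    "topology",
    "detect_modules",
    "natural_connectivity",
    "efficiency",
    "vulnerability",
    "robustness_curve",
    "random_network_ensemble",
    "node_metrics",
]


# ---------------------------------------------------------------------------
# graph-level metrics
# ---------------------------------------------------------------------------

def natural_connectivity(graph: nx.Graph) -> float:
    """Natural connectivity: ln of the mean exponentiated adjacency eigenvalue.

    lambda-bar = ln( (1/n) sum_i exp(lambda_i) ), computed with a
    log-sum-exp so large eigenvalues cannot overflow.  An edgeless graph has
    all eigenvalues 0, hence lambda-bar = 0.
    """
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("natural connectivity undefined for the empty graph")
    if graph.number_of_edges() == 0:
        return 0.0
    a = nx.to_numpy_array(graph, weight=None)
    eig = np.linalg.eigvalsh(a)
    return float(logsumexp(eig) - np.log(n))


def efficiency(graph: nx.Graph) -> float:
    """Network efficiency E = mean over ordered pairs of 1/d(i,j).

    Disconnected pairs contribute 0.
    """
    if graph.number_of_nodes() < 2:
        raise ValueError("efficiency needs at least 2 nodes")
    return float(nx.global_efficiency(graph))


def vulnerability(graph: nx.Graph):
    """Per-node relative efficiency loss and the network maximum.

    v_i = (E - E_without_i) / E; V = max_i v_i.  If E = 0 the network has no
    efficiency to lose and V is defined as 0 (with a warning).
    """
    if graph.number_of_nodes() < 3:
        raise ValueError("vulnerability needs at least 3 nodes")
    e = efficiency(graph)
    nodes = list(graph.nodes())
    if e == 0:
        warnings.warn("efficiency is 0; vulnerability defined as 0", stacklevel=2)
        return 0.0, dict.fromkeys(nodes, 0.0)
    v = {}
    for node in nodes:
        h = graph.copy()
        h.remove_node(node)
        v[node] = (e - efficiency(h)) / e
    return float(max(v.values())), v


def detect_modules(graph: nx.Graph, seed: int = 0) -> dict:
    """Louvain module partition; deterministic given the seed.

    Returns node -> module index, modules numbered by decreasing size with
    ties broken by smallest member node id.
    """
    if graph.number_of_edges() == 0:
        return {n: i for i, n in enumerate(sorted(graph.nodes()))}
    comms = nx.community.louvain_communities(graph, seed=seed)
    comms = sorted(comms, key=lambda c: (-len(c), min(str(x) for x in c)))
    return {node: i for i, comm in enumerate(comms) for node in comm}


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    positive_edge_fraction: float
    average_degree: float
    average_clustering: float
    average_path_length: float
    modularity: float
    powerlaw_exponent: float
    powerlaw_r2: float

    def as_series(self) -> pd.Series:
        return pd.Series(vars(self))


def _powerlaw_fit(degrees) -> tuple[float, float]:
    """Descriptive OLS fit of log10 P(k) on log10 k over observed degrees.

    Returns (gamma, R^2) for P(k) ~ k^-gamma; degrees 0 are excluded (log
    undefined).  Fewer than 3 distinct degrees -> (nan, nan).
    """
    degrees = np.asarray([d for d in degrees if d > 0])
    if degrees.size == 0:
        return float("nan"), float("nan")
    ks, counts = np.unique(degrees, return_counts=True)
    if ks.size < 3:
        return float("nan"), float("nan")
    pk = counts / counts.sum()
    x, y = np.log10(ks), np.log10(pk)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    sstot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / sstot if sstot > 0 else 1.0
    return float(-slope), float(r2)


def topology(graph: nx.Graph, modules: dict | None = None, seed: int = 0) -> TopologySummary:
    """Topology summary of a (possibly signed) co-occurrence graph."""
    n = graph.number_of_nodes()
    if n < 2:
        raise ValueError("topology needs at least 2 nodes")
    m = graph.number_of_edges()
    signs = [d.get("sign", 1) for _, _, d in graph.edges(data=True)]
    pos_frac = float(np.mean([s > 0 for s in signs])) if m else float("nan")
    if modules is None:
        modules = detect_modules(graph, seed=seed)
    groups = {}
    for node, mod in modules.items():
        groups.setdefault(mod, set()).add(node)
    q = nx.community.modularity(graph, groups.values()) if m else float("nan")
    if m:
        lcc = graph.subgraph(max(nx.connected_components(graph), key=len))
        apl = (
            nx.average_shortest_path_length(lcc)
            if lcc.number_of_nodes() > 1
            else float("nan")
        )
    else:
        apl = float("nan")
    gamma, r2 = _powerlaw_fit([d for _, d in graph.degree()])
    return TopologySummary(
        n_nodes=n,
        n_edges=m,
        positive_edge_fraction=pos_frac,
        average_degree=2 * m / n,
        average_clustering=float(nx.average_clustering(graph)) if m else 0.0,
        average_path_length=float(apl),
        modularity=float(q) if m else float("nan"),
        powerlaw_exponent=gamma,
        powerlaw_r2=r2,
    )


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def build_network(
    rho: np.ndarray,
    q: np.ndarray,
    taxon_ids,
    rho_min: float = 0.8,
    alpha: float = 0.01,
    prune_isolates: bool = True,
    taxonomy: dict | None = None,
) -> nx.Graph:
    """Threshold the correlation matrix into an undirected graph.

    An edge exists iff ``|rho| > rho_min`` AND ``q < alpha`` — both strict,
    so a pair at exactly rho = 0.8 is excluded.  Isolated nodes are pruned by
    default (network node counts then refer to connected taxa only).
    """
    taxon_ids = list(taxon_ids)
    n = len(taxon_ids)
    if rho.shape != (n, n) or q.shape != (n, n):
        raise ValueError("matrix shapes do not match taxon ids")
    g = nx.Graph()
    g.add_nodes_from(taxon_ids)
    iu = np.triu_indices(n, k=1)
    keep = (np.abs(rho[iu]) > rho_min) & (q[iu] < alpha)
    for i, j in zip(iu[0][keep], iu[1][keep]):
        r = float(rho[i, j])
        g.add_edge(
            taxon_ids[i],
            taxon_ids[j],
            rho=r,
            q=float(q[i, j]),
            sign=1 if r > 0 else -1,
        )
    if prune_isolates:
        g.remove_nodes_from(list(nx.isolates(g)))
    if taxonomy:
        nx.set_node_attributes(
            g, {t: taxonomy.get(t, "") for t in g.nodes()}, "taxonomy"
        )
    return g


# ---------------------------------------------------------------------------
# robustness and nulls
# ---------------------------------------------------------------------------

@dataclass
class RobustnessCurve:
    """Natural-connectivity decline under node removal.

    ``slope`` regresses mean lambda-bar on the removal fraction;
    ``relative_slope`` uses lambda-bar scaled by its intact value, which is
    the scale-free quantity to compare across networks of different density.
    """

    fractions: np.ndarray
    mean_nc: np.ndarray
    sd_nc: np.ndarray
    slope: float
    relative_slope: float
    order: str = "random"

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fraction": self.fractions, "mean_nc": self.mean_nc, "sd_nc": self.sd_nc}
        )


def robustness_curve(
    graph: nx.Graph,
    order: str = "random",
    fractions=None,
    n_reps: int = 100,
    seed: int = 0,
) -> RobustnessCurve:
    """Remove growing fractions of nodes and track natural connectivity.

    ``order='random'`` averages uniformly random removals over ``n_reps``
    repetitions; ``order='degree'`` removes by descending degree
    (deterministic, ties broken by node id).
    """
    if order not in ("random", "degree"):
        raise ValueError("order must be 'random' or 'degree'")
    if fractions is None:
        fractions = np.arange(0.0, 0.81, 0.1)
    fractions = np.asarray(sorted(fractions), dtype=float)
    if fractions.min() < 0 or fractions.max() > 0.9:
        raise ValueError("fractions must lie within [0, 0.9]")
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    if int(round(fractions.max() * n)) >= n:
        raise ValueError("largest fraction would remove every node")
    rng = np.random.default_rng(seed)
    nodes = sorted(graph.nodes(), key=str)
    by_degree = sorted(nodes, key=lambda v: (-graph.degree(v), str(v)))
    mean_nc, sd_nc = [], []
    for f in fractions:
        k = int(round(f * n))
        if order == "degree" or k == 0:
            h = graph.copy()
            h.remove_nodes_from(by_degree[:k] if order == "degree" else [])
            vals = [natural_connectivity(h)]
        else:
            vals = []
            for _ in range(n_reps):
                drop = rng.choice(len(nodes), size=k, replace=False)
                h = graph.copy()
                h.remove_nodes_from([nodes[i] for i in drop])
                vals.append(natural_connectivity(h))
        mean_nc.append(float(np.mean(vals)))
        sd_nc.append(float(np.std(vals)))
    mean_nc = np.array(mean_nc)
    slope = float(np.polyfit(fractions, mean_nc, 1)[0])
    base = mean_nc[0] if mean_nc[0] != 0 else 1.0
    relative_slope = float(np.polyfit(fractions, mean_nc / base, 1)[0])
    return RobustnessCurve(fractions, mean_nc, np.array(sd_nc), slope,
                           relative_slope, order)


def random_network_ensemble(
    graph: nx.Graph, n_reps: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Erdos-Renyi G(n, m) null ensemble matched on node and edge counts.

    Returns a frame indexed by metric with columns ``empirical``, ``mean``,
    ``sd`` and ``z`` (z = (empirical - mean) / sd).
    """
    if n_reps < 2:
        raise ValueError("need at least 2 replicates")
    n, m = graph.number_of_nodes(), graph.number_of_edges()
    emp = topology(graph, seed=seed)
    metrics = ("average_clustering", "average_path_length", "modularity")
    seeds = spawn_seeds(seed, n_reps)
    rows = {k: [] for k in metrics + ("natural_connectivity",)}
    for s in seeds:
        g = nx.gnm_random_graph(n, m, seed=int(s))
        t = topology(g, seed=int(s))
        for k in metrics:
            rows[k].append(getattr(t, k))
        rows["natural_connectivity"].append(natural_connectivity(g))
    emp_vals = {k: getattr(emp, k) for k in metrics}
    emp_vals["natural_connectivity"] = natural_connectivity(graph)
    out = []
    for k, vals in rows.items():
        vals = np.array(vals, dtype=float)
        mu, sd = float(np.nanmean(vals)), float(np.nanstd(vals))
        z = (emp_vals[k] - mu) / sd if sd > 0 else float("nan")
        out.append((k, emp_vals[k], mu, sd, z))
    return pd.DataFrame(
        out, columns=["metric", "empirical", "mean", "sd", "z"]
    ).set_index("metric")


def node_metrics(graph: nx.Graph) -> pd.DataFrame:
    """Per-node degree/betweenness centrality, vulnerability contribution
    v_i, and natural-connectivity contribution r_i = nc - nc_without_i."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    deg_c = nx.degree_centrality(graph)
    btw = nx.betweenness_centrality(graph, normalized=False)
    nc = natural_connectivity(graph)
    if graph.number_of_nodes() >= 3:
        _, v = vulnerability(graph)
    else:
        v = dict.fromkeys(graph.nodes(), 0.0)
    r = {}
    for node in graph.nodes():
        h = graph.copy()
        h.remove_node(node)
        r[node] = nc - (natural_connectivity(h) if h.number_of_nodes() else 0.0)
    return pd.DataFrame(
        {
            "degree": dict(graph.degree()),
            "degree_centrality": deg_c,
            "betweenness": btw,
            "vulnerability": v,
            "robustness_contribution": r,
        }
    )


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class CooccurrenceNetwork:
    """Spearman co-occurrence network model for a community table.

    Parameters
    ----------
    table : CommunityTable
        Typically prevalence-filtered and rarefied.
    rho_min, alpha : float
        Strict edge thresholds on |rho| and on the (BH-adjusted by default)
        p-value.
    use_adjusted : bool
        Apply the threshold to BH-adjusted q-values (default) or raw p.
    prune_isolates : bool
        Drop unconnected taxa from the graph.
    """

    def __init__(
        self,
        table: CommunityTable,
        rho_min: float = 0.8,
        alpha: float = 0.01,
        use_adjusted: bool = True,
        prune_isolates: bool = True,
    ):
        if table.n_samples < 4:
            raise ValueError("need >= 4 samples")
        self.table = table
        self.rho_min = rho_min
        self.alpha = alpha
        self.use_adjusted = use_adjusted
        self.prune_isolates = prune_isolates

    def fit(self, seed: int = 0) -> "NetworkResults":
        rho, p, constant = spearman_matrix(self.table.counts)
        n = rho.shape[0]
        iu = np.triu_indices(n, k=1)
        q_vec = bh_fdr(p[iu]) if self.use_adjusted else p[iu]
        q = np.ones_like(p)
        q[iu] = q_vec
        q = np.minimum(q, q.T)
        np.fill_diagonal(q, 0.0)
        graph = build_network(
            rho,
            q,
            self.table.taxon_ids,
            rho_min=self.rho_min,
            alpha=self.alpha,
            prune_isolates=self.prune_isolates,
            taxonomy=self.table.taxonomy,
        )
        modules = detect_modules(graph, seed=seed)
        nx.set_node_attributes(graph, modules, "module")
        return NetworkResults(self, graph, rho, q, modules, constant, seed)


@dataclass
class NetworkResults:
    """Fitted co-occurrence network with topology and robustness accessors."""

    model: CooccurrenceNetwork
    graph: nx.Graph
    rho: np.ndarray
    q: np.ndarray
    modules: dict
    constant_taxa: list = field(default_factory=list)
    seed: int = 0

    def topology(self) -> TopologySummary:
        return topology(self.graph, modules=self.modules, seed=self.seed)

    def random_ensemble(self, n_reps: int = 100, seed: int | None = None):
        return random_network_ensemble(
            self.graph, n_reps=n_reps, seed=self.seed if seed is None else seed
        )

    def robustness(self, order="random", fractions=None, n_reps=100, seed=None):
        return robustness_curve(
            self.graph,
            order=order,
            fractions=fractions,
            n_reps=n_reps,
            seed=self.seed if seed is None else seed,
        )

    def node_metrics(self) -> pd.DataFrame:
        df = node_metrics(self.graph)
        df["module"] = pd.Series(self.modules)
        return df

    def top_modules(self, k: int = 5) -> list[list]:
        """Member lists of the k largest modules."""
        groups = {}
        for node, mod in self.modules.items():
            groups.setdefault(mod, []).append(node)
        ranked = sorted(groups.values(), key=lambda ms: (-len(ms), sorted(ms)))
        return [sorted(ms) for ms in ranked[:k]]

    def edge_table(self) -> pd.DataFrame:
        rows = [
            (u, v, d["rho"], d["q"], d["sign"])
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "rho", "q", "sign"])

    def summary(self) -> str:
        t = self.topology()
        lines = [
            "Co-occurrence network summary",
            "=" * 34,
            f"taxa analysed     {self.model.table.n_taxa}",
            f"nodes (connected) {t.n_nodes}",
            f"edges             {t.n_edges}",
            f"positive edges    {t.positive_edge_fraction:.3f}",
            f"average degree    {t.average_degree:.3f}",
            f"clustering coeff  {t.average_clustering:.3f}",
            f"avg path length   {t.average_path_length:.3f}",
            f"modularity Q      {t.modularity:.3f}",
            f"power-law gamma   {t.powerlaw_exponent:.3f} (R2 {t.powerlaw_r2:.3f})",
            f"edge rule         |rho| > {self.model.rho_min}, "
            f"{'q' if self.model.use_adjusted else 'p'} < {self.model.alpha}",
        ]
        if self.constant_taxa:
            lines.append(f"zero-variance taxa flagged: {len(self.constant_taxa)}")
        return "\n".join(lines)
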