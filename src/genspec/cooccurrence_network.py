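"""Correlation-based co-occurrence networks and their topology.

The network is built in two steps: a correlation screen (Spearman by
default, on within-sample relative abundances, Benjamini–Hochberg
adjusted) followed by thresholding (|rho| >= r_min and adjusted
p <= p_max). Edges carry sign; module detection ignores sign. Topology
statistics follow the usual microbial-network reporting set: node and
edge counts, average degree 2E/N, average shortest path length on the
largest connected component, mean local clustering coefficient,
modularity of the detected partition, and the positive-edge ratio.
Node roles use the Guimerà–Amaral Zi-Pi plane (module hub Zi > 2.5,
connector Pi > 0.62).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import OtuTable
from .niche_classification import NicheClassification

logger = logging.getLogger("genspec")


def correlation_screen(
    table: OtuTable, method: str = "spearman", min_prevalence: float = 0.2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise OTU correlations with BH-adjusted two-sided p-values.

    OTUs below the prevalence threshold are removed first; constant
    OTU vectors (undefined correlation) are dropped with a warning.
    Returns (correlation matrix, adjusted-p matrix).
    """
    prevalence = (table.counts > 0).mean(axis=0)
    keep = [o for o, pv in zip(table.otu_ids, prevalence) if pv >= min_prevalence]
    if len(keep) < 2:
        raise ValueError("fewer than 2 OTUs pass the prevalence filter")
    sub = table.subset_otus(keep)
    rel = sub.relative_abundance()
    constant = rel.std(axis=0) == 0
    if constant.any():
        logger.warning("dropping %d constant OTUs from the screen", int(constant.sum()))
        keep = [o for o, c in zip(sub.otu_ids, constant) if not c]
        sub = sub.subset_otus(keep)
        rel = sub.relative_abundance()
    n = sub.n_otus

    if method == "spearman":
        corr, pval = stats.spearmanr(rel)
        if np.ndim(corr) == 0:  # scipy collapses the 2-variable case to a scalar
            corr = np.array([[1.0, corr], [corr, 1.0]])
            pval = np.array([[0.0, pval], [pval, 0.0]])
    elif method == "pearson":
        corr = np.corrcoef(rel, rowvar=False)
        df = sub.n_samples - 2
        t = corr * np.sqrt(df / np.clip(1 - corr**2, 1e-300, None))
        pval = 2 * stats.t.sf(np.abs(t), df)
    else:
        raise ValueError(f"unknown correlation method {method!r}")

    iu = np.triu_indices(n, k=1)
    flat_p = pval[iu]
    adj = multipletests(flat_p, method="fdr_bh")[1]
    p_adj = np.ones((n, n))
    p_adj[iu] = adj
    p_adj.T[iu] = adj
    np.fill_diagonal(p_adj, 0.0)
    ids = sub.otu_ids
    return (
        pd.DataFrame(corr, index=ids, columns=ids),
        pd.DataFrame(p_adj, index=ids, columns=ids),
    )


@dataclass
class CoocNetwork:
    """Thresholded signed correlation graph with modules and topology."""

    graph: nx.Graph
    partition: dict[str, int] = field(default_factory=dict)
    modularity: float | None = None

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            (u, v, d["rho"], d["sign"], d["p_adj"]) for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "rho", "sign", "p_adj"])

    def positive_edge_ratio(self) -> float:
        signs = [d["sign"] for _, _, d in self.graph.edges(data=True)]
        return float(np.mean([s > 0 for s in signs])) if signs else np.nan


def build_network(
    corr: pd.DataFrame, p_adj: pd.DataFrame, r_min: float = 0.6, p_max: float = 0.05
) -> CoocNetwork:
    """Keep edges with |rho| >= r_min and adjusted p <= p_max.

    Isolated nodes are dropped. An empty result raises with advice to
    relax the thresholds.
    """
    if list(corr.index) != list(p_adj.index):
        raise ValueError("correlation and p matrices must be aligned")
    ids = list(corr.index)
    c = corr.to_numpy()
    p = p_adj.to_numpy()
    g = nx.Graph()
    n = len(ids)
    iu, ju = np.triu_indices(n, k=1)
    mask = (np.abs(c[iu, ju]) >= r_min) & (p[iu, ju] <= p_max)
    for i, j in zip(iu[mask], ju[mask]):
        rho = float(c[i, j])
        g.add_edge(ids[i], ids[j], rho=rho, sign=1 if rho > 0 else -1, p_adj=float(p[i, j]))
    if g.number_of_edges() == 0:
        raise ValueError(
            "no edges pass the thresholds; relax r_min and/or p_max"
        )
    return CoocNetwork(graph=g)


def topology(network: CoocNetwork) -> dict[str, float]:
    """Standard topology summary of the co-occurrence graph.

    Average path length is computed unweighted on the largest connected
    component; local clustering of degree-<2 nodes counts as 0.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    n, e = g.number_of_nodes(), g.number_of_edges()
    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    giant = g.subgraph(comps[0])
    apl = nx.average_shortest_path_length(giant) if giant.number_of_nodes() > 1 else 0.0
    stats_ = {
        "n_nodes": float(n),
        "n_edges": float(e),
        "average_degree": 2.0 * e / n,
        "average_path_length": float(apl),
        "clustering_coefficient": float(nx.average_clustering(g, count_zeros=True)),
        "positive_edge_ratio": network.positive_edge_ratio(),
        "n_components": float(len(comps)),
    }
    if network.modularity is not None:
        stats_["modularity"] = float(network.modularity)
    return stats_


def detect_modules(network: CoocNetwork, seed: int = 0) -> CoocNetwork:
    """Louvain modularity maximisation on the unsigned graph (seeded).

    Modules are renumbered by decreasing size; Newman modularity Q of
    the final partition is stored on the network.
    """
    g = network.graph
    commus = nx.community.louvain_communities(g, weight=None, seed=seed)
    commus = sorted(commus, key=lambda c: (-len(c), sorted(c)[0]))
    partition = {node: k for k, comm in enumerate(commus) for node in comm}
    q = nx.community.modularity(g, commus, weight=None)
    network.partition = partition
    network.modularity = float(q)
    return network


def module_composition(
    network: CoocNetwork, classification: NicheClassification
) -> pd.DataFrame:
    """Counts and fractions of generalist/specialist/neutral per module."""
    if not network.partition:
        raise ValueError("run detect_modules first")
    cats = classification.categories
    missing = [n for n in network.nodes if n not in cats.index]
    if missing:
        raise ValueError(f"nodes without category label: {missing[:5]}...")
    rows = []
    total_nodes = len(network.nodes)
    modules = sorted(set(network.partition.values()))
    for mod in modules:
        members = [n for n, m in network.partition.items() if m == mod]
        counts = cats.loc[members].value_counts()
        row = {"module": mod, "size": len(members), "size_fraction": len(members) / total_nodes}
        for cat in ("generalist", "specialist", "neutral"):
            row[f"n_{cat}"] = int(counts.get(cat, 0))
            row[f"frac_{cat}"] = counts.get(cat, 0) / len(members)
        rows.append(row)
    return pd.DataFrame(rows).set_index("module")


def keystone_taxa(network: CoocNetwork) -> pd.DataFrame:
    """Zi-Pi node roles plus degree and betweenness centrality.

    Zi is the within-module degree z-score, Pi = 1 - sum_m (k_im/k_i)^2
    the among-module connectivity. Roles follow the Guimerà–Amaral
    thresholds: module hub Zi > 2.5, connector Pi > 0.62, network hub
    both, else peripheral. Keystones are the non-peripheral nodes.
    """
    if not network.partition:
        raise ValueError("run detect_modules first")
    g = network.graph
    part = network.partition
    degree = dict(g.degree())
    betweenness = nx.betweenness_centrality(g)

    modules: dict[int, list[str]] = {}
    for node, mod in part.items():
        modules.setdefault(mod, []).append(node)

    within_deg = {
        node: sum(1 for nb in g.neighbors(node) if part[nb] == part[node]) for node in g
    }
    zi = {}
    for mod, members in modules.items():
        vals = np.array([within_deg[m] for m in members], dtype=float)
        sd = vals.std()
        if len(members) < 2 or sd == 0:
            if len(members) < 2:
                logger.warning("singleton module %d: Zi set to 0", mod)
            for m in members:
                zi[m] = 0.0
        else:
            for m, v in zip(members, vals):
                zi[m] = (v - vals.mean()) / sd

    pi = {}
    for node in g:
        k = degree[node]
        shares = {}
        for nb in g.neighbors(node):
            shares[part[nb]] = shares.get(part[nb], 0) + 1
        pi[node] = 1.0 - sum((c / k) ** 2 for c in shares.values()) if k else 0.0

    def role(z: float, p: float) -> str:
        if z > 2.5 and p > 0.62:
            return "network_hub"
        if z > 2.5:
            return "module_hub"
        if p > 0.62:
            return "connector"
        return "peripheral"

    df = pd.DataFrame(
        {
            "module": pd.Series(part),
            "degree": pd.Series(degree),
            "betweenness": pd.Series(betweenness),
            "Zi": pd.Series(zi),
            "Pi": pd.Series(pi),
        }
    )
    df["role"] = [role(z, p) for z, p in zip(df["Zi"], df["Pi"])]
    df["keystone"] = df["role"] != "peripheral"
    return df.sort_index()
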