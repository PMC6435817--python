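"""Co-occurrence networks and their topology.

Edges are robust pairwise associations: Spearman rho > 0.6 (one-sided
positive, per the construction rule; ``absolute=True`` switches to |rho|)
with Benjamini-Hochberg q < 0.01 over all pairs tested in one build, after
removing OTUs with mean relative abundance below 0.01%.

Node metrics: degree; betweenness (shortest-path, pair-normalized within
each connected component); closeness as normalized harmonic centrality
(well-defined on disconnected graphs); eigenvector centrality of the
largest component, max-normalized to 1, zero elsewhere.  Network metrics:
average degree 2E/N, density, average local clustering (degree-<2 nodes
contribute 0), average path length and diameter of the largest component,
and the modularity of a greedy modularity-maximizing partition.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .community import RelAbundanceTable
from .stats_core import TestResult, bh_fdr, kruskal_wallis, spearman, wilcoxon_rank_sum

__all__ = [
    "NodeMetrics",
    "NetworkMetrics",
    "filter_rare",
    "correlation_edges",
    "build_network",
    "subnetwork",
    "node_metrics",
    "network_metrics",
    "partition_edge_counts",
    "compare_node_metrics",
]

NODE_METRIC_NAMES = ("degree", "betweenness", "closeness", "eigenvector")


@dataclass
class NetworkMetrics:
    average_degree: float
    graph_density: float
    clustering_coefficient: float
    average_path_length: float   # NaN when the graph has no edges
    diameter: float              # largest connected component; NaN if edgeless
    modularity: float

    def as_dict(self) -> dict:
        return {
            "average_degree": self.average_degree,
            "graph_density": self.graph_density,
            "clustering_coefficient": self.clustering_coefficient,
            "average_path_length": self.average_path_length,
            "diameter": self.diameter,
            "modularity": self.modularity,
        }


def filter_rare(relab: RelAbundanceTable, min_mean_ra: float = 1e-4) -> RelAbundanceTable:
    """Keep OTUs whose mean relative abundance is >= the threshold
    (0.01% by default)."""
    mean_ra = relab.mean_ra()
    keep = list(mean_ra.index[mean_ra >= min_mean_ra])
    if not keep:
        raise ValueError("all OTUs fall below the rare-abundance threshold")
    return relab.select_otus(keep)


def correlation_edges(
    relab: RelAbundanceTable,
    rho_min: float = 0.6,
    q_max: float = 0.01,
    absolute: bool = False,
) -> pd.DataFrame:
    """Test every OTU pair with Spearman correlation and BH-correct over
    all tested pairs; keep rho > rho_min (or |rho| > rho_min) and q < q_max.

    Returns a DataFrame with columns source, target, rho, q.
    """
    n, k = relab.n_samples, relab.n_otus
    if n < 5:
        raise ValueError("need >= 5 samples")
    if k < 2:
        return pd.DataFrame(columns=["source", "target", "rho", "q"])
    if n <= 9:
        # small-sample route through the exact-permutation primitive
        pairs = list(itertools.combinations(range(k), 2))
        rhos, ps = [], []
        for i, j in pairs:
            r, p = spearman(relab.values[:, i], relab.values[:, j])
            rhos.append(0.0 if np.isnan(r) else r)
            ps.append(1.0 if np.isnan(p) else p)
        rho_flat = np.array(rhos)
        p_flat = np.array(ps)
        iu = np.array([i for i, _ in pairs])
        ju = np.array([j for _, j in pairs])
    else:
        ranks = sps.rankdata(relab.values, axis=0)
        constant = np.ptp(relab.values, axis=0) == 0
        sd = ranks.std(axis=0)
        sd[sd == 0] = 1.0
        z = (ranks - ranks.mean(axis=0)) / sd
        rho_mat = (z.T @ z) / n
        np.clip(rho_mat, -1.0, 1.0, out=rho_mat)
        rho_mat[constant, :] = 0.0
        rho_mat[:, constant] = 0.0
        iu, ju = np.triu_indices(k, k=1)
        rho_flat = rho_mat[iu, ju]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rho_flat * np.sqrt((n - 2) / (1.0 - rho_flat**2))
        p_flat = np.where(
            np.abs(rho_flat) >= 1.0, 0.0, 2.0 * sps.t.sf(np.abs(t), df=n - 2)
        )
        p_flat[constant[iu] | constant[ju]] = 1.0
    q_flat = bh_fdr(p_flat)
    strength = np.abs(rho_flat) if absolute else rho_flat
    keep = (strength > rho_min) & (q_flat < q_max)
    otus = np.array(relab.otu_ids)
    return pd.DataFrame(
        {
            "source": otus[iu[keep]],
            "target": otus[ju[keep]],
            "rho": rho_flat[keep],
            "q": q_flat[keep],
        }
    ).reset_index(drop=True)


def build_network(edges: pd.DataFrame, node_attributes: pd.DataFrame | None = None) -> nx.Graph:
    """Assemble the undirected simple graph from an edge list.

    ``node_attributes`` (indexed by otu_id, e.g. columns mean_ra and
    subcommunity) adds its index as isolated nodes and attaches attributes.
    """
    g = nx.Graph()
    if node_attributes is not None:
        for otu, row in node_attributes.iterrows():
            g.add_node(str(otu), **row.to_dict())
    for row in edges.itertuples(index=False):
        if row.source == row.target:
            continue
        g.add_edge(str(row.source), str(row.target), rho=float(row.rho), q=float(row.q))
    return g


def subnetwork(net: nx.Graph, nodes) -> nx.Graph:
    """Induced subgraph on ``nodes`` (both endpoints inside)."""
    nodes = list(nodes)
    unknown = [v for v in nodes if v not in net]
    if unknown:
        raise KeyError(f"unknown node id {unknown[0]!r}")
    return net.subgraph(nodes).copy()


def node_metrics(net: nx.Graph) -> pd.DataFrame:
    """Degree, betweenness, closeness (harmonic), eigenvector centrality."""
    if net.number_of_nodes() < 1:
        raise ValueError("need >= 1 node")
    nodes = list(net.nodes)
    n = len(nodes)
    out = pd.DataFrame(index=nodes, columns=list(NODE_METRIC_NAMES), dtype=float)
    out["degree"] = [net.degree(v) for v in nodes]

    betw = {v: 0.0 for v in nodes}
    components = sorted(nx.connected_components(net), key=lambda c: (-len(c), min(c)))
    for comp in components:
        sub = net.subgraph(comp)
        if len(comp) > 2:
            betw.update(nx.betweenness_centrality(sub, normalized=True))
    out["betweenness"] = [betw[v] for v in nodes]

    harm = nx.harmonic_centrality(net)
    out["closeness"] = [harm[v] / (n - 1) if n > 1 else 0.0 for v in nodes]

    eig = {v: 0.0 for v in nodes}
    if components and len(components[0]) > 1:
        giant = net.subgraph(components[0])
        centrality = nx.eigenvector_centrality(giant, max_iter=100_000, tol=1e-13)
        top = max(centrality.values())
        eig.update({v: c / top for v, c in centrality.items()})
    out["eigenvector"] = [eig[v] for v in nodes]
    return out


def network_metrics(net: nx.Graph, seed: int = 0) -> NetworkMetrics:
    """The six network-level topological features."""
    n = net.number_of_nodes()
    if n < 2:
        raise ValueError("need >= 2 nodes")
    e = net.number_of_edges()
    avg_degree = 2.0 * e / n
    density = 2.0 * e / (n * (n - 1))
    clustering = float(np.mean(list(nx.clustering(net).values())))
    if e == 0:
        apl = math.nan
        diam = math.nan
        modularity = math.nan
    else:
        giant = net.subgraph(max(nx.connected_components(net), key=lambda c: (len(c), min(c))))
        apl = float(nx.average_shortest_path_length(giant)) if len(giant) > 1 else math.nan
        diam = float(nx.diameter(giant)) if len(giant) > 1 else math.nan
        communities = nx.community.greedy_modularity_communities(net)
        modularity = float(nx.community.modularity(net, communities))
    return NetworkMetrics(
        average_degree=avg_degree,
        graph_density=density,
        clustering_coefficient=clustering,
        average_path_length=apl,
        diameter=diam,
        modularity=modularity,
    )


def partition_edge_counts(net: nx.Graph, labels: dict) -> tuple[dict, dict]:
    """Within-group ("inner") and between-group ("external") edge counts.

    ``labels`` maps every node to its subcommunity.  Returns
    ``(inner, external)`` where inner is keyed by label and external by the
    sorted label pair; their totals sum to the edge count.
    """
    unlabeled = [v for v in net.nodes if v not in labels]
    if unlabeled:
        raise ValueError(f"unlabeled node {unlabeled[0]!r}")
    inner: dict = {g: 0 for g in sorted(set(labels[v] for v in net.nodes))}
    external: dict = {}
    for u, v in net.edges:
        gu, gv = labels[u], labels[v]
        if gu == gv:
            inner[gu] += 1
        else:
            key = tuple(sorted((gu, gv)))
            external[key] = external.get(key, 0) + 1
    return inner, external


def _letter_display(group_names, sig_pairs) -> dict:
    """Compact letter display: groups not significantly different share a
    letter (insert-and-absorb)."""
    letters: list[set] = [set(group_names)]
    for a, b in sig_pairs:
        split: list[set] = []
        for s in letters:
            if a in s and b in s:
                split.extend([s - {a}, s - {b}])
            else:
                split.append(s)
        # absorb: drop empties, duplicates, and sets contained in another
        absorbed: list[set] = []
        for s in split:
            if not s or s in absorbed:
                continue
            if any(s < t for t in split):
                continue
            absorbed.append(s)
        letters = absorbed
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    assignment = {g: "" for g in group_names}
    for i, s in enumerate(sorted(letters, key=lambda s: sorted(s))):
        for g in sorted(s):
            assignment[g] += alphabet[i % len(alphabet)]
    return assignment


def compare_node_metrics(
    metrics: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test each node metric between groups of nodes.

    Two groups: Wilcoxon rank-sum.  More: Kruskal-Wallis, followed by
    BH-corrected pairwise rank-sum comparisons summarized as a compact
    letter display (groups sharing a letter are not significantly
    different).
    """
    groups = groups.loc[metrics.index]
    names = sorted(groups.unique())
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    rows = {}
    for metric in metrics.columns:
        by_group = [metrics.loc[groups == g, metric].to_numpy() for g in names]
        if len(names) == 2:
            res = wilcoxon_rank_sum(by_group[0], by_group[1])
            rows[metric] = {
                "method": res.method,
                "statistic": res.statistic,
                "p": res.p_value,
                "letters": None,
            }
        else:
            res = kruskal_wallis(by_group)
            pair_idx = list(itertools.combinations(range(len(names)), 2))
            raw_p = []
            for i, j in pair_idx:
                pres = wilcoxon_rank_sum(by_group[i], by_group[j])
                raw_p.append(1.0 if pres.is_na else pres.p_value)
            q = bh_fdr(raw_p)
            sig = [
                (names[i], names[j])
                for (i, j), qv in zip(pair_idx, q)
                if qv < alpha
            ]
            rows[metric] = {
                "method": res.method,
                "statistic": res.statistic,
                "p": res.p_value,
                "letters": _letter_display(names, sig),
            }
    return pd.DataFrame.from_dict(rows, orient="index")
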