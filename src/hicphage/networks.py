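"""Infection networks and co-occurrence networks with centrality ranking.

The infection network is bipartite between vOTUs and dereplicated host
populations, keeping only pairs supported by at least two replicates.
Co-occurrence networks are inferred from argS-proxy transcript abundances
by three methods — Pearson correlation (|r| > 0.8), a CLR
(context-likelihood-of-relatedness) transform of a binned mutual
information matrix with top-k edge selection, and a GENIE3-style
tree-ensemble importance network (directed). Centrality (betweenness and
degree) ranks candidate keystone taxa; hosts identified by Hi-C can then
be cross-referenced against the most central nodes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import ExtraTreesRegressor
from sklearn.metrics import mutual_info_score

from .linkage import InfectionPair

__all__ = [
    "CooccurrenceNetwork",
    "build_infection_network",
    "pearson_network",
    "clr_network",
    "rf_importance_network",
    "centrality",
    "cross_reference_hosts",
]


@dataclass
class CooccurrenceNetwork:
    method: str  # "pearson" | "clr" | "rf_importance"
    graph: nx.Graph | nx.DiGraph
    selection_rule: str
    scores: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def directed(self) -> bool:
        return self.graph.is_directed()


def build_infection_network(
    pairs: Sequence[InfectionPair], min_support: int = 2
) -> nx.Graph:
    """Bipartite vOTU-host network from replicate-supported infection pairs.

    Pairs seen in fewer than ``min_support`` replicates are excluded; edge
    weight is the number of supporting replicates. When the same pair is
    supported in several conditions the edge keeps a per-condition support
    mapping and its weight is the maximum support.
    """
    g = nx.Graph()
    for p in sorted(pairs, key=lambda p: (p.votu_id, p.population_id, p.condition)):
        support = len(p.replicate_support)
        if support < min_support:
            continue
        g.add_node(p.votu_id, kind="votu")
        g.add_node(p.population_id, kind="population")
        if g.has_edge(p.votu_id, p.population_id):
            e = g.edges[p.votu_id, p.population_id]
            e["support"][p.condition] = support
            e["weight"] = max(e["weight"], support)
        else:
            g.add_edge(
                p.votu_id,
                p.population_id,
                weight=support,
                support={p.condition: support},
                host_range_class=p.host_range_class,
            )
    return g


def _clean_matrix(abund: pd.DataFrame, min_samples: int) -> pd.DataFrame:
    if abund.shape[0] < min_samples:
        raise ValueError(f"need at least {min_samples} samples, got {abund.shape[0]}")
    variances = abund.var(axis=0, ddof=0)
    dead = variances[variances == 0.0].index.tolist()
    if dead:
        warnings.warn(
            f"excluding {len(dead)} zero-variance node(s): {dead[:5]}",
            stacklevel=3,
        )
        abund = abund.drop(columns=dead)
    return abund.reindex(sorted(abund.columns), axis=1)


def pearson_network(abund: pd.DataFrame, cutoff: float = 0.8) -> CooccurrenceNetwork:
    """Undirected network with an edge wherever |Pearson r| > cutoff (strict)."""
    abund = _clean_matrix(abund, min_samples=3)
    nodes = list(abund.columns)
    r = np.corrcoef(abund.to_numpy(), rowvar=False)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if abs(r[i, j]) > cutoff:
                g.add_edge(nodes[i], nodes[j], weight=float(r[i, j]))
    return CooccurrenceNetwork(
        method="pearson",
        graph=g,
        selection_rule=f"|r| > {cutoff} (strict); {g.number_of_edges()} edges",
        scores=pd.DataFrame(r, index=nodes, columns=nodes),
    )


def _quantile_bins(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency binning via ranks; invariant to monotone rescaling."""
    ranks = rankdata(x, method="average")
    return np.ceil(ranks * bins / len(x)).astype(int)


def clr_network(abund: pd.DataFrame, top_edges: int = 200) -> CooccurrenceNetwork:
    """Context-likelihood-of-relatedness network from binned mutual information.

    MI(i, j) is estimated on equal-frequency binned abundances with
    ``ceil(sqrt(n_samples))`` bins. The CLR score is
    ``sqrt(max(z_i(j), 0)**2 + max(z_j(i), 0)**2)`` where ``z_i(j)``
    z-scores MI(i, j) within row i (excluding the diagonal). The top
    ``top_edges`` unordered pairs are retained; when the matrix is small
    enough that this would exceed the 95th percentile of pairs, the
    95th-percentile count is used instead. Score ties at the boundary are
    all kept; the applied rule is recorded on the result.
    """
    abund = _clean_matrix(abund, min_samples=3)
    nodes = list(abund.columns)
    n = len(nodes)
    if n < 3:
        raise ValueError("need at least 3 non-constant nodes for CLR z-scores")
    bins = math.ceil(math.sqrt(abund.shape[0]))
    binned = np.column_stack(
        [_quantile_bins(abund[c].to_numpy(), bins) for c in nodes]
    )
    mi = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mi[i, j] = mi[j, i] = mutual_info_score(binned[:, i], binned[:, j])
    off = ~np.eye(n, dtype=bool)
    mean = np.array([mi[i, off[i]].mean() for i in range(n)])
    std = np.array([mi[i, off[i]].std() for i in range(n)])
    std[std == 0] = 1.0
    z = (mi - mean[:, None]) / std[:, None]
    zp = np.maximum(z, 0.0)
    clr = np.sqrt(zp**2 + zp.T**2)

    pairs = [
        (float(clr[i, j]), nodes[i], nodes[j])
        for i in range(n)
        for j in range(i + 1, n)
    ]
    n_pairs = len(pairs)
    if top_edges >= n_pairs:  # matrix too small for a meaningful top-k
        k = max(1, math.ceil(0.05 * n_pairs))
        rule = f"95th-percentile cutoff ({k} of {n_pairs} pairs)"
    else:
        k, rule = top_edges, f"top {top_edges} of {n_pairs} pairs"
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    boundary = pairs[k - 1][0]
    selected = [p for p in pairs if p[0] > boundary] + [
        p for p in pairs if p[0] == boundary
    ]  # keep all ties at the boundary
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for s, a, b in selected:
        g.add_edge(a, b, weight=s)
    return CooccurrenceNetwork(
        method="clr",
        graph=g,
        selection_rule=rule + f"; {g.number_of_edges()} edges (boundary ties kept)",
        scores=pd.DataFrame(clr, index=nodes, columns=nodes),
    )


def rf_importance_network(
    abund: pd.DataFrame,
    top_fraction: float = 0.05,
    seed: int = 0,
    n_estimators: int = 100,
) -> CooccurrenceNetwork:
    """GENIE3-style directed importance network from tree ensembles.

    For each target node an extremely randomized trees regression of its
    abundance on all other nodes is fitted (features in sorted-id order;
    no bootstrap, so the fit does not depend on sample order), and feature
    importances become directed edge weights into the target. The top
    ``top_fraction`` of all directed pairs is retained (ties at the
    boundary kept), mirroring 95th-percentile edge selection. Constant
    targets are skipped with a warning. The seed is mandatory for
    reproducibility; fewer than 5 samples triggers a warning.
    """
    if abund.shape[0] < 5:
        warnings.warn("fewer than 5 samples: importances will be unstable")
    abund = _clean_matrix(abund, min_samples=3)
    nodes = list(abund.columns)
    x_all = abund.to_numpy()
    edges: list[tuple[float, str, str]] = []
    for t_idx, target in enumerate(nodes):
        y = x_all[:, t_idx]
        feats = [j for j in range(len(nodes)) if j != t_idx]
        model = ExtraTreesRegressor(
            n_estimators=n_estimators,
            max_features="sqrt",
            bootstrap=False,
            random_state=seed + t_idx,
        )
        model.fit(x_all[:, feats], y)
        for j, imp in zip(feats, model.feature_importances_):
            edges.append((float(imp), nodes[j], target))
    n_directed = len(edges)
    k = max(1, math.ceil(top_fraction * n_directed))
    edges.sort(key=lambda t: (-t[0], t[1], t[2]))
    boundary = edges[k - 1][0]
    selected = [e for e in edges if e[0] > boundary] + [
        e for e in edges if e[0] == boundary
    ]
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for w, a, b in selected:
        g.add_edge(a, b, weight=w)
    return CooccurrenceNetwork(
        method="rf_importance",
        graph=g,
        selection_rule=(
            f"top {top_fraction:.0%} of {n_directed} directed pairs; "
            f"{g.number_of_edges()} edges (boundary ties kept)"
        ),
    )


def _competition_ranks(values: Sequence[float]) -> list[int]:
    # descending competition ranking: ties share the smaller rank
    order = np.asarray(values, dtype=float)
    return [int(r) for r in rankdata(-order, method="min")]


def centrality(net: CooccurrenceNetwork | nx.Graph) -> pd.DataFrame:
    """Betweenness and degree centrality with competition ranks.

    Betweenness uses unweighted all-pairs shortest paths (directed paths
    on directed networks) and is reported unnormalized, as raw pair
    counts. Degree is the edge count per node (in + out on directed
    networks). Ranks are 1-based, descending; ties share the smaller
    rank.
    """
    g = net.graph if isinstance(net, CooccurrenceNetwork) else net
    if g.number_of_nodes() == 0:
        raise ValueError("centrality of an empty network is undefined")
    btw = nx.betweenness_centrality(g, normalized=False)
    deg = dict(g.degree())
    nodes = sorted(g.nodes())
    table = pd.DataFrame(
        {
            "node": nodes,
            "betweenness": [btw[n] for n in nodes],
            "degree": [deg[n] for n in nodes],
        }
    )
    table["rank_betweenness"] = _competition_ranks(table["betweenness"])
    table["rank_degree"] = _competition_ranks(table["degree"])
    return table


def cross_reference_hosts(
    cent: pd.DataFrame, hosts: Iterable[str], top_n: int = 5
) -> dict:
    """Annotate a centrality table with phage-host membership.

    Returns the annotated table, the top-``top_n`` nodes by betweenness
    and by degree with hosts highlighted, and any host ids that could not
    be mapped to network nodes (listed, never silently dropped).
    """
    hosts = set(hosts)
    known = set(cent["node"])
    table = cent.copy()
    table["is_host"] = table["node"].isin(hosts)
    top_btw = table.sort_values(["rank_betweenness", "node"]).head(top_n)
    top_deg = table.sort_values(["rank_degree", "node"]).head(top_n)
    return {
        "table": table,
        "top_betweenness": top_btw[["node", "betweenness", "rank_betweenness", "is_host"]],
        "top_degree": top_deg[["node", "degree", "rank_degree", "is_host"]],
        "hosts_in_top_betweenness": sorted(set(top_btw["node"]) & hosts),
        "hosts_in_top_degree": sorted(set(top_deg["node"]) & hosts),
        "unmapped_hosts": sorted(hosts - known),
    }
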