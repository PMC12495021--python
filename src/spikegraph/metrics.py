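"""Graph-level and node-level measures for binary directed connectivity graphs.

All functions accept a labelled square 0/1 adjacency ``pandas.DataFrame``
(rows = sources, columns = targets, zero diagonal).  Conventions:

* density = m / (n(n-1)), self-loops excluded;
* characteristic path length = mean shortest directed distance over ordered
  pairs that are actually reachable (real connectivity graphs routinely
  contain nodes with no incoming edges, so infinite distances must be
  excluded for the measure to exist);
* global efficiency = mean of 1/distance over all ordered pairs, with
  1/infinity = 0;
* clustering is the directed (Fagiolo) coefficient
  ``C_i = [(A + A^T)^3]_ii / (2 [d_tot(d_tot - 1) - 2 d_bidir])``, counting
  all directed triangle motifs; nodes whose denominator is zero are
  undefined (NaN) and excluded from the global mean;
* betweenness is directed shortest-path betweenness (Brandes), fractionally
  counted and normalized by (n-1)(n-2);
* a node is "high degree" when its total degree exceeds the mean plus one
  population standard deviation; hubs are the high-degree nodes ordered by
  total degree, then betweenness, then label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ParameterError

logger = logging.getLogger(__name__)


def _validate(adj: pd.DataFrame) -> np.ndarray:
    a = adj.to_numpy()
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ParameterError("adjacency must be square")
    if not np.isin(a, (0, 1)).all():
        raise ParameterError("adjacency entries must be 0/1")
    if np.diag(a).any():
        raise ParameterError("adjacency must have a zero diagonal")
    return a.astype(int)


def to_networkx(adj: pd.DataFrame) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(adj.index)
    for i in adj.index:
        for j in adj.columns:
            if adj.loc[i, j]:
                g.add_edge(i, j)
    return g


def density(adj: pd.DataFrame) -> float:
    a = _validate(adj)
    n = a.shape[0]
    if n < 2:
        raise ParameterError("need n >= 2")
    return float(a.sum() / (n * (n - 1)))


def degrees(adj: pd.DataFrame) -> pd.DataFrame:
    """Per-node in-, out-, and total degree."""
    a = _validate(adj)
    return pd.DataFrame(
        {
            "in_degree": a.sum(axis=0),
            "out_degree": a.sum(axis=1),
            "total_degree": a.sum(axis=0) + a.sum(axis=1),
        },
        index=adj.index,
    )


def high_degree_nodes(deg: pd.DataFrame) -> set:
    """Nodes whose total degree exceeds mean + 1 SD (population SD)."""
    total = deg["total_degree"].to_numpy(dtype=float)
    thr = total.mean() + total.std(ddof=0)
    return set(deg.index[total > thr])


def local_clustering(adj: pd.DataFrame) -> pd.Series:
    """Directed (Fagiolo) clustering coefficient per node; NaN when undefined."""
    a = _validate(adj).astype(float)
    s = a + a.T
    tri = np.diagonal(s @ s @ s)
    d_tot = a.sum(axis=0) + a.sum(axis=1)
    d_bi = np.diagonal(a @ a)
    denom = 2.0 * (d_tot * (d_tot - 1) - 2.0 * d_bi)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, tri / denom, np.nan)
    return pd.Series(c, index=adj.index)


def global_clustering(adj: pd.DataFrame) -> float:
    """Mean local clustering over nodes where it is defined."""
    c = local_clustering(adj)
    if c.notna().sum() == 0:
        logger.warning("global clustering undefined: no node has a defined coefficient")
        return float("nan")
    return float(c.mean(skipna=True))


def shortest_path_stats(adj: pd.DataFrame) -> tuple[float, float]:
    """(characteristic path length over reachable pairs, global efficiency)."""
    a = _validate(adj)
    n = a.shape[0]
    if n < 2:
        raise ParameterError("need n >= 2")
    g = to_networkx(adj)
    dist_sum = 0.0
    inv_sum = 0.0
    n_reachable = 0
    for src, dists in nx.all_pairs_shortest_path_length(g):
        for tgt, d in dists.items():
            if src == tgt:
                continue
            dist_sum += d
            inv_sum += 1.0 / d
            n_reachable += 1
    efficiency = inv_sum / (n * (n - 1))
    if n_reachable == 0:
        logger.warning("characteristic path length undefined: no reachable pair")
        return float("nan"), float(efficiency)
    return dist_sum / n_reachable, float(efficiency)


def betweenness(adj: pd.DataFrame) -> pd.Series:
    """Directed shortest-path betweenness, normalized by (n-1)(n-2)."""
    a = _validate(adj)
    if a.shape[0] < 3:
        raise ParameterError("need n >= 3")
    bc = nx.betweenness_centrality(to_networkx(adj), normalized=True)
    return pd.Series(bc).reindex(adj.index)


@dataclass
class GraphMetricsReport:
    density: float
    char_path_length: float
    global_efficiency: float
    global_clustering: float
    per_node: pd.DataFrame  # in/out/total degree, local_clustering, betweenness
    high_degree_nodes: set
    hubs: list

    def summary(self) -> dict:
        return {
            "density": self.density,
            "char_path_length": self.char_path_length,
            "global_efficiency": self.global_efficiency,
            "global_clustering": self.global_clustering,
            "high_degree_nodes": sorted(self.high_degree_nodes),
            "hubs": list(self.hubs),
        }


def find_hubs(deg: pd.DataFrame, btw: pd.Series, k: int | None = None) -> list:
    """High-degree nodes ordered by total degree, then betweenness, then label."""
    flagged = high_degree_nodes(deg)
    order = sorted(
        flagged,
        key=lambda node: (-deg.loc[node, "total_degree"], -btw.loc[node], node),
    )
    return order if k is None else order[:k]


def compute_report(adj: pd.DataFrame) -> GraphMetricsReport:
    """All graph measures for one connectivity matrix."""
    deg = degrees(adj)
    cpl, eff = shortest_path_stats(adj)
    clus = local_clustering(adj)
    btw = betweenness(adj)
    per_node = deg.assign(local_clustering=clus, betweenness=btw)
    return GraphMetricsReport(
        density=density(adj),
        char_path_length=cpl,
        global_efficiency=eff,
        global_clustering=float(clus.mean(skipna=True)) if clus.notna().any() else float("nan"),
        per_node=per_node,
        high_degree_nodes=high_degree_nodes(deg),
        hubs=find_hubs(deg, btw),
    )
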