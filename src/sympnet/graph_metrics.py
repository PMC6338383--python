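"""Weighted centrality and clustering metrics for symptom networks.

Conventions (recorded in the returned table's attrs):

* Signed edge weights enter every metric through their absolute value.
* Distances use edge length 1 / |w|, so strong associations are short, and
  shortest paths follow Dijkstra's algorithm.
* Betweenness splits credit fractionally across tied shortest paths and is
  reported unnormalized (total pair count, not a fraction).
* Closeness is (r - 1) / sum of distances to the r - 1 reachable nodes —
  the reachable-fraction-scaled inverse average path length, which reduces
  to the textbook (n - 1) / sum(d) on connected graphs and to 0 for an
  isolated node.
* The clustering coefficient is the Zhang–Horvath weighted measure on
  weights normalized by the network's maximum |w|.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd

from .network import SymptomNetwork
from .symptoms import DOMAINS

CONVENTIONS = {
    "distance_transform": "1/|w|",
    "negative_weights": "absolute value",
    "betweenness": "fractional, unnormalized",
    "closeness": "reachable-fraction scaled",
    "clustering": "zhang-horvath, weights scaled by max |w|",
}


def _abs_weights(net: SymptomNetwork) -> np.ndarray:
    w = np.abs(np.asarray(net.weights, dtype=float))
    np.fill_diagonal(w, 0.0)
    return w


def node_strength(net: SymptomNetwork) -> pd.Series:
    """Strength s_i = sum of |w_ij| over incident edges; weighted degree."""
    w = _abs_weights(net)
    return pd.Series(w.sum(axis=1), index=list(net.nodes), name="strength")


def shortest_distances(net: SymptomNetwork) -> pd.DataFrame:
    """All-pairs Dijkstra distances with edge length 1/|w|; inf if unreachable."""
    g = net.to_graph(absolute=True)
    dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
    nodes = list(net.nodes)
    mat = np.full((len(nodes), len(nodes)), np.inf)
    for i, u in enumerate(nodes):
        for j, v in enumerate(nodes):
            d = dist.get(u, {}).get(v)
            if d is not None:
                mat[i, j] = d
    np.fill_diagonal(mat, 0.0)
    return pd.DataFrame(mat, index=nodes, columns=nodes)


def betweenness(net: SymptomNetwork) -> pd.Series:
    """Unnormalized weighted betweenness: for every unordered pair (s, t),
    an intermediate node accrues the fraction of shortest s-t paths that
    pass through it."""
    g = net.to_graph(absolute=True)
    b = nx.betweenness_centrality(g, weight="length", normalized=False)
    return pd.Series({n: b[n] for n in net.nodes}, name="betweenness")


def closeness(net: SymptomNetwork) -> pd.Series:
    """Inverse average shortest-path length, scaled for disconnection.

    c_i = (r_i - 1) / sum_j d(i, j) over the r_i - 1 reachable others;
    isolated nodes score 0.  Equals (n - 1) / sum(d) when connected.
    """
    d = shortest_distances(net).to_numpy()
    vals = {}
    for i, name in enumerate(net.nodes):
        finite = np.isfinite(d[i]) & (np.arange(len(net.nodes)) != i)
        r = int(finite.sum())
        total = d[i, finite].sum()
        vals[name] = r / total if r > 0 and total > 0 else 0.0
    return pd.Series(vals, name="closeness")


def zhang_horvath_clustering(net: SymptomNetwork) -> pd.Series:
    """Zhang–Horvath weighted clustering coefficient per node.

    With w_hat = |w| / max|w|:

        C_i = sum_{j != k != i} w_hat_ij w_hat_jk w_hat_ik
              / ((sum_j w_hat_ij)^2 - sum_j w_hat_ij^2)

    i.e. the total triangle weight around i over its maximum possible value;
    reduces to the classical clustering coefficient on {0,1} weights; 0 when
    the denominator vanishes (fewer than two distinct-strength neighbours).
    """
    w = _abs_weights(net)
    wmax = w.max()
    if wmax == 0:
        return pd.Series(0.0, index=list(net.nodes), name="clustering")
    wh = w / wmax
    numer = np.diag(wh @ wh @ wh)                 # 2x the triangle product sum, symmetric
    s1 = wh.sum(axis=1)
    s2 = (wh**2).sum(axis=1)
    denom = s1**2 - s2
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, numer / denom, 0.0)
    return pd.Series(np.clip(c, 0.0, 1.0), index=list(net.nodes), name="clustering")


def centrality_table(net: SymptomNetwork) -> pd.DataFrame:
    """All four node metrics plus per-metric descending rank.

    Columns: node, domain, betweenness, closeness, strength, clustering and
    ``<metric>_rank`` (1 = most central).  Metric conventions are recorded in
    ``DataFrame.attrs['conventions']``.
    """
    table = pd.DataFrame(
        {
            "node": list(net.nodes),
            "domain": [DOMAINS.get(n, "") for n in net.nodes],
            "betweenness": betweenness(net).to_numpy(),
            "closeness": closeness(net).to_numpy(),
            "strength": node_strength(net).to_numpy(),
            "clustering": zhang_horvath_clustering(net).to_numpy(),
        }
    )
    for metric in ("betweenness", "closeness", "strength", "clustering"):
        table[f"{metric}_rank"] = (
            table[metric].rank(ascending=False, method="min").astype(int)
        )
    table.attrs["conventions"] = dict(CONVENTIONS)
    return table
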