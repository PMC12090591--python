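"""Weighted centrality indices of the symptom network.

Definitions follow the psychometric-network convention:

- strength: sum of absolute edge weights at a node;
- expected influence: signed sum of edge weights (distinguishes negative ties);
- closeness: reciprocal of the summed shortest-path distances to all other
  nodes, with edge length 1/|w| (strong edges are short);
- betweenness: number of shortest paths between other node pairs passing
  through the node, each unordered pair counted once with fractional credit
  when several shortest paths tie.

A node that cannot reach some other node has closeness 0 (the sum is
infinite); this is the documented convention for disconnected networks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse import csr_array
from scipy.sparse.csgraph import dijkstra
import networkx as nx

from .network import WeightedNetwork


def strength(net: WeightedNetwork) -> np.ndarray:
    return np.abs(net.weights).sum(axis=1)


def expected_influence(net: WeightedNetwork) -> np.ndarray:
    return net.weights.sum(axis=1)


def shortest_path_lengths(net: WeightedNetwork) -> np.ndarray:
    """All-pairs shortest-path distances with edge length 1/|weight|.

    Unreachable pairs get +inf; the diagonal is 0.
    """
    with np.errstate(divide="ignore"):
        lengths = np.where(net.weights != 0, 1.0 / np.abs(net.weights), 0.0)
    return dijkstra(csr_array(lengths), directed=False)


def closeness(net: WeightedNetwork) -> np.ndarray:
    d = shortest_path_lengths(net)
    p = net.p
    out = np.zeros(p)
    if p == 1:
        return out
    off = d + np.diag(np.full(p, np.nan))
    totals = np.nansum(off, axis=1)
    reachable = np.isfinite(off) | np.isnan(off)
    ok = reachable.all(axis=1) & (totals > 0)
    out[ok] = 1.0 / totals[ok]
    return out


def betweenness(net: WeightedNetwork, ordered_pairs: bool = False) -> np.ndarray:
    """Weighted betweenness by the standard accumulation algorithm.

    ``ordered_pairs=True`` counts each pair in both directions (doubling the
    undirected values), provided for cross-checks against conventions that do.
    """
    g = net.to_graph()
    # networkx dispatches on the edge attribute; use the 1/|w| length
    for _, _, attrs in g.edges(data=True):
        attrs["length"] = 1.0 / attrs["abs_weight"]
    bc = nx.betweenness_centrality(g, weight="length", normalized=False)
    vals = np.array([bc[lab] for lab in net.labels])
    return 2.0 * vals if ordered_pairs else vals


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1) if x.size > 1 else 0.0
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def centrality_table(net: WeightedNetwork) -> pd.DataFrame:
    """Raw and z-standardized centrality indices, sorted by strength descending."""
    s = strength(net)
    ei = expected_influence(net)
    c = closeness(net)
    b = betweenness(net)
    df = pd.DataFrame(
        {
            "node": list(net.labels),
            "strength": s,
            "closeness": c,
            "betweenness": b,
            "expected_influence": ei,
            "strength_z": _zscore(s),
            "closeness_z": _zscore(c),
            "betweenness_z": _zscore(b),
            "expected_influence_z": _zscore(ei),
        }
    )
    order = np.lexsort((np.arange(net.p), -s))
    return df.iloc[order].reset_index(drop=True)

CENTRALITY_FUNCS = {
    "strength": strength,
    "expected_influence": expected_influence,
    "closeness": closeness,
    "betweenness": betweenness,
}
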