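"""Weighted graph-theory metrics for structural brain networks.

Edge weights quantify connection strength, so shortest paths run over
*lengths* ``l = 1/w`` (stronger connections are shorter).  All metrics follow
the standard weighted-undirected conventions used for connectomes:

* **degree** — number of nonzero connections of a node;
* **nodal strength** — sum of edge weights at a node;
* **clustering coefficient** — geometric-mean triangle form on weights
  normalised by the network maximum (reduces to the edges-among-neighbours
  ratio on binary graphs);
* **betweenness centrality** — raw count of shortest paths a node lies on
  (endpoints excluded), with fractional credit split over tied geodesics;
* **characteristic path length** — mean finite shortest-path length over
  node pairs (disconnected pairs excluded and counted);
* **global efficiency** — mean inverse shortest-path length over ordered
  pairs, disconnected pairs contributing zero;
* **local efficiency** — global efficiency of the subgraph induced by a
  node's neighbours.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra as _dijkstra

from .networks import ConnectivityMatrix

#: relative tolerance for treating two path lengths as tied
TIE_RTOL = 1e-9

#: network-level metric names, in the documented pruning-priority order
SUMMARY_METRICS = (
    "mean_strength",
    "mean_clustering",
    "mean_betweenness",
    "characteristic_path_length",
    "global_efficiency",
)


def _as_weights(m) -> np.ndarray:
    if isinstance(m, ConnectivityMatrix):
        return m.weights
    w = np.asarray(m, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("expected a square weight matrix")
    return w


def weight_to_length(m) -> np.ndarray:
    """Length matrix ``l = 1/w``; absent edges (and the diagonal) are ``inf``."""
    w = _as_weights(m)
    with np.errstate(divide="ignore"):
        length = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(length, np.inf)
    return length


def shortest_paths(m) -> np.ndarray:
    """All-pairs shortest-path distance matrix over lengths ``1/w``.

    Symmetric with zero diagonal; ``inf`` marks disconnected pairs.
    """
    w = _as_weights(m)
    if w.shape[0] == 0:
        return np.zeros((0, 0))
    lengths = np.where(w > 0, weight_to_length(w), 0.0)
    lengths[~np.isfinite(lengths)] = 0.0
    return _dijkstra(lengths, directed=False)


class PathLengthResult(NamedTuple):
    """Characteristic path length plus the number of excluded infinite pairs."""

    value: float
    n_infinite_pairs: int


def characteristic_path_length(m) -> PathLengthResult:
    """Mean finite shortest-path length over unordered node pairs."""
    d = shortest_paths(m)
    n = d.shape[0]
    if n < 2:
        raise ValueError("characteristic path length needs at least 2 nodes")
    iu = np.triu_indices(n, k=1)
    vals = d[iu]
    finite = np.isfinite(vals)
    n_inf = int((~finite).sum())
    if not finite.any():
        raise ValueError("network is fully disconnected: no finite path lengths")
    return PathLengthResult(float(vals[finite].mean()), n_inf)


def global_efficiency(m) -> float:
    """Average inverse shortest-path length over ordered pairs (inf -> 0)."""
    d = shortest_paths(m)
    n = d.shape[0]
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    with np.errstate(divide="ignore"):
        inv = np.where(d > 0, 1.0 / np.where(d > 0, d, 1.0), 0.0)
    inv[~np.isfinite(d)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def degree(m) -> np.ndarray:
    """Number of nonzero connections per node."""
    w = _as_weights(m)
    return (w > 0).sum(axis=1).astype(float)


def nodal_strength(m) -> np.ndarray:
    """Sum of edge weights per node (row sums)."""
    return _as_weights(m).sum(axis=1)


def clustering_coefficient(m) -> np.ndarray:
    """Weighted clustering per node, geometric-mean triangle form.

    Weights are normalised by the matrix maximum before taking cube roots, so
    the statistic is invariant to global rescaling and equals the classic
    edges-among-neighbours ratio on binary graphs.  Nodes of degree < 2
    score 0.
    """
    w = _as_weights(m)
    n = w.shape[0]
    if n == 0:
        return np.zeros(0)
    wmax = w.max()
    if wmax <= 0:
        return np.zeros(n)
    what = np.cbrt(w / wmax)
    triangles = np.diag(what @ what @ what)  # 2x the triangle sum per node
    k = degree(w)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, triangles / np.where(denom > 0, denom, 1.0), 0.0)
    return c


def betweenness_centrality(m, *, tie_rtol: float = TIE_RTOL) -> np.ndarray:
    """Shortest-path betweenness with fractional credit for tied geodesics.

    Dijkstra distances feed a shortest-path DAG per source; path counts and
    dependency accumulation follow Brandes' scheme.  Values are raw
    (unnormalised) counts of intermediate memberships; each unordered pair is
    counted once.
    """
    w = _as_weights(m)
    n = w.shape[0]
    if n == 0:
        return np.zeros(0)
    lengths = weight_to_length(w)
    dist = shortest_paths(w)
    bc = np.zeros(n)
    finite_len = np.isfinite(lengths)
    for s in range(n):
        d = dist[s]
        reach = np.isfinite(d)
        # DAG edge u->v iff u,v reachable and d[u] + l(u,v) == d[v] (within tol)
        cand = d[:, None] + np.where(finite_len, lengths, np.inf)
        dag = finite_len & np.isclose(cand, d[None, :], rtol=tie_rtol, atol=0.0)
        dag &= reach[:, None] & reach[None, :]
        order = np.argsort(d, kind="stable")
        sigma = np.zeros(n)
        sigma[s] = 1.0
        for v in order:
            if v == s or not reach[v]:
                continue
            preds = dag[:, v]
            if preds.any():
                sigma[v] = sigma[preds].sum()
        delta = np.zeros(n)
        for v in order[::-1]:
            if v == s or not reach[v] or sigma[v] == 0:
                continue
            preds = dag[:, v]
            delta[preds] += sigma[preds] / sigma[v] * (1.0 + delta[v])
        delta[s] = 0.0
        bc += delta
    return bc / 2.0  # each unordered pair visited from both endpoints


def local_efficiency(m) -> np.ndarray:
    """Global efficiency of each node's neighbour-induced subgraph."""
    w = _as_weights(m)
    n = w.shape[0]
    eff = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(w[i] > 0)
        if nb.size < 2:
            continue
        eff[i] = global_efficiency(w[np.ix_(nb, nb)])
    return eff


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def node_metric_table(m: ConnectivityMatrix) -> pd.DataFrame:
    """Per-node metrics for one participant network."""
    return pd.DataFrame(
        {
            "degree": degree(m),
            "strength": nodal_strength(m),
            "clustering": clustering_coefficient(m),
            "betweenness": betweenness_centrality(m),
            "local_efficiency": local_efficiency(m),
        },
        index=pd.Index(m.node_labels, name="node"),
    )


def network_summary(m: ConnectivityMatrix) -> dict[str, float]:
    """Network-wide summary: means of node metrics plus path-based measures."""
    cpl = characteristic_path_length(m)
    return {
        "mean_strength": float(nodal_strength(m).mean()),
        "mean_clustering": float(clustering_coefficient(m).mean()),
        "mean_betweenness": float(betweenness_centrality(m).mean()),
        "characteristic_path_length": cpl.value,
        "global_efficiency": global_efficiency(m),
        "n_disconnected_pairs": float(cpl.n_infinite_pairs),
    }


class RedundancyScreen(NamedTuple):
    """Outcome of the metric-redundancy screen for one network."""

    retained: tuple[str, ...]
    dropped: tuple[str, ...]
    correlations: pd.DataFrame


def metric_redundancy_prune(table: pd.DataFrame, cutoff: float = 0.85,
                            priority: Sequence[str] = SUMMARY_METRICS) -> RedundancyScreen:
    """Drop metrics that duplicate information already carried by another.

    Pearson correlations are computed across participants for every metric
    pair; metrics are visited in the documented priority order and kept only
    if their |r| with every already-kept metric stays below ``cutoff``.
    Constant columns yield undefined (NaN) correlations, which are reported
    as such and never trigger a drop.
    """
    if len(table) < 3:
        raise ValueError("redundancy screen needs at least 3 participants")
    cols = [c for c in priority if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    corr = table[cols].corr()  # pandas leaves constant columns as NaN
    retained: list[str] = []
    dropped: list[str] = []
    for c in cols:
        high = any(abs(corr.loc[c, k]) >= cutoff for k in retained
                   if np.isfinite(corr.loc[c, k]))
        (dropped if high else retained).append(c)
    return RedundancyScreen(tuple(retained), tuple(dropped), corr)
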