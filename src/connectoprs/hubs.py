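"""Composite hubness and rich-club / feeder / local connectivity.

Hub nodes are identified with a composite *hubness* score rather than any
single centrality: per participant, node degree, nodal strength, betweenness
centrality and local efficiency are each divided by their across-node maximum
(so the four ingredients weigh equally) and averaged.  Hubness is averaged
over participants, and nodes whose mean hubness is at least one standard
deviation above the average of the mean hubnesses are hubs.

Edges are then classified by their endpoints — hub–hub (*rich club*),
hub–non-hub (*feeder*), non-hub–non-hub (*local*) — and each participant's
class connectivity is the sum of edge weights in that class.  The three
class sums partition the total edge weight exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .networks import ConnectivityMatrix

HUBNESS_INGREDIENTS = ("degree", "strength", "betweenness", "local_efficiency")

EDGE_CLASSES = ("rich_club", "feeder", "local")


def node_hubness(metrics: pd.DataFrame) -> pd.Series:
    """Per-node hubness for one participant: mean of max-normalised metrics.

    ``metrics`` is a node-by-metric table containing the four hubness
    ingredients.  An all-zero ingredient column has no maximum to divide by:
    it contributes zero to every node (with a warning), which keeps complete
    graphs — whose betweenness is identically zero — well defined.  A table
    where every ingredient is all-zero (an empty network) raises.
    """
    missing = [c for c in HUBNESS_INGREDIENTS if c not in metrics.columns]
    if missing:
        raise ValueError(f"metric table lacks hubness ingredients {missing}")
    block = metrics[list(HUBNESS_INGREDIENTS)].to_numpy(dtype=float)
    maxima = block.max(axis=0)
    if (maxima <= 0).all():
        raise ValueError("all hubness ingredients are all-zero: empty network")
    if (maxima <= 0).any():
        bad = [c for c, mx in zip(HUBNESS_INGREDIENTS, maxima) if mx <= 0]
        warnings.warn(f"all-zero metric column(s) {bad} contribute zero to hubness",
                      stacklevel=2)
    return pd.Series((block / np.where(maxima > 0, maxima, 1.0)).mean(axis=1),
                     index=metrics.index, name="hubness")


@dataclass(frozen=True)
class HubPartition:
    """Hub set and resulting edge classification for a node set."""

    mean_hubness: pd.Series
    hub_cutoff: float
    hub_nodes: tuple[str, ...]

    @property
    def is_hub(self) -> np.ndarray:
        return np.asarray([n in set(self.hub_nodes) for n in self.mean_hubness.index])


def identify_hubs(hubness: pd.DataFrame) -> HubPartition:
    """Apply the mean + 1 SD rule to cohort-averaged hubness.

    ``hubness`` is a participant-by-node table.  The cutoff uses the sample
    (n−1) standard deviation across nodes.  Zero variance across nodes means
    no node stands out; an empty hub set is returned with a warning.
    """
    if len(hubness) < 2:
        raise ValueError("hub identification needs at least 2 participants")
    mean_hub = hubness.mean(axis=0)
    sd = float(mean_hub.std(ddof=1))
    if sd == 0.0:
        warnings.warn("zero variance in mean hubness across nodes: no hubs identified",
                      stacklevel=2)
        return HubPartition(mean_hub, float("inf"), ())
    cutoff = float(mean_hub.mean()) + sd
    hubs = tuple(mean_hub.index[mean_hub >= cutoff])
    return HubPartition(mean_hub, cutoff, hubs)


def classify_edges(partition: HubPartition) -> pd.DataFrame:
    """Classify every unordered node pair as rich-club, feeder or local."""
    nodes = list(partition.mean_hubness.index)
    is_hub = partition.is_hub
    n = len(nodes)
    iu, ju = np.triu_indices(n, k=1)
    n_hub_ends = is_hub[iu].astype(int) + is_hub[ju].astype(int)
    labels = np.array(EDGE_CLASSES)[2 - n_hub_ends]  # 2 hubs->rich, 1->feeder, 0->local
    return pd.DataFrame({
        "node_i": [nodes[i] for i in iu],
        "node_j": [nodes[j] for j in ju],
        "edge_class": labels,
    })


def class_connectivity(m: ConnectivityMatrix, partition: HubPartition) -> dict[str, float]:
    """Weight sums of rich-club, feeder and local edges for one participant."""
    if tuple(partition.mean_hubness.index) != m.node_labels:
        raise ValueError("hub partition node set does not match matrix labels")
    is_hub = partition.is_hub
    w = m.weights
    hub_idx = np.flatnonzero(is_hub)
    non_idx = np.flatnonzero(~is_hub)
    rich = w[np.ix_(hub_idx, hub_idx)].sum() / 2.0
    local = w[np.ix_(non_idx, non_idx)].sum() / 2.0
    feeder = w[np.ix_(hub_idx, non_idx)].sum()
    return {"rich_club": float(rich), "feeder": float(feeder), "local": float(local)}
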