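"""Connectivity-matrix I/O, validation, thresholding and subnetwork extraction.

Structural connectomes are undirected weighted networks on the 90 cerebrum
regions of the AAL parcellation.  Edge weights are either streamline counts
(NS) or mean fractional anisotropy along the tract (FA).  Connections
reconstructed from very few streamlines are unreliable, so NS edges with
``weight <= t`` (default ``t = 5``) are discarded; robustness sweeps vary
``t`` from 1 to 12.  FA-weighted networks inherit the edge mask of the
participant's NS network, since both weightings describe the same tractogram.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: weightings supported for connectome edges
WEIGHTINGS = ("NS", "FA")

#: the four analysis networks
SUBNETWORKS = ("whole_brain", "dmn", "limbic", "visual")

#: streamline-count thresholds swept in robustness analyses
THRESHOLD_SWEEP = tuple(range(1, 13))

#: default streamline-count threshold (edges with NS <= 5 discarded)
DEFAULT_THRESHOLD = 5

_SYMMETRY_RTOL = 1e-8


class ConnectomeError(ValueError):
    """Raised for invalid connectivity matrices or configuration."""


@dataclass(frozen=True)
class ConnectivityMatrix:
    """One participant's weighted undirected brain network.

    Parameters
    ----------
    weights
        Square symmetric nonnegative matrix with zero diagonal.
    node_labels
        Ordered region names, one per row/column.
    weighting
        ``"NS"`` (streamline count) or ``"FA"`` (mean fractional anisotropy).
    participant_id
        Identifier of the participant the matrix belongs to.
    """

    weights: np.ndarray
    node_labels: tuple[str, ...]
    weighting: str = "NS"
    participant_id: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ConnectomeError(f"weight matrix must be square, got shape {w.shape}")
        if len(self.node_labels) != w.shape[0]:
            raise ConnectomeError(
                f"{len(self.node_labels)} labels for a {w.shape[0]}-node matrix"
            )
        if self.weighting not in WEIGHTINGS:
            raise ConnectomeError(f"unknown weighting {self.weighting!r}")
        if np.isnan(w).any():
            raise ConnectomeError("weight matrix contains NaN entries")
        if (w < 0).any():
            raise ConnectomeError("weight matrix contains negative entries")
        scale = max(np.abs(w).max(), 1.0)
        if np.abs(w - w.T).max() > _SYMMETRY_RTOL * scale:
            raise ConnectomeError("matrix asymmetric beyond tolerance; refusing to symmetrize")
        if np.abs(np.diag(w)).max() > 0:
            raise ConnectomeError("diagonal must be zero (no self-connections)")
        if self.weighting == "FA" and (w[w > 0] >= 1.0).any():
            raise ConnectomeError("FA weights must lie in (0, 1)")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "node_labels", tuple(self.node_labels))

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConnectivityMatrix):
            return NotImplemented
        return (
            self.node_labels == other.node_labels
            and self.weighting == other.weighting
            and self.participant_id == other.participant_id
            and np.array_equal(self.weights, other.weights)
        )


# ---------------------------------------------------------------------------
# Atlas registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtlasRegistry:
    """The AAL-90 parcellation with subnetwork membership flags."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"region", "hemisphere", "dmn", "limbic", "visual"}
        if not required <= set(self.table.columns):
            raise ConnectomeError(f"atlas table missing columns {required - set(self.table.columns)}")
        if len(self.table) != 90:
            raise ConnectomeError(f"expected 90 atlas regions, got {len(self.table)}")
        if self.table["region"].duplicated().any():
            raise ConnectomeError("duplicate atlas region names")

    @property
    def region_names(self) -> tuple[str, ...]:
        return tuple(self.table["region"])

    @property
    def n_regions(self) -> int:
        return len(self.table)

    def subnetwork_indices(self, name: str) -> np.ndarray:
        """Node indices (into the canonical ordering) of a named subnetwork."""
        key = name.lower()
        if key == "whole_brain":
            return np.arange(self.n_regions)
        if key not in ("dmn", "limbic", "visual"):
            raise ConnectomeError(f"unknown subnetwork {name!r}; expected one of {SUBNETWORKS}")
        return np.flatnonzero(self.table[key].to_numpy(dtype=bool))

    def subnetwork(self, name: str) -> "SubnetworkDefinition":
        return SubnetworkDefinition(name=name.lower(), node_indices=tuple(self.subnetwork_indices(name)))


@dataclass(frozen=True)
class SubnetworkDefinition:
    """A named node subset of the atlas."""

    name: str
    node_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = self.node_indices
        if len(set(idx)) != len(idx):
            raise ConnectomeError("duplicate node indices in subnetwork definition")


def load_atlas() -> AtlasRegistry:
    """Load the canonical AAL-90 registry shipped with the package."""
    ref = importlib.resources.files("connectoprs.data") / "aal90.tsv"
    with importlib.resources.as_file(ref) as path:
        table = pd.read_csv(path, sep="\t")
    return AtlasRegistry(table=table)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_connectome(path, weighting: str = "NS", node_labels=None,
                    participant_id: str = "") -> ConnectivityMatrix:
    """Read a connectome from a square-matrix or long-format edge-list file.

    A file whose first non-comment line has exactly three or four fields with
    a recognisable header (``node_i``/``node_j``/``weight``) is parsed as an
    edge list; anything else is parsed as a whitespace- or comma-delimited
    square matrix.
    """
    path = str(path)
    with open(path) as fh:
        first = fh.readline()
    sep = "," if "," in first else None
    tokens = first.replace(",", " ").split()
    is_edge_list = {"node_i", "node_j", "weight"} <= set(t.lower() for t in tokens)
    if is_edge_list:
        df = pd.read_csv(path, sep=sep if sep else r"\s+")
        cols = {c.lower(): c for c in df.columns}
        if node_labels is None:
            nodes = sorted(set(df[cols["node_i"]]) | set(df[cols["node_j"]]))
        else:
            nodes = list(node_labels)
        index = {lab: i for i, lab in enumerate(nodes)}
        w = np.zeros((len(nodes), len(nodes)))
        for _, row in df.iterrows():
            i, j = index[row[cols["node_i"]]], index[row[cols["node_j"]]]
            w[i, j] = w[j, i] = row[cols["weight"]]
        return ConnectivityMatrix(w, tuple(nodes), weighting, participant_id)
    w = np.loadtxt(path, delimiter="," if sep else None)
    if node_labels is None:
        node_labels = tuple(f"node{i}" for i in range(w.shape[0]))
    return ConnectivityMatrix(w, tuple(node_labels), weighting, participant_id)


def save_connectome(m: ConnectivityMatrix, path, fmt: str = "matrix") -> None:
    """Write a connectome as a square matrix or long-format edge list."""
    if fmt == "matrix":
        np.savetxt(path, m.weights, fmt="%.10g")
    elif fmt == "edgelist":
        rows = []
        n = m.n_nodes
        iu, ju = np.triu_indices(n, k=1)
        for i, j in zip(iu, ju):
            if m.weights[i, j] > 0:
                rows.append((m.participant_id, m.node_labels[i], m.node_labels[j], m.weights[i, j]))
        pd.DataFrame(rows, columns=["participant", "node_i", "node_j", "weight"]).to_csv(
            path, sep="\t", index=False)
    else:
        raise ConnectomeError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Thresholding and subsetting
# ---------------------------------------------------------------------------

def apply_streamline_threshold(m: ConnectivityMatrix, t: int, *,
                               override: bool = False) -> ConnectivityMatrix:
    """Discard edges reconstructed from ``t`` or fewer streamlines.

    Applies to NS-weighted matrices; edges with weight ``<= t`` are zeroed,
    all others kept unchanged.  ``t`` outside the 1–12 sweep requires
    ``override=True``.
    """
    if m.weighting != "NS":
        raise ConnectomeError("streamline threshold applies to NS-weighted matrices; "
                              "use threshold_with_mask for FA networks")
    if t not in THRESHOLD_SWEEP and not override:
        raise ConnectomeError(f"threshold {t} outside 1-12 sweep (pass override=True to force)")
    w = m.weights.copy()
    w[w <= t] = 0.0
    return replace(m, weights=w)


def threshold_with_mask(fa: ConnectivityMatrix, ns: ConnectivityMatrix, t: int, *,
                        override: bool = False) -> ConnectivityMatrix:
    """Apply the NS-derived edge mask of the same participant to an FA matrix."""
    if fa.node_labels != ns.node_labels:
        raise ConnectomeError("FA and NS matrices must share node labels")
    ns_thr = apply_streamline_threshold(ns, t, override=override)
    w = np.where(ns_thr.weights > 0, fa.weights, 0.0)
    return replace(fa, weights=w)


def extract_subnetwork(m: ConnectivityMatrix, d: SubnetworkDefinition) -> ConnectivityMatrix:
    """Principal submatrix on the subnetwork's nodes, labels subset to match."""
    idx = np.asarray(d.node_indices, dtype=int)
    if len(idx) and (idx.min() < 0 or idx.max() >= m.n_nodes):
        raise ConnectomeError(f"subnetwork {d.name!r} indices out of range for {m.n_nodes} nodes")
    w = m.weights[np.ix_(idx, idx)].copy()
    labels = tuple(m.node_labels[i] for i in idx)
    return replace(m, weights=w, node_labels=labels)
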