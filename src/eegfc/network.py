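"""Connectivity-matrix thresholding and graph-theoretic network metrics.

Three thresholding strategies are supported: an absolute cutoff (default
0.7), a proportional threshold keeping the top p% strongest connections,
and no thresholding.  "Strongest" is ranked by absolute value so signed
Corr/AEC matrices are handled coherently; retained weights keep their
sign.  Thresholded matrices can be z-score normalized (retained entries
standardized, zeroed entries untouched) before classification, or
binarized into an undirected graph for the four network summaries: mean
degree, mean local clustering coefficient, global efficiency, and mean
(unnormalized) shortest-path betweenness centrality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np

from .connectivity import ConnectivityMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ThresholdSpec:
    """How a connectivity matrix is thresholded.

    mode 'absolute': zero off-diagonal entries with |value| < ``value``
    (default cutoff 0.7).  mode 'proportional': keep the top ``value``
    percent of upper-triangle entries by |value| (ties straddling the cut
    are all kept).  mode 'none': identity.
    """

    mode: str = "absolute"
    value: float = 0.7
    magnitude_based: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("absolute", "proportional", "none"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if self.mode == "absolute" and not (0 < self.value <= 1):
            raise ValueError("absolute cutoff must lie in (0, 1]")
        if self.mode == "proportional" and not (0 < self.value < 100):
            raise ValueError("proportional percentage must lie in (0, 100)")


@dataclass(frozen=True)
class BrainGraph:
    """Binary undirected graph over channels (no self-loops)."""

    adjacency: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        a = self.adjacency
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a)):
            raise ValueError("no self-loops allowed")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def to_networkx(self) -> nx.Graph:
        g = nx.from_numpy_array(self.adjacency)
        if self.labels:
            g = nx.relabel_nodes(g, dict(enumerate(self.labels)))
        return g


@dataclass(frozen=True)
class GraphMetricSet:
    """The four scalar network summaries."""

    mean_degree: float
    clustering_coefficient: float
    efficiency: float
    betweenness_centrality: float


def apply_threshold(m: ConnectivityMatrix, spec: ThresholdSpec) -> ConnectivityMatrix:
    """Threshold a connectivity matrix, recording provenance.

    Proportional mode keeps ``round(p/100 * n_pairs)`` upper-triangle
    entries ranked by magnitude; any entries tied with the cut value are
    all kept (the retained count may then exceed the quota, which is
    logged).
    """
    if spec.mode == "none":
        return replace(m, threshold_provenance=spec)

    v = m.values.copy()
    n = v.shape[0]
    iu = np.triu_indices(n, k=1)
    mag = np.abs(v[iu]) if spec.magnitude_based else v[iu]

    if spec.mode == "absolute":
        keep = mag >= spec.value
    else:
        quota = int(round(spec.value / 100 * mag.size))
        if quota == 0:
            keep = np.zeros(mag.size, dtype=bool)
        else:
            order = np.argsort(mag, kind="stable")[::-1]
            cut = mag[order[quota - 1]]
            keep = mag >= cut
            if keep.sum() > quota:
                logger.info(
                    "proportional threshold %s%%: ties at %.6g, keeping %d "
                    "entries (quota %d)", spec.value, cut, keep.sum(), quota,
                )
    out = np.zeros_like(v)
    np.fill_diagonal(out, np.diag(v))
    rows, cols = iu[0][keep], iu[1][keep]
    out[rows, cols] = v[rows, cols]
    out[cols, rows] = v[cols, rows]
    return replace(m, values=out, threshold_provenance=spec)


def zscore_normalize(m: ConnectivityMatrix) -> ConnectivityMatrix:
    """Standardize the retained (nonzero) off-diagonal entries to mean 0,
    population SD 1; zeroed entries and the diagonal are untouched."""
    v = m.values.copy()
    n = v.shape[0]
    off = ~np.eye(n, dtype=bool)
    retained = off & (v != 0)
    vals = v[retained]
    if np.unique(vals).size < 2:
        raise ValueError("need >= 2 distinct retained off-diagonal values")
    sd = vals.std()
    v[retained] = (vals - vals.mean()) / sd
    return replace(m, values=v)


def binarize(m: ConnectivityMatrix, labels: tuple[str, ...] = ()) -> BrainGraph:
    """Edge wherever a (thresholded) off-diagonal entry is nonzero."""
    a = (m.values != 0).astype(np.int8)
    np.fill_diagonal(a, 0)
    return BrainGraph(adjacency=a, labels=labels)


def graph_metrics(g: BrainGraph) -> GraphMetricSet:
    """Compute the four network summaries of a binary graph.

    Conventions: clustering is the node-average Watts-Strogatz local
    clustering (degree < 2 contributes 0); efficiency is global
    efficiency (disconnected pairs contribute 0); betweenness is the
    node-average unnormalized shortest-path betweenness.
    """
    if g.n_nodes < 2:
        raise ValueError("need at least two nodes")
    gx = nx.from_numpy_array(g.adjacency)
    degrees = np.array([d for _, d in gx.degree()], dtype=float)
    clustering = float(np.mean(list(nx.clustering(gx).values())))
    efficiency = float(nx.global_efficiency(gx))
    betweenness = float(np.mean(list(
        nx.betweenness_centrality(gx, normalized=False).values()
    )))
    return GraphMetricSet(
        mean_degree=float(degrees.mean()),
        clustering_coefficient=clustering,
        efficiency=efficiency,
        betweenness_centrality=betweenness,
    )
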