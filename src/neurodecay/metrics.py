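"""Network observables of the degenerating network.

All metrics operate on the *functional* subgraph: removed links do not
carry signal.  Affected-but-not-removed links participate with their
decayed strength, so a link of strength ``eps`` contributes weight
``1/eps`` (its resistance) to any path through it.

The weight of a directed path is the sum of its link weights; for each
ordered node pair (i, j) the minimum such weight w_ij defines the
pair's best transmission efficiency 1/w_ij.  Global efficiency is the
mean of 1/w_ij over all ordered pairs, with unreachable pairs
contributing zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph

from .network import DirectedWeightedNetwork, REMOVED


class ParameterError(ValueError):
    pass


# ----------------------------------------------------------------------
def lscc_fraction(network: DirectedWeightedNetwork) -> float:
    """Fraction of nodes in the largest strongly connected component.

    The LSCC is the maximal node set in which every ordered pair is
    joined by a directed path of functional links.  A network with no
    functional edges (or a DAG) has only singleton components, giving
    ``1/n``.
    """
    adj = network.functional_csr(weighted=False)
    if adj.nnz == 0:
        return 1.0 / network.n
    ncomp, labels = csgraph.connected_components(adj, directed=True,
                                                 connection="strong")
    return float(np.bincount(labels, minlength=ncomp).max()) / network.n


def _is_unit_weighted(network: DirectedWeightedNetwork) -> bool:
    mask = network.functional_mask
    return bool(np.all(network.eps[mask] == 1.0))


def path_weights(network: DirectedWeightedNetwork,
                 sources: np.ndarray | None = None) -> np.ndarray:
    """Minimum path weights from every source over functional links.

    Returns a dense ``(len(sources), n)`` matrix of Dijkstra distances
    with link weights ``1/eps``; unreachable pairs are ``inf``.  With
    all strengths equal to 1 this reduces to hop distance and a BFS is
    used instead.
    """
    adj = network.functional_csr(weighted=True)
    unit = _is_unit_weighted(network)
    if sources is None:
        sources = np.arange(network.n)
    return csgraph.dijkstra(adj, directed=True, indices=sources,
                            unweighted=unit)


def _pair_stats(network: DirectedWeightedNetwork,
                sources: np.ndarray | None = None,
                bin_edges: np.ndarray | None = None,
                chunk: int = 512):
    """One pass of chunked shortest paths accumulating pair statistics.

    Returns (n_reachable_pairs, sum of w_ij, sum of 1/w_ij,
    histogram counts of 1/w_ij) over ordered pairs (i, j), i != j,
    restricted to the given source nodes.
    """
    n = network.n
    adj = network.functional_csr(weighted=True)
    unit = _is_unit_weighted(network)
    if sources is None:
        sources = np.arange(n)
    sources = np.asarray(sources)
    n_pairs = 0
    w_sum = 0.0
    inv_sum = 0.0
    counts = (np.zeros(len(bin_edges) - 1, dtype=np.int64)
              if bin_edges is not None else None)
    for lo in range(0, sources.size, chunk):
        idx = sources[lo:lo + chunk]
        dist = csgraph.dijkstra(adj, directed=True, indices=idx,
                                unweighted=unit)
        dist[np.arange(idx.size), idx] = np.inf  # exclude w_ii
        finite = np.isfinite(dist)
        d = dist[finite]
        n_pairs += d.size
        w_sum += float(d.sum())
        inv = 1.0 / d
        inv_sum += float(inv.sum())
        if counts is not None:
            # right-closed bins (lo, hi], first bin closed: histogram on
            # the negated axis reverses the open side
            c, _ = np.histogram(-inv, bins=-bin_edges[::-1])
            counts += c[::-1]
    return n_pairs, w_sum, inv_sum, counts


def global_efficiency(network: DirectedWeightedNetwork,
                      sources: np.ndarray | None = None) -> float:
    """Mean best-path efficiency 1/w_ij over ordered pairs.

    Unreachable pairs contribute zero, so the measure decays to 0 as
    the network disintegrates.  ``sources`` restricts the outer sum to
    a subsample of nodes (an unbiased estimate for large networks).
    """
    if network.n < 2:
        raise ParameterError("global efficiency needs at least 2 nodes")
    n_src = network.n if sources is None else len(sources)
    _, _, inv_sum, _ = _pair_stats(network, sources)
    return inv_sum / (n_src * (network.n - 1))


def average_path_length(network: DirectedWeightedNetwork,
                        sources: np.ndarray | None = None) -> float | None:
    """Mean minimum path weight over *reachable* ordered pairs.

    With identical unit strengths this is the mean hop distance.
    Returns ``None`` when no ordered pair is reachable.
    """
    n_pairs, w_sum, _, _ = _pair_stats(network, sources)
    if n_pairs == 0:
        return None
    return w_sum / n_pairs


DEFAULT_BIN_EDGES = np.round(np.arange(0.0, 1.0001, 0.05), 10)


@dataclass
class EfficiencyHistogram:
    """Counts of ordered node pairs binned by best-path efficiency.

    Bins are right-closed ``(lo, hi]`` (the first also closed below),
    so an efficiency sitting exactly on an edge counts toward the bin
    below it -- e.g. a two-hop unit path, efficiency 0.5, lands in
    ``(0, 0.5]`` for edges ``{0, 0.5, 1}``.  The
    counts sum to the number of reachable ordered pairs (scaled up by
    ``n / len(sources)`` when computed from a source subsample).
    """

    bin_edges: np.ndarray
    counts: np.ndarray

    def total(self) -> int:
        return int(self.counts.sum())


def efficiency_histogram(network: DirectedWeightedNetwork,
                         bin_edges: np.ndarray | None = None,
                         sources: np.ndarray | None = None
                         ) -> EfficiencyHistogram:
    """Histogram of best-path efficiencies 1/w_ij over reachable pairs."""
    if bin_edges is None:
        bin_edges = DEFAULT_BIN_EDGES
    bin_edges = np.asarray(bin_edges, dtype=np.float64)
    if bin_edges.ndim != 1 or bin_edges.size < 2 or \
            np.any(np.diff(bin_edges) <= 0):
        raise ParameterError("bin_edges must be strictly increasing")
    _, _, _, counts = _pair_stats(network, sources, bin_edges=bin_edges)
    return EfficiencyHistogram(bin_edges=bin_edges, counts=counts)


# ----------------------------------------------------------------------
def clustering_coefficient(network: DirectedWeightedNetwork) -> float:
    """Average local clustering of the undirected projection.

    Each node's local coefficient is the fraction of its neighbour
    pairs (in the undirected projection of functional links) that are
    themselves connected; nodes of degree < 2 contribute 0.  Computed
    by sparse triangle counting: tri(v) = diag(A^3)/2 for the binary
    symmetric adjacency A.
    """
    n = network.n
    adj = network.functional_csr(weighted=False)
    und = adj + adj.T
    und.data = np.ones_like(und.data)
    deg = np.asarray(und.sum(axis=1)).ravel()
    # diag(A^3) without forming A^3: row-sums of (A @ A) restricted to A
    a2 = (und @ und).multiply(und)
    tri = np.asarray(a2.sum(axis=1)).ravel() / 2.0
    denom = deg * (deg - 1) / 2.0
    local = np.divide(tri, denom, out=np.zeros(n), where=denom > 0)
    return float(local.mean())


def total_strength(network: DirectedWeightedNetwork) -> float:
    """Sum of current coupling strengths over functional links.

    The model quantity directly comparable with mean spine density.
    """
    mask = network.functional_mask
    return float(network.eps[mask].sum())
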