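"""Directed weighted network container used throughout the package.

Edges carry an initial coupling strength ``eps0`` (synaptic efficacy at
time zero), a current strength ``eps`` that decays once the edge is
affected by synapse loss, and a degeneration state.  Edges are stored in
flat numpy arrays so that per-day simulation steps and sparse-graph
metric evaluations are vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

# Edge states.  Transitions are one-way: HEALTHY -> AFFECTED -> REMOVED.
HEALTHY = 0
AFFECTED = 1
REMOVED = 2

#: removal threshold: a link whose strength has fallen to 1/e of its
#: initial value is considered non-functional.
INV_E = float(np.exp(-1.0))


class InvalidNetworkError(ValueError):
    """The network violates a structural invariant."""


@dataclass
class DirectedWeightedNetwork:
    """A directed graph on ``n`` nodes with decaying edge strengths.

    Parameters
    ----------
    n
        Number of nodes (labelled ``0 .. n-1``).
    src, dst
        Integer arrays of equal length giving each edge's tail and head.
        Self-loops and duplicate ordered pairs are rejected.
    eps0
        Initial coupling strength of each edge, in ``(0, 1]``.
    eps
        Current coupling strength, ``0 < eps <= eps0``.  Defaults to
        ``eps0`` (all edges healthy).
    state
        Per-edge state code (HEALTHY / AFFECTED / REMOVED).
    affected_at
        Day at which the edge became affected; ``-1`` for healthy edges.
    """

    n: int
    src: np.ndarray
    dst: np.ndarray
    eps0: np.ndarray
    eps: np.ndarray = None  # type: ignore[assignment]
    state: np.ndarray = None  # type: ignore[assignment]
    affected_at: np.ndarray = None  # type: ignore[assignment]
    node_ids: list = field(default_factory=list)  # original labels, optional

    def __post_init__(self) -> None:
        self.src = np.asarray(self.src, dtype=np.int64)
        self.dst = np.asarray(self.dst, dtype=np.int64)
        self.eps0 = np.asarray(self.eps0, dtype=np.float64)
        m = self.src.size
        if self.eps is None:
            self.eps = self.eps0.copy()
        else:
            self.eps = np.asarray(self.eps, dtype=np.float64)
        if self.state is None:
            self.state = np.zeros(m, dtype=np.int8)
        else:
            self.state = np.asarray(self.state, dtype=np.int8)
        if self.affected_at is None:
            self.affected_at = np.full(m, -1, dtype=np.int64)
        else:
            self.affected_at = np.asarray(self.affected_at, dtype=np.int64)
        self.validate_structure()

    # ------------------------------------------------------------------
    @property
    def m(self) -> int:
        """Total number of edges (any state)."""
        return int(self.src.size)

    @property
    def functional_mask(self) -> np.ndarray:
        """Boolean mask of non-removed edges."""
        return self.state != REMOVED

    def counts(self) -> tuple[int, int, int]:
        """(n_healthy, n_affected, n_removed)."""
        return (
            int(np.count_nonzero(self.state == HEALTHY)),
            int(np.count_nonzero(self.state == AFFECTED)),
            int(np.count_nonzero(self.state == REMOVED)),
        )

    # ------------------------------------------------------------------
    def validate_structure(self) -> None:
        if self.n < 1:
            raise InvalidNetworkError("node count must be positive")
        if not (self.src.size == self.dst.size == self.eps0.size):
            raise InvalidNetworkError("edge arrays have mismatched lengths")
        if self.m:
            if self.src.min() < 0 or self.dst.min() < 0 or \
                    max(self.src.max(), self.dst.max()) >= self.n:
                raise InvalidNetworkError("edge endpoint outside 0..n-1")
            if np.any(self.src == self.dst):
                raise InvalidNetworkError("self-loops are not allowed")
            keys = self.src * self.n + self.dst
            if np.unique(keys).size != keys.size:
                raise InvalidNetworkError("duplicate directed edges")
            if np.any(self.eps0 <= 0) or np.any(self.eps0 > 1):
                raise InvalidNetworkError("initial strengths must lie in (0, 1]")

    def validate_state(self) -> None:
        """Check the decay-state invariants (strength vs. state coherence)."""
        self.validate_structure()
        if np.any(self.eps > self.eps0 + 1e-15):
            raise InvalidNetworkError("current strength exceeds initial strength")
        healthy = self.state == HEALTHY
        if not np.allclose(self.eps[healthy], self.eps0[healthy]):
            raise InvalidNetworkError("healthy edge with decayed strength")
        removed = self.state == REMOVED
        thr = self.eps0 * INV_E
        if np.any(self.eps[removed] > thr[removed]):
            raise InvalidNetworkError("removed edge above the 1/e threshold")
        live = self.state == AFFECTED
        if np.any(self.eps[live] <= thr[live]):
            raise InvalidNetworkError("affected edge at/below 1/e but not removed")

    # ------------------------------------------------------------------
    def functional_csr(self, weighted: bool = True) -> sparse.csr_matrix:
        """CSR adjacency of functional (non-removed) edges.

        Entries are link weights ``1 / eps`` (resistance) when
        ``weighted``, else 1.  This is the graph on which paths,
        components and efficiencies are evaluated.
        """
        mask = self.functional_mask
        s, d = self.src[mask], self.dst[mask]
        if weighted:
            e = self.eps[mask]
            if np.any(e <= 0):
                raise InvalidNetworkError("functional edge with non-positive strength")
            data = 1.0 / e
        else:
            data = np.ones(s.size, dtype=np.float64)
        return sparse.csr_matrix((data, (s, d)), shape=(self.n, self.n))

    def copy(self) -> "DirectedWeightedNetwork":
        return DirectedWeightedNetwork(
            n=self.n,
            src=self.src.copy(),
            dst=self.dst.copy(),
            eps0=self.eps0.copy(),
            eps=self.eps.copy(),
            state=self.state.copy(),
            affected_at=self.affected_at.copy(),
            node_ids=list(self.node_ids),
        )
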