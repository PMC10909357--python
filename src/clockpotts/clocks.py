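"""Per-cell oscillator phases and their Kuramoto-type neighbor coupling.

Every cell carries a phase theta_s in [0, 2*pi).  Once per Monte Carlo
step, after the lattice sweep, all phases advance synchronously:

    theta_s <- theta_s + omega * (1 + K * mean over contact neighbors u
                                          of sin(theta_u - theta_s))

Cells are neighbors when any site of one is an order-2 lattice neighbor
of a site of the other.  K > 0 pulls neighboring clocks together,
K < 0 pushes them toward opposite phase.  A cell with no contact
neighbors free-runs at omega (the only continuous extension of the
mean-coupling term).  All dynamics depend only on phase *differences*,
so trajectories of differences are invariant under the shift
theta_s -> theta_s - omega * t; the clock speed omega enters only through
the product omega * K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .core import TWO_PI, LatticeState, half_offsets

__all__ = ["ContactGraph", "build_contact_graph", "update_clocks",
           "relative_phase", "principal_value"]


def principal_value(d):
    """Map phase differences to the principal interval (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(d, dtype=np.float64), TWO_PI)


@njit(cache=True)
def _pair_count_kernel(spins, half_off, n_cells):
    """Heterotypic boundary site-pair counts between every spin pair.

    ``counts[a, b]`` is the number of unordered neighboring site pairs with
    spins (a, b); stored symmetrically, row/column 0 holding medium contacts.
    """
    counts = np.zeros((n_cells + 1, n_cells + 1), np.int64)
    L1, L2 = spins.shape
    for i1 in range(L1):
        for i2 in range(L2):
            a = spins[i1, i2]
            for m in range(half_off.shape[0]):
                b = spins[(i1 + half_off[m, 0]) % L1, (i2 + half_off[m, 1]) % L2]
                if a != b:
                    counts[a, b] += 1
                    counts[b, a] += 1
    return counts


@dataclass
class ContactGraph:
    """Cell-cell adjacency induced by the lattice configuration.

    ``pair_counts[s, u]`` is the heterotypic boundary site-pair count
    between spins ``s`` and ``u`` (symmetric; row/column 0 = medium
    contacts, excluded from adjacency).
    """

    pair_counts: np.ndarray  # int64, (N+1, N+1)
    _adj_f: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n_cells(self) -> int:
        return self.pair_counts.shape[0] - 1

    @property
    def adjacency(self) -> np.ndarray:
        """Boolean (N+1, N+1) cell-cell adjacency; medium row/col all False."""
        adj = self.pair_counts > 0
        adj[0, :] = False
        adj[:, 0] = False
        return adj

    @property
    def adjacency_f(self) -> np.ndarray:
        """Float adjacency matrix, cached for the phasor matmul."""
        if self._adj_f is None:
            self._adj_f = self.adjacency.astype(np.float64)
        return self._adj_f

    @property
    def degree(self) -> np.ndarray:
        """Neighbor count per cell id (slot 0 = 0)."""
        return self.adjacency.sum(axis=1)

    def neighbors(self, s: int) -> np.ndarray:
        """Cell ids adjacent to cell ``s``."""
        return np.nonzero(self.adjacency[s])[0]


def build_contact_graph(state: LatticeState, neighbor_order: int = 2,
                        n_cells: int | None = None) -> ContactGraph:
    """Exact cell adjacency from an exhaustive scan of all neighboring site pairs."""
    if n_cells is None:
        n_cells = int(state.spins.max())
    counts = _pair_count_kernel(state.spins, half_offsets(neighbor_order), n_cells)
    return ContactGraph(counts)


@njit(cache=True)
def _coupling_kernel(counts, thetas):
    """Per-cell mean of sin(theta_u - theta_s) over contact neighbors u.

    Zero for cells without neighbors (the free-running case).
    """
    n = counts.shape[0] - 1
    out = np.zeros(n + 1)
    for s in range(1, n + 1):
        acc = 0.0
        deg = 0
        for u in range(1, n + 1):
            if u != s and counts[s, u] > 0:
                acc += np.sin(thetas[u] - thetas[s])
                deg += 1
        if deg > 0:
            out[s] = acc / deg
    return out


def update_clocks(thetas: np.ndarray, graph: ContactGraph, K: float,
                  omega: float) -> np.ndarray:
    """One synchronous clock update; returns the new phase vector mod 2*pi.

    ``thetas`` is indexed by cell id (length N + 1, slot 0 unused and
    passed through unchanged).  All new phases are computed from the
    pre-update vector.
    """
    thetas = np.asarray(thetas, dtype=np.float64)
    if thetas.size != graph.n_cells + 1:
        raise ValueError(
            f"phase vector length {thetas.size} does not match graph with "
            f"{graph.n_cells} cells"
        )
    coupling = _coupling_kernel(graph.pair_counts, thetas)
    new = np.mod(thetas + omega * (1.0 + K * coupling), TWO_PI)
    new[0] = thetas[0]
    return new


def relative_phase(thetas: np.ndarray, mcs: int, omega: float) -> np.ndarray:
    """Phase shift relative to a reference clock advancing steadily at omega.

    Used for coloring and snapshots only; the dynamics never consume it.
    Order parameters are unchanged by this global shift.
    """
    return np.mod(np.asarray(thetas, dtype=np.float64) - omega * mcs, TWO_PI)
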