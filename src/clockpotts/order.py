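"""Order parameters and phase-state classification.

Three scalars summarize a configuration:

* ``r_global`` — the Kuramoto order parameter, the modulus of the mean
  unit phasor over all cells.  1 means every clock agrees; 0 means the
  phasors cancel (uniform spread, or balanced opposite-phase groups).
* ``r_local`` — a neighborhood version: for each cell, the modulus of the
  mean phasor of its *contact neighbors*, averaged over cells.  Stays
  near 1 for locally synchronized patches even when patches disagree
  globally.  For fully random phases it does not vanish — with s_k
  neighbors the expected modulus is about sqrt(pi) / (2 * sqrt(s_k)),
  roughly 0.2 at typical contact numbers.
* ``psi`` — the checkerboard parameter: the number of neighboring site
  pairs belonging to two distinct cells whose phase difference is within
  pi/8 of pi (a 6.25% tolerance band around perfect anti-phase).

The long-run behavior falls into four phase states over the (J, K)
plane: global synchronization (r_global near 1), anti-synchronization /
checkerboard (large psi), local synchronization (r_local near 1 with
r_global near 0), and incoherence (everything small).  Classification
uses configurable thresholds; psi is an extensive count, so its
threshold scales with lattice area relative to the 126 x 126 reference.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np

from .clocks import ContactGraph, _pair_count_kernel
from .core import TWO_PI, LatticeState, half_offsets

logger = logging.getLogger("clockpotts")

__all__ = ["OrderParamRecord", "PhaseLabel", "ClassifyThresholds",
           "r_global", "r_local", "checkerboard_psi", "classify_phase",
           "phase_histogram", "PSI_BAND"]

#: half-width of the anti-phase acceptance band around pi (inclusive endpoints)
PSI_BAND = np.pi / 8.0


class UndefinedInputError(ValueError):
    """Raised when an order parameter is requested for an empty population."""


class PhaseLabel(str, enum.Enum):
    GLOBAL_SYNC = "global_sync"
    LOCAL_SYNC = "local_sync"
    INCOHERENT = "incoherent"
    ANTI_SYNC = "anti_sync"
    AMBIGUOUS = "ambiguous"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class OrderParamRecord:
    """One time-series row of order parameters."""

    mcs: int
    r_global: float
    r_local: float
    psi: int
    n_isolated_cells: int = 0
    n_fragments: int = 0


def r_global(thetas: np.ndarray) -> float:
    """Modulus of the population-mean unit phasor, in [0, 1]."""
    thetas = np.asarray(thetas, dtype=np.float64)
    if thetas.size == 0:
        raise UndefinedInputError("r_global of an empty phase vector is undefined")
    return float(np.abs(np.mean(np.exp(1j * thetas))))


def r_local(thetas: np.ndarray, graph: ContactGraph, include_self: bool = False,
            return_isolated: bool = False):
    """Mean over cells of the modulus of the mean *neighbor* phasor.

    ``thetas`` is indexed by cell id (length ``graph.n_cells + 1``, slot 0
    unused).  By default the cell itself is excluded from its own
    neighbor average (``include_self=True`` materially raises the
    incoherence baseline and is provided for comparison).  Cells with no
    contact neighbors are omitted from the average; their count is
    logged, and returned as well when ``return_isolated`` is set.
    """
    thetas = np.asarray(thetas, dtype=np.float64)
    if thetas.size != graph.n_cells + 1:
        raise ValueError("phase vector length does not match contact graph")
    z = np.exp(1j * thetas)
    z[0] = 0.0
    adj = graph.adjacency_f
    sums = adj @ z
    deg = adj.sum(axis=1)
    alive = np.zeros(thetas.size, dtype=bool)
    alive[1:] = True
    has_nb = alive & (deg > 0)
    n_isolated = int(np.count_nonzero(alive) - np.count_nonzero(has_nb))
    if not np.any(has_nb):
        raise UndefinedInputError("every cell is isolated; r_local is undefined")
    if include_self:
        moduli = np.abs((sums[has_nb] + z[has_nb]) / (deg[has_nb] + 1.0))
    else:
        moduli = np.abs(sums[has_nb] / deg[has_nb])
    value = float(np.mean(moduli))
    if n_isolated:
        logger.debug("r_local: %d isolated cells omitted from the average", n_isolated)
    if return_isolated:
        return value, n_isolated
    return value


def _qualifying_pair_matrix(thetas: np.ndarray) -> np.ndarray:
    """Boolean (N+1, N+1): cell pairs whose phase difference is pi +/- pi/8."""
    th = np.asarray(thetas, dtype=np.float64)
    d = np.mod(th[:, None] - th[None, :], TWO_PI)
    ok = (d >= np.pi - PSI_BAND) & (d <= np.pi + PSI_BAND)
    ok[0, :] = False
    ok[:, 0] = False
    return ok


def checkerboard_psi(state: LatticeState, thetas: np.ndarray,
                     neighbor_order: int = 2,
                     graph: ContactGraph | None = None) -> int:
    """Count near-anti-phase heterotypic neighboring site pairs.

    Unordered neighboring site pairs (order-2 by default) whose spins are
    two distinct cells and whose clock phase difference lies in
    [pi - pi/8, pi + pi/8] (mod 2*pi, endpoints included).  Pairs
    involving the medium, or two sites of the same cell, never count.
    A precomputed contact graph for the same state may be passed to
    avoid rescanning the lattice.
    """
    thetas = np.asarray(thetas, dtype=np.float64)
    if graph is None:
        n_cells = max(int(state.spins.max()), thetas.size - 1)
        counts = _pair_count_kernel(state.spins, half_offsets(neighbor_order), n_cells)
    else:
        counts = graph.pair_counts
    ok = _qualifying_pair_matrix(thetas)
    # counts is stored symmetrically; sum the upper triangle for unordered pairs
    iu = np.triu_indices(counts.shape[0], k=1)
    return int(np.sum(counts[iu][ok[iu]]))


@dataclass
class ClassifyThresholds:
    """Decision thresholds separating the four phase states.

    Defaults put clean margins between the reported plateau levels
    (r_global ~ 1 for global sync, r_local ~ 1 vs ~ 0.2 for local sync
    vs incoherence, psi > 1000 for checkerboards on the reference
    126 x 126 lattice).  ``psi_threshold`` refers to the reference area
    and is rescaled to the actual lattice because psi is extensive.
    """

    r_global_sync: float = 0.9
    r_local_sync: float = 0.8
    r_local_incoherent: float = 0.35
    psi_threshold: float = 1000.0
    reference_area: int = 126 * 126

    def psi_for(self, dims: tuple[int, int]) -> float:
        return self.psi_threshold * (dims[0] * dims[1]) / self.reference_area


def classify_phase(record: OrderParamRecord,
                   thresholds: ClassifyThresholds | None = None,
                   dims: tuple[int, int] = (126, 126)) -> PhaseLabel:
    """Label a (plateaued) order-parameter record with its phase state.

    Decision order: global sync by r_global, then checkerboard by psi,
    then local sync / incoherence by r_local; borderline records come
    back ``ambiguous`` rather than being forced into a bin (the local
    sync <-> incoherence transition is gradual).
    """
    t = thresholds or ClassifyThresholds()
    if record.r_global >= t.r_global_sync:
        return PhaseLabel.GLOBAL_SYNC
    if record.psi > t.psi_for(dims):
        return PhaseLabel.ANTI_SYNC
    if record.r_local >= t.r_local_sync:
        return PhaseLabel.LOCAL_SYNC
    if record.r_local <= t.r_local_incoherent:
        return PhaseLabel.INCOHERENT
    return PhaseLabel.AMBIGUOUS


def phase_histogram(thetas: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Counts of phases in ``n_bins`` equal-width bins partitioning [0, 2*pi)."""
    if n_bins < 1:
        raise ValueError("need at least one bin")
    thetas = np.mod(np.asarray(thetas, dtype=np.float64), TWO_PI)
    counts, _ = np.histogram(thetas, bins=n_bins, range=(0.0, TWO_PI))
    return counts
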