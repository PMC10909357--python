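"""Lattice engine for the clock-coupled Cellular Potts Model.

Each biological cell is a set of lattice sites sharing an integer index
("spin"); index 0 is extracellular medium.  The configuration energy is

    H = sum over neighboring site pairs (i, j), sigma(i) != sigma(j) of
            f(sigma(i), sigma(j))
      + lam * sum over cells s of (Area(s) - A_target)^2

where the contact energy between two distinct cells depends on the phase
difference of their internal clocks,

    f(s, u) = J0 * (1 - J * cos(theta_s - theta_u))    (both cells)
    f(s, 0) = J0                                        (cell-medium)
    f(0, 0) = 0                                         (medium-medium)

``J > 0`` means cells in the same clock phase adhere most strongly ("like
attracts like"); ``J < 0`` means opposite phases adhere most strongly
("opposites attract").  Time advances by Metropolis spin flips: a random
site copies the spin of a random neighbor with probability 1 if the energy
change ``dH <= 0`` and ``exp(-dH / T)`` otherwise.  One Monte Carlo step
(MCS) is as many flip attempts as there are lattice sites.

The sum over neighboring pairs runs over *unordered* pairs, each counted
once, with order-2 (Moore, 8-site) adjacency by default.  Sequential
in-place updating is used within an MCS.  A flip that would reduce a cell
to zero area is rejected, so the cell count is conserved.

The Metropolis sweep is JIT-compiled with numba.  Because numpy Generators
cannot be used inside nopython kernels and their state cannot be frozen
into resumable snapshots, proposals and acceptance draws come from an
explicit-state xorshift128+ generator (:class:`XorShift128Plus`); a
bit-exact pure-Python mirror backs the testable single-flip operations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

logger = logging.getLogger("clockpotts")

TWO_PI = 2.0 * np.pi

__all__ = [
    "ModelParams",
    "LatticeState",
    "CellTable",
    "XorShift128Plus",
    "ConsistencyError",
    "UnsupportedOrderError",
    "neighborhood",
    "half_offsets",
    "full_offsets",
    "contact_energy",
    "hamiltonian",
    "delta_H",
    "accept_flip",
    "propose_flip",
    "monte_carlo_step",
    "count_cell_fragments",
]


class ConsistencyError(RuntimeError):
    """Raised when cached per-cell areas disagree with a lattice recount."""


class UnsupportedOrderError(ValueError):
    """Raised for a neighbor order outside {1, 2}."""


# --------------------------------------------------------------------------
# Parameters and state containers
# --------------------------------------------------------------------------

@dataclass
class ModelParams:
    """All model parameters.

    Defaults are the reference parameter set: a 126 x 126 periodic lattice
    holding N = 445 cells of target area 25 (70% confluency), temperature
    T = 20, cell-medium contact energy J0 = 16, area stiffness lam = 25,
    clock speed omega = 0.001 rad/MCS, order-2 (Moore) adjacency.

    ``J`` (phase-dependent adhesion) and ``K`` (Kuramoto clock coupling)
    are the two swept control parameters; both are meaningful on (-1, 1).
    Values outside that range cause cell fragmentation (|J| > 1 makes some
    cell-cell contact energies non-positive) or clocks that stall or run
    backwards (|K| >= 1), so they elicit a warning but are not rejected.
    """

    J: float = 0.0
    K: float = 0.0
    J0: float = 16.0
    T: float = 20.0
    lam: float = 25.0
    A_target: int = 25
    omega: float = 0.001
    neighbor_order: int = 2
    dims: tuple[int, int] = (126, 126)
    N: int = 445
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError(f"temperature must be positive, got T={self.T}")
        if self.lam < 0:
            raise ValueError(f"area stiffness must be >= 0, got lam={self.lam}")
        if self.A_target < 1:
            raise ValueError(f"target area must be >= 1, got {self.A_target}")
        if self.neighbor_order not in (1, 2):
            raise UnsupportedOrderError(
                f"neighbor order must be 1 or 2, got {self.neighbor_order}"
            )
        if abs(self.J) >= 1:
            warnings.warn(
                f"|J| >= 1 (J={self.J}) gives non-positive cell-cell contact "
                "energies and causes cell fragmentation",
                stacklevel=2,
            )
        if abs(self.K) >= 1:
            warnings.warn(
                f"|K| >= 1 (K={self.K}) lets individual clocks stop or run "
                "backwards",
                stacklevel=2,
            )
        self.dims = (int(self.dims[0]), int(self.dims[1]))

    @property
    def n_sites(self) -> int:
        return self.dims[0] * self.dims[1]

    @property
    def confluency(self) -> float:
        """Fraction of the lattice covered by cells at target area."""
        return self.N * self.A_target / self.n_sites

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass
class LatticeState:
    """The spin grid: ``spins[i1, i2]`` is the cell index at a site (0 = medium).

    Boundaries are periodic in both directions.
    """

    spins: np.ndarray

    def __post_init__(self) -> None:
        self.spins = np.ascontiguousarray(self.spins, dtype=np.int32)
        if self.spins.ndim != 2:
            raise ValueError("spin grid must be 2-D")

    @classmethod
    def empty(cls, dims: tuple[int, int]) -> "LatticeState":
        return cls(np.zeros(dims, dtype=np.int32))

    @property
    def dims(self) -> tuple[int, int]:
        return self.spins.shape

    @property
    def n_sites(self) -> int:
        return self.spins.size

    def copy(self) -> "LatticeState":
        return LatticeState(self.spins.copy())


@dataclass
class CellTable:
    """Per-cell bookkeeping, indexed by cell id 1..N (slot 0 is the medium).

    ``area[0]`` caches the medium site count so that
    ``area.sum() == L1 * L2`` always; ``theta[0]`` is unused.
    """

    area: np.ndarray   # int64, shape (N + 1,)
    theta: np.ndarray  # float64, shape (N + 1,), radians in [0, 2*pi)

    def __post_init__(self) -> None:
        self.area = np.ascontiguousarray(self.area, dtype=np.int64)
        self.theta = np.ascontiguousarray(self.theta, dtype=np.float64)
        if self.area.shape != self.theta.shape:
            raise ValueError("area and theta must have equal length")

    @classmethod
    def from_state(cls, state: LatticeState, theta: np.ndarray, n_cells: int | None = None) -> "CellTable":
        """Build a table by recounting areas from the lattice."""
        theta = np.asarray(theta, dtype=np.float64)
        if n_cells is None:
            n_cells = max(int(state.spins.max()), theta.size - 1)
        area = np.bincount(state.spins.ravel(), minlength=n_cells + 1).astype(np.int64)
        full_theta = np.zeros(n_cells + 1)
        if theta.size == n_cells + 1:
            full_theta[:] = theta
        elif theta.size == n_cells:
            full_theta[1:] = theta
        else:
            raise ValueError(f"expected {n_cells} or {n_cells + 1} phases, got {theta.size}")
        return cls(area, np.mod(full_theta, TWO_PI))

    @property
    def n_cells(self) -> int:
        return self.area.size - 1

    @property
    def alive(self) -> np.ndarray:
        """Boolean mask over cell ids 1..N (True where the cell has sites)."""
        return self.area[1:] > 0

    def copy(self) -> "CellTable":
        return CellTable(self.area.copy(), self.theta.copy())

    def check_against(self, state: LatticeState) -> None:
        recount = np.bincount(state.spins.ravel(), minlength=self.area.size)
        if recount.size != self.area.size or not np.array_equal(recount, self.area):
            raise ConsistencyError("cached cell areas disagree with lattice recount")


# --------------------------------------------------------------------------
# Explicit-state RNG (shared between the numba kernel and pure Python)
# --------------------------------------------------------------------------

_MASK64 = (1 << 64) - 1
_INV_2_53 = 1.0 / 9007199254740992.0  # 2**-53


class XorShift128Plus:
    """xorshift128+ pseudo-random generator with a serializable uint64[2] state.

    The same state array is consumed, in the same draw order, by the
    JIT-compiled Metropolis sweep and by the pure-Python mirror methods
    here, so single-flip operations and full sweeps share one stream.
    """

    def __init__(self, seed: int | None = None, state: np.ndarray | None = None):
        if state is not None:
            state = np.asarray(state, dtype=np.uint64).copy()
            if state.shape != (2,):
                raise ValueError("RNG state must be two uint64 words")
            if int(state[0]) == 0 and int(state[1]) == 0:
                raise ValueError("all-zero xorshift state is invalid")
            self._state = state
        else:
            words = np.random.SeedSequence(seed).generate_state(2, np.uint64)
            if int(words[0]) == 0 and int(words[1]) == 0:  # pragma: no cover
                words[0] = np.uint64(0x9E3779B97F4A7C15)
            self._state = words.copy()

    @property
    def state(self) -> np.ndarray:
        """The live state array (mutated in place by every draw)."""
        return self._state

    def next_u64(self) -> int:
        s = self._state
        s1 = int(s[0])
        s0 = int(s[1])
        s[0] = np.uint64(s0)
        s1 ^= (s1 << 23) & _MASK64
        s1 ^= s1 >> 17
        s1 ^= s0 ^ (s0 >> 26)
        s[1] = np.uint64(s1)
        return (s0 + s1) & _MASK64

    def random(self) -> float:
        """Uniform double in [0, 1) with 53 random bits."""
        return (self.next_u64() >> 11) * _INV_2_53

    def randint(self, n: int) -> int:
        """Uniform integer in {0, ..., n-1} (same mapping as the kernel)."""
        return int(self.random() * n)

    def copy(self) -> "XorShift128Plus":
        return XorShift128Plus(state=self._state)


@njit(cache=True)
def _rng_u64(state):
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 ^= s1 << np.uint64(23)
    s1 ^= s1 >> np.uint64(17)
    s1 ^= s0
    s1 ^= s0 >> np.uint64(26)
    state[1] = s1
    return s0 + s1


@njit(cache=True)
def _rng_double(state):
    return (_rng_u64(state) >> np.uint64(11)) * _INV_2_53


# --------------------------------------------------------------------------
# Neighborhoods
# --------------------------------------------------------------------------

# Order-1 (von Neumann) offsets first, then the diagonals that order 2 adds.
_OFFSETS_8 = np.array(
    [(-1, 0), (1, 0), (0, -1), (0, 1), (-1, -1), (-1, 1), (1, -1), (1, 1)],
    dtype=np.int64,
)
# Half-neighborhoods for unordered pair sums (each pair visited once).
_HALF_8 = np.array([(0, 1), (1, 0), (1, 1), (1, -1)], dtype=np.int64)


def full_offsets(order: int) -> np.ndarray:
    """All neighbor offsets for the given order (4 for order 1, 8 for order 2)."""
    if order == 1:
        return _OFFSETS_8[:4]
    if order == 2:
        return _OFFSETS_8
    raise UnsupportedOrderError(f"neighbor order must be 1 or 2, got {order}")


def half_offsets(order: int) -> np.ndarray:
    """Offsets covering each unordered neighbor pair exactly once."""
    if order == 1:
        return _HALF_8[:2]
    if order == 2:
        return _HALF_8
    raise UnsupportedOrderError(f"neighbor order must be 1 or 2, got {order}")


def neighborhood(site: tuple[int, int], order: int, dims: tuple[int, int]) -> list[tuple[int, int]]:
    """Periodic-wrapped neighbor coordinates of ``site``.

    Order 1 is the 4 edge-adjacent sites; order 2 adds the 4 diagonal
    sites (the 8-site Moore neighborhood).  The site itself is excluded
    and duplicates (possible only on degenerate tiny lattices) removed.
    """
    L1, L2 = dims
    i1, i2 = site
    if not (0 <= i1 < L1 and 0 <= i2 < L2):
        raise ValueError(f"site {site} outside lattice {dims}")
    out: list[tuple[int, int]] = []
    for d1, d2 in full_offsets(order):
        c = ((i1 + int(d1)) % L1, (i2 + int(d2)) % L2)
        if c != (i1, i2) and c not in out:
            out.append(c)
    return out


# --------------------------------------------------------------------------
# Energies
# --------------------------------------------------------------------------

def contact_energy(sigma1: int, sigma2: int, theta1: float, theta2: float,
                   params: ModelParams) -> float:
    """Contact energy of one heterotypic neighboring site pair.

    Same-spin pairs contribute nothing to the Hamiltonian and are never
    passed here; medium-medium contact energy is 0.
    """
    if sigma1 == 0 and sigma2 == 0:
        return 0.0
    if sigma1 == 0 or sigma2 == 0:
        return params.J0
    return params.J0 * (1.0 - params.J * np.cos(theta1 - theta2))


def hamiltonian(state: LatticeState, cells: CellTable, params: ModelParams) -> float:
    """Total configuration energy (vectorized over half-neighborhood shifts)."""
    cells.check_against(state)
    s = state.spins
    th = cells.theta
    total = 0.0
    for d1, d2 in half_offsets(params.neighbor_order):
        t = np.roll(np.roll(s, -int(d1), axis=0), -int(d2), axis=1)
        het = s != t
        a = s[het]
        b = t[het]
        both = (a > 0) & (b > 0)
        # each heterotypic pair is either cell-cell or cell-medium (J0)
        total += params.J0 * (
            np.sum(1.0 - params.J * np.cos(th[a[both]] - th[b[both]]))
            + np.count_nonzero(~both)
        )
    dev = cells.area[1:][cells.alive] - params.A_target
    total += params.lam * float(np.sum(dev.astype(np.float64) ** 2))
    return float(total)


def delta_H(state: LatticeState, cells: CellTable, site: tuple[int, int],
            new_spin: int, params: ModelParams) -> float:
    """Energy change of flipping ``site`` to ``new_spin``, computed locally.

    Only the neighbor pairs touching the site and the two affected area
    terms are evaluated; agrees with a full recompute to ~1e-9.
    """
    i1, i2 = site
    a = int(state.spins[i1, i2])
    b = int(new_spin)
    if a == b:
        raise ValueError("proposed spin equals current spin (no-op flip)")
    th = cells.theta
    dH = 0.0
    for j1, j2 in neighborhood(site, params.neighbor_order, state.dims):
        c = int(state.spins[j1, j2])
        if c != a:
            dH -= contact_energy(a, c, th[a], th[c], params)
        if c != b:
            dH += contact_energy(b, c, th[b], th[c], params)
    if a != 0:
        da = int(cells.area[a]) - params.A_target
        dH += params.lam * ((da - 1) ** 2 - da ** 2)
    if b != 0:
        db = int(cells.area[b]) - params.A_target
        dH += params.lam * ((db + 1) ** 2 - db ** 2)
    return dH


# --------------------------------------------------------------------------
# Metropolis kinetics
# --------------------------------------------------------------------------

def accept_flip(dH: float, T: float, u: float) -> bool:
    """Metropolis rule: accept if dH <= 0, else iff u < exp(-dH / T)."""
    if dH <= 0.0:
        return True
    return u < np.exp(-dH / T)


def propose_flip(state: LatticeState, rng: XorShift128Plus,
                 neighbor_order: int = 2):
    """Draw one flip proposal: a uniform site copies a uniform neighbor's spin.

    Returns ``((i1, i2), new_spin)`` or ``None`` when the chosen neighbor
    already has the same spin (the draw still counts as an attempt).
    Consumes exactly three uniform draws, matching the JIT sweep.
    """
    L1, L2 = state.dims
    off = full_offsets(neighbor_order)
    i1 = rng.randint(L1)
    i2 = rng.randint(L2)
    k = rng.randint(len(off))
    j1 = (i1 + int(off[k, 0])) % L1
    j2 = (i2 + int(off[k, 1])) % L2
    a = int(state.spins[i1, i2])
    b = int(state.spins[j1, j2])
    if a == b:
        return None
    return (i1, i2), b


@njit(cache=True)
def _build_site_neighbors(L1, L2, off):
    """Flat neighbor-site index table: ``out[site, m]`` for each offset."""
    n = off.shape[0]
    out = np.empty((L1 * L2, n), np.int32)
    for i1 in range(L1):
        for i2 in range(L2):
            s = i1 * L2 + i2
            for m in range(n):
                out[s, m] = ((i1 + off[m, 0]) % L1) * L2 + (i2 + off[m, 1]) % L2
    return out


@njit(cache=True)
def _mcs_kernel(spins_flat, nb_idx, area, cos_t, sin_t, counts, J0, J, lam,
                A_t, T, n_attempts, rng_state, L1, L2):
    """One Metropolis sweep of ``n_attempts`` flip attempts (in place).

    ``cos_t``/``sin_t`` cache cos(theta)/sin(theta) per cell id, valid for
    the whole sweep because clocks only advance between sweeps.  ``area``
    includes the medium count at index 0.  ``counts`` is the symmetric
    heterotypic boundary-pair matrix, maintained incrementally on every
    accepted flip (exactly matching a from-scratch lattice scan).
    ``nb_idx`` is the precomputed periodic neighbor table over the
    flattened lattice.  Draw order per attempt: site row, site column,
    neighbor choice, then (only if dH > 0) the acceptance uniform.
    """
    n_off = nb_idx.shape[1]
    cvals = np.empty(n_off, np.int32)
    accepted = 0
    for _ in range(n_attempts):
        i1 = int(_rng_double(rng_state) * L1)
        i2 = int(_rng_double(rng_state) * L2)
        k = int(_rng_double(rng_state) * n_off)
        site = i1 * L2 + i2
        a = spins_flat[site]
        b = spins_flat[nb_idx[site, k]]
        if a == b:
            continue
        if a != 0 and area[a] == 1:
            continue  # cell death forbidden: N is constant
        dH = 0.0
        for m in range(n_off):
            c = spins_flat[nb_idx[site, m]]
            cvals[m] = c
            if c != a:
                if a == 0 or c == 0:
                    dH -= J0
                else:
                    dH -= J0 * (1.0 - J * (cos_t[a] * cos_t[c] + sin_t[a] * sin_t[c]))
            if c != b:
                if b == 0 or c == 0:
                    dH += J0
                else:
                    dH += J0 * (1.0 - J * (cos_t[b] * cos_t[c] + sin_t[b] * sin_t[c]))
        if a != 0:
            da = area[a] - A_t
            dH += lam * ((da - 1.0) * (da - 1.0) - da * da)
        if b != 0:
            db = area[b] - A_t
            dH += lam * ((db + 1.0) * (db + 1.0) - db * db)
        ok = dH <= 0.0
        if not ok:
            ok = _rng_double(rng_state) < np.exp(-dH / T)
        if ok:
            spins_flat[site] = b
            area[a] -= 1
            area[b] += 1
            for m in range(n_off):
                c = cvals[m]
                if c != a:
                    counts[a, c] -= 1
                    counts[c, a] -= 1
                if c != b:
                    counts[b, c] += 1
                    counts[c, b] += 1
            accepted += 1
    return accepted


#: cached flat neighbor-site tables, keyed by (L1, L2, neighbor order)
_NEIGHBOR_TABLES: dict[tuple[int, int, int], np.ndarray] = {}


@dataclass
class FlipStats:
    attempted: int
    accepted: int

    @property
    def acceptance_rate(self) -> float:
        return self.accepted / self.attempted if self.attempted else 0.0


def monte_carlo_step(state: LatticeState, cells: CellTable, params: ModelParams,
                     rng: XorShift128Plus, n_attempts: int | None = None,
                     pair_counts: np.ndarray | None = None) -> FlipStats:
    """Perform one MCS: ``L1 * L2`` sequential flip attempts (in place).

    Area bookkeeping is maintained incrementally inside the kernel; same-spin
    proposals consume attempt budget, and a flip that would annihilate a cell
    is rejected.  When ``pair_counts`` (the symmetric heterotypic
    boundary-pair matrix for the current state) is passed it is kept exactly
    up to date across the sweep, sparing the caller a fresh lattice scan.
    """
    if n_attempts is None:
        n_attempts = state.n_sites
    if pair_counts is None:
        pair_counts = np.zeros((cells.n_cells + 1, cells.n_cells + 1),
                               dtype=np.int64)  # throwaway accumulator
    L1, L2 = state.dims
    key = (L1, L2, params.neighbor_order)
    nb_idx = _NEIGHBOR_TABLES.get(key)
    if nb_idx is None:
        nb_idx = _build_site_neighbors(L1, L2,
                                       full_offsets(params.neighbor_order))
        _NEIGHBOR_TABLES[key] = nb_idx
    cos_t = np.cos(cells.theta)
    sin_t = np.sin(cells.theta)
    accepted = _mcs_kernel(
        state.spins.reshape(-1), nb_idx, cells.area, cos_t, sin_t,
        pair_counts, float(params.J0), float(params.J), float(params.lam),
        float(params.A_target), float(params.T),
        int(n_attempts), rng.state, L1, L2,
    )
    return FlipStats(attempted=int(n_attempts), accepted=int(accepted))


# --------------------------------------------------------------------------
# Fragmentation diagnostic
# --------------------------------------------------------------------------

@njit(cache=True)
def _component_counts(spins, off, n_cells):
    """Connected components per cell id under the given adjacency offsets."""
    L1, L2 = spins.shape
    comps = np.zeros(n_cells + 1, np.int64)
    visited = np.zeros((L1, L2), np.uint8)
    stack = np.empty((L1 * L2, 2), np.int64)
    for i1 in range(L1):
        for i2 in range(L2):
            s = spins[i1, i2]
            if s == 0 or visited[i1, i2]:
                continue
            comps[s] += 1
            top = 0
            stack[0, 0] = i1
            stack[0, 1] = i2
            visited[i1, i2] = 1
            while top >= 0:
                x1 = stack[top, 0]
                x2 = stack[top, 1]
                top -= 1
                for m in range(off.shape[0]):
                    y1 = (x1 + off[m, 0]) % L1
                    y2 = (x2 + off[m, 1]) % L2
                    if visited[y1, y2] == 0 and spins[y1, y2] == s:
                        visited[y1, y2] = 1
                        top += 1
                        stack[top, 0] = y1
                        stack[top, 1] = y2
    return comps


def count_cell_fragments(state: LatticeState, n_cells: int,
                         neighbor_order: int = 2) -> int:
    """Number of cells split into more than one connected piece.

    Fragmentation is permitted by the dynamics (no connectivity constraint)
    but monitored as a diagnostic.
    """
    comps = _component_counts(state.spins, full_offsets(neighbor_order), n_cells)
    return int(np.count_nonzero(comps > 1))
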