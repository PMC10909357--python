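"""Configuration parsing, snapshot serialization, rendering and fixtures.

Snapshots are single-file ``.npz`` bundles (spin grid, per-cell area and
phase arrays, kernel RNG state) with a JSON metadata block carrying the
parameter set, the MCS index, the seed and a format version; runs resumed
from a snapshot bit-match uninterrupted ones.  CSV exports of the site
and cell tables are provided for portability.

The fixture generator builds tiny hand-checkable lattice states (single
cell, touching cell pairs, a 2x2 cell ring, an 8-cell checkerboard, a
seeded random lattice), each shipping its expected energies, adjacency
and order parameters as computed by the brute-force oracles in this
module — deliberately naive, independent code paths used to validate the
incremental engine.
"""

from __future__ import annotations

import json
import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .clocks import relative_phase
from .core import (
    CellTable,
    LatticeState,
    ModelParams,
    contact_energy,
    full_offsets,
)
from .driver import RunSpec, initialize

__all__ = ["SNAPSHOT_VERSION", "SnapshotFormatError", "load_config",
           "params_from_config", "runspec_from_config", "write_snapshot",
           "read_snapshot", "export_csv", "render", "Fixture", "make_fixture",
           "FIXTURE_NAMES", "brute_force_hamiltonian",
           "brute_force_contact_pairs", "brute_force_psi"]

SNAPSHOT_VERSION = 1


class SnapshotFormatError(ValueError):
    """Raised for corrupt, incomplete or wrong-version snapshot files."""


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Read a TOML config with [lattice], [model], [run] and [sweep] tables."""
    with open(path, "rb") as fh:
        return tomllib.load(fh)


_MODEL_KEYS = {"J", "K", "J0", "T", "lam", "A_target", "omega",
               "neighbor_order", "N", "seed"}


def params_from_config(cfg: dict, **overrides) -> ModelParams:
    """Build :class:`ModelParams` from a config dict; kwargs win over the file."""
    kwargs: dict = {}
    lattice = cfg.get("lattice", {})
    if "dims" in lattice:
        kwargs["dims"] = tuple(lattice["dims"])
    model = cfg.get("model", {})
    unknown = set(model) - _MODEL_KEYS
    if unknown:
        raise ValueError(f"unknown [model] keys: {sorted(unknown)}")
    kwargs.update(model)
    kwargs.update({k: v for k, v in overrides.items() if v is not None})
    return ModelParams(**kwargs)


def runspec_from_config(cfg: dict, params: ModelParams | None = None,
                        **overrides) -> RunSpec:
    run_cfg = dict(cfg.get("run", {}))
    run_cfg.update({k: v for k, v in overrides.items() if v is not None})
    params = params if params is not None else params_from_config(cfg)
    return RunSpec(params=params,
                   mcs_budget=int(run_cfg.get("mcs_budget", 1000)),
                   record_every=int(run_cfg.get("record_every", 500)),
                   snapshot_every=int(run_cfg.get("snapshot_every", 0)),
                   seed=run_cfg.get("seed"))


# --------------------------------------------------------------------------
# Snapshots
# --------------------------------------------------------------------------

def write_snapshot(path: str | Path, state: LatticeState, cells: CellTable,
                   mcs: int, params: ModelParams, rng_state: np.ndarray,
                   seed: int | None = None) -> None:
    """Write a lossless single-file snapshot (arrays + JSON metadata block)."""
    meta = {
        "version": SNAPSHOT_VERSION,
        "mcs": int(mcs),
        "seed": None if seed is None else int(seed),
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in params.__dict__.items()},
    }
    np.savez_compressed(
        Path(path),
        spins=state.spins,
        area=cells.area,
        theta=cells.theta,
        rng_state=np.asarray(rng_state, dtype=np.uint64),
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def read_snapshot(path: str | Path
                  ) -> tuple[LatticeState, CellTable, ModelParams, dict]:
    """Read a snapshot; returns (state, cells, params, meta).

    ``meta`` includes ``mcs``, ``seed`` and the raw ``rng_state`` needed to
    resume the run bit-exactly.
    """
    with np.load(Path(path)) as npz:
        for fieldname in ("spins", "area", "theta", "rng_state", "meta"):
            if fieldname not in npz:
                raise SnapshotFormatError(f"snapshot missing field '{fieldname}'")
        try:
            meta = json.loads(bytes(npz["meta"].tobytes()).decode())
        except (ValueError, UnicodeDecodeError) as exc:
            raise SnapshotFormatError("snapshot field 'meta' is not valid JSON") from exc
        if meta.get("version") != SNAPSHOT_VERSION:
            raise SnapshotFormatError(
                f"unsupported snapshot version {meta.get('version')!r}; "
                f"this reader supports version {SNAPSHOT_VERSION}"
            )
        state = LatticeState(npz["spins"])
        cells = CellTable(npz["area"], npz["theta"])
        meta["rng_state"] = npz["rng_state"].astype(np.uint64)
    pkw = dict(meta["params"])
    pkw["dims"] = tuple(pkw["dims"])
    params = ModelParams(**pkw)
    cells.check_against(state)
    return state, cells, params, meta


def export_csv(state: LatticeState, cells: CellTable,
               sites_path: str | Path, cells_path: str | Path) -> None:
    """Portable CSV export: sites (x,y,spin) and cells (id,area,theta)."""
    L1, L2 = state.dims
    with open(sites_path, "w") as fh:
        fh.write("x,y,spin\n")
        for i1 in range(L1):
            row = state.spins[i1]
            fh.writelines(f"{i1},{i2},{row[i2]}\n" for i2 in range(L2))
    with open(cells_path, "w") as fh:
        fh.write("id,area,theta\n")
        for s in range(1, cells.n_cells + 1):
            fh.write(f"{s},{cells.area[s]},{cells.theta[s]:.17g}\n")


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------

def render(state: LatticeState, thetas: np.ndarray, mcs: int, omega: float,
           path: str | Path, outline: bool = False) -> None:
    """Write a phase-wheel image: relative phase -> hue, medium -> white.

    Cells are colored by their phase shift relative to a reference clock
    moving at constant speed omega, so frames from different times are
    directly comparable.  Deterministic: identical inputs give identical
    bytes.
    """
    from matplotlib import colormaps
    from matplotlib.image import imsave

    rel = relative_phase(thetas, mcs, omega) / (2.0 * np.pi)
    rgba = colormaps["hsv"](rel[state.spins])
    rgba[state.spins == 0] = (1.0, 1.0, 1.0, 1.0)
    if outline:
        border = np.zeros(state.dims, dtype=bool)
        for d1, d2 in ((0, 1), (1, 0)):
            t = np.roll(np.roll(state.spins, -d1, axis=0), -d2, axis=1)
            border |= state.spins != t
        rgba[border & (state.spins > 0)] *= (0.55, 0.55, 0.55, 1.0)
    imsave(Path(path), rgba)


# --------------------------------------------------------------------------
# Brute-force oracles
# --------------------------------------------------------------------------

def brute_force_hamiltonian(state: LatticeState, cells: CellTable,
                            params: ModelParams) -> float:
    """Naive double-loop energy: every ordered neighbor pair, halved.

    Independent of the vectorized/incremental code paths; areas are
    recounted from the lattice rather than read from the cell table.
    """
    L1, L2 = state.dims
    offs = full_offsets(params.neighbor_order)
    th = cells.theta
    contact = 0.0
    for i1 in range(L1):
        for i2 in range(L2):
            a = int(state.spins[i1, i2])
            for d1, d2 in offs:
                b = int(state.spins[(i1 + int(d1)) % L1, (i2 + int(d2)) % L2])
                if a != b:
                    contact += contact_energy(a, b, th[a], th[b], params)
    energy = contact / 2.0
    counts: dict[int, int] = {}
    for v in state.spins.ravel():
        counts[int(v)] = counts.get(int(v), 0) + 1
    for s, area in counts.items():
        if s != 0:
            energy += params.lam * (area - params.A_target) ** 2
    return energy


def brute_force_contact_pairs(state: LatticeState, neighbor_order: int = 2
                              ) -> dict[tuple[int, int], int]:
    """Unordered heterotypic cell-cell boundary pair counts, by naive scan."""
    L1, L2 = state.dims
    pairs: dict[tuple[int, int], int] = {}
    for i1 in range(L1):
        for i2 in range(L2):
            a = int(state.spins[i1, i2])
            for d1, d2 in full_offsets(neighbor_order):
                j1, j2 = (i1 + int(d1)) % L1, (i2 + int(d2)) % L2
                b = int(state.spins[j1, j2])
                if a > 0 and b > 0 and a != b and (i1, i2, a) < (j1, j2, b):
                    key = (min(a, b), max(a, b))
                    pairs[key] = pairs.get(key, 0) + 1
    return pairs


def brute_force_psi(state: LatticeState, thetas: np.ndarray,
                    neighbor_order: int = 2) -> int:
    """Checkerboard parameter by naive enumeration of qualifying site pairs."""
    psi = 0
    for (a, b), count in brute_force_contact_pairs(state, neighbor_order).items():
        d = (float(thetas[a]) - float(thetas[b])) % (2.0 * math.pi)
        if math.pi - math.pi / 8.0 <= d <= math.pi + math.pi / 8.0:
            psi += count
    return psi


# --------------------------------------------------------------------------
# Fixtures
# --------------------------------------------------------------------------

FIXTURE_NAMES = ("single_cell_5x5", "two_cell_edge", "two_cell_corner",
                 "four_cell_ring", "checkerboard_8cell", "random_small")


@dataclass
class Fixture:
    """A tiny deterministic lattice state with oracle-derived expectations."""

    name: str
    state: LatticeState
    cells: CellTable
    params: ModelParams
    expected: dict = field(default_factory=dict)


def _block_state(dims, blocks, thetas, params) -> tuple[LatticeState, CellTable]:
    """Place rectangular cells given as (row, col, height, width) blocks."""
    spins = np.zeros(dims, dtype=np.int32)
    for cell_id, (r, c, h, w) in enumerate(blocks, start=1):
        spins[r:r + h, c:c + w] = cell_id
    state = LatticeState(spins)
    return state, CellTable.from_state(state, np.asarray(thetas, float),
                                       n_cells=len(blocks))


def make_fixture(name: str) -> Fixture:
    """Build one of the named fixtures (deterministic).

    Expected quantities are recomputed at construction by this module's
    brute-force oracles, so the fixture is self-verifying.
    """
    base = dict(J=0.0, K=0.0, dims=(20, 20), N=1)
    if name == "single_cell_5x5":
        params = ModelParams(**base)
        state, cells = _block_state((20, 20), [(5, 5, 5, 5)], [0.0], params)
    elif name == "two_cell_edge":
        params = ModelParams(**{**base, "N": 2})
        state, cells = _block_state((20, 20), [(5, 5, 5, 5), (5, 10, 5, 5)],
                                    [0.0, np.pi], params)
    elif name == "two_cell_corner":
        params = ModelParams(**{**base, "N": 2})
        state, cells = _block_state((20, 20), [(5, 5, 5, 5), (10, 10, 5, 5)],
                                    [0.0, np.pi], params)
    elif name == "four_cell_ring":
        params = ModelParams(**{**base, "N": 4})
        state, cells = _block_state(
            (20, 20),
            [(5, 5, 5, 5), (5, 10, 5, 5), (10, 5, 5, 5), (10, 10, 5, 5)],
            [0.0, np.pi, np.pi, 0.0], params)
    elif name == "checkerboard_8cell":
        params = ModelParams(**{**base, "N": 8})
        blocks = [(5 + 5 * i, 2 + 5 * j, 5, 5)
                  for i in range(2) for j in range(4)]
        thetas = [((i + j) % 2) * np.pi for i in range(2) for j in range(4)]
        state, cells = _block_state((24, 24), blocks, thetas, params)
    elif name == "random_small":
        params = ModelParams(J=0.0, K=0.0, dims=(20, 20), N=6, A_target=9,
                             seed=1234)
        state, cells = initialize(params, np.random.default_rng(1234))
    else:
        raise ValueError(
            f"unknown fixture {name!r}; valid names: {', '.join(FIXTURE_NAMES)}"
        )

    pair_counts = brute_force_contact_pairs(state, params.neighbor_order)
    adjacency = {}
    for (a, b) in pair_counts:
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)
    expected = {
        "hamiltonian": brute_force_hamiltonian(state, cells, params),
        "adjacency": adjacency,
        "pair_counts": pair_counts,
        "heterotypic_pairs": sum(pair_counts.values()),
        "psi": brute_force_psi(state, cells.theta, params.neighbor_order),
    }
    return Fixture(name, state, cells, params, expected)
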