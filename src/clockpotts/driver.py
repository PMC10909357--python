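"""Initialization, the main MCS loop, replicate management and J-K sweeps.

A run alternates, once per Monte Carlo step: (1) a full Metropolis lattice
sweep, then (2) a contact-graph rebuild and one synchronous clock update.
Order parameters are recorded on a fixed cadence; a run is considered
plateaued when the trailing stretch of each recorded series has stopped
drifting (see :func:`has_plateaued`).

Initial conditions follow the reference setup: N square cells of target
area placed at random non-colliding positions (rejection sampling, with a
fallback to a shuffled regular grid when the packing is too dense for
rejection to finish), and clock phases drawn i.i.d. uniform on [0, 2*pi).
Confluency — the covered fraction N * A_target / (L1 * L2) — is emergent
from those inputs, never set directly; the defaults give 70%.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clocks import ContactGraph, _pair_count_kernel, update_clocks
from .core import half_offsets
from .core import (
    CellTable,
    LatticeState,
    ModelParams,
    XorShift128Plus,
    count_cell_fragments,
    monte_carlo_step,
)
from .order import (
    ClassifyThresholds,
    OrderParamRecord,
    PhaseLabel,
    UndefinedInputError,
    checkerboard_psi,
    classify_phase,
    r_global,
    r_local,
)

logger = logging.getLogger("clockpotts")

__all__ = ["RunSpec", "SweepSpec", "RunResult", "PackingError", "initialize",
           "run", "sweep", "sweep_matrices", "synchronization_dynamics",
           "has_plateaued", "RECORD_COLUMNS"]

RECORD_COLUMNS = ["mcs", "r_global", "r_local", "psi",
                  "n_isolated_cells", "n_fragments"]


class PackingError(RuntimeError):
    """Raised when the requested cells cannot be placed on the lattice."""


# --------------------------------------------------------------------------
# Specs and results
# --------------------------------------------------------------------------

@dataclass
class RunSpec:
    """One simulation run: parameters, MCS budget, cadences and seed."""

    params: ModelParams
    mcs_budget: int
    record_every: int = 500
    snapshot_every: int = 0   # 0 = no periodic snapshots
    seed: int | None = None   # defaults to params.seed

    def __post_init__(self) -> None:
        if self.mcs_budget < 1:
            raise ValueError("mcs_budget must be >= 1")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")
        if self.seed is None:
            self.seed = self.params.seed


@dataclass
class SweepSpec:
    """A J x K parameter sweep with replicates per grid cell."""

    J_values: list[float]
    K_values: list[float]
    base: RunSpec
    replicates: int = 1


@dataclass
class RunResult:
    records: pd.DataFrame
    state: LatticeState
    cells: CellTable
    params: ModelParams
    seed: int
    converged: bool
    label: PhaseLabel
    mean_acceptance: float
    snapshots: list[Path] = field(default_factory=list)

    @property
    def final(self) -> OrderParamRecord:
        row = self.records.iloc[-1]
        return OrderParamRecord(
            mcs=int(row["mcs"]), r_global=float(row["r_global"]),
            r_local=float(row["r_local"]), psi=int(row["psi"]),
            n_isolated_cells=int(row["n_isolated_cells"]),
            n_fragments=int(row["n_fragments"]),
        )


# --------------------------------------------------------------------------
# Initialization
# --------------------------------------------------------------------------

def _footprint(A_target: int) -> tuple[int, int]:
    """Most-square integer rectangle of exactly A_target sites (5x5 for 25)."""
    h = int(np.sqrt(A_target))
    while A_target % h:
        h -= 1
    return h, A_target // h


def initialize(params: ModelParams, rng: np.random.Generator
               ) -> tuple[LatticeState, CellTable]:
    """Place N non-overlapping rectangular cells and draw uniform phases.

    Anchors are sampled by rejection; if the packing is too dense for
    rejection to finish (as at the default 70% confluency) placement
    restarts on a shuffled regular grid with a random global offset,
    which preserves a random assignment of cells to positions.
    """
    L1, L2 = params.dims
    if params.N * params.A_target > L1 * L2:
        raise PackingError(
            f"cannot place {params.N} cells of area {params.A_target} on "
            f"{L1}x{L2}: occupancy {params.N * params.A_target / (L1 * L2):.2f} > 1"
        )
    h, w = _footprint(params.A_target)
    spins = np.zeros((L1, L2), dtype=np.int32)
    occ = np.zeros((L1, L2), dtype=bool)
    anchors: list[tuple[int, int]] = []
    budget = 200 * params.N
    attempts = 0
    while len(anchors) < params.N and attempts < budget:
        attempts += 1
        r = int(rng.integers(L1))
        c = int(rng.integers(L2))
        rows = (r + np.arange(h)) % L1
        cols = (c + np.arange(w)) % L2
        if not occ[np.ix_(rows, cols)].any():
            occ[np.ix_(rows, cols)] = True
            anchors.append((r, c))
    if len(anchors) < params.N:
        # dense packing: restart on a shuffled regular grid of block slots
        n_slots = (L1 // h) * (L2 // w)
        if n_slots < params.N:
            raise PackingError(
                f"grid fallback offers {n_slots} slots for {params.N} cells "
                f"(occupancy {params.N * params.A_target / (L1 * L2):.2f})"
            )
        slots = [(i * h, j * w) for i in range(L1 // h) for j in range(L2 // w)]
        idx = rng.permutation(n_slots)[:params.N]
        r0 = int(rng.integers(L1))
        c0 = int(rng.integers(L2))
        anchors = [((slots[i][0] + r0) % L1, (slots[i][1] + c0) % L2) for i in idx]
        logger.debug("initialize: rejection stalled after %d attempts; "
                     "grid fallback used", attempts)
    for cell_id, (r, c) in enumerate(anchors, start=1):
        rows = (r + np.arange(h)) % L1
        cols = (c + np.arange(w)) % L2
        spins[np.ix_(rows, cols)] = cell_id
    state = LatticeState(spins)
    theta = rng.uniform(0.0, 2.0 * np.pi, params.N)
    cells = CellTable.from_state(state, theta, n_cells=params.N)
    return state, cells


# --------------------------------------------------------------------------
# Plateau detection
# --------------------------------------------------------------------------

def has_plateaued(records: pd.DataFrame, min_records: int = 20) -> bool:
    """True when every order parameter has stopped drifting.

    Compares the mean of the trailing 10% of recorded points against the
    mean of the preceding equal-sized window; a series is flat when the
    difference is below 2% of its overall range, with a small floor so a
    converged-but-noisy flat series still qualifies (absolute 0.003 for
    the bounded r parameters, 5% of the trailing level for the extensive
    count psi).
    """
    n = len(records)
    if n < min_records:
        return False
    w = max(3, n // 10)
    for col in ("r_global", "r_local", "psi"):
        v = records[col].to_numpy(dtype=float)
        if not np.isfinite(v).all():
            continue  # undefined stretches (e.g. r_local with no contacts)
        rng_ = float(v.max() - v.min())
        tail = float(v[-w:].mean())
        drift = abs(tail - float(v[-2 * w:-w].mean()))
        floor = 0.05 * abs(tail) if col == "psi" else 0.003
        if drift > 0.02 * rng_ + floor:
            return False
    return True


# --------------------------------------------------------------------------
# The main loop
# --------------------------------------------------------------------------

def _make_record(mcs: int, state: LatticeState, cells: CellTable,
                 graph, params: ModelParams) -> OrderParamRecord:
    alive_thetas = cells.theta[1:][cells.alive]
    rg = r_global(alive_thetas)
    try:
        rl, n_iso = r_local(cells.theta, graph, return_isolated=True)
    except UndefinedInputError:
        # nothing touches anything: r_local has no meaning this instant
        rl, n_iso = float("nan"), int(np.count_nonzero(cells.alive))
    psi = checkerboard_psi(state, cells.theta, params.neighbor_order, graph=graph)
    n_frag = count_cell_fragments(state, cells.n_cells, params.neighbor_order)
    return OrderParamRecord(mcs, rg, rl, psi, n_iso, n_frag)


def run(spec: RunSpec, outdir: str | Path | None = None,
        stop_on_plateau: bool = False, min_mcs: int = 0,
        thresholds: ClassifyThresholds | None = None,
        initial: tuple[LatticeState, CellTable] | None = None,
        rng: XorShift128Plus | None = None, start_mcs: int = 0) -> RunResult:
    """Execute one run and return its order-parameter time series.

    Deterministic given ``spec.seed``: one seed sequence drives both the
    numpy generator used for initialization and the kernel RNG driving
    proposals and acceptance draws.  ``initial``/``rng``/``start_mcs``
    allow resuming from a snapshot (the resumed trajectory bit-matches an
    uninterrupted one).  With ``stop_on_plateau`` the loop exits early
    once :func:`has_plateaued` holds (checked at every record).
    """
    params = spec.params
    ss = np.random.SeedSequence(spec.seed)
    init_ss, kernel_ss = ss.spawn(2)
    if initial is None:
        state, cells = initialize(params, np.random.default_rng(init_ss))
    else:
        state, cells = initial
        cells.check_against(state)
    if rng is None:
        rng = XorShift128Plus(state=kernel_ss.generate_state(2, np.uint64))
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    records: list[OrderParamRecord] = []
    snapshots: list[Path] = []
    accepted_total = 0
    attempted_total = 0
    # exhaustive scan once; the sweep kernel keeps the pair counts exact
    pair_counts = _pair_count_kernel(
        state.spins, half_offsets(params.neighbor_order), cells.n_cells)
    graph = ContactGraph(pair_counts)
    if start_mcs == 0:
        records.append(_make_record(0, state, cells, graph, params))
    converged = False
    from . import __version__
    logger.info("run: clockpotts %s seed=%s J=%.4g K=%.4g dims=%s N=%d "
                "budget=%d MCS", __version__, spec.seed, params.J, params.K,
                params.dims, params.N, spec.mcs_budget)

    for mcs in range(start_mcs + 1, spec.mcs_budget + 1):
        stats = monte_carlo_step(state, cells, params, rng,
                                 pair_counts=pair_counts)
        accepted_total += stats.accepted
        attempted_total += stats.attempted
        graph = ContactGraph(pair_counts)
        cells.theta = update_clocks(cells.theta, graph, params.K, params.omega)
        if mcs % spec.record_every == 0:
            rec = _make_record(mcs, state, cells, graph, params)
            records.append(rec)
            logger.debug("mcs=%d r_global=%.3f r_local=%.3f psi=%d accept=%.3f",
                         mcs, rec.r_global, rec.r_local, rec.psi,
                         stats.acceptance_rate)
            if stop_on_plateau and mcs >= min_mcs:
                df_sofar = pd.DataFrame([r.__dict__ for r in records])
                if has_plateaued(df_sofar):
                    converged = True
                    break
        if spec.snapshot_every and outdir is not None and mcs % spec.snapshot_every == 0:
            from .io import write_snapshot  # deferred: io imports this module
            path = outdir / f"snapshot_{mcs:08d}.npz"
            write_snapshot(path, state, cells, mcs, params, rng.state,
                           seed=spec.seed)
            snapshots.append(path)

    df = pd.DataFrame([r.__dict__ for r in records], columns=RECORD_COLUMNS)
    if not converged:
        converged = has_plateaued(df)
    if not converged:
        logger.info("run: budget exhausted before plateau; terminal record "
                    "classified but flagged unconverged")
    if len(df):
        last = df.iloc[-1]
        final_rec = OrderParamRecord(
            int(last["mcs"]), float(last["r_global"]), float(last["r_local"]),
            int(last["psi"]), int(last["n_isolated_cells"]),
            int(last["n_fragments"]))
        label = classify_phase(final_rec, thresholds, params.dims)
    else:
        label = PhaseLabel.AMBIGUOUS
    result = RunResult(df, state, cells, params, int(spec.seed), converged,
                       label, accepted_total / max(attempted_total, 1),
                       snapshots)
    if outdir is not None:
        from .io import write_snapshot
        final_path = outdir / "final_snapshot.npz"
        write_snapshot(final_path, state, cells,
                       int(df["mcs"].iloc[-1]) if len(df) else 0,
                       params, rng.state, seed=spec.seed)
        result.snapshots.append(final_path)
        df.to_csv(outdir / "timeseries.csv", index=False)
        cfg = {"seed": int(spec.seed), "mcs_budget": spec.mcs_budget,
               "record_every": spec.record_every,
               "snapshot_every": spec.snapshot_every,
               "converged": converged, "label": str(label),
               "params": {k: (list(v) if isinstance(v, tuple) else v)
                          for k, v in params.__dict__.items()}}
        (outdir / "run.json").write_text(json.dumps(cfg, indent=2))
    return result


# --------------------------------------------------------------------------
# Sweeps and replicate experiments
# --------------------------------------------------------------------------

def _cell_seed(base_seed: int, *key: int) -> int:
    """Stable per-(grid-cell, replicate) seed below 2**31."""
    return int(np.random.SeedSequence((base_seed, *key)).generate_state(1)[0]
               & 0x7FFFFFFF)


SWEEP_COLUMNS = ["J", "K", "seed", "final_r_global", "final_r_local",
                 "final_psi", "label", "converged"]


def sweep(spec: SweepSpec, outdir: str | Path | None = None,
          stop_on_plateau: bool = True,
          thresholds: ClassifyThresholds | None = None) -> pd.DataFrame:
    """Run the J x K grid and classify each terminal state.

    Individual run failures are recorded (label ``error``, NaN order
    parameters) and the sweep continues.  Returns the phase-diagram table;
    also writes ``phase_diagram.csv`` when ``outdir`` is given.
    """
    rows = []
    for jdx, J in enumerate(spec.J_values):
        for kdx, K in enumerate(spec.K_values):
            for rep in range(spec.replicates):
                seed = _cell_seed(spec.base.seed, jdx, kdx, rep)
                rspec = RunSpec(
                    params=spec.base.params.replace(J=J, K=K, seed=seed),
                    mcs_budget=spec.base.mcs_budget,
                    record_every=spec.base.record_every,
                    seed=seed,
                )
                try:
                    res = run(rspec, stop_on_plateau=stop_on_plateau,
                              thresholds=thresholds)
                    fin = res.final
                    rows.append((J, K, seed, fin.r_global, fin.r_local,
                                 fin.psi, str(res.label), res.converged))
                except Exception:
                    logger.exception("sweep cell J=%g K=%g rep=%d failed",
                                     J, K, rep)
                    rows.append((J, K, seed, np.nan, np.nan, np.nan,
                                 "error", False))
    df = pd.DataFrame(rows, columns=SWEEP_COLUMNS)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df.to_csv(outdir / "phase_diagram.csv", index=False)
    return df


def sweep_matrices(df: pd.DataFrame) -> dict[str, np.ndarray]:
    """Heat-map-ready matrices (J rows x K columns, replicate means)."""
    out = {}
    for col in ("final_r_global", "final_r_local", "final_psi"):
        out[col.removeprefix("final_")] = (
            df.pivot_table(index="J", columns="K", values=col, aggfunc="mean")
            .to_numpy()
        )
    return out


def synchronization_dynamics(J_values, K: float, replicates: int,
                             mcs_budget: int, params: ModelParams | None = None,
                             record_every: int = 200, base_seed: int = 0
                             ) -> pd.DataFrame:
    """Replicate-averaged r_global(t) and r_local(t) per J at fixed K.

    Spread is the standard error of the mean over replicate seeds.
    """
    params = params or ModelParams()
    frames = []
    for jdx, J in enumerate(J_values):
        for rep in range(replicates):
            seed = _cell_seed(base_seed, jdx, rep)
            rspec = RunSpec(params=params.replace(J=J, K=K, seed=seed),
                            mcs_budget=mcs_budget, record_every=record_every,
                            seed=seed)
            res = run(rspec)
            d = res.records[["mcs", "r_global", "r_local"]].copy()
            d["J"] = J
            d["rep"] = rep
            frames.append(d)
    all_df = pd.concat(frames, ignore_index=True)
    g = all_df.groupby(["J", "mcs"])
    out = g.agg(
        r_global_mean=("r_global", "mean"),
        r_global_sem=("r_global", "sem"),
        r_local_mean=("r_local", "mean"),
        r_local_sem=("r_local", "sem"),
        n=("rep", "count"),
    ).reset_index()
    return out
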