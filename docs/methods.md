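# Methods

## Model and update cycle

The simulator couples two dynamical layers on a periodic 2-D lattice.

**Lattice layer (Cellular Potts Model).**  Cells are sets of lattice
sites with a shared integer index; index 0 is medium.  The Hamiltonian
is the sum over unordered order-2 (Moore) neighboring site pairs of a
heterotypic contact energy, plus a quadratic area constraint per cell.
Cell–cell contact energy is J₀(1 − J cos Δθ), so the *clock phase
difference* of the two cells modulates adhesion: same-phase contact is
cheapest for J > 0, opposite-phase contact for J < 0, and cell–medium
contact always costs J₀.  Medium–medium contact costs nothing.  Time
advances by Metropolis spin flips: a uniformly random site proposes to
copy the spin of a uniformly random order-2 neighbor; the flip is
accepted with probability 1 if ΔH ≤ 0 and e^(−ΔH/T) otherwise.  One
Monte Carlo step (MCS) is L₁·L₂ such attempts, applied sequentially and
in place.  Same-spin proposals consume attempt budget (the common CPM
convention), and a flip that would erase a cell's last site is rejected,
so the cell count N is an invariant of the dynamics.  Cell
fragmentation is *not* forbidden — near |J| = 1 same-phase cell–cell
boundaries become nearly free and cells do fragment — but it is counted
(connected components per cell id under order-2 connectivity) and
reported in every record.

**Clock layer (Kuramoto coupling on the contact graph).**  After each
lattice sweep, every cell's phase advances synchronously by
ω(1 + K · mean over contact neighbors of sin(θ_u − θ_s)).  Two cells
are contact neighbors when any site of one is an order-2 neighbor of a
site of the other; the graph is recomputed exactly every MCS (see
*Performance*).  A cell with no neighbors free-runs at ω — the only
continuous extension of the neighbor mean.  Phases are stored mod 2π.
Because every term depends only on phase differences, trajectories of
differences are invariant under θ → θ − ωt and depend on ω only through
the product ωK; renders therefore color cells by their phase *shift*
relative to a reference clock of speed ω, which makes frames from
different times comparable.

The clock update is applied after the lattice sweep within an MCS.  The
opposite order would differ per MCS by at most ω = 10⁻³ rad of phase
against a slightly staler graph; at the default parameters the two
schedules are statistically indistinguishable, but the order is fixed
and documented rather than assumed away.

## Parameters

| symbol | default | meaning |
|---|---|---|
| dims | 126 × 126 | periodic lattice (≈2 µm/site in the motivating calibration) |
| N | 445 | cell count (invariant) |
| A_target | 25 sites | target cell area (5 × 5 at initialization) |
| λ | 25 | area stiffness (energy/site²) |
| T | 20 | Metropolis temperature (energy) |
| J₀ | 16 | contact energy scale (energy); also the cell–medium energy |
| J | swept, (−1, 1) | adhesion–phase coupling (dimensionless) |
| K | swept, (−1, 1) | clock coupling (dimensionless) |
| ω | 0.001 rad/MCS | clock speed (period ≈ 6300 MCS ≈ 40 min at 10⁴ MCS/h) |
| neighbor order | 2 | Moore adjacency for energies, proposals, contact |

N·A_target/(L₁L₂) gives 70% confluency; confluency is emergent, never an
input.  |J| ≥ 1 makes some cell–cell contact energies non-positive
(fragmentation), |K| ≥ 1 lets clocks stop or run backwards; both raise a
warning but are permitted for exploration.

## Order parameters and classification

* `r_global`: modulus of the population-mean unit phasor; 1 = full
  synchrony, ~N^(−1/2) for random phases.
* `r_local`: for each cell with ≥1 contact neighbor, the modulus of the
  mean *neighbor* phasor (the cell itself excluded; an `include_self`
  switch exists because the convention changes the random baseline from
  √π/(2√n) to √π/(2√(n+1))); averaged over cells, isolated cells
  omitted and counted.  With n ≈ 6 contact neighbors the random-phase
  baseline is ≈0.36.
* `ψ`: the number of unordered order-2 neighboring site pairs whose
  spins are two distinct cells and whose phase difference lies within
  π/8 of π (endpoints included).  ψ is extensive; at the reference
  geometry a random-phase configuration has ≈8500 heterotypic site
  pairs and hence ψ ≈ 1060 by band fraction 1/8.

Classification applies thresholds in a fixed order: r_global ≥ 0.9 →
global sync; else ψ above a threshold (1000 at the reference lattice,
scaled proportionally to lattice area) → anti-sync; else r_local ≥ 0.8 →
local sync; r_local ≤ 0.35 → incoherent; otherwise *ambiguous* — the
local-sync/incoherence transition is genuinely gradual and borderline
records are not forced into a bin.  All thresholds are configurable.

## Initialization

N axis-aligned A_target-site rectangles (5 × 5 by default) on random
non-colliding anchors by rejection sampling, phases i.i.d. uniform on
[0, 2π).  Random sequential adsorption of aligned squares jams near ~63%
coverage, below the 70% reference confluency, so at reference density
the rejection loop cannot finish; placement then restarts on a shuffled
regular grid of block slots with a random global offset (random
cell-to-position assignment, zero initial fragmentation).  The lattice
roughens within a few hundred MCS, after which no trace of the block
grid remains in the energies; whether long-run states depend on the
seeding geometry beyond that has not been exhaustively explored.

## Convergence ("plateau") rule

A run is considered plateaued when, for each of r_global, r_local and
ψ, the mean of the trailing 10% of recorded points differs from the
mean of the preceding equal-sized window by less than 2% of the series'
overall range, plus a small floor (0.003 absolute for the bounded r
parameters; 5% of the trailing level for the extensive ψ) so that a
converged-but-noisy flat series terminates.  Window *means* are
compared, not within-window ranges — a fluctuating stationary series
never has a small internal range.  Runs that exhaust their budget
before plateauing are classified anyway but flagged unconverged.

## Numerical choices

* Energies in double precision; cosines evaluated directly.  The sweep
  kernel caches cos θ and sin θ per cell (phases are constant within a
  sweep) and expands cos(θ_a − θ_c) as a product, which matches the
  direct form to ~1 ulp; the incremental ΔH is property-tested against
  a full Hamiltonian recompute at 10⁻⁹ tolerance.
* The Hamiltonian counts each unordered site pair once.  Double
  counting would only rescale J₀, λ and T jointly; single counting
  keeps the parameter table meaningful as given.
* Phase differences are reduced to the principal interval before band
  tests; the ψ band is closed at both endpoints.
* RNG: initialization (placement, phases) uses numpy's PCG64 via
  `SeedSequence`; the Metropolis kernel uses an explicit-state
  xorshift128+ generator whose two-word state lives in snapshots, so
  interrupted runs resume bit-exactly.  A pure-Python mirror of the
  generator backs the single-flip operations; a test replays a full
  sweep flip-for-flip through both paths.
* Degenerate inputs: an empty phase population or an all-isolated
  contact graph make r_global / r_local undefined and raise (or record
  NaN inside a run, where the condition can be transient).

## Performance

The Metropolis sweep and the boundary-pair scan are numba kernels
(~1–2 ms per full-lattice MCS on one core).  The heterotypic
boundary-pair matrix is maintained *incrementally* by the sweep kernel
(updated on every accepted flip) and is verified in tests to equal a
from-scratch lattice rescan after every MCS; the contact graph, clock
coupling and ψ all read this matrix, so the per-MCS cost of exact graph
maintenance is a few percent.

## Problem sizes in the test suite

Unit and property tests run on 16–32² lattices with ≤ 20 cells.  The
steady-state regressions use the full reference lattice: the
anti-synchronization, incoherence and global-synchronization regimes
plateau within 10–30 k MCS; the local-synchronization regime coarsens
slowly (r_local ≈ 0.74 at 10 k MCS, ≈ 0.79 at 100 k, ≈ 0.81 past 200 k,
still creeping) and is given a 200 k MCS minimum within a 250 k budget,
matching the reference protocol's run length.  The quadrant-structure
regression uses a quarter-area lattice (64 × 64, 112 cells) where the
sharp phases (global sync, anti-sync) keep their classifier labels;
finite-size saturation caps r_local near 0.73 in the local-sync corner
there, so the gradual corners are checked through order-parameter
signatures instead of labels.

## What the simulations do and do not show

The model is a minimal abstraction: phase-only clocks with identical
speeds, adhesion depending only on phase difference, no chemotaxis,
polarity, division, death or differentiation, strictly 2-D.  Passing
tests show the four-phase structure and its dynamics are reproduced
for this idealization; they say nothing about parameter calibration to
a specific tissue.  Two quantitative caveats from our runs:

* In the incoherent corner (J = 0, K = −1) the stationary state is not
  pair-random: repulsive clock coupling on the slowly-churning contact
  graph enriches near-anti-phase neighbor pairs (ψ ≈ 2.2× the
  random-pair baseline) and holds r_local ≈ 0.30, below the ≈0.36
  random baseline but above the ≈0.2 sometimes quoted for incoherence —
  a value that would correspond to an effective neighborhood of ~19
  cells (roughly second-order cell adjacency) rather than the ~6
  direct-contact neighbors used here.  The neighborhood convention
  materially shifts r_local levels; this package pins the
  direct-contact reading.
* Because ψ's natural threshold sits at the random-pair baseline,
  pair-enriched incoherent states can cross it; the classifier's
  decision order (ψ checked before r_local) then labels such states
  anti-sync.  At the reference scale this affects only the J = 0
  boundary column of the phase diagram.
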