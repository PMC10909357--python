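"""Lattice engine: neighborhoods, energies, Metropolis kinetics."""

import numpy as np
import pytest
from scipy import stats

from clockpotts import (
    CellTable,
    LatticeState,
    ModelParams,
    UnsupportedOrderError,
    XorShift128Plus,
    accept_flip,
    contact_energy,
    delta_H,
    hamiltonian,
    make_fixture,
    monte_carlo_step,
    neighborhood,
    propose_flip,
)


class TestNeighborhood:
    def test_moore_wraps_periodically(self):
        nb = neighborhood((0, 0), 2, (126, 126))
        assert len(nb) == 8
        assert (125, 125) in nb and (125, 0) in nb and (0, 125) in nb

    def test_order1_is_edge_adjacent(self):
        assert set(neighborhood((5, 5), 1, (126, 126))) == {
            (4, 5), (6, 5), (5, 4), (5, 6)}

    def test_no_duplicates_and_self_excluded(self):
        for order in (1, 2):
            nb = neighborhood((3, 7), order, (10, 10))
            assert len(nb) == len(set(nb))
            assert (3, 7) not in nb

    def test_unsupported_order(self):
        with pytest.raises(UnsupportedOrderError):
            neighborhood((0, 0), 3, (10, 10))

    def test_unordered_pair_count_on_reference_lattice(self):
        # exhaustive enumeration: every site has 8 order-2 neighbors under
        # periodic wrap, so there are 126 * 126 * 8 / 2 unordered pairs
        dims = (126, 126)
        total = sum(len(neighborhood((i, j), 2, dims))
                    for i in range(dims[0]) for j in range(dims[1]))
        assert total // 2 == 63504


class TestContactEnergy:
    @pytest.mark.parametrize("J, th1, th2, expected", [
        (0.0, 1.3, 2.9, 16.0),            # J = 0: phase independence
        (1.0, 0.7, 0.7, 0.0),             # equal phases, maximal like-adhesion
        (-0.95, 0.0, np.pi, 0.8),         # opposite phases, opposites attract
    ])
    def test_cell_cell(self, J, th1, th2, expected):
        p = ModelParams(J=J)
        assert contact_energy(1, 2, th1, th2, p) == pytest.approx(expected)

    def test_medium_contacts(self):
        p = ModelParams(J=0.5)
        assert contact_energy(0, 3, 0.0, 1.0, p) == p.J0
        assert contact_energy(3, 0, 1.0, 0.0, p) == p.J0
        assert contact_energy(0, 0, 0.0, 0.0, p) == 0.0

    def test_depends_only_on_phase_difference(self):
        p = ModelParams(J=0.6)
        for c in (0.1, 2.0, 5.5):
            assert contact_energy(1, 2, 1.0 + c, 2.4 + c, p) == pytest.approx(
                contact_energy(1, 2, 1.0, 2.4, p))


class TestHamiltonian:
    def test_single_cell_at_target_area(self):
        fx = make_fixture("single_cell_5x5")
        # 56 heterotypic cell-medium site pairs x J0=16, zero area penalty
        assert hamiltonian(fx.state, fx.cells, fx.params) == pytest.approx(896.0)

    def test_empty_lattice(self):
        state = LatticeState.empty((12, 12))
        cells = CellTable.from_state(state, np.zeros(3), n_cells=3)
        assert hamiltonian(state, cells, ModelParams(N=3)) == 0.0

    def test_inconsistent_area_bookkeeping_detected(self, small_system):
        from clockpotts import ConsistencyError
        state, cells, params = small_system
        broken = cells.copy()
        broken.area[1] += 1
        with pytest.raises(ConsistencyError):
            hamiltonian(state, broken, params)

    def test_area_penalty_for_one_missing_site(self):
        fx = make_fixture("single_cell_5x5")
        spins = fx.state.spins.copy()
        spins[5, 5] = 0  # remove one corner site -> area 24
        state = LatticeState(spins)
        cells = CellTable.from_state(state, fx.cells.theta, n_cells=1)
        with_pen = hamiltonian(state, cells, fx.params)
        no_pen = hamiltonian(state, cells, fx.params.replace(lam=0.0))
        assert with_pen - no_pen == pytest.approx(25.0 * (24 - 25) ** 2)


class TestDeltaH:
    def test_noop_flip_rejected(self, small_system):
        state, cells, params = small_system
        spin = int(state.spins[0, 0])
        with pytest.raises(ValueError):
            delta_H(state, cells, (0, 0), spin, params)

    @pytest.mark.parametrize("J,K", [(0.0, 0.0), (0.8, -0.5), (-0.95, 1.0)])
    def test_matches_full_recompute_over_random_flips(self, J, K):
        """Incremental dH equals H(after) - H(before) for >= 1000 flips."""
        params = ModelParams(J=J, K=K, dims=(16, 16), N=4, A_target=9, seed=1)
        from clockpotts import initialize
        state, cells = initialize(params, np.random.default_rng(1))
        # roughen the configuration first so flips hit varied environments
        rng = XorShift128Plus(5)
        monte_carlo_step(state, cells, params, rng)
        gen = np.random.default_rng(2)
        checked = 0
        h_before = hamiltonian(state, cells, params)
        while checked < 1000:
            site = (int(gen.integers(16)), int(gen.integers(16)))
            new_spin = int(gen.integers(0, params.N + 1))
            old_spin = int(state.spins[site])
            if new_spin == old_spin:
                continue
            if old_spin != 0 and cells.area[old_spin] == 1:
                continue  # lethal flips never occur in the dynamics
            dh = delta_H(state, cells, site, new_spin, params)
            state.spins[site] = new_spin
            cells = CellTable.from_state(state, cells.theta, n_cells=params.N)
            h_after = hamiltonian(state, cells, params)
            assert dh == pytest.approx(h_after - h_before, abs=1e-9)
            h_before = h_after
            checked += 1

    def test_corner_removal_area_term(self):
        fx = make_fixture("single_cell_5x5")
        dh = delta_H(fx.state, fx.cells, (5, 5), 0, fx.params)
        # contact change: 5 cell-medium pairs removed, 3 created -> -2 * J0
        assert dh == pytest.approx(-2 * 16.0 + 25.0)

    def test_global_phase_shift_leaves_dH_unchanged(self, small_system):
        state, cells, params = small_system
        shifted = cells.copy()
        shifted.theta = np.mod(shifted.theta + 1.234, 2 * np.pi)
        gen = np.random.default_rng(3)
        for _ in range(50):
            site = (int(gen.integers(20)), int(gen.integers(20)))
            new_spin = int(gen.integers(0, params.N + 1))
            if new_spin == state.spins[site]:
                continue
            assert delta_H(state, cells, site, new_spin, params) == pytest.approx(
                delta_H(state, shifted, site, new_spin, params), abs=1e-9)


class TestAcceptFlip:
    def test_nonpositive_dH_always_accepted(self):
        assert accept_flip(-5.0, 20.0, 0.999999)
        assert accept_flip(0.0, 20.0, 0.999999)

    def test_positive_dH_boltzmann_frequency(self):
        """Acceptance frequency for dH = T converges to exp(-1)."""
        rng = XorShift128Plus(42)
        n = 100_000
        hits = sum(accept_flip(20.0, 20.0, rng.random()) for _ in range(n))
        test = stats.binomtest(hits, n, float(np.exp(-1.0)))
        assert test.pvalue > 1e-3

    def test_vanishing_temperature_blocks_uphill_moves(self):
        assert not accept_flip(1.0, 1e-12, 0.0)
        assert accept_flip(-1e-12, 1e-12, 0.0)


class TestProposeFlip:
    def test_all_medium_lattice_never_proposes(self, rng):
        state = LatticeState.empty((10, 10))
        assert all(propose_flip(state, rng) is None for _ in range(200))

    def test_seeded_proposals_reproducible(self, small_system):
        state, _, params = small_system
        seqs = []
        for _ in range(2):
            r = XorShift128Plus(99)
            seqs.append([propose_flip(state, r, params.neighbor_order)
                         for _ in range(100)])
        assert seqs[0] == seqs[1]

    def test_site_selection_uniform(self):
        """Chi-square of site pick frequencies against uniform on 10x10."""
        state = LatticeState(np.arange(100, dtype=np.int32).reshape(10, 10) % 3)
        r = XorShift128Plus(7)
        counts = np.zeros(100, dtype=int)
        n = 100_000
        for _ in range(n):
            i1 = r.randint(10)
            i2 = r.randint(10)
            r.random()  # neighbor draw
            counts[i1 * 10 + i2] += 1
        res = stats.chisquare(counts)
        assert res.pvalue > 1e-3


class TestMonteCarloStep:
    def test_attempts_equal_lattice_sites(self, small_system, rng):
        state, cells, params = small_system
        stats_ = monte_carlo_step(state, cells, params, rng)
        assert stats_.attempted == state.n_sites

    def test_reference_lattice_attempt_budget(self):
        assert ModelParams().n_sites == 15876

    def test_area_bookkeeping_and_site_conservation(self, small_system, rng):
        state, cells, params = small_system
        for _ in range(10):
            monte_carlo_step(state, cells, params, rng)
            cells.check_against(state)  # raises on any bookkeeping drift
            assert cells.area.sum() == state.n_sites

    def test_energy_never_increases_at_vanishing_temperature(self):
        params = ModelParams(J=0.4, dims=(20, 20), N=6, A_target=9, T=1e-9,
                             seed=3)
        from clockpotts import initialize
        state, cells = initialize(params, np.random.default_rng(3))
        rng = XorShift128Plus(3)
        h = hamiltonian(state, cells, params)
        with np.errstate(under="ignore"):
            for _ in range(10):
                monte_carlo_step(state, cells, params, rng)
                h_new = hamiltonian(state, cells, params)
                assert h_new <= h + 1e-9
                h = h_new

    def test_kernel_matches_pure_python_sweep(self, small_system):
        """The JIT sweep reproduces, flip for flip, a pure-Python Metropolis
        loop built from propose_flip / delta_H / accept_flip on the same
        RNG stream."""
        state, cells, params = small_system
        state_py = state.copy()
        cells_py = cells.copy()
        rng_kernel = XorShift128Plus(31)
        rng_py = XorShift128Plus(31)

        monte_carlo_step(state, cells, params, rng_kernel)

        for _ in range(state_py.n_sites):
            prop = propose_flip(state_py, rng_py, params.neighbor_order)
            if prop is None:
                continue
            site, new_spin = prop
            old_spin = int(state_py.spins[site])
            if old_spin != 0 and cells_py.area[old_spin] == 1:
                continue  # cell death forbidden
            dh = delta_H(state_py, cells_py, site, new_spin, params)
            ok = dh <= 0 or accept_flip(dh, params.T, rng_py.random())
            if ok:
                state_py.spins[site] = new_spin
                cells_py.area[old_spin] -= 1
                cells_py.area[new_spin] += 1

        assert np.array_equal(state.spins, state_py.spins)
        assert np.array_equal(cells.area, cells_py.area)
        assert np.array_equal(rng_kernel.state, rng_py.state)

    def test_incremental_pair_counts_match_fresh_scan(self, small_system, rng):
        """Boundary-pair bookkeeping kept inside the sweep equals an
        exhaustive lattice rescan after every MCS."""
        from clockpotts.clocks import _pair_count_kernel
        from clockpotts.core import half_offsets
        state, cells, params = small_system
        counts = _pair_count_kernel(state.spins, half_offsets(2),
                                    cells.n_cells)
        for _ in range(20):
            monte_carlo_step(state, cells, params, rng, pair_counts=counts)
            fresh = _pair_count_kernel(state.spins, half_offsets(2),
                                       cells.n_cells)
            assert np.array_equal(counts, fresh)

    def test_zero_J_contact_energies_are_phase_independent(self, rng):
        """With J = 0 the engine reduces to a phase-blind CPM: identical
        seeds with different phase vectors give identical lattices."""
        params = ModelParams(J=0.0, dims=(20, 20), N=6, A_target=9, seed=5)
        from clockpotts import initialize
        results = []
        for phase_seed in (1, 2):
            state, cells = initialize(params, np.random.default_rng(5))
            cells.theta[1:] = np.random.default_rng(phase_seed).uniform(
                0, 2 * np.pi, params.N)
            r = XorShift128Plus(11)
            for _ in range(5):
                monte_carlo_step(state, cells, params, r)
            results.append(state.spins.copy())
        assert np.array_equal(results[0], results[1])
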