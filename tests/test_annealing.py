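import numpy as np
import pytest

import ocnlab as o
from ocnlab.annealing import AnnealingSchedule, delta_energy, energy, temperature
from ocnlab.lattice import accumulate_areas, build_lattice, neighbor_table

from conftest import make_state, random_flow


class TestEnergy:
    def test_chain_gamma_one(self, chain4):
        assert energy(accumulate_areas(chain4), 1.0) == pytest.approx(10.0)

    def test_chain_gamma_zero_limit(self, chain4):
        assert energy(accumulate_areas(chain4), 1e-12) == pytest.approx(4.0)

    def test_chain_gamma_half(self, chain4):
        expected = 1 + np.sqrt(2) + np.sqrt(3) + 2
        assert energy(accumulate_areas(chain4), 0.5) == pytest.approx(expected)

    @pytest.mark.parametrize("gamma", [0.0, -0.5, 1.5])
    def test_gamma_domain(self, chain4, gamma):
        with pytest.raises(ValueError):
            energy(accumulate_areas(chain4), gamma)


class TestTemperature:
    def test_starts_at_T0_and_decreases(self):
        sched = AnnealingSchedule(n_iter=1000, T0=2.0, cooling_rate=1.0)
        temps = [temperature(k, sched, n_pixels=100) for k in range(1000)]
        assert temps[0] == pytest.approx(2.0)
        assert np.all(np.diff(temps) <= 0)

    def test_no_cooling_phase_holds_T0(self):
        sched = AnnealingSchedule(
            n_iter=1000, T0=2.0, no_cooling_fraction=0.5
        )
        assert temperature(499, sched, 100) == pytest.approx(2.0)
        assert temperature(999, sched, 100) < 2.0

    def test_fast_cooling_is_greedy(self):
        sched = AnnealingSchedule(n_iter=100, T0=2.0, cooling_rate=1e9)
        assert temperature(99, sched, 100) == pytest.approx(0.0, abs=1e-30)

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            AnnealingSchedule(n_iter=0)
        with pytest.raises(ValueError):
            AnnealingSchedule(T0=-1.0)
        with pytest.raises(ValueError):
            AnnealingSchedule(no_cooling_fraction=1.0)


class TestCreatesLoop:
    def test_reciprocal_rewire_is_loop(self, yjunction):
        # 3 drains into 1; sending 1 into 3 closes a 2-cycle
        assert o.creates_loop(yjunction, 1, 3)

    def test_no_op_is_not_loop(self, yjunction):
        assert not o.creates_loop(yjunction, 3, 1)

    def test_lateral_rewire_avoiding_source_ok(self, yjunction):
        # 2 currently drains into 1; rewiring 2 to the outlet is legal
        assert not o.creates_loop(yjunction, 2, 0)

    def test_non_neighbor_rejected(self):
        lat = build_lattice(5, 5, outlets=(("S", 0),))
        flow = o.initial_flow(lat)
        with pytest.raises(ValueError):
            o.creates_loop(flow, lat.index(4, 4), lat.index(0, 0))

    def test_outlet_never_rewired(self, chain4):
        with pytest.raises(ValueError):
            o.creates_loop(chain4, 0, 1)


class TestDeltaEnergy:
    def test_no_op_is_zero(self, yjunction):
        state = make_state(yjunction)
        assert delta_energy(state, 3, 1) == pytest.approx(0.0)

    @pytest.mark.parametrize("gamma", [0.5, 1.0])
    def test_matches_full_recomputation(self, gamma):
        """Incremental dH along the affected paths equals a from-scratch
        energy difference for random legal rewires on a 6x6 field."""
        flow = random_flow(6, 6, seed=3, n_moves=40)
        nbr, count, _ = neighbor_table(flow.lattice)
        rng = np.random.default_rng(11)
        non_outlet = np.setdiff1d(
            np.arange(flow.lattice.n_pixels), np.array(flow.lattice.outlets)
        )
        checked = 0
        while checked < 20:
            i = int(rng.choice(non_outlet))
            opts = [int(j) for j in nbr[i, : count[i]] if j != flow.receiver[i]]
            j = int(rng.choice(opts))
            if o.creates_loop(flow, i, j):
                continue
            state = make_state(flow, gamma)
            dH = delta_energy(state, i, j)
            after = flow.copy()
            after.receiver[i] = j
            H_after = energy(accumulate_areas(after), gamma)
            assert dH == pytest.approx(H_after - state.H, rel=1e-12, abs=1e-12)
            flow = after
            checked += 1

    def test_illegal_rewire_rejected(self, yjunction):
        state = make_state(yjunction)
        with pytest.raises(ValueError):
            delta_energy(state, 1, 3)


class TestAnneal:
    def test_greedy_energy_never_increases(self):
        lat = build_lattice(10, 10, outlets=(("S", 5),))
        sched = AnnealingSchedule(n_iter=4000, T0=1e-12, seed=2)
        state = o.anneal(o.initial_flow(lat), schedule=sched)
        assert np.all(np.diff(state.history["H"]) <= 1e-9)

    def test_same_seed_same_result(self):
        lat = build_lattice(10, 10, outlets=(("S", 5),))
        flow = o.initial_flow(lat)
        sched = AnnealingSchedule(n_iter=5000, seed=42)
        a = o.anneal(flow, schedule=sched)
        b = o.anneal(flow, schedule=sched)
        assert np.array_equal(a.flow.receiver, b.flow.receiver)
        assert a.H == b.H

    def test_energy_decreases_on_default_schedule(self):
        lat = build_lattice(12, 12, outlets=(("S", 6),))
        state = o.anneal(o.initial_flow(lat), schedule=AnnealingSchedule(seed=5))
        assert state.H < state.history["H"].iloc[0]

    def test_tree_and_incremental_energy_hold_at_checkpoints(self):
        """After ~1e4 moves on a 10x10 lattice, the spanning-tree invariant
        holds at every checkpoint and the incrementally maintained energy
        matches a full recomputation."""
        lat = build_lattice(10, 10, outlets=(("S", 5),))
        sched = AnnealingSchedule(n_iter=10_000, seed=3, record_every=500)
        state = o.anneal(
            o.initial_flow(lat), schedule=sched, validate_checkpoints=True
        )
        assert abs(state.H - state.energy_check()) <= 1e-6 * state.H
        assert state.areas.A[list(lat.outlets)].sum() == lat.n_pixels

    def test_initial_state_heritage_under_fast_cooling(self):
        """With fast cooling the final networks retain the heritage of
        their distinct initial styles (feasible optimality)."""
        lat = build_lattice(12, 12, outlets=(("S", 6),))
        sched = AnnealingSchedule(cooling_rate=1e6, seed=9, T0=1e-9)
        a = o.anneal(o.initial_flow(lat, "I"), schedule=sched)
        b = o.anneal(o.initial_flow(lat, "V"), schedule=sched)
        assert not np.array_equal(a.flow.receiver, b.flow.receiver)

    def test_history_records_iteration_H_T(self):
        lat = build_lattice(8, 8, outlets=(("S", 0),))
        sched = AnnealingSchedule(n_iter=1000, record_every=100, seed=0)
        state = o.anneal(o.initial_flow(lat), schedule=sched)
        h = state.history
        assert list(h.columns) == ["iteration", "H", "T", "n_accepted"]
        assert h["iteration"].iloc[-1] == 1000
        assert h["n_accepted"].is_monotonic_increasing

    def test_invalid_flow_rejected(self, chain4):
        bad = chain4.copy()
        bad.receiver[2] = -1
        with pytest.raises(ValueError):
            o.anneal(bad)
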