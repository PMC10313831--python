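"""Unit and property tests of the lattice chain: queries, propensities, SSA."""

import numpy as np
import pytest

import oracles
from rpalattice.lattice import (
    LatticeState,
    Mode,
    NoEventPossible,
    Phase,
    Protocol,
    RateSet,
    ensemble,
    extendable,
    free_windows,
    propensities,
    simulate,
    ssa_step,
    three_step_protocol,
)


class TestFreeWindows:
    def test_empty_lattice_counts_all_starts(self):
        state = LatticeState(100)
        assert free_windows(state, 20) == set(range(81))

    def test_one_molecule_blocks_left_windows(self, state_factory):
        state = state_factory(60, (0, 20))
        assert free_windows(state, 20) == set(range(20, 41))

    def test_width_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            free_windows(LatticeState(50), 0)
        with pytest.raises(ValueError):
            free_windows(LatticeState(50), 51)

    def test_matches_per_site_scan_on_random_states(self, rng):
        for _ in range(200):
            L = int(rng.integers(20, 81))
            state = oracles.random_state(rng, L)
            width = int(rng.integers(1, min(L, 30) + 1))
            assert free_windows(state, width) == oracles.scan_free_windows(state, width)


class TestExtendable:
    def test_footprint_must_fit_on_lattice(self, state_factory):
        state = state_factory(25, (0, 20))
        assert extendable(state) == set()

    def test_blocked_by_close_downstream_neighbor(self, state_factory):
        state = state_factory(60, (0, 20), (25, 20))
        ext = extendable(state)
        assert {m.start for m in ext} == {25}

    def test_matches_per_molecule_scan(self, rng):
        for _ in range(200):
            state = oracles.random_state(rng, int(rng.integers(20, 81)))
            assert extendable(state) == oracles.scan_extendable(state)


class TestPropensities:
    def test_empty_lattice_fold_zero_is_absorbing(self, basic_rates):
        assert propensities(LatticeState(100), basic_rates, 0.0) == (0, 0, 0, 0)

    def test_hand_counted_single_flbm30(self, state_factory, basic_rates):
        # FLBM30 on [0,30) of L=60: free run [30,60) admits 11 starts of width 20
        state = state_factory(60, (0, 30))
        a = propensities(state, basic_rates, 2.0)
        assert a[0] == pytest.approx(2.0 * basic_rates.k_bind * 11)
        assert a[1] == 0.0
        assert a[2] == 0.0
        assert a[3] == pytest.approx(basic_rates.k_retr)

    def test_matches_oracle_recomputation(self, rng, basic_rates):
        for _ in range(100):
            state = oracles.random_state(rng, int(rng.integers(20, 81)))
            a = propensities(state, basic_rates, 3.0)
            n_win = len(oracles.scan_free_windows(state, 20))
            n_ext = len(oracles.scan_extendable(state))
            assert a[0] == pytest.approx(3.0 * basic_rates.k_bind * n_win)
            assert a[1] == pytest.approx(basic_rates.k_off20 * state.n20)
            assert a[2] == pytest.approx(basic_rates.k_ext * n_ext)
            assert a[3] == pytest.approx(basic_rates.k_retr * state.n30)


class TestSsaStep:
    def test_single_channel_exponential_waiting_time(self, rng, state_factory):
        state = state_factory(60, (10, 20))
        rates = RateSet("off-only", 0.0, 2.0, 0.0, 0.0)
        taus = []
        for _ in range(4000):
            event, tau, new = ssa_step(state, rates, 0.0, rng)
            assert event == "unbind"
            assert new.molecules == []
            taus.append(tau)
        # mean 1/k_off20 = 0.5 within 4 standard errors
        assert np.mean(taus) == pytest.approx(0.5, abs=4 * 0.5 / np.sqrt(len(taus)))

    def test_zero_propensity_signals_no_event(self, rng):
        with pytest.raises(NoEventPossible):
            ssa_step(LatticeState(100), RateSet("dead", 1e-3, 0, 0, 0), 0.0, rng)

    def test_irreversible_binding_jams_without_overlap(self, rng):
        rates = RateSet("rsa", 1.0, 0.0, 0.0, 0.0)
        state = LatticeState(120)
        while True:
            try:
                _, _, state = ssa_step(state, rates, 1.0, rng)
            except NoEventPossible:
                break
            state.validate()
        assert len(free_windows(state, 20)) == 0
        assert all(m.mode is Mode.PBM20 for m in state.molecules)

    def test_state_invariants_hold_along_random_trajectories(self, rng, basic_rates):
        state = LatticeState(90)
        occupied_plus_free = []
        for _ in range(300):
            try:
                _, _, state = ssa_step(state, basic_rates, 5.0, rng)
            except NoEventPossible:
                break
            state.validate()
            occupied_plus_free.append(state.occupied_nt + state.free_nt)
        assert set(occupied_plus_free) == {90}


class TestSimulate:
    def test_fold_zero_protocol_stays_empty(self):
        proto = Protocol((Phase(100.0, 0.0, "r"),), reference_time=50.0)
        rates = {"r": RateSet("r", 1.0, 0.1, 0.1, 0.1)}
        traj = simulate(proto, rates, 200, seed=7, sample_dt=10.0)
        assert traj.n20.sum() == 0 and traj.n30.sum() == 0
        assert np.all(traj.free_fraction == 1.0)

    def test_equal_seeds_give_bit_identical_trajectories(self, basic_rates):
        proto = three_step_protocol(5.0, "test", pre_label="test",
                                    pre_duration=200.0, treat_duration=100.0)
        rates = {"test": basic_rates}
        a = simulate(proto, rates, 500, seed=42, sample_dt=5.0,
                     snapshot_times=(200.0,))
        b = simulate(proto, rates, 500, seed=42, sample_dt=5.0,
                     snapshot_times=(200.0,))
        assert np.array_equal(a.n20, b.n20)
        assert np.array_equal(a.n30, b.n30)
        assert a.snapshots[200.0].molecules == b.snapshots[200.0].molecules

    def test_unknown_rate_label_is_a_configuration_error(self, basic_rates):
        proto = Protocol((Phase(10.0, 1.0, "nope"),), reference_time=5.0)
        with pytest.raises(KeyError):
            simulate(proto, {"test": basic_rates}, 100, seed=1)

    def test_site_conservation_at_every_sample(self, basic_rates):
        proto = three_step_protocol(10.0, "test", pre_label="test",
                                    pre_duration=300.0, treat_duration=200.0)
        traj = simulate(proto, {"test": basic_rates}, 400, seed=3, sample_dt=7.0)
        occupied = 20 * traj.n20 + 30 * traj.n30
        free = traj.free_fraction * traj.L
        np.testing.assert_allclose(occupied + free, traj.L, rtol=0, atol=1e-9)

    def test_snapshots_match_sampled_counts(self, basic_rates):
        proto = Protocol((Phase(500.0, 2.0, "test"),), reference_time=250.0)
        traj = simulate(proto, {"test": basic_rates}, 300, seed=11,
                        sample_dt=50.0, snapshot_times=(250.0,))
        snap = traj.snapshots[250.0]
        idx = int(np.argmin(np.abs(traj.times - 250.0)))
        assert snap.n20 == traj.n20[idx]
        assert snap.n30 == traj.n30[idx]


class TestEnsemble:
    def test_single_replicate_summary_is_that_trajectory(self, basic_rates):
        proto = Protocol((Phase(200.0, 1.0, "test"),), reference_time=100.0)
        ens = ensemble(proto, {"test": basic_rates}, 300, n_rep=1, seed_base=5,
                       sample_dt=20.0)
        np.testing.assert_array_equal(ens.mean["n20"], ens.trajectories[0].n20)
        assert np.all(ens.sd["n20"] == 0.0)

    def test_mean_bound_count_monotone_in_fold(self, basic_rates):
        # low-density regime: more free RPA binds more, within MC error
        means = []
        for fold in (1.0, 4.0, 10.0, 25.0):
            proto = Protocol((Phase(100.0, fold, "test"),), reference_time=50.0)
            ens = ensemble(proto, {"test": basic_rates}, 400, n_rep=30,
                           seed_base=100, sample_dt=25.0)
            means.append(ens.mean["n_bound"][-1])
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_low_density_binding_scales_linearly_with_fold(self):
        # expected first-order count ~ fold * k_bind * (L-19) * t while coverage ~ 0
        rates = {"r": RateSet("r", 1e-6, 0.0, 0.0, 0.0)}
        L, t = 2000, 50.0
        expected_slope = 1e-6 * (L - 19) * t
        for fold in (1.0, 4.0):
            proto = Protocol((Phase(t, fold, "r"),), reference_time=t / 2)
            ens = ensemble(proto, rates, L, n_rep=200, seed_base=0, sample_dt=t)
            mean = ens.mean["n_bound"][-1]
            expect = fold * expected_slope
            sem = ens.sd["n_bound"][-1] / np.sqrt(200)
            assert mean == pytest.approx(expect, abs=max(4 * sem, 0.05 * expect))
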