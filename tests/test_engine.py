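"""SSA engine tests: statistics of waiting times, selection, and the
continuous-time Markov-chain oracle on an enumerable lattice."""

import itertools
import math

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import binomtest

from isletsim.engine import build, check_consistency, run_until, step
from isletsim.lattice import (
    HEALTHY,
    INFINITE_TAU,
    TUMOR,
    EventKind,
    Lattice,
    ModelParams,
    enumerate_events,
    propensity,
)
from conftest import random_lattice


def single_voxel_lattice(dx=0.3) -> Lattice:
    states = np.zeros((3, 3, 3), np.int8)
    states[1, 1, 1] = TUMOR
    return Lattice(states, dx, periodic=(True, True, True))


JUMP_ONLY = ModelParams(
    kBT=0.3167, tau_jump=3.178, tau_dup=INFINITE_TAU, tau_die=INFINITE_TAU,
    tend=5.0, dx=0.3,
)


class TestBuild:
    def test_all_healthy_has_zero_propensity(self, cube3):
        st = build(cube3, JUMP_ONLY, seed=0)
        assert st.total_propensity == 0.0

    def test_isolated_voxel_jump_only_total(self):
        st = build(single_voxel_lattice(), JUMP_ONLY, seed=0)
        assert st.total_propensity == pytest.approx(6 / 3.178)

    def test_rebuild_is_deterministic(self):
        rng = np.random.default_rng(0)
        lat = random_lattice(rng)
        p = JUMP_ONLY.with_(tau_dup=1.0, tau_die=0.5, dx=0.5)
        a = build(lat, p, seed=1)
        b = build(lat, p, seed=2)  # seed affects trajectory, not the index
        np.testing.assert_array_equal(a.tree, b.tree)

    def test_spacing_mismatch_rejected(self, cube3):
        with pytest.raises(ValueError):
            build(cube3, JUMP_ONLY.with_(dx=0.25), seed=0)

    def test_index_matches_reference_propensities(self):
        rng = np.random.default_rng(21)
        p = ModelParams(kBT=0.8, tau_jump=2.0, tau_dup=1.5, tau_die=0.7, dx=0.5)
        for periodic in (False, True):
            lat = random_lattice(rng, periodic=periodic)
            st = build(lat, p, seed=0)
            assert check_consistency(st) < 1e-9


class TestStep:
    def test_tend_zero_changes_nothing(self, center_tumor):
        st = build(center_tumor, JUMP_ONLY.with_(tend=0.0), seed=3)
        before = st.lattice.states.copy()
        run_until(st)
        np.testing.assert_array_equal(st.lattice.states, before)
        assert st.clock == 0.0

    def test_absorbing_state_jumps_to_horizon(self, cube3):
        st = build(cube3, JUMP_ONLY, seed=3)
        ev, clock = step(st, tend=5.0)
        assert ev is None and clock == 5.0

    def test_waiting_time_is_exponential(self):
        # a 1x1x1 lattice with one tumor voxel has exactly one event (DIE)
        # with rate 1/tau_die (no neighbours, dE = 0)
        lat = Lattice(np.full((1, 1, 1), TUMOR, np.int8), 0.5)
        p = ModelParams(kBT=1.0, tau_jump=INFINITE_TAU, tau_dup=INFINITE_TAU,
                        tau_die=2.0, tend=1e9, dx=0.5)
        n = 10_000
        times = np.empty(n)
        for k in range(n):
            st = build(lat, p, seed=k)
            ev, clock = step(st)
            assert ev.kind == EventKind.DIE
            times[k] = clock
        mean, se = times.mean(), times.std(ddof=1) / math.sqrt(n)
        assert abs(mean - 2.0) < 5 * se

    def test_selection_frequency_matches_rates(self):
        # 1x1x2 lattice, one tumor voxel: jump rate 1, dup rate 3 (die off)
        kbt = 1.0
        tau_dup = math.exp(2.0 / kbt) / 3.0  # dup dE = -2 -> rate 3
        lat = Lattice(np.array([[[TUMOR, HEALTHY]]], np.int8), 0.5)
        p = ModelParams(kBT=kbt, tau_jump=1.0, tau_dup=tau_dup,
                        tau_die=INFINITE_TAU, tend=1e9, dx=0.5)
        n = 10_000
        dup = 0
        for k in range(n):
            st = build(lat, p, seed=k)
            ev, _ = step(st)
            dup += ev.kind == EventKind.DUP
        assert binomtest(dup, n, 0.75).pvalue > 1e-3

    def test_mean_event_count_is_poisson(self):
        # constant-rate walker: fired events ~ Poisson(6 T / tau_jump)
        lam = 6 * 5.0 / 3.178
        n = 256
        counts = np.empty(n)
        for k in range(n):
            st = build(single_voxel_lattice(), JUMP_ONLY, seed=k)
            run_until(st, 5.0)
            counts[k] = st.counts.sum()
        se = math.sqrt(lam / n)
        assert abs(counts.mean() - lam) < 4 * se

    def test_reproducible_trajectories(self):
        rng = np.random.default_rng(5)
        lat = random_lattice(rng, shape=(5, 5, 5))
        p = ModelParams(kBT=0.9, tau_jump=1.0, tau_dup=1.2, tau_die=0.8,
                        tend=2.0, dx=0.5)
        a = run_until(build(lat, p, seed=77))
        b = run_until(build(lat, p, seed=77))
        np.testing.assert_array_equal(a.lattice.states, b.lattice.states)
        assert a.clock == b.clock
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_index_stays_consistent_along_trajectory(self):
        rng = np.random.default_rng(9)
        lat = random_lattice(rng, shape=(5, 5, 5))
        p = ModelParams(kBT=0.9, tau_jump=1.0, tau_dup=1.2, tau_die=0.8,
                        tend=50.0, dx=0.5)
        st = build(lat, p, seed=123)
        for _ in range(60):
            ev, _ = step(st)
            if ev is None:
                break
            assert check_consistency(st) < 1e-9

    def test_stepwise_equals_batch_run(self):
        rng = np.random.default_rng(14)
        lat = random_lattice(rng, shape=(4, 4, 4))
        p = ModelParams(kBT=0.8, tau_jump=1.0, tau_dup=1.0, tau_die=1.0,
                        tend=1.0, dx=0.5)
        batch = run_until(build(lat, p, seed=5))
        st = build(lat, p, seed=5)
        while step(st)[0] is not None:
            pass
        np.testing.assert_array_equal(st.lattice.states, batch.lattice.states)


class TestEventLog:
    def test_log_matches_counts(self):
        st = build(single_voxel_lattice(), JUMP_ONLY, seed=8)
        run_until(st, 5.0, record=True)
        assert len(st.event_log) == st.counts.sum()
        assert (st.event_log["kind"] == "jump").all()
        assert st.event_log["time"].is_monotonic_increasing

    def test_max_events_truncates(self):
        st = build(single_voxel_lattice(), JUMP_ONLY, seed=8)
        run_until(st, 5.0, max_events=3)
        assert st.counts.sum() == 3
        assert st.clock < 5.0


def ctmc_distribution(lat_shape, params, t_end, init_mask):
    """Exact end-state law of the lattice CTMC by matrix exponential.

    Enumerates every tumor-configuration of the (tiny) lattice, assembles
    the generator from the reference propensities, and exponentiates.
    """
    n_sites = int(np.prod(lat_shape))
    sites = list(itertools.product(*[range(s) for s in lat_shape]))
    n_states = 2**n_sites

    def lattice_of(mask):
        states = np.zeros(lat_shape, np.int8)
        for b, s in enumerate(sites):
            if mask >> b & 1:
                states[s] = TUMOR
        return Lattice(states, params.dx)

    def mask_after(mask, ev):
        out = mask
        if ev.kind in (EventKind.DIE, EventKind.JUMP):
            out &= ~(1 << sites.index(ev.source))
        if ev.kind in (EventKind.DUP, EventKind.JUMP):
            out |= 1 << sites.index(ev.target)
        return out

    Q = np.zeros((n_states, n_states))
    for mask in range(n_states):
        lat = lattice_of(mask)
        for s in sites:
            for ev in enumerate_events(lat, s):
                rate = propensity(ev, lat, params)
                if rate > 0:
                    Q[mask, mask_after(mask, ev)] += rate
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    return expm(Q * t_end)[init_mask]


class TestCTMCOracle:
    def test_end_state_distribution_matches_matrix_exponential(self):
        """Empirical SSA end-state law on a 1x1x3 lattice (jump + die)
        agrees with the exact generator solution within 3 MC standard
        errors per configuration."""
        shape = (1, 1, 3)
        params = ModelParams(kBT=1.0, tau_jump=1.0, tau_dup=INFINITE_TAU,
                             tau_die=2.0, tend=0.8, dx=0.5)
        t_end = 0.8
        init = np.zeros(shape, np.int8)
        init[0, 0, 1] = TUMOR
        init_mask = 1 << 1  # site order: (0,0,0), (0,0,1), (0,0,2)

        exact = ctmc_distribution(shape, params, t_end, init_mask)

        n = 10_000
        freq = np.zeros(2**3)
        for k in range(n):
            st = build(Lattice(init.copy(), 0.5), params, seed=k)
            run_until(st, t_end)
            final = st.lattice.states
            mask = sum(1 << b for b in range(3) if final[0, 0, b] == TUMOR)
            freq[mask] += 1
        freq /= n

        for mask in range(8):
            se = math.sqrt(max(exact[mask] * (1 - exact[mask]), 1e-12) / n)
            assert abs(freq[mask] - exact[mask]) <= max(3 * se, 1e-9), (
                f"state {mask:03b}: empirical {freq[mask]:.4f} "
                f"vs exact {exact[mask]:.4f}"
            )

    def test_two_state_toy(self):
        """Single site with death only: P(alive at t) = exp(-t/tau)."""
        lat = Lattice(np.full((1, 1, 1), TUMOR, np.int8), 0.5)
        p = ModelParams(kBT=1.0, tau_jump=INFINITE_TAU, tau_dup=INFINITE_TAU,
                        tau_die=1.0, tend=0.7, dx=0.5)
        n = 10_000
        alive = 0
        for k in range(n):
            st = run_until(build(lat, p, seed=k))
            alive += st.lattice.states[0, 0, 0] == TUMOR
        expect = math.exp(-0.7)
        se = math.sqrt(expect * (1 - expect) / n)
        assert abs(alive / n - expect) <= 3 * se
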