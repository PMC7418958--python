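"""Micro-dynamics: credibility, influence, gossip, pairing, iterations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leviathan import (
    EsteemState,
    GroupAssignment,
    ModelParams,
    credibility,
    fixture_state,
    gossip,
    influence,
    interaction,
    run_iteration,
    run_simulation,
    select_partner,
)
from leviathan import dynamics as dyn


class TestCredibility:
    @pytest.mark.parametrize("sigma", [0.01, 0.1, 1.0, 3.0, 100.0])
    def test_zero_difference_gives_half(self, sigma):
        assert credibility(0.3, 0.3, sigma) == 0.5

    @pytest.mark.parametrize(
        "diff, sigma, expected, places",
        [
            (+0.1, 3.0, 0.5, 1),  # very open-minded: status barely matters
            (-0.1, 3.0, 0.5, 1),
            (-0.1, 0.05, 0.1, 1),  # status-sensitive: lower speaker dismissed
            (+0.1, 0.05, 0.8808, 4),  # logistic evaluated directly
        ],
    )
    def test_anchor_values(self, diff, sigma, expected, places):
        assert round(credibility(diff, 0.0, sigma), places) == pytest.approx(expected)

    def test_limits(self):
        assert credibility(1.0, -1.0, 0.01) > 1 - 1e-12
        assert credibility(-1.0, 1.0, 0.01) < 1e-12
        # huge sigma flattens the curve entirely
        assert abs(credibility(0.1, 0.0, 1e3) - 0.5) < 1e-3

    def test_rejects_bad_sigma(self):
        with pytest.raises(ValueError):
            credibility(0.1, 0.0, 0.0)
        with pytest.raises(ValueError):
            credibility(0.1, 0.0, -1.0)

    def test_vectorized(self):
        d = np.linspace(-1, 1, 11)
        p = credibility(d, 0.0, 0.5)
        assert p.shape == d.shape
        assert np.all(np.diff(p) > 0)

    @given(
        d=st.floats(-5, 5, allow_nan=False),
        sigma=st.floats(0.01, 100, allow_nan=False),
    )
    @settings(max_examples=200, derandomize=True)
    def test_complement_identity(self, d, sigma):
        assert credibility(d, 0.0, sigma) + credibility(-d, 0.0, sigma) == pytest.approx(
            1.0, abs=1e-12
        )

    @given(
        d1=st.floats(-3, 3, allow_nan=False),
        d2=st.floats(-3, 3, allow_nan=False),
        sigma=st.floats(0.01, 50, allow_nan=False),
    )
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_difference(self, d1, d2, sigma):
        lo, hi = sorted([d1, d2])
        assert credibility(lo, 0.0, sigma) <= credibility(hi, 0.0, sigma)


class TestInfluence:
    def test_zero_state_is_fixed_point_without_noise(self, rng):
        params = ModelParams(
            n_agents=4, n_small=2, n_large=2, noise_half_width=0.0, gossip_count=0
        )
        groups = GroupAssignment.from_params(params)
        state = EsteemState.zeros(4)
        influence(state, 0, 1, params, groups, rng)
        assert np.all(state.a == 0.0)

    def test_worked_example(self, rng):
        # listener 0 sees speaker 1 at equal esteem -> p = 0.5 for any sigma;
        # speaker esteems listener at 0.4 and itself at -0.2
        state, groups = fixture_state("worked_example")
        params = ModelParams(
            n_agents=2, n_small=1, n_large=1, noise_half_width=0.0, gossip_count=0
        )
        influence(state, 0, 1, params, groups, rng)
        assert state.a[0, 0] == pytest.approx(0.2)
        assert state.a[0, 1] == pytest.approx(-0.1)
        # speaker row untouched
        assert state.a[1, 0] == 0.4 and state.a[1, 1] == -0.2

    def test_rejects_self_influence(self, small_params, small_groups, rng):
        state = EsteemState.zeros(6)
        with pytest.raises(ValueError):
            influence(state, 2, 2, small_params, small_groups, rng)

    def test_clipping_engages_at_bounds(self):
        # near-saturated listener pushed past the ceiling by noise must be
        # clipped exactly to the bound, never beyond
        params = ModelParams(
            n_agents=2, n_small=1, n_large=1, sigma_small=0.001, sigma_large=0.001,
            noise_half_width=0.5, gossip_count=0,
        )
        groups = GroupAssignment.from_params(params)
        hit_bound = False
        for seed in range(50):
            state = EsteemState.zeros(2)
            state.a[0, 0] = 0.95
            state.a[0, 1] = 1.0  # perceived far above self -> p ~ 1
            state.a[1, 0] = 1.0
            state.a[1, 1] = 1.0
            influence(state, 0, 1, params, groups, np.random.default_rng(seed))
            assert np.all(state.a <= 1.0) and np.all(state.a >= -1.0)
            hit_bound = hit_bound or state.a[0, 0] == 1.0
        assert hit_bound


class TestGossip:
    def test_k_zero_is_identity(self, small_groups, rng):
        params = ModelParams(
            n_agents=6, n_small=3, n_large=3, gossip_count=0, noise_half_width=0.2
        )
        state, _ = fixture_state("random_small", seed=3)
        before = state.a.copy()
        gossip(state, 0, 1, params, small_groups, rng)
        assert np.array_equal(state.a, before)

    def test_three_agent_forced_target(self, rng):
        # with N = 3 and pair (0, 1) the only gossip target is agent 2
        params = ModelParams(
            n_agents=3, n_small=1, n_large=2, gossip_count=1, noise_half_width=0.0
        )
        groups = GroupAssignment.from_params(params)
        state = EsteemState.zeros(3)
        state.a[1, 2] = 0.6  # speaker's esteem of the third party
        gossip(state, 0, 1, params, groups, rng)
        assert state.a[0, 2] == pytest.approx(0.3)  # p = 0.5, pulled halfway

    def test_identical_rows_are_invariant_without_noise(self, rng):
        params = ModelParams(
            n_agents=6, n_small=3, n_large=3, gossip_count=5, noise_half_width=0.0
        )
        groups = GroupAssignment.from_params(params)
        state, _ = fixture_state("random_small", seed=4)
        state.a[1] = state.a[0]  # speaker agrees with listener on everyone
        before = state.a.copy()
        gossip(state, 0, 1, params, groups, rng)
        assert np.allclose(state.a, before)

    def test_too_few_agents_rejected(self, rng):
        # a 2-agent state leaves no valid third party z
        params = ModelParams(n_agents=3, n_small=1, n_large=2, gossip_count=1)
        groups = GroupAssignment.from_params(params)
        state = EsteemState.zeros(2)
        with pytest.raises(ValueError):
            gossip(state, 0, 1, params, groups, rng)


class TestSelectPartner:
    def test_mixing_frequency_matches_coin(self):
        params = ModelParams(n_agents=40, n_small=20, n_large=20)
        groups = GroupAssignment.from_params(params)
        rng = np.random.default_rng(123)
        n_draws = 100_000
        labels = groups.labels
        same = 0
        for _ in range(n_draws):
            j = select_partner(5, groups, params, rng)
            assert j != 5
            same += labels[j] == labels[5]
        se = np.sqrt(0.25 / n_draws)
        assert abs(same / n_draws - 0.5) < 3 * se

    def test_singleton_group_falls_back(self):
        params = ModelParams(n_agents=4, n_small=1, n_large=3)
        groups = GroupAssignment.from_params(params)
        rng = np.random.default_rng(5)
        partners = {select_partner(0, groups, params, rng) for _ in range(200)}
        assert partners == {1, 2, 3}  # only L-group members, never self

    def test_single_group_population_uniform(self):
        params = ModelParams(n_agents=5, n_small=0, n_large=5)
        groups = GroupAssignment.from_params(params)
        rng = np.random.default_rng(5)
        partners = {select_partner(2, groups, params, rng) for _ in range(500)}
        assert partners == {0, 1, 3, 4}

    def test_uniform_pairing_covers_everyone(self):
        params = ModelParams(n_agents=6, n_small=3, n_large=3, pair_selection="uniform")
        groups = GroupAssignment.from_params(params)
        rng = np.random.default_rng(5)
        partners = {select_partner(3, groups, params, rng) for _ in range(500)}
        assert partners == {0, 1, 2, 4, 5}


class TestInteraction:
    def test_locality_without_gossip(self, rng):
        params = ModelParams(
            n_agents=6, n_small=3, n_large=3, gossip_count=0, noise_half_width=0.2
        )
        groups = GroupAssignment.from_params(params)
        state, _ = fixture_state("random_small", seed=9)
        before = state.a.copy()
        interaction(state, 1, 4, params, groups, rng)
        changed = np.argwhere(state.a != before)
        assert {tuple(rc) for rc in changed} <= {(1, 1), (1, 4), (4, 4), (4, 1)}

    def test_sequential_composition_matches_manual_chain(self):
        # the four sub-steps applied one by one must equal interaction()
        params = ModelParams(
            n_agents=6, n_small=3, n_large=3, gossip_count=2, noise_half_width=0.2
        )
        groups = GroupAssignment.from_params(params)
        s1, _ = fixture_state("random_small", seed=11)
        s2 = s1.copy()
        rng_a = np.random.default_rng(42)
        rng_b = np.random.default_rng(42)
        interaction(s1, 0, 3, params, groups, rng_a)
        influence(s2, 0, 3, params, groups, rng_b)
        influence(s2, 3, 0, params, groups, rng_b)
        gossip(s2, 0, 3, params, groups, rng_b)
        gossip(s2, 3, 0, params, groups, rng_b)
        assert np.array_equal(s1.a, s2.a)


class TestIterationAndSimulation:
    def test_interactions_per_iteration(self, monkeypatch):
        calls = []
        real = dyn.interaction
        monkeypatch.setattr(
            dyn, "interaction", lambda *args: calls.append(1) or real(*args)
        )
        for n, expected in [(40, 20), (7, 3)]:
            calls.clear()
            params = ModelParams(
                n_agents=n, n_small=n // 2, n_large=n - n // 2, gossip_count=0
            )
            groups = GroupAssignment.from_params(params)
            state = EsteemState.zeros(n)
            run_iteration(state, params, groups, np.random.default_rng(1))
            assert len(calls) == expected
            assert state.t == 1

    def test_zero_state_fixed_point_without_noise(self):
        params = ModelParams(
            n_agents=6, n_small=3, n_large=3, noise_half_width=0.0,
            n_iterations=50, measure_every=10,
        )
        series = run_simulation(params, engine="python")
        assert np.all(series.snapshots == 0.0)

    def test_zero_iterations_yields_initial_snapshot_only(self):
        params = ModelParams(n_iterations=0, measure_every=10)
        series = run_simulation(params)
        assert series.n_snapshots == 1
        assert series.times[0] == 0
        assert np.all(series.snapshots[0] == 0.0)

    def test_deterministic_reruns(self, small_params):
        a = run_simulation(small_params)
        b = run_simulation(small_params)
        assert np.array_equal(a.snapshots, b.snapshots)
        assert np.array_equal(a.times, b.times)

    @pytest.mark.parametrize("pair_selection", ["group-coin", "uniform"])
    def test_reference_oracle_equivalence(self, pair_selection):
        """The naive per-operation loop and the compiled engine must agree
        entry-wise over a 6-agent, 100-iteration run with a shared seed."""
        params = ModelParams(
            n_agents=6, n_small=3, n_large=3, sigma_small=0.1, sigma_large=0.15,
            noise_half_width=0.2, gossip_count=3, pair_selection=pair_selection,
            n_iterations=100, measure_every=10, seed=7,
        )
        ref = run_simulation(params, engine="python")
        fast = run_simulation(params, engine="numba")
        assert np.array_equal(ref.snapshots, fast.snapshots)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {},
            {"pair_selection": "uniform"},
            {"n_small": 5, "n_large": 35, "gossip_count": 0},
            {"noise_half_width": 0.5, "sigma_small": 0.03, "sigma_large": 0.045},
        ],
    )
    def test_boundedness(self, kwargs):
        params = ModelParams(n_iterations=2000, measure_every=200, seed=3, **kwargs)
        series = run_simulation(params)
        lo, hi = params.esteem_bounds
        assert series.snapshots.min() >= lo
        assert series.snapshots.max() <= hi

    def test_stationary_window_selects_trailing_half(self, small_params):
        series = run_simulation(small_params)
        idx = series.stationary_indices()
        assert idx[0] == series.n_snapshots // 2
        assert idx[-1] == series.n_snapshots - 1


class TestParamsValidation:
    def test_partition_enforced(self):
        with pytest.raises(ValueError):
            ModelParams(n_agents=40, n_small=25, n_large=25)

    def test_sigma_positive(self):
        with pytest.raises(ValueError):
            ModelParams(sigma_small=0.0)

    def test_bounds_ordered(self):
        with pytest.raises(ValueError):
            ModelParams(esteem_bounds=(1.0, -1.0))

    def test_gossip_needs_third_party(self):
        with pytest.raises(ValueError):
            ModelParams(n_agents=2, n_small=1, n_large=1, gossip_count=1)

    def test_group_assignment_counts(self):
        params = ModelParams(n_agents=10, n_small=4, n_large=6)
        groups = GroupAssignment.from_params(params)
        assert (groups.labels == "S").sum() == 4
        assert (groups.labels == "L").sum() == 6
        assert groups.sigma_of(0) == params.sigma_small
        assert groups.sigma_of(9) == params.sigma_large
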