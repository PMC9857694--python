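"""The EMA solver: E-step, A-step, M-step, convergence, and invariants."""

import numpy as np
import pytest

from emaplex import EmaConfig, mask_nodes, run_ema
from emaplex.ema import (
    DegenerateLayerError,
    ReconstructionState,
    _aggregate_from_observations,
    a_step,
    convergence_error,
    e_step,
    init_state,
    m_step_approx,
    m_step_exact,
)

from conftest import random_multiplex


def _blank_state(n, m_layers, d, e_est):
    return ReconstructionState(
        p=[np.zeros((n, n)) for _ in range(m_layers)],
        prior_p=[np.zeros((n, n)) for _ in range(m_layers)],
        d=[np.asarray(di, dtype=float) for di in d],
        edge_count_est=list(e_est),
        aggregate=np.full((n, n), -1, dtype=np.int8),
    )


@pytest.fixture
def obs_half():
    net = random_multiplex(12, 2, 0.3, seed=2)
    return net, mask_nodes(net, 0.5, rng_seed=4)


class TestInitState:
    def test_full_observation_leaves_nothing_to_infer(self):
        net = random_multiplex(8, 2, 0.4, seed=1)
        obs = mask_nodes(net, 1.0, rng_seed=0)
        st = init_state(obs, EmaConfig(rng_seed=0))
        for p, a in zip(st.p, net.adjacency):
            off = ~np.eye(8, dtype=bool)
            np.testing.assert_array_equal(p[off], a[off].astype(float))

    def test_deterministic_given_seed(self, obs_half):
        _, obs = obs_half
        s1 = init_state(obs, EmaConfig(rng_seed=5))
        s2 = init_state(obs, EmaConfig(rng_seed=5))
        for a, b in zip(s1.p, s2.p):
            np.testing.assert_array_equal(a, b)
        for a, b in zip(s1.d, s2.d):
            np.testing.assert_array_equal(a, b)

    def test_aggregate_or_rule(self):
        net = random_multiplex(6, 2, 0.0, seed=0)
        net.adjacency[0][0, 1] = net.adjacency[0][1, 0] = 1
        obs = mask_nodes(net, 1.0, rng_seed=0)
        agg = _aggregate_from_observations(obs)
        assert agg[0, 1] == 1  # a witnessed link in layer 1
        assert agg[2, 3] == 0  # observed absence in every layer

    def test_aggregate_unknown_without_full_coverage(self):
        net = random_multiplex(6, 2, 0.0, seed=0)
        obs = mask_nodes(net, 0.0, rng_seed=0)
        agg = _aggregate_from_observations(obs)
        off = ~np.eye(6, dtype=bool)
        assert (agg[off] == -1).all()


class TestESstep:
    def test_configuration_model_arithmetic(self):
        # d_i=3, d_j=4, |E|=10 -> p = 12/19
        net = random_multiplex(2, 1, 0.0, seed=0)
        obs = mask_nodes(net, 0.0, rng_seed=0)
        st = _blank_state(2, 1, [[3.0, 4.0]], [10.0])
        e_step(st, obs)
        assert st.p[0][0, 1] == pytest.approx(12 / 19)

    def test_zero_degree_gives_zero_probability(self):
        net = random_multiplex(2, 1, 0.0, seed=0)
        obs = mask_nodes(net, 0.0, rng_seed=0)
        st = _blank_state(2, 1, [[0.0, 4.0]], [10.0])
        e_step(st, obs)
        assert st.p[0][0, 1] == 0.0

    def test_capping_at_one(self):
        net = random_multiplex(2, 1, 0.0, seed=0)
        obs = mask_nodes(net, 0.0, rng_seed=0)
        st = _blank_state(2, 1, [[5.0, 5.0]], [5.0])  # 25/9 capped
        e_step(st, obs)
        assert st.p[0][0, 1] == 1.0

    def test_degenerate_layer_raises(self):
        net = random_multiplex(3, 1, 0.0, seed=0)
        obs = mask_nodes(net, 0.0, rng_seed=0)
        st = _blank_state(3, 1, [[1.0, 1.0, 1.0]], [0.25])
        with pytest.raises(DegenerateLayerError):
            e_step(st, obs)

    def test_observed_entries_clamped(self, obs_half):
        net, obs = obs_half
        st = init_state(obs, EmaConfig(rng_seed=0))
        e_step(st, obs)
        for p, x, m in zip(st.p, obs.X, obs.observed_pair_mask):
            np.testing.assert_array_equal(p[m], x[m].astype(float))


class TestAStep:
    def _two_layer_pair_state(self, p1, p2):
        net = random_multiplex(2, 2, 0.0, seed=0)
        obs = mask_nodes(net, 0.0, rng_seed=0)
        st = _blank_state(2, 2, [[1, 1], [1, 1]], [1.0, 1.0])
        for l, v in enumerate((p1, p2)):
            st.prior_p[l] = np.array([[0.0, v], [v, 0.0]])
            st.p[l] = st.prior_p[l].copy()
        st.aggregate[0, 1] = st.aggregate[1, 0] = 1
        return st, obs

    def test_bayes_update_arithmetic(self):
        # priors 0.5/0.5 with a witnessed aggregate link -> 0.5/(1-0.25)=2/3
        st, obs = self._two_layer_pair_state(0.5, 0.5)
        a_step(st, obs, "evidence")
        assert st.p[0][0, 1] == pytest.approx(2 / 3)
        assert st.p[1][0, 1] == pytest.approx(2 / 3)

    def test_certain_other_layer_is_identity(self):
        # prior 1 in layer 2 -> P(A=1)=1 -> layer-1 posterior equals prior
        st, obs = self._two_layer_pair_state(0.4, 1.0)
        a_step(st, obs, "evidence")
        assert st.p[0][0, 1] == pytest.approx(0.4)

    def test_zero_denominator_guard(self):
        st, obs = self._two_layer_pair_state(0.0, 0.0)
        a_step(st, obs, "evidence")
        assert st.p[0][0, 1] == 0.0

    def test_evidence_gating_skips_unwitnessed_pairs(self):
        st, obs = self._two_layer_pair_state(0.5, 0.5)
        st.aggregate[:] = -1
        a_step(st, obs, "evidence")
        assert st.p[0][0, 1] == pytest.approx(0.5)  # untouched
        a_step(st, obs, "all_pairs")
        assert st.p[0][0, 1] == pytest.approx(2 / 3)  # literal variant updates

    def test_single_layer_noop(self):
        net = random_multiplex(4, 1, 0.5, seed=3)
        obs = mask_nodes(net, 0.5, rng_seed=1)
        st = init_state(obs, EmaConfig(rng_seed=0))
        e_step(st, obs)
        before = st.p[0].copy()
        a_step(st, obs, "evidence")
        np.testing.assert_array_equal(before, st.p[0])

    def test_update_never_decreases_probability(self, obs_half):
        # denominator <= 1, so the Bayes update is monotone upward (pre-cap)
        net, obs = obs_half
        st = init_state(obs, EmaConfig(rng_seed=1))
        e_step(st, obs)
        before = [p.copy() for p in st.p]
        a_step(st, obs, "evidence")
        for b, p in zip(before, st.p):
            assert (p >= b - 1e-12).all()


class TestMStep:
    def test_approx_degree_is_row_sum(self):
        st = _blank_state(3, 1, [[0, 0, 0]], [1.0])
        st.p[0] = np.array([[0, 1, 2], [1, 0, 0.5], [2, 0.5, 0]], dtype=float)
        m_step_approx(st)
        np.testing.assert_allclose(st.d[0], [3.0, 1.5, 2.5])
        assert st.edge_count_est[0] == pytest.approx(3.5)
        # self-consistency: sum d = 2 |E| exactly
        assert st.d[0].sum() == pytest.approx(2 * st.edge_count_est[0], abs=1e-12)

    def test_fully_observed_recovers_true_degrees(self):
        net = random_multiplex(8, 1, 0.4, seed=6)
        obs = mask_nodes(net, 1.0, rng_seed=0)
        st = init_state(obs, EmaConfig(rng_seed=0))
        e_step(st, obs)
        m_step_approx(st)
        np.testing.assert_allclose(st.d[0], net.adjacency[0].sum(axis=1))

    def test_all_zero_probabilities(self):
        st = _blank_state(3, 1, [[1, 1, 1]], [1.0])
        m_step_approx(st)
        assert st.edge_count_est[0] == 0.0
        assert (st.d[0] == 0).all()

    def test_exact_root_value(self):
        # |E|=10, s=3 -> d = 10 - sqrt(43)
        st = _blank_state(2, 1, [[0, 0]], [10.0])
        # row sums s = 3 (entries above 1 are fine here: the update reads
        # only the sums)
        st.p[0] = np.array([[0.0, 3.0], [3.0, 0.0]])
        m_step_exact(st, update_edge_count=False)
        assert st.d[0][0] == pytest.approx(10 - np.sqrt(43))

    def test_exact_root_satisfies_fixed_point(self):
        # d (2|E| - d) = (2|E| - 1) s for the retained quadratic root
        rng = np.random.default_rng(0)
        for _ in range(50):
            e = rng.uniform(5, 500)
            s = rng.uniform(0, min(2 * e - 1, e**2 / (2 * e - 1)))
            d = e - np.sqrt(e * e - 2 * e * s + s)
            assert d * (2 * e - d) == pytest.approx((2 * e - 1) * s, rel=1e-9)

    def test_exact_zero_sum_gives_zero_degree(self):
        st = _blank_state(2, 1, [[0, 0]], [10.0])
        m_step_exact(st)
        assert (st.d[0] == 0).all()

    def test_exact_approaches_approx_for_large_edge_counts(self):
        # |E|=1000, s=3: the exact root 3.00301 agrees with the sparse
        # approximation (d = s) to well under 1%
        d = 1000 - np.sqrt(1000**2 - 2 * 1000 * 3 + 3)
        assert d == pytest.approx(3.003009, abs=1e-6)
        assert abs(d - 3.0) / 3.0 < 0.01


class TestConvergenceError:
    def _obs(self):
        net = random_multiplex(4, 1, 0.5, seed=0)
        return mask_nodes(net, 0.0, rng_seed=0)

    def test_identical_states_give_zero(self):
        obs = self._obs()
        p = [np.random.default_rng(0).random((4, 4))]
        assert convergence_error(p, [p[0].copy()], obs) == 0.0

    def test_mean_of_absolute_changes(self):
        obs = self._obs()
        prev = [np.zeros((4, 4))]
        curr = [np.zeros((4, 4))]
        curr[0][0, 1] = 0.1
        curr[0][2, 3] = 0.3
        # 6 unobserved pairs, two changed -> (0.1+0.3)/6
        assert convergence_error(prev, curr, obs) == pytest.approx(0.4 / 6)

    def test_no_unobserved_entries_returns_zero(self):
        net = random_multiplex(4, 1, 0.5, seed=0)
        obs = mask_nodes(net, 1.0, rng_seed=0)
        p = [np.zeros((4, 4))]
        q = [np.ones((4, 4))]
        assert convergence_error(p, q, obs) == 0.0


class TestRunEma:
    def test_full_observation_exact_recovery(self):
        net = random_multiplex(30, 2, 0.2, seed=8)
        obs = mask_nodes(net, 1.0, rng_seed=0)
        res = run_ema(obs, EmaConfig(rng_seed=123))
        assert res.converged and res.iterations <= 2
        for p, a in zip(res.p, net.adjacency):
            np.testing.assert_array_equal(p, a.astype(float))

    def test_recovery_independent_of_seed(self):
        net = random_multiplex(15, 2, 0.3, seed=9)
        obs = mask_nodes(net, 1.0, rng_seed=0)
        for seed in (0, 99, 1234):
            res = run_ema(obs, EmaConfig(rng_seed=seed))
            for p, a in zip(res.p, net.adjacency):
                np.testing.assert_array_equal(p, a.astype(float))

    def test_single_layer_equals_em(self):
        net = random_multiplex(20, 1, 0.2, seed=10)
        obs = mask_nodes(net, 0.5, rng_seed=2)
        ema = run_ema(obs, EmaConfig(a_step_mode="evidence", rng_seed=7))
        em = run_ema(obs, EmaConfig(a_step_mode="off", rng_seed=7))
        for a, b in zip(ema.p, em.p):
            np.testing.assert_array_equal(a, b)

    def test_probabilities_and_degrees_in_range(self):
        net = random_multiplex(25, 2, 0.15, seed=11)
        obs = mask_nodes(net, 0.4, rng_seed=3)
        res = run_ema(obs, EmaConfig(rng_seed=1))
        for p in res.p:
            assert (p >= 0).all() and (p <= 1).all()
            np.testing.assert_array_equal(p, p.T)
            assert not np.diagonal(p).any()
        for d in res.d:
            assert (d >= 0).all()

    def test_observed_entries_clamped_in_result(self):
        net = random_multiplex(25, 2, 0.15, seed=12)
        obs = mask_nodes(net, 0.5, rng_seed=5)
        res = run_ema(obs, EmaConfig(rng_seed=1))
        for p, x, m in zip(res.p, obs.X, obs.observed_pair_mask):
            np.testing.assert_array_equal(p[m], x[m].astype(float))

    def test_error_trace_one_entry_per_iteration(self):
        net = random_multiplex(20, 2, 0.2, seed=13)
        obs = mask_nodes(net, 0.5, rng_seed=6)
        res = run_ema(obs, EmaConfig(rng_seed=1, max_iterations=7))
        assert len(res.error_trace) == res.iterations

    def test_exact_m_step_runs_and_agrees_qualitatively(self):
        net = random_multiplex(20, 2, 0.2, seed=14)
        obs = mask_nodes(net, 0.5, rng_seed=6)
        res_a = run_ema(obs, EmaConfig(m_step="approx", a_step_mode="off", rng_seed=1))
        res_e = run_ema(obs, EmaConfig(m_step="exact", a_step_mode="off", rng_seed=1))
        assert res_e.converged
        # both estimate comparable total degree mass
        assert sum(d.sum() for d in res_e.d) == pytest.approx(
            sum(d.sum() for d in res_a.d), rel=0.2
        )

    def test_self_consistent_mode_keeps_mass_identity(self):
        net = random_multiplex(20, 2, 0.2, seed=15)
        obs = mask_nodes(net, 0.5, rng_seed=6)
        res = run_ema(obs, EmaConfig(edge_count_mode="self_consistent", rng_seed=1, max_iterations=5))
        for d, e in zip(res.d, res.edge_count_est):
            assert d.sum() == pytest.approx(2 * e, abs=1e-9)

    def test_known_edge_counts_mode(self):
        net = random_multiplex(20, 2, 0.2, seed=16)
        obs = mask_nodes(net, 0.5, rng_seed=6)
        cfg = EmaConfig(edge_count_mode="known",
                        known_edge_counts=[float(e) for e in net.edge_counts], rng_seed=1)
        res = run_ema(obs, cfg)
        assert res.edge_count_est == [float(e) for e in net.edge_counts]

    def test_nonconvergence_is_flagged_not_raised(self):
        net = random_multiplex(30, 2, 0.2, seed=17)
        obs = mask_nodes(net, 0.5, rng_seed=6)
        res = run_ema(obs, EmaConfig(rng_seed=1, max_iterations=2))
        assert not res.converged and res.iterations == 2
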