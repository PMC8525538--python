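"""Cascade mechanics: relation matrix, propagation power, iteration, norm."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crowdanx.contagion import (ContagionParams, build_relation_matrix,
                                collective_anxiety, default_iteration_depth,
                                iterate_anxiety, polarization_assessment,
                                propagation_power, run_cascade)


def params(**kw):
    defaults = dict(epsilon=0.1, ub=1.0, clip_to_ub=True, tau=1.0)
    defaults.update(kw)
    return ContagionParams(**defaults)


def cascade_oracle(a0, edges, n, p, k):
    """Naive per-edge double-loop reference for the matrix iteration."""
    a = list(map(float, a0))
    for _ in range(k):
        delta = [p.epsilon * math.exp((x - p.ub) / p.ub) for x in a]
        nxt = list(a)
        for (i, j) in edges:
            nxt[i] += delta[j]
            nxt[j] += delta[i]
        if p.clip_to_ub:
            nxt = [min(max(x, 0.0), p.ub) for x in nxt]
        a = nxt
    return np.array(a)


class TestRelationMatrix:
    def test_single_directed_repost_sets_both_entries(self):
        R = build_relation_matrix(["u1", "u2", "u3"], [("u1", "u2")])
        expected = np.zeros((3, 3))
        expected[0, 1] = expected[1, 0] = 1.0
        assert np.array_equal(R, expected)

    def test_no_edges_gives_zero_matrix(self):
        assert not build_relation_matrix(["a", "b"], []).any()

    def test_self_edges_dropped(self):
        R = build_relation_matrix(["a", "b"], [("a", "a")])
        assert not R.any()

    def test_foreign_endpoint_is_an_error(self):
        with pytest.raises(ValueError, match="non-members"):
            build_relation_matrix(["a", "b"], [("a", "zz")])


class TestPropagationPower:
    def test_at_the_upper_bound_delta_equals_epsilon(self):
        assert propagation_power(1.0, params(epsilon=0.1)) == pytest.approx(0.1)

    def test_at_zero_closed_form(self):
        assert propagation_power(0.0, params(epsilon=0.1)) == \
            pytest.approx(0.1 * math.exp(-1.0), abs=1e-12)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(deadline=None)
    def test_strictly_increasing(self, x1, x2):
        p = params()
        d1, d2 = propagation_power(x1, p), propagation_power(x2, p)
        if x2 - x1 > 1e-9:
            assert d1 < d2
        assert d1 > 0 and d2 > 0


class TestIteration:
    def test_two_connected_members_hand_computed(self):
        R = build_relation_matrix([0, 1], [(0, 1)])
        a1 = iterate_anxiety([0.0, 1.0], R, params(epsilon=0.1))
        # u1 gains delta(1)=0.1; u2 gains delta(0)=0.0368 then clips at UB
        assert a1 == pytest.approx([0.1, 1.0])

    def test_isolated_member_never_changes(self):
        R = build_relation_matrix([0, 1, 2], [(0, 1)])
        a = run_cascade([0.2, 0.4, 0.7], R, params(), k=5)
        assert a[2] == pytest.approx(0.7)

    def test_unclipped_iteration_is_monotone(self):
        rng = np.random.default_rng(0)
        R = build_relation_matrix(range(6), [(i, (i + 1) % 6) for i in range(6)])
        a = rng.random(6)
        nxt = iterate_anxiety(a, R, params(clip_to_ub=False))
        assert np.all(nxt >= a)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            iterate_anxiety([0.1, 0.2, 0.3], np.zeros((2, 2)), params())


class TestCascade:
    def test_zero_iterations_is_identity(self):
        R = build_relation_matrix([0, 1], [(0, 1)])
        a0 = [0.3, 0.6]
        assert np.array_equal(run_cascade(a0, R, params(), k=0), a0)

    def test_influence_arrives_at_graph_distance(self):
        # path u1-u2-u3 with extra anxiety only at u3: relative to an
        # all-calm baseline, u1 is first touched at k = 2 (its graph
        # distance from u3)
        R = build_relation_matrix([0, 1, 2], [(0, 1), (1, 2)])
        p = params(epsilon=0.1, clip_to_ub=False)
        for k in (1, 2):
            seeded = run_cascade([0.0, 0.0, 1.0], R, p, k=k)
            baseline = run_cascade([0.0, 0.0, 0.0], R, p, k=k)
            diff = seeded[0] - baseline[0]
            if k < 2:
                assert diff == pytest.approx(0.0, abs=1e-15)
            else:
                assert diff > 1e-4

    def test_matches_per_edge_oracle_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(2, 21))
            k = int(rng.integers(0, 6))
            edges = {(int(i), int(j)) for i, j in
                     rng.integers(0, n, size=(rng.integers(1, 3 * n), 2)) if i != j}
            edges = {(min(e), max(e)) for e in edges}
            R = build_relation_matrix(range(n), list(edges))
            a0 = rng.random(n)
            p = params(epsilon=float(rng.uniform(0.01, 0.3)),
                       clip_to_ub=bool(rng.integers(0, 2)))
            got = run_cascade(a0, R, p, k=k)
            want = cascade_oracle(a0, edges, n, p, k)
            assert np.allclose(got, want, atol=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        n = 9
        edges = [(int(i), int(j)) for i, j in rng.integers(0, n, (15, 2)) if i != j]
        R = build_relation_matrix(range(n), edges)
        a0 = rng.random(n)
        perm = rng.permutation(n)
        Rp = R[np.ix_(perm, perm)]
        got = run_cascade(a0[perm], Rp, params(), k=3)
        want = run_cascade(a0, R, params(), k=3)[perm]
        assert np.allclose(got, want)

    def test_default_depth_is_capped_diameter(self):
        path = [(i, i + 1) for i in range(9)]
        R = build_relation_matrix(range(10), path)
        assert default_iteration_depth(R) == 6
        R3 = build_relation_matrix(range(4), [(0, 1), (1, 2), (2, 3)])
        assert default_iteration_depth(R3) == 3


class TestCollectiveAnxiety:
    def test_zero_sum_is_zero_in_both_modes(self):
        assert collective_anxiety(np.zeros(5), params(tau=3.0)) == 0.0
        p = ContagionParams(norm_mode="global_max", n_max=10)
        assert collective_anxiety(np.zeros(5), p) == 0.0

    def test_saturating_closed_form_at_tau(self):
        p = params(tau=4.0)
        a = np.full(8, 0.5)   # s = 4 = tau
        assert collective_anxiety(a, p) == pytest.approx(1 - math.exp(-1), abs=1e-12)

    def test_community_size_matters_at_equal_mean_anxiety(self):
        p_sat = params(tau=500.0)
        p_max = ContagionParams(norm_mode="global_max", n_max=1000)
        small, large = np.full(10, 0.5), np.full(1000, 0.5)
        for p in (p_sat, p_max):
            assert collective_anxiety(large, p) > collective_anxiety(small, p)

    def test_strictly_increasing_in_the_sum(self):
        p = params(tau=7.0)
        sums = np.linspace(0, 30, 40)
        vals = [collective_anxiety(np.array([s]), p) for s in sums]
        assert np.all(np.diff(vals) > 0)

    def test_missing_norm_parameters_are_errors(self):
        with pytest.raises(ValueError, match="tau"):
            collective_anxiety(np.ones(3), ContagionParams(tau=None))
        with pytest.raises(ValueError, match="N_max"):
            collective_anxiety(np.ones(3), ContagionParams(norm_mode="global_max"))


class TestPolarization:
    def test_constant_series(self):
        res = polarization_assessment([0.4, 0.4, 0.4, 0.4])
        assert res.trend_slope == 0.0
        assert res.polarized is False
        assert res.fluctuation == 0.0

    def test_exact_line_recovers_increment(self):
        series = 0.1 + 0.02 * np.arange(10)
        res = polarization_assessment(series)
        assert res.trend_slope == pytest.approx(0.02, abs=1e-12)
        assert res.polarized is True

    def test_fluctuation_matches_brute_force_sd(self):
        series = np.array([0.1, 0.3, 0.2, 0.4, 0.25])
        mean = sum(series) / len(series)
        sd = math.sqrt(sum((x - mean) ** 2 for x in series) / (len(series) - 1))
        res = polarization_assessment(series)
        assert res.fluctuation == pytest.approx(sd, abs=1e-12)

    def test_too_few_points_reported_as_undefined(self):
        res = polarization_assessment([0.2, 0.3])
        assert res.trend_slope is None and res.polarized is None
        assert res.fluctuation is not None
        assert polarization_assessment([0.2]).fluctuation is None
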