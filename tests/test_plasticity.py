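"""STDP rules against explicit kernel-sum / pair-enumeration oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sparsev1 as s
from sparsev1.errors import ConfigurationError, ContractError
from sparsev1.plasticity import (SYMMETRIC_GROUPS, TRIPLET_GROUPS, TraceSet,
                                 apply_symmetric_inplace,
                                 apply_triplet_inplace)

TP = s.TripletParams()
SP = s.SymmetricParams()
DT = 1.0


# -- independent oracles ------------------------------------------------------

def kernel_sum(spike_steps, t, tau, dt=DT, inclusive=True):
    """Explicit sum of exp(-(t - t_i)/tau) over past spikes."""
    steps = np.asarray(spike_steps)
    past = steps <= t if inclusive else steps < t
    return float(np.sum(np.exp(-(t - steps[past]) * dt / tau)))


def triplet_oracle(pre_steps, post_steps, params, dt=DT):
    """All-pairs / all-triplets summation of the triplet rule."""
    total = 0.0
    for tj in post_steps:
        u_p = kernel_sum(pre_steps, tj, params.tau_p, dt, inclusive=False)
        u_a = kernel_sum(post_steps, tj, params.tau_a, dt, inclusive=False)
        total += params.a_p * u_p * u_a
    for ti in pre_steps:
        u_d = kernel_sum(post_steps, ti, params.tau_d, dt, inclusive=False)
        total -= params.a_d * u_d
    return total


def symmetric_oracle(pre_steps, post_steps, params, dt=DT):
    total = 0.0
    for tj in post_steps:
        total += params.a_sym * kernel_sum(pre_steps, tj, params.tau_sym, dt,
                                           inclusive=False)
    for ti in pre_steps:
        total += params.a_sym * kernel_sum(post_steps, ti, params.tau_sym, dt,
                                           inclusive=False)
    return total


def run_rule(rule, pre_steps, post_steps, n_steps):
    """Drive the incremental implementation with single pre/post neurons."""
    tr = TraceSet(1, 1, 1, TP, SP, dt=DT)
    total = 0.0
    for t in range(n_steps):
        pre = np.array([1.0 if t in pre_steps else 0.0])
        post = np.array([1.0 if t in post_steps else 0.0])
        tr.decay()
        if rule == "triplet":
            dw = s.triplet_update("EX", pre, post, tr.up_x, tr.ud_e,
                                  tr.ua_e, TP)
            total += dw[0, 0]
            tr.accumulate(pre, post, np.zeros(1))
        else:
            dw = s.symmetric_update("IX", pre, post, tr.sym_x, tr.sym_i, SP)
            total += dw[0, 0]
            tr.accumulate(pre, np.zeros(1), post)
    return total


# -- traces -------------------------------------------------------------------

class TestTraces:
    def test_single_spike_decay(self):
        """One spike at t=0: the trace at t=10 ms equals exp(-0.5)."""
        trace = np.zeros(1)
        for t in range(11):
            trace = s.decay_and_accumulate(trace, np.array([1.0 if t == 0
                                                            else 0.0]),
                                           tau=20.0, dt=DT)
        assert trace[0] == pytest.approx(np.exp(-0.5), abs=1e-12)

    def test_two_spikes(self):
        """Spikes at 0 and 10 ms: post-increment trace = exp(-0.5) + 1."""
        trace = np.zeros(1)
        for t in range(11):
            spike = np.array([1.0 if t in (0, 10) else 0.0])
            trace = s.decay_and_accumulate(trace, spike, tau=20.0, dt=DT)
        assert trace[0] == pytest.approx(np.exp(-0.5) + 1.0, abs=1e-12)

    def test_long_silence_decays_to_nothing(self):
        trace = np.array([1.0])
        zero = np.zeros(1)
        for _ in range(2000):  # 100 tau at tau=20
            trace = s.decay_and_accumulate(trace, zero, tau=20.0, dt=DT)
        assert trace[0] < 1e-40

    def test_incremental_equals_kernel_sum_on_random_trains(self):
        """Incremental decay+increment vs explicit kernel sums to 1e-10."""
        rng = np.random.default_rng(7)
        spikes = rng.random(1000) < 0.05
        steps = np.flatnonzero(spikes)
        for tau in (20.0, 50.0):
            trace = np.zeros(1)
            for t in range(1000):
                trace = s.decay_and_accumulate(
                    trace, np.array([float(spikes[t])]), tau, DT)
                expected = kernel_sum(steps, t, tau, inclusive=True)
                assert abs(trace[0] - expected) < 1e-10


# -- triplet rule -------------------------------------------------------------

class TestTriplet:
    def test_first_post_spike_no_potentiation(self):
        """With no post history the slow trace is zero at the first post spike."""
        total = run_rule("triplet", pre_steps={5}, post_steps={10},
                         n_steps=11)
        # only depression could fire, and pre precedes post -> nothing at pre
        assert total == pytest.approx(0.0, abs=1e-15)

    def test_isolated_post_then_pre_depression(self):
        """Pre 10 ms after a lone post spike: dW = -A_d * exp(-0.5)."""
        total = run_rule("triplet", pre_steps={10}, post_steps={0},
                         n_steps=11)
        assert total == pytest.approx(-0.1 * np.exp(-0.5), abs=1e-12)

    @pytest.mark.parametrize("pattern", [
        ({30}, {0, 10, 20}),              # post-post-pre(-post) motifs
        ({5, 12, 40}, {0, 10, 20, 41}),
        ({0, 1, 2}, {0, 1, 2}),           # simultaneous pre/post steps
    ])
    def test_matches_enumeration_oracle(self, pattern):
        pre, post = pattern
        total = run_rule("triplet", pre, post, n_steps=60)
        assert total == pytest.approx(triplet_oracle(sorted(pre), sorted(post), TP),
                                      abs=1e-12)

    def test_random_trains_match_oracle(self):
        rng = np.random.default_rng(3)
        pre = set(np.flatnonzero(rng.random(1000) < 0.02).tolist())
        post = set(np.flatnonzero(rng.random(1000) < 0.02).tolist())
        total = run_rule("triplet", pre, post, n_steps=1000)
        assert total == pytest.approx(
            triplet_oracle(sorted(pre), sorted(post), TP), abs=1e-12)

    def test_wrong_group_rejected(self):
        with pytest.raises(ContractError):
            s.triplet_update("EI", np.zeros(1), np.zeros(1), np.zeros(1),
                             np.zeros(1), np.zeros(1), TP)

    def test_inplace_matches_dense(self):
        rng = np.random.default_rng(11)
        n_post, n_pre = 6, 9
        w = rng.random((n_post, n_pre))
        pre = (rng.random(n_pre) < 0.4).astype(float)
        post = (rng.random(n_post) < 0.4).astype(float)
        up = rng.random(n_pre)
        ud = rng.random(n_post)
        ua = rng.random(n_post)
        eta = 0.3
        dense = w + s.triplet_update("EX", pre, post, up, ud, ua, TP, eta=eta)
        np.maximum(dense, 0.0, out=dense)
        w2 = w.copy()
        apply_triplet_inplace(w2, np.flatnonzero(pre), np.flatnonzero(post),
                              up, ud, ua, TP, eta)
        np.testing.assert_allclose(w2, dense, atol=1e-12)


# -- phi ----------------------------------------------------------------------

class TestPhi:
    def test_default_constants_give_target_rate(self):
        """A_d tau_d / (A_p tau_p tau_a) = 2 Hz for the reference constants."""
        assert s.compute_phi(TP) == pytest.approx(2.0, abs=1e-12)

    def test_linearity_in_a_d(self):
        doubled = s.TripletParams(a_d=0.2)
        assert s.compute_phi(doubled) == pytest.approx(4.0, abs=1e-12)

    def test_inverse_in_a_p(self):
        halved = s.TripletParams(a_p=2.0)
        assert s.compute_phi(halved) == pytest.approx(1.0, abs=1e-12)


# -- symmetric rule -----------------------------------------------------------

class TestSymmetric:
    def test_pre_then_post(self):
        """Pre at 0, post at 10 ms: dW = A_sym * exp(-0.5)."""
        total = run_rule("symmetric", {0}, {10}, n_steps=11)
        assert total == pytest.approx(0.5 * np.exp(-0.5), abs=1e-12)

    def test_time_order_symmetry(self):
        forward = run_rule("symmetric", {0}, {10}, n_steps=11)
        backward = run_rule("symmetric", {10}, {0}, n_steps=11)
        assert forward == pytest.approx(backward, abs=1e-14)

    def test_one_sided_spike_alone_is_null(self):
        assert run_rule("symmetric", {50}, set(), n_steps=60) == 0.0

    def test_random_trains_match_oracle(self):
        rng = np.random.default_rng(5)
        pre = set(np.flatnonzero(rng.random(1000) < 0.03).tolist())
        post = set(np.flatnonzero(rng.random(1000) < 0.03).tolist())
        total = run_rule("symmetric", pre, post, n_steps=1000)
        assert total == pytest.approx(
            symmetric_oracle(sorted(pre), sorted(post), SP), abs=1e-12)

    def test_wrong_group_rejected(self):
        with pytest.raises(ContractError):
            s.symmetric_update("EX", np.zeros(1), np.zeros(1), np.zeros(1),
                               np.zeros(1), SP)

    def test_inplace_matches_dense(self):
        rng = np.random.default_rng(12)
        w = rng.random((5, 7))
        pre = (rng.random(7) < 0.5).astype(float)
        post = (rng.random(5) < 0.5).astype(float)
        u_pre, u_post = rng.random(7), rng.random(5)
        dense = w + s.symmetric_update("EI", pre, post, u_pre, u_post, SP,
                                       eta=0.7)
        w2 = w.copy()
        apply_symmetric_inplace(w2, np.flatnonzero(pre), np.flatnonzero(post),
                                u_pre, u_post, SP, 0.7)
        np.testing.assert_allclose(w2, dense, atol=1e-12)


# -- normalization ------------------------------------------------------------

class TestNormalizeRow:
    def test_three_stage_hand_example(self):
        out = s.normalize_row(np.array([3.0, 2.0, 1.0]), 3.0, 3)
        np.testing.assert_allclose(out, [2.0, 1.0, 0.0], atol=1e-12)

    def test_clip_then_rescale_hand_example(self):
        out = s.normalize_row(np.array([2.5, 0.2, 0.3]), 2.0, 3)
        np.testing.assert_allclose(out, [2.0, 0.0, 0.0], atol=1e-12)

    def test_under_bound_returned_unchanged(self):
        row = np.array([0.5, 0.25, 0.1])
        out = s.normalize_row(row, 3.0, 3)
        np.testing.assert_array_equal(out, row)

    def test_nonpositive_bound_rejected(self):
        with pytest.raises(ConfigurationError):
            s.normalize_row(np.ones(3), 0.0, 3)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.floats(0, 100), min_size=2, max_size=20),
           st.floats(0.1, 50))
    def test_l1_and_nonnegativity_invariants(self, row, bound):
        row = np.asarray(row)
        out = s.normalize_row(row, bound, row.size)
        assert np.all(out >= 0)
        assert out.sum() == pytest.approx(min(row.sum(), bound), abs=1e-9)

    def test_matrix_form_matches_row_form(self):
        rng = np.random.default_rng(4)
        w = rng.random((10, 6)) * 3
        expected = np.stack([s.normalize_row(r, 2.0, 6) for r in w])
        s.normalize_rows(w, 2.0)
        np.testing.assert_allclose(w, expected, atol=1e-12)


# -- adaptive threshold -------------------------------------------------------

class TestThreshold:
    def test_hand_example(self):
        """1 spike in 0.4 s at rho=2 Hz, eta=0.1 -> dtheta = +0.05."""
        theta = s.update_threshold(np.array([10.0]), np.array([1]), 0.4,
                                   rho=2.0, eta_theta=0.1, delta_cap=1.0)
        assert theta[0] == pytest.approx(10.05, abs=1e-12)

    def test_fixed_point_at_target(self):
        theta = s.update_threshold(np.array([7.0]), np.array([4]), 2.0,
                                   rho=2.0, eta_theta=0.1, delta_cap=1.0)
        assert theta[0] == 7.0

    def test_cap_binds(self):
        theta = s.update_threshold(np.array([10.0]), np.array([10_000]), 0.4,
                                   rho=2.0, eta_theta=0.1, delta_cap=1.0)
        assert theta[0] == pytest.approx(11.0, abs=1e-12)

    def test_monotone_in_spike_count(self):
        counts = np.arange(0, 50)
        thetas = s.update_threshold(np.full(50, 10.0), counts, 0.4, 2.0,
                                    0.1, 1.0)
        assert np.all(np.diff(thetas) >= 0)
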