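"""Value functions, soft-max and the accumulator models."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gazecontext.arrays import ParticipantArrays
from gazecontext.models import (
    GBdynParams,
    GBstatParams,
    GLAParams,
    ValueParams,
    gb_dyn_choice_probs,
    gb_dyn_probs_arrays,
    gb_stat_choice_probs,
    gla_accumulate,
    gla_choice_probs,
    gla_probs_arrays,
    pt_choice_probs,
    softmax,
    subjective_value,
    utility,
    weight_probability,
)
from gazecontext.types import ATTRACTION, Gamble, Trial, ValidationError

from conftest import make_fixations


class TestValueFunctions:
    def test_weighting_identity_at_gamma_one(self):
        p = np.linspace(0, 1, 21)
        assert np.allclose(weight_probability(p, 1.0), p)

    def test_weighting_known_value(self):
        # w(0.5; gamma=0.5) = 0.5^0.5 / (2 * 0.5^0.5)^2 = 1 / (4 * 0.5^0.5)
        assert weight_probability(0.5, 0.5) == pytest.approx(0.353553, abs=1e-6)

    def test_weighting_endpoints(self):
        for g in (0.28, 0.5, 1.0):
            assert weight_probability(0.0, g) == 0.0
            assert weight_probability(1.0, g) == 1.0

    def test_weighting_gamma_bounds(self):
        with pytest.raises(ValidationError):
            weight_probability(0.5, 0.2)

    @pytest.mark.parametrize("m,alpha,expect", [(10, 1.0, 10.0), (9, 0.5, 3.0), (1.5, 2.0, 2.25)])
    def test_power_utility(self, m, alpha, expect):
        assert utility(m, alpha) == pytest.approx(expect)

    def test_subjective_value_composition(self):
        assert subjective_value(Gamble(75, 10), ValueParams(1.0, 1.0)) == pytest.approx(7.5)
        assert subjective_value(Gamble(100, 7), ValueParams(1.0, 1.0)) == pytest.approx(7.0)
        assert subjective_value(Gamble(50, 9), ValueParams(0.5, 0.5)) == pytest.approx(1.06066, abs=1e-5)


class TestSoftmax:
    def test_beta_zero_uniform(self):
        assert np.allclose(softmax([3.0, -1.0, 99.0], 0.0), 1 / 3)

    def test_hand_value(self):
        p = softmax(np.array([1.0, 0.0, 0.0]), np.log(2.0))
        assert np.allclose(p, [0.5, 0.25, 0.25])

    @given(
        st.lists(st.floats(-50, 50), min_size=3, max_size=3),
        st.floats(0, 5),
        st.floats(-20, 20),
    )
    @settings(max_examples=60, deadline=None)
    def test_sums_to_one_and_shift_invariant(self, vals, beta, shift):
        p = softmax(np.array(vals), beta)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(p > 0)
        q = softmax(np.array(vals) + shift, beta)
        assert np.allclose(p, q, atol=1e-9)

    def test_overflow_guard(self):
        p = softmax(np.array([1000.0, 0.0, 0.0]), 10.0)
        assert np.isfinite(p).all() and p[0] == pytest.approx(1.0)


class TestPT:
    def test_identical_gambles_uniform(self):
        t = Trial(1, ATTRACTION, (Gamble(70, 10),) * 3, ("target", "competitor", "decoy"))
        assert np.allclose(pt_choice_probs(t, ValueParams(1, 1), 2.0), 1 / 3)

    def test_dominated_decoy_least_likely(self, attraction_trial):
        p = pt_choice_probs(attraction_trial, ValueParams(1.0, 1.0), 1.0)
        decoy = attraction_trial.position_of("decoy")
        assert p[decoy] == p.min()

    def test_gaze_independence(self, attraction_trial):
        # PT ignores fixations by construction: same probabilities whatever gaze
        p = pt_choice_probs(attraction_trial, ValueParams(0.9, 0.7), 0.5)
        assert p.sum() == pytest.approx(1.0)


class TestGLA:
    def test_two_step_hand_trace(self):
        """x = (1,1,1), fixations [0, 1], lam = 0.5, theta = 0.5:
        step 1: X = (1, .5, .5); step 2: X = (.5, .25, .25) + (.5, 1, .5)
        = (1.0, 1.25, 0.75)."""
        t = Trial(1, ATTRACTION, (Gamble(100, 1), Gamble(100, 1), Gamble(100, 1)),
                  ("target", "competitor", "decoy"))
        params = GLAParams(alpha=1.0, gamma=1.0, beta=1.0, lam=0.5, theta=0.5)
        X, degenerate = gla_accumulate(t, make_fixations([0, 1]), params)
        assert not degenerate
        assert np.allclose(X, [1.0, 1.25, 0.75])

    def test_no_leak_no_discount_degenerates_to_sum(self, attraction_trial):
        params = GLAParams(1.0, 1.0, 1.0, lam=0.0, theta=1.0)
        fix = make_fixations([0, 2, 1, 0])
        X, _ = gla_accumulate(attraction_trial, fix, params)
        x = np.array([subjective_value(g, ValueParams(1, 1)) for g in attraction_trial.gambles])
        assert np.allclose(X, 4 * x)

    def test_full_leak_keeps_only_last_fixation(self, attraction_trial):
        params = GLAParams(1.0, 1.0, 1.0, lam=1.0, theta=0.5)
        X, _ = gla_accumulate(attraction_trial, make_fixations([0, 2, 1]), params)
        x = np.array([subjective_value(g, ValueParams(1, 1)) for g in attraction_trial.gambles])
        expect = 0.5 * x
        expect[1] = x[1]
        assert np.allclose(X, expect)

    def test_order_insensitive_without_leak_and_discount(self, attraction_trial):
        params = GLAParams(0.9, 0.7, 0.3, lam=0.0, theta=1.0)
        p1 = gla_choice_probs(attraction_trial, make_fixations([0, 1, 2, 0]), params)
        p2 = gla_choice_probs(attraction_trial, make_fixations([0, 0, 2, 1]), params)
        assert np.allclose(p1, p2)

    def test_reduces_to_pt_when_gaze_blind(self, attraction_trial):
        """theta = 1, lam = 0: after n fixations X = n*x, so the soft-max equals
        PT's with inverse temperature n * beta."""
        n = 5
        params = GLAParams(0.9, 0.7, 0.2, lam=0.0, theta=1.0)
        p_gla = gla_choice_probs(attraction_trial, make_fixations([0, 1, 2, 1, 0]), params)
        p_pt = pt_choice_probs(attraction_trial, ValueParams(0.9, 0.7), 0.2 * n)
        assert np.allclose(p_gla, p_pt, atol=1e-12)

    def test_more_gaze_never_hurts(self, attraction_trial, rng):
        """Holding values fixed with theta < 1, adding a fixation to i never
        lowers i's choice probability."""
        params = GLAParams(1.0, 1.0, 0.5, lam=0.2, theta=0.5)
        for _ in range(50):
            alts = list(rng.integers(0, 3, size=6))
            base = gla_choice_probs(attraction_trial, make_fixations(alts), params)
            more = gla_choice_probs(attraction_trial, make_fixations(alts + [0]), params)
            assert more[0] >= base[0] - 1e-12

    def test_empty_sequence_uniform_with_warning(self, attraction_trial):
        params = GLAParams(1.0, 1.0, 1.0, lam=0.1, theta=0.5)
        with pytest.warns(UserWarning, match="empty fixation sequence"):
            p = gla_choice_probs(attraction_trial, make_fixations([]), params)
        assert np.allclose(p, 1 / 3)

    def test_duration_resolution_uses_10ms_steps(self, attraction_trial):
        """At 10 ms resolution a 300 ms fixation counts 30 steps, so identical
        alternatives' probabilities shift relative to fixation resolution."""
        params = GLAParams(1.0, 1.0, 0.1, lam=0.3, theta=0.5)
        fix = make_fixations([0, 1], durations=[300.0, 100.0])
        p_fix = gla_choice_probs(attraction_trial, fix, params, resolution="fixation")
        p_dur = gla_choice_probs(attraction_trial, fix, params, resolution="10ms")
        assert not np.allclose(p_fix, p_dur)
        # 10 ms resolution equals fixation resolution on the sequence with each
        # fixation repeated round(duration / 10) times
        expanded = make_fixations([0] * 30 + [1] * 10)
        p_exp = gla_choice_probs(attraction_trial, expanded, params, resolution="fixation")
        assert np.allclose(p_dur, p_exp, atol=1e-12)


class TestGazeBaselines:
    def test_gb_dyn_counts_without_leak(self, attraction_trial):
        p = gb_dyn_choice_probs(attraction_trial, make_fixations([0, 0, 1, 2, 0]),
                                GBdynParams(lam=0.0, beta=1.0))
        expect = softmax(np.array([3.0, 1.0, 1.0]), 1.0)
        assert np.allclose(p, expect)

    def test_gb_dyn_equal_counts_uniform(self, attraction_trial):
        p = gb_dyn_choice_probs(attraction_trial, make_fixations([0, 1, 2]),
                                GBdynParams(lam=0.0, beta=2.0))
        assert np.allclose(p, 1 / 3)

    def test_gb_stat_dwell_softmax_in_seconds(self, attraction_trial):
        fix = make_fixations([0, 1, 2], durations=[1200.0, 600.0, 200.0])
        p = gb_stat_choice_probs(attraction_trial, fix, GBstatParams(beta=1.0))
        assert np.allclose(p, softmax(np.array([1.2, 0.6, 0.2]), 1.0))

    def test_gb_stat_attribute_blind(self):
        t1 = Trial(1, ATTRACTION, (Gamble(75, 10), Gamble(65, 15), Gamble(73, 9)),
                   ("target", "competitor", "decoy"))
        t2 = Trial(1, ATTRACTION, (Gamble(20, 50), Gamble(80, 2), Gamble(33, 3)),
                   ("target", "competitor", "decoy"))
        fix = make_fixations([0, 1], durations=[500.0, 900.0])
        p1 = gb_stat_choice_probs(t1, fix, GBstatParams(beta=2.0))
        p2 = gb_stat_choice_probs(t2, fix, GBstatParams(beta=2.0))
        assert np.allclose(p1, p2)


class TestVectorizedKernels:
    """The padded-array kernels agree with the single-trial implementations."""

    def test_gla_and_gb_dyn_match_loop(self, small_session):
        trials = small_session[:40]
        arr = ParticipantArrays.from_trials(trials)
        params = GLAParams(0.85, 0.6, 0.4, lam=0.25, theta=0.55)
        pv = gla_probs_arrays(arr, 0.85, 0.6, 0.4, 0.25, 0.55)
        pd_ = gb_dyn_probs_arrays(arr, 0.3, 0.9)
        for i, t in enumerate(trials):
            assert np.allclose(pv[i], gla_choice_probs(t, t.fixations, params), atol=1e-12)
            assert np.allclose(
                pd_[i], gb_dyn_choice_probs(t, t.fixations, GBdynParams(0.3, 0.9)), atol=1e-12
            )

    def test_gla_10ms_matches_loop(self, small_session):
        trials = small_session[:15]
        arr = ParticipantArrays.from_trials(trials)
        params = GLAParams(0.85, 0.6, 0.05, lam=0.1, theta=0.55)
        pv = gla_probs_arrays(arr, 0.85, 0.6, 0.05, 0.1, 0.55, resolution="10ms")
        for i, t in enumerate(trials):
            assert np.allclose(
                pv[i], gla_choice_probs(t, t.fixations, params, resolution="10ms"), atol=1e-10
            )
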