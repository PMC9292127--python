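"""Switchboard enumeration, identifiability, feedback assembly and variant
likelihoods."""

import numpy as np
import pytest

from gazecontext.arrays import ParticipantArrays
from gazecontext.mdft import AttributeScaler
from gazecontext.models import GLAParams, gla_choice_probs, subjective_value, ValueParams
from gazecontext.switchboard import (
    GLA_EQUIVALENT,
    SwitchSpec,
    SWITCH_LEVELS,
    build_feedback,
    enumerate_variants,
    gla_params_to_variant,
    identifiability_classes,
    integrate_attributes,
    param_names,
    switch_level_bic_summary,
    variant_choice_probs,
    variant_probs_arrays,
)
from gazecontext.types import ValidationError

from conftest import make_fixations


@pytest.fixture(scope="module")
def specs():
    return enumerate_variants()


@pytest.fixture(scope="module")
def session_arrays(small_session):
    arr = ParticipantArrays.from_trials(small_session)
    scaler = AttributeScaler.fit(arr.p01 * 100.0, arr.m)
    return arr, scaler


class TestEnumeration:
    def test_counts(self, specs):
        assert len(specs) == 192
        assert len(identifiability_classes(specs)) == 160

    def test_contains_gla_variant(self, specs):
        assert GLA_EQUIVALENT in specs

    def test_deterministic_ordering(self, specs):
        assert specs == enumerate_variants()

    def test_collapsed_pairs_are_uniform_feedback_variants(self, specs):
        classes = identifiability_classes(specs)
        merged = [c for c in classes if len(c) == 2]
        assert len(merged) == 32
        for c in merged:
            s = specs[c[0]]
            assert s.leak in ("none", "constant")
            assert s.inhibition in ("none", "constant")
            assert {specs[i].comparison for i in c} == {"independent", "comparative"}

    def test_parameter_count_formula(self, specs):
        for s in specs:
            k = 1  # beta
            k += 2 if s.integration == "multiplicative" else 1
            if s.integration != "additive" and s.inhibition == "distance":
                k += 1  # w_p enters through the distance function
            k += int(s.gd_alt) + int(s.gd_att)
            k += int(s.leak != "none") + int(s.inhibition != "none")
            k += int(s.inhibition == "distance")  # w_d
            assert len(param_names(s)) == k, s

    def test_invalid_level_rejected(self):
        with pytest.raises(ValidationError):
            SwitchSpec("multiplicative", "nope", True, False, "none", "none")


class TestIntegration:
    def test_additive_equal_attributes_flat(self):
        p01 = np.full(3, 0.6)
        m = np.full(3, 12.0)
        for wp in (0.0, 0.4, 1.0):
            spec = SwitchSpec("additive", "independent", False, False, "none", "none")
            x = integrate_attributes(p01, m, spec, {"w_p": wp})
            assert np.allclose(x, 1 / 3)

    def test_divisive_normalization_columns_sum_to_one(self, rng):
        spec = SwitchSpec("additive", "independent", False, False, "none", "none")
        p01 = rng.uniform(0.2, 0.9, size=3)
        m = rng.uniform(5, 20, size=3)
        x = integrate_attributes(p01, m, spec, {"w_p": 1.0})
        assert x.sum() == pytest.approx(1.0)
        x = integrate_attributes(p01, m, spec, {"w_p": 0.0})
        assert x.sum() == pytest.approx(1.0)

    def test_multiplicative_matches_subjective_value(self, rng):
        from gazecontext.types import Gamble

        spec = SwitchSpec("multiplicative", "independent", False, False, "none", "none")
        for _ in range(20):
            p = rng.uniform(5, 100, size=3)
            m = rng.uniform(1, 25, size=3)
            x = integrate_attributes(p / 100.0, m, spec, {"alpha": 0.8, "gamma": 0.6})
            ref = [subjective_value(Gamble(pi, mi), ValueParams(0.8, 0.6)) for pi, mi in zip(p, m)]
            assert np.allclose(x, ref)

    def test_attribute_discount_applied_before_integration(self):
        spec = SwitchSpec("multiplicative", "independent", False, True, "none", "none")
        p01 = np.array([0.6, 0.7, 0.8])
        m = np.array([10.0, 12.0, 9.0])
        params = {"alpha": 1.0, "gamma": 1.0, "eta": 0.5}
        # outcome attended -> probabilities discounted before weighting
        x = integrate_attributes(p01, m, spec, params, fixated_attribute="m")
        assert np.allclose(x, (0.5 * p01) * m)
        x = integrate_attributes(p01, m, spec, params, fixated_attribute="p")
        assert np.allclose(x, p01 * (0.5 * m))


class TestFeedback:
    def test_no_leak_no_inhibition_identity(self):
        spec = SwitchSpec("multiplicative", "independent", False, False, "none", "none")
        fb = build_feedback(spec, {}, fixated_alt=0)
        assert np.allclose(fb.S, np.eye(3))

    def test_gaze_inhibition_targets_fixated_column(self):
        spec = SwitchSpec("multiplicative", "independent", False, False, "none", "gaze")
        fb = build_feedback(spec, {"phi": 0.3}, fixated_alt=0)
        expect = np.eye(3)
        expect[1, 0] = expect[2, 0] = -0.3
        assert np.allclose(fb.S, expect)

    def test_gaze_leak_spares_fixated_alternative(self):
        spec = SwitchSpec("multiplicative", "independent", False, False, "gaze", "none")
        fb = build_feedback(spec, {"lam": 0.7}, fixated_alt=1)
        assert np.allclose(np.diag(fb.S), [0.7, 1.0, 0.7])

    def test_distance_inhibition_maximal_at_zero_distance(self):
        spec = SwitchSpec("multiplicative", "independent", False, False, "none", "distance")
        D = np.zeros((3, 3))
        fb = build_feedback(spec, {"phi": 0.4}, fixated_alt=0, D=D)
        off = fb.S - np.diag(np.diag(fb.S))
        assert np.allclose(off[off != 0], -0.4)

    def test_theta_vector(self):
        spec = SwitchSpec("multiplicative", "independent", True, False, "none", "none")
        fb = build_feedback(spec, {"theta": 0.25}, fixated_alt=2)
        assert np.allclose(fb.theta_vec, [0.25, 0.25, 1.0])


class TestVariantProbs:
    def test_gla_equivalent_matches_direct_gla(self, small_session):
        """The switchboard variant with multiplicative integration,
        alternative-wise discount, constant leak and no inhibition equals the
        stand-alone GLA (after the leak-convention mapping) to 1e-10."""
        gla = GLAParams(alpha=0.85, gamma=0.65, beta=0.3, lam=0.35, theta=0.45)
        vparams = gla_params_to_variant(0.85, 0.65, 0.3, 0.35, 0.45)
        arr = ParticipantArrays.from_trials(small_session)
        pv = variant_probs_arrays(arr, GLA_EQUIVALENT, vparams)
        for i, t in enumerate(small_session):
            ref = gla_choice_probs(t, t.fixations, gla)
            assert np.allclose(pv[i], ref, atol=1e-10)

    def test_beta_zero_uniform_for_every_spec(self, specs, session_arrays, rng):
        arr, scaler = session_arrays
        for s in rng.choice(len(specs), size=10, replace=False):
            spec = specs[s]
            params = {n: 0.5 for n in param_names(spec)}
            params.update(beta=0.0, gamma=0.6, w_d=5.0)
            p = variant_probs_arrays(arr, spec, params, scaler=scaler)
            assert np.allclose(p, 1 / 3)

    def test_hybrid_variant_runs(self, session_arrays):
        """Variant B: multiplicative + alternative-wise discount + constant
        leak + distance inhibition + comparative accumulation."""
        arr, scaler = session_arrays
        spec = SwitchSpec("multiplicative", "comparative", True, False, "constant", "distance")
        params = {"beta": 0.2, "alpha": 0.9, "gamma": 0.7, "theta": 0.5,
                  "lam": 0.8, "phi": 0.3, "w_p": 0.5, "w_d": 10.0}
        p = variant_probs_arrays(arr, spec, params, scaler=scaler)
        assert p.shape == (arr.n_trials, 3)
        assert np.all(np.isfinite(p))
        assert np.allclose(p.sum(axis=1), 1.0)
        assert np.all(p >= 0)

    def test_vectorized_matches_loop_across_switches(self, small_session, rng):
        trials = small_session[:25]
        arr = ParticipantArrays.from_trials(trials)
        scaler = AttributeScaler.fit(arr.p01 * 100.0, arr.m)
        specs = enumerate_variants()
        for si in rng.choice(len(specs), size=16, replace=False):
            spec = specs[si]
            params = {}
            from gazecontext.switchboard import param_bounds

            for n, (lo, hi) in zip(param_names(spec), param_bounds(spec)):
                params[n] = float(rng.uniform(lo + 0.1 * (hi - lo), lo + 0.6 * (hi - lo)))
            params["beta"] = 0.25
            pv = variant_probs_arrays(arr, spec, params, scaler=scaler)
            for i in (0, 9, 21):
                pl = variant_choice_probs(trials[i], trials[i].fixations, spec, params, scaler=scaler)
                assert np.allclose(pv[i], pl, atol=1e-11), spec.label

    def test_collapsed_pairs_numerically_equivalent(self, specs, session_arrays, rng):
        """For every merged pair, the comparative member with beta equals the
        independent member with beta * 3/2 (the contrast rescales values by
        3/2 and adds a common shift)."""
        arr, scaler = session_arrays
        from gazecontext.switchboard import param_bounds

        classes = identifiability_classes(specs)
        for cls in classes:
            if len(cls) != 2:
                continue
            s1, s2 = specs[cls[0]], specs[cls[1]]
            si = s1 if s1.comparison == "independent" else s2
            sc = s2 if si is s1 else s1
            params_c = {n: float(rng.uniform(lo + 0.2 * (hi - lo), lo + 0.8 * (hi - lo)))
                        for n, (lo, hi) in zip(param_names(sc), param_bounds(sc))}
            params_c["beta"] = 0.2
            params_i = dict(params_c, beta=0.3)
            pc = variant_probs_arrays(arr, sc, params_c, scaler=scaler)
            pi = variant_probs_arrays(arr, si, params_i, scaler=scaler)
            assert np.allclose(pi, pc, atol=1e-10), si.label


class TestSummary:
    def test_switch_level_summary_shape(self, specs):
        import pandas as pd

        rng = np.random.default_rng(0)
        rows = []
        for s in specs:
            for pid in ("p1", "p2"):
                rows.append({
                    "participant_id": pid, "integration": s.integration,
                    "comparison": s.comparison, "gd_alt": s.gd_alt, "gd_att": s.gd_att,
                    "leak": s.leak, "inhibition": s.inhibition,
                    "bic": float(rng.normal(300, 30)),
                })
        fits = pd.DataFrame(rows)
        summary = switch_level_bic_summary(fits)
        assert len(summary) == 15
        for switch in SWITCH_LEVELS:
            counts = summary[summary.switch == switch]["n_variants"].sum()
            assert counts == 192
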