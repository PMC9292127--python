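"""MDFT matrices, asymptotic moments, Thurstone probabilities and the
simulation oracle."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from gazecontext.mdft import (
    AttributeScaler,
    InstabilityError,
    MDFTParams,
    PreferenceMoments,
    asymptotic_moments,
    bvn_cdf,
    choice_probs_thurstone,
    contrast_matrix,
    distance_matrix,
    feedback_matrix,
    mdft_choice_probs,
    mdft_mc_choice_probs,
    mdft_probs_arrays,
    preprocess_attributes,
    simulate_preference,
    spectral_radius,
    valence_moments,
)
from gazecontext.arrays import ParticipantArrays
from gazecontext.types import ATTRACTION, Gamble, Trial


def _trial(gambles):
    return Trial(1, ATTRACTION, tuple(gambles), ("target", "competitor", "decoy"))


@pytest.fixture(scope="module")
def trial():
    return _trial([Gamble(75, 10), Gamble(65, 15), Gamble(73, 9)])


class TestMatrices:
    def test_contrast_matrix(self):
        C = contrast_matrix(3)
        assert np.allclose(np.diag(C), 1.0)
        assert np.allclose(C[0, 1], -0.5)
        assert np.allclose(C.sum(axis=1), 0.0)
        assert np.allclose(C @ np.full(3, 7.0), 0.0)

    def test_preprocess_rescales_to_unit_range(self, trial):
        M = preprocess_attributes(trial)
        assert M.min() == pytest.approx(0.0)
        assert M.max() == pytest.approx(1.0)
        assert M.shape == (3, 2)

    def test_preprocess_preserves_dominance_order(self, trial):
        M = preprocess_attributes(trial)
        # alternative 0 = (75, 10) dominates alternative 2 = (73, 9)
        assert M[0, 0] > M[2, 0] and M[0, 1] > M[2, 1]

    def test_distance_identical_alternatives_zero(self):
        M = np.tile([0.4, 0.6], (3, 1))
        assert np.allclose(distance_matrix(M, wd=10.0), 0.0)

    def test_distance_reduces_to_euclidean_at_unit_weight(self, rng):
        M = rng.random((3, 2))
        D = distance_matrix(M, wd=1.0)
        for i in range(3):
            for j in range(3):
                assert D[i, j] == pytest.approx(np.sum((M[i] - M[j]) ** 2))

    def test_distance_pure_indifference_direction(self):
        M = np.array([[0.5, 0.5], [0.7, 0.3], [0.5, 0.5]])
        D = distance_matrix(M, wd=25.0)
        # difference (0.2, -0.2) lies in the indifference direction:
        # D = ((0.2 + 0.2) / sqrt(2))**2 = 0.08, independent of wd
        assert D[0, 1] == pytest.approx(0.08)
        assert distance_matrix(M, wd=1.0)[0, 1] == pytest.approx(0.08)

    def test_feedback_limits(self):
        D = distance_matrix(np.array([[0.0, 0.0], [1.0, 0.2], [0.3, 0.9]]), wd=2.0)
        assert np.allclose(feedback_matrix(D, 1.0, 0.0), np.eye(3))
        S = feedback_matrix(D, 1e6, 0.4)
        assert np.allclose(np.diag(S), 0.6)
        assert np.allclose(S - np.diag(np.diag(S)), 0.0, atol=1e-12)
        # at zero distance inhibition is maximal: off-diagonals reach -phi2
        S0 = feedback_matrix(np.zeros((3, 3)), 2.0, 1.0)
        assert np.allclose(np.diag(S0), 0.0)
        assert np.allclose(S0 - np.diag(np.diag(S0)), -(1.0 - np.eye(3)))


class TestMoments:
    def test_identical_alternatives_give_null_mean(self):
        M = np.tile([0.3, 0.8], (3, 1))
        mu, phi = valence_moments(M, w=0.4, sigma=0.7)
        assert np.allclose(mu, 0.0)
        assert np.allclose(phi, 0.49 * np.eye(3))

    def test_degenerate_attention_has_pure_noise_covariance(self, rng):
        M = rng.random((3, 2))
        for w in (0.0, 1.0):
            _, phi = valence_moments(M, w=w, sigma=0.5)
            assert np.allclose(phi, 0.25 * np.eye(3))

    def test_valence_mean_sums_to_zero(self, rng):
        M = rng.random((3, 2))
        mu, _ = valence_moments(M, w=0.6, sigma=1.0)
        assert mu.sum() == pytest.approx(0.0, abs=1e-12)

    def test_no_feedback_moments(self, rng):
        mu = rng.normal(size=3)
        phi = np.eye(3) * 0.3
        mom = asymptotic_moments(np.zeros((3, 3)), mu, phi)
        assert np.allclose(mom.xi, mu)
        assert np.allclose(mom.omega, phi)

    def test_scalar_lyapunov_closed_form(self):
        s = 0.8
        mom = asymptotic_moments(s * np.eye(3), np.zeros(3), np.eye(3))
        assert np.allclose(mom.omega, np.eye(3) / (1 - s**2))

    def test_instability_raises(self):
        with pytest.raises(InstabilityError):
            asymptotic_moments(1.01 * np.eye(3), np.zeros(3), np.eye(3))

    def test_moments_match_simulation(self, trial):
        params = MDFTParams(w=0.5, phi1=2.0, phi2=0.2, wd=10.0, sigma=0.5)
        M = preprocess_attributes(trial)
        S = feedback_matrix(distance_matrix(M, params.wd), params.phi1, params.phi2)
        mu, phi = valence_moments(M, params.w, params.sigma)
        mom = asymptotic_moments(S, mu, phi)
        P = simulate_preference(trial, params, 300, np.random.default_rng(7), n_reps=40000)
        X = P[:, -1, :]
        assert np.allclose(X.mean(axis=0), mom.xi, atol=0.02)
        assert np.allclose(np.cov(X.T), mom.omega, atol=0.05)


class TestBVN:
    def test_against_scipy(self, rng):
        for _ in range(100):
            h, k = rng.normal(0, 2.5, size=2)
            rho = rng.uniform(-0.999, 0.999)
            ref = multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]]).cdf([h, k])
            assert bvn_cdf(h, k, rho) == pytest.approx(ref, abs=1e-10)

    def test_independence_factorises(self):
        from scipy.special import ndtr

        assert bvn_cdf(0.3, -1.2, 0.0) == pytest.approx(ndtr(0.3) * ndtr(-1.2), abs=1e-12)


class TestThurstone:
    def test_symmetric_moments_uniform(self):
        mom = PreferenceMoments(np.zeros(3), np.eye(3))
        assert np.allclose(choice_probs_thurstone(mom), 1 / 3)

    def test_separation_limit(self):
        mom = PreferenceMoments(np.array([10.0, 0.0, 0.0]), np.eye(3))
        p = choice_probs_thurstone(mom)
        assert p[0] == pytest.approx(1.0, abs=1e-8)

    def test_against_gaussian_mc(self, rng):
        for _ in range(5):
            xi = rng.normal(0, 1, size=3)
            A = rng.normal(0, 1, size=(3, 3))
            omega = A @ A.T + 0.2 * np.eye(3)
            mom = PreferenceMoments(xi, omega)
            p = choice_probs_thurstone(mom, normalize=False)
            assert p.sum() == pytest.approx(1.0, abs=1e-6)
            draws = rng.multivariate_normal(xi, omega, size=100000)
            freq = np.bincount(draws.argmax(axis=1), minlength=3) / 100000
            assert np.allclose(p, freq, atol=0.01)


class TestChoiceProbs:
    def test_identical_gambles_uniform(self):
        t = _trial([Gamble(70, 10)] * 3)
        scaler = AttributeScaler.fit(np.array([60.0, 80.0]), np.array([5.0, 20.0]))
        params = MDFTParams(w=0.5, phi1=1.0, phi2=0.1, wd=5.0, sigma=0.5)
        assert np.allclose(mdft_choice_probs(t, params, scaler=scaler), 1 / 3)

    def test_permutation_equivariance(self, trial):
        params = MDFTParams(w=0.5, phi1=1.5, phi2=0.2, wd=8.0, sigma=0.6)
        scaler = AttributeScaler.fit(
            np.array([g.p for g in trial.gambles]), np.array([g.m for g in trial.gambles])
        )
        p = mdft_choice_probs(trial, params, scaler=scaler)
        perm = _trial([trial.gambles[2], trial.gambles[0], trial.gambles[1]])
        q = mdft_choice_probs(perm, params, scaler=scaler)
        assert np.allclose(q, p[[2, 0, 1]], atol=1e-9)

    def test_analytic_matches_dynamics_oracle(self, trial):
        """Analytic Thurstone probabilities agree with the discrete-time
        simulator within Monte-Carlo error at realistic noise levels."""
        rng = np.random.default_rng(11)
        n_reps = 30000
        for i in range(3):
            while True:
                params = MDFTParams(
                    w=rng.uniform(0.3, 0.7),
                    phi1=rng.uniform(0.5, 4.0),
                    phi2=rng.uniform(0.05, 0.5),
                    wd=rng.uniform(2.0, 20.0),
                    sigma=rng.uniform(1.0, 3.0),
                )
                M = preprocess_attributes(trial)
                S = feedback_matrix(distance_matrix(M, params.wd), params.phi1, params.phi2)
                if spectral_radius(S) < 0.9:
                    break
            pa = mdft_choice_probs(trial, params)
            pm = mdft_mc_choice_probs(trial, params, np.random.default_rng(100 + i),
                                      T=250, n_reps=n_reps)
            se = np.sqrt(pm * (1 - pm) / n_reps)
            assert np.all(np.abs(pa - pm) < 3 * se + 1e-3)

    def test_attraction_configuration_favours_target(self):
        """Distance-dependent inhibition with strong dominance overweighting
        boosts the option that dominates a nearby decoy."""
        t = _trial([Gamble(75, 13), Gamble(65, 15), Gamble(73, 12)])
        params = MDFTParams(w=0.5, phi1=5.0, phi2=0.1, wd=30.0, sigma=0.5)
        p = mdft_choice_probs(t, params)
        assert p[0] > p[1]
        pm = mdft_mc_choice_probs(t, params, np.random.default_rng(0), T=250, n_reps=20000)
        assert pm[0] > pm[1]

    def test_batched_path_matches_single_trial(self, small_session):
        trials = small_session[:50]
        arr = ParticipantArrays.from_trials(trials)
        p_all = np.array([g.p for t in trials for g in t.gambles])
        m_all = np.array([g.m for t in trials for g in t.gambles])
        scaler = AttributeScaler.fit(p_all, m_all)
        probs = mdft_probs_arrays(arr, 0.5, 1.5, 0.2, 8.0, 0.8, scaler=scaler)
        for i in (0, 13, 37):
            ref = mdft_choice_probs(trials[i], MDFTParams(0.5, 1.5, 0.2, 8.0, 0.8), scaler=scaler)
            assert np.allclose(probs[i], ref, atol=1e-9)

    def test_simulator_seed_reproducible(self, trial):
        params = MDFTParams(0.5, 1.0, 0.2, 5.0, 1.0)
        a = simulate_preference(trial, params, 50, np.random.default_rng(3), n_reps=4)
        b = simulate_preference(trial, params, 50, np.random.default_rng(3), n_reps=4)
        assert np.array_equal(a, b)

    def test_deterministic_linear_growth_without_noise_feedback(self, trial):
        """phi2 = 0 and vanishing noise: preferences grow linearly in t."""
        params = MDFTParams(w=1.0, phi1=1.0, phi2=0.0, wd=5.0, sigma=1e-12)
        P = simulate_preference(trial, params, 40, np.random.default_rng(0), n_reps=1)[0]
        inc = np.diff(P, axis=0)
        assert np.allclose(inc, inc[0], atol=1e-6)
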