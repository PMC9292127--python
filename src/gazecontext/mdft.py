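"""Analytic Multialternative Decision Field Theory (MDFT).

Preferences over the three alternatives evolve as a linear stochastic
system driven by attribute-wise valences,

    P(t) = S P(t-1) + V(t),      V(t) = C M W(t) + eps(t),

where M holds the (log-transformed, min-max rescaled) attribute values, C is
the contrast matrix comparing each alternative against the mean of the
others, W(t) is a one-hot attribute indicator (probability attended with
probability ``w``), eps(t) is iid N(0, sigma^2) noise per alternative, and
the feedback matrix

    S = I - phi2 * exp(-phi1 * D)

carries decay on its diagonal and distance-dependent lateral inhibition off
it.  D holds squared pairwise distances in attribute space, expressed in
indifference / dominance directions with the dominance component
overweighted by ``w_d`` (Hotaling-style distance).  When the spectral radius
of S is below one the preference state is asymptotically normal with mean
xi = (I-S)^{-1} mu and covariance Omega solving the discrete Lyapunov
equation Omega = S Omega S' + Phi; choice probabilities follow the general
Thurstone model, P(i) = P(P_i > P_j, P_i > P_k) under N(xi, Omega).

A discrete-time simulator of the same system doubles as a brute-force
Monte-Carlo oracle for the analytic path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.linalg import solve_discrete_lyapunov
from scipy.special import ndtr

from .arrays import ParticipantArrays
from .types import Trial, ValidationError

__all__ = [
    "MDFTParams",
    "PreferenceMoments",
    "InstabilityError",
    "AttributeScaler",
    "preprocess_attributes",
    "contrast_matrix",
    "distance_matrix",
    "feedback_matrix",
    "valence_moments",
    "asymptotic_moments",
    "choice_probs_thurstone",
    "simulate_preference",
    "mdft_mc_choice_probs",
    "mdft_choice_probs",
    "mdft_probs_arrays",
    "bvn_cdf",
]

SQRT2 = np.sqrt(2.0)


class InstabilityError(ValidationError):
    """Spectral radius of the feedback matrix is >= 1; no stationary solution."""


@dataclass(frozen=True)
class MDFTParams:
    """The five free MDFT parameters.

    w : probability-attribute share of attention, in [0, 1]
    phi1 : distance sensitivity of lateral inhibition, >= 0
    phi2 : decay, in [0, 1]
    wd : overweighting of the dominance direction in the distance, >= 1
    sigma : valence noise standard deviation, > 0
    """

    w: float
    phi1: float
    phi2: float
    wd: float
    sigma: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.w <= 1.0):
            raise ValidationError("w must be in [0, 1]")
        if self.phi1 < 0:
            raise ValidationError("phi1 must be >= 0")
        if not (0.0 <= self.phi2 <= 1.0):
            raise ValidationError("phi2 must be in [0, 1]")
        if self.wd < 1.0:
            raise ValidationError("wd must be >= 1")
        if self.sigma <= 0:
            raise ValidationError("sigma must be > 0")


@dataclass(frozen=True)
class PreferenceMoments:
    """Asymptotic mean and covariance of the preference state."""

    xi: np.ndarray
    omega: np.ndarray


class AttributeScaler:
    """Log-transform and min-max rescale gamble attributes to [0, 1].

    The rescaling range is fixed at fit time over the whole dataset being
    analysed (not per trial), so between-trial magnitude differences — in
    particular the extremity of compromise decoys — survive the transform.
    """

    def __init__(self, lo: np.ndarray, hi: np.ndarray):
        self.lo = np.asarray(lo, dtype=float)
        self.hi = np.asarray(hi, dtype=float)

    @classmethod
    def fit(cls, p_percent: np.ndarray, m: np.ndarray) -> "AttributeScaler":
        p_percent = np.asarray(p_percent, dtype=float)
        m = np.asarray(m, dtype=float)
        if np.any(p_percent <= 0) or np.any(m <= 0):
            raise ValidationError("attributes must be positive for the log transform")
        logs = np.stack([np.log(p_percent).ravel(), np.log(m).ravel()])
        return cls(lo=logs.min(axis=1), hi=logs.max(axis=1))

    def transform(self, p_percent: np.ndarray, m: np.ndarray) -> np.ndarray:
        """Return M with shape (..., 3, 2): columns = scaled log p, log m."""
        if np.any(np.asarray(p_percent) <= 0) or np.any(np.asarray(m) <= 0):
            raise ValidationError("attributes must be positive for the log transform")
        span = np.where(self.hi > self.lo, self.hi - self.lo, 1.0)
        a1 = (np.log(p_percent) - self.lo[0]) / span[0]
        a2 = (np.log(m) - self.lo[1]) / span[1]
        return np.stack([a1, a2], axis=-1)


def preprocess_attributes(trial: Trial, scaler: Optional[AttributeScaler] = None) -> np.ndarray:
    """Build the 3 x 2 attribute matrix M for one trial.

    Without an explicit scaler the rescaling range is the trial's own
    attribute range (convenience for single-trial use); fitting pipelines
    pass a dataset-level scaler.
    """
    p = np.array([g.p for g in trial.gambles])
    m = np.array([g.m for g in trial.gambles])
    if scaler is None:
        scaler = AttributeScaler.fit(p, m)
    return scaler.transform(p, m)


def contrast_matrix(n: int = 3) -> np.ndarray:
    """Diagonal 1, off-diagonal -1/(n-1): each option against the others' mean."""
    return (np.eye(n) * n - np.ones((n, n))) / (n - 1)


def distance_matrix(M: np.ndarray, wd: float) -> np.ndarray:
    """Squared pairwise distances in indifference / dominance coordinates.

    The attribute-difference vector is rotated into an indifference component
    (attributes trading off) and a dominance component (both attributes
    moving together); the dominance component's square is overweighted by
    ``wd``.  Supports batched M of shape (..., 3, 2).
    """
    diff = M[..., :, None, :] - M[..., None, :, :]  # (..., 3, 3, 2)
    d_ind = (diff[..., 0] - diff[..., 1]) / SQRT2
    d_dom = (diff[..., 0] + diff[..., 1]) / SQRT2
    return d_ind**2 + wd * d_dom**2


def feedback_matrix(D: np.ndarray, phi1: float, phi2: float) -> np.ndarray:
    """S = I - phi2 * exp(-phi1 * D) with D carrying squared distances."""
    eye = np.eye(D.shape[-1])
    return eye - phi2 * np.exp(-phi1 * D)


def valence_moments(M: np.ndarray, w: float, sigma: float) -> Tuple[np.ndarray, np.ndarray]:
    """Mean and covariance of the valence V = C M W + eps.

    W is one-hot over attributes with P(probability attended) = w, so
    cov(W) = diag(wbar) - wbar wbar'; eps is iid N(0, sigma^2) per
    alternative and enters after the contrast.  Batched over leading axes.
    """
    C = contrast_matrix(M.shape[-2])
    wbar = np.array([w, 1.0 - w])
    CM = C @ M
    mu = CM @ wbar
    cov_w = np.diag(wbar) - np.outer(wbar, wbar)
    phi = CM @ cov_w @ np.swapaxes(CM, -1, -2) + sigma**2 * np.eye(M.shape[-2])
    return mu, phi


def spectral_radius(S: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(S))))


def asymptotic_moments(S: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> PreferenceMoments:
    """Stationary moments of P(t) = S P(t-1) + V(t)."""
    if spectral_radius(S) >= 1.0:
        raise InstabilityError("feedback matrix spectral radius >= 1")
    n = S.shape[0]
    xi = np.linalg.solve(np.eye(n) - S, mu)
    omega = solve_discrete_lyapunov(S, phi)
    omega = (omega + omega.T) / 2.0
    return PreferenceMoments(xi=xi, omega=omega)


# ---------------------------------------------------------------------------
# bivariate normal CDF (Genz's algorithm, vectorized)
# ---------------------------------------------------------------------------

_GL_X = np.array(
    [0.9931285991850949, 0.9639719272779138, 0.9122344282513259, 0.8391169718222188,
     0.7463319064601508, 0.6360536807265150, 0.5108670019508271, 0.3737060887154196,
     0.2277858511416451, 0.07652652113349733]
)
_GL_W = np.array(
    [0.01761400713915212, 0.04060142980038694, 0.06267204833410906, 0.08327674157670475,
     0.1019301198172404, 0.1181945319615184, 0.1316886384491766, 0.1420961093183821,
     0.1491729864726037, 0.1527533871307259]
)


def _bvnu(dh: np.ndarray, dk: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Upper-tail probability P(X > dh, Y > dk) for standard bivariate normal."""
    dh, dk, r = np.broadcast_arrays(dh, dk, r)
    shape = dh.shape
    dh = dh.ravel().astype(float)
    dk = dk.ravel().astype(float)
    r = np.clip(r.ravel().astype(float), -1.0, 1.0)
    out = np.zeros_like(dh)

    near = np.abs(r) < 0.925
    if near.any():
        h, k, rr = dh[near], dk[near], r[near]
        hk = h * k
        hs = (h * h + k * k) / 2.0
        asr = np.arcsin(rr)
        bvn = np.zeros_like(h)
        for xi, wi in zip(_GL_X, _GL_W):
            for sgn in (-1.0, 1.0):
                sn = np.sin(asr * (sgn * xi + 1.0) / 2.0)
                bvn += wi * np.exp((sn * hk - hs) / (1.0 - sn * sn))
        out[near] = bvn * asr / (4.0 * np.pi) + ndtr(-h) * ndtr(-k)

    far = ~near
    if far.any():
        h, k, rr = dh[far].copy(), dk[far].copy(), r[far]
        neg = rr < 0
        k[neg] = -k[neg]
        hk = h * k
        bvn = np.zeros_like(h)
        lt1 = np.abs(rr) < 1.0
        if lt1.any():
            hh, kk, hkk = h[lt1], k[lt1], hk[lt1]
            a_s = (1.0 - rr[lt1]) * (1.0 + rr[lt1])
            a = np.sqrt(a_s)
            bs = (hh - kk) ** 2
            c = (4.0 - hkk) / 8.0
            d = (12.0 - hkk) / 16.0
            asr = -(bs / a_s + hkk) / 2.0
            b_ = np.zeros_like(hh)
            ok = asr > -100.0
            with np.errstate(over="ignore", invalid="ignore"):
                term = a * np.exp(np.where(ok, asr, -np.inf)) * (
                    1.0 - c * (bs - a_s) * (1.0 - d * bs / 5.0) / 3.0 + c * d * a_s * a_s / 5.0
                )
            b_ = np.where(ok, term, 0.0)
            ok2 = -hkk < 100.0
            if ok2.any():
                b = np.sqrt(bs)
                sp = np.sqrt(2.0 * np.pi) * ndtr(-b / a)
                with np.errstate(over="ignore", invalid="ignore"):
                    term2 = (np.exp(np.where(ok2, -hkk / 2.0, -np.inf)) * sp * b
                             * (1.0 - c * bs * (1.0 - d * bs / 5.0) / 3.0))
                b_ = b_ - np.where(ok2, term2, 0.0)
            a_half = a / 2.0
            for xi, wi in zip(_GL_X, _GL_W):
                for sgn in (-1.0, 1.0):
                    xs = (a_half * (sgn * xi + 1.0)) ** 2
                    rs = np.sqrt(1.0 - xs)
                    asr1 = -(bs / xs + hkk) / 2.0
                    ok3 = asr1 > -100.0
                    sp1 = 1.0 + c * xs * (1.0 + d * xs)
                    # combine exponents so large -hkk cannot overflow on its own
                    e1 = asr1 - hkk * (1.0 - rs) / (2.0 * (1.0 + rs))
                    with np.errstate(over="ignore", invalid="ignore"):
                        contrib = a_half * wi * (
                            np.exp(np.where(ok3, e1, -np.inf)) / rs
                            - np.exp(np.where(ok3, asr1, -np.inf)) * sp1
                        )
                    b_ += np.where(ok3, contrib, 0.0)
            bvn[lt1] = -b_ / (2.0 * np.pi)
        pos = rr > 0
        bvn[pos] += ndtr(-np.maximum(h, k))[pos]
        negm = ~pos
        if negm.any():
            bvn[negm] = -bvn[negm]
            swap = negm & (k > h)
            bvn[swap] += (ndtr(k) - ndtr(h))[swap]
        out[far] = bvn

    return np.clip(out, 0.0, 1.0).reshape(shape)


def bvn_cdf(h, k, rho):
    """P(X <= h, Y <= k) for a standard bivariate normal with correlation rho."""
    return _bvnu(-np.asarray(h, dtype=float), -np.asarray(k, dtype=float), np.asarray(rho, dtype=float))


_CONTRASTS = np.array(
    [
        [[1.0, -1.0, 0.0], [1.0, 0.0, -1.0]],
        [[-1.0, 1.0, 0.0], [0.0, 1.0, -1.0]],
        [[-1.0, 0.0, 1.0], [0.0, -1.0, 1.0]],
    ]
)  # (alternative, 2 contrasts, 3)

_RIDGE = 1e-10


def _thurstone_batch(xi: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """P(argmax = i) for N(xi, omega); xi (..., 3), omega (..., 3, 3)."""
    xi = np.asarray(xi, dtype=float)
    omega = np.asarray(omega, dtype=float)
    probs = np.empty(xi.shape[:-1] + (3,))
    for i in range(3):
        A = _CONTRASTS[i]
        mu = np.einsum("cj,...j->...c", A, xi)
        sig = np.einsum("cj,...jk,dk->...cd", A, omega, A)
        v1 = np.maximum(sig[..., 0, 0], _RIDGE)
        v2 = np.maximum(sig[..., 1, 1], _RIDGE)
        s1, s2 = np.sqrt(v1), np.sqrt(v2)
        rho = np.clip(sig[..., 0, 1] / (s1 * s2), -1.0 + 1e-12, 1.0 - 1e-12)
        probs[..., i] = bvn_cdf(mu[..., 0] / s1, mu[..., 1] / s2, rho)
    return probs


def choice_probs_thurstone(moments: PreferenceMoments, normalize: bool = True) -> np.ndarray:
    """Thurstone choice probabilities from the asymptotic preference moments."""
    p = _thurstone_batch(moments.xi, moments.omega)
    return p / p.sum() if normalize else p


def simulate_preference(
    trial: Trial,
    params: MDFTParams,
    T: int,
    rng: np.random.Generator,
    scaler: Optional[AttributeScaler] = None,
    n_reps: int = 1,
) -> np.ndarray:
    """Simulate preference trajectories of Eq-style dynamics.

    Returns an array of shape (n_reps, T + 1, 3) including the zero initial
    state; serves as the Monte-Carlo oracle for the analytic solution.
    """
    M = preprocess_attributes(trial, scaler)
    C = contrast_matrix(3)
    D = distance_matrix(M, params.wd)
    S = feedback_matrix(D, params.phi1, params.phi2)
    CM = C @ M
    P = np.zeros((n_reps, T + 1, 3))
    for t in range(1, T + 1):
        attend_p = rng.random(n_reps) < params.w
        val = np.where(attend_p[:, None], CM[:, 0], CM[:, 1])
        eps = rng.normal(0.0, params.sigma, size=(n_reps, 3))
        P[:, t] = P[:, t - 1] @ S.T + val + eps
    return P


def mdft_mc_choice_probs(
    trial: Trial,
    params: MDFTParams,
    rng: np.random.Generator,
    T: int = 200,
    n_reps: int = 20000,
    scaler: Optional[AttributeScaler] = None,
) -> np.ndarray:
    """Monte-Carlo choice frequencies: argmax of the preference state at time T."""
    P = simulate_preference(trial, params, T, rng, scaler=scaler, n_reps=n_reps)
    winners = P[:, -1, :].argmax(axis=1)
    return np.bincount(winners, minlength=3) / n_reps


def mdft_choice_probs(
    trial: Trial, params: MDFTParams, scaler: Optional[AttributeScaler] = None
) -> np.ndarray:
    """Analytic MDFT choice probabilities for one trial (gaze-independent)."""
    M = preprocess_attributes(trial, scaler)
    if np.allclose(M, M[0]):
        # three identical alternatives: the preference differences follow a
        # driftless symmetric walk, so the choice is uniform by symmetry
        return np.full(3, 1.0 / 3.0)
    D = distance_matrix(M, params.wd)
    S = feedback_matrix(D, params.phi1, params.phi2)
    mu, phi = valence_moments(M, params.w, params.sigma)
    moments = asymptotic_moments(S, mu, phi)
    return choice_probs_thurstone(moments)


def mdft_probs_arrays(
    arr: ParticipantArrays,
    w: float,
    phi1: float,
    phi2: float,
    wd: float,
    sigma: float,
    scaler: Optional[AttributeScaler] = None,
) -> np.ndarray:
    """Batched analytic MDFT probabilities for all trials of a participant.

    Stimuli repeat across trials, so moments are computed once per unique
    attribute matrix.  Raises :class:`InstabilityError` when any trial's
    feedback matrix is non-stationary (fitting treats the parameter point as
    invalid).
    """
    mats, inverse = arr.unique_stimuli()  # (U, 3, 2) with columns p01, m
    if scaler is None:
        scaler = AttributeScaler.fit(arr.p01 * 100.0, arr.m)
    M = scaler.transform(mats[:, :, 0] * 100.0, mats[:, :, 1])  # (U, 3, 2)
    degenerate = np.all(np.ptp(M, axis=1) < 1e-12, axis=-1)  # identical alternatives
    if degenerate.any():
        M = M.copy()
        M[degenerate] = np.linspace(0.1, 0.9, 6).reshape(3, 2)  # placeholder, overwritten below
    D = distance_matrix(M, wd)
    S = feedback_matrix(D, phi1, phi2)
    eigs = np.linalg.eigvals(S)
    if np.max(np.abs(eigs)) >= 1.0:
        raise InstabilityError("feedback matrix spectral radius >= 1")
    mu, phi = valence_moments(M, w, sigma)
    eye = np.eye(3)
    xi = np.linalg.solve(eye[None] - S, mu[..., None])[..., 0]
    # batched discrete Lyapunov via vec: (I9 - S (x) S) vec(Omega) = vec(Phi)
    U = S.shape[0]
    kron = np.einsum("uij,ukl->uikjl", S, S).reshape(U, 9, 9)
    omega = np.linalg.solve(np.eye(9)[None] - kron, phi.reshape(U, 9, 1)).reshape(U, 3, 3)
    omega = (omega + np.swapaxes(omega, 1, 2)) / 2.0
    p = _thurstone_batch(xi, omega)
    p = p / p.sum(axis=1, keepdims=True)
    if degenerate.any():
        p[degenerate] = 1.0 / 3.0
    return p[inverse]
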