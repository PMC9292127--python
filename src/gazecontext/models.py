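"""A priori choice models: Prospect Theory, the Gaze-dependent Leaky
Accumulator (GLA), static and dynamic gaze baselines, and random choice.

All models map a trial (and, for the gaze-dependent ones, its fixation
sequence) to a triple of choice probabilities via a soft-max over final
preference values.

Value construction follows prospect theory: outcomes enter through a power
utility U(m) = m**alpha and winning probabilities through the weighting
function w(p) = p**gamma / (p**gamma + (1-p)**gamma)**(1/gamma), so the
subjective value of a gamble is x = w(p) * U(m).  For the all-or-nothing
gambles used here this coincides with cumulative prospect theory.

The GLA accumulates these values over the fixation sequence with leak
``lam`` and a multiplicative discount ``theta`` applied to the momentary
input of every non-fixated alternative:

    X_i(n) = (1 - lam) * X_i(n-1) + x_i        if alternative i is fixated
    X_i(n) = (1 - lam) * X_i(n-1) + theta*x_i  otherwise

with X_i(0) = 0.  Fixating either attribute cell of an alternative counts as
fixating that alternative.  At the default fixation resolution each fixation
is one accumulation step; at 10 ms resolution each fixation contributes
round(duration / 10) steps (minimum one), so fixation durations matter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple, Union

import numpy as np

from .arrays import ParticipantArrays
from .types import FixationSequence, Gamble, Trial, ValidationError

__all__ = [
    "ValueParams",
    "GLAParams",
    "GBdynParams",
    "GBstatParams",
    "weight_probability",
    "utility",
    "subjective_value",
    "softmax",
    "pt_choice_probs",
    "gla_accumulate",
    "gla_choice_probs",
    "gb_dyn_choice_probs",
    "gb_stat_choice_probs",
    "random_choice_probs",
    "pt_probs_arrays",
    "gla_probs_arrays",
    "gb_dyn_probs_arrays",
    "gb_stat_probs_arrays",
]

GAMMA_MIN = 0.28


@dataclass(frozen=True)
class ValueParams:
    """Prospect-theory value parameters: utility curvature and weighting shape."""

    alpha: float
    gamma: float

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValidationError(f"alpha must be > 0, got {self.alpha}")
        if not (GAMMA_MIN <= self.gamma <= 1.0):
            raise ValidationError(f"gamma must be in [{GAMMA_MIN}, 1], got {self.gamma}")


@dataclass(frozen=True)
class GLAParams:
    """GLA parameters: value parameters plus softmax beta, leak and gaze discount.

    ``lam`` follows the loss convention (0 = no leak); ``theta`` = 1 means no
    gaze discount.
    """

    alpha: float
    gamma: float
    beta: float
    lam: float
    theta: float

    def __post_init__(self) -> None:
        ValueParams(self.alpha, self.gamma)
        if self.beta < 0:
            raise ValidationError("beta must be >= 0")
        if not (0.0 <= self.lam <= 1.0):
            raise ValidationError("lam must be in [0, 1]")
        if not (0.0 <= self.theta <= 1.0):
            raise ValidationError("theta must be in [0, 1]")

    @property
    def value_params(self) -> ValueParams:
        return ValueParams(self.alpha, self.gamma)


@dataclass(frozen=True)
class GBdynParams:
    """Dynamic gaze baseline: leak (loss convention) and softmax beta."""

    lam: float
    beta: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lam <= 1.0):
            raise ValidationError("lam must be in [0, 1]")
        if self.beta < 0:
            raise ValidationError("beta must be >= 0")


@dataclass(frozen=True)
class GBstatParams:
    """Static gaze baseline: softmax beta over total dwell times in seconds."""

    beta: float

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValidationError("beta must be >= 0")


def weight_probability(p, gamma: float):
    """Probability weighting w(p) = p^g / (p^g + (1-p)^g)^(1/g) for p in [0, 1]."""
    if not (GAMMA_MIN <= gamma <= 1.0):
        raise ValidationError(f"gamma must be in [{GAMMA_MIN}, 1], got {gamma}")
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValidationError("probabilities must lie in [0, 1]")
    num = p ** gamma
    den = (p ** gamma + (1.0 - p) ** gamma) ** (1.0 / gamma)
    out = num / den
    return out if out.ndim else float(out)


def utility(m, alpha: float):
    """Power utility U(m) = m^alpha."""
    if alpha <= 0:
        raise ValidationError(f"alpha must be > 0, got {alpha}")
    out = np.asarray(m, dtype=float) ** alpha
    return out if out.ndim else float(out)


def subjective_value(gamble: Gamble, vp: ValueParams) -> float:
    """x = w(p/100) * U(m): the prospect-theory value of one gamble."""
    return float(weight_probability(gamble.p / 100.0, vp.gamma) * utility(gamble.m, vp.alpha))


def softmax(values, beta: float) -> np.ndarray:
    """Soft-max choice rule p_i = exp(beta*x_i) / sum_j exp(beta*x_j).

    Invariant under adding a constant to all values (guarded by max-shift).
    Accepts a (..., K) array and normalises along the last axis.
    """
    if beta < 0:
        raise ValidationError("beta must be >= 0")
    z = beta * np.asarray(values, dtype=float)
    z = z - z.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


def random_choice_probs(trial: Optional[Trial] = None) -> np.ndarray:
    """The random baseline: uniform probabilities for all three alternatives."""
    return np.full(3, 1.0 / 3.0)


def pt_choice_probs(trial: Trial, vp: ValueParams, beta: float) -> np.ndarray:
    """Prospect-theory choice probabilities; independent of gaze."""
    x = np.array([subjective_value(g, vp) for g in trial.gambles])
    return softmax(x, beta)


def _alt_steps(fixations: FixationSequence, resolution: str) -> list:
    alts = fixations.alternative_sequence()
    if resolution == "fixation":
        return alts
    if resolution == "10ms":
        steps = []
        for f in fixations:
            if f.alt is None:
                continue
            n = max(int(round(f.duration / 10.0)), 1)
            steps.extend([f.alt] * n)
        return steps
    raise ValueError(f"unknown resolution {resolution!r}; use 'fixation' or '10ms'")


def gla_accumulate(
    trial: Trial,
    fixations: FixationSequence,
    params: GLAParams,
    resolution: str = "fixation",
) -> Tuple[np.ndarray, bool]:
    """Run the GLA accumulator over a fixation sequence.

    Returns the final accumulator state and a degeneracy flag; an empty
    sequence leaves the accumulators at zero and is flagged degenerate.
    """
    x = np.array([subjective_value(g, params.value_params) for g in trial.gambles])
    steps = _alt_steps(fixations, resolution)
    X = np.zeros(3)
    if not steps:
        return X, True
    keep = 1.0 - params.lam
    for alt in steps:
        inp = params.theta * x
        inp[alt] = x[alt]
        X = keep * X + inp
    return X, False


def gla_choice_probs(
    trial: Trial,
    fixations: FixationSequence,
    params: GLAParams,
    resolution: str = "fixation",
) -> np.ndarray:
    """Soft-max over the final GLA accumulator values."""
    X, degenerate = gla_accumulate(trial, fixations, params, resolution)
    if degenerate:
        warnings.warn(
            f"trial {trial.trial_id}: empty fixation sequence, returning uniform probabilities",
            stacklevel=2,
        )
        return np.full(3, 1.0 / 3.0)
    return softmax(X, params.beta)


def gb_dyn_choice_probs(trial: Trial, fixations: FixationSequence, params: GBdynParams) -> np.ndarray:
    """Dynamic gaze baseline: leaky accumulation of fixation indicators."""
    X = np.zeros(3)
    steps = fixations.alternative_sequence()
    if not steps:
        return np.full(3, 1.0 / 3.0)
    keep = 1.0 - params.lam
    for alt in steps:
        X = keep * X
        X[alt] += 1.0
    return softmax(X, params.beta)


def gb_stat_choice_probs(trial: Trial, fixations: FixationSequence, params: GBstatParams) -> np.ndarray:
    """Static gaze baseline: soft-max over total dwell times in seconds."""
    d = np.array(fixations.dwell_per_alternative()) / 1000.0
    return softmax(d, params.beta)


# ---------------------------------------------------------------------------
# vectorized likelihood kernels over ParticipantArrays
# ---------------------------------------------------------------------------


def _values_arrays(arr: ParticipantArrays, alpha: float, gamma: float) -> np.ndarray:
    return weight_probability(arr.p01, gamma) * (arr.m ** alpha)


def pt_probs_arrays(arr: ParticipantArrays, alpha: float, gamma: float, beta: float) -> np.ndarray:
    return softmax(_values_arrays(arr, alpha, gamma), beta)


def _accumulate_arrays(
    alt_seq: np.ndarray, inputs_fix: np.ndarray, inputs_unfix: np.ndarray, lam: float
) -> np.ndarray:
    """Shared leaky-accumulation loop.

    ``inputs_fix``/``inputs_unfix`` are (T, 3) momentary inputs for the
    fixated / non-fixated case; padded steps (alt < 0) freeze the state.
    """
    T, L = alt_seq.shape
    X = np.zeros((T, 3))
    keep = 1.0 - lam
    eye = np.eye(3)
    for n in range(L):
        a = alt_seq[:, n]
        active = a >= 0
        if not active.any():
            break
        mask = eye[np.where(active, a, 0)]  # (T, 3) one-hot of fixated alt
        inp = np.where(mask > 0, inputs_fix, inputs_unfix)
        Xn = keep * X + inp
        X = np.where(active[:, None], Xn, X)
    return X


def gla_probs_arrays(
    arr: ParticipantArrays,
    alpha: float,
    gamma: float,
    beta: float,
    lam: float,
    theta: float,
    resolution: str = "fixation",
) -> np.ndarray:
    """GLA choice probabilities for all trials of one participant at once."""
    x = _values_arrays(arr, alpha, gamma)
    if resolution == "fixation":
        alt_seq = arr.alt_seq
    elif resolution == "10ms":
        alt_seq, _ = arr.expanded_10ms()
    else:
        raise ValueError(f"unknown resolution {resolution!r}")
    X = _accumulate_arrays(alt_seq, x, theta * x, lam)
    probs = softmax(X, beta)
    empty = arr.n_fix == 0
    if empty.any():
        probs[empty] = 1.0 / 3.0
    return probs


def gb_dyn_probs_arrays(arr: ParticipantArrays, lam: float, beta: float) -> np.ndarray:
    ones = np.ones((arr.n_trials, 3))
    X = _accumulate_arrays(arr.alt_seq, ones, np.zeros_like(ones), lam)
    probs = softmax(X, beta)
    empty = arr.n_fix == 0
    if empty.any():
        probs[empty] = 1.0 / 3.0
    return probs


def gb_stat_probs_arrays(arr: ParticipantArrays, beta: float) -> np.ndarray:
    return softmax(arr.dwell_seconds(), beta)
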