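"""The switchboard model space: 192 accumulator variants from six switches.

Every variant follows one accumulation scheme over the fixation sequence,

    X(t) = S X(t-1) + C (Theta * x(t)),      X(0) = 0,

with a soft-max over the final accumulator values.  Six switches set the
pieces:

* ``integration``: item values x from multiplicative prospect-theory
  weighting (w(p) * U(m)) or from weighted-additive combination of
  divisively normalized attributes.
* ``comparison``: C is the identity (independent accumulation) or the MDFT
  contrast matrix (each item against the mean of the others).  The contrast
  is applied to the gaze-discounted inputs.
* ``gd_alt``: alternative-wise gaze discount Theta (1 for the fixated
  alternative, theta for the others) — on or off.
* ``gd_att``: attribute-wise gaze discount (the currently unattended
  attribute dimension is scaled by eta before integration) — on or off.
* ``leak``: diagonal of S — none (1), constant (lam) or gaze-dependent
  (fixated alternative keeps 1, others lam).  ``lam`` uses the retention
  convention here: 1 means perfect memory, 0 full leak.
* ``inhibition``: off-diagonal of S — none, constant (-phi), gaze-dependent
  (-phi in the fixated alternative's column) or distance-dependent
  (-phi * exp(-phi * D_ij) on Hotaling-style squared distances over
  log-rescaled attributes, with dominance overweighting w_d and attribute
  weighting w_p).

Variants whose comparative and independent versions give identical soft-max
probabilities (leak and inhibition both uniform, i.e. in {none, constant})
are collapsed into one identifiability class: the contrast matrix then
commutes with S and amounts to a common rescaling plus shift of the final
accumulators, which the free inverse temperature absorbs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .arrays import ParticipantArrays
from .mdft import AttributeScaler, contrast_matrix, distance_matrix
from .models import softmax, weight_probability
from .types import FixationSequence, Trial, ValidationError

__all__ = [
    "SwitchSpec",
    "enumerate_variants",
    "identifiability_classes",
    "param_names",
    "param_bounds",
    "integrate_attributes",
    "build_feedback",
    "variant_choice_probs",
    "variant_probs_arrays",
    "switch_level_bic_summary",
    "GLA_EQUIVALENT",
    "gla_params_to_variant",
    "SWITCH_LEVELS",
]

INTEGRATIONS = ("multiplicative", "additive")
COMPARISONS = ("independent", "comparative")
ONOFF = (True, False)
LEAKS = ("none", "constant", "gaze")
INHIBITIONS = ("none", "constant", "distance", "gaze")

SWITCH_LEVELS = {
    "integration": INTEGRATIONS,
    "comparison": COMPARISONS,
    "gd_alt": ONOFF,
    "gd_att": ONOFF,
    "leak": LEAKS,
    "inhibition": INHIBITIONS,
}


@dataclass(frozen=True)
class SwitchSpec:
    """Six switch settings identifying one model variant."""

    integration: str
    comparison: str
    gd_alt: bool
    gd_att: bool
    leak: str
    inhibition: str

    def __post_init__(self) -> None:
        for name, levels in SWITCH_LEVELS.items():
            if getattr(self, name) not in levels:
                raise ValidationError(f"invalid {name} level {getattr(self, name)!r}")

    @property
    def label(self) -> str:
        return (
            f"{self.integration[:4]}-{self.comparison[:4]}"
            f"-gdalt{int(self.gd_alt)}-gdatt{int(self.gd_att)}"
            f"-leak_{self.leak}-inh_{self.inhibition}"
        )


#: The variant that coincides with the a priori GLA model.
GLA_EQUIVALENT = SwitchSpec(
    integration="multiplicative",
    comparison="independent",
    gd_alt=True,
    gd_att=False,
    leak="constant",
    inhibition="none",
)


def gla_params_to_variant(alpha: float, gamma: float, beta: float, lam: float, theta: float) -> Dict[str, float]:
    """Map GLA parameters (leak-loss convention) onto the GLA-equivalent variant.

    The switchboard's ``lam`` is retention (1 = perfect memory), so the GLA
    loss-rate lam maps to retention 1 - lam.
    """
    return {"beta": beta, "alpha": alpha, "gamma": gamma, "theta": theta, "lam": 1.0 - lam}


def enumerate_variants() -> List[SwitchSpec]:
    """All 192 switch combinations in canonical order."""
    return [
        SwitchSpec(integration=ig, comparison=cp, gd_alt=ga, gd_att=gt, leak=lk, inhibition=ih)
        for ig, cp, ga, gt, lk, ih in itertools.product(
            INTEGRATIONS, COMPARISONS, ONOFF, ONOFF, LEAKS, INHIBITIONS
        )
    ]


def _collapses(spec: SwitchSpec) -> bool:
    return spec.leak in ("none", "constant") and spec.inhibition in ("none", "constant")


def identifiability_classes(specs: Sequence[SwitchSpec]) -> List[Tuple[int, ...]]:
    """Partition variant indices into identifiability classes.

    Comparative and independent versions merge exactly when both leak and
    inhibition are uniform across alternatives (levels 'none' or 'constant').
    """
    key_to_members: Dict[tuple, List[int]] = {}
    order: List[tuple] = []
    for idx, s in enumerate(specs):
        if _collapses(s):
            key = (s.integration, "n.d.", s.gd_alt, s.gd_att, s.leak, s.inhibition)
        else:
            key = (s.integration, s.comparison, s.gd_alt, s.gd_att, s.leak, s.inhibition)
        if key not in key_to_members:
            key_to_members[key] = []
            order.append(key)
        key_to_members[key].append(idx)
    return [tuple(key_to_members[k]) for k in order]


_PARAM_ORDER = ("beta", "alpha", "gamma", "w_p", "theta", "eta", "lam", "phi", "w_d")


def param_names(spec: SwitchSpec) -> List[str]:
    """Free parameters of a variant, in canonical order."""
    names = {"beta"}
    if spec.integration == "multiplicative":
        names |= {"alpha", "gamma"}
    else:
        names.add("w_p")
    if spec.gd_alt:
        names.add("theta")
    if spec.gd_att:
        names.add("eta")
    if spec.leak != "none":
        names.add("lam")
    if spec.inhibition != "none":
        names.add("phi")
    if spec.inhibition == "distance":
        names |= {"w_p", "w_d"}
    return [n for n in _PARAM_ORDER if n in names]


_BOUNDS = {
    "beta": (0.0, 100.0),
    "alpha": (0.01, 3.0),
    "gamma": (0.28, 1.0),
    "w_p": (0.0, 1.0),
    "theta": (0.0, 1.0),
    "eta": (0.0, 1.0),
    "lam": (0.0, 1.0),
    "phi": (0.0, 1.0),
    "w_d": (1.0, 50.0),
}


def param_bounds(spec: SwitchSpec) -> List[Tuple[float, float]]:
    return [_BOUNDS[n] for n in param_names(spec)]


def integrate_attributes(
    p01: np.ndarray,
    m: np.ndarray,
    spec: SwitchSpec,
    params: Dict[str, float],
    fixated_attribute: Optional[str] = None,
) -> np.ndarray:
    """Momentary item values x for one (or a batch of) trial(s).

    ``p01``/``m`` have shape (..., 3).  With the attribute-wise discount on,
    the currently unattended dimension is scaled by eta — before weighting
    and utility under multiplicative integration, after divisive
    normalization under additive integration.
    """
    p01 = np.asarray(p01, dtype=float)
    m = np.asarray(m, dtype=float)
    eta = params.get("eta", 1.0)
    discount_p = spec.gd_att and fixated_attribute == "m"
    discount_m = spec.gd_att and fixated_attribute == "p"
    if spec.gd_att and fixated_attribute not in ("p", "m", None):
        raise ValidationError(f"unknown fixated attribute {fixated_attribute!r}")
    if spec.integration == "multiplicative":
        pe = eta * p01 if discount_p else p01
        me = eta * m if discount_m else m
        return weight_probability(pe, params["gamma"]) * me ** params["alpha"]
    psum = p01.sum(axis=-1, keepdims=True)
    msum = m.sum(axis=-1, keepdims=True)
    if np.any(psum == 0) or np.any(msum == 0):
        raise ValidationError("divisive normalization needs a non-zero attribute column")
    pn = p01 / psum
    mn = m / msum
    if discount_p:
        pn = eta * pn
    if discount_m:
        mn = eta * mn
    wp = params["w_p"]
    return wp * pn + (1.0 - wp) * mn


@dataclass(frozen=True)
class FeedbackPieces:
    """Per-fixation update pieces: feedback matrix, discount vector, contrast."""

    S: np.ndarray
    theta_vec: np.ndarray
    C: np.ndarray


def _weighted_distances(M: np.ndarray, w_p: float, w_d: float) -> np.ndarray:
    """Squared Hotaling distances with attribute weighting w_p."""
    Mw = M * np.array([2.0 * w_p, 2.0 * (1.0 - w_p)])
    return distance_matrix(Mw, w_d)


def build_feedback(
    spec: SwitchSpec,
    params: Dict[str, float],
    fixated_alt: int,
    D: Optional[np.ndarray] = None,
) -> FeedbackPieces:
    """Assemble S, Theta and C for one fixation.

    The diagonal of S is governed solely by the leak switch, the off-diagonal
    solely by the inhibition switch.  ``D`` (squared distances on
    log-rescaled attributes) is required for distance inhibition.
    """
    eye = np.eye(3)
    if spec.leak == "none":
        diag = np.ones(3)
    elif spec.leak == "constant":
        diag = np.full(3, params["lam"])
    else:  # gaze
        diag = np.full(3, params["lam"])
        diag[fixated_alt] = 1.0
    off = np.zeros((3, 3))
    if spec.inhibition == "constant":
        off = -params["phi"] * (1.0 - eye)
    elif spec.inhibition == "gaze":
        off[:, fixated_alt] = -params["phi"]
        off[fixated_alt, fixated_alt] = 0.0
    elif spec.inhibition == "distance":
        if D is None:
            raise ValidationError("distance inhibition requires a distance matrix")
        off = -params["phi"] * np.exp(-params["phi"] * D) * (1.0 - eye)
    S = np.diag(diag) + off
    theta_vec = np.ones(3)
    if spec.gd_alt:
        theta_vec[:] = params["theta"]
        theta_vec[fixated_alt] = 1.0
    C = contrast_matrix(3) if spec.comparison == "comparative" else eye
    return FeedbackPieces(S=S, theta_vec=theta_vec, C=C)


def variant_choice_probs(
    trial: Trial,
    fixations: FixationSequence,
    spec: SwitchSpec,
    params: Dict[str, float],
    scaler: Optional[AttributeScaler] = None,
) -> np.ndarray:
    """Reference (loop) implementation of one variant's choice probabilities."""
    p01 = np.array([g.p / 100.0 for g in trial.gambles])
    m = np.array([g.m for g in trial.gambles])
    D = None
    if spec.inhibition == "distance":
        if scaler is None:
            scaler = AttributeScaler.fit(p01 * 100.0, m)
        M = scaler.transform(p01 * 100.0, m)
        D = _weighted_distances(M, params["w_p"], params["w_d"])
    X = np.zeros(3)
    n_steps = 0
    for f in fixations:
        if not f.is_aoi:
            continue
        n_steps += 1
        x = integrate_attributes(p01, m, spec, params, fixated_attribute=f.attribute)
        pieces = build_feedback(spec, params, f.alt, D=D)
        X = pieces.S @ X + pieces.C @ (pieces.theta_vec * x)
    if n_steps == 0:
        return np.full(3, 1.0 / 3.0)
    if not np.all(np.isfinite(X)):
        raise OverflowError("accumulator overflow; treat parameter point as invalid")
    return softmax(X, params["beta"])


def variant_probs_arrays(
    arr: ParticipantArrays,
    spec: SwitchSpec,
    params: Dict[str, float],
    scaler: Optional[AttributeScaler] = None,
) -> np.ndarray:
    """Vectorized variant probabilities for all trials of one participant."""
    T = arr.n_trials
    eye3 = np.eye(3)
    if spec.gd_att:
        x_by_att = np.stack(
            [
                integrate_attributes(arr.p01, arr.m, spec, params, fixated_attribute="p"),
                integrate_attributes(arr.p01, arr.m, spec, params, fixated_attribute="m"),
            ]
        )  # (2, T, 3)
    else:
        x_fixed = integrate_attributes(arr.p01, arr.m, spec, params)
    off_dist = None
    if spec.inhibition == "distance":
        if scaler is None:
            scaler = AttributeScaler.fit(arr.p01 * 100.0, arr.m)
        mats, inverse = arr.unique_stimuli()
        M = scaler.transform(mats[:, :, 0] * 100.0, mats[:, :, 1])
        D = _weighted_distances(M, params["w_p"], params["w_d"])
        off_dist = (-params["phi"] * np.exp(-params["phi"] * D) * (1.0 - eye3))[inverse]  # (T,3,3)
    comparative = spec.comparison == "comparative"
    C = contrast_matrix(3)
    lam = params.get("lam", 1.0)
    phi = params.get("phi", 0.0)
    theta = params.get("theta", 1.0)
    X = np.zeros((T, 3))
    L = arr.alt_seq.shape[1]
    for n in range(L):
        a = arr.alt_seq[:, n]
        active = a >= 0
        if not active.any():
            break
        onehot = eye3[np.where(active, a, 0)]  # (T, 3)
        # feedback applied to the previous state
        if spec.leak == "none":
            SX = X.copy()
        elif spec.leak == "constant":
            SX = lam * X
        else:
            SX = X * (onehot + lam * (1.0 - onehot))
        if spec.inhibition == "constant":
            SX = SX - phi * (X.sum(axis=1, keepdims=True) - X)
        elif spec.inhibition == "gaze":
            x_fix = np.take_along_axis(X, np.where(active, a, 0)[:, None], axis=1)
            SX = SX - phi * x_fix * (1.0 - onehot)
        elif spec.inhibition == "distance":
            SX = SX + np.einsum("tij,tj->ti", off_dist, X)
        # momentary inputs
        if spec.gd_att:
            att = np.where(active, arr.att_seq[:, n], 0)
            x = x_by_att[att, np.arange(T)]
        else:
            x = x_fixed
        if spec.gd_alt:
            tvec = theta + (1.0 - theta) * onehot
            v = tvec * x
        else:
            v = x
        if comparative:
            v = v @ C.T
        Xn = SX + v
        X = np.where(active[:, None], Xn, X)
    if not np.all(np.isfinite(X)):
        raise OverflowError("accumulator overflow; treat parameter point as invalid")
    probs = softmax(X, params["beta"])
    empty = arr.n_fix == 0
    if empty.any():
        probs[empty] = 1.0 / 3.0
    return probs


def switch_level_bic_summary(fits: pd.DataFrame) -> pd.DataFrame:
    """Mean BIC per switch level over a variant x participant fit table.

    ``fits`` must carry the six switch columns and a ``bic`` column; the
    result has one row per (switch, level) — 15 rows in total — averaging
    over every fit whose variant has that switch at that level.
    """
    rows = []
    for switch, levels in SWITCH_LEVELS.items():
        for level in levels:
            sel = fits[fits[switch] == level]
            rows.append(
                {
                    "switch": switch,
                    "level": str(level),
                    "n_variants": sel.drop_duplicates(list(SWITCH_LEVELS)).shape[0],
                    "mean_bic": sel["bic"].mean(),
                }
            )
    return pd.DataFrame(rows)
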