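"""Synthetic gaze and choice generation.

Fixation sequences are generated by a first-order Markov chain over the six
alternative x attribute AOIs: with probability ``p_within`` the next fixation
stays on the current alternative and switches attribute; otherwise it jumps
to another alternative, with selection weights tilted towards the trial's
target (``target_bias``) and towards the previously visited alternative
(``p_return``).  Fixation durations are ``min_duration`` plus a gamma draw,
and the sequence terminates after each fixation with probability
``stop_prob``, so response time emerges as the summed duration.

The empirical signature this emulates: targets receive slightly greater
relative dwell than competitors (on the order of 0.01-0.02), information
search mixes within- and between-alternative transitions, and all fixation
durations respect the 80 ms detection threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import RunConfig
from .design import AgentParams, build_session
from .types import (
    ATTR_M,
    ATTR_P,
    Dataset,
    Fixation,
    FixationSequence,
    TARGET,
    Trial,
    ValidationError,
)

__all__ = [
    "GazeProcessParams",
    "generate_fixation_sequence",
    "clean_fixations",
    "simulate_choice",
    "generate_dataset",
]


@dataclass(frozen=True)
class GazeProcessParams:
    """Parameters of the Markov fixation process (durations in ms)."""

    p_within: float = 0.55
    p_return: float = 0.1
    target_bias: float = 0.15
    dwell_shape: float = 2.0
    dwell_scale: float = 90.0
    stop_prob: float = 0.08
    min_duration: float = 80.0
    max_fixations: int = 60

    def __post_init__(self) -> None:
        for name in ("p_within", "p_return", "stop_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.stop_prob <= 0:
            raise ValidationError("stop_prob must be positive (sequences must terminate)")
        if self.target_bias < 0:
            raise ValidationError("target_bias must be >= 0")
        if self.dwell_shape <= 0 or self.dwell_scale <= 0:
            raise ValidationError("dwell gamma parameters must be positive")
        if self.min_duration < 0:
            raise ValidationError("min_duration must be >= 0")

    @classmethod
    def from_config(cls, config: RunConfig) -> "GazeProcessParams":
        return cls(
            p_within=config.p_within,
            p_return=config.p_return,
            target_bias=config.target_bias,
            dwell_shape=config.dwell_shape,
            dwell_scale=config.dwell_scale,
            stop_prob=config.stop_prob,
            min_duration=config.min_duration,
        )


def generate_fixation_sequence(
    trial: Trial, gp: GazeProcessParams, rng: np.random.Generator
) -> FixationSequence:
    """Draw one fixation sequence over the six AOIs for a trial."""
    try:
        target = trial.position_of(TARGET)
    except ValidationError:
        target = None  # distractor trials have no target to favour

    fixes: List[Fixation] = []
    alt = int(rng.integers(3))
    attribute = ATTR_P if rng.random() < 0.5 else ATTR_M
    prev_alt: Optional[int] = None
    for n in range(gp.max_fixations):
        duration = gp.min_duration + rng.gamma(gp.dwell_shape, gp.dwell_scale)
        fixes.append(Fixation(alt=alt, attribute=attribute, duration=duration, onset_index=n))
        if rng.random() < gp.stop_prob:
            break
        if rng.random() < gp.p_within:
            attribute = ATTR_M if attribute == ATTR_P else ATTR_P
        else:
            others = [a for a in range(3) if a != alt]
            w = np.ones(len(others))
            for k, a in enumerate(others):
                if target is not None and a == target:
                    w[k] += gp.target_bias
                if prev_alt is not None and a == prev_alt:
                    w[k] += gp.p_return
            prev_alt = alt
            alt = int(rng.choice(others, p=w / w.sum()))
            attribute = ATTR_P if rng.random() < 0.5 else ATTR_M
    return FixationSequence(tuple(fixes))


def clean_fixations(raw: FixationSequence) -> FixationSequence:
    """Re-code or discard non-AOI fixations.

    A run of non-AOI fixations flanked by fixations to the *same* AOI is
    re-coded to that AOI; flanked by different AOIs it is discarded.
    Leading and trailing non-AOI fixations are discarded.
    """
    fixes = list(raw)
    out: List[Fixation] = []
    i = 0
    while i < len(fixes):
        f = fixes[i]
        if f.is_aoi:
            out.append(f)
            i += 1
            continue
        j = i
        while j < len(fixes) and not fixes[j].is_aoi:
            j += 1
        prev = out[-1] if out else None
        nxt = fixes[j] if j < len(fixes) else None
        if prev is not None and nxt is not None and (prev.alt, prev.attribute) == (nxt.alt, nxt.attribute):
            for g in fixes[i:j]:
                out.append(Fixation(alt=prev.alt, attribute=prev.attribute, duration=g.duration,
                                    onset_index=g.onset_index))
        i = j
    reindexed = [
        Fixation(alt=f.alt, attribute=f.attribute, duration=f.duration, onset_index=k)
        for k, f in enumerate(out)
    ]
    return FixationSequence(tuple(reindexed))


def simulate_choice(
    probs: np.ndarray, rng: np.random.Generator, tol: float = 1e-9
) -> int:
    """Draw one choice from a model's predicted trinomial."""
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (3,) or abs(probs.sum() - 1.0) > tol or np.any(probs < 0):
        raise ValidationError(f"invalid choice probability triple {probs}")
    return int(rng.choice(3, p=probs / probs.sum()))


def generate_dataset(
    true_model,
    true_params: Sequence[Dict[str, float]],
    config: RunConfig,
    gp: GazeProcessParams,
    seed: int,
    agents: Optional[Sequence[AgentParams]] = None,
) -> Tuple[Dataset, pd.DataFrame]:
    """Simulate a full synthetic experiment from one generating model.

    For each participant a fresh staircase calibration and session of
    ``3 x 75`` trials is built, fixation sequences are drawn from the gaze
    process and choices from ``true_model`` at the participant's true
    parameters.  Returns the dataset and a long-format ground-truth table
    (participant_id, model, parameter, value).  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    n_participants = len(true_params)
    if agents is None:
        agents = [_default_agent(dict(p)) for p in true_params]
    data = {}
    truth_rows = []
    for i in range(n_participants):
        pid = f"sim-{i + 1:03d}"
        prng = np.random.default_rng(rng.integers(2**31))
        trials, _ = build_session(agents[i], config, prng)
        true_model.prepare(trials)
        done = []
        for t in trials:
            seq = clean_fixations(generate_fixation_sequence(t, gp, prng))
            probs = true_model.choice_probs(t, seq, true_params[i])
            choice = simulate_choice(probs, prng)
            rt = sum(f.duration for f in seq)
            done.append(t.with_outcome(seq, choice, rt))
        data[pid] = done
        for name, value in true_params[i].items():
            truth_rows.append(
                {"participant_id": pid, "model": true_model.name, "parameter": name, "value": value}
            )
    return Dataset(data), pd.DataFrame(truth_rows)


def _default_agent(params: Dict[str, float]) -> AgentParams:
    """Staircase agent matching the participant's value function when known."""
    return AgentParams(
        alpha=float(params.get("alpha", 0.9)),
        gamma=float(params.get("gamma", 0.7)),
        beta=3.0,
    )
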