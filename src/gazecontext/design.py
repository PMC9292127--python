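"""Stimulus design: indifference-calibrated gamble sets and trial lists.

A session consists of three block pairs.  Each estimation block runs an
adaptive staircase in which a simulated prospect-theory agent makes binary
choices; outcome amounts are adjusted until four gambles C_B, B, A, C_A with
winning probabilities 55 / 65 / 75 / 85 % are approximately equally
preferred.  Two dominated decoys D_A and D_B sit exactly 2 percentage points
and 1 EUR below A and B.  The following experimental block holds 75 ternary
trials: 16 of each decoy set {A,B,C_A}, {A,B,C_B}, {A,B,D_A}, {A,B,D_B} plus
11 distractor trials, with small attribute noise added per trial.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .config import RunConfig
from .models import softmax, subjective_value, ValueParams
from .types import (
    ATTRACTION,
    COMPETITOR,
    COMPROMISE,
    DECOY,
    DISTRACTOR,
    Gamble,
    NONE,
    TARGET,
    Trial,
    ValidationError,
)

__all__ = [
    "AgentParams",
    "StimulusSet",
    "CalibrationError",
    "simulate_indifference_block",
    "build_trial_list",
    "build_session",
    "apply_trial_noise",
    "LABELS",
]

LABELS = ("C_B", "B", "A", "C_A", "D_A", "D_B")
DESIGN_P = {"C_B": 55.0, "B": 65.0, "A": 75.0, "C_A": 85.0}
REFERENCE_B = Gamble(p=65.0, m=15.0)

NOISE_DP = (-3.0, 3.0)
NOISE_DM = (-1.0, 0.0)

DISTRACTOR_BANDS = ((16.0, 32.0), (37.0, 67.0), (72.0, 89.0))


class CalibrationError(ValidationError):
    """Raised when no feasible stimulus set satisfies the design constraints."""


@dataclass(frozen=True)
class AgentParams:
    """Prospect-theory agent answering the staircase's binary choices.

    ``beta`` is the softmax inverse temperature; ``beta=None`` denotes the
    deterministic (beta -> infinity) agent used for calibration checks.
    """

    alpha: float = 1.0
    gamma: float = 1.0
    beta: Optional[float] = None

    @property
    def value_params(self) -> ValueParams:
        return ValueParams(self.alpha, self.gamma)

    def prefers_adjustable(self, reference: Gamble, adjustable: Gamble, rng: np.random.Generator) -> bool:
        """True if the agent picks the adjustable gamble; ties go to the reference."""
        v_ref = subjective_value(reference, self.value_params)
        v_adj = subjective_value(adjustable, self.value_params)
        if self.beta is None:
            return v_adj > v_ref
        p_adj = softmax(np.array([v_ref, v_adj]), self.beta)[1]
        return bool(rng.random() < p_adj)

    def indifference_outcome(self, reference: Gamble, p_new: float) -> float:
        """Analytic outcome at which (p_new, m) matches the reference's value."""
        from .models import utility, weight_probability

        v_ref = subjective_value(reference, self.value_params)
        w_new = weight_probability(p_new / 100.0, self.gamma)
        return float((v_ref / w_new) ** (1.0 / self.alpha))


@dataclass(frozen=True)
class StimulusSet:
    """The six labelled gambles of one block: C_B, B, A, C_A, D_A, D_B."""

    gambles: Dict[str, Gamble]

    def __post_init__(self) -> None:
        g = self.gambles
        missing = [l for l in LABELS if l not in g]
        if missing:
            raise ValidationError(f"stimulus set missing labels {missing}")
        for label, p in DESIGN_P.items():
            if g[label].p != p:
                raise ValidationError(f"{label} must have p = {p}, got {g[label].p}")
        ms = [g["C_B"].m, g["B"].m, g["A"].m, g["C_A"].m]
        for hi, lo, pair in zip(ms, ms[1:], ("C_B-B", "B-A", "A-C_A")):
            if hi - lo < 2.0:
                raise ValidationError(f"outcome gap {pair} must be >= 2 EUR, got {hi - lo}")
        for decoy, core in (("D_A", "A"), ("D_B", "B")):
            expect = (g[core].p - 2.0, g[core].m - 1.0)
            if (g[decoy].p, g[decoy].m) != expect:
                raise ValidationError(f"{decoy} must sit at (p-2, m-1) of {core}")

    def __getitem__(self, label: str) -> Gamble:
        return self.gambles[label]


class _Staircase:
    """One-up one-down staircase on an outcome amount, halving at reversals."""

    def __init__(self, p: float, start_m: float, start_step: float, min_step: float):
        self.p = p
        self.m = start_m
        self.step = start_step
        self.min_step = min_step
        self.last_up: Optional[bool] = None

    def respond(self, adjustable_preferred: bool) -> None:
        up = not adjustable_preferred  # too unattractive -> raise its outcome
        if self.last_up is not None and up != self.last_up:
            self.step = max(self.step / 2.0, self.min_step)
        self.last_up = up
        self.m = max(self.m + (self.step if up else -self.step), 1.0)

    def gamble(self) -> Gamble:
        return Gamble(p=self.p, m=self.m)


def _round_step(value: float, step: float) -> float:
    return round(value / step) * step


def simulate_indifference_block(
    agent: AgentParams, config: RunConfig, rng: np.random.Generator
) -> StimulusSet:
    """Run the interleaved staircases and return a calibrated stimulus set.

    Three staircases (A against the fixed reference B; C_A against the
    current A estimate; C_B against B) are interleaved round-robin within the
    block's trial budget.  Start values come from the risk-neutral
    expected-value match, the step starts at ``staircase_start_step`` EUR,
    halves at every preference reversal and floors at ``staircase_min_step``.
    At block end the estimates are projected onto the feasible set (gaps of
    at least 2 EUR between neighbouring outcomes).
    """
    b = REFERENCE_B
    min_step = config.staircase_min_step
    sc_a = _Staircase(DESIGN_P["A"], 10.0, config.staircase_start_step, min_step)
    sc_ca = _Staircase(
        DESIGN_P["C_A"],
        _round_step(10.0 * DESIGN_P["A"] / DESIGN_P["C_A"], min_step),
        config.staircase_start_step,
        min_step,
    )
    sc_cb = _Staircase(
        DESIGN_P["C_B"],
        _round_step(b.m * b.p / DESIGN_P["C_B"], min_step),
        config.staircase_start_step,
        min_step,
    )
    for t in range(config.staircase_max_trials):
        which = t % 3
        if which == 0:
            sc_a.respond(agent.prefers_adjustable(b, sc_a.gamble(), rng))
        elif which == 1:
            # C_A is calibrated against the *current* A estimate
            sc_ca.respond(agent.prefers_adjustable(sc_a.gamble(), sc_ca.gamble(), rng))
        else:
            sc_cb.respond(agent.prefers_adjustable(b, sc_cb.gamble(), rng))

    # project onto the feasible set: m decreasing in p with gaps >= 2 EUR
    m_a = min(sc_a.m, b.m - 2.0)
    m_ca = min(sc_ca.m, m_a - 2.0)
    m_cb = max(sc_cb.m, b.m + 2.0)
    if m_ca < 1.0 or m_a - 1.0 < 1.0:
        raise CalibrationError(
            f"indifference estimates infeasible: m_A={m_a}, m_CA={m_ca} (outcomes must stay >= 1 EUR)"
        )
    gambles = {
        "C_B": Gamble(DESIGN_P["C_B"], m_cb),
        "B": b,
        "A": Gamble(DESIGN_P["A"], m_a),
        "C_A": Gamble(DESIGN_P["C_A"], m_ca),
        "D_A": Gamble(DESIGN_P["A"] - 2.0, m_a - 1.0),
        "D_B": Gamble(b.p - 2.0, b.m - 1.0),
    }
    out = StimulusSet(gambles)
    # expose the raw staircase estimates for calibration diagnostics
    object.__setattr__(out, "staircase_estimates", {"A": sc_a.m, "C_A": sc_ca.m, "C_B": sc_cb.m})
    object.__setattr__(out, "terminal_steps", {"A": sc_a.step, "C_A": sc_ca.step, "C_B": sc_cb.step})
    return out


def apply_trial_noise(gamble: Gamble, noise: Tuple[float, float]) -> Gamble:
    """Add one trial's attribute noise (dp in {-3, +3}; dm in {-1, 0}).

    Raises if the draw is outside the allowed sets or the noised gamble
    leaves the valid attribute ranges (callers redraw dm instead of clamping).
    """
    dp, dm = noise
    if dp not in NOISE_DP:
        raise ValidationError(f"probability noise must be one of {NOISE_DP}, got {dp}")
    if dm not in NOISE_DM:
        raise ValidationError(f"outcome noise must be one of {NOISE_DM}, got {dm}")
    return Gamble(p=gamble.p + dp, m=gamble.m + dm)


def _draw_noise(gamble: Gamble, rng: np.random.Generator, min_m: float = 1.0) -> Tuple[float, float]:
    """Draw (dp, dm), redrawing dm = 0 when -1 would push the outcome below min_m."""
    dp = float(rng.choice(NOISE_DP))
    dm = float(rng.choice(NOISE_DM))
    if gamble.m + dm < min_m:
        dm = 0.0
    return dp, dm


# decoy trial sets: (decoy label, trial type, target label)
TRIAL_SETS = (
    ("C_A", COMPROMISE, "A"),
    ("C_B", COMPROMISE, "B"),
    ("D_A", ATTRACTION, "A"),
    ("D_B", ATTRACTION, "B"),
)


def _distractor_gambles(rng: np.random.Generator) -> List[Gamble]:
    out = []
    for lo, hi in DISTRACTOR_BANDS:
        p = float(rng.uniform(lo, hi))
        m = max(round(1000.0 / p), 1.0)  # expected value ~10 EUR, whole EUR
        out.append(Gamble(p=p, m=float(m)))
    return out


def build_trial_list(
    stimuli: StimulusSet, rng: np.random.Generator, start_id: int = 1
) -> List[Trial]:
    """Assemble one experimental block of 75 trials from a stimulus set.

    16 trials per decoy set (32 attraction + 32 compromise) plus 11
    distractors; positions randomised per trial and trial order shuffled.
    Dominated decoys receive the identical noise draw as their target so the
    dominance relation survives.
    """
    specs = []  # (trial_type, {label: gamble}, {label: role})
    for decoy, ttype, target in TRIAL_SETS:
        competitor = "B" if target == "A" else "A"
        for _ in range(16):
            noise_t = _draw_noise(stimuli[target], rng, min_m=2.0 if ttype == ATTRACTION else 1.0)
            noise_c = _draw_noise(stimuli[competitor], rng)
            gambles = {
                target: apply_trial_noise(stimuli[target], noise_t),
                competitor: apply_trial_noise(stimuli[competitor], noise_c),
            }
            if ttype == ATTRACTION:
                gambles[decoy] = apply_trial_noise(stimuli[decoy], noise_t)
            else:
                gambles[decoy] = apply_trial_noise(stimuli[decoy], _draw_noise(stimuli[decoy], rng))
            roles = {target: TARGET, competitor: COMPETITOR, decoy: DECOY}
            specs.append((ttype, gambles, roles))
    for _ in range(11):
        gambles = {f"X{i}": g for i, g in enumerate(_distractor_gambles(rng))}
        specs.append((DISTRACTOR, gambles, {k: NONE for k in gambles}))

    rng.shuffle(specs)
    trials = []
    for i, (ttype, gambles, roles) in enumerate(specs):
        labels = list(gambles)
        order = rng.permutation(len(labels))
        placed = [labels[j] for j in order]
        trials.append(
            Trial(
                trial_id=start_id + i,
                trial_type=ttype,
                gambles=tuple(gambles[l] for l in placed),  # type: ignore[arg-type]
                roles=tuple(roles[l] for l in placed),  # type: ignore[arg-type]
            )
        )
    return trials


def build_session(
    agent: AgentParams, config: RunConfig, rng: np.random.Generator
) -> Tuple[List[Trial], List[StimulusSet]]:
    """Three estimation + experimental block pairs: the full 225-trial session."""
    trials: List[Trial] = []
    sets: List[StimulusSet] = []
    for _ in range(config.n_blocks):
        stimuli = simulate_indifference_block(agent, config, rng)
        sets.append(stimuli)
        trials.extend(build_trial_list(stimuli, rng, start_id=len(trials) + 1))
    return trials, sets
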