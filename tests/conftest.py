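import numpy as np
import pytest

from gazecontext.config import RunConfig
from gazecontext.design import AgentParams, build_session
from gazecontext.gaze import GazeProcessParams, clean_fixations, generate_fixation_sequence
from gazecontext.types import (
    ATTRACTION,
    Fixation,
    FixationSequence,
    Gamble,
    Trial,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture
def attraction_trial():
    """An {A, B, D_A} attraction trial in canonical position order."""
    return Trial(
        trial_id=1,
        trial_type=ATTRACTION,
        gambles=(Gamble(75, 10), Gamble(65, 15), Gamble(73, 9)),
        roles=("target", "competitor", "decoy"),
    )


def make_fixations(alts, attributes=None, durations=None):
    attributes = attributes or ["p"] * len(alts)
    durations = durations or [200.0] * len(alts)
    return FixationSequence(
        tuple(
            Fixation(alt=a, attribute=at, duration=d, onset_index=i)
            for i, (a, at, d) in enumerate(zip(alts, attributes, durations))
        )
    )


@pytest.fixture(scope="session")
def small_session():
    """One simulated participant block: 225 trials with cleaned fixations."""
    rng = np.random.default_rng(123)
    cfg = RunConfig()
    gp = GazeProcessParams()
    trials, _ = build_session(AgentParams(0.9, 0.7, 3.0), cfg, rng)
    out = []
    for t in trials:
        seq = clean_fixations(generate_fixation_sequence(t, gp, rng))
        choice = int(rng.integers(3))
        out.append(t.with_outcome(seq, choice, sum(f.duration for f in seq)))
    return out
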