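"""Domain types for three-alternative risky-choice experiments with eye tracking.

A trial presents three all-or-nothing gambles side by side; each gamble is a
probability ``p`` (in percent) to win an outcome ``m`` (in EUR), and nothing
otherwise.  In attraction and compromise trials the three options carry role
labels (target / competitor / decoy); distractor trials carry no roles.
Fixations are classified into six areas of interest (AOIs), one per
alternative x attribute cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Mapping, Optional, Sequence, Tuple

__all__ = [
    "ATTRACTION",
    "COMPROMISE",
    "DISTRACTOR",
    "TARGET",
    "COMPETITOR",
    "DECOY",
    "NONE",
    "TRIAL_TYPES",
    "ROLES",
    "Gamble",
    "Fixation",
    "FixationSequence",
    "Trial",
    "Dataset",
    "ValidationError",
]

ATTRACTION = "attraction"
COMPROMISE = "compromise"
DISTRACTOR = "distractor"
TRIAL_TYPES = (ATTRACTION, COMPROMISE, DISTRACTOR)

TARGET = "target"
COMPETITOR = "competitor"
DECOY = "decoy"
NONE = "none"
ROLES = (TARGET, COMPETITOR, DECOY, NONE)

#: Attribute labels for the two AOI columns of each alternative.
ATTR_P = "p"
ATTR_M = "m"


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


@dataclass(frozen=True)
class Gamble:
    """An all-or-nothing gamble: win ``m`` EUR with probability ``p`` percent.

    Parameters
    ----------
    p : float
        Winning probability in percent, 0 < p <= 100.
    m : float
        Outcome amount in EUR, m >= 1 (the task's minimum outcome).
    """

    p: float
    m: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 100.0):
            raise ValidationError(f"gamble probability must be in (0, 100], got {self.p}")
        if self.m < 1.0:
            raise ValidationError(f"gamble outcome must be >= 1 EUR, got {self.m}")

    @property
    def ev(self) -> float:
        """Expected value in EUR."""
        return self.p / 100.0 * self.m

    def dominates(self, other: "Gamble") -> bool:
        """Strict dominance on both attributes."""
        return self.p > other.p and self.m > other.m


@dataclass(frozen=True)
class Fixation:
    """A single fixation, classified by AOI.

    ``alt`` is the fixated alternative's screen position (0-2) or None for
    fixations outside every AOI; ``attribute`` is ``"p"`` or ``"m"`` (or None).
    Durations are in milliseconds; cleaned data contain only AOI fixations
    with durations >= 80 ms (the detection threshold).
    """

    alt: Optional[int]
    attribute: Optional[str]
    duration: float
    onset_index: int = 0

    def __post_init__(self) -> None:
        if self.alt is not None and self.alt not in (0, 1, 2):
            raise ValidationError(f"fixation alternative must be 0-2 or None, got {self.alt}")
        if self.attribute is not None and self.attribute not in (ATTR_P, ATTR_M):
            raise ValidationError(f"fixation attribute must be 'p'/'m'/None, got {self.attribute}")
        if (self.alt is None) != (self.attribute is None):
            raise ValidationError("AOI fixations need both alternative and attribute set")
        if self.duration < 0:
            raise ValidationError(f"fixation duration must be >= 0, got {self.duration}")

    @property
    def is_aoi(self) -> bool:
        return self.alt is not None


@dataclass(frozen=True)
class FixationSequence:
    """Ordered sequence of fixations within one trial."""

    fixations: Tuple[Fixation, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixations", tuple(self.fixations))

    def __len__(self) -> int:
        return len(self.fixations)

    def __iter__(self) -> Iterator[Fixation]:
        return iter(self.fixations)

    def __getitem__(self, i: int) -> Fixation:
        return self.fixations[i]

    @property
    def is_clean(self) -> bool:
        """True if every fixation sits inside an AOI."""
        return all(f.is_aoi for f in self.fixations)

    def dwell_per_alternative(self) -> Tuple[float, float, float]:
        """Total dwell time (ms) per alternative; non-AOI fixations ignored."""
        d = [0.0, 0.0, 0.0]
        for f in self.fixations:
            if f.alt is not None:
                d[f.alt] += f.duration
        return (d[0], d[1], d[2])

    def alternative_sequence(self) -> List[int]:
        """Sequence of fixated alternatives (non-AOI fixations dropped)."""
        return [f.alt for f in self.fixations if f.alt is not None]


@dataclass(frozen=True)
class Trial:
    """One experimental trial: three gambles, roles, gaze and choice.

    ``gambles`` are ordered by screen position 0-2 (left / centre / right);
    role labels travel with positions because the screen layout is randomised
    per trial.  ``choice`` is the chosen position (0-2) or None before a
    choice was simulated/observed; ``rt`` is the response time in ms.
    """

    trial_id: int
    trial_type: str
    gambles: Tuple[Gamble, Gamble, Gamble]
    roles: Tuple[str, str, str]
    fixations: FixationSequence = field(default_factory=FixationSequence)
    choice: Optional[int] = None
    rt: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "gambles", tuple(self.gambles))
        object.__setattr__(self, "roles", tuple(self.roles))
        if self.trial_id < 1:
            raise ValidationError(f"trial_id must be a positive integer, got {self.trial_id}")
        if self.trial_type not in TRIAL_TYPES:
            raise ValidationError(f"unknown trial type {self.trial_type!r}")
        if len(self.gambles) != 3:
            raise ValidationError(f"trial {self.trial_id}: needs exactly three gambles, got {len(self.gambles)}")
        if len(self.roles) != 3 or any(r not in ROLES for r in self.roles):
            raise ValidationError(f"trial {self.trial_id}: invalid role labels {self.roles}")
        if self.trial_type == DISTRACTOR:
            if any(r != NONE for r in self.roles):
                raise ValidationError(f"trial {self.trial_id}: distractor trials carry no roles")
        else:
            if sorted(self.roles) != sorted((TARGET, COMPETITOR, DECOY)):
                raise ValidationError(
                    f"trial {self.trial_id}: {self.trial_type} trials need exactly one "
                    f"target, competitor and decoy, got {self.roles}"
                )
        if self.choice is not None and self.choice not in (0, 1, 2):
            raise ValidationError(f"trial {self.trial_id}: choice must be 0-2, got {self.choice}")

    def position_of(self, role: str) -> int:
        """Screen position carrying ``role``; raises for distractor trials."""
        try:
            return self.roles.index(role)
        except ValueError:
            raise ValidationError(f"trial {self.trial_id} has no {role!r} role") from None

    def with_outcome(self, fixations: FixationSequence, choice: int, rt: float) -> "Trial":
        return Trial(
            trial_id=self.trial_id,
            trial_type=self.trial_type,
            gambles=self.gambles,
            roles=self.roles,
            fixations=fixations,
            choice=choice,
            rt=rt,
        )


class Dataset:
    """Mapping participant_id -> chronologically ordered trials."""

    def __init__(self, trials: Mapping[str, Sequence[Trial]]):
        self._data: Dict[str, List[Trial]] = {}
        for pid, ts in trials.items():
            ts = list(ts)
            ids = [t.trial_id for t in ts]
            if len(set(ids)) != len(ids):
                raise ValidationError(f"participant {pid}: duplicate trial_ids")
            if ids != sorted(ids):
                raise ValidationError(f"participant {pid}: trial_ids must be ascending")
            self._data[str(pid)] = ts

    @property
    def participants(self) -> List[str]:
        return list(self._data.keys())

    def trials(self, participant_id: str) -> List[Trial]:
        return self._data[str(participant_id)]

    def __len__(self) -> int:
        return len(self._data)

    def __contains__(self, pid: str) -> bool:
        return str(pid) in self._data

    def __iter__(self) -> Iterator[str]:
        return iter(self._data)

    def items(self):
        return self._data.items()

    def n_trials(self) -> int:
        return sum(len(ts) for ts in self._data.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return self._data == other._data
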