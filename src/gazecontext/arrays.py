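"""Dense array view of one participant's trials, shared by all likelihoods.

Model fitting evaluates choice probabilities thousands of times per
participant, so trials are converted once into padded numpy arrays and every
model's likelihood is computed on the full trial block at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .types import COMPETITOR, DECOY, NONE, TARGET, Trial

__all__ = ["ParticipantArrays", "ROLE_CODES"]

ROLE_CODES = {TARGET: 0, COMPETITOR: 1, DECOY: 2, NONE: 3}
ATT_CODES = {"p": 0, "m": 1}


@dataclass
class ParticipantArrays:
    """Padded arrays for one participant's trial block.

    ``alt_seq``/``att_seq`` hold the fixated alternative / attribute per
    fixation step, padded with -1 beyond each trial's sequence length.
    Probabilities are stored on the [0, 1] scale.
    """

    p01: np.ndarray          # (T, 3)
    m: np.ndarray            # (T, 3)
    choice: np.ndarray       # (T,) int, -1 when unknown
    trial_type: np.ndarray   # (T,) of str objects
    roles: np.ndarray        # (T, 3) int role codes
    trial_ids: np.ndarray    # (T,)
    alt_seq: np.ndarray      # (T, L) int8, pad -1
    att_seq: np.ndarray      # (T, L) int8, pad -1
    dur: np.ndarray          # (T, L) float ms, pad 0
    n_fix: np.ndarray        # (T,)
    _alt_seq_10ms: Optional[np.ndarray] = field(default=None, repr=False)
    _att_seq_10ms: Optional[np.ndarray] = field(default=None, repr=False)
    _unique_cache: Optional[Tuple[np.ndarray, np.ndarray]] = field(default=None, repr=False)

    @property
    def n_trials(self) -> int:
        return self.p01.shape[0]

    @classmethod
    def from_trials(cls, trials: List[Trial]) -> "ParticipantArrays":
        T = len(trials)
        p01 = np.empty((T, 3))
        m = np.empty((T, 3))
        choice = np.full(T, -1, dtype=np.int64)
        ttype = np.empty(T, dtype=object)
        roles = np.empty((T, 3), dtype=np.int64)
        ids = np.empty(T, dtype=np.int64)
        seqs = []
        for i, t in enumerate(trials):
            p01[i] = [g.p / 100.0 for g in t.gambles]
            m[i] = [g.m for g in t.gambles]
            if t.choice is not None:
                choice[i] = t.choice
            ttype[i] = t.trial_type
            roles[i] = [ROLE_CODES[r] for r in t.roles]
            ids[i] = t.trial_id
            seqs.append([(f.alt, ATT_CODES[f.attribute], f.duration) for f in t.fixations if f.is_aoi])
        L = max((len(s) for s in seqs), default=0)
        L = max(L, 1)
        alt_seq = np.full((T, L), -1, dtype=np.int8)
        att_seq = np.full((T, L), -1, dtype=np.int8)
        dur = np.zeros((T, L))
        n_fix = np.zeros(T, dtype=np.int64)
        for i, s in enumerate(seqs):
            n_fix[i] = len(s)
            for j, (a, at, d) in enumerate(s):
                alt_seq[i, j] = a
                att_seq[i, j] = at
                dur[i, j] = d
        return cls(p01, m, choice, ttype, roles, ids, alt_seq, att_seq, dur, n_fix)

    def dwell_seconds(self) -> np.ndarray:
        """Total dwell per alternative in seconds, shape (T, 3)."""
        out = np.zeros((self.n_trials, 3))
        for a in range(3):
            out[:, a] = np.where(self.alt_seq == a, self.dur, 0.0).sum(axis=1) / 1000.0
        return out

    def expanded_10ms(self) -> Tuple[np.ndarray, np.ndarray]:
        """Fixation sequences expanded to 10 ms steps.

        Each fixation contributes round(duration / 10) steps (at least one),
        so longer fixations feed the accumulators for more steps.
        """
        if self._alt_seq_10ms is None:
            steps = np.where(self.alt_seq >= 0, np.maximum(np.rint(self.dur / 10.0), 1), 0).astype(np.int64)
            Lx = max(int(steps.sum(axis=1).max()), 1)
            alt_x = np.full((self.n_trials, Lx), -1, dtype=np.int8)
            att_x = np.full((self.n_trials, Lx), -1, dtype=np.int8)
            for i in range(self.n_trials):
                k = 0
                for j in range(self.alt_seq.shape[1]):
                    if self.alt_seq[i, j] < 0:
                        break
                    n = int(steps[i, j])
                    alt_x[i, k:k + n] = self.alt_seq[i, j]
                    att_x[i, k:k + n] = self.att_seq[i, j]
                    k += n
            self._alt_seq_10ms = alt_x
            self._att_seq_10ms = att_x
        return self._alt_seq_10ms, self._att_seq_10ms

    def unique_stimuli(self) -> Tuple[np.ndarray, np.ndarray]:
        """Unique (3 x 2) attribute matrices and the trial -> unique index map.

        Gaze-independent models only depend on the stimuli, which repeat
        heavily within a session; deduplication makes their likelihoods cheap.
        """
        if self._unique_cache is None:
            flat = np.column_stack([self.p01, self.m])
            uniq, inverse = np.unique(flat, axis=0, return_inverse=True)
            mats = np.stack([uniq[:, :3], uniq[:, 3:]], axis=2)  # (U, 3, 2)
            self._unique_cache = (mats, inverse)
        return self._unique_cache
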