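"""Context-effect and gaze statistics.

The relative choice share of the target (RST) quantifies context effects:
RST = N_target / (N_target + N_competitor), with decoy choices excluded; in
a balanced design 0.5 means no effect.  Gaze statistics summarise relative
dwell per alternative, the dwell-time advantage (an alternative's relative
dwell minus the mean of the others'), psychometric choice-by-advantage
curves with model overlays, a median split of target choice by decoy dwell,
and transition counts between alternatives and roles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import (
    ATTRACTION,
    COMPETITOR,
    COMPROMISE,
    Dataset,
    DECOY,
    DISTRACTOR,
    FixationSequence,
    TARGET,
    Trial,
)

__all__ = [
    "RSTResult",
    "rst",
    "rst_table",
    "decoy_condition",
    "relative_dwell",
    "dwell_advantage",
    "dwell_table",
    "choice_by_advantage_curve",
    "decoy_dwell_median_split",
    "transition_counts",
    "bootstrap_ci",
    "DEFAULT_ADVANTAGE_BINS",
]

CONDITIONS = (ATTRACTION, COMPROMISE, "D_A", "D_B", "C_A", "C_B")

#: right-closed bins of width 0.2 covering the dwell-advantage range [-0.5, 1]
#: (the range is not a multiple of the width, so the last bin runs to 1.1)
DEFAULT_ADVANTAGE_BINS = np.round(np.arange(-0.5, 1.1 + 1e-9, 0.2), 10)


@dataclass(frozen=True)
class RSTResult:
    participant_id: str
    condition: str
    n_target: int
    n_competitor: int

    @property
    def value(self) -> Optional[float]:
        denom = self.n_target + self.n_competitor
        return self.n_target / denom if denom else None


def decoy_condition(trial: Trial) -> str:
    """Identify the decoy condition (D_A / D_B / C_A / C_B) of a role trial.

    The target's winning probability identifies the core option (A sits at
    75 +- 3 %, B at 65 +- 3 %), which together with the trial type names the
    decoy.
    """
    if trial.trial_type == DISTRACTOR:
        raise ValueError("distractor trials have no decoy condition")
    p_target = trial.gambles[trial.position_of(TARGET)].p
    target_is_a = abs(p_target - 75.0) <= 3.0
    if trial.trial_type == ATTRACTION:
        return "D_A" if target_is_a else "D_B"
    return "C_A" if target_is_a else "C_B"


def _in_condition(trial: Trial, condition: str) -> bool:
    if trial.trial_type == DISTRACTOR:
        return False
    if condition in (ATTRACTION, COMPROMISE):
        return trial.trial_type == condition
    return decoy_condition(trial) == condition


def rst(trials: Iterable[Trial], condition: str, participant_id: str = "") -> RSTResult:
    """Relative choice share of the target over the trials in ``condition``.

    Decoy choices enter neither numerator nor denominator.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    n_t = n_c = 0
    for t in trials:
        if t.choice is None or not _in_condition(t, condition):
            continue
        role = t.roles[t.choice]
        if role == TARGET:
            n_t += 1
        elif role == COMPETITOR:
            n_c += 1
    return RSTResult(participant_id, condition, n_t, n_c)


def rst_table(dataset: Dataset, conditions: Sequence[str] = (ATTRACTION, COMPROMISE)) -> pd.DataFrame:
    rows = []
    for pid, trials in dataset.items():
        for cond in conditions:
            r = rst(trials, cond, participant_id=pid)
            rows.append({"participant_id": pid, "condition": cond,
                         "n_target": r.n_target, "n_competitor": r.n_competitor,
                         "rst": r.value})
    return pd.DataFrame(rows)


def relative_dwell(trial: Trial) -> np.ndarray:
    """Per-alternative dwell fractions (post-cleaning); NaN triple if no dwell."""
    d = np.array(trial.fixations.dwell_per_alternative())
    total = d.sum()
    if total == 0:
        return np.full(3, np.nan)
    return d / total


def dwell_advantage(rel: np.ndarray, alt: int) -> float:
    """Relative dwell of ``alt`` minus the mean relative dwell of the others."""
    rel = np.asarray(rel, dtype=float)
    others = [j for j in range(3) if j != alt]
    return float(rel[alt] - rel[others].mean())


def dwell_table(dataset: Dataset) -> pd.DataFrame:
    """Per-trial relative dwell by role for attraction/compromise trials."""
    rows = []
    for pid, trials in dataset.items():
        for t in trials:
            if t.trial_type == DISTRACTOR:
                continue
            rel = relative_dwell(t)
            if np.isnan(rel).any():
                continue
            rows.append({
                "participant_id": pid,
                "trial_id": t.trial_id,
                "trial_type": t.trial_type,
                "target": rel[t.position_of(TARGET)],
                "competitor": rel[t.position_of(COMPETITOR)],
                "decoy": rel[t.position_of(DECOY)],
            })
    return pd.DataFrame(rows)


def choice_by_advantage_curve(
    dataset: Dataset,
    role: str,
    trial_type: str,
    bins: np.ndarray = DEFAULT_ADVANTAGE_BINS,
    model=None,
    fitted_params: Optional[Dict[str, Dict[str, float]]] = None,
    n_sim: int = 50,
    seed: int = 0,
    min_obs: int = 5,
) -> pd.DataFrame:
    """Choice fraction of ``role`` as a function of its dwell-time advantage.

    Observed fractions come from even-numbered trials; when a fitted model
    is supplied, predictions come from ``n_sim`` simulated choices of each
    odd-numbered trial, so observation and prediction never share a trial.
    Bins with fewer than ``min_obs`` observations are suppressed (NaN).
    """
    rng = np.random.default_rng(seed)
    obs_adv, obs_choice, pred_adv, pred_frac = [], [], [], []
    for pid, trials in dataset.items():
        for t in trials:
            if t.trial_type != trial_type or t.choice is None:
                continue
            rel = relative_dwell(t)
            if np.isnan(rel).any():
                continue
            pos = t.position_of(role)
            adv = dwell_advantage(rel, pos)
            if t.trial_id % 2 == 0:
                obs_adv.append(adv)
                obs_choice.append(1.0 if t.choice == pos else 0.0)
            elif model is not None:
                params = fitted_params[pid] if fitted_params else {}
                probs = model.choice_probs(t, t.fixations, params)
                sims = rng.choice(3, size=n_sim, p=np.asarray(probs) / np.sum(probs))
                pred_adv.append(adv)
                pred_frac.append(float(np.mean(sims == pos)))
    rows = []
    for lo, hi in zip(bins[:-1], bins[1:]):
        def _sel(adv):  # right-closed bins; the lowest bin keeps its left edge
            adv = np.asarray(adv)
            left = adv > lo if lo > bins[0] else adv >= lo
            return left & (adv <= hi)
        om = _sel(obs_adv)
        pm = _sel(pred_adv)
        n_obs = int(om.sum())
        frac = float(np.mean(np.asarray(obs_choice)[om])) if n_obs >= min_obs else np.nan
        se = (float(np.std(np.asarray(obs_choice)[om], ddof=1) / np.sqrt(n_obs))
              if n_obs >= min_obs and n_obs > 1 else np.nan)
        rows.append({
            "bin_left": lo, "bin_right": hi, "bin_mid": (lo + hi) / 2,
            "observed": frac, "observed_se": se, "n_observed": n_obs,
            "predicted": float(np.mean(np.asarray(pred_frac)[pm])) if pm.sum() >= min_obs else np.nan,
            "n_predicted": int(pm.sum()),
        })
    return pd.DataFrame(rows)


def decoy_dwell_median_split(dataset: Dataset) -> pd.DataFrame:
    """Per participant and trial type: target-choice share for long vs short
    decoy dwell, split at the individual's median decoy dwell.

    Positive delta = more target choices when the decoy was looked at longer.
    """
    rows = []
    for pid, trials in dataset.items():
        for ttype in (ATTRACTION, COMPROMISE):
            dwell, chose_target = [], []
            for t in trials:
                if t.trial_type != ttype or t.choice is None:
                    continue
                rel = relative_dwell(t)
                if np.isnan(rel).any():
                    continue
                dwell.append(rel[t.position_of(DECOY)])
                chose_target.append(t.roles[t.choice] == TARGET)
            if len(dwell) < 4:
                continue
            dwell = np.asarray(dwell)
            chose_target = np.asarray(chose_target, dtype=float)
            med = np.median(dwell)
            long_mask = dwell > med
            if long_mask.sum() == 0 or (~long_mask).sum() == 0:
                continue
            delta = float(chose_target[long_mask].mean() - chose_target[~long_mask].mean())
            rows.append({"participant_id": pid, "trial_type": ttype,
                         "p_target_long": float(chose_target[long_mask].mean()),
                         "p_target_short": float(chose_target[~long_mask].mean()),
                         "delta": delta})
    return pd.DataFrame(rows)


def transition_counts(fixations: FixationSequence, roles: Sequence[str]) -> Dict[str, int]:
    """Classify consecutive fixation pairs.

    Returns within- and between-alternative counts (their sum is
    n_fixations - 1) plus the between-role counts target<->decoy and
    competitor<->decoy.
    """
    counts = {"within": 0, "between": 0, "target_decoy": 0, "competitor_decoy": 0}
    prev = None
    for f in fixations:
        if not f.is_aoi:
            continue
        if prev is not None:
            if f.alt == prev.alt:
                counts["within"] += 1
            else:
                counts["between"] += 1
                pair = {roles[prev.alt], roles[f.alt]}
                if pair == {TARGET, DECOY}:
                    counts["target_decoy"] += 1
                elif pair == {COMPETITOR, DECOY}:
                    counts["competitor_decoy"] += 1
        prev = f
    return counts


def bootstrap_ci(
    values: Sequence[float],
    level: float = 0.95,
    n_boot: int = 5000,
    seed: int = 0,
) -> Tuple[float, float]:
    """Percentile bootstrap interval for the mean of a per-participant statistic."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty statistic vector")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    lo = float(np.quantile(means, (1 - level) / 2))
    hi = float(np.quantile(means, 1 - (1 - level) / 2))
    return lo, hi
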