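"""Readers and writers for the long-format trial and fixation tables.

Two plain-text tables describe an experiment:

``trials.csv``
    one row per (trial, screen position):
    participant_id, trial_id, trial_type, pos, p, m, role, chosen, rt_ms

``fixations.csv``
    one row per fixation:
    participant_id, trial_id, fix_index, alt_pos, attribute, duration_ms
    (alt_pos / attribute are empty for non-AOI fixations)

Reading and writing are exact inverses on valid datasets.
"""

from __future__ import annotations

import os
from typing import Dict, Mapping, Tuple

import pandas as pd

from .types import (
    Dataset,
    Fixation,
    FixationSequence,
    Gamble,
    NONE,
    Trial,
    ValidationError,
)

__all__ = [
    "FormatError",
    "read_trials",
    "write_trials",
    "read_fixations",
    "write_fixations",
    "load_dataset",
    "save_dataset",
]

TRIAL_COLUMNS = [
    "participant_id",
    "trial_id",
    "trial_type",
    "pos",
    "p",
    "m",
    "role",
    "chosen",
    "rt_ms",
]

FIXATION_COLUMNS = [
    "participant_id",
    "trial_id",
    "fix_index",
    "alt_pos",
    "attribute",
    "duration_ms",
]


class FormatError(ValueError):
    """Raised for malformed trial / fixation tables."""


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")


def write_trials(dataset: Dataset, path: str) -> None:
    rows = []
    for pid, trials in dataset.items():
        for t in trials:
            for pos, g in enumerate(t.gambles):
                rows.append(
                    {
                        "participant_id": pid,
                        "trial_id": t.trial_id,
                        "trial_type": t.trial_type,
                        "pos": pos,
                        "p": g.p,
                        "m": g.m,
                        "role": t.roles[pos],
                        "chosen": int(t.choice == pos) if t.choice is not None else "",
                        "rt_ms": t.rt if t.rt is not None else "",
                    }
                )
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def read_trials(path: str) -> Dataset:
    """Parse ``trials.csv`` into a validated :class:`Dataset` (no fixations)."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"participant_id": str}, float_precision="round_trip")
    _require_columns(df, TRIAL_COLUMNS, path)
    data: Dict[str, list] = {}
    for (pid, tid), grp in df.groupby(["participant_id", "trial_id"], sort=True):
        if len(grp) != 3:
            raise FormatError(
                f"{path}: participant {pid} trial {tid} has {len(grp)} gamble rows, expected 3"
            )
        grp = grp.sort_values("pos")
        if list(grp["pos"]) != [0, 1, 2]:
            raise FormatError(f"{path}: participant {pid} trial {tid} positions must be 0,1,2")
        try:
            gambles = tuple(Gamble(p=float(r.p), m=float(r.m)) for r in grp.itertuples())
            roles = tuple(str(r.role) for r in grp.itertuples())
            chosen = grp["chosen"]
            if chosen.isna().all():
                choice = None
            else:
                picked = grp.loc[chosen.astype(float) == 1.0, "pos"]
                if len(picked) != 1:
                    raise FormatError(
                        f"{path}: participant {pid} trial {tid} must mark exactly one chosen row"
                    )
                choice = int(picked.iloc[0])
            rt = grp["rt_ms"].iloc[0]
            trial = Trial(
                trial_id=int(tid),
                trial_type=str(grp["trial_type"].iloc[0]),
                gambles=gambles,  # type: ignore[arg-type]
                roles=roles,  # type: ignore[arg-type]
                choice=choice,
                rt=None if pd.isna(rt) else float(rt),
            )
        except ValidationError as err:
            raise FormatError(f"{path}: participant {pid} trial {tid}: {err}") from err
        data.setdefault(str(pid), []).append(trial)
    for pid in data:
        data[pid].sort(key=lambda t: t.trial_id)
    return Dataset(data)


def write_fixations(fixmap: Mapping[Tuple[str, int], FixationSequence], path: str) -> None:
    rows = []
    for (pid, tid), seq in fixmap.items():
        for i, f in enumerate(seq):
            rows.append(
                {
                    "participant_id": pid,
                    "trial_id": tid,
                    "fix_index": i,
                    "alt_pos": f.alt if f.alt is not None else "",
                    "attribute": f.attribute if f.attribute is not None else "",
                    "duration_ms": f.duration,
                }
            )
    pd.DataFrame(rows, columns=FIXATION_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def read_fixations(path: str) -> Dict[Tuple[str, int], FixationSequence]:
    """Parse ``fixations.csv`` into a map (participant_id, trial_id) -> sequence."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"participant_id": str}, float_precision="round_trip")
    _require_columns(df, FIXATION_COLUMNS, path)
    out: Dict[Tuple[str, int], FixationSequence] = {}
    for (pid, tid), grp in df.groupby(["participant_id", "trial_id"], sort=True):
        grp = grp.sort_values("fix_index")
        fixes = []
        for r in grp.itertuples():
            alt = None if pd.isna(r.alt_pos) else int(r.alt_pos)
            att = None if (isinstance(r.attribute, float) and pd.isna(r.attribute)) else str(r.attribute)
            if r.duration_ms < 0:
                raise FormatError(
                    f"{path}: participant {pid} trial {tid} fixation {r.fix_index}: "
                    f"negative duration {r.duration_ms}"
                )
            try:
                fixes.append(
                    Fixation(alt=alt, attribute=att, duration=float(r.duration_ms), onset_index=int(r.fix_index))
                )
            except ValidationError as err:
                raise FormatError(
                    f"{path}: participant {pid} trial {tid} fixation {r.fix_index}: {err}"
                ) from err
        out[(str(pid), int(tid))] = FixationSequence(tuple(fixes))
    return out


def save_dataset(dataset: Dataset, trials_path: str, fixations_path: str) -> None:
    write_trials(dataset, trials_path)
    fixmap = {
        (pid, t.trial_id): t.fixations for pid, trials in dataset.items() for t in trials
    }
    write_fixations(fixmap, fixations_path)


def load_dataset(trials_path: str, fixations_path: str) -> Dataset:
    """Join the trial and fixation tables into one Dataset."""
    ds = read_trials(trials_path)
    fixmap = read_fixations(fixations_path)
    joined = {}
    for pid, trials in ds.items():
        out = []
        for t in trials:
            seq = fixmap.get((pid, t.trial_id), FixationSequence())
            out.append(
                Trial(
                    trial_id=t.trial_id,
                    trial_type=t.trial_type,
                    gambles=t.gambles,
                    roles=t.roles,
                    fixations=seq,
                    choice=t.choice,
                    rt=t.rt,
                )
            )
        joined[pid] = out
    return Dataset(joined)
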