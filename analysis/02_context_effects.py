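#!/usr/bin/env python
"""Context effects in choices and dwell times of the synthetic study.

Computes the relative choice share of the target (RST) per participant for
attraction and compromise trials with bootstrap intervals, relative dwell
times by role, the decoy-dwell median split and transition counts.
"""

import sys, os
sys.path.insert(0, os.path.dirname(__file__))

import numpy as np
import pandas as pd

from gazecontext.metrics import (
    bootstrap_ci,
    choice_by_advantage_curve,
    decoy_dwell_median_split,
    dwell_table,
    rst_table,
    transition_counts,
)

from _common import load_or_simulate_study, results_path


def main():
    dataset, _ = load_or_simulate_study()

    rst = rst_table(dataset, conditions=("attraction", "compromise", "D_A", "D_B", "C_A", "C_B"))
    rst.to_csv(results_path("rst.csv"), index=False)
    for cond in ("attraction", "compromise"):
        vals = rst[rst.condition == cond]["rst"].dropna()
        lo, hi = bootstrap_ci(vals.values, seed=1)
        print(f"mean RST ({cond}): {vals.mean():.3f}  bootstrap 95% CI [{lo:.3f}, {hi:.3f}]")

    dw = dwell_table(dataset)
    dsum = dw.groupby(["participant_id", "trial_type"])[["target", "competitor", "decoy"]].mean()
    dsum.reset_index().to_csv(results_path("dwell.csv"), index=False)
    for ttype, grp in dsum.groupby("trial_type"):
        diff = grp["target"] - grp["competitor"]
        lo, hi = bootstrap_ci(diff.values, seed=2)
        print(f"relative dwell target - competitor ({ttype}): "
              f"{diff.mean():.4f}  CI [{lo:.4f}, {hi:.4f}]")

    split = decoy_dwell_median_split(dataset)
    split.to_csv(results_path("decoy_median_split.csv"), index=False)
    for ttype, grp in split.groupby("trial_type"):
        lo, hi = bootstrap_ci(grp["delta"].values, seed=3)
        print(f"target-choice delta for long vs short decoy dwell ({ttype}): "
              f"{grp.delta.mean():+.3f}  CI [{lo:+.3f}, {hi:+.3f}]")

    curves = []
    for ttype in ("attraction", "compromise"):
        for role in ("target", "competitor", "decoy"):
            c = choice_by_advantage_curve(dataset, role, ttype)
            c.insert(0, "trial_type", ttype)
            c.insert(1, "role", role)
            curves.append(c)
    pd.concat(curves).to_csv(results_path("curves.csv"), index=False)
    top = curves[0].dropna(subset=["observed"]).iloc[-1]
    print(f"observed P(choose target | attraction) in top advantage bin: {top['observed']:.2f}")

    rows = []
    for pid in dataset.participants:
        totals = {"within": 0, "between": 0, "target_decoy": 0, "competitor_decoy": 0}
        for t in dataset.trials(pid):
            if t.trial_type == "distractor":
                continue
            c = transition_counts(t.fixations, t.roles)
            for k in totals:
                totals[k] += c[k]
        totals["participant_id"] = pid
        rows.append(totals)
    trans = pd.DataFrame(rows)
    trans.to_csv(results_path("transitions.csv"), index=False)
    print(f"transitions within vs between alternatives: "
          f"{trans.within.sum()} vs {trans.between.sum()}; "
          f"target-decoy vs competitor-decoy: "
          f"{trans.target_decoy.sum()} vs {trans.competitor_decoy.sum()}")


if __name__ == "__main__":
    main()
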