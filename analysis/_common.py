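"""Shared helpers for the analysis scripts.

The synthetic study emulates the empirical setting: 40 participants, three
block pairs of staircase calibration plus 75 experimental trials, gaze with
a small target-directed bias, and choices from a gaze-dependent leaky
accumulator whose parameters are drawn around the empirically reported
estimate distributions (gaze discount theta ~ 0.69 +- 0.18, leak
lam ~ 0.29 +- 0.20).
"""

import os

import numpy as np

from gazecontext.config import RunConfig
from gazecontext.gaze import GazeProcessParams, generate_dataset
from gazecontext.inference import GLAModel
from gazecontext.io import load_dataset, save_dataset

SCRATCH = os.path.join(os.path.dirname(__file__), "..", "scratch", "synthetic")
RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")

N_PARTICIPANTS = 40
STUDY_SEED = 20220706


def study_truth_sampler(rng: np.random.Generator) -> dict:
    return {
        "alpha": float(rng.uniform(0.7, 1.1)),
        "gamma": float(rng.uniform(0.5, 1.0)),
        "beta": float(rng.uniform(0.4, 0.8)),
        "lam": float(np.clip(rng.normal(0.29, 0.20), 0.05, 0.65)),
        "theta": float(np.clip(rng.normal(0.69, 0.18), 0.13, 0.95)),
    }


def load_or_simulate_study():
    """Return (dataset, truth table); simulate and cache under scratch/ once."""
    import pandas as pd

    trials_path = os.path.join(SCRATCH, "trials.csv")
    fix_path = os.path.join(SCRATCH, "fixations.csv")
    truth_path = os.path.join(SCRATCH, "truth.csv")
    if all(os.path.exists(p) for p in (trials_path, fix_path, truth_path)):
        return load_dataset(trials_path, fix_path), pd.read_csv(truth_path)
    rng = np.random.default_rng(STUDY_SEED)
    config = RunConfig()
    from gazecontext import __version__
    from gazecontext.config import config_digest
    print(f"[run] gazecontext {__version__}  seed {STUDY_SEED}  config {config_digest(config)}")
    gp = GazeProcessParams.from_config(config)
    truths = [study_truth_sampler(rng) for _ in range(N_PARTICIPANTS)]
    dataset, truth = generate_dataset(GLAModel(), truths, config, gp,
                                      seed=int(rng.integers(2**31)))
    os.makedirs(SCRATCH, exist_ok=True)
    save_dataset(dataset, trials_path, fix_path)
    truth.to_csv(truth_path, index=False)
    return dataset, truth


def results_path(name: str) -> str:
    os.makedirs(RESULTS, exist_ok=True)
    return os.path.join(RESULTS, name)
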