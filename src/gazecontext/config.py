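"""Run configuration: seeds, parameter bounds, optimizer and design settings.

A configuration is a flat YAML/JSON key-value document.  Every key has a
documented default; unknown keys and out-of-range values are rejected so that
typos cannot silently change an analysis.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Any, Dict, Optional

import yaml

__all__ = ["RunConfig", "load_config", "config_digest", "ConfigError"]


class ConfigError(ValueError):
    """Raised for unknown configuration keys or out-of-range values."""


@dataclass
class RunConfig:
    """All tunable run settings with their defaults.

    Parameter-bound defaults follow the model definitions: the probability
    weighting shape gamma lives in [0.28, 1] (the weighting function is not
    monotone below ~0.28), utility curvature alpha in (0, 3], and the softmax
    inverse temperature beta in [0, 100].
    """

    seed: int = 0

    # parameter bounds used by the fitting routines
    gamma_lower: float = 0.28
    gamma_upper: float = 1.0
    alpha_lower: float = 0.01
    alpha_upper: float = 3.0
    beta_upper: float = 100.0

    # differential evolution settings
    de_popsize: int = 15
    de_maxiter: int = 150
    de_tol: float = 1e-7

    # experimental design
    n_blocks: int = 3
    staircase_start_step: float = 2.0
    staircase_min_step: float = 0.25
    staircase_max_trials: int = 30

    # gaze process
    p_within: float = 0.55
    p_return: float = 0.1
    target_bias: float = 0.15
    dwell_shape: float = 2.0
    dwell_scale: float = 90.0
    stop_prob: float = 0.08
    min_duration: float = 80.0

    def __post_init__(self) -> None:
        checks = [
            (0.0 < self.gamma_lower <= 1.0, "gamma_lower must be in (0, 1]"),
            (self.gamma_lower <= self.gamma_upper <= 1.0, "gamma_upper must be in [gamma_lower, 1]"),
            (0.0 < self.alpha_lower < self.alpha_upper, "alpha bounds must satisfy 0 < lower < upper"),
            (self.beta_upper > 0, "beta_upper must be positive"),
            (self.de_popsize >= 4, "de_popsize must be >= 4"),
            (self.de_maxiter >= 1, "de_maxiter must be >= 1"),
            (self.de_tol > 0, "de_tol must be positive"),
            (self.n_blocks >= 1, "n_blocks must be >= 1"),
            (self.staircase_start_step > 0, "staircase_start_step must be positive"),
            (0 < self.staircase_min_step <= self.staircase_start_step,
             "staircase_min_step must be in (0, staircase_start_step]"),
            (1 <= self.staircase_max_trials <= 30, "staircase_max_trials must be in [1, 30]"),
            (0.0 <= self.p_within <= 1.0, "p_within must be a probability"),
            (0.0 <= self.p_return <= 1.0, "p_return must be a probability"),
            (self.target_bias >= 0.0, "target_bias must be >= 0"),
            (self.dwell_shape > 0 and self.dwell_scale > 0, "dwell gamma parameters must be positive"),
            (0.0 < self.stop_prob <= 1.0, "stop_prob must be in (0, 1]"),
            (self.min_duration >= 0, "min_duration must be >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)

    def to_dict(self) -> Dict[str, Any]:
        return asdict(self)


def load_config(path: Optional[str] = None) -> RunConfig:
    """Load a configuration document; missing keys take their defaults.

    An empty or absent document yields all defaults.  Unknown keys raise
    :class:`ConfigError` naming the offending key.
    """
    if path is None:
        return RunConfig()
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        return RunConfig()
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: configuration must be a key/value mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = sorted(set(doc) - known)
    if unknown:
        raise ConfigError(f"{path}: unknown configuration keys {unknown}")
    try:
        return RunConfig(**doc)
    except ConfigError:
        raise
    except TypeError as err:
        raise ConfigError(f"{path}: {err}") from err


def config_digest(config: RunConfig) -> str:
    """Stable short digest of a configuration, for run logging."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
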