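"""Synthetic trial-sequence generator with known ground truth.

Emulates the sampling model of the meta-analysis itself: each trial
contributes a pair of independent binomial counts with true failure
probabilities ``true_p_control`` / ``true_p_treated``.  Optional between-trial
heterogeneity is injected on the logit scale — per-trial rates are
``expit(logit(p) + N(0, tau^2))`` — so ``tau = 0`` recovers the homogeneous
world the conjugate model assumes, while ``tau > 0`` produces the kind of
dispersion a random-effects comparator should detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit, logit

from .data_model import TrialRecord

__all__ = ["SyntheticConfig", "generate"]


@dataclass(frozen=True)
class SyntheticConfig:
    true_p_control: float
    true_p_treated: float
    trial_sizes: Sequence[tuple[int, int]] = field(default=((100, 100),))  # (n_control, n_treated)
    tau: float = 0.0
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("true_p_control", "true_p_treated"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise ValueError(f"{name}={p} must be in (0,1)")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        for nc, nt in self.trial_sizes:
            if nc < 1 or nt < 1:
                raise ValueError("trial sizes must be >= 1")


def generate(config: SyntheticConfig) -> list[TrialRecord]:
    """One TrialRecord per size pair; deterministic given the config seed."""
    rng = np.random.default_rng(config.seed)
    records: list[TrialRecord] = []
    for i, (n_c, n_t) in enumerate(config.trial_sizes, start=1):
        if config.tau > 0:
            p_c = float(expit(logit(config.true_p_control) + rng.normal(0.0, config.tau)))
            p_t = float(expit(logit(config.true_p_treated) + rng.normal(0.0, config.tau)))
        else:
            p_c, p_t = config.true_p_control, config.true_p_treated
        records.append(
            TrialRecord(
                trial_id=f"syn{i:03d}",
                label=f"synthetic trial {i}",
                order_key=i,
                n_control=n_c,
                events_control=int(rng.binomial(n_c, p_c)),
                n_treated=n_t,
                events_treated=int(rng.binomial(n_t, p_t)),
            )
        )
    return records
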