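"""Frequentist sensitivity comparator: DerSimonian-Laird random effects.

Pools per-trial risk differences (treated minus control) by inverse-variance
weighting with the DerSimonian-Laird moment estimate of the between-trial
variance tau^2, and reports Cochran's Q, its chi-squared p-value, and the I^2
heterogeneity percentage.  Zero-event handling follows common Cochrane
practice: an arm with no failures gets 0.5 added to its events and non-events
(so n grows by 1); trials with no failures in *either* arm are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .data_model import TrialRecord

__all__ = ["PooledResult", "dl_pool", "cumulative_dl"]


@dataclass(frozen=True)
class PooledResult:
    pooled_rd: float
    ci_low: float
    ci_high: float
    tau2: float
    Q: float
    Q_pvalue: float
    I2: float  # percent
    k: int  # eligible trials pooled


def _corrected_arms(trial: TrialRecord) -> tuple[float, float, float, float] | None:
    """(events_c, n_c, events_t, n_t) after the zero-cell policy; None = excluded."""
    ec, nc = float(trial.events_control), float(trial.n_control)
    et, nt = float(trial.events_treated), float(trial.n_treated)
    if ec == 0 and et == 0:
        return None
    if ec == 0:
        ec, nc = 0.5, nc + 1.0
    if et == 0:
        et, nt = 0.5, nt + 1.0
    return ec, nc, et, nt


def _effects(trials: Sequence[TrialRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial RD (treated - control) and its variance, after corrections."""
    ys, vs = [], []
    for trial in trials:
        arms = _corrected_arms(trial)
        if arms is None:
            continue
        ec, nc, et, nt = arms
        pc, pt = ec / nc, et / nt
        ys.append(pt - pc)
        vs.append(pc * (1.0 - pc) / nc + pt * (1.0 - pt) / nt)
    return np.asarray(ys), np.asarray(vs)


def dl_pool(trials: Sequence[TrialRecord]) -> PooledResult:
    """Pool trials with DerSimonian-Laird random-effects on the RD scale."""
    y, v = _effects(trials)
    k = len(y)
    if k < 2:
        raise ValueError(f"need >= 2 eligible trials after zero-event exclusions, got {k}")
    w = 1.0 / v
    fixed = np.sum(w * y) / np.sum(w)
    Q = float(np.sum(w * (y - fixed) ** 2))
    df = k - 1
    tau2 = max(0.0, (Q - df) / (np.sum(w) - np.sum(w**2) / np.sum(w)))
    w_star = 1.0 / (v + tau2)
    pooled = float(np.sum(w_star * y) / np.sum(w_star))
    se = float(np.sqrt(1.0 / np.sum(w_star)))
    z = stats.norm.isf(0.025)
    i2 = max(0.0, 100.0 * (Q - df) / Q) if Q > 0 else 0.0
    return PooledResult(
        pooled_rd=pooled,
        ci_low=float(pooled - z * se),
        ci_high=float(pooled + z * se),
        tau2=float(tau2),
        Q=Q,
        Q_pvalue=float(stats.chi2.sf(Q, df)),
        I2=i2,
        k=k,
    )


def cumulative_dl(trials: Sequence[TrialRecord]) -> list[PooledResult | None]:
    """DL pooling on every prefix; entries with < 2 eligible trials are None."""
    out: list[PooledResult | None] = []
    for k in range(1, len(trials) + 1):
        try:
            out.append(dl_pool(trials[:k]))
        except ValueError:
            out.append(None)
    return out
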