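"""Conjugate beta-binomial updating and cumulative evidence sequencing.

Each arm's failure probability p carries a Beta(alpha, beta) law; observing
``events`` failures out of ``n`` patients multiplies in a binomial likelihood
and returns Beta(alpha + events, beta + n - events).  A cumulative
meta-analysis is nothing more than chaining these updates in publication
order, each trial's posterior serving as the next trial's prior.  Because the
shape parameters are plain sums, absorbing trials one at a time is *exactly*
equivalent to absorbing the pooled totals in a single update.
"""

from __future__ import annotations

from typing import Sequence

from scipy import optimize, stats

from .data_model import UNIFORM, BetaParams, EvidenceState, TrialRecord, check_sorted

__all__ = ["update", "cumulate", "posterior_summary"]


def update(prior: BetaParams, events: int, n: int) -> BetaParams:
    """Posterior beta after observing ``events`` failures in ``n`` patients."""
    if not 0 <= events <= n:
        raise ValueError(f"events={events} outside [0, n={n}]")
    return BetaParams(prior.alpha + events, prior.beta + (n - events))


def cumulate(
    trials: Sequence[TrialRecord],
    prior_control: BetaParams = UNIFORM,
    prior_treated: BetaParams = UNIFORM,
) -> list[EvidenceState]:
    """Absorb trials in order; state k holds both posteriors after trials 1..k.

    Default priors are uniform Beta(1, 1) on each arm, representing near-total
    ignorance of the failure rates before the first trial.
    """
    check_sorted(trials)
    states: list[EvidenceState] = []
    control, treated = prior_control, prior_treated
    cn = ce = tn = te = 0
    for k, trial in enumerate(trials, start=1):
        control = update(control, trial.events_control, trial.n_control)
        treated = update(treated, trial.events_treated, trial.n_treated)
        cn += trial.n_control
        ce += trial.events_control
        tn += trial.n_treated
        te += trial.events_treated
        states.append(
            EvidenceState(
                k=k,
                control=control,
                treated=treated,
                cum_n_control=cn,
                cum_events_control=ce,
                cum_n_treated=tn,
                cum_events_treated=te,
                trial_id=trial.trial_id,
            )
        )
    return states


def _hpd_interval(p: BetaParams, level: float) -> tuple[float, float]:
    # shortest interval containing `level` mass: optimise the lower tail split
    dist = stats.beta(p.alpha, p.beta)

    def width(lo_tail: float) -> float:
        return dist.ppf(lo_tail + level) - dist.ppf(lo_tail)

    res = optimize.minimize_scalar(width, bounds=(0.0, 1.0 - level), method="bounded")
    lo_tail = float(res.x)
    return float(dist.ppf(lo_tail)), float(dist.ppf(lo_tail + level))


def posterior_summary(
    p: BetaParams, level: float = 0.95, hpd: bool = False
) -> tuple[float, tuple[float, float]]:
    """Posterior mean and credible interval of one arm's failure probability.

    The default interval is equal-tailed (the (1-level)/2 and 1-(1-level)/2
    beta quantiles); ``hpd=True`` returns the highest-posterior-density
    (shortest) interval instead.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0,1), got {level}")
    if hpd:
        interval = _hpd_interval(p, level)
    else:
        tail = (1.0 - level) / 2.0
        dist = stats.beta(p.alpha, p.beta)
        interval = (float(dist.ppf(tail)), float(dist.isf(tail)))
    return p.mean, interval
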