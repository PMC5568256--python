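"""Posterior-predictive probabilities for a future trial's *observed* rates.

Whereas :mod:`cumeta.probabilities` asks about the latent failure
probabilities, the predictive layer asks the question a trialist actually
faces: if a new sample of n_c control and n_t treated patients were enrolled
now, what is the probability the *observed* failure rates would differ by at
least delta in favour of the treatment?  Averaging the binomial sampling
distribution over the current beta posteriors makes each future count
beta-binomial, so the answer is an exact double sum over the joint pmf —
evaluated here by enumeration, with a seeded Monte Carlo route (rates first,
then counts) as cross-check and fallback for huge future samples.

"At least delta" is implemented as >= on the observed rate difference; ties
carry positive probability on the discrete scale, so the choice matters and
is deliberate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .data_model import BetaParams, EvidenceState

__all__ = ["FutureSampleSpec", "predictive_prob", "cumulative_predictive"]

_ENUM_LIMIT = 10**7


@dataclass(frozen=True)
class FutureSampleSpec:
    """Size and thresholds of the hypothetical future sample."""

    n_control_new: int
    n_treated_new: int
    thresholds: Sequence[float] = field(default=(0.05, 0.10))

    def __post_init__(self) -> None:
        if self.n_control_new < 1 or self.n_treated_new < 1:
            raise ValueError("future sample sizes must be >= 1")
        for d in self.thresholds:
            if not 0.0 <= d < 1.0:
                raise ValueError(f"threshold {d} outside [0, 1)")


def _enumerate_prob(
    control: BetaParams, treated: BetaParams, n_c: int, n_t: int, delta: float
) -> float:
    """Exact Pr(X_c/n_c - X_t/n_t >= delta) for beta-binomial X_c, X_t.

    The double sum is rearranged: for each treated count x_t the admissible
    control counts are an upper tail, so one survival-function evaluation per
    x_t suffices.
    """
    x_t = np.arange(n_t + 1)
    pmf_t = stats.betabinom.pmf(x_t, n_t, treated.alpha, treated.beta)
    # smallest x_c with x_c/n_c - x_t/n_t >= delta (1e-9 guards float ties)
    m = np.ceil(delta * n_c + x_t * (n_c / n_t) - 1e-9)
    sf_c = stats.betabinom.sf(m - 1, n_c, control.alpha, control.beta)
    return float(np.sum(pmf_t * sf_c))


def predictive_prob(
    control: BetaParams,
    treated: BetaParams,
    spec: FutureSampleSpec,
    method: str = "enumerate",
    draws: int = 10**6,
    seed: int = 42,
) -> dict[float, float]:
    """Map threshold -> Pr(observed control rate - treated rate >= threshold).

    ``enumerate`` is exact but limited to (n_c+1)(n_t+1) <= 1e7 pmf cells;
    ``monte_carlo`` draws rates from the posteriors then binomial counts.
    """
    n_c, n_t = spec.n_control_new, spec.n_treated_new
    if method == "enumerate":
        if (n_c + 1) * (n_t + 1) > _ENUM_LIMIT:
            raise ValueError(
                f"enumeration over {(n_c + 1) * (n_t + 1)} cells exceeds {_ENUM_LIMIT}; "
                "use method='monte_carlo'"
            )
        return {d: _enumerate_prob(control, treated, n_c, n_t, d) for d in spec.thresholds}
    if method == "monte_carlo":
        rng = np.random.default_rng(seed)
        p_c = rng.beta(control.alpha, control.beta, size=draws)
        p_t = rng.beta(treated.alpha, treated.beta, size=draws)
        rate_diff = rng.binomial(n_c, p_c) / n_c - rng.binomial(n_t, p_t) / n_t
        return {d: float(np.mean(rate_diff >= d - 1e-12)) for d in spec.thresholds}
    raise ValueError(f"unknown method {method!r}")


def cumulative_predictive(
    states: Sequence[EvidenceState],
    thresholds: Sequence[float] = (0.05, 0.10),
    draws: int = 10**6,
    seed: int = 42,
    method: str = "enumerate",
) -> list[dict[float, float]]:
    """Predictive probabilities per state, future sample = cumulative sizes.

    State k predicts a new sample as large as everything enrolled through
    trial k (cum_n_control / cum_n_treated) — the convention under which the
    cumulative table's predictive columns reproduce the worked example.
    """
    out: list[dict[float, float]] = []
    seed_seq = np.random.SeedSequence(seed)
    state_seeds = seed_seq.generate_state(max(len(states), 1))
    for state, s in zip(states, state_seeds):
        spec = FutureSampleSpec(
            n_control_new=state.cum_n_control,
            n_treated_new=state.cum_n_treated,
            thresholds=thresholds,
        )
        out.append(
            predictive_prob(state.control, state.treated, spec, method=method, draws=draws, seed=int(s))
        )
    return out
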