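"""Forward-looking design tools: evidence-shift grids and Bayesian sample size.

Two questions a trialist asks before committing to a 14th trial:

1. *Could a new trial shift the accumulated evidence?*  For a grid of design
   parameters (per-arm size n, assumed treated failure rate p_t*), simulate
   fictive trials — control rate drawn from the current control posterior,
   counts binomial — fold each into the cumulative posteriors, and record how
   often the updated Pr(p_c - p_t > 0.05) clears a decision threshold.

2. *How large must a trial be for the evidence to become precise?*  The
   average coverage criterion: the smallest per-arm n such that, averaging
   over data predicted from the current posteriors, a fixed-length credible
   interval centred at the updated posterior mean risk difference holds at
   least the target probability mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import EvidenceState
from .probabilities import exceedance_vector

__all__ = ["DesignGrid", "evidence_shift_grid", "acc_sample_size"]


@dataclass(frozen=True)
class DesignGrid:
    """Evidence-shift probabilities over (fictive-trial size x assumed rate).

    ``shift_prob[i, j]`` is the fraction of simulated fictive trials of
    ``n_values[i]`` patients per arm, with treated failure probability
    ``p_treated_values[j]``, whose updated posterior exceedance probability
    Pr(p_c - p_t > delta) passes ``decision_threshold``;
    ``mean_exceedance[i, j]`` is the mean of that updated probability, so
    either reading of "shifts the evidence" is available.
    """

    n_values: tuple[int, ...]
    p_treated_values: tuple[float, ...]
    shift_prob: np.ndarray
    mean_exceedance: np.ndarray
    decision_threshold: float
    delta: float
    sims_per_cell: int
    seed: int


def evidence_shift_grid(
    state: EvidenceState,
    n_values: Sequence[int],
    p_treated_values: Sequence[float],
    sims: int = 2000,
    seed: int = 42,
    decision_threshold: float = 0.8,
    delta: float = 0.05,
) -> DesignGrid:
    """Simulate fictive next trials over a design grid and score evidence shifts.

    Per cell: draw the control rate from the control posterior, simulate a
    fictive trial of ``n`` patients per arm (treated counts from the fixed
    assumed rate p_t*), update both cumulative posteriors with the fictive
    counts, and evaluate the updated Pr(p_c - p_t > delta) by quadrature.
    ``n = 0`` cells are allowed and leave the posterior untouched — useful as
    a no-update identity check.
    """
    if len(n_values) == 0 or len(p_treated_values) == 0:
        raise ValueError("design grid must have at least one n and one p_treated value")
    if sims < 1000:
        raise ValueError("sims must be >= 1000 for stable cell estimates")
    for p in p_treated_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p_treated value {p} outside [0, 1]")

    rng = np.random.default_rng(seed)
    shift = np.empty((len(n_values), len(p_treated_values)))
    mean_exc = np.empty_like(shift)
    c, t = state.control, state.treated
    for i, n in enumerate(n_values):
        for j, p_star in enumerate(p_treated_values):
            p_c = rng.beta(c.alpha, c.beta, size=sims)
            x_c = rng.binomial(n, p_c) if n > 0 else np.zeros(sims, dtype=int)
            x_t = rng.binomial(n, p_star, size=sims) if n > 0 else np.zeros(sims, dtype=int)
            probs = exceedance_vector(
                c.alpha + x_c, c.beta + (n - x_c),
                t.alpha + x_t, t.beta + (n - x_t),
                delta,
            )
            shift[i, j] = np.mean(probs > decision_threshold)
            mean_exc[i, j] = np.mean(probs)
    return DesignGrid(
        n_values=tuple(int(n) for n in n_values),
        p_treated_values=tuple(float(p) for p in p_treated_values),
        shift_prob=shift,
        mean_exceedance=mean_exc,
        decision_threshold=decision_threshold,
        delta=delta,
        sims_per_cell=sims,
        seed=seed,
    )


def average_coverage(
    state: EvidenceState,
    n: int,
    interval_length: float,
    sims: int = 400,
    seed: int = 42,
) -> float:
    """Mean posterior mass of the RD inside a fixed-length interval.

    Simulates new-trial data of ``n`` patients per arm from the current
    posterior predictive, updates the posteriors, and averages
    Pr(|RD - posterior mean RD| <= interval_length / 2) over simulations.
    """
    rng = np.random.default_rng(seed)
    c, t = state.control, state.treated
    p_c = rng.beta(c.alpha, c.beta, size=sims)
    p_t = rng.beta(t.alpha, t.beta, size=sims)
    x_c = rng.binomial(n, p_c) if n > 0 else np.zeros(sims, dtype=int)
    x_t = rng.binomial(n, p_t) if n > 0 else np.zeros(sims, dtype=int)
    half = interval_length / 2.0
    a_c, b_c = c.alpha + x_c, c.beta + (n - x_c)
    a_t, b_t = t.alpha + x_t, t.beta + (n - x_t)
    m = a_t / (a_t + b_t) - a_c / (a_c + b_c)  # updated posterior mean RD
    # mass of D = p_t - p_c inside [m - half, m + half]; Pr(D > x) via the
    # exceedance kernel with treated in the X1 role, vectorised over sims
    upper = exceedance_vector(a_t, b_t, a_c, b_c, m - half)
    lower = exceedance_vector(a_t, b_t, a_c, b_c, m + half)
    return float(np.mean(upper - lower))


def acc_sample_size(
    state: EvidenceState,
    interval_length: float = 0.05,
    target_coverage: float = 0.95,
    sims: int = 400,
    seed: int = 42,
    n_search_bounds: tuple[int, int] = (1, 1 << 17),
) -> int:
    """Smallest per-arm n meeting the average coverage criterion.

    Bisects over n between the search bounds, treating the Monte Carlo
    average-coverage curve as monotone in n (it is, up to simulation noise:
    more data always tightens the posterior).  Each candidate n is evaluated
    with a seed derived from (seed, n) so reruns are reproducible.
    """
    if not 0.0 < interval_length < 1.0:
        raise ValueError(f"interval_length must be in (0,1), got {interval_length}")
    if not 0.0 < target_coverage < 1.0:
        raise ValueError(f"target_coverage must be in (0,1), got {target_coverage}")
    lo, hi = n_search_bounds
    if lo < 0 or hi <= lo:
        raise ValueError(f"bad search bounds {n_search_bounds}")

    def cov(n: int) -> float:
        child = int(np.random.SeedSequence((seed, n)).generate_state(1)[0] % (1 << 31))
        return average_coverage(state, n, interval_length, sims=sims, seed=child)

    cov_lo = cov(lo)
    if cov_lo >= target_coverage:
        return lo
    cov_hi = cov(hi)
    if cov_hi < target_coverage:
        raise ValueError(
            f"criterion not met within bounds: coverage({lo})={cov_lo:.4f}, "
            f"coverage({hi})={cov_hi:.4f} < target {target_coverage}"
        )
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if cov(mid) >= target_coverage:
            hi = mid
        else:
            lo = mid
    return hi
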