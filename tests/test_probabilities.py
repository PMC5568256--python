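import numpy as np
import pytest

from cumeta import (
    BetaParams,
    cumulative_table,
    funnel_data,
    load_fixture,
    prob_delta_exceeds,
    rd_summary,
)

FINAL_C = BetaParams(133, 407)
FINAL_T = BetaParams(134, 422)


def test_final_exceedance_probabilities():
    assert prob_delta_exceeds(FINAL_C, FINAL_T, 0.05) == pytest.approx(0.042, abs=5e-4)
    assert prob_delta_exceeds(FINAL_C, FINAL_T, 0.10) == pytest.approx(0.00013, abs=5e-6)


def test_state3_exceedance():
    assert prob_delta_exceeds(BetaParams(27, 127), BetaParams(22, 123), 0.05) == pytest.approx(0.267, abs=1e-3)


def test_identical_arms_delta_zero_is_half():
    p = BetaParams(7, 13)
    assert prob_delta_exceeds(p, p, 0.0) == pytest.approx(0.5, abs=1e-10)


def test_delta_out_of_range():
    with pytest.raises(ValueError):
        prob_delta_exceeds(FINAL_C, FINAL_T, 1.0)


def test_monte_carlo_matches_quadrature():
    rng = np.random.default_rng(7)
    draws = 10**6
    for _ in range(20):
        a1, b1, a2, b2 = rng.uniform(0.5, 80, size=4)
        c, t = BetaParams(a1, b1), BetaParams(a2, b2)
        delta = float(rng.uniform(0, 0.2))
        q = prob_delta_exceeds(c, t, delta, method="quadrature")
        mc = prob_delta_exceeds(c, t, delta, method="monte_carlo", draws=draws, seed=int(rng.integers(2**31)))
        se = max(np.sqrt(q * (1 - q) / draws), 1e-5)
        assert abs(mc - q) <= 3 * se + 1e-4


def test_monte_carlo_requires_enough_draws():
    with pytest.raises(ValueError):
        prob_delta_exceeds(FINAL_C, FINAL_T, 0.05, method="monte_carlo", draws=10)


def test_partition_of_unity():
    c, t = BetaParams(9, 31), BetaParams(6, 44)
    delta = 0.07
    p_c_wins = prob_delta_exceeds(c, t, delta)
    p_t_wins = prob_delta_exceeds(t, c, delta)
    # middle band Pr(|p_c - p_t| <= delta) via Monte Carlo
    rng = np.random.default_rng(3)
    d = rng.beta(9, 31, 10**6) - rng.beta(6, 44, 10**6)
    middle = np.mean(np.abs(d) <= delta)
    assert p_c_wins + p_t_wins + middle == pytest.approx(1.0, abs=2e-3)


def test_threshold_monotonicity_on_fixture(knee_states):
    for s in knee_states:
        probs = [prob_delta_exceeds(s.control, s.treated, d) for d in (0.0, 0.05, 0.10)]
        assert probs[0] >= probs[1] >= probs[2]


def test_arm_swap_antisymmetry():
    c, t = BetaParams(14, 26), BetaParams(9, 41)
    s = rd_summary(c, t, thresholds=(0.05,), draws=2 * 10**5, seed=11)
    s_swapped = rd_summary(t, c, thresholds=(0.05,), draws=2 * 10**5, seed=11)
    assert s_swapped.mean_rd == pytest.approx(-s.mean_rd, abs=1e-12)
    assert s_swapped.prob_exceeds[0.05] == pytest.approx(
        prob_delta_exceeds(t, c, 0.05), abs=1e-12
    )


def test_rd_summary_final_state():
    s = rd_summary(FINAL_C, FINAL_T, draws=10**6, seed=42)
    assert s.mean_rd == pytest.approx(-0.005, abs=5e-4)
    assert s.cri_low == pytest.approx(-0.057, abs=2e-3)
    assert s.cri_high == pytest.approx(0.045, abs=2e-3)


def test_rd_summary_exchangeable_arms_symmetric():
    s = rd_summary(BetaParams(1, 1), BetaParams(1, 1), draws=5 * 10**5, seed=5)
    assert s.mean_rd == 0.0
    assert s.cri_low == pytest.approx(-s.cri_high, abs=5e-3)


def test_rd_summary_first_trial():
    s = rd_summary(BetaParams(4, 38), BetaParams(2, 40), draws=5 * 10**5, seed=2)
    assert s.mean_rd == pytest.approx(-0.048, abs=5e-4)
    assert s.cri_low == pytest.approx(-0.161, abs=3e-3)
    assert s.cri_high == pytest.approx(0.059, abs=3e-3)


def test_cumulative_table_rows(knee_states):
    rows = cumulative_table(knee_states, draws=2 * 10**5, seed=42)
    assert len(rows) == 13
    assert rows[4].mean_control == pytest.approx(0.1908, abs=5e-5)
    assert rows[4].mean_treated == pytest.approx(0.2218, abs=5e-5)
    # Pr(RD > 0.05) first drops below 5% at row 5 (after trial #4)
    below = [row.prob_exceeds[0.05] < 0.05 for row in rows]
    assert below.index(True) == 4
    # deterministic given seed
    again = cumulative_table(knee_states, draws=2 * 10**5, seed=42)
    assert [r.rd_cri_low for r in again] == [r.rd_cri_low for r in rows]


def test_funnel_data():
    trials = load_fixture("knee13")
    pairs = funnel_data(trials)
    assert len(pairs) == 13
    rd, n = pairs[0]
    assert rd == pytest.approx(-0.05, abs=1e-12)
    assert n == 80
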